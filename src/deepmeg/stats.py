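"""Repeated-measures ANCOVA with within-subject factors and one
continuous between-subject covariate.

The implementation uses the multivariate-contrast formulation: for every
within-subject effect, per-subject contrast scores are formed with
orthonormal contrasts (Kronecker products over the involved factors,
averaging over the others) and regressed on the mean-centred covariate.

* the effect's F tests the regression intercept,
* the effect × covariate F tests the slope,
* the covariate main effect is tested on per-subject grand means.

With n subjects and one covariate every 1-df within effect is reported with
(1, n−2) denominator degrees of freedom — (1, 13) for the emulated
15-subject cohort.  Effects spanning more than one degree of freedom get a
Greenhouse–Geisser epsilon estimated from the covariance of the
covariate-residualized contrast scores, and GG-adjusted p values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import IncompleteDesignError, InvalidConfigError

logger = logging.getLogger(__name__)


def orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1, k) orthonormal contrast matrix (normalized Helmert), rows
    orthogonal to the unit vector."""
    if k < 2:
        raise InvalidConfigError("contrasts need at least 2 levels")
    C = np.zeros((k - 1, k))
    for j in range(1, k):
        C[j - 1, :j] = 1.0
        C[j - 1, j] = -j
        C[j - 1] /= np.sqrt(j * (j + 1))
    return C


def gg_epsilon(covariance: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon of a k×k repeated-measures covariance.

    epsilon = tr(C S C')^2 / ((k−1) · tr((C S C')^2)) with orthonormal
    contrasts C; equals 1 under compound symmetry and is floored at
    1/(k−1) (attained for rank-one non-spherical covariances).
    """
    S = np.asarray(covariance, float)
    k = S.shape[0]
    if S.shape != (k, k):
        raise InvalidConfigError("covariance must be square")
    C = orthonormal_contrasts(k)
    M = C @ S @ C.T
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    eps = tr**2 / ((k - 1) * tr2)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _epsilon_from_scores(resid: np.ndarray) -> float:
    """GG epsilon from residualized orthonormal contrast scores (n, q)."""
    q = resid.shape[1]
    if q == 1:
        return 1.0
    S = resid.T @ resid
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    if tr2 <= 0:
        return 1.0
    return float(np.clip(tr**2 / (q * tr2), 1.0 / q, 1.0))


@dataclass
class EffectRecord:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    epsilon: float | None = None
    p_gg: float | None = None
    covariate_slope: float | None = None


@dataclass
class AncovaResult:
    effects: dict  # name -> EffectRecord
    n_subjects: int
    covariate_used: bool
    factor_levels: dict
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> EffectRecord:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.effects.values():
            rows.append(
                {
                    "effect": rec.effect,
                    "F": rec.F,
                    "df_num": rec.df_num,
                    "df_den": rec.df_den,
                    "p": rec.p,
                    "epsilon_gg": rec.epsilon,
                    "p_gg": rec.p_gg,
                    "covariate_slope": rec.covariate_slope,
                }
            )
        return pd.DataFrame(rows)

    def report(self) -> str:
        lines = [f"RM-ANCOVA ({self.n_subjects} subjects, covariate={'yes' if self.covariate_used else 'no'})"]
        for rec in self.effects.values():
            s = f"  {rec.effect}: F({rec.df_num:g}, {rec.df_den:g}) = {rec.F:.2f}, p = {rec.p:.4f}"
            if rec.epsilon is not None and rec.df_num > 1:
                s += f", eps_GG = {rec.epsilon:.2f}, p_GG = {rec.p_gg:.4f}"
            lines.append(s)
        return "\n".join(lines)


def _effect_contrast(factor_levels: dict, effect_factors: tuple) -> np.ndarray:
    """Kronecker contrast matrix for one effect over the factorial cells."""
    mat = np.ones((1, 1))
    for f_name, levels in factor_levels.items():
        k = len(levels)
        block = orthonormal_contrasts(k) if f_name in effect_factors else np.full((1, k), 1.0 / k)
        mat = np.kron(mat, block)
    return mat


def _f_test(ss_num: float, df_num: float, sse: float, df_den: float) -> tuple[float, float]:
    if sse <= 0 or df_den <= 0:
        return (0.0, 1.0) if ss_num <= 0 else (np.inf, 0.0)
    F = (ss_num / df_num) / (sse / df_den)
    return float(F), float(f_dist.sf(F, df_num, df_den))


def ancova_matrix(
    Y: np.ndarray,
    factor_levels: dict,
    covariate: np.ndarray | None = None,
) -> AncovaResult:
    """Engine: RM-ANCOVA on a wide (n_subjects, n_cells) matrix.

    Cells are the cartesian product of ``factor_levels`` values in order
    (last factor varying fastest).  ``covariate`` is one value per subject
    or None.
    """
    Y = np.asarray(Y, float)
    n, n_cells = Y.shape
    expected = int(np.prod([len(v) for v in factor_levels.values()]))
    if n_cells != expected:
        raise IncompleteDesignError(f"expected {expected} cells, got {n_cells}")

    use_cov = covariate is not None
    if use_cov:
        x = np.asarray(covariate, float)
        if np.var(x) == 0.0:
            logger.warning("zero-variance covariate dropped; reducing to RM-ANOVA")
            use_cov = False
    if use_cov:
        xc = x - x.mean()
        sxx = float(xc @ xc)
        df_unit = n - 2
    else:
        xc, sxx = None, 0.0
        df_unit = n - 1

    factor_names = list(factor_levels)
    effects: dict[str, EffectRecord] = {}
    for r in range(1, len(factor_names) + 1):
        for combo in itertools.combinations(factor_names, r):
            C = _effect_contrast(factor_levels, combo)
            q = C.shape[0]
            scores = Y @ C.T  # (n, q)
            a = scores.mean(axis=0)
            if use_cov:
                b = (xc @ scores) / sxx
                resid = scores - a[None, :] - np.outer(xc, b)
            else:
                b = None
                resid = scores - a[None, :]
            sse = float(np.sum(resid**2))
            df_den = q * df_unit
            name = ":".join(combo)

            F, p = _f_test(n * float(a @ a), q, sse, df_den)
            eps = _epsilon_from_scores(resid)
            p_gg = float(f_dist.sf(F, q * eps, df_den * eps)) if np.isfinite(F) else p
            effects[name] = EffectRecord(
                effect=name, F=F, df_num=q, df_den=df_den, p=p,
                epsilon=eps if q > 1 else None,
                p_gg=p_gg if q > 1 else None,
            )
            if use_cov:
                Fi, pi = _f_test(sxx * float(b @ b), q, sse, df_den)
                eps_i = _epsilon_from_scores(resid)
                effects[f"{name}:covariate"] = EffectRecord(
                    effect=f"{name}:covariate", F=Fi, df_num=q, df_den=df_den, p=pi,
                    epsilon=eps_i if q > 1 else None,
                    p_gg=float(f_dist.sf(Fi, q * eps_i, df_den * eps_i)) if q > 1 and np.isfinite(Fi) else None,
                    covariate_slope=float(b[0]) if q == 1 else None,
                )

    if use_cov:
        m = Y.mean(axis=1)
        a0 = m.mean()
        b0 = (xc @ m) / sxx
        resid = m - a0 - xc * b0
        sse = float(resid @ resid)
        F, p = _f_test(sxx * b0**2, 1, sse, n - 2)
        effects["covariate"] = EffectRecord(
            effect="covariate", F=F, df_num=1, df_den=n - 2, p=p, covariate_slope=float(b0)
        )

    return AncovaResult(
        effects=effects,
        n_subjects=n,
        covariate_used=use_cov,
        factor_levels={k: list(v) for k, v in factor_levels.items()},
    )


def _pivot(
    measurements: pd.DataFrame,
    dv: str,
    subject: str,
    within: list,
    factor_levels: dict | None = None,
) -> tuple[np.ndarray, list, dict]:
    """Wide (n_subjects, n_cells) matrix of cell means, canonical cell order."""
    if factor_levels is None:
        factor_levels = {f: sorted(measurements[f].unique()) for f in within}
    cells = list(itertools.product(*factor_levels.values()))
    grouped = measurements.groupby([subject, *within], sort=True)[dv].mean()
    subjects = sorted(measurements[subject].unique())
    Y = np.empty((len(subjects), len(cells)))
    for i, subj in enumerate(subjects):
        for j, cell in enumerate(cells):
            key = (subj, *cell)
            if key not in grouped.index:
                raise IncompleteDesignError(f"missing cell {key}")
            Y[i, j] = grouped.loc[key]
    return Y, subjects, factor_levels


def _covariate_vector(covariate, subjects) -> np.ndarray | None:
    if covariate is None:
        return None
    if isinstance(covariate, pd.Series):
        covariate = covariate.to_dict()
    return np.array([covariate[s] for s in subjects], float)


def rm_ancova(
    measurements: pd.DataFrame,
    within: list,
    covariate=None,
    dv: str = "value",
    subject: str = "subject",
    factor_levels: dict | None = None,
) -> AncovaResult:
    """Repeated-measures ANCOVA on a tidy measurement table.

    ``measurements`` must contain one (or more, averaged) value per subject
    × factorial cell.  ``covariate`` maps subject id to its score (dict or
    Series); None, or a constant covariate, reduces to an RM-ANOVA.
    """
    Y, subjects, factor_levels = _pivot(measurements, dv, subject, within, factor_levels)
    x = _covariate_vector(covariate, subjects)
    res = ancova_matrix(Y, factor_levels, x)
    res.metadata["subjects"] = subjects
    return res


def planned_comparison(
    measurements: pd.DataFrame,
    contrast_spec: dict,
    covariate=None,
    dv: str = "value",
    subject: str = "subject",
) -> EffectRecord:
    """Covariate-adjusted test of one planned cell contrast.

    ``contrast_spec`` maps cell selectors to weights, e.g.
    ``{(("hemisphere", "right"), ("emotion", "fearful"), ("gaze", "direct")): +1,
       (("hemisphere", "right"), ("emotion", "fearful"), ("gaze", "averted")): -1}``.
    Each selector picks the matching cells (averaged); the per-subject
    contrast score is the weighted sum, tested with df (1, n−2) given a
    covariate, (1, n−1) without.
    """
    subjects = sorted(measurements[subject].unique())
    scores = np.zeros(len(subjects))
    for selector, weight in contrast_spec.items():
        sel = measurements
        for col, level in selector:
            sel = sel[sel[col] == level]
        if sel.empty:
            raise IncompleteDesignError(f"selector {selector} matches no rows")
        cell_means = sel.groupby(subject)[dv].mean()
        scores += weight * np.array([cell_means[s] for s in subjects])

    n = len(subjects)
    x = _covariate_vector(covariate, subjects)
    use_cov = x is not None and np.var(x) > 0
    a = scores.mean()
    if use_cov:
        xc = x - x.mean()
        b = (xc @ scores) / (xc @ xc)
        resid = scores - a - xc * b
        df_den = n - 2
    else:
        resid = scores - a
        df_den = n - 1
    sse = float(resid @ resid)
    F, p = _f_test(n * a**2, 1, sse, df_den)
    return EffectRecord(effect="planned", F=F, df_num=1, df_den=df_den, p=p)
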