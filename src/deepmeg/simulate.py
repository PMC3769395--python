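"""Synthetic-data generator emulating the fearful/neutral × direct/averted
gaze face experiment.

The emulated study: 15 subjects view 6 blocks of 64 face trials (16 face
identities × 2 emotions × 2 gaze directions, each combination once per
block), with 8–12 occasional blue-dot target trials interleaved per block.
Recordings are 151-channel axial-gradiometer MEG at 1250 Hz; the stimulus
projector introduces a 20 ms delay between trigger and actual face onset.

Source dynamics are planted in three structures per hemisphere: the amygdala
(early peak near 140 ms plus a sustained response over 190–350 ms), and the
fusiform and lateral-occipital cortices.  Condition effects are fractional
(multiplicative) amplitude increases wired to specific waveform components:
an early emotion effect, a late emotion effect confined to 310–350 ms, a
sustained gaze effect, and a right-hemisphere fearful×direct interaction.
A per-subject anxiety score (STAI-like) acts as a pure gain on amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .errors import InvalidConfigError
from .forward import GainMatrix
from .anatomy import VolumeSourceSpace, SurfaceSourceSpace

logger = logging.getLogger(__name__)

EMOTIONS = ("fearful", "neutral")
GAZES = ("direct", "averted")
HEMISPHERES = ("left", "right")
STRUCTURES = ("amygdala", "fusiform", "lateral_occipital")

N_BLOCKS = 6
N_IDENTITIES = 16
FACE_DURATION_S = 0.5
FIXATION_RANGE_S = (0.7, 0.9)
ISI_RANGE_S = (1.0, 2.0)
TARGET_RANGE = (8, 12)  # inclusive

DEFAULT_SFREQ = 1250.0
PROJECTOR_DELAY_S = 0.020
TRIAL_TMIN, TRIAL_TMAX = -0.3, 0.7


# ---------------------------------------------------------------------------
# design


def generate_design(seed: int) -> pd.DataFrame:
    """One session's trial table.

    Face trials: 6 blocks × 64 = 384, each block containing every
    (identity × emotion × gaze) combination exactly once.  Per block,
    8–12 target (blue dot) trials are interleaved at random positions.
    Fixation 0.7–0.9 s, face 0.5 s, ISI 1–2 s.
    """
    rng = np.random.default_rng(seed)
    base = np.stack(
        np.meshgrid(np.arange(1, N_IDENTITIES + 1), [0, 1], [0, 1], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    cols: dict[str, list] = {k: [] for k in (
        "block", "trial_index", "identity", "emotion", "gaze", "is_target"
    )}
    for block in range(1, N_BLOCKS + 1):
        faces = base[rng.permutation(len(base))]
        n_targets = int(rng.integers(TARGET_RANGE[0], TARGET_RANGE[1] + 1))
        n_total = len(faces) + n_targets
        is_target = np.zeros(n_total, bool)
        is_target[rng.choice(n_total, size=n_targets, replace=False)] = True

        identity = np.zeros(n_total, int)
        emotion = np.full(n_total, "", object)
        gaze = np.full(n_total, "", object)
        identity[~is_target] = faces[:, 0]
        emotion[~is_target] = np.array(EMOTIONS, object)[faces[:, 1]]
        gaze[~is_target] = np.array(GAZES, object)[faces[:, 2]]

        cols["block"].append(np.full(n_total, block))
        cols["trial_index"].append(np.arange(n_total))
        cols["identity"].append(identity)
        cols["emotion"].append(emotion)
        cols["gaze"].append(gaze)
        cols["is_target"].append(is_target)

    arrays = {k: np.concatenate(v) for k, v in cols.items()}
    n = len(arrays["block"])
    fixation = rng.uniform(*FIXATION_RANGE_S, size=n)
    isi = rng.uniform(*ISI_RANGE_S, size=n)
    # onset_i = sum of all preceding (fixation + face + isi) + own fixation
    trial_len = fixation + FACE_DURATION_S + isi
    onsets = np.cumsum(trial_len) - trial_len + fixation
    return pd.DataFrame(
        {
            "block": arrays["block"],
            "trial_index": arrays["trial_index"],
            "onset_s": onsets,
            "identity": arrays["identity"],
            "emotion": arrays["emotion"],
            "gaze": arrays["gaze"],
            "is_target": arrays["is_target"],
            "fixation_duration_s": fixation,
            "isi_s": isi,
        }
    )


def face_trials(design: pd.DataFrame) -> pd.DataFrame:
    return design[~design["is_target"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# subjects


@dataclass(frozen=True)
class AnxietyConfig:
    """Observed-scale anxiety (STAI state) distribution parameters.

    ``mean`` is the target mean of the *truncated* draw; the latent normal
    location is calibrated by root-finding so the truncated distribution's
    mean equals it (plain truncation of N(mean, sd) would bias the mean
    upward by about one STAI point on this asymmetric range).
    """

    mean: float = 26.0
    sd: float = 5.2
    lower: float = 20.0
    upper: float = 38.0


@dataclass
class SubjectProfile:
    subject_id: str
    anxiety_score: float
    gain_multipliers: dict  # structure -> dimensionless gain


def _calibrated_loc(cfg: AnxietyConfig) -> float:
    """Latent normal location whose [lower, upper]-truncation has mean cfg.mean."""

    def truncated_mean(mu: float) -> float:
        a, b = (cfg.lower - mu) / cfg.sd, (cfg.upper - mu) / cfg.sd
        return truncnorm.mean(a, b, loc=mu, scale=cfg.sd) - cfg.mean

    lo, hi = cfg.mean - 4 * cfg.sd, cfg.mean + 1 * cfg.sd
    return brentq(truncated_mean, lo, hi, xtol=1e-10)


def generate_subject_profiles(
    n_subjects: int,
    seed: int,
    anxiety: AnxietyConfig = AnxietyConfig(),
    anxiety_slopes: dict | None = None,
) -> list[SubjectProfile]:
    """Subject anxiety scores and the per-structure gains they induce.

    Gains are ``1 + slope * (score - mean)``: anxiety acts as a pure,
    condition-independent amplitude gain.
    """
    if n_subjects < 1:
        raise InvalidConfigError("need at least one subject")
    if not (anxiety.lower < anxiety.mean < anxiety.upper):
        raise InvalidConfigError("anxiety truncation range must contain the mean")
    if anxiety_slopes is None:
        anxiety_slopes = {s: DEFAULT_SOURCE_PARAMS[s].anxiety_slope for s in STRUCTURES}
    mu = _calibrated_loc(anxiety)
    a, b = (anxiety.lower - mu) / anxiety.sd, (anxiety.upper - mu) / anxiety.sd
    rng = np.random.default_rng(seed)
    scores = truncnorm.rvs(a, b, loc=mu, scale=anxiety.sd, size=n_subjects, random_state=rng)
    return [
        SubjectProfile(
            subject_id=f"sub{k + 1:02d}",
            anxiety_score=float(scores[k]),
            gain_multipliers={
                s: 1.0 + anxiety_slopes[s] * (scores[k] - anxiety.mean)
                for s in STRUCTURES
            },
        )
        for k in range(n_subjects)
    ]


# ---------------------------------------------------------------------------
# source dynamics


@dataclass(frozen=True)
class SourceParams:
    """Condition-dependent source dynamics for one structure.

    Amplitudes are in ampere-metres (single-trial net moments are
    order-of-magnitude choices, ~10 nAm scale; the emulated study reports no
    single-trial source amplitudes).  Effects are fractional increases wired
    to waveform components: ``emotion_effect_early`` scales the early peak
    for fearful faces; ``emotion_effect_late`` scales the sustained component
    inside ``late_emotion_window`` only; ``gaze_effect_late`` scales the
    whole sustained component for direct gaze; the interaction term adds a
    further increase for right-hemisphere fearful×direct (or bilaterally if
    ``interaction_lateralized`` is off); ``hemisphere_effect`` is a static
    right-over-left gain.
    """

    base_amplitude: float = 10e-9
    early_peak_latency_s: float = 0.140
    early_peak_width_s: float = 0.022
    sustained_window_s: tuple = (0.19, 0.35)
    sustained_fraction: float = 0.6
    sustained_smooth_s: float = 0.02
    emotion_effect_early: float = 0.0
    emotion_effect_late: float = 0.0
    late_emotion_window_s: tuple = (0.31, 0.35)
    gaze_effect_late: float = 0.0
    interaction_right_fear_direct: float = 0.0
    interaction_lateralized: bool = True
    hemisphere_effect: float = 0.0
    anxiety_slope: float = 0.02
    trial_amplitude_jitter: float = 0.3
    trial_latency_jitter_s: float = 0.010

    def __post_init__(self):
        if self.early_peak_width_s <= 0 or self.sustained_smooth_s <= 0:
            raise InvalidConfigError("waveform widths must be positive")
        if self.sustained_window_s[1] <= self.sustained_window_s[0]:
            raise InvalidConfigError("sustained window must have positive length")


DEFAULT_SOURCE_PARAMS = {
    "amygdala": SourceParams(
        base_amplitude=10e-9,
        emotion_effect_early=0.30,
        emotion_effect_late=0.30,
        gaze_effect_late=0.18,
        interaction_right_fear_direct=0.25,
        anxiety_slope=0.02,
    ),
    "fusiform": SourceParams(
        base_amplitude=25e-9,
        emotion_effect_early=0.25,
        emotion_effect_late=0.30,
        gaze_effect_late=0.0,
        interaction_right_fear_direct=0.20,
        interaction_lateralized=False,
        hemisphere_effect=0.15,
        anxiety_slope=0.02,
    ),
    "lateral_occipital": SourceParams(
        base_amplitude=25e-9,
        emotion_effect_early=0.20,
        emotion_effect_late=0.30,
        gaze_effect_late=0.0,
        anxiety_slope=0.02,
    ),
}


def null_source_params() -> dict:
    """All condition effects and jitter switched off (null model)."""
    return {
        s: replace(
            p,
            emotion_effect_early=0.0,
            emotion_effect_late=0.0,
            gaze_effect_late=0.0,
            interaction_right_fear_direct=0.0,
            hemisphere_effect=0.0,
            anxiety_slope=0.0,
        )
        for s, p in DEFAULT_SOURCE_PARAMS.items()
    }


def trial_times(sfreq: float = DEFAULT_SFREQ) -> np.ndarray:
    n = int(round((TRIAL_TMAX - TRIAL_TMIN) * sfreq)) + 1
    return TRIAL_TMIN + np.arange(n) / sfreq


def waveform_components(
    params: SourceParams, times: np.ndarray, latency_shift: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """(early, sustained) unit waveform components on ``times``.

    Early: Gaussian peak (unit height).  Sustained: boxcar over the
    sustained window smoothed by a Gaussian kernel, scaled to
    ``sustained_fraction``.
    """
    lat = params.early_peak_latency_s + latency_shift
    early = np.exp(-0.5 * ((times - lat) / params.early_peak_width_s) ** 2)
    lo, hi = params.sustained_window_s
    # analytic Gaussian-smoothed boxcar: difference of error functions
    from scipy.special import erf

    s = params.sustained_smooth_s * np.sqrt(2.0)
    box = 0.5 * (erf((times - lo - latency_shift) / s) - erf((times - hi - latency_shift) / s))
    return early, params.sustained_fraction * box


@dataclass
class SourceTraces:
    """Per-trial planted source amplitudes: trials × structures × hemis × time."""

    amplitudes: np.ndarray  # (n_trials, n_structures, 2, n_times), A·m
    times: np.ndarray
    structures: tuple = STRUCTURES
    hemispheres: tuple = HEMISPHERES
    design: pd.DataFrame | None = None


def condition_multipliers(
    params: SourceParams, emotion: str, gaze: str, hemisphere: str
) -> tuple[float, float, float]:
    """(early, sustained, sustained-late-extra) multipliers for one cell."""
    fearful = emotion == "fearful"
    direct = gaze == "direct"
    right = hemisphere == "right"
    early = 1.0 + params.emotion_effect_early * fearful
    sustained = 1.0 + params.gaze_effect_late * direct
    if params.interaction_right_fear_direct and fearful and direct:
        if right or not params.interaction_lateralized:
            sustained *= 1.0 + params.interaction_right_fear_direct
    hemi_gain = 1.0 + params.hemisphere_effect * right
    late_extra = 1.0 + params.emotion_effect_late * fearful
    return early * hemi_gain, sustained * hemi_gain, late_extra


def simulate_source_timecourses(
    design: pd.DataFrame,
    profile: SubjectProfile,
    params: dict | None = None,
    seed: int = 0,
    sfreq: float = DEFAULT_SFREQ,
) -> SourceTraces:
    """Planted per-trial source amplitude traces for one subject.

    amplitude(t) = base × gain_subject × jitter ×
        [m_early · g_early(t) + m_sus(t) · g_sus(t)]

    with the late emotion multiplier applied to the sustained component
    inside the late emotion window only.  Negative post-jitter amplitudes
    are clipped at zero (logged).
    """
    if params is None:
        params = DEFAULT_SOURCE_PARAMS
    faces = face_trials(design)
    times = trial_times(sfreq)
    rng = np.random.default_rng(seed)
    n_trials = len(faces)
    out = np.zeros((n_trials, len(STRUCTURES), 2, len(times)))
    n_clipped = 0
    for si, structure in enumerate(STRUCTURES):
        p = params[structure]
        gain = profile.gain_multipliers.get(structure, 1.0)
        amp_jit = 1.0 + rng.normal(0.0, p.trial_amplitude_jitter, size=n_trials)
        lat_jit = rng.normal(0.0, p.trial_latency_jitter_s, size=n_trials)
        n_clipped += int(np.sum(amp_jit < 0))
        amp_jit = np.clip(amp_jit, 0.0, None)
        late_mask = (times >= p.late_emotion_window_s[0]) & (
            times < p.late_emotion_window_s[1]
        )
        for ti in range(n_trials):
            emotion = faces.at[ti, "emotion"]
            gaze = faces.at[ti, "gaze"]
            early_wave, sus_wave = waveform_components(p, times, lat_jit[ti])
            for hi, hemi in enumerate(HEMISPHERES):
                m_early, m_sus, m_late = condition_multipliers(p, emotion, gaze, hemi)
                sus = m_sus * sus_wave
                sus[late_mask] *= m_late
                out[ti, si, hi] = (
                    p.base_amplitude * gain * amp_jit[ti] * (m_early * early_wave + sus)
                )
    if n_clipped:
        logger.warning("clipped %d negative trial amplitudes to zero", n_clipped)
    return SourceTraces(out, times, design=faces)


# ---------------------------------------------------------------------------
# sensor projection


@dataclass
class SourceActivation:
    """How planted structure amplitudes load onto gain columns.

    ``entries[(structure, hemisphere)]`` is ``(columns, weights)``: a unit
    structure amplitude drives gain column ``columns[j]`` with moment
    ``weights[j]`` (A·m per A·m of structure amplitude; weights sum to the
    identity moment budget, i.e. |weights| sums to 1 per entry).
    """

    entries: dict
    topographies: dict = field(default_factory=dict)  # (structure, hemi) -> (n_chan,)

    @classmethod
    def build(cls, gain: GainMatrix, source_spaces: list, active_fraction: dict | None = None):
        """Distribute each structure's amplitude over its sources.

        Surface structures: the amplitude is split evenly over the vertices
        (along their normals).  Volume structures: split evenly over nodes,
        each node driven along a fixed tangential direction (deterministic),
        expressed in its trihedral frame.
        """
        entries = {}
        topo = {}
        offset = 0
        for space in source_spaces:
            n_cols = space.n_sources * space.n_orientations
            for hemi in HEMISPHERES:
                sel = np.flatnonzero(space.hemisphere == hemi)
                if sel.size == 0:
                    continue
                if isinstance(space, SurfaceSourceSpace):
                    cols = offset + sel
                    weights = np.full(sel.size, 1.0 / sel.size)
                elif isinstance(space, VolumeSourceSpace):
                    cols = offset + (3 * sel[:, None] + np.arange(3)).ravel()
                    weights = np.empty(3 * sel.size)
                    for j, i in enumerate(sel):
                        t = tangential_unit(space.nodes[i])
                        weights[3 * j : 3 * j + 3] = space.frames[i] @ t / sel.size
                else:  # pragma: no cover
                    raise TypeError(type(space))
                key = (space.structure_label, hemi)
                entries[key] = (np.asarray(cols, int), weights)
                topo[key] = gain.values[:, cols] @ weights
            offset += n_cols
        return cls(entries, topo)


def tangential_unit(node: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """A deterministic unit vector tangential to the sphere through ``node``."""
    r = np.asarray(node, float) - (0.0 if center is None else np.asarray(center, float))
    rhat = r / np.linalg.norm(r)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(rhat @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t = np.cross(rhat, ref)
    return t / np.linalg.norm(t)


@dataclass
class TrialData:
    """Per-trial channel × time segments around the stimulus trigger."""

    data: np.ndarray  # (n_trials, n_channels, n_times), tesla
    times: np.ndarray  # seconds relative to the trigger
    sfreq: float
    trigger_sample: int  # index of t=0 in ``times``
    photodiode_sample: int  # trigger + projector delay, in samples
    design: pd.DataFrame  # face-trial rows aligned with axis 0
    artifact_flags: np.ndarray | None = None  # ground-truth contamination
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sfreq <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(len(self.data), bool)

    @property
    def n_trials(self) -> int:
        return len(self.data)


def project_to_sensors(
    traces: SourceTraces,
    gain: GainMatrix,
    activation: SourceActivation,
    noise_sd: float,
    seed: int = 0,
    sfreq: float = DEFAULT_SFREQ,
    delay_s: float = PROJECTOR_DELAY_S,
    dtype=np.float64,
) -> TrialData:
    """Forward-project planted traces and add white sensor noise.

    sensor(t) = Σ_structures topography × amplitude(t) + N(0, noise_sd) per
    channel per sample.  The photodiode onset is the trigger plus the
    projector delay (rounded to the nearest sample).
    """
    rng = np.random.default_rng(seed)
    n_chan = gain.n_channels
    n_trials, _, _, n_times = traces.amplitudes.shape
    if len(traces.times) != n_times:
        raise InvalidConfigError("trace time axis mismatch")
    topo = np.zeros((len(STRUCTURES), 2, n_chan))
    for si, s in enumerate(STRUCTURES):
        for hi, h in enumerate(HEMISPHERES):
            if (s, h) in activation.topographies:
                topo[si, hi] = activation.topographies[(s, h)]
    clean = np.einsum("tshn,shc->tcn", traces.amplitudes, topo)
    data = clean.astype(dtype)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape).astype(dtype)
    trigger = int(round(-TRIAL_TMIN * sfreq))
    photodiode = trigger + int(round(delay_s * sfreq))
    return TrialData(
        data=data,
        times=traces.times,
        sfreq=sfreq,
        trigger_sample=trigger,
        photodiode_sample=photodiode,
        design=traces.design,
        metadata={"noise_sd": noise_sd, "delay_s": delay_s},
    )


def inject_artifacts(
    trials: TrialData,
    sensors,
    blink_rate: float = 0.1,
    blink_amplitude: float = 2e-12,
    seed: int = 0,
) -> TrialData:
    """Contaminate a random subset of trials with blink-like transients.

    Blinks are low-frequency (Gaussian pulse, ~150 ms width) transients with
    a frontal topography (anterior channels weighted by y-position).  Flags
    record the ground truth for rejection benchmarking.
    """
    rng = np.random.default_rng(seed)
    flags = rng.random(trials.n_trials) < blink_rate
    y = sensors.inner_coil_position[:, 1]
    topo = np.clip(y - 0.02, 0.0, None)
    if topo.max() > 0:
        topo = topo / topo.max()
    data = trials.data.copy()
    pulse_width = 0.075
    for ti in np.flatnonzero(flags):
        t0 = rng.uniform(trials.times[0] + 0.1, trials.times[-1] - 0.1)
        pulse = np.exp(-0.5 * ((trials.times - t0) / pulse_width) ** 2)
        data[ti] += blink_amplitude * topo[:, None] * pulse[None, :]
    return TrialData(
        data=data,
        times=trials.times,
        sfreq=trials.sfreq,
        trigger_sample=trials.trigger_sample,
        photodiode_sample=trials.photodiode_sample,
        design=trials.design,
        artifact_flags=flags,
        metadata=dict(trials.metadata, blink_rate=blink_rate),
    )


# ---------------------------------------------------------------------------
# HDF5 / TSV IO


def save_trials(trials: TrialData, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.data)
        f.create_dataset("times", data=trials.times)
        f.create_dataset("artifact_flags", data=trials.artifact_flags)
        f.attrs["sfreq"] = trials.sfreq
        f.attrs["trigger_sample"] = trials.trigger_sample
        f.attrs["photodiode_sample"] = trials.photodiode_sample
        f.create_dataset(
            "design_tsv",
            data=np.bytes_(trials.design.to_csv(sep="\t", index=False)),
        )


def load_trials(path) -> TrialData:
    import io

    import h5py

    with h5py.File(path, "r") as f:
        design = pd.read_csv(
            io.BytesIO(f["design_tsv"][()]), sep="\t"
        )
        return TrialData(
            data=f["data"][()],
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            trigger_sample=int(f.attrs["trigger_sample"]),
            photodiode_sample=int(f.attrs["photodiode_sample"]),
            design=design,
            artifact_flags=f["artifact_flags"][()].astype(bool),
        )
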