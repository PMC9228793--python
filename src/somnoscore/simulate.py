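"""Seed-reproducible synthetic polysomnography.

Generates stage sequences (sticky Markov chains with a prescribed stationary
law), nine-channel signal records whose per-epoch spectral content follows
the AASM stage signatures, and noisy "second scorers" for exercising the
agreement statistics — so the whole pipeline is testable without clinical
recordings.

Stage signatures emulated (amplitudes in µV at the scalp):

* W — posterior-dominant alpha (~10 Hz) over occipital leads, high chin tone,
  eye blinks. An *alpha-deficient* variant (a trait of a sizeable minority of
  the population) suppresses the alpha rhythm, leaving low-amplitude theta.
* N1 — low-amplitude mixed-frequency (LAMF) theta, slow rolling eye movements.
* N2 — LAMF background plus sleep spindles (~13 Hz bursts, 0.5–1.5 s) and
  K-complexes (biphasic slow waves), spindles central-dominant.
* N3 — high-amplitude delta (0.5–2 Hz), frontal-dominant.
* R — LAMF theta, chin atonia, bursts of rapid conjugate eye movements.

What this generator does *not* emulate: arousals, artifacts, respiratory
events, age effects, or realistic EEG microstructure beyond band content and
the two N2 transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core import STAGE_ORDER, ChannelSignal, Hypnogram, PolysomnogramRecord, StageLabel
from .psg_io import MONTAGE_LABELS

__all__ = [
    "BandComponent",
    "StageRecipe",
    "StageSignalModel",
    "CohortConfig",
    "ScorerNoiseModel",
    "default_signal_model",
    "alpha_deficient_signal_model",
    "stationary_transition_matrix",
    "generate_hypnogram",
    "synthesize_record",
    "generate_cohort",
    "corrupt_hypnogram",
]

#: Cohort-mean stage proportions (fraction of scored epochs) used as defaults.
DEFAULT_STAGE_PROPORTIONS = {
    StageLabel.W: 0.165,
    StageLabel.N1: 0.152,
    StageLabel.N2: 0.502,
    StageLabel.N3: 0.027,
    StageLabel.R: 0.154,
}


@dataclass(frozen=True)
class BandComponent:
    """Band-limited noise component: Butterworth-filtered white noise."""

    lo_hz: float
    hi_hz: float
    rms_uV: float
    #: multiplicative gain per cortical site (frontal, central, occipital)
    site_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class StageRecipe:
    components: tuple[BandComponent, ...]
    spindle_rate: float = 0.0  # expected events per 30-s epoch
    kcomplex_rate: float = 0.0
    eog_event_rate: float = 0.0  # blinks / SEMs / REMs per epoch
    eog_event_dur_s: tuple[float, float] = (0.3, 1.0)
    eog_event_amp_uV: float = 80.0
    emg_rms_uV: float = 10.0


@dataclass(frozen=True)
class StageSignalModel:
    recipes: dict[StageLabel, StageRecipe]

    def __post_init__(self) -> None:
        missing = [s for s in STAGE_ORDER if s not in self.recipes]
        if missing:
            raise ValueError(f"signal model missing recipes for {missing}")


_BROADBAND = BandComponent(0.5, 30.0, 5.0)
_LAMF = (
    _BROADBAND,
    BandComponent(2.0, 7.0, 12.0),
)


def default_signal_model() -> StageSignalModel:
    """Stage recipes with the canonical spectral signatures."""
    return StageSignalModel(
        {
            StageLabel.W: StageRecipe(
                components=(
                    _BROADBAND,
                    BandComponent(8.0, 12.0, 25.0, site_gains=(0.3, 0.6, 1.0)),
                    BandComponent(15.0, 30.0, 6.0),
                ),
                eog_event_rate=4.0,
                eog_event_dur_s=(0.2, 0.5),
                eog_event_amp_uV=100.0,
                emg_rms_uV=25.0,
            ),
            StageLabel.N1: StageRecipe(
                components=_LAMF,
                eog_event_rate=2.0,
                eog_event_dur_s=(1.0, 2.0),  # slow rolling movements
                eog_event_amp_uV=60.0,
                emg_rms_uV=10.0,
            ),
            StageLabel.N2: StageRecipe(
                components=_LAMF,
                spindle_rate=2.0,
                kcomplex_rate=1.0,
                eog_event_rate=0.0,
                emg_rms_uV=8.0,
            ),
            StageLabel.N3: StageRecipe(
                components=(
                    _BROADBAND,
                    BandComponent(0.5, 2.0, 60.0, site_gains=(1.0, 0.9, 0.7)),
                ),
                emg_rms_uV=6.0,
            ),
            StageLabel.R: StageRecipe(
                components=_LAMF,
                eog_event_rate=5.0,
                eog_event_dur_s=(0.1, 0.3),  # rapid eye movements
                eog_event_amp_uV=120.0,
                emg_rms_uV=2.0,  # atonia
            ),
        }
    )


def alpha_deficient_signal_model() -> StageSignalModel:
    """Wake recipe for subjects generating little or no alpha rhythm."""
    base = default_signal_model()
    w = base.recipes[StageLabel.W]
    recipes = dict(base.recipes)
    recipes[StageLabel.W] = replace(
        w,
        components=(
            _BROADBAND,
            BandComponent(8.0, 12.0, 2.0, site_gains=(0.3, 0.6, 1.0)),
            BandComponent(4.0, 7.0, 10.0),
            BandComponent(15.0, 30.0, 6.0),
        ),
    )
    return StageSignalModel(recipes)


@dataclass(frozen=True)
class CohortConfig:
    """Desk-scale synthetic cohort: sizes, stage mix, rates, and the master seed."""

    n_subjects: int = 30
    epochs_per_subject: int = 120
    stage_proportions: dict[StageLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PROPORTIONS)
    )
    alpha_deficient_fraction: float = 0.1
    #: Dirichlet concentration for between-subject jitter of the stage mix
    proportion_concentration: float = 13.0
    stickiness: float = 0.9
    fs: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.array([self.stage_proportions[s] for s in STAGE_ORDER], float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("stage proportions must be non-negative and sum to 1")
        if not (0.0 <= self.alpha_deficient_fraction <= 1.0):
            raise ValueError("alpha_deficient_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ScorerNoiseModel:
    """Row-stochastic confusion model: P(observed stage | true stage)."""

    matrix: np.ndarray  # (5, 5) rows in STAGE_ORDER

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (5, 5) or (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("noise model rows must be non-negative and sum to 1")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "ScorerNoiseModel":
        return cls(np.eye(5))

    @classmethod
    def from_row_percentages(cls, rows: np.ndarray) -> "ScorerNoiseModel":
        m = np.asarray(rows, dtype=np.float64)
        return cls(m / m.sum(axis=1, keepdims=True))


def _rng(seed, *subkeys) -> np.random.Generator:
    """Deterministic sub-stream derivation: one master seed, fixed purpose keys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *subkeys]))


def stationary_transition_matrix(proportions: np.ndarray, stickiness: float) -> np.ndarray:
    """Sticky Markov kernel ``P = s·I + (1−s)·1πᵀ`` with stationary law π.

    π P = s·π + (1−s)·π = π for any stickiness s ∈ [0, 1), so the chain's
    stationary distribution equals the target proportions exactly; mean run
    length in stage i is 1 / ((1−s)(1−π_i)).
    """
    pi = np.asarray(proportions, dtype=np.float64)
    if not (0.0 <= stickiness < 1.0):
        raise ValueError("stickiness must lie in [0, 1)")
    return stickiness * np.eye(len(pi)) + (1.0 - stickiness) * pi[None, :]


def generate_hypnogram(
    stage_proportions: dict[StageLabel, float],
    epochs: int,
    seed,
    stickiness: float = 0.9,
) -> Hypnogram:
    """Sample a stage sequence from the sticky Markov chain.

    Starts in W (the natural start of a recording) when W has positive mass,
    otherwise from the stationary law.
    """
    if epochs < 1:
        raise ValueError("need at least one epoch")
    pi = np.array([stage_proportions.get(s, 0.0) for s in STAGE_ORDER], float)
    if (pi < 0).any() or pi.sum() <= 0:
        raise ValueError("invalid stage proportions")
    pi = pi / pi.sum()
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 1)
    idx = np.empty(epochs, dtype=np.int64)
    idx[0] = 0 if pi[0] > 0 else rng.choice(5, p=pi)
    stay = rng.random(epochs)  # pre-drawn for reproducibility
    jump = rng.choice(5, size=epochs, p=pi)
    for t in range(1, epochs):
        idx[t] = idx[t - 1] if stay[t] < stickiness else jump[t]
    return Hypnogram.from_indices(idx)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, rms: float, rows: int = 1
) -> np.ndarray:
    """White noise Butterworth-bandpassed to [lo, hi] Hz and scaled to target RMS.

    Returns shape (rows, n); rows are independent realizations (one filter call).
    """
    hi = min(hi, 0.49 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    pad = int(2 * fs)
    x = sps.sosfiltfilt(sos, rng.standard_normal((rows, n + 2 * pad)), axis=-1)[:, pad : pad + n]
    std = x.std(axis=-1, keepdims=True)
    return x * np.where(std > 0, rms / np.maximum(std, 1e-300), 1.0)


def _spindle(fs: float, dur_s: float, amp: float, phase: float) -> np.ndarray:
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * 13.0 * t + phase) * np.hanning(t.size)


def _kcomplex(fs: float, amp: float) -> np.ndarray:
    # biphasic slow wave: sharp negative then slower positive deflection, ~1 s
    t = np.linspace(-1.0, 1.0, int(1.0 * fs))
    wave = -np.exp(-((t + 0.25) ** 2) / 0.02) + 0.8 * np.exp(-((t - 0.2) ** 2) / 0.08)
    return amp * wave


def _eog_event(fs: float, dur_s: float, amp: float) -> np.ndarray:
    # smooth monophasic deflection (half-sine), conjugate across eyes
    n = max(int(dur_s * fs), 4)
    return amp * np.sin(np.linspace(0, np.pi, n))


def _add_at(x: np.ndarray, start: int, patch: np.ndarray) -> None:
    stop = min(start + patch.size, x.size)
    if stop > start >= 0:
        x[start:stop] += patch[: stop - start]


def synthesize_record(
    hypnogram: Hypnogram,
    model: StageSignalModel | None = None,
    fs: float = 200.0,
    seed=0,
    subject_id: str = "synthetic",
) -> PolysomnogramRecord:
    """Render a nine-channel polysomnogram whose epochs follow the stage recipes."""
    model = model or default_signal_model()
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 2)
    n_ep = len(hypnogram)
    epl = int(round(hypnogram.epoch_len_s * fs))
    n = n_ep * epl

    eeg = {lab: np.zeros(n) for lab in MONTAGE_LABELS[:6]}
    eog_l, eog_r = np.zeros(n), np.zeros(n)
    emg = np.zeros(n)
    site_of = {lab: i for i, site_labels in enumerate(
        (MONTAGE_LABELS[0:2], MONTAGE_LABELS[2:4], MONTAGE_LABELS[4:6])
    ) for lab in site_labels}

    for e, stage in enumerate(hypnogram):
        sl = slice(e * epl, (e + 1) * epl)
        rec = model.recipes[stage]
        for comp in rec.components:
            noise = _bandlimited_noise(rng, epl, fs, comp.lo_hz, comp.hi_hz, comp.rms_uV, rows=6)
            for row, lab in zip(noise, eeg):
                gain = comp.site_gains[site_of[lab]]
                if gain > 0:
                    eeg[lab][sl] += gain * row
        for _ in range(rng.poisson(rec.spindle_rate)):
            dur = rng.uniform(0.5, 1.5)
            amp = rng.uniform(20.0, 35.0)
            patch = _spindle(fs, dur, amp, rng.uniform(0, 2 * np.pi))
            start = e * epl + rng.integers(0, max(epl - patch.size, 1))
            for lab, g in zip(eeg, (0.6, 0.6, 1.0, 1.0, 0.5, 0.5)):
                _add_at(eeg[lab], start, g * patch)
        for _ in range(rng.poisson(rec.kcomplex_rate)):
            patch = _kcomplex(fs, rng.uniform(60.0, 90.0))
            start = e * epl + rng.integers(0, max(epl - patch.size, 1))
            for lab, g in zip(eeg, (1.0, 1.0, 0.9, 0.9, 0.6, 0.6)):
                _add_at(eeg[lab], start, g * patch)
        # EOG: low background plus conjugate deflections (mirrored polarity)
        eog_noise = _bandlimited_noise(rng, epl, fs, 0.5, 15.0, 3.0, rows=2)
        eog_l[sl] += eog_noise[0]
        eog_r[sl] += eog_noise[1]
        for _ in range(rng.poisson(rec.eog_event_rate)):
            dur = rng.uniform(*rec.eog_event_dur_s)
            amp = rec.eog_event_amp_uV * rng.uniform(0.7, 1.3) * rng.choice((-1.0, 1.0))
            patch = _eog_event(fs, dur, amp)
            start = e * epl + rng.integers(0, max(epl - patch.size, 1))
            _add_at(eog_l, start, patch)
            _add_at(eog_r, start, -patch)
        emg[sl] += rec.emg_rms_uV * rng.standard_normal(epl)

    channels = [ChannelSignal(lab, eeg[lab], fs) for lab in MONTAGE_LABELS[:6]]
    channels += [
        ChannelSignal("EOG-L", eog_l, fs),
        ChannelSignal("EOG-R", eog_r, fs),
        ChannelSignal("chin-EMG", emg, fs),
    ]
    return PolysomnogramRecord(subject_id, channels)


def generate_cohort(config: CohortConfig) -> list[tuple[PolysomnogramRecord, Hypnogram]]:
    """Generate ``n_subjects`` (record, truth hypnogram) pairs.

    Per-subject stage proportions are Dirichlet-jittered around the cohort
    means; the first ``alpha_deficient_fraction`` of subjects (by derived
    per-subject draw) use the alpha-suppressed wake recipe.
    """
    base = default_signal_model()
    deficient = alpha_deficient_signal_model()
    pi0 = np.array([config.stage_proportions[s] for s in STAGE_ORDER], float)
    out = []
    for i in range(config.n_subjects):
        rng_subj = _rng(config.seed, 10, i)
        if config.proportion_concentration > 0:
            alpha = np.maximum(pi0 * config.proportion_concentration, 1e-3)
            pi = rng_subj.dirichlet(alpha)
        else:
            pi = pi0
        props = {s: float(p) for s, p in zip(STAGE_ORDER, pi)}
        h = generate_hypnogram(
            props, config.epochs_per_subject, _rng(config.seed, 11, i), config.stickiness
        )
        is_deficient = rng_subj.random() < config.alpha_deficient_fraction
        rec = synthesize_record(
            h,
            deficient if is_deficient else base,
            fs=config.fs,
            seed=_rng(config.seed, 12, i),
            subject_id=f"subj{i:03d}",
        )
        out.append((rec, h))
    return out


def corrupt_hypnogram(truth: Hypnogram, noise: ScorerNoiseModel, seed) -> Hypnogram:
    """Resample each label independently from its confusion row (a synthetic second scorer)."""
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 3)
    idx = truth.to_indices()
    cum = np.cumsum(noise.matrix, axis=1)
    u = rng.random(idx.size)
    new = (u[:, None] > cum[idx]).sum(axis=1)
    return Hypnogram.from_indices(np.minimum(new, 4), truth.epoch_len_s)
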