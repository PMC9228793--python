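"""Per-epoch feature extraction from EEG, EOG, and EMG signals.

Each 30-s epoch is split into 29 two-second sub-epochs with one-second
overlap — short enough that a sleep spindle (~0.5–1.5 s) or K-complex
dominates at least one window. Per sub-epoch, multitaper power spectral
densities yield delta/theta/alpha/beta band fractions (normalized by the
epoch's total 0.5–30 Hz power) for each contralateral-averaged EEG pair
(frontal, central, occipital), plus delta–theta / theta–alpha / delta–alpha
ratios, line length, and kurtosis. EOG channels contribute slow-band
(0.3–5 Hz) spectral energy, the chin EMG its mean-square energy. Every
sub-epoch track is summarized by its 95th percentile, minimum, mean, and
(sample) standard deviation, giving a fixed-length vector per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal.windows import dpss

from .core import (
    ConfigurationError,
    DegenerateSignalError,
    PolysomnogramRecord,
    epoch_count,
)
from .psg_io import EEG_PAIRS

__all__ = [
    "SubEpochSpec",
    "BandDefinition",
    "FeatureConfig",
    "FeatureSet",
    "DEFAULT_BANDS",
    "segment_subepochs",
    "multitaper_psd",
    "band_power",
    "band_power_fractions",
    "contralateral_average",
    "power_ratios",
    "line_length",
    "kurtosis",
    "summarize_track",
    "eog_band_energy",
    "emg_energy",
    "extract_features",
    "feature_layout",
    "write_features_tsv",
    "read_features_tsv",
]


@dataclass(frozen=True)
class SubEpochSpec:
    """Sliding sub-epoch grid: 2-s windows stepping by 1 s → 29 per 30-s epoch."""

    window_s: float = 2.0
    step_s: float = 1.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or not (0 < self.step_s <= self.window_s):
            raise ValueError("need window_s > 0 and 0 < step_s <= window_s")

    def count(self, epoch_len_s: float) -> int:
        if epoch_len_s < self.window_s:
            raise ValueError("epoch shorter than sub-epoch window")
        return int(np.floor((epoch_len_s - self.window_s) / self.step_s + 1e-9)) + 1


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ValueError(f"band {self.name}: need 0 <= lo < hi")


#: Conventional EEG bands; theta 4–7 Hz per AASM usage, alpha from 8 Hz.
DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

RATIO_NAMES = ("delta_theta_ratio", "theta_alpha_ratio", "delta_alpha_ratio")
SUMMARY_NAMES = ("p95", "min", "mean", "sd")
EEG_FEATURE_NAMES = (
    "delta_frac",
    "theta_frac",
    "alpha_frac",
    "beta_frac",
) + RATIO_NAMES + ("line_length", "kurtosis")


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the extraction pipeline (defaults are the package contract)."""

    subepoch: SubEpochSpec = SubEpochSpec()
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    nw: float = 2.0  # multitaper time-bandwidth product
    k_tapers: int = 3
    total_band: tuple[float, float] = (0.5, 30.0)
    eog_band: tuple[float, float] = (0.3, 5.0)
    epoch_len_s: float = 30.0
    eps: float = 1e-12
    sd_ddof: int = 1


@dataclass
class FeatureSet:
    """Feature matrix (n_epochs × n_features) with its named layout."""

    matrix: np.ndarray
    names: list[str]
    epoch_flags: np.ndarray  # True where the epoch was degenerate and zero-filled
    subject_id: str = ""

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def layout_fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256("\n".join(self.names).encode()).hexdigest()[:16]


def segment_subepochs(epoch_samples: np.ndarray, fs: float, spec: SubEpochSpec = SubEpochSpec()) -> np.ndarray:
    """Slice an epoch into overlapping windows; shape (n_windows, window_samples)."""
    x = np.asarray(epoch_samples, dtype=np.float64)
    w = int(round(spec.window_s * fs))
    s = int(round(spec.step_s * fs))
    if x.size < w:
        raise ValueError(f"epoch of {x.size} samples shorter than {w}-sample window")
    n = (x.size - w) // s + 1
    idx = np.arange(w)[None, :] + s * np.arange(n)[:, None]
    return x[idx]


def _dpss_tapers(n: int, nw: float, k: int) -> np.ndarray:
    if k > 2 * nw - 1 + 1e-9:
        raise ValueError(f"k={k} exceeds 2*nw-1={2 * nw - 1}")
    tapers = dpss(n, nw, Kmax=k)
    # unit-energy tapers -> PSD integrates to the window's power
    return tapers / np.sqrt(np.sum(tapers**2, axis=1, keepdims=True))


def _psd_batch(windows: np.ndarray, fs: float, nw: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper PSD of each row; returns (freqs, psd[n_windows, n_freqs])."""
    n = windows.shape[-1]
    tapers = _dpss_tapers(n, nw, k)
    spec = np.fft.rfft(windows[:, None, :] * tapers[None, :, :], axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=1) / fs
    # one-sided: double everything except DC (and Nyquist when n is even)
    psd[:, 1:] *= 2.0
    if n % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def multitaper_psd(window: np.ndarray, fs: float, nw: float = 2.0, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper (DPSS) power spectral density of a single window.

    The estimate averages direct spectral estimates over ``k`` orthogonal
    Slepian tapers with time-bandwidth product ``nw``; the integrated PSD
    approximates the window's power (Parseval).
    """
    x = np.asarray(window, dtype=np.float64)
    if x.size < 8:
        raise ValueError("window too short for spectral estimation (need >= 8 samples)")
    freqs, psd = _psd_batch(x[None, :], fs, nw, k)
    return freqs, psd[0]


def band_power(freqs: np.ndarray, psd: np.ndarray, lo_hz: float, hi_hz: float) -> float | np.ndarray:
    """Integrated PSD over [lo_hz, hi_hz) via the rectangle rule on the rfft grid."""
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    sel = (freqs >= lo_hz) & (freqs < hi_hz)
    return psd[..., sel].sum(axis=-1) * df


def band_power_fractions(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    total_power: float | None = None,
    *,
    total_band: tuple[float, float] = (0.5, 30.0),
    eps: float = 1e-12,
) -> dict[str, float]:
    """Band powers normalized by total power (defaults to this PSD's 0.5–30 Hz power)."""
    if total_power is None:
        total_power = float(band_power(freqs, psd, *total_band))
    if total_power <= eps:
        raise DegenerateSignalError("total power is ~0; flat or dead channel")
    return {b.name: float(band_power(freqs, psd, b.lo_hz, b.hi_hz)) / total_power for b in bands}


def contralateral_average(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Element-wise mean of the left/right feature tracks (noise reduction)."""
    left, right = np.asarray(left, float), np.asarray(right, float)
    if left.shape != right.shape:
        raise ValueError(f"track shapes differ: {left.shape} vs {right.shape}")
    return 0.5 * (left + right)


def power_ratios(fractions: dict[str, float | np.ndarray], eps: float = 1e-12) -> dict[str, np.ndarray | float]:
    """Slow/fast band ratios; denominators are eps-guarded so ratios stay finite."""
    d, t, a = (np.asarray(fractions[k], float) for k in ("delta", "theta", "alpha"))
    return {
        "delta_theta_ratio": d / (t + eps),
        "theta_alpha_ratio": t / (a + eps),
        "delta_alpha_ratio": d / (a + eps),
    }


def line_length(window: np.ndarray) -> float:
    """Sum of absolute first differences — tracks amplitude and waveform complexity."""
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("line_length needs a 1-D window of >= 2 samples")
    return float(np.abs(np.diff(x)).sum())


def kurtosis(window: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis m4/m2²; ≈3 for Gaussian background, higher for transients."""
    x = np.asarray(window, dtype=np.float64)
    if x.size < 4:
        raise ValueError("kurtosis needs >= 4 samples")
    x = x - x.mean()
    m2 = np.mean(x**2)
    if m2 <= 1e-300:
        raise DegenerateSignalError("zero-variance window has undefined kurtosis")
    return float(np.mean(x**4) / m2**2)


def summarize_track(track: np.ndarray, sd_ddof: int = 1) -> dict[str, float]:
    """{p95, min, mean, sd} of one sub-epoch feature track (p95 linearly interpolated)."""
    t = np.asarray(track, dtype=np.float64)
    if t.size == 0:
        raise ValueError("cannot summarize an empty track")
    return {
        "p95": float(np.percentile(t, 95, method="linear")),
        "min": float(t.min()),
        "mean": float(t.mean()),
        "sd": float(t.std(ddof=sd_ddof)) if t.size > sd_ddof else 0.0,
    }


def eog_band_energy(
    window: np.ndarray, fs: float, band: tuple[float, float] = (0.3, 5.0), nw: float = 2.0, k: int = 3
) -> float:
    """Spectral energy of the slow EOG band (covers slow and rapid eye movements)."""
    freqs, psd = multitaper_psd(np.asarray(window, float) - np.mean(window), fs, nw, k)
    return float(band_power(freqs, psd, band[0], band[1]))


def emg_energy(window: np.ndarray) -> float:
    """Mean squared amplitude of the mean-removed window (muscle tone, µV²)."""
    x = np.asarray(window, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty EMG window")
    x = x - x.mean()
    return float(np.mean(x**2))


def feature_layout(config: FeatureConfig = FeatureConfig()) -> list[str]:
    """Stable, documented ordering of the per-epoch feature vector."""
    names = [
        f"{site}_{feat}_{summ}"
        for site in EEG_PAIRS
        for feat in EEG_FEATURE_NAMES
        for summ in SUMMARY_NAMES
    ]
    names += [f"eog_band_energy_{s}" for s in SUMMARY_NAMES]
    names += [f"emg_energy_{s}" for s in SUMMARY_NAMES]
    return names


def _required_channels() -> list[str]:
    req = [ch for pair in EEG_PAIRS.values() for ch in pair]
    return req + ["chin-EMG"]


def extract_features(record: PolysomnogramRecord, config: FeatureConfig = FeatureConfig()) -> FeatureSet:
    """Compute the per-epoch feature matrix for one polysomnogram.

    Requires the three contralateral EEG pairs, at least one EOG channel, and
    the chin EMG. Epochs whose EEG total power vanishes (dead channel) are
    flagged in ``epoch_flags`` and zero-filled rather than dropped, keeping
    the epoch grid aligned with the reference hypnogram.
    """
    for ch in _required_channels():
        if not record.has_channel(ch):
            raise ConfigurationError(f"feature extraction requires channel {ch!r}")
    eog_labels = [l for l in ("EOG-L", "EOG-R") if record.has_channel(l)]
    if not eog_labels:
        raise ConfigurationError("feature extraction requires at least one EOG channel")

    n_epochs = epoch_count(record, config.epoch_len_s)
    names = feature_layout(config)
    mat = np.zeros((n_epochs, len(names)), dtype=np.float64)
    flags = np.zeros(n_epochs, dtype=bool)
    sd = config.sd_ddof

    def summaries(track: np.ndarray) -> list[float]:
        s = summarize_track(track, sd)
        return [s[k] for k in SUMMARY_NAMES]

    for e in range(n_epochs):
        row: list[float] = []
        degenerate = False
        for site, (lab_l, lab_r) in EEG_PAIRS.items():
            ch_l, ch_r = record.channel(lab_l), record.channel(lab_r)
            win_l = segment_subepochs(ch_l.epoch_slice(e, config.epoch_len_s), ch_l.fs, config.subepoch)
            win_r = segment_subepochs(ch_r.epoch_slice(e, config.epoch_len_s), ch_r.fs, config.subepoch)
            win_l = win_l - win_l.mean(axis=1, keepdims=True)
            win_r = win_r - win_r.mean(axis=1, keepdims=True)
            freqs, psd_l = _psd_batch(win_l, ch_l.fs, config.nw, config.k_tapers)
            _, psd_r = _psd_batch(win_r, ch_r.fs, config.nw, config.k_tapers)
            psd = contralateral_average(psd_l, psd_r)
            # epoch total power: 0.5-30 Hz integral averaged over sub-epochs
            total = float(np.mean(band_power(freqs, psd, *config.total_band)))
            if total <= config.eps:
                degenerate = True
                break
            fracs = {
                b.name: np.asarray(band_power(freqs, psd, b.lo_hz, b.hi_hz)) / total
                for b in config.bands
            }
            ratios = power_ratios(fracs, config.eps)
            ll = contralateral_average(
                np.abs(np.diff(win_l, axis=1)).sum(axis=1),
                np.abs(np.diff(win_r, axis=1)).sum(axis=1),
            )
            kt = contralateral_average(_kurt_rows(win_l), _kurt_rows(win_r))
            for feat in EEG_FEATURE_NAMES:
                if feat.endswith("_frac"):
                    row += summaries(fracs[feat.removesuffix("_frac")])
                elif feat in ratios:
                    row += summaries(ratios[feat])
                elif feat == "line_length":
                    row += summaries(ll)
                else:
                    row += summaries(kt)
        if degenerate:
            flags[e] = True
            continue

        eog_tracks = []
        for lab in eog_labels:
            ch = record.channel(lab)
            wins = segment_subepochs(ch.epoch_slice(e, config.epoch_len_s), ch.fs, config.subepoch)
            wins = wins - wins.mean(axis=1, keepdims=True)
            freqs, psd = _psd_batch(wins, ch.fs, config.nw, config.k_tapers)
            eog_tracks.append(np.asarray(band_power(freqs, psd, *config.eog_band)))
        row += summaries(np.mean(eog_tracks, axis=0))

        emg = record.channel("chin-EMG")
        wins = segment_subepochs(emg.epoch_slice(e, config.epoch_len_s), emg.fs, config.subepoch)
        wins = wins - wins.mean(axis=1, keepdims=True)
        row += summaries(np.mean(wins**2, axis=1))

        mat[e] = row
    return FeatureSet(mat, names, flags, subject_id=record.subject_id)


def _kurt_rows(wins: np.ndarray) -> np.ndarray:
    m2 = np.mean(wins**2, axis=1)
    m4 = np.mean(wins**4, axis=1)
    return np.where(m2 > 1e-300, m4 / np.maximum(m2, 1e-300) ** 2, 0.0)


def write_features_tsv(fs: FeatureSet, path) -> str:
    """Export one row per epoch as TSV with a header, plus the degenerate-epoch flag."""
    import pandas as pd

    df = pd.DataFrame(fs.matrix, columns=fs.names)
    df.insert(0, "epoch", np.arange(len(fs)))
    df["degenerate"] = fs.epoch_flags.astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return str(path)


def read_features_tsv(path, subject_id: str = "") -> FeatureSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    flags = df.pop("degenerate").to_numpy(bool) if "degenerate" in df else np.zeros(len(df), bool)
    df = df.drop(columns=[c for c in ("epoch",) if c in df])
    return FeatureSet(df.to_numpy(np.float64), list(df.columns), flags, subject_id=subject_id)
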