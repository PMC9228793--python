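"""Inter-scorer agreement statistics for epoch-scored hypnograms.

Given a reference scorer (e.g. a sleep expert) and a candidate scorer (e.g.
an automated stager), this module computes the 5×5 stage confusion matrix,
Cohen's κ with a qualitative interpretation scale, per-stage specific
agreement after collapsing to 2×2 tables, and subject-resampled bootstrap
confidence intervals.

Specific agreement follows the Cicchetti–Feinstein definitions: with ``a``
epochs scored as stage s by both, ``b`` by the reference only, ``c`` by the
candidate only and ``d`` by neither,

* positive agreement  PA = 2a / (2a + b + c)
* negative agreement  NA = 2d / (2d + b + c)
* overall agreement   OA = (a + d) / n

all reported as percentages. Undefined ratios (zero denominators) are
reported as NaN markers, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import STAGE_ORDER, Hypnogram, StageLabel

__all__ = [
    "PairedConfusion",
    "StageCollapse",
    "KappaScale",
    "LANDIS_KOCH",
    "AgreementReport",
    "confusion_matrix",
    "row_percentages",
    "cohens_kappa",
    "interpret_kappa",
    "stage_collapse",
    "specific_agreement",
    "pooled_specific_agreement",
    "bootstrap_agreement",
    "per_subject_kappa_summary",
    "hypnogram_overlay",
]


@dataclass(frozen=True)
class PairedConfusion:
    """5×5 count matrix, rows = reference stage, columns = candidate stage."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.counts, dtype=np.float64)
        if m.shape != (5, 5) or (m < 0).any() or m.sum() < 1:
            raise ValueError("confusion matrix must be 5x5, non-negative, with n >= 1")
        object.__setattr__(self, "counts", m)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_row_percentages(cls, row_pct: np.ndarray, row_totals: np.ndarray) -> "PairedConfusion":
        """Reconstruct counts from printed row percentages and per-stage totals."""
        rows = np.asarray(row_pct, dtype=np.float64) / 100.0
        return cls(rows * np.asarray(row_totals, dtype=np.float64)[:, None])


@dataclass(frozen=True)
class StageCollapse:
    """2×2 collapse of the confusion matrix for one stage."""

    stage: StageLabel
    a: float  # both scorers said s
    b: float  # reference only
    c: float  # candidate only
    d: float  # neither

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


def confusion_matrix(reference: Hypnogram, candidate: Hypnogram) -> PairedConfusion:
    if len(reference) != len(candidate):
        raise ValueError(f"hypnogram lengths differ: {len(reference)} vs {len(candidate)}")
    if len(reference) < 1:
        raise ValueError("cannot build a confusion matrix from empty hypnograms")
    r, c = reference.to_indices(), candidate.to_indices()
    m = np.zeros((5, 5), dtype=np.float64)
    np.add.at(m, (r, c), 1.0)
    return PairedConfusion(m)


def row_percentages(m: PairedConfusion) -> np.ndarray:
    """Row-normalized matrix in percent; rows with no epochs become NaN markers."""
    totals = m.counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * m.counts / totals
    out[totals[:, 0] == 0] = np.nan
    return out


def cohens_kappa(m: PairedConfusion) -> float:
    """Chance-corrected agreement κ = (p_o − p_e)/(1 − p_e).

    Returns NaN when both scorers use a single identical category (p_e = 1),
    where κ is undefined.
    """
    n = m.n
    p_o = np.trace(m.counts) / n
    p_e = float(np.sum(m.counts.sum(axis=1) * m.counts.sum(axis=0))) / n**2
    if abs(1.0 - p_e) < 1e-12:
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass(frozen=True)
class KappaScale:
    """Qualitative κ interpretation: label i applies on (breakpoint_{i-1}, breakpoint_i]."""

    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need one more label than breakpoints")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must strictly increase")


#: Conventional Landis–Koch agreement-strength scale.
LANDIS_KOCH = KappaScale(
    breakpoints=(0.0, 0.20, 0.40, 0.60, 0.80),
    labels=("poor", "slight", "fair", "moderate", "substantial", "almost perfect"),
)


def interpret_kappa(kappa: float, scale: KappaScale = LANDIS_KOCH) -> str:
    if np.isnan(kappa):
        return "undefined"
    if kappa > 1.0 + 1e-12:
        raise ValueError("kappa cannot exceed 1")
    # intervals closed on the right: label i applies on (b_{i-1}, b_i];
    # strictly below the first breakpoint -> first label ("poor" for kappa < 0)
    if kappa < scale.breakpoints[0]:
        return scale.labels[0]
    for b, label in zip(scale.breakpoints[1:], scale.labels[1:-1]):
        if kappa <= b:
            return label
    return scale.labels[-1]


def stage_collapse(m: PairedConfusion, s: StageLabel) -> StageCollapse:
    i = s.index
    a = float(m.counts[i, i])
    b = float(m.counts[i, :].sum() - a)
    c = float(m.counts[:, i].sum() - a)
    d = float(m.n - a - b - c)
    return StageCollapse(s, a, b, c, d)


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def specific_agreement(c: StageCollapse) -> dict[str, float]:
    """{PA, NA, OA} percentages for one stage collapse (NaN where undefined)."""
    return {
        "PA": _ratio(2 * c.a, 2 * c.a + c.b + c.c),
        "NA": _ratio(2 * c.d, 2 * c.d + c.b + c.c),
        "OA": _ratio(c.a + c.d, c.n),
    }


def pooled_specific_agreement(m: PairedConfusion) -> dict[str, float]:
    """Total row: PA/NA pooled over the five stage collapses, OA as their mean.

    Pooled PA = 100·Σ2aₛ/Σ(2aₛ+bₛ+cₛ); since Σbₛ = Σcₛ = n − Σaₛ this equals
    100·Σaₛ/n, the raw percent concordance.
    """
    collapses = [stage_collapse(m, s) for s in STAGE_ORDER]
    a = sum(c.a for c in collapses)
    b = sum(c.b for c in collapses)
    cc = sum(c.c for c in collapses)
    d = sum(c.d for c in collapses)
    oa = [specific_agreement(c)["OA"] for c in collapses]
    return {
        "PA": _ratio(2 * a, 2 * a + b + cc),
        "NA": _ratio(2 * d, 2 * d + b + cc),
        "OA": float(np.nanmean(oa)),
    }


@dataclass
class AgreementReport:
    """Bootstrap medians and 95% percentile CIs for PA/NA/OA, plus pooled κ."""

    per_stage: dict[str, dict[str, tuple[float, float, float]]]  # stage -> metric -> (median, lo, hi)
    total: dict[str, tuple[float, float, float]]
    kappa: float
    kappa_label: str
    n_epochs: float
    n_subjects: int
    R: int
    seed: int
    undefined_metrics: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def tidy(t):
            return {"median": t[0], "ci_lo": t[1], "ci_hi": t[2]}

        return {
            "per_stage": {
                s: {m: tidy(v) for m, v in row.items()} for s, row in self.per_stage.items()
            },
            "total": {m: tidy(v) for m, v in self.total.items()},
            "kappa": self.kappa,
            "kappa_label": self.kappa_label,
            "n_epochs": self.n_epochs,
            "n_subjects": self.n_subjects,
            "R": self.R,
            "seed": self.seed,
            "undefined_metrics": self.undefined_metrics,
        }


def _metrics_from_counts(counts: np.ndarray) -> np.ndarray:
    """(6 rows: 5 stages + total) × (PA, NA, OA) from one pooled 5×5 matrix."""
    n = counts.sum()
    a = np.diag(counts).astype(float)
    b = counts.sum(axis=1) - a
    c = counts.sum(axis=0) - a
    d = n - a - b - c
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(2 * a + b + c > 0, 100.0 * 2 * a / (2 * a + b + c), np.nan)
        na = np.where(2 * d + b + c > 0, 100.0 * 2 * d / (2 * d + b + c), np.nan)
        oa = 100.0 * (a + d) / n
    tot_pa = 100.0 * 2 * a.sum() / (2 * a.sum() + b.sum() + c.sum())
    tot_na = 100.0 * 2 * d.sum() / (2 * d.sum() + b.sum() + c.sum())
    tot_oa = np.nanmean(oa)
    return np.vstack([np.column_stack([pa, na, oa]), [tot_pa, tot_na, tot_oa]])


def bootstrap_agreement(
    pairs: list[tuple[Hypnogram, Hypnogram]],
    R: int = 1000,
    seed: int = 0,
    scale: KappaScale = LANDIS_KOCH,
) -> AgreementReport:
    """Subject-resampled bootstrap of the specific-agreement metrics.

    Each of ``R`` resamples draws subjects with replacement (same count),
    pools their confusion matrices, and computes per-stage and total
    PA/NA/OA; the report carries the median and the 2.5/97.5 percentiles of
    each metric over resamples. The resampling unit is the subject because
    epochs within a night are strongly dependent.
    """
    if not pairs:
        raise ValueError("need at least one subject pair")
    if R < 1:
        raise ValueError("R must be >= 1")
    per_subject = np.stack([confusion_matrix(r, c).counts for r, c in pairs])
    pooled = PairedConfusion(per_subject.sum(axis=0))
    rng = np.random.default_rng(int(seed) % 2**31)
    n_subj = len(pairs)
    stats = np.empty((R, 6, 3))
    for r in range(R):
        idx = rng.integers(0, n_subj, size=n_subj)
        stats[r] = _metrics_from_counts(per_subject[idx].sum(axis=0))

    row_names = [s.value for s in STAGE_ORDER] + ["total"]
    metric_names = ("PA", "NA", "OA")
    undefined: list[str] = []
    table: dict[str, dict[str, tuple[float, float, float]]] = {}
    for i, rname in enumerate(row_names):
        row = {}
        for j, mname in enumerate(metric_names):
            vals = stats[:, i, j]
            n_ok = np.sum(~np.isnan(vals))
            if n_ok <= R / 2:
                row[mname] = (float("nan"),) * 3
                undefined.append(f"{rname}.{mname}")
            else:
                ok = vals[~np.isnan(vals)]
                row[mname] = (
                    float(np.median(ok)),
                    float(np.percentile(ok, 2.5, method="linear")),
                    float(np.percentile(ok, 97.5, method="linear")),
                )
        table[rname] = row

    kappa = cohens_kappa(pooled)
    return AgreementReport(
        per_stage={k: v for k, v in table.items() if k != "total"},
        total=table["total"],
        kappa=kappa,
        kappa_label=interpret_kappa(kappa, scale),
        n_epochs=pooled.n,
        n_subjects=n_subj,
        R=R,
        seed=int(seed),
        undefined_metrics=undefined,
    )


def per_subject_kappa_summary(pairs: list[tuple[Hypnogram, Hypnogram]]) -> dict[str, float]:
    """Median/mean/SD/min/max of Cohen's κ computed per subject."""
    ks = np.array([cohens_kappa(confusion_matrix(r, c)) for r, c in pairs], float)
    ok = ks[~np.isnan(ks)]
    if ok.size == 0:
        raise ValueError("kappa undefined for every subject")
    return {
        "median": float(np.median(ok)),
        "mean": float(np.mean(ok)),
        "sd": float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0,
        "min": float(np.min(ok)),
        "max": float(np.max(ok)),
        "n": int(ok.size),
    }


#: hypnogram plotting depth order, top to bottom
_PLOT_ORDER = (StageLabel.W, StageLabel.R, StageLabel.N1, StageLabel.N2, StageLabel.N3)


def hypnogram_overlay(reference: Hypnogram, candidate: Hypnogram, path) -> str:
    """Step-plot both hypnograms on the conventional depth axis (W, R, N1, N2, N3)."""
    if len(reference) != len(candidate):
        raise ValueError("hypnograms must have equal length")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    depth = {s: len(_PLOT_ORDER) - 1 - i for i, s in enumerate(_PLOT_ORDER)}
    t = np.arange(len(reference)) * reference.epoch_len_s / 3600.0
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.step(t, [depth[s] for s in reference], where="post", lw=1.2, label="reference scorer")
    ax.step(t, [depth[s] for s in candidate], where="post", lw=1.0, alpha=0.75, label="automated scorer")
    ax.set_yticks([depth[s] for s in _PLOT_ORDER])
    ax.set_yticklabels([s.value for s in _PLOT_ORDER])
    ax.set_xlabel("time (h)")
    ax.set_ylabel("stage")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": None} if str(path).endswith(".png") else None)
    plt.close(fig)
    return str(path)
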