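"""Polysomnogram and hypnogram I/O: EDF signals, plain-text stage files, montage mapping.

The standard six-EEG / two-EOG / one-EMG staging montage is::

    F3-M2  F4-M1  C3-M2  C4-M1  O1-M2  O2-M1  EOG-L  EOG-R  chin-EMG

``read_edf`` accepts either pre-derived channels (already referenced to the
contralateral mastoid) or raw electrode channels, in which case derivations
are formed by subtraction (F3-M2 = F3 − M2).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .core import (
    ChannelSignal,
    ConfigurationError,
    Hypnogram,
    PolysomnogramRecord,
    parse_stage,
)
from .edf import EdfSignal, read_edf_file, write_edf_file

__all__ = [
    "MONTAGE_LABELS",
    "EEG_PAIRS",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "derive_montage",
]

logger = logging.getLogger(__name__)

#: Canonical montage labels in output order.
MONTAGE_LABELS = (
    "F3-M2",
    "F4-M1",
    "C3-M2",
    "C4-M1",
    "O1-M2",
    "O2-M1",
    "EOG-L",
    "EOG-R",
    "chin-EMG",
)

#: Contralateral EEG pairs averaged during feature extraction, by cortical site.
EEG_PAIRS = {
    "frontal": ("F3-M2", "F4-M1"),
    "central": ("C3-M2", "C4-M1"),
    "occipital": ("O1-M2", "O2-M1"),
}


def read_edf(path, montage_map: dict[str, str] | None = None, subject_id: str | None = None) -> PolysomnogramRecord:
    """Read an EDF file into a :class:`PolysomnogramRecord`.

    Parameters
    ----------
    path
        EDF/EDF+ file path.
    montage_map
        Mapping from raw stored labels to montage names. ``None`` keeps stored
        labels as-is. Channels whose label is in neither the map nor the
        canonical montage are dropped with a warning; if nothing maps, a
        :class:`ConfigurationError` is raised.
    """
    path = Path(path)
    signals = read_edf_file(path)
    keep: list[ChannelSignal] = []
    for sig in signals:
        if montage_map is None:
            keep.append(ChannelSignal(sig.label, sig.samples, sig.fs))
        elif sig.label in montage_map:
            keep.append(ChannelSignal(montage_map[sig.label], sig.samples, sig.fs))
        elif sig.label in MONTAGE_LABELS:
            keep.append(ChannelSignal(sig.label, sig.samples, sig.fs))
        else:
            logger.warning("dropping unmapped channel %r in %s", sig.label, path.name)
    if not keep:
        raise ConfigurationError(
            f"montage map matches no channel in {path.name}; stored labels: "
            f"{[s.label for s in signals]}"
        )
    record = PolysomnogramRecord(subject_id or path.stem, keep)
    return derive_montage(record)


def write_edf(record: PolysomnogramRecord, path) -> str:
    """Write a record to EDF; round-trips labels, rates, and samples within 16-bit quantization."""
    signals = [EdfSignal(c.label, c.samples, c.fs) for c in record.channels]
    return write_edf_file(path, signals)


def derive_montage(record: PolysomnogramRecord) -> PolysomnogramRecord:
    """Form mastoid-referenced derivations from raw electrodes where needed.

    Pre-derived channels (label containing ``-``, e.g. ``F3-M2``) are used
    as-is. Otherwise, for each canonical derivation ``X-Y`` with both raw
    electrodes present at the same rate, the difference ``X − Y`` is added.
    Raw electrode channels consumed by a derivation are dropped.
    """
    have = {c.label for c in record.channels}
    out = list(record.channels)
    consumed: set[str] = set()
    for deriv in MONTAGE_LABELS[:6]:
        if deriv in have:
            continue
        x, y = deriv.split("-")
        if x in have and y in have:
            cx, cy = record.channel(x), record.channel(y)
            if cx.fs != cy.fs:
                raise ConfigurationError(
                    f"cannot derive {deriv}: {x} at {cx.fs} Hz but {y} at {cy.fs} Hz"
                )
            n = min(cx.samples.size, cy.samples.size)
            out.append(ChannelSignal(deriv, cx.samples[:n] - cy.samples[:n], cx.fs))
            consumed.update((x, y))
    out = [c for c in out if c.label not in consumed]
    return PolysomnogramRecord(record.subject_id, out, record.start_time)


def read_hypnogram(path) -> Hypnogram:
    """Read a one-stage-token-per-line hypnogram text file.

    Lines starting with ``#`` and blank lines are ignored. Unknown tokens
    raise a :class:`ValueError` naming the offending line.
    """
    labels = []
    with open(path, "r", encoding="utf-8") as f:
        for lineno, line in enumerate(f, start=1):
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            try:
                labels.append(parse_stage(token))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unknown stage label {token!r}") from None
    if not labels:
        raise ValueError(f"{path}: no stage labels found")
    return Hypnogram(tuple(labels))


def write_hypnogram(h: Hypnogram, path) -> str:
    with open(path, "w", encoding="utf-8") as f:
        for s in h.labels:
            f.write(s.value + "\n")
    return str(path)
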