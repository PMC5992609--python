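"""Deep-amplicon per-base error model and detection-limit calls.

Deep targeted resequencing (thousands-fold coverage) can verify mutations at
allele frequencies far below exome detection limits — but only down to the
platform's background mismatch rate.  That background is estimated from
amplicon positions *not* affected by true mutations or polymorphism: the
pooled fraction of non-reference base calls among all (quality-filtered) base
calls at those clean positions.  A substitution observed at an allele
frequency below the pooled rate is reported as below the detection limit.
Small insertions/deletions show a background so low that any observed indel
allele fraction is reported as detected.

Pileups arrive as per-position base counts (the Phred > 30 quality floor is
applied upstream when counting); this module never touches reads or BAMs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import ParseError, ValidationError

BASE_COLUMNS = ("A", "C", "G", "T", "ins", "del")


class DetectionCall(str, Enum):
    DETECTED = "detected"
    BELOW_LIMIT = "below_limit"


@dataclass
class AmpliconPileup:
    """Per-position base-call counts for one amplicon.

    ``counts`` has shape (n_positions, 6) ordered A, C, G, T, ins, del;
    ``ref`` holds the reference base per position; ``flagged`` marks positions
    carrying a known mutation or polymorphism, which are excluded from error
    estimation.
    """

    positions: np.ndarray
    ref: np.ndarray
    counts: np.ndarray
    flagged: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.positions)
        if self.counts.shape != (n, len(BASE_COLUMNS)):
            raise ValidationError(f"counts must have shape ({n}, {len(BASE_COLUMNS)})")
        if len(self.ref) != n or len(self.flagged) != n:
            raise ValidationError("positions, ref and flagged must have equal length")
        if (self.counts < 0).any():
            raise ValidationError("base counts must be non-negative")
        for base in self.ref:
            if base not in "ACGT":
                raise ValidationError(f"reference base must be one of ACGT, got {base!r}")

    @property
    def total_calls(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def ref_calls(self) -> np.ndarray:
        ref_idx = np.array([BASE_COLUMNS.index(b) for b in self.ref])
        return self.counts[np.arange(len(self.ref)), ref_idx]


@dataclass(frozen=True)
class ErrorModel:
    """Pooled per-base background error rate of one amplicon."""

    per_base_error_rate: float
    n_positions_used: int
    n_bases_used: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            raise ValidationError("error rate must lie in [0, 1]")


def estimate_per_base_error(pileup: AmpliconPileup, per_position: bool = False):
    """Background error rate from non-flagged amplicon positions.

    Pooled mode (default) returns one :class:`ErrorModel`: total non-reference
    calls over total calls at clean covered positions — equivalently the
    coverage-weighted mean of per-position mismatch rates.  With
    ``per_position=True`` an array of per-position rates is returned instead.
    """
    clean = ~pileup.flagged & (pileup.total_calls > 0)
    if not clean.any():
        raise ValidationError("no unflagged covered position to estimate the error rate from")
    total = pileup.total_calls[clean]
    mismatches = total - pileup.ref_calls[clean]
    if per_position:
        return mismatches / total
    return ErrorModel(
        per_base_error_rate=float(mismatches.sum() / total.sum()),
        n_positions_used=int(clean.sum()),
        n_bases_used=int(total.sum()),
    )


def detection_call(af: float, model: ErrorModel, is_indel: bool = False) -> DetectionCall:
    """Is an observed allele fraction distinguishable from background error?

    Substitutions at ``af`` below the per-base error rate are below the
    detection limit (at the boundary they are still reported as detected);
    indels are detected whenever ``af`` is positive.
    """
    if not 0.0 <= af <= 1.0:
        raise ValidationError(f"allele fraction must lie in [0, 1], got {af}")
    if is_indel:
        return DetectionCall.DETECTED if af > 0 else DetectionCall.BELOW_LIMIT
    return DetectionCall.DETECTED if af >= model.per_base_error_rate else DetectionCall.BELOW_LIMIT


def read_pileup_tsv(path: str | Path) -> AmpliconPileup:
    """Read a pileup TSV: pos, ref, A, C, G, T, ins, del, flagged."""
    path = Path(path)
    positions, refs, counts, flagged = [], [], [], []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"pos", "ref", *BASE_COLUMNS, "flagged"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                positions.append(int(row["pos"]))
                refs.append(row["ref"].strip().upper())
                counts.append([int(row[b]) for b in BASE_COLUMNS])
                flagged.append(row["flagged"].strip().lower() in {"true", "1", "yes"})
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed pileup record: {exc}") from exc
    return AmpliconPileup(
        positions=np.array(positions),
        ref=np.array(refs),
        counts=np.array(counts, dtype=np.int64),
        flagged=np.array(flagged, dtype=bool),
    )


def write_pileup_tsv(pileup: AmpliconPileup, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["pos", "ref", *BASE_COLUMNS, "flagged"])
        for i in range(len(pileup.positions)):
            writer.writerow(
                [int(pileup.positions[i]), pileup.ref[i], *map(int, pileup.counts[i]),
                 str(bool(pileup.flagged[i])).lower()]
            )


__all__ = [
    "BASE_COLUMNS",
    "DetectionCall",
    "AmpliconPileup",
    "ErrorModel",
    "estimate_per_base_error",
    "detection_call",
    "read_pileup_tsv",
    "write_pileup_tsv",
]
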