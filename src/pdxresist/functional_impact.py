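"""Consensus deleteriousness labels and the two-proportion comparison.

A mutation is *deleterious* when its consequence is protein-truncating or
splice-disrupting (frameshift, nonsense, canonical splice site) or when it is
a missense change predicted damaging by **both** SIFT and PolyPhen-2; every
other missense change is *non-deleterious*.  PolyPhen-2's probably/possibly
damaging grades are collapsed to "deleterious" upstream of this module (see
:func:`collapse_polyphen`).  Missense variants lacking predictions default to
non-deleterious — the deleterious set is kept specific rather than sensitive.

The fractions of deleterious mutations in two mutation categories are compared
with a pooled-variance two-proportion z-test (normal approximation, no
continuity correction).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from scipy.stats import norm

from .errors import ParseError, ValidationError
from .variant_model import VariantKey

logger = logging.getLogger(__name__)

SIFT_LABELS = frozenset({"deleterious", "tolerated", "unknown"})
POLYPHEN_LABELS = frozenset({"deleterious", "benign", "unknown"})


class ImpactLabel(str, Enum):
    DELETERIOUS = "deleterious"
    NON_DELETERIOUS = "non_deleterious"


@dataclass(frozen=True)
class PredictionLabels:
    """SIFT and (collapsed) PolyPhen-2 calls for a missense variant."""

    sift: str = "unknown"
    polyphen: str = "unknown"

    def __post_init__(self) -> None:
        if self.sift not in SIFT_LABELS:
            raise ValidationError(f"unknown SIFT label {self.sift!r}")
        if self.polyphen not in POLYPHEN_LABELS:
            raise ValidationError(f"unknown PolyPhen label {self.polyphen!r}")


def collapse_polyphen(raw: str, damaging_grades: frozenset[str] = frozenset({"probably_damaging", "possibly_damaging"})) -> str:
    """Collapse PolyPhen-2 grades to the binary vocabulary used here."""
    raw = raw.strip().lower()
    if raw in damaging_grades or raw == "deleterious":
        return "deleterious"
    if raw == "benign":
        return "benign"
    return "unknown"


def classify_impact(consequence: str, labels: PredictionLabels | None = None) -> ImpactLabel:
    """Consensus deleteriousness call for one somatic mutation."""
    if consequence in {"frameshift", "nonsense", "splice_site"}:
        return ImpactLabel.DELETERIOUS
    if consequence != "missense":
        raise ValidationError(
            f"impact classification applies to somatic consequences only, got {consequence!r}"
        )
    if labels is None:
        logger.warning("missense variant without predictions classified non_deleterious")
        return ImpactLabel.NON_DELETERIOUS
    if labels.sift == "deleterious" and labels.polyphen == "deleterious":
        return ImpactLabel.DELETERIOUS
    return ImpactLabel.NON_DELETERIOUS


def read_prediction_labels(path: str | Path) -> dict[VariantKey, PredictionLabels]:
    """Read a predictions TSV: chrom, pos, ref, alt, sift, polyphen."""
    path = Path(path)
    labels: dict[VariantKey, PredictionLabels] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt", "sift", "polyphen"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
                labels[key] = PredictionLabels(
                    sift=row["sift"].strip().lower(),
                    polyphen=collapse_polyphen(row["polyphen"]),
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return labels


def normal_two_sided_p(z: float) -> float:
    """Two-sided standard-normal p-value, ``2 * (1 - Phi(|z|))``."""
    return float(2.0 * norm.sf(abs(z)))


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance z-test comparing two proportions ``k1/n1`` vs ``k2/n2``.

    Returns ``(z, p)`` with a two-sided p-value.  When the pooled proportion
    is degenerate (0 or 1) the difference is zero by construction; z is
    reported as 0 with p = 1 and a warning.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValidationError(f"invalid counts k={k}, n={n}")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.warning("degenerate pooled proportion %s; z undefined, reporting 0", pooled)
        return 0.0, 1.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    return z, normal_two_sided_p(z)


__all__ = [
    "ImpactLabel",
    "PredictionLabels",
    "collapse_polyphen",
    "classify_impact",
    "read_prediction_labels",
    "normal_two_sided_p",
    "two_proportion_ztest",
]
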