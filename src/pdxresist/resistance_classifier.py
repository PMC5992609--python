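"""Per-arm resistance classification of somatic mutations.

Each somatic mutation is compared between the parental xenograft and one
treatment-adapted xenograft and assigned exactly one status:

``de_novo``
    Called in the adapted model but completely absent from the parental one —
    zero mutant reads at >= 20-fold parental coverage certify the absence.
``completely_depleted``
    Called in the parental model but completely absent (certified as above)
    from the adapted one.
``enriched`` / ``partially_depleted`` / ``common_unchanged``
    Present in both (at least one mutant read with >= 20-fold coverage on each
    side).  For these *common* mutations a two-sided Fisher exact test on the
    2x2 mutant/reference read-count table, followed by Benjamini-Hochberg FDR
    correction within the arm, decides whether the allele-frequency shift is
    significant; subtle shifts are ignored — the shift must also be at least
    10 percentage points in magnitude.
``undetermined``
    Anything else: missing observations or coverage too shallow to certify
    presence or absence on one side.

The Fisher test is two-sided ("probability mass <= observed table"); the
direction of a significant shift is then read off the sign of the AF change.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, ValidationError
from .somatic_filters import (
    DEFAULT_MIN_ALT_READS,
    DEFAULT_MIN_COVERAGE,
    passes_calling_thresholds,
)
from .variant_model import (
    GenomicVariant,
    SampleRoles,
    VariantKey,
    VariantObservation,
    VariantTable,
    allele_fraction,
)

logger = logging.getLogger(__name__)

DEFAULT_FDR_LEVEL = 0.05
DEFAULT_MIN_DELTA = 0.10


class ResistanceStatus(str, Enum):
    DE_NOVO = "de_novo"
    COMPLETELY_DEPLETED = "completely_depleted"
    ENRICHED = "enriched"
    PARTIALLY_DEPLETED = "partially_depleted"
    COMMON_UNCHANGED = "common_unchanged"
    UNDETERMINED = "undetermined"


class _Branch(Enum):
    """Marker for the shared branch, resolved by :func:`classify_cohort`."""

    COMMON = "common"


COMMON_BRANCH = _Branch.COMMON

#: Statuses that pool into the "completely or partially depleted" category.
DEPLETED_STATUSES = (ResistanceStatus.COMPLETELY_DEPLETED, ResistanceStatus.PARTIALLY_DEPLETED)


def _certified_absent(obs: VariantObservation | None, min_coverage: int) -> bool:
    return obs is not None and obs.alt_reads == 0 and obs.total_reads >= min_coverage


def _present_any(obs: VariantObservation | None, min_coverage: int) -> bool:
    # "minimum of one read with 20-fold coverage"
    return obs is not None and obs.alt_reads >= 1 and obs.total_reads >= min_coverage


def classify_variant_status(
    parental: VariantObservation | None,
    adapted: VariantObservation | None,
    consequence: str,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> ResistanceStatus | _Branch:
    """Status of one (variant, arm) pair, or :data:`COMMON_BRANCH` if shared.

    Degenerate inputs (missing observations, shallow coverage) map to
    ``UNDETERMINED``; nothing raises.
    """
    adapted_called = adapted is not None and passes_calling_thresholds(
        adapted, consequence, min_coverage, min_alt_reads
    )
    parental_called = parental is not None and passes_calling_thresholds(
        parental, consequence, min_coverage, min_alt_reads
    )
    if adapted_called and _certified_absent(parental, min_coverage):
        return ResistanceStatus.DE_NOVO
    if parental_called and _certified_absent(adapted, min_coverage):
        return ResistanceStatus.COMPLETELY_DEPLETED
    if _present_any(parental, min_coverage) and _present_any(adapted, min_coverage):
        return COMMON_BRANCH
    return ResistanceStatus.UNDETERMINED


def fisher_af_shift(
    parental: VariantObservation,
    adapted: VariantObservation,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> tuple[float, float]:
    """Two-sided Fisher exact p and signed AF shift for a shared mutation.

    The 2x2 table is ``[[parental alt, parental ref], [adapted alt, adapted
    ref]]``; the shift is adapted AF minus parental AF.
    """
    for name, obs in (("parental", parental), ("adapted", adapted)):
        if obs.total_reads < min_coverage or obs.alt_reads < 1:
            raise ContractError(
                f"fisher_af_shift requires >= {min_coverage}x coverage and >= 1 alt read; "
                f"{name} observation is ({obs.alt_reads}, {obs.total_reads})"
            )
    table = [
        [parental.alt_reads, parental.total_reads - parental.alt_reads],
        [adapted.alt_reads, adapted.total_reads - adapted.alt_reads],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    delta = allele_fraction(adapted) - allele_fraction(parental)
    return float(p), float(delta)


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    pvals = np.asarray(pvalues, dtype=float)
    if pvals.size == 0:
        return []
    if np.any(np.isnan(pvals)) or np.any((pvals < 0) | (pvals > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class ClassificationRecord:
    """Resistance status of one somatic mutation in one treatment arm.

    ``fisher_p``/``fdr_q`` are populated only for pairs evaluated on the
    common branch; AF fields are ``None`` where coverage is zero or the
    observation is missing.
    """

    variant: GenomicVariant
    arm: str
    status: ResistanceStatus
    parental_af: float | None
    adapted_af: float | None
    delta_af: float | None
    fisher_p: float | None = None
    fdr_q: float | None = None


def _safe_af(obs: VariantObservation | None) -> float | None:
    if obs is None or obs.total_reads == 0:
        return None
    return allele_fraction(obs)


def classify_cohort(
    table: VariantTable,
    roles: SampleRoles,
    fdr_level: float = DEFAULT_FDR_LEVEL,
    min_delta: float = DEFAULT_MIN_DELTA,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> list[ClassificationRecord]:
    """Classify every (somatic variant, adapted arm) pair.

    Fisher p-values of common-branch pairs are FDR-adjusted *within each arm*
    (each arm is an independent comparison against the same parental sample),
    and a shift is called enriched / partially depleted only when the adjusted
    value is below ``fdr_level`` *and* the AF moved by at least ``min_delta``
    (10 percentage points by default) in the corresponding direction.
    """
    if len(table) == 0:
        logger.warning("classify_cohort called on an empty somatic set")
        return []
    records: list[ClassificationRecord] = []
    for arm, adapted_sample in roles.adapted:
        prelim: list[tuple[GenomicVariant, ResistanceStatus | _Branch, VariantObservation | None, VariantObservation | None]] = []
        for variant in table.variants:
            parental = table.get(variant, roles.parental)
            adapted = table.get(variant, adapted_sample)
            status = classify_variant_status(
                parental, adapted, variant.consequence, min_coverage, min_alt_reads
            )
            prelim.append((variant, status, parental, adapted))

        common = [(v, p, a) for v, s, p, a in prelim if s is COMMON_BRANCH]
        pvals: list[float] = []
        deltas: list[float] = []
        for _, parental, adapted in common:
            p, delta = fisher_af_shift(parental, adapted, min_coverage)
            pvals.append(p)
            deltas.append(delta)
        qvals = bh_fdr(pvals)
        common_results = {
            v.key: (p, q, d) for (v, _, _), p, q, d in zip(common, pvals, qvals, deltas)
        }

        for variant, status, parental, adapted in prelim:
            p_af, a_af = _safe_af(parental), _safe_af(adapted)
            delta = a_af - p_af if (p_af is not None and a_af is not None) else None
            if status is COMMON_BRANCH:
                p, q, delta = common_results[variant.key]
                if q < fdr_level and delta >= min_delta:
                    final = ResistanceStatus.ENRICHED
                elif q < fdr_level and delta <= -min_delta:
                    final = ResistanceStatus.PARTIALLY_DEPLETED
                else:
                    final = ResistanceStatus.COMMON_UNCHANGED
                records.append(
                    ClassificationRecord(variant, arm, final, p_af, a_af, delta, p, q)
                )
            else:
                records.append(
                    ClassificationRecord(variant, arm, status, p_af, a_af, delta)
                )
    return records


@dataclass
class CrossModelSummary:
    """Cross-arm overlap of classification results.

    ``arm_multiplicity[status][k]`` counts variants holding ``status`` in
    exactly ``k`` arms; ``shared_all_arms[status]`` lists variants holding it
    in every arm.  The pooled ``depleted`` entries merge completely and
    partially depleted statuses, deduplicating variants that carry one status
    in one arm and the other elsewhere.
    """

    n_arms: int
    arms: tuple[str, ...]
    per_arm_status_counts: dict[str, dict[str, int]]
    arm_multiplicity: dict[str, dict[int, int]]
    shared_all_arms: dict[str, list[VariantKey]]
    depleted_pooled_multiplicity: dict[int, int]
    depleted_pooled_shared_all: list[VariantKey]

    def status_total(self, status: ResistanceStatus | str) -> int:
        """Number of distinct variants holding ``status`` in at least one arm."""
        status = ResistanceStatus(status).value
        return sum(self.arm_multiplicity.get(status, {}).values())

    def single_arm_count(self, status: ResistanceStatus | str) -> int:
        status = ResistanceStatus(status).value
        return self.arm_multiplicity.get(status, {}).get(1, 0)

    @property
    def depleted_pooled_total(self) -> int:
        return sum(self.depleted_pooled_multiplicity.values())


def summarize_overlap(records: Iterable[ClassificationRecord]) -> CrossModelSummary:
    """Count per-arm statuses and cross-arm sharing of classified mutations."""
    records = list(records)
    arms = tuple(dict.fromkeys(r.arm for r in records))
    per_arm: dict[str, dict[str, int]] = {
        arm: Counter() for arm in arms
    }
    status_arms: dict[str, dict[VariantKey, set[str]]] = defaultdict(lambda: defaultdict(set))
    depleted_arms: dict[VariantKey, set[str]] = defaultdict(set)
    for rec in records:
        per_arm[rec.arm][rec.status.value] += 1
        status_arms[rec.status.value][rec.variant.key].add(rec.arm)
        if rec.status in DEPLETED_STATUSES:
            depleted_arms[rec.variant.key].add(rec.arm)

    n_arms = len(arms)
    multiplicity: dict[str, dict[int, int]] = {}
    shared_all: dict[str, list[VariantKey]] = {}
    for status, by_variant in status_arms.items():
        counts: Counter = Counter(len(a) for a in by_variant.values())
        multiplicity[status] = dict(sorted(counts.items()))
        shared_all[status] = sorted(k for k, a in by_variant.items() if len(a) == n_arms)
    pooled_counts = Counter(len(a) for a in depleted_arms.values())
    pooled_shared = sorted(k for k, a in depleted_arms.items() if len(a) == n_arms)
    return CrossModelSummary(
        n_arms=n_arms,
        arms=arms,
        per_arm_status_counts={arm: dict(c) for arm, c in per_arm.items()},
        arm_multiplicity=multiplicity,
        shared_all_arms=shared_all,
        depleted_pooled_multiplicity=dict(sorted(pooled_counts.items())),
        depleted_pooled_shared_all=pooled_shared,
    )


__all__ = [
    "DEFAULT_FDR_LEVEL",
    "DEFAULT_MIN_DELTA",
    "COMMON_BRANCH",
    "DEPLETED_STATUSES",
    "ResistanceStatus",
    "ClassificationRecord",
    "CrossModelSummary",
    "classify_variant_status",
    "fisher_af_shift",
    "bh_fdr",
    "classify_cohort",
    "summarize_overlap",
]
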