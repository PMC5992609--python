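"""Mutation-calling thresholds and exclusion filters.

Calling rule: a point mutation is called when the locus is covered at least
20-fold and the mutant nucleotide is seen in at least two independent reads;
frameshifts need only the two mutant reads, with no coverage requirement
(indel-supporting reads certify presence even at shallow depth).

Exclusion filters reduce the cohort to the somatic mutation set analysed
downstream: dbSNP-common variants (population MAF > 1%), presumed-neutral
consequence classes (synonymous, intronic, UTR, in-frame indels) and variants
with germline support are removed.  Certifying that a variant is somatic
requires positive evidence of absence in the germline: zero mutant reads at
>= ``min_coverage`` germline depth.  Variants whose germline coverage is too
shallow to certify either way are dropped and logged, not guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ConfigurationError
from .variant_model import (
    RETAINED_CONSEQUENCES,
    GenomicVariant,
    SampleRoles,
    VariantObservation,
    VariantTable,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 20
DEFAULT_MIN_ALT_READS = 2


def passes_calling_thresholds(
    obs: VariantObservation,
    consequence: str,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_alt_reads: int = DEFAULT_MIN_ALT_READS,
) -> bool:
    """True if the observation supports calling a mutation of this consequence."""
    if consequence == "frameshift":
        return obs.alt_reads >= min_alt_reads
    return obs.total_reads >= min_coverage and obs.alt_reads >= min_alt_reads


@dataclass(frozen=True)
class FilterDecision:
    variant: GenomicVariant
    reason: str


def apply_exclusion_filters(
    table: VariantTable,
    roles: SampleRoles,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> tuple[VariantTable, list[FilterDecision]]:
    """Reduce ``table`` to the somatic mutation set.

    Retains variants that are (a) not dbSNP-common, (b) of a retained
    consequence class (frameshift, nonsense, splice_site, missense) and
    (c) certified absent from the germline sample (0 mutant reads at
    >= ``min_coverage`` depth).

    Returns the filtered table and the list of per-variant removal reasons.
    The operation is idempotent and never modifies observation values.
    """
    if not roles.germline:
        raise ConfigurationError("germline role is not configured")
    kept: list[GenomicVariant] = []
    dropped: list[FilterDecision] = []
    for variant in table.variants:
        if variant.is_common:
            dropped.append(FilterDecision(variant, "common_variant"))
            continue
        if variant.consequence not in RETAINED_CONSEQUENCES:
            dropped.append(FilterDecision(variant, f"excluded_consequence:{variant.consequence}"))
            continue
        germline = table.get(variant, roles.germline)
        if germline is None or germline.total_reads < min_coverage:
            dropped.append(FilterDecision(variant, "insufficient_germline_coverage"))
            continue
        if germline.alt_reads > 0:
            dropped.append(FilterDecision(variant, "germline_support"))
            continue
        kept.append(variant)
    if dropped:
        logger.info(
            "exclusion filters removed %d of %d variants", len(dropped), len(table.variants)
        )
    return table.subset(kept), dropped


__all__ = [
    "DEFAULT_MIN_COVERAGE",
    "DEFAULT_MIN_ALT_READS",
    "FilterDecision",
    "passes_calling_thresholds",
    "apply_exclusion_filters",
]
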