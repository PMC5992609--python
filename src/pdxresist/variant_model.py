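"""Core data types for variants, sample roles and per-sample allele counts.

The pipeline consumes *allele counts*, not reads: for every variant and every
sample role (germline, parental xenograft, one or more treatment-adapted
xenografts) it records how many sequencing reads supported the mutant allele
out of how many covered the locus.  Two states are deliberately distinct:

* a variant/sample pair **absent from the input** — no statement about the
  locus can be made for that sample;
* a variant **observed with zero mutant reads** at some coverage — positive
  evidence of absence, which is what certifying a de novo or depleted call
  requires.

Coordinates are 1-based inclusive (VCF convention).  Multi-allelic VCF
records are split into one variant per alternate allele.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import (
    ConfigurationError,
    ParseError,
    RoleMappingError,
    UndefinedAlleleFractionError,
    ValidationError,
)

#: Closed vocabulary of variant consequences the pipeline understands.
CONSEQUENCES = frozenset(
    {
        "frameshift",
        "nonsense",
        "splice_site",
        "missense",
        "synonymous",
        "intronic",
        "utr",
        "inframe_indel",
    }
)

#: Consequences retained by the somatic exclusion filters (everything else is
#: excluded as presumed-neutral annotation classes).
RETAINED_CONSEQUENCES = frozenset({"frameshift", "nonsense", "splice_site", "missense"})

TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "is_common",
    "sample",
    "alt_reads",
    "total_reads",
]

#: (chrom, pos, ref, alt) — the coordinate identity of a variant.
VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class GenomicVariant:
    """A single-nucleotide or small indel variant with its annotation.

    ``is_common`` means "present in dbSNP with a population minor allele
    frequency > 1%" and marks the variant for removal as presumed germline
    polymorphism rather than somatic mutation.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    is_common: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"unknown consequence {self.consequence!r}; expected one of {sorted(CONSEQUENCES)}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantObservation:
    """Alt/total read counts for one variant in one sample."""

    alt_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.alt_reads < 0 or self.total_reads < 0:
            raise ValidationError("read counts must be non-negative")
        if self.alt_reads > self.total_reads:
            raise ValidationError(
                f"alt_reads ({self.alt_reads}) exceeds total_reads ({self.total_reads})"
            )


def allele_fraction(obs: VariantObservation) -> float:
    """Mutant-read fraction: alt_reads / total_reads.

    Raises
    ------
    UndefinedAlleleFractionError
        If the locus has zero total reads (the fraction is undefined, not 0).
    """
    if obs.total_reads == 0:
        raise UndefinedAlleleFractionError("allele fraction undefined at zero coverage")
    return obs.alt_reads / obs.total_reads


@dataclass(frozen=True)
class SampleRoles:
    """Mapping from study roles to sample identifiers.

    ``adapted`` is an ordered list of ``(arm_name, sample_id)`` pairs, one per
    treatment arm (e.g. cisplatin, fluorouracil, lurbinectedin, olaparib).
    """

    germline: str
    parental: str
    adapted: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.adapted:
            raise ConfigurationError("at least one adapted arm is required")
        ids = [self.germline, self.parental] + [s for _, s in self.adapted]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"sample identifiers must be unique, got {ids}")
        arms = [a for a, _ in self.adapted]
        if len(set(arms)) != len(arms):
            raise ConfigurationError(f"arm names must be unique, got {arms}")

    @property
    def arm_names(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.adapted)

    @property
    def all_samples(self) -> tuple[str, ...]:
        return (self.germline, self.parental) + tuple(s for _, s in self.adapted)

    def sample_for_arm(self, arm: str) -> str:
        for name, sample in self.adapted:
            if name == arm:
                return sample
        raise ConfigurationError(f"unknown adapted arm {arm!r}")


@dataclass
class VariantTable:
    """All variants of a cohort plus their per-sample observations.

    ``observations`` maps ``(variant_key, sample_id)`` to an observation; a
    missing key means the pair was absent from the input.
    """

    variants: list[GenomicVariant] = field(default_factory=list)
    observations: dict[tuple[VariantKey, str], VariantObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate variant keys in table")

    def get(self, variant: GenomicVariant | VariantKey, sample: str) -> VariantObservation | None:
        key = variant.key if isinstance(variant, GenomicVariant) else variant
        return self.observations.get((key, sample))

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[GenomicVariant]:
        return iter(self.variants)

    def subset(self, keep: Iterable[GenomicVariant]) -> "VariantTable":
        """New table restricted to ``keep``; observation values are shared, not copied."""
        keep = list(keep)
        kept_keys = {v.key for v in keep}
        obs = {
            (key, sample): o
            for (key, sample), o in self.observations.items()
            if key in kept_keys
        }
        return VariantTable(variants=keep, observations=obs)


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in {"true", "1", "yes"}:
        return True
    if t in {"false", "0", "no", ""}:
        return False
    raise ValueError(f"cannot interpret {text!r} as boolean")


def _read_tsv(path: Path, roles: SampleRoles) -> VariantTable:
    known_samples = set(roles.all_samples)
    variants: dict[VariantKey, GenomicVariant] = {}
    observations: dict[tuple[VariantKey, str], VariantObservation] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file")
        missing = set(TSV_COLUMNS) - {"is_common"} - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                variant = GenomicVariant(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    gene=row["gene"],
                    consequence=row["consequence"],
                    is_common=_parse_bool(row.get("is_common", "false") or "false"),
                )
                obs = VariantObservation(int(row["alt_reads"]), int(row["total_reads"]))
            except (KeyError, ValueError, TypeError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
            sample = row["sample"]
            if sample not in known_samples:
                raise RoleMappingError(
                    f"{path}:{lineno}: sample {sample!r} matches no declared role "
                    f"(known: {sorted(known_samples)})"
                )
            existing = variants.get(variant.key)
            if existing is None:
                variants[variant.key] = variant
            elif existing != variant:
                raise ParseError(
                    f"{path}:{lineno}: variant {variant.key} re-declared with different annotation"
                )
            if (variant.key, sample) in observations:
                raise ParseError(f"{path}:{lineno}: duplicate observation for {variant.key}/{sample}")
            observations[(variant.key, sample)] = obs
    return VariantTable(variants=list(variants.values()), observations=observations)


def _read_vcf(path: Path, roles: SampleRoles) -> VariantTable:
    from cyvcf2 import VCF  # deferred: htslib handles are costly to set up

    vcf = VCF(str(path))
    known = set(roles.all_samples)
    file_samples = list(vcf.samples)
    unknown = [s for s in file_samples if s not in known]
    if unknown:
        raise RoleMappingError(f"{path}: VCF samples {unknown} match no declared role")
    variants: dict[VariantKey, GenomicVariant] = {}
    observations: dict[tuple[VariantKey, str], VariantObservation] = {}
    for rec in vcf:
        ad = rec.format("AD")
        dp = rec.format("DP")
        if ad is None or dp is None:
            raise ParseError(f"{path}: record {rec.CHROM}:{rec.POS} lacks AD/DP per-sample fields")
        gene = rec.INFO.get("GENE")
        csq = rec.INFO.get("CSQ")
        common = bool(rec.INFO.get("COMMON", False))
        if gene is None or csq is None:
            raise ParseError(f"{path}: record {rec.CHROM}:{rec.POS} lacks GENE/CSQ INFO annotation")
        # multi-allelic records are split into one variant per alternate allele
        for alt_index, alt in enumerate(rec.ALT, start=1):
            try:
                variant = GenomicVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    gene=str(gene),
                    consequence=str(csq),
                    is_common=common,
                )
            except ValidationError as exc:
                raise ParseError(f"{path}: record {rec.CHROM}:{rec.POS}: {exc}") from exc
            variants.setdefault(variant.key, variant)
            for sample_index, sample in enumerate(file_samples):
                alt_reads = int(ad[sample_index][alt_index])
                total = int(dp[sample_index][0])
                if alt_reads < 0:  # htslib encodes missing as negative
                    continue
                try:
                    obs = VariantObservation(alt_reads, total)
                except ValidationError as exc:
                    raise ValidationError(
                        f"{path}: {rec.CHROM}:{rec.POS} sample {sample}: {exc}"
                    ) from exc
                observations[(variant.key, sample)] = obs
    return VariantTable(variants=list(variants.values()), observations=observations)


def read_variant_table(path: str | Path, roles: SampleRoles, format: str = "tsv") -> VariantTable:
    """Read per-sample allele counts from a TSV or VCF file.

    The TSV layout is one row per (variant, sample) with columns
    ``chrom pos ref alt gene consequence [is_common] sample alt_reads total_reads``.
    A VCF must carry per-sample ``AD``/``DP`` FORMAT fields and ``GENE``/``CSQ``
    INFO annotations.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    if format == "tsv":
        return _read_tsv(path, roles)
    if format == "vcf":
        return _read_vcf(path, roles)
    raise ConfigurationError(f"unknown variant-table format {format!r}")


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    """Write a table as the TSV layout ``read_variant_table`` accepts (round-trips)."""
    path = Path(path)
    by_key = {v.key: v for v in table.variants}
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for (key, sample), obs in sorted(table.observations.items()):
            v = by_key[key]
            writer.writerow(
                [v.chrom, v.pos, v.ref, v.alt, v.gene, v.consequence,
                 str(v.is_common).lower(), sample, obs.alt_reads, obs.total_reads]
            )


__all__ = [
    "CONSEQUENCES",
    "RETAINED_CONSEQUENCES",
    "GenomicVariant",
    "VariantObservation",
    "SampleRoles",
    "VariantTable",
    "VariantKey",
    "allele_fraction",
    "read_variant_table",
    "write_variant_table",
]
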