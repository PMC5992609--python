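"""Synthetic cohorts with planted ground truth for every pipeline stage.

No sequencing data accompanies the resistance-modeling study this pipeline
re-implements, so every input is emulated with known truth:

* an exome-like variant cohort over six sample roles (germline, parental
  xenograft, four treatment-adapted xenografts) with planted de novo /
  depleted / enriched / unchanged mutations, germline and dbSNP-common
  contaminants and excluded consequence classes;
* a gene x cell-line expression matrix and a drug IC50 profile with a planted
  negatively correlated gene set;
* a deep-amplicon pileup with a planted background error rate and planted
  mutations.

Read counts follow a negative-binomial coverage model around the configured
mean (80x by default, the exome regime) with binomially sampled mutant reads
at each variant's true allele fraction.  A ``noise_free`` mode replaces the
sampling with its rounded expectation so classifier-recovery tests are
deterministic.

The default cohort structure mirrors the published study's headline numbers:
187 somatic mutations — 64 de novo (55 private to a single arm), 43 depleted
(each completely depleted in >= 1 arm; 36 shared by all four arms, 19 of
those also partially depleted in some arm), 22 enriched (17 private) and 58
shared-unchanged — with consequence counts 6 frameshift / 7 nonsense /
1 splice site / 173 missense.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .targeted_seq_error import BASE_COLUMNS, AmpliconPileup
from .variant_model import (
    GenomicVariant,
    SampleRoles,
    VariantObservation,
    VariantTable,
)

DEFAULT_ARMS = ("cisplatin", "fluorouracil", "lurbinectedin", "olaparib")

#: Per-consequence counts of the default somatic cohort.
DEFAULT_CONSEQUENCE_COUNTS = {
    "frameshift": 6,
    "nonsense": 7,
    "splice_site": 1,
    "missense": 173,
}

#: Fraction of each mutation family planted as deleterious (non-missense
#: consequences are deleterious by definition and count toward the target).
DEFAULT_DELETERIOUS_FRACTIONS = {
    "de_novo": 0.60,
    "enriched": 0.70,
    "depleted": 0.50,
    "partially_depleted": 0.40,
    "common_unchanged": 0.50,
}

_EXCLUDED_CONSEQUENCES = ("synonymous", "intronic", "utr", "inframe_indel")
_NON_BOTH_PREDICTIONS = (
    ("tolerated", "benign"),
    ("deleterious", "benign"),
    ("tolerated", "deleterious"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the three simulators; ``seed`` is mandatory."""

    seed: int
    arms: tuple[str, ...] = DEFAULT_ARMS
    mean_coverage: float = 80.0
    dispersion: float = 0.1
    noise_free: bool = False

    # cohort structure
    n_de_novo: int = 64
    n_de_novo_single: int = 55
    n_depleted: int = 43
    n_depleted_shared: int = 36
    n_depleted_mixed: int = 19
    n_enriched: int = 22
    n_enriched_single: int = 17
    n_common_unchanged: int = 58
    n_germline_contaminant: int = 25
    n_common_snp: int = 25
    n_excluded_consequence: int = 25

    # true allele fractions per family
    de_novo_af: float = 0.30
    depleted_parental_af: float = 0.40
    partial_adapted_af: float = 0.15
    enriched_parental_af: float = 0.05
    enriched_adapted_af: float = 0.30
    unchanged_af: float = 0.30

    consequence_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_COUNTS)
    )
    deleterious_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DELETERIOUS_FRACTIONS)
    )

    # expression / drug response simulator
    n_genes: int = 1000
    n_cell_lines: int = 200
    planted_rho: float = -0.4
    planted_set_size: int = 20
    drug_name: str = "cisplatin"

    # pathway-collection simulator
    n_pathways: int = 20
    pathway_size: int = 10

    # amplicon simulator
    amplicon_length: int = 500
    amplicon_mean_coverage: float = 2000.0
    amplicon_error_rate: float = 0.002
    planted_mutations: tuple[tuple[float, str], ...] = (
        (0.30, "sub"),
        (0.05, "sub"),
        (0.001, "sub"),
        (0.004, "ins"),
    )

    def __post_init__(self) -> None:
        counts = [
            self.n_de_novo, self.n_depleted, self.n_enriched, self.n_common_unchanged,
            self.n_germline_contaminant, self.n_common_snp, self.n_excluded_consequence,
        ]
        if any(c < 0 for c in counts):
            raise ValidationError("category counts must be non-negative")
        if not self.arms:
            raise ValidationError("at least one adapted arm is required")
        if self.n_de_novo_single > self.n_de_novo:
            raise ValidationError("n_de_novo_single exceeds n_de_novo")
        if self.n_depleted_shared > self.n_depleted:
            raise ValidationError("n_depleted_shared exceeds n_depleted")
        if self.n_depleted_mixed > self.n_depleted_shared:
            raise ValidationError("n_depleted_mixed exceeds n_depleted_shared")
        if self.n_enriched_single > self.n_enriched:
            raise ValidationError("n_enriched_single exceeds n_enriched")
        afs = [
            self.de_novo_af, self.depleted_parental_af, self.partial_adapted_af,
            self.enriched_parental_af, self.enriched_adapted_af, self.unchanged_af,
        ]
        if any(not 0.0 <= a <= 1.0 for a in afs):
            raise ValidationError("allele fractions must lie in [0, 1]")
        if self.mean_coverage <= 0 or self.dispersion < 0:
            raise ValidationError("mean_coverage must be positive and dispersion non-negative")
        if not 0.0 <= self.amplicon_error_rate < 1.0:
            raise ValidationError("amplicon error rate must lie in [0, 1)")

    @property
    def n_somatic(self) -> int:
        return self.n_de_novo + self.n_depleted + self.n_enriched + self.n_common_unchanged

    def roles(self) -> SampleRoles:
        return SampleRoles(
            germline="germline",
            parental="parental",
            adapted=tuple((arm, f"adapted_{arm}") for arm in self.arms),
        )


@dataclass
class PlantedTruth:
    """Ground truth of one simulation; only the relevant fields are set.

    ``variant_truth`` has one row per simulated variant (family, consequence,
    deleterious flag, prediction labels); ``arm_truth`` one row per
    (somatic variant, arm) with the expected classification status.
    """

    variant_truth: pd.DataFrame | None = None
    arm_truth: pd.DataFrame | None = None
    predictions: pd.DataFrame | None = None
    planted_genes: list[str] | None = None
    rho: float | None = None
    error_rate: float | None = None
    amplicon_mutations: pd.DataFrame | None = None


def _coverage(rng: np.random.Generator, config: SimulationConfig, mean: float, size: int) -> np.ndarray:
    if config.noise_free:
        return np.full(size, int(round(mean)), dtype=np.int64)
    if config.dispersion == 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    n = 1.0 / config.dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size).astype(np.int64)


def _alt_reads(rng: np.random.Generator, config: SimulationConfig, coverage: np.ndarray, af: float) -> np.ndarray:
    if af == 0.0:
        return np.zeros_like(coverage)
    if config.noise_free:
        return np.round(coverage * af).astype(np.int64)
    return rng.binomial(coverage, af)


def _alleles_for(consequence: str, i: int) -> tuple[str, str]:
    bases = "ACGT"
    ref = bases[i % 4]
    if consequence == "frameshift":
        return ref + "T", ref  # single-base deletion
    if consequence == "inframe_indel":
        return ref + "TTT", ref  # 3-base deletion
    return ref, bases[(i + 1) % 4]


def _round_robin(items: Sequence, bins: Sequence[str]) -> dict:
    assignment = {}
    cycle = itertools.cycle(bins)
    for item in items:
        assignment[item] = next(cycle)
    return assignment


def simulate_variant_cohort(config: SimulationConfig) -> tuple[VariantTable, PlantedTruth]:
    """Simulate per-sample allele counts with planted classification truth.

    Families and their per-arm expected statuses:

    * ``de_novo`` — absent from parental (AF 0); carried at ``de_novo_af`` in
      one arm (single) or all arms (shared), absent elsewhere.
    * ``depleted`` — parental AF ``depleted_parental_af``; completely depleted
      (AF 0) or partially depleted (``partial_adapted_af``) per arm, unchanged
      in arms not involved.  Every depleted variant is completely depleted in
      at least one arm.
    * ``enriched`` — parental ``enriched_parental_af``; ``enriched_adapted_af``
      in enriched arms, unchanged elsewhere.
    * ``common_unchanged`` — ``unchanged_af`` everywhere.
    * contaminant families (germline, dbSNP-common, excluded consequence) that
      the exclusion filters must remove.
    """
    rng = np.random.default_rng(config.seed)
    roles = config.roles()
    arms = list(config.arms)
    n_arms = len(arms)

    # --- per-variant plan: family, parental AF, per-arm (status, adapted AF)
    plans: list[dict] = []

    def _plan(family: str, parental_af: float, per_arm: dict[str, tuple[str, float]]) -> None:
        plans.append({"family": family, "parental_af": parental_af, "arms": per_arm})

    # de novo: singles round-robin over arms, the rest present in every arm
    singles = _round_robin(range(config.n_de_novo_single), arms)
    for i in range(config.n_de_novo):
        if i < config.n_de_novo_single:
            home = singles[i]
            per_arm = {
                arm: (("de_novo", config.de_novo_af) if arm == home else ("absent", 0.0))
                for arm in arms
            }
        else:
            per_arm = {arm: ("de_novo", config.de_novo_af) for arm in arms}
        _plan("de_novo", 0.0, per_arm)

    # depleted: shared variants are depleted in every arm; "mixed" ones are
    # completely depleted in the first half of the arms and partially in the
    # rest; singles are completely depleted in one arm, unchanged elsewhere
    n_pure_shared = config.n_depleted_shared - config.n_depleted_mixed
    n_single = config.n_depleted - config.n_depleted_shared
    dep_singles = _round_robin(range(n_single), arms)
    half = max(1, n_arms // 2)
    for i in range(config.n_depleted):
        if i < n_pure_shared:
            per_arm = {arm: ("completely_depleted", 0.0) for arm in arms}
        elif i < config.n_depleted_shared:
            per_arm = {
                arm: (
                    ("completely_depleted", 0.0)
                    if j < half
                    else ("partially_depleted", config.partial_adapted_af)
                )
                for j, arm in enumerate(arms)
            }
        else:
            home = dep_singles[i - config.n_depleted_shared]
            per_arm = {
                arm: (
                    ("completely_depleted", 0.0)
                    if arm == home
                    else ("common_unchanged", config.depleted_parental_af)
                )
                for arm in arms
            }
        _plan("depleted", config.depleted_parental_af, per_arm)

    # enriched
    enr_singles = _round_robin(range(config.n_enriched_single), arms)
    for i in range(config.n_enriched):
        if i < config.n_enriched_single:
            home = enr_singles[i]
            per_arm = {
                arm: (
                    ("enriched", config.enriched_adapted_af)
                    if arm == home
                    else ("common_unchanged", config.enriched_parental_af)
                )
                for arm in arms
            }
        else:
            per_arm = {arm: ("enriched", config.enriched_adapted_af) for arm in arms}
        _plan("enriched", config.enriched_parental_af, per_arm)

    for _ in range(config.n_common_unchanged):
        _plan(
            "common_unchanged",
            config.unchanged_af,
            {arm: ("common_unchanged", config.unchanged_af) for arm in arms},
        )

    n_somatic = len(plans)

    # --- consequences: exact counts, shuffled over the somatic variants
    consequence_pool: list[str] = []
    for csq, count in config.consequence_counts.items():
        consequence_pool.extend([csq] * count)
    if len(consequence_pool) != n_somatic:
        raise ValidationError(
            f"consequence counts sum to {len(consequence_pool)} but the cohort has "
            f"{n_somatic} somatic variants"
        )
    order = rng.permutation(n_somatic)
    consequences = [""] * n_somatic
    for slot, csq in zip(order, consequence_pool):
        consequences[slot] = csq
    for plan, csq in zip(plans, consequences):
        plan["consequence"] = csq

    # --- deleteriousness: per family a target count; truncating consequences
    # are deleterious by definition, the remainder is planted on missense
    # variants via both-algorithm-damaging prediction labels
    fam_pred = {
        "de_novo": lambda p: "de_novo",
        "enriched": lambda p: "enriched",
        "common_unchanged": lambda p: "common_unchanged",
        "depleted": lambda p: "depleted",
    }
    by_family: dict[str, list[dict]] = {}
    for plan in plans:
        by_family.setdefault(fam_pred[plan["family"]](plan), []).append(plan)
    for plan in plans:
        plan["deleterious"] = plan["consequence"] in {"frameshift", "nonsense", "splice_site"}

    def _top_up(members: list[dict], target: int, pool: list[dict] | None = None) -> None:
        already = sum(p["deleterious"] for p in members)
        pool = members if pool is None else pool
        missense = [p for p in pool if p["consequence"] == "missense" and not p["deleterious"]]
        need = max(0, target - already)
        picks = rng.permutation(len(missense))[:need]
        for idx in picks:
            missense[idx]["deleterious"] = True

    fractions = config.deleterious_fractions
    # mixed depleted variants (those also partially depleted somewhere) get
    # the lower partially-depleted fraction; the family target then tops up
    # the purely completely-depleted variants only
    depleted = by_family.get("depleted", [])
    mixed = [p for p in depleted if any(s == "partially_depleted" for s, _ in p["arms"].values())]
    pure = [p for p in depleted if p not in mixed]
    _top_up(mixed, int(round(fractions.get("partially_depleted", 0.4) * len(mixed))))
    _top_up(depleted, int(round(fractions.get("depleted", 0.5) * len(depleted))), pool=pure)
    for family in ("de_novo", "enriched", "common_unchanged"):
        members = by_family.get(family, [])
        _top_up(members, int(round(fractions.get(family, 0.5) * len(members))))

    # --- contaminant families
    for i in range(config.n_germline_contaminant):
        af = 0.5 if i % 2 == 0 else 1.0
        plans.append(
            {
                "family": "germline_contaminant",
                "parental_af": af,
                "germline_af": af,
                "arms": {arm: ("filtered", af) for arm in arms},
                "consequence": "missense",
                "deleterious": False,
            }
        )
    for _ in range(config.n_common_snp):
        plans.append(
            {
                "family": "common_snp",
                "parental_af": 0.5,
                "germline_af": 0.5,
                "arms": {arm: ("filtered", 0.5) for arm in arms},
                "consequence": "missense",
                "deleterious": False,
                "is_common": True,
            }
        )
    for i in range(config.n_excluded_consequence):
        csq = _EXCLUDED_CONSEQUENCES[i % len(_EXCLUDED_CONSEQUENCES)]
        plans.append(
            {
                "family": "excluded_consequence",
                "parental_af": config.unchanged_af,
                "arms": {arm: ("filtered", config.unchanged_af) for arm in arms},
                "consequence": csq,
                "deleterious": False,
            }
        )

    # --- materialise variants and observations
    variants: list[GenomicVariant] = []
    observations: dict = {}
    truth_rows = []
    arm_rows = []
    pred_rows = []
    non_both = itertools.cycle(_NON_BOTH_PREDICTIONS)
    for i, plan in enumerate(plans):
        ref, alt = _alleles_for(plan["consequence"], i)
        variant = GenomicVariant(
            chrom=f"chr{(i % 22) + 1}",
            pos=10_000 + 50 * i,
            ref=ref,
            alt=alt,
            gene=f"GENE{i:04d}",
            consequence=plan["consequence"],
            is_common=bool(plan.get("is_common", False)),
        )
        variants.append(variant)
        sample_afs = {"germline": plan.get("germline_af", 0.0), "parental": plan["parental_af"]}
        for arm in arms:
            sample_afs[f"adapted_{arm}"] = plan["arms"][arm][1]
        cov = _coverage(rng, config, config.mean_coverage, len(sample_afs))
        for (sample, af), c in zip(sample_afs.items(), cov):
            alt_n = int(_alt_reads(rng, config, np.array([c]), af)[0])
            observations[(variant.key, sample)] = VariantObservation(alt_n, int(c))
        truth_rows.append(
            {
                "chrom": variant.chrom, "pos": variant.pos, "ref": ref, "alt": alt,
                "gene": variant.gene, "family": plan["family"],
                "consequence": plan["consequence"], "deleterious": plan["deleterious"],
            }
        )
        for arm in arms:
            arm_rows.append(
                {
                    "chrom": variant.chrom, "pos": variant.pos, "ref": ref, "alt": alt,
                    "gene": variant.gene, "arm": arm, "true_status": plan["arms"][arm][0],
                }
            )
        if plan["consequence"] == "missense":
            sift, polyphen = (
                ("deleterious", "deleterious") if plan["deleterious"] else next(non_both)
            )
            pred_rows.append(
                {"chrom": variant.chrom, "pos": variant.pos, "ref": ref, "alt": alt,
                 "sift": sift, "polyphen": polyphen}
            )

    table = VariantTable(variants=variants, observations=observations)
    truth = PlantedTruth(
        variant_truth=pd.DataFrame(truth_rows),
        arm_truth=pd.DataFrame(arm_rows),
        predictions=pd.DataFrame(pred_rows),
    )
    return table, truth


def simulate_expression_drug(
    config: SimulationConfig,
    gene_names: Sequence[str] | None = None,
    planted_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Expression matrix and drug IC50 profile with a planted correlated set.

    The IC50 vector is standard normal across cell lines; each planted gene's
    expression is bivariate-normal with correlation ``planted_rho`` to it, all
    other genes are independent noise.  Pass ``gene_names``/``planted_genes``
    to align the simulation with a variant cohort's gene symbols.
    """
    if not abs(config.planted_rho) < 1.0:
        raise ValidationError("planted correlation must satisfy |rho| < 1")
    rng = np.random.default_rng(config.seed)
    if gene_names is None:
        gene_names = [f"GENE{i:04d}" for i in range(config.n_genes)]
    gene_names = list(gene_names)
    if planted_genes is None:
        planted_genes = gene_names[: config.planted_set_size]
    planted_genes = list(planted_genes)
    unknown = set(planted_genes) - set(gene_names)
    if unknown:
        raise ValidationError(f"planted genes absent from the gene list: {sorted(unknown)}")
    cells = [f"CL{i:04d}" for i in range(config.n_cell_lines)]
    ic50 = rng.standard_normal(config.n_cell_lines)
    expr = rng.standard_normal((len(gene_names), config.n_cell_lines))
    rho = config.planted_rho
    planted_idx = [gene_names.index(g) for g in planted_genes]
    expr[planted_idx, :] = rho * ic50 + np.sqrt(1.0 - rho**2) * expr[planted_idx, :]
    matrix = pd.DataFrame(expr, index=pd.Index(gene_names, name="gene"), columns=cells)
    drug = pd.Series(ic50, index=cells, name=config.drug_name)
    truth = PlantedTruth(planted_genes=planted_genes, rho=rho)
    return matrix, drug, truth


def simulate_pathway_collection(
    config: SimulationConfig,
    universe: Sequence[str],
    planted_genes: Sequence[str],
) -> tuple[dict[str, set[str]], str]:
    """Pathway sets over ``universe`` with one pathway planted inside
    ``planted_genes`` (over-represented by construction) plus random
    background pathways.  Returns (sets, planted pathway name)."""
    rng = np.random.default_rng(config.seed)
    universe = list(universe)
    planted_genes = [g for g in planted_genes if g in set(universe)]
    if not planted_genes:
        raise ValidationError("no planted gene is part of the universe")
    size = min(config.pathway_size, len(planted_genes))
    planted = set(rng.choice(planted_genes, size=size, replace=False))
    sets = {"PLANTED_PATHWAY": planted}
    for i in range(config.n_pathways):
        members = rng.choice(universe, size=min(config.pathway_size + 5, len(universe)), replace=False)
        sets[f"BACKGROUND_{i:02d}"] = set(members)
    return sets, "PLANTED_PATHWAY"


def simulate_amplicon_pileup(config: SimulationConfig) -> tuple[AmpliconPileup, PlantedTruth]:
    """Deep-amplicon pileup with planted background errors and mutations.

    Every position draws its coverage around ``amplicon_mean_coverage``;
    non-reference calls arrive binomially at ``amplicon_error_rate`` and are
    spread over the three non-reference bases.  Planted mutations add mutant
    calls at their allele fraction on top of the background and are flagged
    (excluded from error estimation).
    """
    rng = np.random.default_rng(config.seed)
    length = config.amplicon_length
    if len(config.planted_mutations) > length:
        raise ValidationError("more planted mutations than amplicon positions")
    positions = np.arange(1, length + 1)
    ref = np.array(list("ACGT" * (length // 4 + 1)))[:length]
    coverage = _coverage(rng, config, config.amplicon_mean_coverage, length)
    counts = np.zeros((length, len(BASE_COLUMNS)), dtype=np.int64)
    eps = config.amplicon_error_rate
    if config.noise_free:
        n_err = np.round(coverage * eps).astype(np.int64)
    else:
        n_err = rng.binomial(coverage, eps)
    base_index = {b: i for i, b in enumerate(BASE_COLUMNS)}
    for i in range(length):
        ref_i = base_index[ref[i]]
        counts[i, ref_i] = coverage[i] - n_err[i]
        others = [base_index[b] for b in "ACGT" if b != ref[i]]
        if n_err[i] > 0:
            if config.noise_free:
                counts[i, others[0]] += n_err[i]
            else:
                split = rng.multinomial(n_err[i], [1 / 3] * 3)
                for o, k in zip(others, split):
                    counts[i, o] += k

    mut_positions = rng.choice(length, size=len(config.planted_mutations), replace=False)
    flagged = np.zeros(length, dtype=bool)
    mut_rows = []
    for (af, kind), idx in zip(config.planted_mutations, mut_positions):
        flagged[idx] = True
        mutant = int(_alt_reads(rng, config, coverage[[idx]], af)[0])
        ref_i = base_index[ref[idx]]
        if kind == "sub":
            target = [base_index[b] for b in "ACGT" if b != ref[idx]][0]
        elif kind in ("ins", "del"):
            target = base_index[kind]
        else:
            raise ValidationError(f"unknown planted mutation kind {kind!r}")
        take = min(mutant, int(counts[idx, ref_i]))
        counts[idx, ref_i] -= take  # mutant calls replace reference calls
        counts[idx, target] += mutant
        total = counts[idx].sum()
        mut_rows.append(
            {"pos": int(positions[idx]), "kind": kind, "true_af": af,
             "observed_af": float(mutant / total) if total else 0.0,
             "is_indel": kind != "sub"}
        )
    pileup = AmpliconPileup(positions=positions, ref=ref, counts=counts, flagged=flagged)
    mut_frame = pd.DataFrame(
        mut_rows, columns=["pos", "kind", "true_af", "observed_af", "is_indel"]
    )
    truth = PlantedTruth(
        error_rate=eps,
        amplicon_mutations=mut_frame.sort_values("pos").reset_index(drop=True),
    )
    return pileup, truth


def noise_free(config: SimulationConfig) -> SimulationConfig:
    """Copy of ``config`` with sampling replaced by rounded expectations."""
    return replace(config, noise_free=True)


__all__ = [
    "DEFAULT_ARMS",
    "DEFAULT_CONSEQUENCE_COUNTS",
    "DEFAULT_DELETERIOUS_FRACTIONS",
    "SimulationConfig",
    "PlantedTruth",
    "simulate_variant_cohort",
    "simulate_expression_drug",
    "simulate_pathway_collection",
    "simulate_amplicon_pileup",
    "noise_free",
]
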