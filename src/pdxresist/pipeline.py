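"""End-to-end orchestration: filter → classify → impact → overlap → pathways → drug correlations.

A single YAML config drives the whole analysis.  Layout::

    roles:
      germline: germline
      parental: parental
      adapted:            # ordered arm -> sample id
        cisplatin: adapted_cisplatin
        olaparib: adapted_olaparib
    inputs:
      variant_table: cohort.tsv        # or .vcf with format: vcf
      format: tsv
      predictions: predictions.tsv     # optional; SIFT/PolyPhen labels
      gene_sets: pathways.gmt          # optional; pathway stage
      expression: expression.tsv       # optional; drug-correlation stage
      ic50: ic50.tsv                   # optional; drugs x cell lines
      drugs: [cisplatin]               # rows of ic50 to analyse
    params:
      min_coverage: 20
      min_alt_reads: 2
      fdr_level: 0.05
      min_delta: 0.10
      n_random_sets: 1000
      seed: 1

Optional stages run only when their inputs are present.  Every parameter in
effect is echoed into the JSON report so a run is self-describing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .drug_sensitivity_null import (
    DEFAULT_N_SETS,
    gene_set_negative_enrichment,
    negative_fdr_threshold,
    per_gene_drug_pcc,
    random_set_null,
)
from .errors import ConfigurationError, PdxResistError
from .functional_impact import ImpactLabel, classify_impact, read_prediction_labels, two_proportion_ztest
from .pathway_enrichment import GeneSetCollection, pathway_enrichment
from .resistance_classifier import (
    DEFAULT_FDR_LEVEL,
    DEFAULT_MIN_DELTA,
    ClassificationRecord,
    ResistanceStatus,
    classify_cohort,
    summarize_overlap,
)
from .somatic_filters import DEFAULT_MIN_ALT_READS, DEFAULT_MIN_COVERAGE, apply_exclusion_filters
from .variant_model import SampleRoles, VariantTable, read_variant_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """Analysis thresholds; defaults are the published calling rules."""

    min_coverage: int = DEFAULT_MIN_COVERAGE
    min_alt_reads: int = DEFAULT_MIN_ALT_READS
    fdr_level: float = DEFAULT_FDR_LEVEL
    min_delta: float = DEFAULT_MIN_DELTA
    n_random_sets: int = DEFAULT_N_SETS
    seed: int = 0


@dataclass
class PipelineConfig:
    roles: SampleRoles
    variant_table: Path
    table_format: str = "tsv"
    predictions: Path | None = None
    gene_sets: Path | None = None
    expression: Path | None = None
    ic50: Path | None = None
    drugs: list[str] = field(default_factory=list)
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        try:
            roles_raw = raw["roles"]
            adapted = roles_raw["adapted"]
        except KeyError as exc:
            raise ConfigurationError(f"{path}: missing roles section ({exc})") from exc
        if not isinstance(adapted, dict) or not adapted:
            raise ConfigurationError(f"{path}: roles.adapted must map arm names to sample ids")
        roles = SampleRoles(
            germline=roles_raw.get("germline", ""),
            parental=roles_raw.get("parental", ""),
            adapted=tuple(adapted.items()),
        )
        if not roles.germline or not roles.parental:
            raise ConfigurationError(f"{path}: germline and parental roles are required")
        inputs = raw.get("inputs", {})
        if "variant_table" not in inputs:
            raise ConfigurationError(f"{path}: inputs.variant_table is required")
        base = path.parent

        def _resolve(key: str) -> Path | None:
            value = inputs.get(key)
            return (base / value) if value else None

        params = PipelineParams(**raw.get("params", {}))
        return cls(
            roles=roles,
            variant_table=base / inputs["variant_table"],
            table_format=inputs.get("format", "tsv"),
            predictions=_resolve("predictions"),
            gene_sets=_resolve("gene_sets"),
            expression=_resolve("expression"),
            ic50=_resolve("ic50"),
            drugs=list(inputs.get("drugs", [])),
            params=params,
        )


def records_to_frame(records: list[ClassificationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.variant.chrom, "pos": r.variant.pos, "ref": r.variant.ref,
                "alt": r.variant.alt, "gene": r.variant.gene,
                "consequence": r.variant.consequence, "arm": r.arm,
                "status": r.status.value, "parental_af": r.parental_af,
                "adapted_af": r.adapted_af, "delta_af": r.delta_af,
                "fisher_p": r.fisher_p, "fdr_q": r.fdr_q,
            }
        )
    return pd.DataFrame(rows)


def _deleterious_by_category(
    records: list[ClassificationRecord],
    impacts: dict,
) -> dict[str, dict[str, int]]:
    """Distinct-variant deleterious counts per resistance category."""
    out: dict[str, dict[str, set]] = {}
    for r in records:
        if r.status is ResistanceStatus.UNDETERMINED:
            continue
        bucket = out.setdefault(r.status.value, {"deleterious": set(), "total": set()})
        bucket["total"].add(r.variant.key)
        if impacts.get(r.variant.key) is ImpactLabel.DELETERIOUS:
            bucket["deleterious"].add(r.variant.key)
    return {
        status: {"deleterious": len(b["deleterious"]), "total": len(b["total"])}
        for status, b in out.items()
    }


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path,
) -> dict[str, Any]:
    """Execute every configured stage; write per-stage TSVs and a JSON report.

    Returns the report dict.  Any stage failure aborts with a stage-named
    diagnostic; an ``incomplete`` marker file is left next to partial outputs.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "INCOMPLETE"
    marker.write_text("run in progress\n")
    params = config.params
    report: dict[str, Any] = {
        "parameters": asdict(params),
        "arms": list(config.roles.arm_names),
    }
    stage = "read"
    try:
        table = read_variant_table(config.variant_table, config.roles, config.table_format)
        report["n_input_variants"] = len(table)

        stage = "filter"
        somatic, dropped = apply_exclusion_filters(table, config.roles, params.min_coverage)
        report["n_somatic_variants"] = len(somatic)
        report["filter_reasons"] = (
            pd.Series([d.reason for d in dropped]).value_counts().to_dict() if dropped else {}
        )

        stage = "classify"
        records = classify_cohort(
            somatic, config.roles,
            fdr_level=params.fdr_level, min_delta=params.min_delta,
            min_coverage=params.min_coverage, min_alt_reads=params.min_alt_reads,
        )
        frame = records_to_frame(records)
        frame.to_csv(out_dir / "classification.tsv", sep="\t", index=False)

        stage = "overlap"
        summary = summarize_overlap(records)
        report["per_arm_status_counts"] = summary.per_arm_status_counts
        report["arm_multiplicity"] = {
            s: {str(k): v for k, v in mult.items()} for s, mult in summary.arm_multiplicity.items()
        }
        report["category_totals"] = {
            s: summary.status_total(s)
            for s in ("de_novo", "completely_depleted", "enriched", "partially_depleted")
        }
        report["depleted_pooled"] = {
            "total": summary.depleted_pooled_total,
            "shared_all_arms": len(summary.depleted_pooled_shared_all),
            "multiplicity": {str(k): v for k, v in summary.depleted_pooled_multiplicity.items()},
        }

        stage = "impact"
        labels = read_prediction_labels(config.predictions) if config.predictions else {}
        impacts = {
            v.key: classify_impact(v.consequence, labels.get(v.key))
            for v in somatic.variants
        }
        by_category = _deleterious_by_category(records, impacts)
        report["deleterious_by_category"] = by_category
        if {"enriched", "partially_depleted"} <= by_category.keys():
            enr, dep = by_category["enriched"], by_category["partially_depleted"]
            z, p = two_proportion_ztest(
                enr["deleterious"], enr["total"], dep["deleterious"], dep["total"]
            )
            report["enriched_vs_partially_depleted"] = {"z": z, "p": p}

        acquired_deleterious = sorted(
            {
                r.variant.gene
                for r in records
                if r.status in (ResistanceStatus.DE_NOVO, ResistanceStatus.ENRICHED)
                and impacts.get(r.variant.key) is ImpactLabel.DELETERIOUS
            }
        )
        report["n_acquired_deleterious_genes"] = len(acquired_deleterious)

        if config.gene_sets is not None:
            stage = "pathways"
            collection = GeneSetCollection.from_gmt(config.gene_sets)
            enrichment = pathway_enrichment(
                set(acquired_deleterious), collection, params.fdr_level
            )
            enrichment.to_csv(out_dir / "pathway_enrichment.tsv", sep="\t", index=False)
            report["significant_pathways"] = enrichment.loc[
                enrichment["significant"], "pathway"
            ].tolist()

        if config.expression is not None and config.ic50 is not None:
            stage = "drugcorr"
            expr = pd.read_csv(config.expression, sep="\t", index_col=0)
            ic50 = pd.read_csv(config.ic50, sep="\t", index_col=0)
            drug_report = {}
            for drug in config.drugs or list(ic50.index):
                if drug not in ic50.index:
                    raise ConfigurationError(f"drug {drug!r} not present in IC50 matrix")
                profile = ic50.loc[drug]
                correlations = per_gene_drug_pcc(expr, profile)
                correlations.to_csv(out_dir / f"pcc_{drug}.tsv", sep="\t")
                query = set(acquired_deleterious) & set(correlations.index)
                entry: dict[str, Any] = {
                    "n_genes_tested": int(len(correlations)),
                    "negative_fdr_threshold": negative_fdr_threshold(
                        correlations, params.fdr_level
                    ),
                }
                if query:
                    null = random_set_null(
                        len(query), expr, profile,
                        n_sets=params.n_random_sets, seed=params.seed,
                        correlations=correlations,
                    )
                    u, p = gene_set_negative_enrichment(
                        query, expr, profile, null, correlations=correlations
                    )
                    entry["query_size"] = len(query)
                    entry["mannwhitney_u"] = u
                    entry["mannwhitney_p"] = p
                drug_report[drug] = entry
            report["drug_sensitivity"] = drug_report
    except PdxResistError as exc:
        raise PdxResistError(f"stage {stage!r} failed: {exc}") from exc

    with open(out_dir / "summary.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    marker.unlink()
    logger.info("pipeline finished; report written to %s", out_dir / "summary.json")
    return report


__all__ = ["PipelineParams", "PipelineConfig", "run_pipeline", "records_to_frame"]
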