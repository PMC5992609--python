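"""Per-arm resistance classification: statuses, Fisher/FDR machinery, overlap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import bh_step_up, fisher_two_sided
from pdxresist.errors import ContractError, ValidationError
from pdxresist.resistance_classifier import (
    COMMON_BRANCH,
    ClassificationRecord,
    ResistanceStatus,
    bh_fdr,
    classify_cohort,
    classify_variant_status,
    fisher_af_shift,
    summarize_overlap,
)
from pdxresist.somatic_filters import apply_exclusion_filters
from pdxresist.synthetic_data import SimulationConfig, simulate_variant_cohort
from pdxresist.variant_model import (
    GenomicVariant,
    SampleRoles,
    VariantObservation,
    VariantTable,
)


def obs(alt, total):
    return VariantObservation(alt, total)


class TestStatusRules:
    @pytest.mark.parametrize(
        "parental,adapted,expected",
        [
            ((0, 25), (8, 40), ResistanceStatus.DE_NOVO),
            ((6, 25), (0, 22), ResistanceStatus.COMPLETELY_DEPLETED),
            ((0, 15), (8, 40), ResistanceStatus.UNDETERMINED),  # parental too shallow to certify absence
            ((6, 25), (0, 15), ResistanceStatus.UNDETERMINED),  # adapted too shallow
            ((1, 25), (9, 40), COMMON_BRANCH),                  # one read with 20x counts as present
            ((0, 25), (0, 40), ResistanceStatus.UNDETERMINED),  # absent everywhere
            ((0, 25), (1, 40), ResistanceStatus.UNDETERMINED),  # one adapted read cannot be called
        ],
    )
    def test_examples(self, parental, adapted, expected):
        result = classify_variant_status(obs(*parental), obs(*adapted), "missense")
        assert result is expected

    def test_missing_observations_are_undetermined(self):
        assert classify_variant_status(None, obs(8, 40), "missense") is ResistanceStatus.UNDETERMINED
        assert classify_variant_status(obs(0, 25), None, "missense") is ResistanceStatus.UNDETERMINED

    def test_frameshift_called_without_coverage_floor(self):
        # two mutant reads at 5x suffice on the adapted side; parental absence
        # still needs 20x certification
        assert classify_variant_status(obs(0, 25), obs(2, 5), "frameshift") is ResistanceStatus.DE_NOVO
        assert classify_variant_status(obs(0, 15), obs(2, 5), "frameshift") is ResistanceStatus.UNDETERMINED


class TestFisherShift:
    def test_identical_tables_give_p_one(self):
        p, delta = fisher_af_shift(obs(10, 20), obs(10, 20))
        assert p == 1.0 and delta == 0.0

    def test_extreme_table_matches_enumeration(self):
        # parental 1/11 vs adapted 10/11: enumeration sums the four tables no
        # more likely than the observed one (a = 0, 1, 10, 11)
        p, delta = fisher_af_shift(obs(1, 11), obs(10, 11), min_coverage=10)
        assert p == pytest.approx(fisher_two_sided(1, 10, 10, 1), rel=1e-12)
        assert p == pytest.approx(244 / 705432, rel=1e-9)
        assert delta == pytest.approx(9 / 11)

    def test_enrichment_example_matches_enumeration(self):
        p, delta = fisher_af_shift(obs(2, 20), obs(12, 20))
        assert p == pytest.approx(fisher_two_sided(2, 18, 12, 8), rel=1e-12)
        assert delta == pytest.approx(0.5)

    def test_precondition_violation_raises(self):
        with pytest.raises(ContractError):
            fisher_af_shift(obs(0, 40), obs(10, 40))
        with pytest.raises(ContractError):
            fisher_af_shift(obs(5, 19), obs(10, 40))

    @given(
        a=st.integers(1, 25), n1=st.integers(0, 24),
        c=st.integers(1, 25), n2=st.integers(0, 24),
    )
    def test_matches_enumeration_on_random_tables(self, a, n1, c, n2):
        parental = obs(a, a + n1 + 19)  # guarantee >= 20x
        adapted = obs(c, c + n2 + 19)
        p, _ = fisher_af_shift(parental, adapted)
        expected = fisher_two_sided(
            parental.alt_reads, parental.total_reads - parental.alt_reads,
            adapted.alt_reads, adapted.total_reads - adapted.alt_reads,
        )
        assert p == pytest.approx(expected, rel=1e-9, abs=1e-12)


class TestBhFdr:
    @pytest.mark.parametrize(
        "pvalues,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_examples(self, pvalues, expected):
        assert bh_fdr(pvalues) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_step_up_definition(self, pvalues):
        result = bh_fdr(pvalues)
        expected = bh_step_up(pvalues)
        assert result == pytest.approx(expected, rel=1e-12, abs=1e-12)
        for q, p in zip(result, pvalues):
            assert p - 1e-12 <= q <= 1.0 + 1e-12


def _single_variant_table(parental, adapted):
    variant = GenomicVariant("chr1", 100, "A", "T", "G1", "missense")
    roles = SampleRoles("GL", "PX", (("cisplatin", "CIS"),))
    table = VariantTable(
        variants=[variant],
        observations={
            (variant.key, "GL"): obs(0, 50),
            (variant.key, "PX"): parental,
            (variant.key, "CIS"): adapted,
        },
    )
    return table, roles


class TestClassifyCohort:
    def test_single_strong_shift_is_enriched(self):
        # 5% -> 30% at 200x as the only test: BH leaves the p untouched
        table, roles = _single_variant_table(obs(10, 200), obs(60, 200))
        (record,) = classify_cohort(table, roles)
        assert record.status is ResistanceStatus.ENRICHED
        assert record.fdr_q == record.fisher_p < 0.05
        assert record.delta_af == pytest.approx(0.25)

    def test_small_shift_fails_ten_percent_rule(self):
        # significant q but |delta| = 5 percentage points: stays unchanged
        table, roles = _single_variant_table(obs(50, 1000), obs(100, 1000))
        (record,) = classify_cohort(table, roles)
        assert record.fdr_q < 0.05
        assert abs(record.delta_af) < 0.10
        assert record.status is ResistanceStatus.COMMON_UNCHANGED

    def test_arm_without_common_pairs_has_no_fisher_values(self):
        table, roles = _single_variant_table(obs(0, 50), obs(30, 60))
        (record,) = classify_cohort(table, roles)
        assert record.status is ResistanceStatus.DE_NOVO
        assert record.fisher_p is None and record.fdr_q is None

    def test_empty_cohort_returns_empty(self):
        roles = SampleRoles("GL", "PX", (("cisplatin", "CIS"),))
        assert classify_cohort(VariantTable(), roles) == []

    def test_every_pair_gets_exactly_one_status(self, somatic_cohort):
        somatic, _, _, roles = somatic_cohort
        records = classify_cohort(somatic, roles)
        assert len(records) == len(somatic) * len(roles.adapted)
        pairs = {(r.variant.key, r.arm) for r in records}
        assert len(pairs) == len(records)


class TestPlantedRecovery:
    def test_noise_free_recovery_is_exact(self, somatic_cohort):
        """Every planted per-arm status is recovered verbatim on the
        noise-free cohort (planted 'absent' arms come back undetermined)."""
        somatic, _, truth, roles = somatic_cohort
        records = classify_cohort(somatic, roles)
        expected = truth.arm_truth.set_index(["chrom", "pos", "ref", "alt", "arm"])["true_status"]
        for record in records:
            want = expected.loc[record.variant.key + (record.arm,)]
            if want == "absent":
                want = "undetermined"
            assert record.status.value == want, (record.variant.key, record.arm)

    def test_power_monotone_in_coverage_and_shift(self):
        """Detection of planted enrichment rises with coverage and AF shift."""

        def recovery(coverage, adapted_af, seeds=range(4)):
            rates = []
            for seed in seeds:
                config = SimulationConfig(
                    seed=seed, mean_coverage=coverage,
                    n_de_novo=0, n_de_novo_single=0, n_depleted=0,
                    n_depleted_shared=0, n_depleted_mixed=0,
                    n_enriched=60, n_enriched_single=0,
                    n_common_unchanged=60,
                    n_germline_contaminant=0, n_common_snp=0, n_excluded_consequence=0,
                    enriched_adapted_af=adapted_af,
                    consequence_counts={"missense": 120},
                    arms=("cisplatin",),
                )
                table, truth = simulate_variant_cohort(config)
                somatic, _ = apply_exclusion_filters(table, config.roles())
                records = classify_cohort(somatic, config.roles())
                enriched_keys = set(
                    truth.arm_truth.query("true_status == 'enriched'")
                    .set_index(["chrom", "pos", "ref", "alt"]).index
                )
                hit = sum(
                    1 for r in records
                    if r.variant.key in enriched_keys and r.status is ResistanceStatus.ENRICHED
                )
                rates.append(hit / len(enriched_keys))
            return float(np.mean(rates))

        by_coverage = [recovery(c, 0.30) for c in (30, 100, 300)]
        assert by_coverage == sorted(by_coverage)
        by_shift = [recovery(100, af) for af in (0.15, 0.30, 0.55)]
        assert by_shift == sorted(by_shift)
        assert by_shift[-1] > 0.9

    def test_null_cohort_false_label_rate_controlled(self):
        """With no planted shifts, shared mutations are called enriched or
        partially depleted in at most ~5% of cases at FDR 5%."""
        flagged = total = 0
        for seed in range(5):
            config = SimulationConfig(
                seed=seed, n_de_novo=0, n_de_novo_single=0, n_depleted=0,
                n_depleted_shared=0, n_depleted_mixed=0, n_enriched=0,
                n_enriched_single=0, n_common_unchanged=150,
                n_germline_contaminant=0, n_common_snp=0, n_excluded_consequence=0,
                consequence_counts={"missense": 150},
            )
            table, _ = simulate_variant_cohort(config)
            somatic, _ = apply_exclusion_filters(table, config.roles())
            records = classify_cohort(somatic, config.roles())
            common = [
                r for r in records
                if r.status in (
                    ResistanceStatus.ENRICHED,
                    ResistanceStatus.PARTIALLY_DEPLETED,
                    ResistanceStatus.COMMON_UNCHANGED,
                )
            ]
            flagged += sum(r.status is not ResistanceStatus.COMMON_UNCHANGED for r in common)
            total += len(common)
        mc_error = 3 * np.sqrt(0.05 * 0.95 / total)
        assert flagged / total <= 0.05 + mc_error


def _record(variant, arm, status):
    return ClassificationRecord(variant, arm, status, None, None, None)


class TestSummarizeOverlap:
    def _variants(self, n):
        return [
            GenomicVariant("chr1", 100 + i, "A", "T", f"G{i}", "missense") for i in range(n)
        ]

    def test_full_overlap(self):
        (v,) = self._variants(1)
        records = [_record(v, arm, ResistanceStatus.DE_NOVO) for arm in "ABCD"]
        summary = summarize_overlap(records)
        assert summary.arm_multiplicity["de_novo"] == {4: 1}
        assert summary.single_arm_count("de_novo") == 0
        assert summary.shared_all_arms["de_novo"] == [v.key]

    def test_disjoint_sets(self):
        variants = self._variants(4)
        records = [
            _record(v, arm, ResistanceStatus.DE_NOVO) for v, arm in zip(variants, "ABCD")
        ]
        # pairs without the status still appear as records in other arms
        records += [
            _record(v, arm, ResistanceStatus.UNDETERMINED)
            for v in variants for arm in "ABCD"
            if _record(v, arm, ResistanceStatus.DE_NOVO) not in records
        ]
        summary = summarize_overlap(records)
        assert summary.single_arm_count("de_novo") == 4
        assert summary.shared_all_arms["de_novo"] == []

    def test_pooled_depletion_deduplicates_across_statuses(self):
        (v,) = self._variants(1)
        records = [
            _record(v, "A", ResistanceStatus.COMPLETELY_DEPLETED),
            _record(v, "B", ResistanceStatus.PARTIALLY_DEPLETED),
        ]
        summary = summarize_overlap(records)
        assert summary.depleted_pooled_total == 1
        assert summary.depleted_pooled_multiplicity == {2: 1}
        assert summary.depleted_pooled_shared_all == [v.key]

    def test_counts_sum_to_classified_pairs(self, somatic_cohort):
        somatic, _, _, roles = somatic_cohort
        records = classify_cohort(somatic, roles)
        summary = summarize_overlap(records)
        for arm in roles.arm_names:
            assert sum(summary.per_arm_status_counts[arm].values()) == len(somatic)
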