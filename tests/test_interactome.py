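import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apexflux import (
    ConfigError,
    NormalizationError,
    apply_evidence_filters,
    compute_ribaq,
    drop_decoys_and_flags,
    filter_control_contaminants,
    quantify_interactome,
    summarize_interactors,
)
from apexflux.simulate import ProteomeSimConfig, generate_proteomics
from conftest import make_row
from oracles import naive_filter_pipeline


def minus_ir(v1, v2=None, v3=None):
    vals = {"minus_ir_r1": v1}
    if v2 is not None:
        vals["minus_ir_r2"] = v2
    if v3 is not None:
        vals["minus_ir_r3"] = v3
    return vals


class TestDropDecoysAndFlags:
    def test_one_decoy_among_five_removed(self):
        rows = [make_row(f"P{i}", minus_ir(1.0, 1.0)) for i in range(4)]
        rows.append(make_row("REV1", minus_ir(1.0, 1.0), decoy=True))
        assert len(drop_decoys_and_flags(rows)) == 4

    def test_no_flags_is_identity(self):
        rows = [make_row(f"P{i}", minus_ir(1.0, 1.0)) for i in range(3)]
        assert drop_decoys_and_flags(rows) == rows

    def test_all_flagged_gives_empty(self):
        rows = [
            make_row("A", minus_ir(1.0, 1.0), decoy=True),
            make_row("B", minus_ir(1.0, 1.0), contaminant=True),
        ]
        assert drop_decoys_and_flags(rows) == []


class TestComputeRibaq:
    def test_single_protein_normalizes_to_one(self, design3):
        rows = [make_row("P1", {"minus_ir_r1": 500.0})]
        ribaq = compute_ribaq(rows, design3, on_empty="drop")
        assert ribaq.values.loc["P1", "minus_ir_r1"] == 1.0

    def test_equal_ibaq_gives_half_half(self, design3):
        rows = [
            make_row("A", {"minus_ir_r1": 7.0}),
            make_row("B", {"minus_ir_r1": 7.0}),
        ]
        ribaq = compute_ribaq(rows, design3, on_empty="drop")
        assert list(ribaq.values["minus_ir_r1"]) == [0.5, 0.5]

    def test_hand_computed_fractions(self, design3):
        rows = [
            make_row("A", {"minus_ir_r1": 2.0}),
            make_row("B", {"minus_ir_r1": 3.0}),
            make_row("C", {"minus_ir_r1": 5.0}),
        ]
        ribaq = compute_ribaq(rows, design3, on_empty="drop")
        np.testing.assert_allclose(
            ribaq.values["minus_ir_r1"].values, [0.2, 0.3, 0.5]
        )

    def test_zero_total_sample_raises_naming_sample(self, design3):
        rows = [make_row("A", {"minus_ir_r1": 1.0})]
        with pytest.raises(NormalizationError, match="control_r1"):
            compute_ribaq(rows, design3, on_empty="error")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_columns_sum_to_one_on_random_fixtures(self, seed):
        rows, design, _ = generate_proteomics(
            ProteomeSimConfig(n_background=30, n_contaminants=8, n_ir_up=4,
                              n_ir_down=4, seed=seed)
        )
        ribaq = compute_ribaq(rows, design, on_empty="drop")
        sums = ribaq.values.sum(axis=0, skipna=True)
        np.testing.assert_allclose(sums.values, 1.0, atol=1e-9)
        present = ribaq.values.values[np.isfinite(ribaq.values.values)]
        assert ((present > 0) & (present <= 1)).all()


class TestControlContaminantFilter:
    def test_detected_in_one_control_replicate_removed(self, design3):
        row = make_row("P1", {"control_r2": 5.0, "minus_ir_r1": 9.0,
                              "minus_ir_r2": 9.0})
        kept, removed = filter_control_contaminants([row], design3)
        assert kept == [] and removed == {"P1"}

    def test_absent_from_control_retained(self, design3):
        row = make_row("P1", minus_ir(9.0, 9.0))
        kept, removed = filter_control_contaminants([row], design3)
        assert kept == [row] and removed == set()

    def test_ten_proteins_three_in_control(self, design3):
        rows = [make_row(f"P{i}", minus_ir(1.0, 1.0)) for i in range(7)]
        rows += [
            make_row(f"C{i}", {"control_r1": 2.0, "minus_ir_r1": 1.0})
            for i in range(3)
        ]
        kept, removed = filter_control_contaminants(rows, design3)
        assert len(kept) == 7
        assert removed == {"C0", "C1", "C2"}

    def test_no_control_arm_is_config_error(self):
        from apexflux import ExperimentDesign, Sample

        design = ExperimentDesign(
            (Sample("m1", "minus_ir", 1), Sample("m2", "minus_ir", 2))
        )
        with pytest.raises(ConfigError, match="control"):
            filter_control_contaminants([], design)


class TestEvidenceFilters:
    def test_single_unique_peptide_excluded(self, design3):
        row = make_row("P1", minus_ir(1.0, 1.0, 1.0), peptides=1)
        assert apply_evidence_filters([row], design3) == []

    def test_two_of_three_replicates_retained(self, design3):
        row = make_row("P1", minus_ir(1.0, 1.0), peptides=3)
        assert apply_evidence_filters([row], design3) == [row]

    def test_one_replicate_only_excluded(self, design3):
        row = make_row("P1", minus_ir(1.0), peptides=3)
        assert apply_evidence_filters([row], design3) == []

    def test_empty_input_gives_empty_output(self, design3):
        assert apply_evidence_filters([], design3) == []

    def test_min_replicates_beyond_arm_size_is_config_error(self, design3):
        with pytest.raises(ConfigError, match="min_replicates"):
            apply_evidence_filters([], design3, min_replicates=4)

    def test_retention_is_per_arm(self, design3):
        # detected twice in minus_ir but once in plus_ir: only minus_ir kept
        row = make_row(
            "P1", {"minus_ir_r1": 1.0, "minus_ir_r2": 1.0, "plus_ir_r1": 1.0}
        )
        kept = apply_evidence_filters([row], design3)
        ribaq = compute_ribaq(kept, design3, on_empty="drop")
        (rec,) = summarize_interactors(ribaq, kept, design3)
        assert set(rec.mean_ribaq_by_arm) == {"minus_ir"}


class TestSummarize:
    def test_mean_over_detected_replicates_only(self, design3):
        rows = [
            make_row("P1", {"plus_ir_r1": 1.0, "plus_ir_r2": 2.0}),
            make_row("P2", {"plus_ir_r1": 9.0, "plus_ir_r2": 8.0,
                            "plus_ir_r3": 10.0}),
        ]
        ribaq = compute_ribaq(rows, design3, on_empty="drop")
        recs = summarize_interactors(ribaq, rows, design3)
        p1 = next(r for r in recs if r.protein_id == "P1")
        # riBAQ of P1: r1 1/10, r2 2/10; mean over its 2 detected replicates
        assert p1.replicate_support_by_arm["plus_ir"] == 2
        np.testing.assert_allclose(p1.mean_ribaq_by_arm["plus_ir"], 0.15)

    def test_constant_values_mean_is_value(self, design3):
        rows = [make_row("P1", {f"plus_ir_r{i}": 4.0 for i in (1, 2, 3)})]
        ribaq = compute_ribaq(rows, design3, on_empty="drop")
        (rec,) = summarize_interactors(ribaq, rows, design3)
        assert rec.mean_ribaq_by_arm["plus_ir"] == 1.0

    def test_hand_arithmetic_mean(self, design3):
        # two proteins, so riBAQ fractions are nontrivial
        rows = [
            make_row("A", {"plus_ir_r1": 1.0, "plus_ir_r2": 2.0,
                           "plus_ir_r3": 3.0}),
            make_row("B", {"plus_ir_r1": 9.0, "plus_ir_r2": 8.0,
                           "plus_ir_r3": 7.0}),
        ]
        ribaq = compute_ribaq(rows, design3, on_empty="drop")
        recs = summarize_interactors(ribaq, rows, design3)
        a = next(r for r in recs if r.protein_id == "A")
        np.testing.assert_allclose(
            a.mean_ribaq_by_arm["plus_ir"], (0.1 + 0.2 + 0.3) / 3
        )

    def test_rank_ties_broken_lexicographically(self, design3):
        rows = [
            make_row(p, {"plus_ir_r1": 5.0, "plus_ir_r2": 5.0})
            for p in ("B", "A", "C")
        ]
        ribaq = compute_ribaq(rows, design3, on_empty="drop")
        recs = summarize_interactors(ribaq, rows, design3)
        ranks = {r.protein_id: r.rank_by_arm["plus_ir"] for r in recs}
        assert ranks == {"A": 1, "B": 2, "C": 3}


class TestPipelineProperties:
    def test_matches_naive_reference_on_random_fixture(self, design3):
        rows, design, _ = generate_proteomics(
            ProteomeSimConfig(n_background=30, n_contaminants=10, n_ir_up=5,
                              n_ir_down=5, detect_prob=0.8, seed=42)
        )
        result = quantify_interactome(rows, design)
        expected = naive_filter_pipeline(rows, design)
        for arm in ("minus_ir", "plus_ir"):
            assert result.ids_in_arm(arm) == expected[arm]

    def test_filters_are_idempotent(self, design3):
        rows, design, _ = generate_proteomics(
            ProteomeSimConfig(n_background=25, n_contaminants=5, n_ir_up=3,
                              n_ir_down=3, seed=5)
        )
        once = apply_evidence_filters(
            filter_control_contaminants(drop_decoys_and_flags(rows), design)[0],
            design,
        )
        twice = apply_evidence_filters(
            filter_control_contaminants(drop_decoys_and_flags(once), design)[0],
            design,
        )
        assert twice == once

    def test_global_rescaling_leaves_ribaq_and_ranks_unchanged(self):
        rows, design, _ = generate_proteomics(
            ProteomeSimConfig(n_background=25, n_contaminants=5, n_ir_up=3,
                              n_ir_down=3, seed=9)
        )
        scale = {sid: 10.0 ** (i % 4) for i, sid in enumerate(design.sample_ids)}
        scaled = [
            make_row(
                r.protein_id,
                {s: v * scale[s] for s, v in r.ibaq_by_sample.items()},
                peptides=dict(r.unique_peptides_by_sample),
            )
            for r in rows
        ]
        res = quantify_interactome(rows, design)
        res_scaled = quantify_interactome(scaled, design)
        assert len(res.records) == len(res_scaled.records)
        for a, b in zip(res.records, res_scaled.records):
            assert a.protein_id == b.protein_id
            assert a.rank_by_arm == b.rank_by_arm
            for arm in a.mean_ribaq_by_arm:
                np.testing.assert_allclose(
                    a.mean_ribaq_by_arm[arm], b.mean_ribaq_by_arm[arm]
                )
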