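"""Reassignment calling rules and the iterative recoding loop."""

import random
from collections import Counter

import pytest

import mitocode as mc
from mitocode.conservation import OccupancyMatrix
from mitocode.inference import (
    STATUS_INSUFFICIENT,
    STATUS_SPECIFIC,
    STATUS_STANDARD,
    STATUS_UNKNOWN,
    InferenceParams,
    OrthologSet,
    call_codon_meaning,
    infer_codes_iterative,
    two_stage_analysis,
)


def _occ(codon, row):
    occ = OccupancyMatrix(taxon="tax")
    occ.counts[codon] = Counter(row)
    occ.n_columns_seen[codon] = sum(row.values())
    return occ


class TestCallingRules:
    def test_single_position_insufficient(self):
        call = call_codon_meaning(_occ("AGG", {"A": 1}), "AGG")
        assert call.status == STATUS_INSUFFICIENT

    def test_ambiguous_top_two_yields_unknown(self):
        # top 10 < 2 x second 7: clear non-standard but no specific meaning
        call = call_codon_meaning(_occ("AGG", {"M": 10, "L": 7}), "AGG")
        assert call.status == STATUS_UNKNOWN
        assert call.inferred_meaning == "X"

    def test_stop_codon_specific_assignment(self):
        call = call_codon_meaning(_occ("UAG", {"A": 24, "S": 1}), "UAG")
        assert call.status == STATUS_SPECIFIC
        assert call.inferred_meaning == "A"

    def test_dominant_standard_fraction_retains(self):
        call = call_codon_meaning(_occ("CGG", {"R": 8, "L": 2}), "CGG")
        assert call.status == STATUS_STANDARD

    def test_standard_fraction_boundary_is_inclusive(self):
        # "no more than 10%": exactly 10% still qualifies as reassigned
        call = call_codon_meaning(_occ("CGG", {"R": 1, "A": 9}), "CGG")
        assert call.status == STATUS_SPECIFIC and call.inferred_meaning == "A"

    def test_dominance_ratio_boundary_is_inclusive(self):
        call = call_codon_meaning(_occ("AGG", {"M": 10, "L": 5}), "AGG")
        assert call.status == STATUS_SPECIFIC and call.inferred_meaning == "M"

    def test_zero_second_count_passes_dominance(self):
        call = call_codon_meaning(_occ("AGG", {"M": 5}), "AGG")
        assert call.status == STATUS_SPECIFIC

    def test_unknown_standard_aa_rejected(self):
        with pytest.raises(ValueError):
            call_codon_meaning(_occ("AGG", {"A": 9}), "AGG", standard_aa="B")

    def test_monotone_in_standard_evidence(self):
        """Adding occurrences under the standard amino acid can never turn
        standard_retained into a reassignment."""
        rng = random.Random(21)
        for _ in range(200):
            row = {aa: rng.randint(0, 12) for aa in rng.sample("ARNDLMS", 3)}
            row["R"] = row.get("R", 0)
            before = call_codon_meaning(_occ("CGG", dict(row)), "CGG")
            row["R"] += rng.randint(1, 10)
            after = call_codon_meaning(_occ("CGG", row), "CGG")
            if before.status == STATUS_STANDARD:
                assert after.status == STATUS_STANDARD


def _oset_from_codons(rows: dict[str, list[str]]) -> OrthologSet:
    cds = {t: "".join(c.replace("U", "T") for c in cods) + "TAA" for t, cods in rows.items()}
    return OrthologSet(gene="g01", cds=cds)


def _upgrade_fixture() -> OrthologSet:
    """Taxon tx carries AGG under 4 Ala- and 2 Ser-conserved columns plus one
    borderline column that only becomes Ala-conserved once taxon ux's UAG is
    recoded to Ala — driving an X → specific-Ala status upgrade."""
    rows = {}
    for i in range(6):
        rows[f"b{i}"] = ["GCU"] * 5 + ["UCU", "UCU"] + ["GCU"]
    for i in range(6, 8):
        rows[f"b{i}"] = ["GCU"] * 5 + ["UCU", "UCU"] + ["CUU"]
    rows["tx"] = ["AGG"] * 4 + ["GCU"] + ["AGG", "AGG"] + ["AGG"]
    rows["ux"] = ["UAG"] * 5 + ["UCU", "UCU"] + ["UAG"]
    return _oset_from_codons(rows)


class TestIterativeLoop:
    def test_all_standard_converges_first_pass(self):
        cfg = mc.SimulationConfig(
            n_taxa=8, n_genes=3, codons_per_gene=80, n_reference=10, seed=2
        )
        ds = mc.simulate_dataset(cfg)
        tables = {
            t: mc.standard_table() for t in ds.focal_taxa + ds.reference_taxa
        }
        res = infer_codes_iterative(ds.joint_sets(), tables)
        assert res.converged and res.n_iterations == 1
        assert res.reassigned_calls() == []

    def test_planted_reassignment_converges_second_pass(self, scenario_dataset):
        ds = scenario_dataset
        tables = {
            t: mc.standard_table() for t in ds.focal_taxa + ds.reference_taxa
        }
        res = infer_codes_iterative(ds.joint_sets(), tables)
        assert res.converged and res.n_iterations == 2
        got = {
            (c.taxon, c.codon): c.inferred_meaning for c in res.reassigned_calls()
        }
        assert got[("A1", "UAG")] == "A"

    def test_status_upgrade_recorded_in_history(self):
        """Recoding can flip a borderline column above threshold, upgrading a
        call from unknown (X) to a specific amino acid in a later pass."""
        oset = _upgrade_fixture()
        tables = {t: mc.standard_table() for t in oset.cds}
        res = infer_codes_iterative([oset], tables)
        assert res.converged
        first = res.history[0]["tx"]["AGG"]
        assert (first.status, first.inferred_meaning) == (STATUS_UNKNOWN, "X")
        last = res.final_calls()["tx"]["AGG"]
        assert (last.status, last.inferred_meaning) == (STATUS_SPECIFIC, "A")
        assert res.tables["tx"].mapping["AGG"] == "A"
        assert res.tables["ux"].mapping["UAG"] == "A"

    def test_determinism(self):
        oset = _upgrade_fixture()
        tables = {t: mc.standard_table() for t in oset.cds}
        r1 = infer_codes_iterative([oset], tables)
        r2 = infer_codes_iterative([oset], tables)
        assert r1.history_frame().equals(r2.history_frame())
        assert {t: tb.mapping for t, tb in r1.tables.items()} == {
            t: tb.mapping for t, tb in r2.tables.items()
        }

    def test_fixpoint_soundness(self, small_dataset):
        ds = small_dataset
        tables = {
            t: mc.standard_table() for t in ds.focal_taxa + ds.reference_taxa
        }
        res = infer_codes_iterative(ds.joint_sets(), tables)
        assert res.converged
        again = infer_codes_iterative(ds.joint_sets(), res.tables)
        assert again.converged and again.n_iterations == 1
        assert {t: tb.mapping for t, tb in again.tables.items()} == {
            t: tb.mapping for t, tb in res.tables.items()
        }

    def test_missing_initial_table_errors(self):
        oset = _oset_from_codons({"a": ["GCU"] * 3, "b": ["GCU"] * 3})
        with pytest.raises(ValueError, match="initial table"):
            infer_codes_iterative([oset], {"a": mc.standard_table()})


class TestTwoStage:
    def test_focal_only_gene_used_in_stage_two_only(self, small_dataset):
        ds = small_dataset
        ref_sets = [o for o in ds.reference_sets if o.gene != "g01"]
        res = two_stage_analysis(
            ref_sets,
            ds.ortholog_sets,
            {t: mc.standard_table() for t in ds.focal_taxa},
        )
        assert res.stage2.converged
        # planted stop-to-sense still recovered without g01 in the panel
        assert res.tables["A1"].mapping["UAG"] == "A"

    def test_overlapping_taxa_rejected(self, small_dataset):
        ds = small_dataset
        with pytest.raises(ValueError, match="both"):
            two_stage_analysis(
                ds.ortholog_sets,
                ds.ortholog_sets,
                {t: mc.standard_table() for t in ds.focal_taxa},
            )

    def test_stage_one_seeds_stage_two(self, scenario_dataset, scenario_result):
        res = scenario_result
        assert any(
            c.is_reassigned
            for per in res.stage1_calls.values()
            for c in per.values()
        )
        assert res.stage2.converged
        got = {
            (c.taxon, c.codon): c.inferred_meaning
            for c in res.stage2.reassigned_calls()
        }
        assert got[("C1", "CGG")] == "L"
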