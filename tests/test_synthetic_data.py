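"""The simulator: self-consistency, determinism, planted-signal structure."""

import filecmp
from collections import Counter

import pytest

import mitocode as mc
from mitocode.codes import STOP, codon_iter, translate_cds
from mitocode.synthetic_data import (
    SimulationConfig,
    SimulationError,
    build_trna_repertoire,
    default_scenario,
    disappearance_trajectory,
    simulate_dataset,
    write_dataset,
)
from mitocode.trna_evidence import wobble_decodes


class TestSelfConsistency:
    def test_translation_under_truth_tables_is_clean(self, small_dataset):
        ds = small_dataset
        for group in (ds.ortholog_sets, ds.reference_sets):
            for oset in group:
                for taxon, cds in oset.cds.items():
                    r = translate_cds(cds, ds.truth.tables[taxon])
                    assert r.internal_stop_positions == (), (oset.gene, taxon)
                    assert ds.truth.tables[taxon].mapping[r.terminal_codon] == STOP

    def test_conserved_sites_are_invariant(self, small_dataset):
        ds = small_dataset
        for gene, sites in ds.truth.conserved_sites.items():
            aln = ds.truth.alignments[gene]
            for i, aa in sites.items():
                column = {seq[i] for seq in aln.values()}
                assert column == {aa}, (gene, i)

    def test_conserved_site_fraction_near_configured(self, small_dataset):
        ds = small_dataset
        total = sum(len(s) for s in ds.truth.conserved_sites.values())
        n_sites = ds.config.n_genes * ds.config.codons_per_gene
        assert abs(total / n_sites - ds.config.conserved_site_fraction) < 0.1


class TestPlantedSignal:
    def test_reassigned_codons_sit_at_new_meaning_sites(self, small_dataset):
        ds = small_dataset
        for taxon, planted in ds.truth.planted.items():
            sense = {c: m for c, m in planted.items() if m != STOP}
            if not sense:
                continue
            for oset in ds.ortholog_sets:
                aln = ds.truth.alignments[oset.gene][taxon]
                codons = list(codon_iter(oset.cds[taxon]))[:-1]
                for i, codon in enumerate(codons):
                    if codon in sense:
                        assert aln[i] == sense[codon], (oset.gene, taxon, i)

    def test_sense_to_stop_codon_only_terminal_in_planted_taxa(self, small_dataset):
        ds = small_dataset
        for oset in ds.ortholog_sets:
            for taxon, cds in oset.cds.items():
                assert "UCA" not in list(codon_iter(cds))[:-1]

    def test_zero_weight_codon_never_emitted(self, small_dataset):
        ds = small_dataset
        # cladeC taxa have AGA usage weight 0 (codon disappearance)
        for oset in ds.ortholog_sets:
            for taxon in ("C1", "C2", "C3"):
                assert "AGA" not in list(codon_iter(oset.cds[taxon]))

    def test_planted_codes_require_usable_codon(self):
        cfg = default_scenario(seed=0, n_reference=4, n_genes=2, codons_per_gene=40)
        cfg.codon_usage.setdefault("A1", {})["UAG"] = 0.0
        with pytest.raises(SimulationError, match="nonzero usage"):
            simulate_dataset(cfg)

    def test_every_planted_sense_codon_has_cognate_trna(self, small_dataset):
        ds = small_dataset
        for taxon, planted in ds.truth.planted.items():
            repertoire = ds.truth.trna_tables[taxon]
            for codon, meaning in planted.items():
                if meaning == STOP:
                    assert not any(
                        wobble_decodes(t.anticodon, codon) for t in repertoire
                    )
                else:
                    matching = [
                        t for t in repertoire
                        if wobble_decodes(t.anticodon, codon) and t.isotype == meaning
                    ]
                    assert matching, (taxon, codon)

    def test_repertoire_never_decodes_a_stop(self, small_dataset):
        ds = small_dataset
        for taxon, repertoire in ds.truth.trna_tables.items():
            for stop in ds.truth.tables[taxon].stop_codons():
                assert not any(
                    wobble_decodes(t.anticodon, stop) for t in repertoire
                ), (taxon, stop)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = default_scenario(seed=7, n_reference=5, n_genes=3, codons_per_gene=50)
        for d in ("a", "b"):
            write_dataset(simulate_dataset(cfg), tmp_path / d)
        cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")

        def assert_equal(c):
            assert not c.diff_files and not c.left_only and not c.right_only
            for sub in c.subdirs.values():
                assert_equal(sub)

        assert_equal(cmp)

    def test_distinct_seeds_distinct_outputs(self):
        cfg1 = default_scenario(seed=1, n_reference=4, n_genes=2, codons_per_gene=40)
        cfg2 = default_scenario(seed=2, n_reference=4, n_genes=2, codons_per_gene=40)
        d1, d2 = simulate_dataset(cfg1), simulate_dataset(cfg2)
        assert d1.ortholog_sets[0].cds != d2.ortholog_sets[0].cds


class TestTrnaRepertoire:
    def test_minimal_cover_decodes_every_used_sense_codon(self):
        table = mc.standard_table()
        reps = build_trna_repertoire(table, {}, "tax")
        for codon in mc.codes.RNA_CODONS:
            if table.mapping[codon] == STOP:
                continue
            assert any(
                wobble_decodes(t.anticodon, codon) for t in reps
            ), codon

    def test_two_cau_species_initiator_and_elongator(self):
        reps = build_trna_repertoire(mc.standard_table(), {}, "tax")
        cau = [t for t in reps if t.anticodon == "CAU"]
        assert sorted(t.isotype for t in cau) == ["M", "fMet"]


class TestDisappearanceTrajectory:
    NEWICK = "(S1,(S2,(S3,(X1,X2)crown)));"

    def _config(self):
        # crown taxa also lose AGG (the whole AGR box leaves Arg service),
        # matching how AGA reassignment co-occurs with AGG change or loss
        return SimulationConfig(
            tree=self.NEWICK,
            n_genes=8,
            codons_per_gene=200,
            n_reference=4,
            planted_codes={"crown": [("AGA", "A")]},
            codon_usage={"X1": {"AGG": 0.0}, "X2": {"AGG": 0.0}},
            seed=29,
        )

    def test_stem_absent_crown_reassigned_counts_decay(self):
        ds = disappearance_trajectory(self._config(), "AGA", "crown")
        assert ds.truth.stages == {
            "S1": "pre", "S2": "pre", "S3": "stem", "X1": "crown", "X2": "crown"
        }
        counts = Counter()
        for oset in ds.ortholog_sets:
            for taxon, cds in oset.cds.items():
                counts[taxon] += list(codon_iter(cds))[:-1].count("AGA")
        assert counts["S3"] == 0                    # stem: codon vanished
        assert counts["X1"] > 0 and counts["X2"] > 0  # crown: reappeared
        assert counts["S1"] >= counts["S2"] >= counts["S3"]  # decay along path
        # crown usage carries the new meaning
        for oset in ds.ortholog_sets:
            aln = ds.truth.alignments[oset.gene]
            for taxon in ("X1", "X2"):
                codons = list(codon_iter(oset.cds[taxon]))[:-1]
                for i, c in enumerate(codons):
                    if c == "AGA":
                        assert aln[taxon][i] == "A"

    def test_tip_only_clade_affects_only_that_tip(self):
        cfg = SimulationConfig(
            tree="(T1,(T2,T3));",
            n_genes=4,
            codons_per_gene=100,
            n_reference=4,
            planted_codes={"T1": [("AGA", "A")]},
            codon_usage={"T1": {"AGG": 0.0}},
            seed=3,
        )
        ds = disappearance_trajectory(cfg, "AGA", "T1")
        assert ds.truth.stages == {"T1": "crown", "T2": "pre", "T3": "pre"}
        counts = Counter()
        for oset in ds.ortholog_sets:
            for taxon, cds in oset.cds.items():
                counts[taxon] += list(codon_iter(cds))[:-1].count("AGA")
        assert counts["T2"] > 0 and counts["T3"] > 0

    def test_codon_must_be_planted_on_clade(self):
        cfg = self._config()
        with pytest.raises(SimulationError, match="planted"):
            disappearance_trajectory(cfg, "UAG", "crown")
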