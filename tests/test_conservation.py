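"""Conserved-column profiling and codon-occupancy tallies."""

import random
from collections import Counter

import pytest

from mitocode.codes import builtin_table, standard_table, translate_cds
from mitocode.conservation import (
    ConservationParams,
    ConservedColumn,
    conservation_profile,
    map_codon_columns,
    tally_occupancy,
)
from mitocode.io_formats import SequenceRecord


def _msa(*rows):
    return [SequenceRecord(id=f"t{i}", residues=r) for i, r in enumerate(rows)]


class TestConservationProfile:
    def test_eight_of_ten_emitted(self):
        msa = _msa(*(["A"] * 8 + ["L", "V"]))
        cols = conservation_profile(msa)
        assert cols == [ConservedColumn(gene="", column=0, dominant_aa="A", fraction=0.8)]

    def test_six_of_ten_not_emitted(self):
        msa = _msa(*(["L"] * 6 + ["A", "V", "G", "K"]))
        assert conservation_profile(msa) == []

    def test_boundary_with_gaps_counted_in_denominator(self):
        msa = _msa(*(["A"] * 7 + ["-"] * 3))
        cols = conservation_profile(msa)
        assert len(cols) == 1 and cols[0].fraction == pytest.approx(0.7)

    def test_exclude_gaps_policy_changes_denominator(self):
        msa = _msa(*(["A"] * 6 + ["-"] * 4))
        assert conservation_profile(msa) == []  # 0.6 < 0.7
        cols = conservation_profile(
            msa, ConservationParams(gap_policy="exclude_gaps")
        )
        assert cols[0].fraction == pytest.approx(1.0)

    def test_x_star_gap_never_dominant(self):
        msa = _msa("X", "X", "X", "*", "-", "A")
        assert conservation_profile(msa) == []

    def test_ragged_alignment_errors(self):
        with pytest.raises(ValueError, match="ragged"):
            conservation_profile(_msa("AA", "A"))

    def test_threshold_must_exceed_half(self):
        with pytest.raises(ValueError):
            ConservationParams(min_fraction=0.5)

    def test_at_most_one_dominant_per_column_randomized(self):
        rng = random.Random(7)
        for _ in range(200):
            col = [rng.choice("AL-X*") for _ in range(rng.randint(2, 15))]
            cols = conservation_profile(_msa(*col))
            assert len(cols) <= 1


class TestMapCodonColumns:
    T1 = builtin_table(1)

    def test_gapped(self):
        assert map_codon_columns("ATGTTT", "M-F", self.T1) == {0: "AUG", 2: "UUU"}

    def test_ungapped(self):
        assert map_codon_columns("ATGTTT", "MF", self.T1) == {0: "AUG", 1: "UUU"}

    def test_mismatch_errors(self):
        with pytest.raises(ValueError, match="match"):
            map_codon_columns("ATG", "MF", self.T1)


def _toy_tally(focal_codons_by_gene, columns_by_gene):
    """Hand-driven tally: columns_by_gene gives (column, dominant) pairs."""
    conserved = {
        g: [ConservedColumn(gene=g, column=c, dominant_aa=aa, fraction=0.9) for c, aa in cols]
        for g, cols in columns_by_gene.items()
    }
    return tally_occupancy("tax", conserved, focal_codons_by_gene)


class TestTallyOccupancy:
    def test_hand_tallied_counts(self):
        # AGG sits under 12 Ala-dominant columns and 1 Ser-dominant column
        cols = [(i, "A") for i in range(12)] + [(12, "S")]
        cmap = {i: "AGG" for i in range(13)}
        occ = _toy_tally({"g": cmap}, {"g": cols})
        assert occ.row("AGG") == Counter({"A": 12, "S": 1})
        assert occ.n_columns_seen["AGG"] == 13

    def test_gapped_taxon_yields_empty_matrix(self):
        occ = _toy_tally({"g": {}}, {"g": [(0, "A"), (1, "L")]})
        assert occ.n_columns_seen == Counter()

    def test_additivity_across_genes(self):
        occ = _toy_tally(
            {"g1": {i: "UAG" for i in range(3)}, "g2": {i: "UAG" for i in range(4)}},
            {"g1": [(i, "A") for i in range(3)], "g2": [(i, "A") for i in range(4)]},
        )
        assert occ.n_columns_seen["UAG"] == 7

    def test_codons_with_n_skipped(self):
        occ = _toy_tally({"g": {0: "ANG", 1: "AGG"}}, {"g": [(0, "A"), (1, "A")]})
        assert occ.n_columns_seen == Counter({"AGG": 1})

    def test_exclude_self_reevaluates_dominance(self):
        # 7 of 10 rows carry A, the focal taxon among them: the column is
        # conserved with the focal row counted (0.7) but not without (6/9)
        msa = _msa(*(["A"] * 7 + ["L"] * 3))
        conserved = conservation_profile(msa, gene="g")
        assert len(conserved) == 1
        cmap = {"g": {0: "GCU"}}
        with_self = tally_occupancy("t0", {"g": conserved}, cmap)
        assert with_self.n_columns_seen["GCU"] == 1
        params = ConservationParams(include_self=False)
        without = tally_occupancy(
            "t0", {"g": conserved}, cmap, msa_by_gene={"g": msa}, params=params
        )
        assert without.n_columns_seen["GCU"] == 0

    def test_row_sums_equal_columns_seen_randomized(self):
        rng = random.Random(13)
        codons = ["AGG", "UAG", "GCU", "CGG"]
        cols = [(i, rng.choice("ALRS")) for i in range(50)]
        cmap = {i: rng.choice(codons) for i in range(50) if rng.random() < 0.8}
        occ = _toy_tally({"g": cmap}, {"g": cols})
        for codon, n in occ.n_columns_seen.items():
            assert sum(occ.row(codon).values()) == n


class TestAgainstBruteForce:
    def _random_alignment(self, rng, n_taxa, n_codons):
        table = standard_table()
        sense = [c for c in table.codons_for("A") + table.codons_for("L")
                 + table.codons_for("R") + table.codons_for("S")]
        cds = {
            f"t{i}": "".join(
                rng.choice(sense).replace("U", "T") for _ in range(n_codons)
            )
            for i in range(n_taxa)
        }
        return table, cds

    def test_naive_double_loop_oracle_agrees(self):
        """Independent naive tally over (column, taxon) pairs must agree
        with the pipeline tally on random gapless alignments."""
        rng = random.Random(99)
        table, cds = self._random_alignment(rng, 20, 200)
        params = ConservationParams()
        proteins = {t: translate_cds(s, table, truncated=True).protein for t, s in cds.items()}
        msa = [SequenceRecord(id=t, residues=p) for t, p in sorted(proteins.items())]
        conserved = conservation_profile(msa, params, gene="g")
        maps = {
            t: map_codon_columns(cds[t], proteins[t], table) for t in cds
        }
        # naive oracle
        n_cols = len(next(iter(proteins.values())))
        for taxon in cds:
            naive = Counter()
            for cc in conserved:
                count = 0
                for rec in msa:
                    if rec.residues[cc.column] == cc.dominant_aa:
                        count += 1
                assert count / len(msa) >= params.min_fraction
                naive[(maps[taxon][cc.column], cc.dominant_aa)] += 1
            occ = tally_occupancy(taxon, {"g": conserved}, {"g": maps[taxon]})
            got = Counter(
                {(c, aa): n for c, row in occ.counts.items() for aa, n in row.items()}
            )
            assert got == naive

    def test_taxon_order_permutation_invariance(self):
        rng = random.Random(5)
        table, cds = self._random_alignment(rng, 10, 60)
        proteins = {t: translate_cds(s, table, truncated=True).protein for t, s in cds.items()}
        order1 = sorted(proteins)
        order2 = list(reversed(order1))
        results = []
        for order in (order1, order2):
            msa = [SequenceRecord(id=t, residues=proteins[t]) for t in order]
            conserved = conservation_profile(msa, gene="g")
            occ = tally_occupancy(
                "t0", {"g": conserved}, {"g": map_codon_columns(cds["t0"], proteins["t0"], table)}
            )
            results.append((occ.counts, occ.n_columns_seen))
        assert results[0] == results[1]
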