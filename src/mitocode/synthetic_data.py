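"""Seeded generator of mitogenome-like ortholog sets with known (possibly
reassigned) genetic codes.

The generator emulates the statistical structure that conserved-position
codon-occupancy inference relies on, not sequence realism:

* a focal clade of taxa on a known phylogeny, plus a panel of standard-code
  outgroup taxa standing in for a broad eukaryote reference set;
* per-gene site structure: a configured fraction of codon sites invariant
  at the amino-acid level across all taxa (synonymous codon resampling
  only), the rest evolving by per-branch amino-acid replacement;
* per-taxon genetic codes: designated clades carry planted reassignments
  (stop-to-sense, sense-to-sense, sense-to-stop); codon usage weights allow
  complete codon disappearance (weight 0);
* tRNA repertoires consistent with each taxon's code under the wobble
  pairing rules, with optional isotype-prediction noise;
* a release-factor protein alignment whose diagnostic residues reflect each
  taxon's stop-codon repertoire.

Everything is deterministic given the seed.  Simulated alignments are
gapless: the true alignment is the sequences themselves, which makes the
codon-to-column mapping exact and keeps the inference logic — not
alignment quality — the thing under test.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from itertools import accumulate
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import codes
from .codes import GeneticCodeTable, RNA_CODONS, STOP, standard_table, derive_table
from .inference import OrthologSet
from .io_formats import SequenceRecord, TRNARecord, write_fasta, write_trna_table
from .phylo_mapping import Node, Phylogeny, parse_newick
from .trna_evidence import PairingRules, wobble_decodes

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Typical globular-protein amino-acid composition, used for site
#: amino-acid draws (normalized at use).
DEFAULT_AA_FREQUENCIES = {
    "A": 0.083, "R": 0.055, "N": 0.041, "D": 0.054, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.022, "I": 0.059,
    "K": 0.058, "L": 0.096, "M": 0.024, "F": 0.038, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.068,
}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    tree: str | None = None          # newick (labeled internal nodes name clades)
    n_taxa: int = 12                 # used when tree is None
    n_genes: int = 13
    codons_per_gene: int = 250
    conserved_site_fraction: float = 0.6
    substitution_rate: float = 0.3   # per-branch aa replacement prob, variable sites
    n_reference: int = 40            # standard-code outgroup panel size
    planted_codes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    clades: dict[str, list[str]] = field(default_factory=dict)
    codon_usage: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_codon_weight: float = 2.0
    derived_stop_weight: float = 6.0
    trna_policy: bool = True
    isotype_noise: float = 0.1
    rf2_like_clades: list[str] = field(default_factory=list)
    aa_frequencies: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in (
            ("conserved_site_fraction", self.conserved_site_fraction),
            ("substitution_rate", self.substitution_rate),
            ("isotype_noise", self.isotype_noise),
        ):
            if not 0 <= val <= 1:
                raise SimulationError(f"{name} must lie in [0, 1], got {val}")


@dataclass
class GroundTruth:
    tables: dict[str, GeneticCodeTable]
    planted: dict[str, dict[str, str]]            # taxon → codon → meaning
    trna_tables: dict[str, list[TRNARecord]]
    alignments: dict[str, dict[str, str]]         # gene → taxon → true aa string
    conserved_sites: dict[str, dict[int, str]]    # gene → site index → aa
    rf_truth: dict[str, dict]                     # taxon → {residues, flags}
    stages: dict[str, str] = field(default_factory=dict)  # trajectory stage per taxon


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    newick: str
    tree: Phylogeny
    focal_taxa: list[str]
    reference_taxa: list[str]
    ortholog_sets: list[OrthologSet]       # focal taxa
    reference_sets: list[OrthologSet]      # outgroup panel (standard code)
    trna_tables: dict[str, list[TRNARecord]]
    rf_msa: list[SequenceRecord]
    rf_reference_id: str
    truth: GroundTruth

    def joint_sets(self) -> list[OrthologSet]:
        """Focal and reference CDSs merged per gene (for single-pass runs)."""
        ref = {o.gene: o for o in self.reference_sets}
        out = []
        for oset in self.ortholog_sets:
            r = ref.get(oset.gene)
            cds = dict(oset.cds)
            if r is not None:
                cds.update(r.cds)
            out.append(OrthologSet(gene=oset.gene, cds=cds))
        return out


# ---------------------------------------------------------------------------
# helpers


def _random_tree(taxa: Sequence[str], rng: np.random.Generator) -> Node:
    if len(taxa) == 1:
        return Node(label=taxa[0])
    k = int(rng.integers(1, len(taxa)))
    return Node(
        label="",
        children=[_random_tree(taxa[:k], rng), _random_tree(taxa[k:], rng)],
    )


def _resolve_clade(config: SimulationConfig, tree: Phylogeny, label: str) -> list[str]:
    if label in config.clades:
        return list(config.clades[label])
    if label == "root":
        return tree.tip_labels()
    node = tree.find_clade(label)
    if node is not None:
        return [n.label for n in node.preorder() if n.is_tip]
    raise SimulationError(f"clade {label!r} is neither a tree node label nor configured")


def _taxon_tables(
    config: SimulationConfig, tree: Phylogeny
) -> tuple[dict[str, GeneticCodeTable], dict[str, dict[str, str]]]:
    std = standard_table()
    planted: dict[str, dict[str, str]] = {t: {} for t in tree.tip_labels()}
    for label in sorted(config.planted_codes):
        members = _resolve_clade(config, tree, label)
        for taxon in members:
            for codon, meaning in config.planted_codes[label]:
                planted[taxon][codes.dna_to_rna(codon)] = meaning
    tables = {}
    for taxon, deviations in planted.items():
        tables[taxon] = (
            derive_table(
                std,
                sorted(deviations.items()),
                name=f"{taxon}_true",
                note="planted",
            )
            if deviations
            else std
        )
    return tables, planted


class _CodonSampler:
    """Per-taxon codon choice: meaning → (codon list, cumulative weights)."""

    def __init__(
        self,
        table: GeneticCodeTable,
        weights: Mapping[str, float],
        derived_stop_weight: float,
    ):
        std = standard_table()
        self.by_meaning: dict[str, tuple[list[str], list[float]]] = {}
        for meaning in set(table.mapping.values()):
            if meaning == STOP:
                cods = [c for c in RNA_CODONS if table.mapping[c] == STOP]
                ws = [
                    derived_stop_weight if std.mapping[c] != STOP else 1.0
                    for c in cods
                ]
            else:
                cods = [
                    c
                    for c in RNA_CODONS
                    if table.mapping[c] == meaning and weights.get(c, 1.0) > 0
                ]
                ws = [weights.get(c, 1.0) for c in cods]
            if cods:
                self.by_meaning[meaning] = (cods, list(accumulate(ws)))

    def draw(self, meaning: str, u: float) -> str:
        cods, cum = self.by_meaning[meaning]
        return cods[bisect_right(cum, u * cum[-1])]


def _effective_weights(
    config: SimulationConfig,
    taxon: str,
    planted: Mapping[str, str],
) -> dict[str, float]:
    weights: dict[str, float] = {}
    for codon, meaning in planted.items():
        if meaning != STOP:
            weights[codon] = config.planted_codon_weight
    weights.update(
        {codes.dna_to_rna(c): w for c, w in config.codon_usage.get(taxon, {}).items()}
    )
    for codon, meaning in planted.items():
        if meaning != STOP and weights.get(codon, 1.0) <= 0:
            raise SimulationError(
                f"planted meaning {meaning} for {codon} in {taxon} requires "
                "nonzero usage weight"
            )
    return weights


# ---------------------------------------------------------------------------
# tRNA repertoire construction


def _anticodon_candidates(codon: str) -> list[str]:
    """Candidate anticodons reading ``codon``, preferred (narrowest) first."""
    third = codon[2]
    base35 = _WC[codon[1]]
    base36 = _WC[codon[0]]
    by_third = {"U": ["G", "A"], "C": ["G"], "A": ["U", "A"], "G": ["C", "U"]}
    return [w + base35 + base36 for w in by_third[third]]


def build_trna_repertoire(
    table: GeneticCodeTable,
    weights: Mapping[str, float],
    taxon: str,
    rules: PairingRules = PairingRules(),
) -> list[TRNARecord]:
    """A minimal anticodon set decoding every used sense codon and nothing
    with a conflicting meaning (no anticodon reads a stop codon or a used
    codon of another amino acid).  Includes an initiator tRNA-fMet(CAU)."""
    used = {
        c
        for c in RNA_CODONS
        if table.mapping[c] not in (STOP, "X") and weights.get(c, 1.0) > 0
    }

    def conflicts(anticodon: str, aa: str) -> bool:
        for c in RNA_CODONS:
            if not wobble_decodes(anticodon, c, rules):
                continue
            meaning = table.mapping[c]
            if meaning == STOP:
                return True
            if meaning != aa and c in used:
                return True
        return False

    chosen: list[tuple[str, str]] = [("CAU", "fMet")]
    for aa in sorted({table.mapping[c] for c in used}):
        targets = sorted(c for c in used if table.mapping[c] == aa)
        covered: set[str] = set()
        for codon in targets:
            if codon in covered:
                continue
            placed = False
            for anticodon in _anticodon_candidates(codon):
                if conflicts(anticodon, aa):
                    continue
                chosen.append((anticodon, aa))
                covered.update(
                    c for c in targets if wobble_decodes(anticodon, c, rules)
                )
                placed = True
                break
            if not placed:
                raise SimulationError(
                    f"no safe anticodon decodes {codon} ({aa}) in {taxon}; "
                    "consider zeroing the codon's usage weight"
                )
    records = []
    pos = 100
    for anticodon, aa in chosen:
        records.append(
            TRNARecord(
                taxon=taxon,
                anticodon=anticodon,
                isotype=aa,
                begin=pos,
                end=pos + 71,
                strand="+",
            )
        )
        pos += 120
    return records


def _apply_isotype_noise(
    records: list[TRNARecord], noise: float, rng: np.random.Generator
) -> list[TRNARecord]:
    out = []
    for rec in records:
        if rec.isotype not in ("fMet", "?") and rng.random() < noise:
            others = [a for a in codes.AMINO_ACIDS if a != rec.isotype]
            wrong = others[int(rng.integers(len(others)))]
            rec = TRNARecord(
                taxon=rec.taxon,
                anticodon=rec.anticodon,
                isotype=wrong,
                begin=rec.begin,
                end=rec.end,
                strand=rec.strand,
                note="noisy_isotype",
            )
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# release-factor alignment

RF_REFERENCE_ID = "RF1_reference"
RF_LENGTH = 230
_RF_DIAGNOSTIC = {181: "Q", 182: "R", 186: "T", 206: "A"}


def _rf_residues_for(
    table: GeneticCodeTable, rf2_like: bool, rng: np.random.Generator
) -> dict[int, str]:
    std = standard_table()
    uag_sense = table.mapping["UAG"] != STOP
    derived_stop = any(
        table.mapping[c] == STOP and std.mapping[c] != STOP for c in RNA_CODONS
    )
    residues = dict(_RF_DIAGNOSTIC)
    if uag_sense:
        residues[181] = "ILV"[int(rng.integers(3))]
    if derived_stop:
        residues[182] = "GKQ"[int(rng.integers(3))]
    if rf2_like:
        residues[186] = "N"
        residues[206] = "S"
    return residues


def _rf_flags_for(residues: Mapping[int, str]) -> list[str]:
    flags = []
    flags.append("UAG_stop_capable" if residues[181] == "Q" else "UAG_blind")
    if residues[186] != "T" and residues[206] == "S":
        flags.append("RF2_like_UGA")
    if residues[182] != "R":
        flags.append("UCA_UCG_hypothesis")
    return flags


# ---------------------------------------------------------------------------
# the generator


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    rng = np.random.default_rng(config.seed)
    freqs = dict(config.aa_frequencies or DEFAULT_AA_FREQUENCIES)
    aa_list = sorted(freqs)
    aa_p = np.array([freqs[a] for a in aa_list], dtype=float)
    aa_p /= aa_p.sum()

    if config.tree is not None:
        tree = parse_newick(config.tree)
    else:
        taxa = [f"t{i+1:02d}" for i in range(config.n_taxa)]
        tree = Phylogeny(root=_random_tree(taxa, rng))
    focal_taxa = tree.tip_labels()
    reference_taxa = [f"ref{i+1:02d}" for i in range(config.n_reference)]

    tables, planted = _taxon_tables(config, tree)
    std = standard_table()
    for taxon in reference_taxa:
        tables[taxon] = std
        planted[taxon] = {}

    weights = {
        taxon: _effective_weights(config, taxon, planted[taxon])
        for taxon in focal_taxa + reference_taxa
    }
    samplers = {
        taxon: _CodonSampler(tables[taxon], weights[taxon], config.derived_stop_weight)
        for taxon in focal_taxa + reference_taxa
    }

    aa_cum = np.cumsum(aa_p)

    def draw_aa(u: float) -> str:
        return aa_list[min(int(np.searchsorted(aa_cum, u, side="right")), len(aa_list) - 1)]

    nodes = list(tree.root.preorder())
    n_sites = config.codons_per_gene

    ortholog_sets: list[OrthologSet] = []
    reference_sets: list[OrthologSet] = []
    alignments: dict[str, dict[str, str]] = {}
    conserved_sites: dict[str, dict[int, str]] = {}

    for g in range(config.n_genes):
        gene = f"g{g+1:02d}"
        # -- site structure
        cons_flags = rng.random(n_sites) < config.conserved_site_fraction
        cons_flags[0] = True
        root_aa = [draw_aa(u) for u in rng.random(n_sites)]
        root_aa[0] = "M"  # initiator site
        gene_conserved = {
            i: root_aa[i] for i in range(n_sites) if cons_flags[i]
        }
        # -- evolve amino acids down the focal tree at variable sites
        aa_by_node: dict[int, list[str]] = {id(tree.root): list(root_aa)}
        for node in tree.root.preorder():
            parent_aa = aa_by_node[id(node)]
            for child in node.children:
                child_aa = list(parent_aa)
                hits = np.nonzero(
                    (rng.random(n_sites) < config.substitution_rate) & ~cons_flags
                )[0]
                for i in hits:
                    child_aa[i] = codes.AMINO_ACIDS[int(rng.integers(20))]
                aa_by_node[id(child)] = child_aa
        gene_aln: dict[str, str] = {}
        focal_cds: dict[str, str] = {}
        for node in tree.tips():
            gene_aln[node.label] = "".join(aa_by_node[id(node)])
        # -- reference taxa: one pseudo-branch off the root sequence
        for taxon in reference_taxa:
            seq = list(root_aa)
            hits = np.nonzero(
                (rng.random(n_sites) < config.substitution_rate) & ~cons_flags
            )[0]
            for i in hits:
                seq[i] = codes.AMINO_ACIDS[int(rng.integers(20))]
            gene_aln[taxon] = "".join(seq)
        # -- amino acids → codons (synonymous resampling everywhere)
        ref_cds: dict[str, str] = {}
        for taxon in focal_taxa + reference_taxa:
            sampler = samplers[taxon]
            us = rng.random(n_sites + 1)
            try:
                cods = [
                    sampler.draw(aa, us[i])
                    for i, aa in enumerate(gene_aln[taxon])
                ]
            except KeyError as exc:
                raise SimulationError(
                    f"taxon {taxon} has no usable codon for amino acid {exc}"
                ) from exc
            cods.append(sampler.draw(STOP, us[n_sites]))
            cds = "".join(codes.rna_to_dna(c) for c in cods)
            if taxon in reference_taxa:
                ref_cds[taxon] = cds
            else:
                focal_cds[taxon] = cds
        ortholog_sets.append(OrthologSet(gene=gene, cds=focal_cds))
        reference_sets.append(OrthologSet(gene=gene, cds=ref_cds))
        alignments[gene] = gene_aln
        conserved_sites[gene] = gene_conserved

    # -- tRNA repertoires
    trna_tables: dict[str, list[TRNARecord]] = {}
    truth_trnas: dict[str, list[TRNARecord]] = {}
    if config.trna_policy:
        for taxon in focal_taxa + reference_taxa:
            clean = build_trna_repertoire(tables[taxon], weights[taxon], taxon)
            truth_trnas[taxon] = clean
            trna_tables[taxon] = _apply_isotype_noise(
                clean, config.isotype_noise, rng
            )

    # -- release-factor alignment
    rf2_taxa: set[str] = set()
    for label in config.rf2_like_clades:
        rf2_taxa.update(_resolve_clade(config, tree, label))
    backbone = [draw_aa(u) for u in rng.random(RF_LENGTH)]
    for pos, aa in _RF_DIAGNOSTIC.items():
        backbone[pos - 1] = aa
    rf_msa = [SequenceRecord(id=RF_REFERENCE_ID, residues="".join(backbone))]
    rf_truth: dict[str, dict] = {}
    diag_cols = {p - 1 for p in _RF_DIAGNOSTIC}
    for taxon in focal_taxa:
        residues = _rf_residues_for(tables[taxon], taxon in rf2_taxa, rng)
        seq = list(backbone)
        hits = np.nonzero(rng.random(RF_LENGTH) < 0.05)[0]
        for i in hits:
            if i not in diag_cols:
                seq[i] = codes.AMINO_ACIDS[int(rng.integers(20))]
        for pos, aa in residues.items():
            seq[pos - 1] = aa
        rf_msa.append(SequenceRecord(id=taxon, residues="".join(seq)))
        rf_truth[taxon] = {"residues": residues, "flags": _rf_flags_for(residues)}

    truth = GroundTruth(
        tables={t: tables[t] for t in focal_taxa + reference_taxa},
        planted=planted,
        trna_tables=truth_trnas,
        alignments=alignments,
        conserved_sites=conserved_sites,
        rf_truth=rf_truth,
    )
    return SimulatedDataset(
        config=config,
        newick=tree.to_newick(),
        tree=tree,
        focal_taxa=focal_taxa,
        reference_taxa=reference_taxa,
        ortholog_sets=ortholog_sets,
        reference_sets=reference_sets,
        trna_tables=trna_tables,
        rf_msa=rf_msa,
        rf_reference_id=RF_REFERENCE_ID,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# codon-disappearance trajectory


def disappearance_trajectory(
    config: SimulationConfig, codon: str, clade: str
) -> SimulatedDataset:
    """Dataset in which ``codon``'s usage decays to zero toward ``clade``.

    Taxa in subtrees branching off the root→clade stem inherit usage
    weights that decay quadratically with the divergence point (the last
    group before the crown is at exactly zero); crown (clade) taxa carry the
    codon with its planted new meaning, which must be present in
    ``config.planted_codes[clade]``.  Taxa hanging directly off the root are
    unaffected.  Stages are recorded per taxon in the ground truth:
    ``pre`` (full or decaying usage), ``stem`` (zero usage), ``crown``.
    """
    codon = codes.dna_to_rna(codon)
    if not any(
        codes.dna_to_rna(c) == codon for c, _m in config.planted_codes.get(clade, [])
    ):
        raise SimulationError(
            f"trajectory codon {codon} must be planted on clade {clade!r}"
        )
    if config.tree is None:
        raise SimulationError("disappearance_trajectory requires an explicit tree")
    tree = parse_newick(config.tree)
    crown = set(_resolve_clade(config, tree, clade))

    # path of nodes from root to the clade's ancestor
    def find_path(node: Node) -> list[Node] | None:
        tips = {n.label for n in node.preorder() if n.is_tip}
        if tips == crown:
            return [node]
        for child in node.children:
            got = find_path(child)
            if got is not None:
                return [node] + got
        return None

    path = find_path(tree.root)
    if path is None:
        raise SimulationError(f"clade {clade!r} is not a node of the tree")
    inner = path[1:-1]  # nodes strictly between root and crown ancestor
    stages: dict[str, str] = {t: "pre" for t in tree.tip_labels()}
    usage = dict(config.codon_usage)
    k_total = len(inner)
    for rank, node in enumerate(inner):
        factor = ((k_total - 1 - rank) / k_total) ** 2 if k_total > 1 else 0.0
        on_path = path[path.index(node) + 1]
        for child in node.children:
            if child is on_path:
                continue
            for tip in (n.label for n in child.preorder() if n.is_tip):
                usage.setdefault(tip, {})[codon] = factor
                stages[tip] = "stem" if factor == 0.0 else "pre"
    for tip in crown:
        stages[tip] = "crown"
    cfg = SimulationConfig(**{**asdict(config), "codon_usage": usage})
    cfg.planted_codes = dict(config.planted_codes)
    cfg.clades = dict(config.clades)
    dataset = simulate_dataset(cfg)
    dataset.truth.stages = stages
    return dataset


# ---------------------------------------------------------------------------
# canonical scenario and writers


def default_scenario(
    seed: int = 0,
    taxa_per_clade: int = 3,
    n_reference: int = 40,
    n_genes: int = 13,
    codons_per_gene: int = 250,
    conserved_site_fraction: float = 0.6,
) -> SimulationConfig:
    """The canonical recovery scenario: four focal clades under distinct
    code variants, one order-wide sense-to-stop reassignment.

    * cladeA: stop-to-sense UAG→Ala (Hydrodictyaceae-like)
    * cladeB: sense-to-sense AGG→Ala and AGA→Ala (Scenedesmaceae-like)
    * cladeC: CGG→Leu and AGG→Met, AGA disappeared (Chromochloris-like)
    * cladeD: standard sense codons (negative control)
    * all focal taxa: Ser-to-stop UCA→STOP
    """

    def clade(prefix: str) -> str:
        tips = [f"{prefix}{i+1}" for i in range(taxa_per_clade)]
        inner = tips[0]
        for t in tips[1:]:
            inner = f"({inner},{t})"
        return f"{inner}clade{prefix}"

    newick = (
        f"({clade('A')},({clade('B')},({clade('C')},{clade('D')})));"
    )
    taxa_c = [f"C{i+1}" for i in range(taxa_per_clade)]
    return SimulationConfig(
        tree=newick,
        n_genes=n_genes,
        codons_per_gene=codons_per_gene,
        conserved_site_fraction=conserved_site_fraction,
        n_reference=n_reference,
        planted_codes={
            "cladeA": [("UAG", "A")],
            "cladeB": [("AGG", "A"), ("AGA", "A")],
            "cladeC": [("CGG", "L"), ("AGG", "M")],
            "root": [("UCA", STOP)],
        },
        codon_usage={t: {"AGA": 0.0} for t in taxa_c},
        seed=seed,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write per-gene FASTA (focal and reference), tRNA TSV, tree newick,
    RF alignment FASTA, and the ground truth as JSON."""
    out = Path(outdir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    (out / "reference").mkdir(exist_ok=True)
    for oset in dataset.ortholog_sets:
        write_fasta(
            [SequenceRecord(id=t, residues=s) for t, s in sorted(oset.cds.items())],
            out / "genes" / f"{oset.gene}.fasta",
        )
    for oset in dataset.reference_sets:
        write_fasta(
            [SequenceRecord(id=t, residues=s) for t, s in sorted(oset.cds.items())],
            out / "reference" / f"{oset.gene}.fasta",
        )
    all_trnas = [
        rec for taxon in sorted(dataset.trna_tables) for rec in dataset.trna_tables[taxon]
    ]
    write_trna_table(all_trnas, out / "trna.tsv")
    (out / "tree.nwk").write_text(dataset.newick + "\n")
    write_fasta(dataset.rf_msa, out / "rf_alignment.fasta")
    truth = {
        "tables": {t: json.loads(tbl.to_json()) for t, tbl in dataset.truth.tables.items()},
        "planted": dataset.truth.planted,
        "conserved_sites": {
            g: {str(i): aa for i, aa in sorted(sites.items())}
            for g, sites in dataset.truth.conserved_sites.items()
        },
        "rf_truth": dataset.truth.rf_truth,
        "stages": dataset.truth.stages,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
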