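"""Reassignment calling and the iterative recoding loop.

The calling rule for one codon in one genome, evaluated on its occupancy row
(conserved columns it occurs under, keyed by the column's dominant amino
acid), with n = number of such columns:

1. n < min_positions                              → insufficient_data
2. counts[standard_aa] / n > max_standard_fraction → standard_retained
   (vacuous for stop codons: a stop has no standard amino acid)
3. otherwise the codon is considered reassigned.  Let top and second be the
   two largest counts over amino acids.  If top >= min_top_count and
   top >= dominance_ratio * second, the codon is assigned that specific
   amino acid (reassigned_specific); otherwise it is translated as the
   unknown amino acid X (reassigned_unknown).

The iterative loop retranslates every CDS under the current per-taxon
tables, recomputes conservation and occupancy, re-calls every codon, and
repeats until an iteration changes no call, mirroring the recoding
iterations that in practice converge after two passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from . import codes
from .codes import GeneticCodeTable, STOP, UNKNOWN, standard_table, derive_table, translate_cds
from .conservation import (
    ConservationParams,
    ConservedColumn,
    OccupancyMatrix,
    conservation_profile,
    map_codon_columns,
    tally_occupancy,
)
from .io_formats import SequenceRecord

_STANDARD = standard_table()


@dataclass(frozen=True)
class InferenceParams:
    min_positions: int = 5
    max_standard_fraction: float = 0.10
    min_top_count: int = 5
    dominance_ratio: float = 2.0
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if min(self.min_positions, self.min_top_count, self.max_iterations) < 1:
            raise ValueError("count parameters must be positive")
        if not 0 <= self.max_standard_fraction <= 1:
            raise ValueError("max_standard_fraction must lie in [0, 1]")
        if self.dominance_ratio <= 0:
            raise ValueError("dominance_ratio must be positive")


STATUS_STANDARD = "standard_retained"
STATUS_INSUFFICIENT = "insufficient_data"
STATUS_SPECIFIC = "reassigned_specific"
STATUS_UNKNOWN = "reassigned_unknown"


@dataclass(frozen=True)
class ReassignmentCall:
    taxon: str
    codon: str
    standard_meaning: str  # one-letter amino acid or '*'
    status: str
    inferred_meaning: str | None
    n_positions: int
    standard_count: int
    top_aa: str | None
    top_count: int
    second_aa: str | None
    second_count: int

    @property
    def is_reassigned(self) -> bool:
        return self.status in (STATUS_SPECIFIC, STATUS_UNKNOWN)


def call_codon_meaning(
    occupancy: OccupancyMatrix,
    codon: str,
    standard_aa: str | None = None,
    params: InferenceParams = InferenceParams(),
) -> ReassignmentCall:
    """Apply the stringent calling rules to one codon of one taxon."""
    codon = codes.dna_to_rna(codon)
    if standard_aa is None:
        standard_aa = _STANDARD.mapping[codon]
    elif standard_aa != STOP and standard_aa not in codes.AMINO_ACIDS:
        raise ValueError(f"unknown standard amino acid {standard_aa!r}")
    row = occupancy.row(codon)
    n = occupancy.n_columns_seen.get(codon, 0)
    std_count = row.get(standard_aa, 0) if standard_aa != STOP else 0
    ranked = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
    top_aa, top_count = (ranked[0] if ranked else (None, 0))
    second_aa, second_count = (ranked[1] if len(ranked) > 1 else (None, 0))

    def _call(status: str, meaning: str | None) -> ReassignmentCall:
        return ReassignmentCall(
            taxon=occupancy.taxon,
            codon=codon,
            standard_meaning=standard_aa,
            status=status,
            inferred_meaning=meaning,
            n_positions=n,
            standard_count=std_count,
            top_aa=top_aa,
            top_count=top_count,
            second_aa=second_aa,
            second_count=second_count,
        )

    if n < params.min_positions:
        return _call(STATUS_INSUFFICIENT, None)
    if standard_aa != STOP and std_count / n > params.max_standard_fraction:
        return _call(STATUS_STANDARD, None)
    # candidate reassignment: try to assign a specific amino acid
    if (
        top_aa is not None
        and top_aa != standard_aa
        and top_count >= params.min_top_count
        and top_count >= params.dominance_ratio * second_count
    ):
        return _call(STATUS_SPECIFIC, top_aa)
    if top_aa is not None and top_aa == standard_aa:
        # top residue IS the standard amino acid yet passed the 10% gate;
        # cannot happen when max_standard_fraction < dominance, guard anyway
        return _call(STATUS_STANDARD, None)
    return _call(STATUS_UNKNOWN, UNKNOWN)


# ---------------------------------------------------------------------------
# Ortholog sets and the iterative loop


@dataclass
class OrthologSet:
    """In-frame coding sequences of one gene across taxa, with an optional
    fixed protein alignment (gap pattern per taxon).  Without an alignment
    the CDSs must be co-linear (equal codon counts), as produced by the
    gapless simulator."""

    gene: str
    cds: dict[str, str]
    alignment: dict[str, str] | None = None
    truncated: set[str] = field(default_factory=set)

    def gap_pattern(self, taxon: str) -> str | None:
        if self.alignment is None:
            return None
        return self.alignment.get(taxon)


def _aligned_protein(
    oset: OrthologSet, taxon: str, table: GeneticCodeTable
) -> tuple[str, str]:
    """Translate a taxon's CDS body and re-apply its stored gap pattern.

    The final codon of a complete CDS is the annotated terminator and is
    always excluded from the profiled protein, whatever the current table
    says it means (a provisional table may read it as sense; terminator
    analysis belongs to the stops module).  Truncated (3'-incomplete) CDSs
    carry no terminator and are translated whole.

    Returns (aligned_protein, raw_protein)."""
    body = oset.cds[taxon]
    if taxon not in oset.truncated:
        body = body[:-3]
    raw = translate_cds(body, table, truncated=True).protein
    pattern = oset.gap_pattern(taxon)
    if pattern is None:
        return raw, raw
    out = []
    k = 0
    for ch in pattern:
        if ch == "-":
            out.append("-")
        else:
            out.append(raw[k])
            k += 1
    if k != len(raw):
        raise ValueError(
            f"gap pattern for {taxon!r} in gene {oset.gene!r} expects {k} "
            f"residues, translation has {len(raw)}"
        )
    return "".join(out), raw


def _profile_and_tally(
    osets: Sequence[OrthologSet],
    tables: Mapping[str, GeneticCodeTable],
    cons_params: ConservationParams,
) -> dict[str, OccupancyMatrix]:
    """One recoding pass: translate, align, profile, tally for every taxon."""
    taxa = sorted({t for oset in osets for t in oset.cds})
    conserved: dict[str, list[ConservedColumn]] = {}
    codon_maps: dict[str, dict[str, dict[int, str]]] = {}
    msa_by_gene: dict[str, list[SequenceRecord]] = {}
    for oset in osets:
        records = []
        maps: dict[str, dict[int, str]] = {}
        for taxon in sorted(oset.cds):
            table = tables[taxon]
            aligned, _raw = _aligned_protein(oset, taxon, table)
            records.append(SequenceRecord(id=taxon, residues=aligned))
            codons = list(codes.codon_iter(oset.cds[taxon]))
            mapping: dict[int, str] = {}
            k = 0
            for col, aa in enumerate(aligned):
                if aa == "-":
                    continue
                mapping[col] = codons[k]
                k += 1
            maps[taxon] = mapping
        conserved[oset.gene] = conservation_profile(records, cons_params, gene=oset.gene)
        codon_maps[oset.gene] = maps
        msa_by_gene[oset.gene] = records
    occupancies = {}
    for taxon in taxa:
        per_gene_maps = {
            g: m[taxon] for g, m in codon_maps.items() if taxon in m
        }
        occupancies[taxon] = tally_occupancy(
            taxon, conserved, per_gene_maps, msa_by_gene, cons_params
        )
    return occupancies


def call_all_codons(
    occupancy: OccupancyMatrix, params: InferenceParams
) -> dict[str, ReassignmentCall]:
    """Call every codon the taxon occupies at least one conserved column with."""
    return {
        codon: call_codon_meaning(occupancy, codon, params=params)
        for codon in sorted(occupancy.n_columns_seen)
    }


def _updated_table(
    initial: GeneticCodeTable, calls: Mapping[str, ReassignmentCall], taxon: str
) -> GeneticCodeTable:
    """Build a taxon's working table from its current call set.

    reassigned_specific/unknown codons take the called meaning;
    standard_retained codons revert to the standard meaning; codons with
    insufficient or no data keep the initial table's meaning.
    """
    reassignments = []
    for codon in codes.RNA_CODONS:
        call = calls.get(codon)
        if call is None or call.status == STATUS_INSUFFICIENT:
            meaning = initial.mapping[codon]
        elif call.status == STATUS_STANDARD:
            meaning = _STANDARD.mapping[codon]
        else:
            meaning = call.inferred_meaning
        if meaning != _STANDARD.mapping[codon]:
            reassignments.append((codon, meaning))
    return derive_table(
        _STANDARD, reassignments, name=f"{taxon}_inferred", note="inferred"
    )


@dataclass
class InferenceResult:
    tables: dict[str, GeneticCodeTable]
    history: list[dict[str, dict[str, ReassignmentCall]]]  # per iteration: taxon → codon → call
    converged: bool
    n_iterations: int

    def final_calls(self) -> dict[str, dict[str, ReassignmentCall]]:
        return self.history[-1] if self.history else {}

    def reassigned_calls(self) -> list[ReassignmentCall]:
        return [
            call
            for per_taxon in self.final_calls().values()
            for call in per_taxon.values()
            if call.is_reassigned
        ]

    def history_frame(self) -> pd.DataFrame:
        rows = []
        for it, per_taxon in enumerate(self.history, 1):
            for taxon, per_codon in sorted(per_taxon.items()):
                for codon, c in sorted(per_codon.items()):
                    rows.append(
                        {
                            "iteration": it,
                            "taxon": taxon,
                            "codon": codon,
                            "status": c.status,
                            "meaning": c.inferred_meaning or "",
                            "n_positions": c.n_positions,
                            "top_aa": c.top_aa or "",
                            "top_count": c.top_count,
                            "second_aa": c.second_aa or "",
                            "second_count": c.second_count,
                        }
                    )
        return pd.DataFrame(rows)


def _call_signature(per_taxon: Mapping[str, Mapping[str, ReassignmentCall]]):
    return {
        (taxon, codon): (c.status, c.inferred_meaning)
        for taxon, per_codon in per_taxon.items()
        for codon, c in per_codon.items()
    }


def infer_codes_iterative(
    ortholog_sets: Sequence[OrthologSet],
    initial_tables: Mapping[str, GeneticCodeTable],
    cons_params: ConservationParams = ConservationParams(),
    params: InferenceParams = InferenceParams(),
    realign_hook: Callable[[Sequence[OrthologSet], Mapping[str, GeneticCodeTable]], Sequence[OrthologSet]] | None = None,
) -> InferenceResult:
    """Iterate translate → profile → tally → call → recode to a fixpoint.

    The default "realignment" preserves each gene's stored column mapping
    and only rewrites residue symbols; a user-supplied ``realign_hook`` may
    rebuild alignments between iterations (e.g. by calling an external
    aligner).  The loop stops when an iteration changes no call's status or
    meaning, or after ``params.max_iterations`` (then flagged unconverged).
    """
    taxa = sorted({t for oset in ortholog_sets for t in oset.cds})
    missing = [t for t in taxa if t not in initial_tables]
    if missing:
        raise ValueError(f"no initial table for taxa: {missing}")
    tables = {t: initial_tables[t] for t in taxa}
    history: list[dict[str, dict[str, ReassignmentCall]]] = []
    converged = False
    osets = list(ortholog_sets)
    for _iteration in range(params.max_iterations):
        if realign_hook is not None:
            osets = list(realign_hook(osets, tables))
        occupancies = _profile_and_tally(osets, tables, cons_params)
        iter_calls = {
            taxon: call_all_codons(occ, params) for taxon, occ in occupancies.items()
        }
        history.append(iter_calls)
        new_tables = {
            taxon: _updated_table(initial_tables[taxon], iter_calls[taxon], taxon)
            for taxon in taxa
        }
        # calls are a deterministic function of the tables, so unchanged
        # tables mean the next iteration would repeat this one verbatim
        if all(
            new_tables[t].mapping == tables[t].mapping for t in taxa
        ):
            converged = True
            tables = new_tables
            break
        tables = new_tables
    return InferenceResult(
        tables=tables,
        history=history,
        converged=converged,
        n_iterations=len(history),
    )


@dataclass
class TwoStageResult:
    stage1_calls: dict[str, dict[str, ReassignmentCall]]
    stage2: InferenceResult

    @property
    def tables(self) -> dict[str, GeneticCodeTable]:
        return self.stage2.tables


def two_stage_analysis(
    reference_sets: Sequence[OrthologSet],
    focal_sets: Sequence[OrthologSet],
    initial_focal_tables: Mapping[str, GeneticCodeTable],
    cons_params: ConservationParams = ConservationParams(),
    params: InferenceParams = InferenceParams(),
) -> TwoStageResult:
    """Broad-panel seeding followed by focal-only iteration.

    Stage 1 profiles conservation jointly over the reference panel (assumed
    standard code) and the focal taxa, and calls focal codons once — the
    analog of the paneukaryotic screen.  Stage 2 runs the full iterative
    loop on the focal taxa alone, seeded with the stage-1 tables, where the
    closer relatives provide many more conserved columns.  A gene present in
    the focal set but missing from the reference panel is used in stage 2
    only.
    """
    ref_taxa = sorted({t for oset in reference_sets for t in oset.cds})
    focal_taxa = sorted({t for oset in focal_sets for t in oset.cds})
    overlap = set(ref_taxa) & set(focal_taxa)
    if overlap:
        raise ValueError(f"taxa in both reference and focal sets: {sorted(overlap)}")

    ref_by_gene = {o.gene: o for o in reference_sets}
    joint_sets = []
    for oset in focal_sets:
        ref = ref_by_gene.get(oset.gene)
        if ref is None:
            continue  # focal-only gene (atp6-style): stage 2 only
        if oset.alignment is not None or ref.alignment is not None:
            joint_align = {**(ref.alignment or {}), **(oset.alignment or {})}
        else:
            joint_align = None
        joint_sets.append(
            OrthologSet(
                gene=oset.gene,
                cds={**ref.cds, **oset.cds},
                alignment=joint_align,
                truncated=set(ref.truncated) | set(oset.truncated),
            )
        )
    std = standard_table()
    joint_tables = {t: std for t in ref_taxa}
    joint_tables.update({t: initial_focal_tables[t] for t in focal_taxa})

    occupancies = _profile_and_tally(joint_sets, joint_tables, cons_params) if joint_sets else {}
    stage1_calls = {
        taxon: call_all_codons(occ, params)
        for taxon, occ in occupancies.items()
        if taxon in set(focal_taxa)
    }
    seeded = {
        taxon: _updated_table(
            initial_focal_tables[taxon], stage1_calls.get(taxon, {}), taxon
        )
        for taxon in focal_taxa
    }
    stage2 = infer_codes_iterative(focal_sets, seeded, cons_params, params)
    return TwoStageResult(stage1_calls=stage1_calls, stage2=stage2)
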