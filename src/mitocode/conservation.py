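"""Conserved alignment columns and codon occupancy beneath them.

The central evidence object of the pipeline: for every alignment column in
which a single amino acid reaches the conservation threshold (default 70%),
tally which codon each focal taxon carries under that column.  A codon that
repeatedly sits under columns conserved for an amino acid other than its
standard one is a reassignment candidate.

``X`` (unknown), ``'*'`` (provisional internal stop), and gaps never count
as dominant residues and never match one; a threshold above 0.5 guarantees
at most one dominant residue per column.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codes import GeneticCodeTable, STOP, UNKNOWN, codon_iter
from .io_formats import SequenceRecord

GAP = "-"
_NON_RESIDUE = {GAP, UNKNOWN, STOP}


@dataclass(frozen=True)
class ConservationParams:
    min_fraction: float = 0.70
    gap_policy: str = "count_gaps_in_denominator"  # or "exclude_gaps"
    include_self: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must lie in (0.5, 1]")
        if self.gap_policy not in ("count_gaps_in_denominator", "exclude_gaps"):
            raise ValueError(f"unknown gap_policy {self.gap_policy!r}")


@dataclass(frozen=True)
class ConservedColumn:
    gene: str
    column: int
    dominant_aa: str
    fraction: float


def _column_counters(records: Sequence[SequenceRecord]) -> list[Counter]:
    length = len(records[0].residues)
    for rec in records:
        if len(rec.residues) != length:
            raise ValueError(
                f"ragged alignment: {rec.id!r} has length {len(rec.residues)}, "
                f"expected {length}"
            )
    counters = [Counter() for _ in range(length)]
    for rec in records:
        for i, aa in enumerate(rec.residues):
            counters[i][aa] += 1
    return counters


def _dominant(counter: Counter, n_rows: int, params: ConservationParams):
    """Return (aa, fraction) for the dominant residue of a column, or None."""
    if params.gap_policy == "exclude_gaps":
        denom = n_rows - counter.get(GAP, 0)
    else:
        denom = n_rows
    if denom == 0:
        return None
    best_aa, best_n = None, 0
    for aa, n in counter.items():
        if aa in _NON_RESIDUE:
            continue
        if n > best_n:
            best_aa, best_n = aa, n
    if best_aa is None:
        return None
    frac = best_n / denom
    if frac >= params.min_fraction:
        return best_aa, frac
    return None


def conservation_profile(
    protein_msa: Sequence[SequenceRecord],
    params: ConservationParams = ConservationParams(),
    gene: str = "",
) -> list[ConservedColumn]:
    """Emit one :class:`ConservedColumn` per column whose dominant amino acid
    reaches ``min_fraction`` under the configured gap policy."""
    if not protein_msa:
        return []
    counters = _column_counters(protein_msa)
    out = []
    for col, counter in enumerate(counters):
        hit = _dominant(counter, len(protein_msa), params)
        if hit is not None:
            out.append(ConservedColumn(gene=gene, column=col, dominant_aa=hit[0], fraction=hit[1]))
    return out


def map_codon_columns(
    codon_cds: str, aligned_protein: str, table: GeneticCodeTable
) -> dict[int, str]:
    """Map alignment columns of ``aligned_protein`` to RNA codons of the CDS.

    The k-th non-gap column maps to the k-th codon.  The ungapped protein
    must equal the conceptual translation of the CDS under ``table``
    (terminal stop ignored; X and '*' kept as is).
    """
    from .codes import translate_cds

    expected = translate_cds(codon_cds, table).protein
    ungapped = aligned_protein.replace(GAP, "")
    if ungapped != expected:
        raise ValueError(
            "aligned protein does not match translation of CDS "
            f"(alignment gives {ungapped!r}, translation gives {expected!r})"
        )
    codons = list(codon_iter(codon_cds))
    mapping: dict[int, str] = {}
    k = 0
    for col, aa in enumerate(aligned_protein):
        if aa == GAP:
            continue
        mapping[col] = codons[k]
        k += 1
    return mapping


@dataclass
class OccupancyMatrix:
    """Per-taxon codon occupancy under conserved columns, aggregated across
    all genes.  ``counts[codon][dominant_aa]`` is the number of conserved
    columns (for that amino acid) where the taxon carries the codon;
    ``n_columns_seen[codon]`` is the row sum."""

    taxon: str
    counts: dict[str, Counter] = field(default_factory=dict)
    n_columns_seen: Counter = field(default_factory=Counter)

    def add(self, codon: str, dominant_aa: str) -> None:
        self.counts.setdefault(codon, Counter())[dominant_aa] += 1
        self.n_columns_seen[codon] += 1

    def row(self, codon: str) -> Counter:
        return self.counts.get(codon, Counter())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon": self.taxon, "codon": c, "dominant_aa": aa, "count": n}
            for c, ctr in sorted(self.counts.items())
            for aa, n in sorted(ctr.items())
        ]
        return pd.DataFrame(rows, columns=["taxon", "codon", "dominant_aa", "count"])


def tally_occupancy(
    taxon: str,
    conserved_columns: Mapping[str, Sequence[ConservedColumn]],
    codon_maps: Mapping[str, Mapping[int, str]],
    msa_by_gene: Mapping[str, Sequence[SequenceRecord]] | None = None,
    params: ConservationParams = ConservationParams(),
) -> OccupancyMatrix:
    """Tally the focal taxon's codons under conserved columns of every gene.

    ``conserved_columns`` and ``codon_maps`` are keyed by gene; a gene absent
    from ``codon_maps`` (taxon missing that gene) contributes nothing.
    Codons containing N are skipped: no amino-acid identity claim is
    possible for them.  With ``params.include_self`` off, each column's
    dominance is re-evaluated with the focal taxon's own row removed
    (``msa_by_gene`` is then required).
    """
    occ = OccupancyMatrix(taxon=taxon)
    for gene, columns in conserved_columns.items():
        cmap = codon_maps.get(gene)
        if cmap is None:
            continue
        counters = None
        n_rows = 0
        if not params.include_self:
            if msa_by_gene is None:
                raise ValueError("include_self=False requires msa_by_gene")
            msa = msa_by_gene[gene]
            counters = _column_counters(msa)
            n_rows = len(msa) - 1
            self_rows = [r for r in msa if r.id == taxon]
            self_seq = self_rows[0].residues if self_rows else None
        for cc in columns:
            codon = cmap.get(cc.column)
            if codon is None or "N" in codon:
                continue
            if not params.include_self and counters is not None:
                ctr = Counter(counters[cc.column])
                if self_seq is not None:
                    ctr[self_seq[cc.column]] -= 1
                hit = _dominant(ctr, n_rows, params)
                if hit is None:
                    continue
                occ.add(codon, hit[0])
            else:
                occ.add(codon, cc.dominant_aa)
    return occ


def occupancy_to_tsv(matrices: Iterable[OccupancyMatrix], dest) -> None:
    """Export long-format TSV (taxon, codon, dominant_aa, count) — the data
    behind per-taxon occupancy bar panels."""
    frames = [m.to_frame() for m in matrices]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["taxon", "codon", "dominant_aa", "count"])
    )
    with open(dest, "w") if isinstance(dest, str) else _nullctx(dest) as fh:
        fh.write("# taxon\tcodon\tdominant_aa\tcount\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


class _nullctx:
    def __init__(self, fh):
        self.fh = fh

    def __enter__(self):
        return self.fh

    def __exit__(self, *exc):
        return False
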