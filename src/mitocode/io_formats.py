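"""Readers and writers for the pipeline's external formats, plus the
ortholog acceptance filter.

Formats handled: FASTA (sequences and gapped alignments), tab-separated
tRNA annotation tables (both the tRNAscan-SE tabular dialect and a minimal
5+-column TSV), and BLAST-outfmt-6-like hit tables carrying an extra
``subject_gene`` column.  Nucleotide sequences are stored DNA-alphabet
internally (U is folded to T on input); codons are reported in the RNA
alphabet in all user-facing outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# FASTA


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    description: str = ""


_NT_CHARS = set("ACGTUN-")


def _looks_nucleotide(residues: str) -> bool:
    return bool(residues) and set(residues) <= _NT_CHARS


def _as_handle(source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source)
    return source


def parse_fasta(source, normalize_u: bool = True) -> list[SequenceRecord]:
    """Parse FASTA text into :class:`SequenceRecord` objects.

    Residues are uppercased; for nucleotide-looking records U is normalized
    to T unless ``normalize_u`` is off.  Duplicate ids and empty input are
    format errors.
    """
    handle = _as_handle(source)
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            residues = str(rec.seq).upper()
            if normalize_u and _looks_nucleotide(residues):
                residues = residues.replace("U", "T")
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    if not records:
        raise FormatError("no FASTA records found (empty input?)")
    return records


def write_fasta(records: Iterable[SequenceRecord], dest) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            SeqIO.write(bio, fh, "fasta-2line")
    else:
        SeqIO.write(bio, dest, "fasta-2line")


# ---------------------------------------------------------------------------
# tRNA tables

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}
_ISOTYPE_SPECIAL = {"fMet", "?"}


def normalize_isotype(raw: str) -> str:
    raw = raw.strip()
    if raw in _ISOTYPE_SPECIAL:
        return raw
    if raw in ("iMet", "fMet"):
        return "fMet"
    if raw in _AA3TO1:
        return _AA3TO1[raw]
    if raw in _AA1TO3:
        return raw
    if raw in ("Undet", "Sup", "Pseudo", "", "???"):
        return "?"
    raise FormatError(f"unrecognized tRNA isotype {raw!r}")


@dataclass(frozen=True)
class TRNARecord:
    """One tRNA gene annotation (tRNAscan-SE-style).

    ``anticodon`` is kept 5'→3' in the RNA alphabet; ``isotype`` is a
    one-letter amino acid, ``"fMet"``, or ``"?"`` for undetermined.
    """

    taxon: str
    anticodon: str
    isotype: str
    begin: int = 0
    end: int = 0
    strand: str = "+"
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or set(self.anticodon) - set("ACGU"):
            raise FormatError(f"invalid anticodon {self.anticodon!r}")
        if self.begin > self.end:
            raise FormatError(f"begin {self.begin} > end {self.end}")


def _norm_anticodon(raw: str, lineno: int) -> str:
    ac = raw.strip().upper().replace("T", "U")
    if len(ac) != 3 or set(ac) - set("ACGU"):
        raise FormatError(f"line {lineno}: malformed anticodon {raw!r}")
    return ac


def parse_trna_table(source) -> list[TRNARecord]:
    """Parse a tRNA annotation table, auto-detecting the dialect.

    Accepted dialects: the tRNAscan-SE tabular output (Sequence/Name header
    banner, columns Name, tRNA#, Begin, End, Type, Codon, ...) and a minimal
    TSV with a header line naming at least taxon/anticodon/isotype/begin/end.
    """
    handle = _as_handle(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    # drop blank lines but keep numbering for error messages
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        return []
    first = rows[0][1]
    if first.lstrip("# ").lower().startswith("sequence") or "trna #" in first.lower():
        return _parse_trnascan(rows)
    return _parse_minimal(rows)


def _parse_trnascan(rows: list[tuple[int, str]]) -> list[TRNARecord]:
    records = []
    for lineno, line in rows:
        if line.lstrip().startswith(("Sequence", "Name", "--")):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 6:
            raise FormatError(f"line {lineno}: expected >= 6 tab-separated columns")
        taxon, _num, begin, end, isotype, anticodon = parts[:6]
        b, e = int(begin), int(end)
        strand = "+" if b <= e else "-"
        if b > e:
            b, e = e, b
        records.append(
            TRNARecord(
                taxon=taxon,
                anticodon=_norm_anticodon(anticodon, lineno),
                isotype=normalize_isotype(isotype),
                begin=b,
                end=e,
                strand=strand,
                note="\t".join(parts[6:]),
            )
        )
    return records


def _parse_minimal(rows: list[tuple[int, str]]) -> list[TRNARecord]:
    header_line = rows[0][1].lstrip("# ").lower()
    cols = [c.strip() for c in header_line.split("\t")]
    required = {"taxon", "anticodon", "isotype", "begin", "end"}
    if not required <= set(cols):
        raise FormatError(
            f"tRNA table header must name columns {sorted(required)}; got {cols}"
        )
    idx = {c: i for i, c in enumerate(cols)}
    records = []
    for lineno, line in rows[1:]:
        if line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        get = lambda c, default="": parts[idx[c]] if c in idx and idx[c] < len(parts) else default
        records.append(
            TRNARecord(
                taxon=get("taxon"),
                anticodon=_norm_anticodon(get("anticodon"), lineno),
                isotype=normalize_isotype(get("isotype")),
                begin=int(get("begin", "0")),
                end=int(get("end", "0")),
                strand=get("strand", "+") or "+",
                note=get("note"),
            )
        )
    return records


def write_trna_table(records: Iterable[TRNARecord], dest) -> None:
    """Write the minimal TSV dialect (round-trips through parse_trna_table)."""
    buf = io.StringIO()
    buf.write("# taxon\tanticodon\tisotype\tbegin\tend\tstrand\tnote\n")
    for r in records:
        buf.write(
            f"{r.taxon}\t{r.anticodon}\t{r.isotype}\t{r.begin}\t{r.end}\t{r.strand}\t{r.note}\n"
        )
    text = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


# ---------------------------------------------------------------------------
# Ortholog acceptance filter


@dataclass(frozen=True)
class HitTableRow:
    query_id: str
    subject_id: str
    subject_gene: str
    evalue: float
    rank: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")


@dataclass(frozen=True)
class OrthologFilterParams:
    """Acceptance rule: a query is an ortholog of gene g iff all of its
    ``top_k`` best-ranked hits are to gene g and every one has
    e-value < ``evalue_max``."""

    top_k: int = 10
    evalue_max: float = 1e-30

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")


def read_hit_table(source) -> list[HitTableRow]:
    """Read a TSV hit table: query_id, subject_id, subject_gene, evalue[, rank].

    When the rank column is absent, ranks are assigned by file order within
    each query (ties in e-value therefore keep file order).
    """
    handle = _as_handle(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    rows: list[HitTableRow] = []
    counters: dict[str, int] = {}
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 4:
            raise FormatError(f"line {lineno}: expected >= 4 columns")
        q, s, gene, ev = parts[:4]
        if len(parts) >= 5 and parts[4]:
            rank = int(parts[4])
        else:
            counters[q] = counters.get(q, 0) + 1
            rank = counters[q]
        rows.append(HitTableRow(q, s, gene, float(ev), rank))
    return rows


def filter_orthologs(
    rows: Sequence[HitTableRow], params: OrthologFilterParams = OrthologFilterParams()
) -> dict[str, str]:
    """Apply the acceptance rule; return accepted query id → ortholog group.

    Queries with fewer than ``top_k`` hits are rejected (the rule is stated
    over the full top-k list; fewer hits is weaker evidence).
    """
    by_query: dict[str, list[HitTableRow]] = {}
    for row in rows:
        by_query.setdefault(row.query_id, []).append(row)
    accepted: dict[str, str] = {}
    for query, hits in by_query.items():
        hits = sorted(hits, key=lambda h: h.rank)
        ranks = [h.rank for h in hits]
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"duplicate ranks for query {query!r}")
        top = hits[: params.top_k]
        if len(top) < params.top_k:
            continue
        genes = {h.subject_gene for h in top}
        if len(genes) == 1 and all(h.evalue < params.evalue_max for h in top):
            accepted[query] = top[0].subject_gene
    return accepted
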