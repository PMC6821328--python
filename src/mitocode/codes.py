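"""Genetic-code tables and conceptual translation.

A :class:`GeneticCodeTable` is a total map from the 64 RNA codons to either a
one-letter amino-acid symbol, the stop sentinel ``"*"``, or the unknown
sentinel ``"X"``.  Codons are handled in the RNA alphabet in all user-facing
interfaces (UAG, UCA, ...), while coding sequences themselves are DNA.

Translation renders in-frame internal stop codons as ``'*'`` (and records
their positions) rather than dropping them: during iterative code inference a
sequence is deliberately translated under a provisional table that may still
be wrong, and downstream conservation counting must be able to ignore those
columns.  ``X`` is treated as a first-class 21st symbol throughout the
package: it never matches any amino acid and never dominates a column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable as _BioCodonTable

STOP = "*"
UNKNOWN = "X"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

RNA_BASES = "ACGU"
RNA_CODONS = tuple(a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES)

_VALID_MEANINGS = set(AMINO_ACIDS) | {STOP, UNKNOWN}


def dna_to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def rna_to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def _standard_mapping() -> dict[str, str]:
    tbl = _BioCodonTable.unambiguous_dna_by_id[1]
    mapping = {dna_to_rna(c): aa for c, aa in tbl.forward_table.items()}
    for c in tbl.stop_codons:
        mapping[dna_to_rna(c)] = STOP
    return mapping


_STANDARD = _standard_mapping()


@dataclass(frozen=True)
class GeneticCodeTable:
    """A complete 64-codon translation table.

    ``deviations`` lists exactly the codons whose meaning differs from the
    standard code, as ``(codon, standard_meaning, new_meaning, note)`` tuples.
    """

    name: str
    mapping: Mapping[str, str]
    deviations: tuple[tuple[str, str, str, str], ...] = ()

    def __post_init__(self) -> None:
        if set(self.mapping) != set(RNA_CODONS):
            missing = set(RNA_CODONS) - set(self.mapping)
            extra = set(self.mapping) - set(RNA_CODONS)
            raise ValueError(
                f"mapping must cover all 64 RNA codons (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )
        bad = {c: m for c, m in self.mapping.items() if m not in _VALID_MEANINGS}
        if bad:
            raise ValueError(f"invalid meanings: {bad}")
        expect = tuple(
            c for c in RNA_CODONS if self.mapping[c] != _STANDARD[c]
        )
        have = tuple(c for c, *_ in self.deviations)
        if tuple(sorted(have)) != tuple(sorted(expect)):
            raise ValueError(
                f"deviations {sorted(have)} inconsistent with mapping "
                f"(expected deviations at {sorted(expect)})"
            )

    def __getitem__(self, codon: str) -> str:
        return self.mapping[dna_to_rna(codon)]

    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in RNA_CODONS if self.mapping[c] == STOP)

    def codons_for(self, meaning: str) -> tuple[str, ...]:
        return tuple(c for c in RNA_CODONS if self.mapping[c] == meaning)

    # -- serialization --------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "mapping": dict(sorted(self.mapping.items())),
                "deviations": [list(d) for d in self.deviations],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneticCodeTable":
        obj = json.loads(text)
        return cls(
            name=obj["name"],
            mapping=dict(obj["mapping"]),
            deviations=tuple(tuple(d) for d in obj["deviations"]),
        )


def standard_table() -> GeneticCodeTable:
    return GeneticCodeTable(name="standard", mapping=dict(_STANDARD))


def derive_table(
    base: GeneticCodeTable,
    reassignments: Sequence[tuple[str, str]],
    name: str | None = None,
    note: str = "derived",
) -> GeneticCodeTable:
    """Return a table differing from ``base`` exactly at ``reassignments``.

    The deviations list of the result is always computed against the
    *standard* table, regardless of what ``base`` was.
    """
    seen: set[str] = set()
    mapping = dict(base.mapping)
    notes = {c: n for c, _s, _m, n in base.deviations}
    for codon, meaning in reassignments:
        codon = dna_to_rna(codon)
        if codon not in mapping:
            raise ValueError(f"invalid codon {codon!r}")
        if meaning not in _VALID_MEANINGS:
            raise ValueError(f"invalid meaning {meaning!r} for codon {codon}")
        if codon in seen:
            raise ValueError(f"duplicate codon {codon} in reassignments")
        seen.add(codon)
        mapping[codon] = meaning
        notes[codon] = note
    deviations = tuple(
        (c, _STANDARD[c], mapping[c], notes.get(c, note))
        for c in RNA_CODONS
        if mapping[c] != _STANDARD[c]
    )
    return GeneticCodeTable(
        name=name if name is not None else base.name + "+derived",
        mapping=mapping,
        deviations=deviations,
    )


#: NCBI-numbered tables the package ships: 1 = standard; 16 = the
#: chlorophycean mitochondrial code (UAG = Leu); 22 = the Scenedesmus
#: obliquus mitochondrial code (UAG = Leu, UCA = stop).
_BUILTIN_IDS = (1, 16, 22)


def builtin_table(table_id: int) -> GeneticCodeTable:
    if table_id == 1:
        return standard_table()
    if table_id == 16:
        return derive_table(
            standard_table(),
            [("UAG", "L")],
            name="chlorophycean_mitochondrial_16",
            note="stop-to-Leu UAG (NCBI table 16)",
        )
    if table_id == 22:
        return derive_table(
            builtin_table(16),
            [("UCA", STOP)],
            name="scenedesmus_obliquus_mitochondrial_22",
            note="Ser-to-stop UCA (NCBI table 22)",
        )
    raise ValueError(
        f"unsupported table id {table_id}; supported ids: {_BUILTIN_IDS}"
    )


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    terminal_codon: str  # RNA 3-mer, or "truncated"
    internal_stop_positions: tuple[int, ...] = ()

    @property
    def has_internal_stops(self) -> bool:
        return bool(self.internal_stop_positions)


def translate_cds(
    cds: str, table: GeneticCodeTable, truncated: bool = False
) -> TranslationResult:
    """Conceptually translate an in-frame coding sequence.

    A trailing codon that maps to stop is reported as ``terminal_codon`` and
    excluded from the protein.  Codons containing any base outside ACGT(U)
    translate to ``X``.  A CDS whose length is not a multiple of 3, or one
    explicitly flagged ``truncated`` (3'-incomplete), gets
    ``terminal_codon="truncated"`` and no terminal-stop removal.
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) < 3:
        raise ValueError(f"CDS shorter than one codon: {len(seq)} nt")
    if len(seq) % 3 != 0:
        truncated = True
        seq = seq[: len(seq) - len(seq) % 3]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]

    def meaning(c: str) -> str:
        if any(b not in "ACGT" for b in c):
            return UNKNOWN
        return table[c]

    meanings = [meaning(c) for c in codons]
    if truncated:
        terminal = "truncated"
        body = meanings
    else:
        terminal = dna_to_rna(codons[-1])
        body = meanings[:-1] if meanings[-1] == STOP else meanings
    internal = tuple(i for i, m in enumerate(body) if m == STOP)
    return TranslationResult(
        protein="".join(body),
        terminal_codon=terminal,
        internal_stop_positions=internal,
    )


def codon_iter(cds: str) -> Iterable[str]:
    """Yield successive RNA codons of an in-frame CDS (complete codons only)."""
    seq = dna_to_rna(cds.upper())
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i : i + 3]
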