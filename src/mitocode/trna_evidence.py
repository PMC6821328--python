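"""Cognate-tRNA lookup under wobble/inosine pairing rules, and concordance
of tRNA repertoires with reassignment calls.

An anticodon (read 5'→3', positions 34-35-36) pairs antiparallel with a
codon: anticodon positions 36 and 35 must be strict Watson–Crick complements
of codon positions 1 and 2, while position 34 pairs with the codon's third
base under relaxed rules.  Defaults: G34 reads U/C; U34 reads A/G; C34 reads
G only; A34 is treated as inosine-capable (reads U/C/A), reflecting the I34
route by which a single tRNA-Arg(ACG) serves the CGN box in most organellar
systems.  A superwobble mode (U34 reads all four) is available.

Predicted tRNA isotypes are soft evidence: covariance-model isotype
predictions are repeatedly overridden by occupancy evidence in this system,
so a mismatching isotype yields a "neutral" verdict with a note rather than
a contradiction.  "Contradicted" is reserved for a reassigned codon whose
only cognate tRNAs carry the codon's *standard* meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .codes import STOP, dna_to_rna
from .inference import ReassignmentCall
from .io_formats import TRNARecord

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class PairingRules:
    superwobble_U: bool = False
    A_as_inosine: bool = True

    def third_position_reads(self, anticodon_34: str) -> frozenset[str]:
        """Codon third bases readable by a given anticodon first base."""
        if anticodon_34 == "G":
            return frozenset("UC")
        if anticodon_34 == "U":
            return frozenset("AGUC") if self.superwobble_U else frozenset("AG")
        if anticodon_34 == "C":
            return frozenset("G")
        if anticodon_34 == "A":
            return frozenset("UCA") if self.A_as_inosine else frozenset("U")
        raise ValueError(f"invalid anticodon base {anticodon_34!r}")


def wobble_decodes(anticodon: str, codon: str, rules: PairingRules = PairingRules()) -> bool:
    """True iff the anticodon reads the codon under the pairing rules."""
    anticodon = dna_to_rna(anticodon)
    codon = dna_to_rna(codon)
    for trip, label in ((anticodon, "anticodon"), (codon, "codon")):
        if len(trip) != 3 or set(trip) - set("ACGU"):
            raise ValueError(f"invalid {label} {trip!r}")
    if _WC[anticodon[2]] != codon[0] or _WC[anticodon[1]] != codon[1]:
        return False
    return codon[2] in rules.third_position_reads(anticodon[0])


def cognate_trnas(
    codon: str,
    trna_set: Sequence[TRNARecord],
    rules: PairingRules = PairingRules(),
) -> list[TRNARecord]:
    """All records in the (single-taxon) set whose anticodon decodes the codon,
    in stable input order."""
    return [t for t in trna_set if wobble_decodes(t.anticodon, codon, rules)]


VERDICT_SUPPORTED = "supported"
VERDICT_CONTRADICTED = "contradicted"
VERDICT_NO_DATA = "no_trna_data"
VERDICT_NEUTRAL = "neutral"


@dataclass(frozen=True)
class ConcordanceRecord:
    taxon: str
    codon: str
    call: ReassignmentCall
    cognate_trnas: tuple[TRNARecord, ...]
    verdict: str
    note: str = ""


def _classify_one(
    call: ReassignmentCall,
    cognates: Sequence[TRNARecord],
    has_trna_data: bool,
) -> tuple[str, str]:
    if not has_trna_data:
        return VERDICT_NO_DATA, "taxon lacks a complete mitogenome; tRNA status unknown"
    if not call.is_reassigned:
        return VERDICT_NEUTRAL, ""
    if not cognates:
        return (
            VERDICT_NEUTRAL,
            "no mitogenome-encoded cognate tRNA found "
            "(cytoplasmic tRNA import not modeled)",
        )
    isotypes = {t.isotype for t in cognates}
    inferred = call.inferred_meaning
    if inferred is not None and (inferred in isotypes or "?" in isotypes):
        return VERDICT_SUPPORTED, ""
    standard = call.standard_meaning
    if standard != STOP and isotypes <= {standard}:
        return (
            VERDICT_CONTRADICTED,
            "only cognate tRNAs carry the codon's standard meaning",
        )
    return (
        VERDICT_NEUTRAL,
        "cognate tRNA present but predicted isotype "
        f"({','.join(sorted(isotypes))}) differs from the inferred meaning; "
        "isotype prediction overridden by occupancy evidence",
    )


def evidence_concordance(
    calls: Iterable[ReassignmentCall],
    trna_tables: Mapping[str, Sequence[TRNARecord]],
    rules: PairingRules = PairingRules(),
    taxa_with_complete_mitogenome: set[str] | None = None,
) -> list[ConcordanceRecord]:
    """Classify each reassignment call against the taxon's tRNA repertoire.

    Taxa outside ``taxa_with_complete_mitogenome`` (default: taxa present in
    ``trna_tables``) get ``no_trna_data``: absence of a tRNA gene can only be
    asserted from a complete mitogenome.
    """
    if taxa_with_complete_mitogenome is None:
        taxa_with_complete_mitogenome = set(trna_tables)
    out = []
    for call in calls:
        complete = call.taxon in taxa_with_complete_mitogenome
        cognates = tuple(
            cognate_trnas(call.codon, trna_tables.get(call.taxon, ()), rules)
        )
        verdict, note = _classify_one(call, cognates, complete)
        out.append(
            ConcordanceRecord(
                taxon=call.taxon,
                codon=call.codon,
                call=call,
                cognate_trnas=cognates,
                verdict=verdict,
                note=note,
            )
        )
    return out


def concordance_to_tsv(records: Sequence[ConcordanceRecord], dest) -> None:
    lines = ["# taxon\tcodon\tn_positions\tmeaning\tcognate_trna\tverdict\tnote"]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.taxon,
                    r.codon,
                    str(r.call.n_positions),
                    r.call.inferred_meaning or r.call.standard_meaning,
                    ";".join(t.anticodon for t in r.cognate_trnas) or "-",
                    r.verdict,
                    r.note,
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            fh.write(text)
    else:
        dest.write(text)
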