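"""Diagnostic-residue scan of mitochondrial release factor (mtRF1a) proteins.

Bacterial-type release factors discriminate stop codons through a handful
of residues; in reference numbering (the Thermus thermophilus RF1 protein)
the positions of interest are:

* 181 (Gln): recognition of guanine at the third codon position.  Q here
  means the factor can read UAG as stop; any other residue predicts UAG
  blindness, permitting stop-to-sense UAG reassignment.
* 186 (Thr): discrimination of adenine against guanine at the second codon
  position (RF1 specificity); 206 (Ser in RF2): acceptance of both A and G
  there.  Loss of Thr186 combined with Ser206 marks an RF2-like factor
  able to read UGA as stop.
* 182 (Arg): its loss is hypothesized to let the factor accept cytosine at
  the second position, i.e. to read the derived stops UCA/UCG.

The 181 and 186/206 rules are established structural findings; the 182 rule
is a hypothesis, and is labeled as such in output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import SequenceRecord

GAP = "-"

FLAG_UAG_STOP = "UAG_stop_capable"
FLAG_UAG_BLIND = "UAG_blind"
FLAG_RF2_LIKE = "RF2_like_UGA"
FLAG_UCA_UCG = "UCA_UCG_hypothesis"

EVIDENCE_LEVEL = {
    FLAG_UAG_STOP: "established",
    FLAG_UAG_BLIND: "established",
    FLAG_RF2_LIKE: "established",
    FLAG_UCA_UCG: "paper_hypothesis",
}

DEFAULT_POSITIONS = (181, 182, 186, 206)


@dataclass(frozen=True)
class RFPositionSet:
    reference_id: str
    positions: tuple[int, ...] = DEFAULT_POSITIONS

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("positions must be nonempty")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be sorted and unique")
        if min(self.positions) < 1:
            raise ValueError("positions are 1-based (>= 1)")


@dataclass(frozen=True)
class RFProfile:
    sequence_id: str
    residues: dict[int, str]  # reference position → residue or '-'
    flags: frozenset[str]
    warnings: tuple[str, ...] = ()


def map_reference_positions(
    msa: Sequence[SequenceRecord], position_set: RFPositionSet
) -> dict[str, dict[int, str]]:
    """Read each sequence's residue at reference-numbered positions.

    Reference position p is the column holding the reference's p-th non-gap
    residue; every sequence reports its residue (or gap) in that column.
    """
    by_id = {r.id: r for r in msa}
    if position_set.reference_id not in by_id:
        raise ValueError(f"reference {position_set.reference_id!r} absent from alignment")
    ref = by_id[position_set.reference_id]
    columns: dict[int, int] = {}
    count = 0
    for col, aa in enumerate(ref.residues):
        if aa == GAP:
            continue
        count += 1
        if count in position_set.positions:
            columns[count] = col
    deficit = [p for p in position_set.positions if p not in columns]
    if deficit:
        raise ValueError(
            f"reference has only {count} non-gap residues; positions {deficit} "
            "out of range"
        )
    out = {}
    for rec in msa:
        if len(rec.residues) != len(ref.residues):
            raise ValueError(f"ragged alignment at {rec.id!r}")
        out[rec.id] = {p: rec.residues[columns[p]] for p in position_set.positions}
    return out


def classify_rf_profile(residues: Mapping[int, str]) -> frozenset[str]:
    """Pure classification of the four diagnostic residues into flags.

    A gap at a diagnostic position yields no flag for the rules it takes
    part in (partial, e.g. transcriptome-derived, sequences).
    """
    flags = set()
    r181 = residues.get(181, GAP)
    r182 = residues.get(182, GAP)
    r186 = residues.get(186, GAP)
    r206 = residues.get(206, GAP)
    if r181 == "Q":
        flags.add(FLAG_UAG_STOP)
    elif r181 != GAP:
        flags.add(FLAG_UAG_BLIND)
    if r186 not in (GAP, "T") and r206 == "S":
        flags.add(FLAG_RF2_LIKE)
    if r182 not in (GAP, "R"):
        flags.add(FLAG_UCA_UCG)
    return frozenset(flags)


def scan_alignment(
    msa: Sequence[SequenceRecord], position_set: RFPositionSet
) -> list[RFProfile]:
    residues_by_id = map_reference_positions(msa, position_set)
    profiles = []
    for rec in msa:
        residues = residues_by_id[rec.id]
        warnings = tuple(
            f"gap at diagnostic position {p}" for p in sorted(residues) if residues[p] == GAP
        )
        profiles.append(
            RFProfile(
                sequence_id=rec.id,
                residues=residues,
                flags=classify_rf_profile(residues),
                warnings=warnings,
            )
        )
    return profiles


def profiles_to_tsv(profiles: Sequence[RFProfile], dest) -> None:
    positions = sorted(profiles[0].residues) if profiles else []
    header = "# sequence_id\t" + "\t".join(f"pos{p}" for p in positions)
    header += "\tflags\tevidence_levels\twarnings"
    lines = [header]
    for pr in profiles:
        flags = sorted(pr.flags)
        lines.append(
            "\t".join(
                [pr.sequence_id]
                + [pr.residues[p] for p in positions]
                + [
                    ";".join(flags) or "-",
                    ";".join(EVIDENCE_LEVEL[f] for f in flags) or "-",
                    ";".join(pr.warnings) or "-",
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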