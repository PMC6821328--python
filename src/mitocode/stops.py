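"""Termination-codon usage per gene and sense-to-stop candidate detection.

A codon is a sense-to-stop candidate in a genome when, across the standard
conserved genes, it never occurs internally (in-frame, non-terminal), it
terminates at least one gene, and no mitogenome-encoded tRNA is cognate to
it.  A codon observed internally at least once is sense; a codon absent
entirely is indeterminate — no evidence either way, but worth reporting for
codon-disappearance bookkeeping.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .codes import GeneticCodeTable, RNA_CODONS, STOP, codon_iter
from .io_formats import TRNARecord
from .trna_evidence import PairingRules, cognate_trnas


@dataclass(frozen=True)
class StopUsage:
    taxon: str
    gene: str
    terminal_codon: str  # RNA 3-mer or "truncated"
    is_standard_stop: bool


@dataclass(frozen=True)
class StopCandidate:
    taxon: str
    codon: str
    n_genes_terminal: int
    n_internal_occurrences: int
    cognate_trna_present: bool | None  # None = tRNA status unknown
    verdict: str  # candidate_stop | sense | indeterminate
    caveat: str = ""


VERDICT_CANDIDATE = "candidate_stop"
VERDICT_SENSE = "sense"
VERDICT_INDETERMINATE = "indeterminate"


def terminal_codons(
    taxon: str,
    genes: Mapping[str, str],
    table: GeneticCodeTable,
    truncated: set[str] | frozenset[str] = frozenset(),
) -> list[StopUsage]:
    """One :class:`StopUsage` per (taxon, gene); 3'-incomplete genes get
    ``terminal_codon="truncated"`` (the Table-1 question marks)."""
    out = []
    for gene in sorted(genes):
        if gene in truncated or len(genes[gene]) % 3 != 0:
            out.append(StopUsage(taxon, gene, "truncated", False))
            continue
        codons = list(codon_iter(genes[gene]))
        last = codons[-1]
        out.append(StopUsage(taxon, gene, last, table[last] == STOP))
    return out


def _codon_counts(
    genes: Mapping[str, str], truncated: set[str] | frozenset[str]
) -> tuple[Counter, Counter]:
    """(internal occurrence counts, terminal counts) over all genes."""
    internal: Counter = Counter()
    terminal: Counter = Counter()
    for gene, cds in genes.items():
        codons = list(codon_iter(cds))
        if gene in truncated or len(cds) % 3 != 0:
            internal.update(codons)  # no annotated terminator
            continue
        internal.update(codons[:-1])
        terminal[codons[-1]] += 1
    return internal, terminal


def detect_sense_to_stop(
    taxon: str,
    genes: Mapping[str, str],
    trna_set: Sequence[TRNARecord] | None = None,
    focus_codons: Iterable[str] | None = None,
    rules: PairingRules = PairingRules(),
    truncated: set[str] | frozenset[str] = frozenset(),
) -> list[StopCandidate]:
    """Scan codon usage of a genome's standard genes for sense-to-stop
    signatures.

    ``genes`` must contain only the standard conserved genes (ORFans and
    intron-encoded proteins are excluded from internal counts by the
    caller).  ``trna_set=None`` means the tRNA repertoire is unknown
    (partial mitogenome); a candidate is then still reported, with a caveat
    flag.
    """
    internal, terminal = _codon_counts(genes, truncated)
    codons = (
        [c.upper().replace("T", "U") for c in focus_codons]
        if focus_codons is not None
        else list(RNA_CODONS)
    )
    out = []
    for codon in codons:
        n_int = internal.get(codon, 0)
        n_term = terminal.get(codon, 0)
        if trna_set is None:
            present: bool | None = None
        else:
            present = bool(cognate_trnas(codon, trna_set, rules))
        caveat = ""
        if n_int >= 1:
            verdict = VERDICT_SENSE
        elif n_term >= 1 and present is not True:
            verdict = VERDICT_CANDIDATE
            if present is None:
                caveat = "tRNA repertoire unknown (incomplete mitogenome)"
        elif n_term >= 1:
            verdict = VERDICT_INDETERMINATE
            caveat = "terminal-only usage but a cognate tRNA is present"
        else:
            verdict = VERDICT_INDETERMINATE
        out.append(
            StopCandidate(
                taxon=taxon,
                codon=codon,
                n_genes_terminal=n_term,
                n_internal_occurrences=n_int,
                cognate_trna_present=present,
                verdict=verdict,
                caveat=caveat,
            )
        )
    return out


def stop_matrix(
    usages: Sequence[StopUsage],
) -> "pd.DataFrame":
    """Table-1-style matrix: rows = genes, columns = taxa, cells = terminal
    codon or '?' for truncated genes."""
    import pandas as pd

    genes = sorted({u.gene for u in usages})
    taxa = sorted({u.taxon for u in usages})
    df = pd.DataFrame("", index=genes, columns=taxa)
    for u in usages:
        df.loc[u.gene, u.taxon] = "?" if u.terminal_codon == "truncated" else u.terminal_codon
    df.index.name = "gene"
    return df
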