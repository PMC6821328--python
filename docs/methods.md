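# Methods

This note documents the models, rules, and numerical choices implemented in
`mitocode`, and what the simulator-based tests do and do not demonstrate.

## Codon-occupancy inference

The core evidence object is the occupancy matrix: for one genome,
`counts[codon][aa]` is the number of protein-alignment columns that are (a)
conserved — a single amino acid `aa` reaches the `min_fraction` threshold
(default 0.70) — and (b) occupied by `codon` in that genome's gene. Columns
are pooled across all genes of the genome, because per-gene counts are far
too sparse for rare codons.

Conservation is evaluated with gaps counted in the denominator by default
(`gap_policy="count_gaps_in_denominator"`), i.e. the threshold is a
fraction of all aligned sequences, not of residues present; the alternative
(`exclude_gaps`) is exposed because the choice matters near the threshold
and should be visible, not buried. The focal genome's own row is included
in the denominator (`include_self=True`); excluding it is supported and
re-evaluates each column's dominance with the focal row removed. A
threshold above 0.5 guarantees at most one dominant amino acid per column.
Neither `X` (unknown), `*` (provisional in-frame stop), nor gaps can be
dominant or match a dominant residue. Columns where the focal genome's
codon contains an ambiguous base (N) are skipped: no amino-acid identity
claim is possible there.

### Calling rules

For a codon with `n` occupied conserved columns (`standard_aa` its meaning
in the standard code):

1. `n < min_positions` (default 5) → `insufficient_data`;
2. `counts[standard_aa]/n > max_standard_fraction` (default 0.10) →
   `standard_retained`; the test is vacuous for stop codons, which have no
   standard amino acid — any conserved in-frame usage of a stop codon is
   already anomalous;
3. otherwise the codon is reassigned. Let `top` and `second` be the two
   largest counts over amino acids. If `top ≥ min_top_count` (default 5)
   and `top ≥ dominance_ratio × second` (default 2.0), the call is
   `reassigned_specific(top_aa)`, else `reassigned_unknown` and the codon
   is thereafter translated as `X`.

Boundary semantics: both comparisons in rule 2 and 3 are inclusive on the
rule's own side — a standard fraction of exactly 10% still qualifies as
reassigned ("no more than 10%"), and a ratio of exactly 2 still assigns the
specific meaning ("at least twice"). `second = 0` passes the dominance test
whenever `top ≥ min_top_count` (division-free formulation). The top/second
comparison runs over all amino acids including the standard one; a codon
whose top residue is its standard amino acid cannot normally reach rule 3
(it would exceed the 10% gate), and the defensive branch returns
`standard_retained`.

### Iteration and the two-stage design

After calling, each genome's working table is rebuilt: reassigned codons
take their called meaning (`X` for unknowns), `standard_retained` codons
revert to the standard meaning, and codons with insufficient or no data
keep the genome's current table entry — weak evidence is not grounds to
change a prior assignment, but explicit evidence is grounds to overturn
one. All CDSs are conceptually retranslated under the updated tables
(in-frame stops rendered `*` and indexed, never dropped — the loop must
tolerate provisional mistranslation), conservation and occupancy are
recomputed, and the cycle repeats. Because the calls are a deterministic
function of the tables, the loop stops as soon as an iteration leaves every
table unchanged; an all-standard dataset therefore converges in one pass
and a dataset with reassignments typically in two, the second confirming
the first. Oscillation is caught by `max_iterations` (default 10) and
flagged rather than raised.

The annotated terminator (final codon) of each complete CDS is always
excluded from the profiled protein, whatever the current table says it
means; terminator analysis belongs to the stops module. By default,
"realignment" between iterations preserves the existing column mapping and
only rewrites residue symbols; true realignment is delegated to an optional
hook, keeping the loop free of external tools.

The two-stage driver mirrors the practical workflow: stage 1 profiles
conservation jointly over a broad standard-code reference panel plus the
focal genomes and calls focal codons once (the distant panel provides
trustworthy but sparse conserved columns); stage 2 iterates over the focal
clade alone, seeded with the stage-1 tables, where close relatives provide
many more conserved columns. A gene with no accepted orthologs in the
reference panel simply enters at stage 2.

## tRNA evidence

Anticodon positions 36 and 35 must be strict Watson–Crick complements of
codon positions 1 and 2; position 34 reads third-codon bases by the wobble
table G→{U,C}, U→{A,G}, C→{G}, A→{U,C,A}. A34 is scored as inosine-capable
by default because organellar CGN decoding runs through a single
tRNA-Arg(ACG) with deaminated A34; a strict-A mode and a superwobble mode
(U34 reads all four) are available. Note the default table makes neither
A34 nor any other base reach a G-ending codon except C34 and U34 — which is
exactly why CGG is poorly served by tRNA-Arg(ACG) and a plausible target
for reassignment.

Predicted isotypes are soft evidence. Covariance-model isotype predictions
for novel tRNA species are frequently wrong, and the occupancy evidence is
the stronger signal, so a cognate tRNA whose predicted isotype merely
differs from the inferred meaning yields `neutral` with an explanatory
note; `contradicted` is reserved for the damning case that the only cognate
tRNAs carry the codon's *standard* meaning. Genomes without a complete
mitogenome get `no_trna_data`: absence of a tRNA gene can only be asserted
from a complete sequence. Cytoplasmic tRNA import is out of model; absence
is reported as absence with a caveat field.

## Stop-codon analysis

`terminal_codons` reports the last in-frame codon of every annotated CDS
(`"truncated"` for 3'-incomplete genes, rendered `?` in the matrix export).
`detect_sense_to_stop` counts internal (non-terminal) and terminal
occurrences of each codon across the standard conserved genes only —
ORFans and intron-encoded proteins are excluded by the caller. Verdicts:
`sense` if internal ≥ 1; `candidate_stop` if internal = 0, terminal ≥ 1 and
no cognate tRNA is present (unknown repertoire → candidate with a caveat;
a present cognate tRNA demotes to indeterminate with a note); otherwise
`indeterminate`, including the completely absent codons that feed
codon-disappearance bookkeeping.

## Parsimony mapping

`fitch_map` runs unit-cost Sankoff parsimony on a rooted, possibly
multifurcating tree (generalized Fitch); unknown tips impose no constraint;
branch lengths are ignored; `min_changes` is invariant under re-rooting.
`ancestral_states` reports, per node, the states attained in at least one
maximally parsimonious labeling (up/down pass).

`min_gains_of[s]` counts the minimum number of independent origins of
state `s`: a second Sankoff pass with asymmetric costs in which an edge
entering `s` costs one gain, an edge leaving `s` is disallowed, all other
transitions are free, and a root labeled `s` counts as one origin. The
irreversibility is deliberate: under symmetric costs a single ancestral
gain plus free reversions explains any distribution of the derived state,
collapsing every origins count to 1 and contradicting the quantity's
meaning (the number of independent acquisitions of a decoding capability).
Reversals of the *observable* state still enter the analysis naturally —
a tip known to have reverted is encoded as unknown for the origins
question, since its present state is uninformative about how often the
derived decoding arose. Both quantities are verified against exhaustive
enumeration over all labelings on small trees.

"Absent" codons are modeled as unknown by default; treating absence as its
own state (for disappearance scenarios) is a caller-side encoding choice —
any string is a valid state.

## Release-factor scan

Reference numbering maps position *p* to the alignment column holding the
reference sequence's *p*-th non-gap residue. Classification of the four
diagnostic residues:

| rule | flag | evidence level |
|---|---|---|
| 181 = Q | `UAG_stop_capable` | established |
| 181 ≠ Q (non-gap) | `UAG_blind` | established |
| 186 ≠ T (non-gap) and 206 = S | `RF2_like_UGA` | established |
| 182 ≠ R (non-gap) | `UCA_UCG_hypothesis` | hypothesis |

Gln181 recognizes guanine at the third stop-codon position (its loss
permits stop-to-sense UAG reassignment); Thr186 discriminates A from G at
the second position while Ser206 is the RF2 residue accepting both (their
combination marks a factor able to read UGA); loss of Arg182 is a proposed
— not demonstrated — enabler of cytosine acceptance at the second position
(the derived stops UCA/UCG), and is labeled `paper_hypothesis` in output.
A gap at a diagnostic position yields no flag and a warning, accommodating
partial transcriptome-derived sequences.

## The simulator

The generator emulates the statistical structure the inference relies on,
not sequence realism. Per gene, a configured fraction of codon sites
(default 0.6) is conserved: strictly invariant at the amino-acid level
across every taxon including the outgroup panel, with codons resampled
synonymously per taxon. The remaining sites evolve by per-branch amino-acid
replacement (default probability 0.3, replacements uniform over the 20
amino acids — conservation structure, not exchangeability realism, drives
the inference). Site amino acids are drawn from a typical globular-protein
composition. The first site of every gene is Met; every CDS ends with a
codon that is a stop under the emitting taxon's true table.

Defaults chosen once for the study conditions: 13 genes × 250 codons; a
40-genome standard-code outgroup panel standing in for a broad eukaryote
reference set; planted (reassigned) codons get usage weight 2.0 against 1.0
per standard synonym, mirroring the heavy use of reassigned codons in real
occupancy data; derived stop codons get terminal-usage weight 6.0 against
1.0, mirroring genomes in which the derived terminator is the most common
one (this also makes "terminates at least one of 13 genes" hold with
probability ≈ 1 − 3⁻¹³ per genome). Codon-usage weights may be zeroed to
model complete codon disappearance; a planted sense meaning on a zero-weight
codon is a configuration error.

tRNA repertoires are built per taxon as a minimal anticodon cover: every
used sense codon is decoded by some emitted anticodon, no emitted anticodon
decodes a stop codon or a used codon of a different amino acid, and
narrow-reading anticodons are preferred (G34 for pyrimidine-ending codons,
C34 for G-ending, U34 then inosine-A34 for A-ending). This reproduces,
without being told to, the canonical organellar solutions — a single
tRNA(CAU) pair for fMet/Met, tRNA-Ala(CUA) appearing exactly when UAG
means Ala, tRNA-Leu(CCG) when CGG means Leu — and refuses configurations
with no safe decoding (e.g. AGA→Ala while AGG still means Arg), which is
itself a faithful constraint: such codes need wobble-incompatible usage
patterns. Isotype-prediction noise (default 0.1) randomly rewrites emitted
isotypes to model wrong covariance-model predictions.

Release-factor alignments are gapless copies of a generated backbone with
5% background substitution away from the four diagnostic columns, whose
residues are set from each taxon's true code (UAG sense → 181 ∈ {I,L,V};
any derived stop → 182 ∈ {G,K,Q}; configurable RF2-like clades → 186 N,
206 S).

The codon-disappearance trajectory decays a codon's usage weight
quadratically for lineages branching off the root→clade path (the last
group before the crown at exactly 0), gives crown taxa the codon with its
planted new meaning, and records a per-taxon stage (`pre`/`stem`/`crown`).
Lineages hanging directly off the root are unaffected.

Everything is driven by one `numpy` generator seeded from the config:
identical seeds give byte-identical outputs, distinct seeds distinct ones.

### What passing tests show — and do not

Because simulated alignments are gapless and conserved sites are perfectly
invariant, recovery results demonstrate the correctness of the counting,
calling, and iteration logic under the stated conservation structure. They
do not demonstrate robustness to alignment error, indels, heterogeneous
conservation levels, compositional biases, or misannotated gene boundaries
— all properties of real data that the out-of-model alignment step absorbs
in practice. The stringent thresholds (5 positions, 10%, ratio 2) are taken
as given and their sensitivity is not explored by the tests.

## Problem sizes

The canonical scenario used throughout testing and in the acceptance script
is 12 focal taxa (four clades of three) + 40 reference genomes, 13 genes ×
250 codons, with recovery evaluated over 20 seeded replicates; the
sense-to-stop check uses the same scenario with a 6-genome panel and
150-codon genes; parsimony and wobble primitives are verified against
exhaustive enumeration (≤ 8 tips × ≤ 4 states; all 64 × 64
anticodon–codon pairs).

## Known limitations

* No statistical scores on calls — the rules are deliberate hard
  thresholds; probabilistic alternatives exist as external tools.
* No handling of introns, frameshifts, or readthrough/polyadenylation-
  completed stops; annotation 3' ends are taken as given.
* Start-codon and initiation-context modeling, selenocysteine, and
  pyrrolysine are out of scope.
* The AUA codon's decoding in reduced tRNA repertoires is reported as
  unresolved rather than adjudicated; likewise conflicting terminator
  evidence (a codon terminal in one lineage, sense in another) is reported,
  not resolved.
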