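# mitocode

Inference of mitochondrial genetic-code variants from comparative sequence
data.

Organellar genomes keep being sequenced faster than they are scrutinized,
and codon reassignments — a stop codon becoming a sense codon, a sense
codon switching amino acids, or a sense codon becoming a terminator — are
easy to miss during annotation. When they are missed, the deposited protein
sequences are simply wrong at every affected position. `mitocode` is a
library and command-line pipeline for detecting such reassignments from the
kind of evidence that requires nothing but sequences: the identity of the
amino acid that *other* genomes place at conserved alignment positions
where the focal genome uses a given codon. It is aimed at people curating
organellar (especially mitochondrial) genome annotations and at students of
genetic-code evolution.

## The method

For each gene, protein multiple alignments are scanned for columns in which
a single amino acid *a* reaches a conservation threshold

  f(column) = max_a n_a / N ≥ 0.70,

and for every focal genome each codon's occupancy under those columns is
tallied into a matrix `counts[codon][dominant_aa]`. A codon occurring at
n ≥ 5 conserved columns with at most 10% of them conserved for its standard
amino acid is considered reassigned; a specific new meaning is assigned when
the top amino acid's count is ≥ 5 and at least twice the runner-up's,
otherwise the codon is translated as the unknown amino acid X. Genes are
then conceptually retranslated under the updated per-genome tables and the
whole analysis is iterated to a fixpoint (in practice the second pass
confirms the first).

Supporting modules corroborate or contextualize the calls:

* **tRNA evidence** — cognate-tRNA lookup under anticodon wobble rules
  (G34 reads U/C; U34 reads A/G; C34 reads G; A34 treated as inosine,
  reading U/C/A) and concordance classification against each call;
* **stops** — termination-codon usage per gene and sense-to-stop candidate
  detection (internal occurrences = 0, terminal ≥ 1, no cognate tRNA);
* **phylo_mapping** — Fitch/Sankoff parsimony of per-codon meanings on a
  phylogeny, including the minimum number of independent origins of a
  derived meaning;
* **rf_scan** — diagnostic residues of the mitochondrial release factor
  mtRF1a (positions 181/182/186/206 in Thermus thermophilus RF1 numbering)
  that govern stop-codon discrimination;
* **synthetic_data** — a seeded simulator of mitogenome-like ortholog sets,
  tRNA repertoires, and release-factor alignments with known planted codes,
  used as the hermetic test surface for everything above.

## Worked example

Simulate a 12-taxon focal clade (four subclades carrying UAG→Ala,
AGG/AGA→Ala, CGG→Leu + AGG→Met, and the standard code, with an order-wide
UCA→stop) plus a 40-genome standard-code reference panel, then run the
two-stage inference:

```python
import mitocode as mc

cfg = mc.default_scenario(seed=7)
ds = mc.simulate_dataset(cfg)
res = mc.two_stage_analysis(
    ds.reference_sets, ds.ortholog_sets,
    {t: mc.standard_table() for t in ds.focal_taxa},
)
print(f"converged: {res.stage2.converged} after {res.stage2.n_iterations} iteration(s)")
for c in sorted(res.stage2.reassigned_calls(), key=lambda c: (c.taxon, c.codon)):
    print(f"{c.taxon}  {c.codon}->{c.inferred_meaning}  ({c.status}, "
          f"n={c.n_positions}, top={c.top_aa}:{c.top_count}, second={c.second_aa}:{c.second_count})")
```

which prints:

```
converged: True after 1 iteration(s)
A1  UAG->A  (reassigned_specific, n=62, top=A:62, second=None:0)
A2  UAG->A  (reassigned_specific, n=55, top=A:55, second=None:0)
A3  UAG->A  (reassigned_specific, n=62, top=A:62, second=None:0)
B1  AGA->A  (reassigned_specific, n=37, top=A:37, second=None:0)
B1  AGG->A  (reassigned_specific, n=45, top=A:45, second=None:0)
B2  AGA->A  (reassigned_specific, n=44, top=A:44, second=None:0)
B2  AGG->A  (reassigned_specific, n=55, top=A:55, second=None:0)
B3  AGA->A  (reassigned_specific, n=44, top=A:44, second=None:0)
B3  AGG->A  (reassigned_specific, n=42, top=A:42, second=None:0)
C1  AGG->M  (reassigned_specific, n=31, top=M:31, second=None:0)
C1  CGG->L  (reassigned_specific, n=41, top=L:41, second=None:0)
C2  AGG->M  (reassigned_specific, n=35, top=M:35, second=None:0)
C2  CGG->L  (reassigned_specific, n=49, top=L:49, second=None:0)
C3  AGG->M  (reassigned_specific, n=38, top=M:38, second=None:0)
C3  CGG->L  (reassigned_specific, n=48, top=L:48, second=None:0)
```

Every planted reassignment is recovered with its true meaning: taxon `A1`'s
UAG, for instance, occurs at 62 conserved columns, all 62 of them dominated
by alanine, so UAG is called an alanine codon (`n` is the number of
conserved columns occupied, `top`/`second` the two most frequent dominant
amino acids under them). The standard-code clade `D*` and the reference
panel receive no reassignment calls. Stage 1 (the broad-panel screen)
already seeds the correct tables here, so the focal-only loop confirms them
in a single pass; starting the same data from standard tables instead takes
two passes, the second confirming the first.

The same pipeline is available from the shell:

```bash
mitocode simulate --out data --seed 7
mitocode infer --genes data/genes --out calls
mitocode stops --genes data/genes --trna data/trna.tsv --out stops
mitocode rf-scan --msa data/rf_alignment.fasta --reference RF1_reference --out rf
```

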