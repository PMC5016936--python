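# ervkit

Structural, phylogenetic and functional characterization of endogenous
retrovirus (ERV) loci, exercised end-to-end on a built-in insertion
simulator so no genome download is required.

Given a FASTA of candidate elements (optionally with genomic flanks) and a
group reference consensus (a canonical LTR-internal-LTR model ships with the
package), ervkit derives per element:

- **Structure** — per-landmark retention (retained at >= 20 % of the
  reference element), insertion/deletion annotation, retroposition
  signatures (poly(A) tail, 5-15 bp target-site duplication, TT/AAAA
  junction), and a provirus / processed-pseudogene / undefined class label.
- **Subgroup** — genotypes at diagnostic LTR key positions (7 main
  positions, plus 2A/2B refinement tiers), a frequency-based subgroup call
  with an explicit abstention band, and majority-rule subgroup consensuses.
- **Integration age** — Kimura 2-parameter divergence (gap columns excluded,
  CpG exclusion switchable) converted by T = D%/rate (rate default
  0.13 %/nt/My; halved for 5'-vs-3' LTR), averaged over LTR-vs-LTR,
  LTR-vs-consensus and gene-window-vs-consensus methods with an
  SD > 20 % low-confidence flag.
- **Motif features** — primer-binding-site extraction and tRNA-type
  assignment, nucleocapsid zinc fingers (CX2CX4HX4C, CX2CX3HX4C), integrase
  GPY/F (WXnGPYXV), nucleotide composition bias, AG-rich leader, positional
  frequency matrices.
- **Env puteins** — reconstruction of envelope putative proteins across
  reading frames with stop/frameshift annotation and functional-domain
  checks against a packaged envelope reference protein.
- **Mosaic assignment** — best-locus ranking and a breakpoint-penalized
  dynamic program assigning a transcript to one locus or a recombinant of
  loci, with discordant-base counts.
- **Genomic context** — locus vs gene/exon interval intersection
  (GFF3/BED), intronic/exonic/mixed relation and sense/antisense
  orientation.

The `ervkit.simulate` module generates elements with known ground truth
(class, subgroup, age, deletions, TSD, PBS) and recombinant transcripts,
so every stage is testable offline.

## Tests

```
python -m pytest -q tests/
```

Unit and property tests per module plus `tests/test_acceptance.py`, which
implements the acceptance criteria (K2P oracle agreement, dating recovery,
classifier and subgroup accuracy on simulated cohorts, NJ consistency,
bootstrap support, mosaic DP optimality and breakpoint recall, putein
reconstruction, formula checks).

## CLI

```
ervkit simulate --n-provirus 50 --n-pseudogene 50 --seed 1 \
    --out-fasta cohort.fasta --out-truth truth.tsv
ervkit annotate cohort.fasta --out master.tsv        # full per-element table
ervkit tree cohort.fasta --ltr 5ltr --bootstrap 100 --seed 1 \
    --out-newick ltr.nwk --out-phylip ltr.phy
ervkit putein env.fasta --out puteins.tsv
ervkit mosaic transcripts.fasta locus_db.fasta --out mosaic.tsv
ervkit context loci.tsv genes.gff3 --format gff3 --out context.tsv
```

`ervkit run-all` is an alias of `annotate`. All outputs are plain text
(TSV / FASTA / Newick / PHYLIP); a custom reference can be supplied with
`--reference consensus.fasta --landmarks landmarks.yaml`.

## Packaged data

`src/ervkit/data/` holds the canonical reference consensus (10,186 nt, two
identical 780-nt LTRs), the landmark/config YAML, the key-position table,
a tRNA 3'-end library, and the envelope reference protein + CDS + domain
annotation. These are deterministic synthetic stand-ins reproducing the
published coordinates and motifs; regenerate with
`python scripts/build_data.py`.
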