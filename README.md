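# chordcomp

Comparative chordate functional-genomics analyses as a tested, reusable
Python package:

* **expression** — cRPKM computation, quantile normalization, strict-threshold
  binarization and the τ tissue-specificity index.
* **orthology** — gene-family tables, 1-to-1 orthologue pairs and
  single-outgroup ohnologue families (2–4 vertebrate copies).
* **hourglass** — Jensen–Shannon transcriptome distance between developmental
  stages of two species, with orthologue-set bootstrap dispersions and
  minimal-divergence stage detection.
* **nacc_coexpr** — neighbourhood analysis of conserved co-expression (NACC)
  with randomized-orthology nulls, upper-tail hypergeometric module-overlap
  tests and motif-z-score module correlations.
* **motifs** — PWM scanning (log-odds, fraction-of-max threshold, both
  strands), per-group hit counting and per-kb enrichment z-scores.
* **landscapes** — peak classification (promoter / gene body / proximal /
  distal), TSS-distance profiles, basal-plus-extension regulatory domains,
  per-gene peak counting, size-stratified gene matching, bidirectional
  promoter detection and conservation-score aggregation.
* **wgd_fates** — nine-domain expression-breadth bias and post-WGD fate
  classification (redundancy / subfunctionalization / specialization, with
  mild/strong specialization subtypes) plus rank-test associations.
* **methylome** — CpG methylation levels, category fractions, region
  summaries, two-cluster (k-means, k=2) separation of regulatory elements
  and cluster–expression association.
* **synthetic** — generators for all of the above with planted ground truth,
  so every stage is verifiable offline.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(JSD metric properties, planted-truth recovery, brute-force oracle
equivalence for PWM scanning / regulatory domains / hypergeometric tests /
k-means, calibration simulations).

## CLI

Everything is available through the `chordcomp` command:

```sh
# generate a complete synthetic bundle with truth labels
chordcomp simulate --config cfg.yaml --outdir bundle/

# expression utilities
chordcomp expr crpkm|qnorm|binarize|tau ...

# orthology filters
chordcomp orth pairs --families fams.tsv --species-a amphioxus --species-b zebrafish --out pairs.tsv
chordcomp orth ohno  --families fams.tsv --outgroup amphioxus --vertebrate zebrafish --out ohno.tsv

# stage-divergence matrix with bootstrap
chordcomp hourglass --expr-a A.tsv --expr-b B.tsv --pairs pairs.tsv \
    --bootstrap 100 --seed 1 --out-prefix hg

# conserved co-expression and module comparisons
chordcomp nacc --expr-a A.tsv --expr-b B.tsv --families fams.tsv \
    --species-a sp1 --species-b sp2 --k 20 --out nacc.tsv
chordcomp modules overlap|motifcorr ...

# motif scanning and enrichment
chordcomp motifs scan|count|zscore ...

# peak landscapes
chordcomp peaks classify|tssdist|great|count|stratify|bidir|conserve ...

# WGD fate analyses
chordcomp fates classify|bias|retention|apre-assoc|div-assoc ...

# methylation analyses
chordcomp meth levels|fractions|regions|cluster|assoc ...
```

All genomic coordinates are 0-based half-open (BED convention); GTF input
is converted on read. Expression TSVs carry `gene_id` in the first column
and one column per sample.
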