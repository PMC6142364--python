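# splicearch

Quantification of the two dominant modes of alternative splicing — **exon
skipping (ES)** and **intron retention (IR)** — from splice-junction-mapped
RNA-seq reads, association of AS events with gene-architecture features, and
prediction of genome-level ES incidence from architecture alone. The package
targets comparative transcriptomics across eukaryotes: the same junction-based
estimators work on any genome with a FASTA + GFF3 annotation and single-end
reads, and a built-in synthetic genome/read generator makes every stage
testable at desk scale with planted ground truth.

## The method

For each gene's canonical transcript (longest CDS), every internal exon E2 of
a consecutive exon triplet (E1, E2, E3) is diagnosed by three **junction
composites** — concatenations of ≤42 bp splice-site-adjacent flanks (84 bp at
full length): two inclusion junctions (E1–E2, E2–E3) and one skip junction
(E1–E3). Reads are assigned to junctions by an exact unique-mapping matcher
(≤2 mismatches, multi-mapping reads discarded). Each junction's **effective
mappability** is the number of its 50-bp windows that map uniquely back to it
(ceiling 35); triplets with any junction under 20 effective positions are
dropped, and counts are corrected by `raw / (n_effective/35)`. The per-exon
skipping rate is

    r_ES = m_E1E3 / ((m_E1E2 + m_E2E3)/2 + m_E1E3)

and the analogous per-intron retention rate, from E–I, I–E and E–E junctions,

    r_IR = (m_IE + m_EI)/2 / (m_EE + (m_IE + m_EI)/2)

Events are classified ES/IR-positive (10% ≤ r < 90% with sufficient coverage),
negative (r < 10%), or undetermined. Species-level AS frequency distributions
(F_ES,sp, F_IR,sp) average rates over bins of 100 classifiable events from
10,000 subsampled reads each.

Architecture statistics compare positive vs negative events per feature
(lengths, ratios, GC, PWM splice-site distances, frame preservation) with
complementary one-sided Kolmogorov–Smirnov tests (signed D at p < 0.01),
Fisher's exact test for 3n-length enrichment, and Spearman correlations. A
binomial logistic regression on 11 quantitative traits + the 3n flag yields
per-exon ES-positive probabilities (p_ES); the fraction of a genome's internal
exons with p_ES above the ROC-optimal threshold is its ES incidence **I_ES**,
swept over 1600 simulated genomes (40 intron densities × 40 mean intron
lengths) and projected onto ancestral genomes via phylogenetically independent
contrasts of intron statistics.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
(`python analysis/01_simulate_genome.py`, then 02–05). On the default seeds,
`02_quantify_splicing.py` prints:

```
ES recovery (planted rate -> mean recovered rate):
  0.0 -> 0.000  (n=550)
  0.3 -> 0.296  (n=40)
  0.5 -> 0.494  (n=32)
IR recovery (planted rate -> mean recovered rate):
  0.0 -> 0.000  (n=873)
  0.3 -> 0.304  (n=43)
  0.5 -> 0.497  (n=42)
```

i.e. junction-ratio estimates recover the planted skip/retention rates to
well under one percentage point per class. `04_train_es_classifier.py` fits
the logistic classifier on a balanced, architecture-coupled event set:

```
AUROC 0.753 (95% CI 0.740-0.766)
optimal probability threshold p* = 0.498
  exon_length                  -0.919  p=1e-47
  upstream_intron_length       +0.363  p=9.2e-15
  downstream_intron_length     +0.441  p=1.1e-21
  ss5_distance                 +0.548  p=2.2e-14
```

— short exons flanked by long introns with weak splice sites predict
skipping. `05_ies_landscape.py` sweeps the I_ES surface (Spearman rho of
I_ES vs mean intron length 0.937, p ≈ 3e-184; real-vs-simulated genome
pairing R² = 0.998) and converts printed ancestral intron densities
(e.g. 8.8 introns/CDS kbp × 1.422 kbp mean CDS = 12.51 introns/gene) onto it.

A one-shot pipeline is also available as a CLI:

```sh
splicearch simulate --out sim/ --n-reads 100000
splicearch run --config cfg.json --out run/
splicearch convert-density 8.8      # -> 12.51
```

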