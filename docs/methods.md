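# Methods

## Junction-based AS quantification

**Junction composites.** Splicing events are observed only by reads that span
a splice boundary, so mapping targets are composites of the ≤42-bp termini
adjacent to each boundary (3' end of the upstream element + 5' start of the
downstream element, in transcript orientation). Elements shorter than 42 bp
contribute their whole length, so composites can be shorter than 84 bp. ES
inclusion junctions sit on exon boundaries and are shared between adjacent
triplets; they are stored once per boundary and referenced by both triplets —
otherwise identical composites would multi-map against each other and erase
their own mappability. ES and IR junctions form *separate* mapping libraries
for the same reason: an IR spliced (E–E) junction is sequence-identical to
the corresponding ES inclusion junction.

**Mapping model.** The library is tiny, so the read assigner is exact, not
heuristic: a read aligns end-to-end to a junction window iff its Hamming
distance is ≤2 (no indels), in either read orientation, and is assigned only
when exactly one (junction, offset, orientation) qualifies. Candidates are
found by the pigeonhole principle (three read-length/3 seed lookups) and
verified exactly; equivalence with a brute-force all-pairs scan is asserted
in tests on 500-junction libraries.

**Effective mappability.** A junction's effective mappability is the number
of its 50-bp windows (≤35) that map uniquely back to their own position;
windows containing N are non-mappable. A junction passes if ≥20 windows are
effective and ≥8 effective windows overlap each side of the boundary by ≥8 bp
(the "≥8 per side" reading that is non-vacuous for ≤84-bp junctions and
reproduces the 27-bp minimum element length: a side of s bp leaves
min(42, s) + 42 − 49 windows, ≥20 iff s ≥ 27). Whole triplets/triads are
dropped if any member fails. Counts are corrected by the ratio of effective
to maximal (35) mappability, so corrected counts are comparable across
junctions of different mappability.

**Rates and classes.** r_ES and r_IR are the corrected skip-form/spliced-form
count ratios given in the README. Classification thresholds (coverage sum
> 10; per-junction floors; positive band 10–90%) are fixed constants of the
procedure, not tunables. The three statuses partition all events; filtered
events are undetermined.

**Species profiles.** Classifiable events are permuted and cut into disjoint
bins (default 100 bins × 100 events); the reads on each bin's junctions are
subsampled without replacement to 10,000 via a multivariate hypergeometric
draw over per-junction counts (count-level subsampling is exactly equivalent
to drawing individual assigned reads). Per-bin value = unweighted mean of
per-event rates recomputed from the subsample, skipping events whose
subsample leaves a zero denominator; values are reported in percent. Species
with fewer classifiable events emit as many full bins as possible and warn;
bins attracting fewer than 10,000 reads use all available and record the
shortfall.

## Synthetic genomes and reads

The generator emulates what the estimators assume about real data: one contig
per gene (100-bp flanks); CDS lengths log-normal with natural-scale mean
1422 bp (log-sd 0.45); introns per gene Poisson(density, default 4); intron
lengths log-normal (natural mean 300 bp — within the range typical of compact
eukaryotic genomes — log-sd 0.6, floor 26 bp to hold the splice windows);
exon boundaries drawn uniformly over the CDS (min exon 3 bp); GC 0.52 exonic
/ 0.42 intronic; splice sites planted as consensus-with-noise (9-bp 5' and
23-bp 3' windows, 5% per-position substitution by default) so introns are
GT..AG unless noise mutates them; per-gene expression log-normal (log-sd 1);
half the genes on the minus strand so strand handling is always exercised.

**Truth models.** The default `isolated` mode plants at most one AS event per
gene (one skipped internal exon *or* one retained intron, rate drawn from
{0, 0.3, 0.5}). This is deliberate: with events on every exon, skipping of a
neighbouring exon deflates a triplet's inclusion junctions and biases r_ES
upward — a genuine property of junction-ratio estimators, not an
implementation artifact — and sparse events are also the realistic regime.
`independent` and architecture-`coupled` (logistic-in-features ψ) modes exist
for stress tests and end-to-end classifier experiments. One side effect of
isolated planting: the per-exon probability of being positive is lower in
intron-rich genes, so synthetic association matrices show negative
gene-size/intron-count associations by construction.

**Read sampling.** Each read realizes its own isoform by Bernoulli draws
(skip per internal exon; retention per intron, suppressed when a flanking
exon is skipped), then draws a start position uniformly over the pre-mRNA
length, rejecting positions past the realized isoform's last valid start.
This equalizes read intensity per position *across* isoforms, making junction
ratios unbiased for the planted rates; sampling starts uniformly within each
isoform instead would inflate r_ES by the isoform-length ratio. No sequencing
errors, paired ends, or poly(A) biases are modelled — tests on these data
therefore validate the estimators' correctness, not robustness to platform
noise.

## Architecture features and statistics

Features are computed on the canonical model in transcript orientation; event
position is the pre-mRNA offset from the start codon; the local intron/exon
ratio is mean flanking intron length over event exon length (and the mirror
for IR); ES intron GC is the mean of the two flanking introns (the
aggregation is otherwise unspecified, and the mean is symmetric).

Splice-site strength is the distance from the species PWM consensus: sum over
positions of (consensus base frequency − observed base frequency), computed
on 9-bp 5' (3 exon + 6 intron) and 23-bp 3' (20 intron + 3 exon) windows with
pseudo-frequency 1e-4 against empty columns; N positions are skipped. This
deficit metric is zero exactly on the per-position consensus and weights
mismatches by positional conservation. Note the direction of its training
monotonicity: reinforcing the consensus weakly *increases* every
non-consensus site's distance.

The signed KS statistic runs both one-sided two-sample tests; D is signed
positive when the positive-class distribution is stochastically greater at
p < 0.01 in exactly one direction, else NA. No multiple-testing correction is
applied, matching the fixed p < 0.01 convention throughout. The spliceosome
rank score inserts each panel gene into 500 random 199-gene subsets (drawn
with replacement from all genes) and averages its 1–200 mid-rank; under
exchangeable expression the expectation is 100.5, and a dominant panel
saturates near 200 minus half the expected panel co-occupancy per subset.

## ES-incidence prediction

The classifier is a maximum-likelihood binomial logistic regression on 11
quantitative traits + the 3n boolean (GC deltas are excluded from the default
set because architecture-only simulated genomes carry no sequence). Length
features are log1p-transformed (heavy-tailed); the transform is toggleable.
Training uses a balanced event set split 2/3 : 1/3; perfect separation falls
back to a weakly penalized fit with a warning. Reported diagnostics: Wald z
p-values, a sequential (type-I) deviance table, the ROC with AUROC and a
Hanley–McNeil 95% CI, and the threshold p* maximizing sensitivity +
specificity.

Simulated architectures are drawn coherently rather than from independent
marginals: introns per gene ~ Poisson(density); CDS log-normal (mean
1422 bp); per-exon lengths log-normal with natural mean CDS/(N+1) (a gene
with N introns has N+1 exons); intron lengths log-normal with natural mean =
the input mean; gene length is the realized sum of parts; splice-site
distances normal (means 0.6/1.2, sd 0.3/0.5 — the scale of the synthetic
genomes' empirical PWM scores), clipped at 0; the 3n flag comes from the
realized exon length. The I_ES grid spans densities 0.5–15 (40 regular
intervals) × mean lengths 10–8000 bp (40 cubic intervals, min + span·(i/39)³,
densifying short introns); full scale is 20,000 genes / 10,000 exons per
cell, and reduced grids (10×10 or 20×20, 3,000 genes / 2,000 exons) are used
where a rendering of the surface suffices. Real-genome pairing picks the
nearest cell in (density, cube-root length) space and clamps out-of-range
genomes with a warning.

The package's reference architecture coupling (`COUPLED_BETA`) encodes the
direction structure of real transcriptomes — skipping favoured by short
exons, long flanking introns, high densities/ratios and weak splice sites —
and is the planted truth for recovery experiments; with it, held-out AUROC
lands near 0.75 and the I_ES surface rises with both density and intron
length.

**Ancestral projection.** Phylogenetically independent contrasts use
Felsenstein pruning: each internal node estimate is the branch-length-
weighted average of its two daughters, with the upward branch extended by
l1·l2/(l1+l2); applied independently per statistic (mean/median/quartiles).
The tree must be fully resolved with positive branch lengths; polytomies and
missing tips raise errors instructing resolution. The implementation is
cross-checked in tests against the two-tip closed form, a brute-force
recursive oracle, Brownian-motion unbiasedness, and R `ape`'s PIC-based
ancestral estimate. Ancestral intron densities printed as introns/CDS kbp
convert to introns/gene via the 1.422-kbp cross-species mean CDS length.

## Numerical and scale choices

Every stochastic stage takes a seed; pipelines derive per-stage seeds from
one run seed via `SeedSequence.spawn`, so reruns are byte-identical. Test and
acceptance problem sizes (e.g. 1,000 genes / 2×10⁶ reads for planted-rate
recovery; 500-junction oracle libraries; n = 10,000 balanced events; 10×10
reduced grids) were chosen as the smallest scales at which the targeted
statistical contracts are sharp — recovery bands of 0.03 on rates, 0.02 on
AUROC — on a single CPU in minutes.

## Known limitations

Single-isoform gene models only (the canonical transcript); no novel-junction
discovery; no indel-aware or quality-aware mapping; no NMD or isoform-level
quantification; the read simulator's lack of an error model means mismatch
tolerance is exercised by constructed tests rather than by simulated data;
fractional multi-mapping is not supported (multi-mapped reads count nowhere);
terminal introns are included as IR triads (an inclusive choice — exclude by
filtering on intron index if undesired).
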