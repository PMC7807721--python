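# Methods

This note documents the models, rules and numerical choices behind
`splicecore`, and what its synthetic test substrate does and does not
establish about real data.

## Quantities and conventions

PSI (percent spliced-in) is the percentage of a gene's transcripts that
include an alternative sequence, estimated upstream from junction reads;
it lives on the 0–100 scale and a missing value is equivalent to coverage
tier `N`. ΔPSI is always signed treated − control (stress) or target
tissue − others (tissue). Genomic coordinates are 1-based inclusive (GTF
convention) throughout; conversions happen only at the IO boundary.
Coverage tiers are an ordered label (`N < VLOW < LOW < OK < SOK`)
produced by the upstream quantifier. When the package itself must derive
a tier (pooling replicates), it uses configurable summed-junction-read
floors of 5/10/20/50 reads for VLOW/LOW/OK/SOK; these cutoffs are
monotone placeholders, not an upstream specification, and only affect
`merge_replicates`.

## Coverage and the IR imbalance filter

A PSI cell is usable when its tier reaches `CoverageRule.min_tier`
(default VLOW — the minimum at which a PSI estimate is considered
quantitative) and, for intron-retention events, when the reads supporting
the 5′ exon–intron and 3′ intron–exon junctions are not significantly
imbalanced. The imbalance test is the exact binomial against p = 0.5 on
the two junction counts; the two-sided p-value sums all outcomes whose
point probability does not exceed the observed one (the standard exact
convention), and cells with P ≤ 0.05 (`ir_alpha`) are dropped. Whether
the upstream tool's test is one- or two-sided is not documented;
two-sided is the default and a flag switches it off entirely. A (0, 0)
junction pair is treated as insufficient coverage rather than as an
undefined p-value, because an intron with no boundary-spanning reads
carries no usable retention signal.

## AS calling and PanAS

An event with ≥ `min_covered_samples` (3) covered samples is alternative
if 10 ≤ PSI ≤ 90 in at least 10% of covered samples **or** its PSI range
is ≥ 25. The 10%-of-samples count rounds **up** to a whole sample (with a
1e-9 guard against floating-point edge cases), so one qualifying sample
suffices in small panels; this choice is deliberate and tested at the
boundary. A relaxed single-sample variant (5 ≤ PSI ≤ 95 in ≥ 1 sample)
is provided for upper-bound estimates and is provably a superset of the
strict call. The percent of AS genes uses as denominator the genes with
≥ 1 event covered in ≥ 3 samples, so poorly covered genes do not deflate
the fraction. PanAS events require ≥ 20 covered samples of the
tissue/development panel and 10 ≤ PSI ≤ 90 in strictly more than 80% of
them. Saturation curves subsample without replacement with a
caller-supplied seed; medians and quartiles are reported per subset size.

## Core sets

**Stress AS.** Per experiment, ΔPSI is computed only when both the
control and treated samples pass coverage; ALTA/ALTD events additionally
require the host exon's PSI to be ≥ 25 (`min_alt_use`) in both samples,
when the host exon is present in the table (otherwise the filter is
skipped with a logged warning). Membership needs |ΔPSI| > 15 with one
sign in ≥ 2 of the 5 experiments; any experiment exceeding the threshold
with the opposite sign makes the event ambiguous and excluded. The
threshold is strict (> 15, not ≥), following the methods-style statement
of the rule over the results-style paraphrase; both thresholds are
dataclass fields.

**Tissue AS.** Per-tissue mean PSI over covered replicates (a tissue is
valid with ≥ 2 covered replicates); a target tissue qualifies when ≥ 3
other valid unrelated tissues exist, the target mean differs from every
one of them by > 15 with one sign, and differs from the unweighted mean
of their means by > 25. Tissue types declared related in the sample
design (e.g. seed/embryo/silique-style groupings) are excluded from the
"every other tissue" comparison; the default declares all tissues
mutually unrelated because no canonical grouping exists.

**GE cores.** Fold changes are (cRPKM + ε)/(cRPKM + ε) with ε = 1 cRPKM
to stabilise ratios near zero (configurable); genes are eligible for the
stress comparison only with cRPKM ≥ 5 and ≥ 50 mapped reads in ≥ 2
samples from ≥ 2 experiments of the class. Tissue-specific genes are
called on per-tissue median cRPKM with a ≥ 5 median floor in at least
one tissue, FC ≥ 3 against every other tissue and FC ≥ 5 against the
median of the others, in one direction.

**Controls.** Genome(context) contains the items passing exactly the
context's coverage/eligibility filters with no PSI or FC requirement.
AS-NR(stress) additionally requires 10 ≤ PSI ≤ 90 in ≥ 1 covered sample
of the class and |ΔPSI| < 5 in every evaluable experiment; AS-NR(tissue)
requires 10 ≤ mean PSI ≤ 90 in ≥ 2 valid tissues and every valid
tissue's mean within 5 PSI units of the mean of the others. Common
controls take items present in ≥ 2 of the 3 per-context sets, and an
item in two AS-NR groups that belongs to the remaining core set is
discarded. Core sets and their own context's AS-NR set are disjoint by
construction.

## ORF impact

The classifier works purely in interval arithmetic plus translation. The
inclusion isoform exonises the alternative interval (merging adjacent
exons); the exclusion isoform splices it out. An event whose alternative
interval lies strand-wise upstream of the start codon is 5′-UTR,
downstream of the stop codon 3′-UTR; intervals overlapping either codon
are uncertain and excluded from profiles. For CDS events both isoforms
are translated from the annotated start codon; an isoform is intact iff
its first in-frame stop falls at the annotated stop codon's genomic
position, which uniformly captures frameshifts (alternative length not a
multiple of 3), in-frame premature stops, and stop loss. NMD is
predicted when the premature stop's last base lies more than 50 nt
upstream of the isoform's final exon–exon junction, measured in spliced
coordinates of the isoform under evaluation. ES events whose skipped
exon is the last or second-to-last exon of the inclusion isoform affect
the final junction; when such an event escapes NMD it is disruptive only
if the truncation removes > 20% of the reference protein or > 300 aa,
otherwise it is treated as a tolerated alternative protein. If both
isoform junction chains match annotated transcripts of the gene, the
event is accepted as alternative-protein on annotation evidence even
when the de-novo scan disagrees (the disagreement is logged); junction
chains rather than sequences are compared so UTR-length differences do
not break the match. Events where **both** isoforms disrupt the ORF have
no intact reference state and are classified uncertain. uORF calling is
not implemented; gene-level uORF labels are consumed from an annotation
table.

## Variation partition

Per event: tissue range = max − min of per-tissue median PSI (a tissue
counts with ≥ 1 covered replicate by default; a flag re-imposes the
2-replicate rule), plus the largest |ΔPSI| among abiotic and among biotic
experiments, counting an experiment only when both its samples pass
coverage. Events need ≥ 4 covered tissues and ≥ 4 covered experiments
per class, and a global variation (sum of the three components) of at
least 10 PSI units. Percentages are exact shares of the sum, so they
conserve to 100 up to floating-point rounding and are invariant to
rescaling all effects. Tissue exclusion (for sensitivity analyses) is an
argument of `partition_variation` so the tissue range is recomputed, not
post-hoc filtered.

## Splice-site strength

PWMs are position frequency matrices over all annotated internal splice
sites of the reference models — donors over 3 exonic + 6 intronic nt,
acceptors over 20 intronic + 3 exonic nt, minus-strand windows
reverse-complemented into transcript orientation — with a pseudocount of
1 per base per position. The strength score is the percentage-of-maximum
similarity, 100 · Σ_p f_p(base_p) / Σ_p max_b f_p(b); the consensus
window scores exactly 100, the score is monotone under replacing a base
by a more frequent one, and non-ACGT bases contribute zero. This is a
deliberately simple similarity in place of species-foreign maximum-
entropy models; per-gene minima over donors and acceptors are the
quantities compared between gene sets. Sites inside introns shorter than
the intronic window (6 nt donors, 20 nt acceptors) are skipped.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the callers assume:
a tissue/development panel (six tissue types — inflorescence, leaf, root,
seed, silique, embryo — with 4 replicates each, so the 24-sample panel
supports the PanAS ≥ 20-covered-samples rule), five abiotic and five
biotic control/treated experiment pairs, planted tissue-specific events
(target shifted by 40 PSI units), stress responders (±40 in 3–5
experiments of one class), PanAS events (baseline 40–60 everywhere),
null events (constant baseline in 5–95), and the analogous planted and
null gene-expression groups (stress FC 4, tissue FC 10, ε-aware
baselines of 10–60 cRPKM, plus deliberately ineligible low-expression
genes).

Observed PSI is a beta draw centred on the planted mean with the
concentration set so the between-sample sd equals `psi_noise_sd`
(default 3 PSI units) at mean 50; the sd shrinks toward the bounds,
keeping PSI in range, and sd 0 returns the means exactly. Junction read
counts are then derived **consistently** from the stored PSI at a
Poisson read depth (mean 50): counts present the PSI rather than adding
a second binomial noise layer, so the stated noise sd is the actual
between-sample PSI sd. Coverage dropout (default 5% of cells to tier N)
and IR junction imbalance (default 5% of IR cells get all reads on one
junction) are independent nuisance channels. Everything is deterministic
given the seed, to the byte in the written files.

Each event sits on its own toy gene, built from a catalogue of 22 locus
templates (cycled over both strands) that plant a known ORF-impact
category by construction: stop-free codon bodies, canonical GT..AG
introns, in-frame planted PTCs at controlled distances from the last
junction (including exactly 50 vs 51 nt), frameshifting exon lengths
followed by a 12-mer cassette that contains stop codons in both shifted
frames but none in frame, and truncation cases on either side of the
20% rule. Genes are compact (exons ~30–200 nt, introns ~60–90 nt),
loosely matching the intron-definition scale of a compact plant genome.

What the generator does **not** emulate: read-level artefacts (mapping
bias, 3′ bias, library chemistry), correlated noise between events of the
same gene, realistic PSI distributions across event types, overlapping
gene structures, multi-isoform annotation, and biologically structured
expression covariance. Passing recovery tests therefore demonstrates that
the callers implement their definitions correctly and are robust to the
modelled noise channels — not that the thresholds are optimal for any
particular real dataset, and not the field-scale prevalence figures
(e.g. genome-wide percent-AS values), which depend on real sample panels.

## Problem sizes used in validation

The bundled validation runs are sized for quick, deterministic execution:
definition-oracle checks use exhaustive small vectors (≤ 6 samples) and
randomized 4–8-event tables; parameter-recovery uses 200 planted + 800
null events at noise sd 3; exact-statistics checks enumerate binomial
totals to 200 and Fisher tables to a grand total of 24; the ORF fixture
bank holds 44 events; pipeline determinism runs a ~100-event bundle
twice. The same library calls scale unchanged to full-size tables.

## Known limitations

* Branch-point and polypyrimidine-tract features, maximum-entropy site
  models, orthology mapping and GO enrichment are out of scope.
* The ORF classifier evaluates one reference transcript per gene;
  annotation evidence from additional transcripts enters only through
  junction-chain matching.
* The stress/tissue callers assume one pooled control/treated sample per
  experiment (replicates are pooled upstream via `merge_replicates`).
* Raw vast-tools output trees are not parsed directly; a thin converter
  to the documented TSV dialect is required.
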