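# Methods

This note documents the models, estimators and numerical choices behind
`sexchrom`, what the simulator does and does not emulate, and the
limitations a user should keep in mind.

## The system being modelled

A dioecious plant with heteromorphic sex chromosomes: females XX, males XY.
The X carries three zones with distinct histories — a pseudoautosomal region
(PAR) on the p-arm that still recombines in both sexes; a very large
pericentromeric region (Xpr) that recombines rarely even in females; and a
small distal q-arm region (qXdr) that recombines actively in females but
stopped recombining with the Y first, so its X/Y gametolog pairs are the
most diverged. Default simulation parameters encode this structure: a
370,597,487 bp X-like chromosome with 25.6 Mb (p) and 15 Mb (q) distal
segments at 2 cM/Mb around a 0 cM/Mb centre; X:Y synonymous divergence
targets of 0.063 (Xpr) and 0.091 (qXdr) with X:outgroup divergence ≈ 0.12;
branch ω of 0.315/0.591 (X/Y, Xpr) and 0.267/0.408 (qXdr); distal gene
density 17.8/Mb against 6.6/Mb in the centre; Y expression at 0.6 (Xpr) and
0.2 (qXdr) of the X copy. These values are the study conditions every
recovery experiment is run under, not tuning knobs.

## Sequence evolution model

Coding sequences evolve on the fixed topology ((X,Y),outgroup). From a
random ancestor of sense codons, each branch applies single-nucleotide
changes drawn by a proposal/acceptance rule: a proposed change is accepted
with relative weight 1 if synonymous, ω if nonsynonymous, 0 if it would
create a stop codon. This is the simplest process with a well-defined
realized dN/dS and is adequate at the low divergences of interest (≤ ~0.15
substitutions/site); it has no transition/transversion bias, no codon-usage
preference and no site-to-site rate heterogeneity.

Branch lengths are tuned **by expectation**: the accepted-event intensity is
set analytically so that the expected number of synonymous events equals
(target dS) × (synonymous sites of the branch-start sequence, Nei–Gojobori
counting), and the event count is drawn Poisson. Per-gene realized
divergence therefore varies stochastically around the target, as in real
data; the truth tables record the realized counts per branch, and tests
check the across-gene mean converges to the target (within 5% at 500
genes). The X:Y divergence target is split evenly between the X and Y
branches; the outgroup branch gets (dS X:OG) − (dS X:Y)/2.

One systematic offset is worth knowing: classical NG86 counts stop-creating
changes as nonsynonymous *sites* (so S + N = 3 per codon) while the
simulator never accepts them as *events*. Roughly 5% of nonsynonymous
changes from a random sense codon are stop-creating, so the ω recovered by
NG86 sits ~5% below the acceptance-ratio ω. At the defaults this is ≈ 0.02
on ω ≈ 0.4, inside the recovery tolerance; it is a property of the site
convention, not an estimator bug.

## The simulated cross

Father: reference X plus the gene's Y haplotype. Mother: two X copies
carrying neutral heterozygous SNPs (default 0.002/bp) placed away from X/Y
divergent positions and never creating stops. Sons inherit the Y and one
maternal X; daughters the paternal X and one maternal X; there is no
recombination within genes. Paired-end reads (150 bp, flat 0.001/bp error)
are placed uniformly per haplotype at half the configured coverage each
(default 20× genomic). Transcriptome-coverage individuals have their Y
haplotype down-weighted by the region's expression-degeneration factor, so
Y alleles can drop out of RNA data in sons — this is what the RNA dropout
tolerance in SNP classification (default 20%) absorbs.

Because reads are placed by construction, per-site allele depths and the
read/site overlap table are exact byproducts of simulation; no aligner runs
anywhere, and mapping error, paralogous mismapping, indels and structural
variation are deliberately absent. Consequently, passing recovery tests
demonstrates the statistical logic of segregation classification and
consensus building, not robustness to alignment artefacts.

The classification rule: mother homozygous (alternate fraction < 0.1,
sequencing-error floor); father carrying a second allele B absent from the
mother; every genome-sequenced son with depth ≥ 5 carrying B; ≥ 80% of
informative RNA sons carrying B; no daughter with depth ≥ 5 carrying B
(hard veto); ≥ 80% of progeny informative. "Carrying" requires ≥ 2 reads
and ≥ 5% allele fraction, so single error reads neither create nor destroy
calls. With multiple families, any informative family's veto rejects the
site; families with insufficient depth abstain.

Consensus over the known CDS replaces de-novo assembly of Y-binned reads:
the downstream use is codon-level divergence of gametologs, which needs the
Y sequence in X coordinates anyway, and restricting to coding regions
avoids the repetitive non-coding sequence that motivates assembly in the
first place.

## Divergence estimation

Pairwise dS/dN uses Nei–Gojobori (1986): per-codon site counts averaged
over the two sequences; difference counts averaged uniformly over all
orderings of the differing positions, excluding orderings that pass through
a stop codon (falling back to all orderings in the rare case every path is
blocked); Jukes–Cantor correction applied per class, with proportions
≥ 3/4 reported as saturated (null estimate, flagged). A brute-force
enumeration over substitution orderings for all 61×61 sense-codon pairs
serves as the oracle for the counting; site counting and the correction are
additionally cross-checked against an independent implementation on
single-step differences (implementations differ on multi-step codons, where
some keep stop-traversing pathways).

Alignment is peptide-guided (Needleman–Wunsch on translations, BLOSUM62,
gap open −11 / extend −1, back-threaded to codons); codons containing gaps,
N or stops in either sequence are masked from counting. This preserves
reading frame by construction, which is the binding requirement; it will
not rescue genuinely frame-shifted input.

Branch rates come from the additive three-taxon decomposition
(dS_X = (d_XY + d_X:OG − d_Y:OG)/2, cyclically; negative raw values clamped
to 0), applied to dS and dN separately — a method-of-moments stand-in for a
maximum-likelihood branch model, accurate at these divergences. Per-branch
ω = dN/dS is null when the branch dS is 0.

Region summaries report, per statistic, the across-gene mean ± SE and, for
the branch ω, also a **pooled** estimate (summed dN over summed dS across
genes). The per-gene branch ω is a ratio of two small noisy counts: at 500
codons its denominator has a ~30% coefficient of variation, which biases
the mean of per-gene ratios upward by roughly E[1/dS]·E[dS] − 1 ≈ +10% and
gives it a heavy right tail. The pooled estimate — equivalent to
concatenating genes, and closest in spirit to a joint likelihood fit — is
the headline number the recovery experiments report; the per-gene mean is
retained for comparability and for the paired ω_Y vs ω_X test, which only
needs within-gene differences.

## Recombination landscape

Marker cM values are the closed-form integral of the piecewise-constant
rate landscape at quantile-placed marker positions (density proportional to
rate plus a floor of 0.15 × distal rate, so the suppressed centre retains
markers), plus truncated-normal noise (default 0.25 cM; 0 for deterministic
geometry runs). The hit table gives each marker 1–3 exon-like hits whose
minimum start is the true position, plus a controlled fraction of hits that
fail the identity (10%) or length (5%) filters.

Anchoring keeps hits with identity > 97% and length > 100 bp (strict),
resolves multi-chromosome markers to the modal chromosome (most passing
hits, then largest summed alignment length) and takes the minimum start —
exon hits of one expressed gene collapse to the gene's lowest coordinate.

Isotonic regression smooths the Marey map before slope estimation because
linkage maps built from transcriptome data contain local order noise that
raw finite differences amplify; outliers beyond a configurable deviation
(default 5 cM) are flagged, never removed. Windowed rates use
(max − min fitted cM)/(marker span) per 10 Mb window at 2 Mb steps — wide
enough for a stable slope at realistic marker densities; the 1 Mb/0.2 Mb
scheme is reserved for density scans, where no slope is needed. Windows
with < 2 markers get a null rate, interpolated only for segmentation.

Segmentation thresholds windows at 0.25 cM/Mb (configurable; the suppressed
centre is "~0 cM/Mb" rather than exactly 0) and takes the longest
qualifying suppressed run nearest the chromosome midpoint (≥ 3 windows).
Boundary placement does **not** use the midpoint between the outermost
suppressed and first recombining window: with 10 Mb windows sliding at
2 Mb, window averaging smears a rate step into a ~10 Mb linear ramp, and
the midpoint rule is biased outward by several Mb. Instead the boundary is
placed where the interpolated window-rate curve crosses halfway between the
flanking recombining plateau (median of flank windows above threshold) and
the suppressed level (median within the run) — the half-amplitude point of
the ramp, which is unbiased under a step landscape and recovers simulated
boundaries to within one window step even at 0.5 cM noise. A suppressed run
touching a chromosome end pins that boundary to the end. Windows are
attributed to a region only when fully contained in it, so
boundary-straddling windows (whose rates mix regimes) never enter regional
rate averages.

## Expression and composition scans

Expression counts are negative binomial (dispersion 0.1; 0 gives the
Poisson limit) with mean `mean_tpm` per X copy and δ × mean for the Y copy;
females sum two X draws. Library sizes are dominated by a background term
(default 10⁶ reads) representing the rest of the transcriptome, so CPM
normalization does not cancel genuine sex differences among the focal
genes — with δ the Y expression fraction, the expected per-gene bias is
log2(2/(1+δ)), recovered within 0.1 at 50 samples. Region comparisons use
Welch's t-test (unequal variances across regions are expected); the X-vs-Y
comparison in males is a paired t-test across genes.

Density scans count gene starts per Mb and TE-covered bp percent in 1 Mb
windows at 0.2 Mb steps, as in the chromosome summary tables this mirrors;
overlapping windows induce autocorrelation, so the Mann–Whitney tests
against autosomes are anti-conservative — setting step = window gives the
conservative non-overlapping variant. Adjustment across the per-autosome
comparisons uses Holm's step-down method.

## Problem sizes and determinism

Recovery experiments run at 150 genes × 500 codons for the divergence
chains (a 2+10 genome-sequenced cross at 20×), 200 triplets for branch-ω,
400 markers for the landscape, and Poisson gene placement for density
recovery — sizes at which across-gene/window standard errors are several
times smaller than the recovery tolerances while a full run stays around a
minute on one CPU. All randomness flows from one root generator per
experiment; identical seeds reproduce outputs byte for byte, including
FASTQ.

## Known limitations

- No indels, structural variants, paralogy or mapping error; recovery
  results certify the statistics, not read-level robustness.
- Universal genetic code only; ambiguity codons are masked, not resolved.
- The additive branch decomposition can clamp at 0 for genes whose
  pairwise distances are non-additive by sampling noise; such genes drop
  out of per-gene ω (reported n per statistic tracks this).
- The sex-averaged landscape machinery supports male maps (PAR-only cM),
  but heterochiasmy beyond the PAR is not modelled by the simulator.
- Jukes–Cantor correction saturates at p = 3/4; the package refuses rather
  than extrapolates there, and these analyses target divergences an order
  of magnitude lower.
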