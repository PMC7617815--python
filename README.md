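# sexchrom

Analysis toolkit for the early stages of sex-chromosome evolution in dioecious
plants, modelled on the *Silene latifolia* X/Y system: a female genome with a
huge, rarely recombining pericentromeric region (Xpr) flanked by two small,
actively recombining distal regions (the pseudoautosomal region on the p-arm
and the q-arm distal region, qXdr), and Y-linked gametologs that can only be
reconstructed indirectly, from segregation in a genetic cross.

The package is aimed at evolutionary geneticists who want these analyses as a
tested, reusable pipeline rather than a one-off collection of scripts. Every
stage has a matched forward simulator with ground-truth records, so each
method can be validated by parameter recovery at desk scale before it is
pointed at real data.

## What it computes

**Recombination landscape** (`mapanchor`). Genetic-map markers (expressed
genes mapped by linkage) are anchored to the genome from a 12-column
alignment hit table, keeping hits with identity > 97% and length > 100 bp and
taking each marker's lowest passing hit position. The Marey map — genetic
position *g* (cM) against physical position *x* (bp) — is smoothed by
isotonic regression, and the local recombination rate is estimated in sliding
windows as Δg/Δx (cM/Mb, 10 Mb windows, 2 Mb steps). Windows below a
threshold (default 0.25 cM/Mb) are suppressed; the central suppressed run is
the pericentromeric region, with boundaries refined by the half-amplitude
crossing of the windowed-rate ramp.

**Y gametolog reconstruction** (`ygametolog`). A Y-diagnostic SNP is an
allele carried heterozygously by the father, absent from the homozygous
mother, transmitted to every son and to no daughter. Read pairs carrying
only diagnostic Y alleles are binned as Y; their pileup over each coding
sequence yields a majority-rule Y consensus (minimum depth 3, ties and thin
positions masked to N).

**Substitution rates** (`codonsub`). For X/Y/outgroup coding triplets,
peptide-guided codon alignment, then Nei–Gojobori (1986) counting: per-codon
synonymous (S) and nonsynonymous (N) sites, pathway-averaged difference
counts (stop-traversing pathways excluded), Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p). Pairwise distances are decomposed onto branches of
the fixed ((X,Y),outgroup) topology additively, e.g.
dS_X = (d_XY + d_X:OG − d_Y:OG)/2, and ω = dN/dS is reported per branch, with
per-region means ± SE and a paired t-test of ω_Y against ω_X.

**Expression bias** (`sexpression`). From allele-resolved counts: CPM
normalization, a paired test of X- vs Y-copy expression in males, per-gene
log2(female/male) bias, and Welch tests of bias between regions.

**Composition scans** (`genomescan`). Gene density (starts/Mb) and TE
coverage (% bp) in 1 Mb windows at 0.2 Mb steps, with two-sided
Mann–Whitney U tests of the X against each autosome, Holm-adjusted.

**Simulator** (`simcross`). Coding sequences evolve by a proposal/acceptance
process (synonymous changes accepted at rate 1, nonsynonymous at ω, stops
rejected) with branch lengths tuned by expectation, so realized per-gene
divergence stays stochastic; the cross produces paired-end reads and
allele-depth tables by construction (no aligner needed); the genetic map
integrates a piecewise-constant rate landscape; expression counts are
negative binomial with region-specific Y degeneration. Truth tables record
every simulated event.

## Worked example

Recover X:Y synonymous divergence through the whole chain — simulate q-arm
distal gametologs and a sequenced cross, classify diagnostic SNPs, partition
reads, build Y consensi and estimate divergence against the X copies:

```python
from sexchrom import recovery

res = recovery.recover_ds_xy("qXdr", n_genes=40, codons=300, seed=1)
print(f"recovered mean dS(X:Y) = {res['mean_ds_percent']:.2f}%  "
      f"(simulated truth {res['truth_mean_ds_percent']:.2f}%)")
print(f"diagnostic sites: precision {res['site_precision']:.3f}, "
      f"recall {res['site_recall']:.3f}")

land = recovery.recover_landscape(seed=1)
b1, b2 = land["boundaries"]
print(f"pericentromeric region: {land['peri_length_mb']:.1f} Mb "
      f"({b1/1e6:.1f}-{b2/1e6:.1f} Mb), distal rate "
      f"{land['distal_rate_mean']:.2f} cM/Mb")
```

prints

```
recovered mean dS(X:Y) = 9.13%  (simulated truth 9.03%)
diagnostic sites: precision 1.000, recall 0.828
pericentromeric region: 328.3 Mb (26.2-354.5 Mb), distal rate 2.00 cM/Mb
```

The recovered divergence matches what the simulator actually realized (the
9.1% target for this region), nearly every called diagnostic site is a true
Y-SNP, and the segmenter finds the ~330 Mb suppressed centre of the
370.6 Mb X-like chromosome with its ~2 cM/Mb distal flanks.

The same stages run from the shell on files:

```
sexchrom simulate --outdir out/sim --seed 1
sexchrom run-all  --outdir out --seed 1      # all stages + manifest.json
```

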