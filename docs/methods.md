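# Methods

## Data model

All scans operate on a `GenotypeMatrix`: one chromosome's sites ×
samples alternate-allele dosage matrix (0/1/2, −1 missing) with
positions (1-based, strictly increasing), REF/ALT alleles and site
QUAL, plus a `PopulationPanel` mapping samples to populations. VCFs are
read through cyvcf2; multi-allelic and indel records are kept at read
time and removed by the filter stage, so the filter report can account
for them.

## Site filter

A site is retained iff it is a bi-allelic SNV, its call rate is > 0.5,
its minor allele count over called genotypes is > 3, and its QUAL is
> 20 — all strict inequalities. "Call rate" is read as a proportion (a
count threshold of 0.5 would be vacuous) and MAC is computed over
called genotypes only, numerator and denominator alike. Missing QUAL
fails the QUAL criterion: a minimum-quality requirement cannot be met
by an absent value. Removals are attributed to the first failing
criterion in the order above, which makes the report deterministic and
its counts sum exactly to sites-in minus sites-out.

## Weir–Cockerham Fst

Per site, with two pooled groups (r = 2), diploid sample sizes n₁, n₂,
allele frequencies p̂₁, p̂₂ and observed heterozygote frequencies
h̄₁, h̄₂, the three variance components are

- a = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
- b = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − (2n̄−1)h̄/(4n̄)]
- c = h̄/2

with n̄ the mean sample size, n_c the variance-corrected size, p̄ and
h̄ the weighted means and s² the weighted between-group variance.
Negative estimates are reported as computed; clamping at zero would
bias window sums. Windows are anchored at position 1, span 20 kb with a
10 kb step by default, are 1-based inclusive, keep the final partial
window, and report both Σa/Σ(a+b+c) (the headline statistic) and the
mean of per-site ratios — on a single-site window the two coincide.
Sites where either group has fewer than two called diploids are
skipped with a recorded reason. Under the Balding–Nichols drift model
E[Fst] ≈ F, which is what the recovery benchmark exploits.

## ABBA-BABA D, jackknife, f̂

Sites are polarized by the outgroup's major allele (ties to REF); sites
where the outgroup is polymorphic are retained, since the frequency
form carries p₄ explicitly — a strict mode would only drop information.
With derived frequencies p₁..p₄,

ABBA = (1−p₁)p₂p₃(1−p₄),  BABA = p₁(1−p₂)p₃(1−p₄),
D = Σ(ABBA−BABA)/Σ(ABBA+BABA).

Sums run over contiguous physical blocks (default 5 Mb; an equal-site
`n_blocks` mode exists for unlinked-site simulations). The SE is the
unweighted delete-one block jackknife on the ratio of sums,
SE² = ((m−1)/m)·Σⱼ(D₋ⱼ−D̄₋)², and Z = D/SE. Blocks whose removal
zeroes the denominator are merged with a neighbour before resampling.

The admixture fraction divides the observed excess S = Σ(ABBA−BABA) by
the excess under complete replacement of P2 by the donor P3, i.e. the
same sum with p₃ substituted in the P2 slot, giving a denominator per
site of (p₃²−p₁p₃)(1−p₄). The plug-in square of a *sampled* donor
frequency is inflated by its sampling variance — with 25 diploids and
F = 0.05 this depressed f̂ to ≈ 0.74α — so the default estimator uses
the unbiased product p̂₃² − p̂₃(1−p̂₃)/(2n₃−1). A split-half variant
(donor sample split into two seeded halves occupying the two donor
slots) is provided and agrees in expectation.

## ROH hidden Markov model

Two states per individual. Non-autozygous sites emit genotypes at
Hardy–Weinberg proportions of the site frequency f; autozygous sites
emit hom-ref/het/hom-alt with (1−f)(1−ε) / ε / f(1−ε), ε being the
genotyping-error rate (default 0.005). Missing genotypes emit 1 in both
states. Adjacent usable sites d bp apart switch state with probability
1−exp(−t·d); a single symmetric rate t (default 10⁻⁸ per bp, an
autozygosity entry/exit hazard on the ~10⁸ bp scale) keeps the model at
one interpretable parameter, and both t and ε are flags. Decoding is
Viterbi with ties broken toward non-autozygous; a posterior-decoding
mode is deliberately absent to keep the decoded segments reproducible
objects. Frequencies come from the analyzed panel itself (pooled by
default, per-population behind a flag); monomorphic sites are skipped
since both states would emit identically. Segment boundaries sit at the
first/last supporting site; FROH counts only runs > 50 kb in its
numerator over the genome length (the VCF contig length unless
overridden). With these defaults the decoder needs roughly 30
consecutive homozygous kb to open a run, so sub-50 kb chance runs are
suppressed twice over.

## LD decay

r² is the squared Pearson correlation of dosages over jointly called
samples — composite LD, free of phasing assumptions. Curves enumerate
all pairs within 300 kb (default) above MAF 0.05, binned at 1 kb; the
sliding-window enumeration keeps memory proportional to the window, not
the pair count, and a no-missing fast path uses standardized dot
products. The half-decay distance (first bin at or below the midpoint
between the first-bin level and the curve floor) summarizes curves for
cross-population comparisons.

## PCA

Sites are centered at 2p̂ and scaled by √(p̂(1−p̂)) with p̂ the MLE
over called genotypes (a (1+count)/(2+2n) shrinkage option exists but
is off: inputs are pre-filtered to MAC > 3). Missing dosages impute to
the site mean, hence exactly 0 after centering. Constant-dosage columns
carry no variance and are dropped with the fixed sites. The
decomposition is an eigendecomposition of the sample×sample covariance,
so variance fractions sum to one by the trace identity; component signs
are fixed by making the largest-magnitude coordinate positive, which
also makes results invariant (not merely equivalent) under sample
permutation. No LD pruning is applied by default.

## Synthetic generators

**Drift tree.** Fixed topology (((P1,P2),P3),O). An ancestral frequency
p₀ ~ U(0.05, 0.95) per site (the range avoids loss of polymorphism
under drift) drifts along each branch by Balding–Nichols sampling
p_child ~ Beta(pθ, (1−p)θ), θ = (1−F)/F, so Var = F·p(1−p). The
admixture pulse sets the recipient's pre-drift frequency to
(1−α)·parent + α·donor, with the donor's post-drift frequency — which
makes the f̂ denominator's donor substitution exact in expectation.
Sites are unlinked (LD lives only in the mosaic model), genotypes are
Binomial(2, p) per diploid, positions are laid out every 100 bp, and
QUAL comes from a two-component mixture straddling 20 so the quality
filter is exercised. The truth records per-population frequencies, the
ancestral (root-major) allele and the recipient's pre-pulse mixture.

**Founder mosaic.** K founder haplotypes (default 40) are drawn
site-wise from U(0.05, 0.95) frequencies; each sample haplotype copies
founders along the chromosome, re-drawing its founder uniformly with
probability 1−exp(−ρ·d) between adjacent sites (ρ default 10⁻⁵/bp ⇒
~100 kb copying segments), which induces r² decaying on that scale.
Planted tracts overwrite both chromosomes of an individual with one
founder segment. The copying process also produces *coincidental*
autozygosity wherever the two haplotypes happen to pick the same
founder (~1/K of the genome, mostly runs ≪ 50 kb at the default ρ);
the truth therefore exposes the founder paths, and recovery benchmarks
score decoded segments against true same-founder runs, not planted
tracts alone. Genotyping error flips alleles at rate e; missingness and
QUAL are applied as in the tree model.

What the generators do **not** emulate: recombination-graph coalescence
(LD is a copying artifact, not a genealogical one), mutation-rate or
allele-frequency-spectrum realism, selection, and linked drift in the
tree model. Passing recovery tests therefore demonstrates estimator
correctness and calibration under the stated models, not robustness to
every property of real sequencing panels (e.g. the jackknife is
validated on independent sites; on real data its block size must exceed
the LD scale).

## Validation scales and numerical choices

The recovery benchmarks (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: 100 null and 4×20 admixed trio replicates
of 2×10⁵ sites × 25 diploids/population with 50 equal-site jackknife
blocks; 10⁵-site × 50-diploid pairs for Fst at F ∈ {0.01, 0.05, 0.1,
0.2}; a 10 Mb mosaic at 1 site/kb with 1/2/5 Mb planted tracts and
ε = 0.005 for ROH; 100 random 10-site instances for the
Viterbi-vs-enumeration check; 5 Mb mosaics for LD decay; and 2×10⁴-site
panels for PCA. These sizes put Monte-Carlo error comfortably inside
the asserted tolerances while keeping a full run at a few minutes on
one CPU core.

Numerical details worth knowing: emission and transition probabilities
are floored at 10⁻³⁰⁰ before logs; Viterbi tie-breaks (equal scores)
choose non-autozygous; the windowed-Fst tie-break ranks equal windows
by start position; polarization ties (outgroup frequency exactly 0.5)
choose REF; derived child seeds for internal random streams come from
`numpy.random.SeedSequence` spawning and stay below 2³¹.

## Known limitations

- Single chromosome per file/matrix; multi-chromosome analyses
  concatenate runs (the generators accept distinct chromosome names).
- The jackknife merges, rather than models, blocks with empty
  denominators; extremely sparse data can collapse below two blocks.
- f̂ assumes the sampled donor population is the actual donor; with a
  drifted proxy donor, f̂ estimates the proportion relative to that
  proxy (the classic f4-ratio caveat).
- The ROH HMM uses hard genotype calls, not genotype likelihoods, so
  very low-coverage data should be filtered upstream.
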