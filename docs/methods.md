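# Methods

## Setting

Maternal plasma cfDNA in a twin pregnancy is a mixture of maternal DNA
(the major contributor) and DNA from one fetal genome (monozygotic, MZ)
or two (dizygotic, DZ). Sequencing a panel of multiallelic
microhaplotype markers gives, per locus, a read depth for each observed
allele. All interpretation starts from these counts plus reference
genotypes typed from maternal white blood cells and, for paternity, from
the alleged father (AF).

## Fetal allele detection and locus patterns

An allele is called *assumed paternal* (PA) when it is absent from the
maternal genotype and its fraction of the total locus depth `D_i`
reaches the detection threshold (default 1.0%, inclusive). The
denominator is deliberately the total depth `D_i` — the same quantity
used by the FF estimator — rather than any maternal-only subtotal.

Loci are classified by PA count: Type I (0), Type II (1), Type III (2).
Two fetuses carry at most two nonmaternal paternal alleles, so a locus
with more than two PAs can only arise from noise; it is left
unclassified, excluded from zygosity and FF estimation, and logged as
suspected drop-in. Loci under a configurable depth floor (default 50
reads, where a 1% threshold stops being meaningful) fail QC the same
way. Equal-depth PAs are ordered by allele string for determinism.

## Zygosity

A case is called DZ when at least `min_informative` (default 1) Type III
loci are present, else MZ. Real cohorts separate cleanly (0 vs. 3–10
informative loci), but a single Type III locus can be a drop-in
artifact, so the informative count is always reported and the threshold
is exposed (`--min-informative`).

## Fetal fraction

At informative locus `i` the two fetus-specific alleles have depths
`d(l)_i ≤ d(h)_i`. Under the working assumption that the lower-depth
allele consistently derives from the lower-FF fetus,
`FF_lower = (1/N) Σ 2·d(l)_i/D_i` and
`FF_higher = (1/N) Σ 2·d(h)_i/D_i` (unweighted means over the `N`
Type III loci), with combined FF their exact sum. The factor 2 reflects
one fetal genome copy per fetus-specific allele. Type II loci are
excluded from the DZ estimate: a single shared allele cannot be
attributed to one fetus. For MZ cases the combined FF is the
singleton-style mean of `2·d_f_i/D_i` over Type II loci.

The per-locus min/max attribution is an order statistic: when the two
true fractions are close, sampling noise swaps attributions, deflating
the lower and inflating the higher estimate. This is a property of the
method's stated assumption, not an implementation artifact; the test
suite demonstrates it at nearly equal fractions and shows recovery
within 1 percentage point at (4%, 8%) with deep noise-free counts.

Validation against fetal reference genotypes defines the *real* PA set
per locus (fetal alleles absent from the mother). Dropouts are real PAs
missed in plasma; drop-ins are assumed PAs carried by neither fetus;
detection rate is `(real − dropout)/real`. Validated FFs use observed
plasma depths of real PAs regardless of the threshold (a dropped-out
allele contributes depth 0). Concordance between estimated and
validated FFs is reported as the squared Pearson correlation, identical
to the regression R² of the scatter.

## Mixture likelihood and paternity LRs

The evidence per locus is qualitative: the set of alleles at fraction ≥
the detection threshold (maternal alleles included). Given contributor
genotypes (mother, twin 1, twin 2):

* each allele copy of twin k drops out independently with probability
  `d_k` (homozygote dropout `d_k²`); maternal copies never drop
  (maternal dropout is fixed at 0 and not configurable — the mother is
  the major contributor);
* at most one drop-in per locus: no drop-in with probability `1 − c`,
  otherwise one allele drawn by population frequency (invisible if
  already observed), so evidence-set probabilities over a locus's allele
  universe sum to exactly 1;
* observed alleles carried by no contributor and not dropped in have
  probability 0.

Fetal genotypes are marginalised over Mendelian priors: the child
receives one maternal and one paternal allele, each transmission passing
the parental allele with probability `1 − r` and otherwise mutating to a
population allele (excluding the parental one, renormalised). Mutation
lives only in transmission — at `r = 10⁻⁸` it is numerically negligible
but keeps LRs finite at apparent exclusions. A random man's allele is a
population draw; with θ > 0 it follows the Balding–Nichols sampling
formula conditioned on the typed parental alleles (the two random men of
H3 are sampled independently, without cross-conditioning — immaterial at
the default θ = 0). Under H2 the two twin labelings (AF fathers twin 1
vs. twin 2) are averaged with equal prior; they coincide when
`d₁ = d₂`.

Defaults: `c = 0.01`, `r = 10⁻⁸`, `θ = 0`, silent-allele probability 0
(values > 0 are rejected as unsupported), dropout floor 0.001 per fetus
(matching the ~0.1% error floor of current sequencing platforms), and a
0.002 population-frequency floor for alleles absent from the frequency
table. Frequencies are *not* renormalised after applying the floor; the
floor is an additive convention and renormalising would silently change
every reported LR.

Cumulative `log₁₀ LR` is the sum of per-locus values (panel loci are
treated as independent), accumulated in the log domain to avoid
underflow across 60 loci. Results are reported over a dropout grid,
default equal `d₁ = d₂ ∈ {0.001, 0.01, 0.05, 0.1, 0.2, …, 0.9}`, with a
full (d₁, d₂) cross grid available. Loci whose evidence lacks a maternal
allele, or that lack a reference genotype, are skipped with a warning.

Implementation note: per-locus likelihoods are evaluated in closed form
per genotype pair (per-allele survival probabilities multiply because
copy dropouts are independent), vectorised over the genotype-pair grid;
alleles outside the evidence/parental set are lumped into one
pseudo-allele carrying their total frequency mass, which is exact
because such alleles only ever have to drop out. The test suite checks
both the elementary likelihood and the marginalised locus likelihood
against independent exhaustive-enumeration oracles to 1e−12 relative.

## Synthetic data

The simulator emulates the study design end to end: a 60-locus panel
with 4–8 SNP-haplotype alleles per locus and flat-Dirichlet frequencies;
Hardy–Weinberg parents; Mendelian twins under MZ/DZ and paternity
AF_BOTH / HS (heteropaternal superfecundation) / NEITHER. Plasma counts
are multinomial at the locus depth with expected proportions
`(1 − ff₁ − ff₂)/2` per maternal allele copy and `ff_k/2` per fetal
allele copy — making a heterozygous fetus-specific allele sit at `ff_k/2`
in expectation, the origin of the estimator's factor 2. Because children
are built as one maternal plus one paternal allele (no mutation in the
simulator), a fetus homozygous for a nonmaternal allele cannot arise, so
the estimator's heterozygosity assumption holds by construction in
simulated data.

Default conditions mirror the study cohort: DZ lower FF 3–8%, higher FF
5–20%, MZ combined FF 9–18%, 13 DZ + 6 MZ cases per 19-case cohort,
mean depth 2000× with negative-binomial overdispersion (variance
`μ(1+φ)`, default `φ = 0.3`; `φ = 0` gives constant depth for
deterministic tests). Optional noise: per-fetal-allele dropout, and
per-locus drop-in of one spurious population allele at a 0.5–1.5%
fraction, deliberately straddling the 1% threshold. The true per-locus
depth distribution of a capture assay is not known here; the depth model
is a configurable placeholder. All randomness flows from one seed and
bundles are byte-identical under it.

What passing simulation tests do *not* show: the generator draws allele
counts as clean multinomials and omits base-level sequencing error, GC
and fragment-length biases, maternal copy-number anomalies, and locus
linkage, so real-data performance (especially dropout behaviour at low
FF) is not established by these tests.

## Problem sizes used in the test suite

Simulation-backed checks use 60-locus panels at depth 2000× (LR
separation: 50 true-father and 50 unrelated replicates over the
d = 0.001–0.3 grid; zygosity accuracy: 200 replicates) and 10000×
noise-free for FF parameter recovery (100 seeds per scenario), sizes at
which the relevant Monte-Carlo margins are comfortably resolved.

## Known limitations

* The likelihood is qualitative: read depths inform detection but not
  the LR itself; a depth-weighted (quantitative) mixture model is out of
  scope, as are more than two fetal contributors.
* At unrealistically high assumed dropout (d ≥ 0.5) the model can
  explain away exclusions, and unrelated men may show `LR_H2,H3 > 1`;
  the specificity screen flags this.
* FF estimation for DZ cases uses only Type III loci; with very few
  informative loci the estimate is noisy, and the lower-FF fetus bounds
  the reliability of any downstream call.
* The 1.0% detection threshold is inclusive (`≥`), and the unseen-allele
  frequency constant 0.002 is taken at face value as a convention.
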