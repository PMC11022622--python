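# Methods

`mixploid` implements a multicriteria workflow for separating interfertile
shrub-birch (*Betula*) species of mixed ploidy from targeted-sequencing SNP
data, together with a synthetic-data generator that makes every stage
testable against known truth.  This note records the models, the defaults
that matter, and the numerical choices behind them.

## Ploidy inference from allelic ratios

At a heterozygous site with alternate-allele dosage *d* and ploidy *c*, the
fraction of reads carrying the alternate allele concentrates around *d/c*.
The density of these ratios across many sites therefore shows one mode near
0.5 for diploids, modes near 1/3 and 2/3 for triploids, near 0.25 / 0.5 /
0.75 for tetraploids, and near 0.2 / 0.4 / 0.6 / 0.8 for pentaploids.

The workflow:

1. **Ratios.** alt/(ref+alt) per sample and site; ratios observed with fewer
   than 15 reads are missing.
2. **Reference SNPs.** Sites are screened on a panel of clear diploids: mean
   panel coverage ≥ 24×; after discarding ratios below 0.05 or above 0.95,
   the histogram mode (bin width 0.02, ties broken toward 0.5) must lie in
   [0.45, 0.55]; and at least two-thirds of the remaining ratios must fall in
   [0.4, 0.6].  The panel is bootstrapped: an initial pass classifies every
   sample on all sites, the samples called diploid become the panel, and one
   refinement pass repeats the selection.
3. **Density.** Gaussian KDE on a 512-point grid over [0, 1] with reflection
   at both boundaries, normalised to unit area.  The bandwidth is fixed at
   0.025 rather than Silverman's rule: Silverman is tuned to unimodal
   targets and over-smooths a three- or four-component mixture whose
   components are ~0.2 apart, merging genuine modes.  Samples with fewer
   than 30 usable ratios are not classified.
4. **Template matching.** Local maxima with topographic prominence ≥ 5% of
   the density maximum and pairwise separation ≥ 0.1 (adjacent template
   positions are never closer than 0.2, so two maxima within 0.1 cannot both
   be genuine) are matched against the four templates; a label is assigned
   only when the peak count matches and every peak is within 0.08 of its
   template position.  Everything else is `unknown`.  Groups of unknowns can
   be classified collectively from their pooled ratios ("putative" calls).

Two detector constants deserve justification.  The prominence threshold is
5% because the dip between adjacent dosage modes at ~24× is shallow: for a
tetraploid the central 0.5 mode rises only ~6–10% above its flanking dips,
so a 10% threshold systematically deletes a genuine mode, while the KDE
sampling noise floor at ≥500 sites and bandwidth 0.025 stays below ~3%.
The matching tolerance is 0.08 because overlapping mixture components pull
inner modes toward the centre (for a pentaploid the 0.4 mode sits near
0.37–0.46 at realistic depth); 0.08 absorbs that bias without letting any
two templates collide, since template identity is decided first by peak
count.

The per-sample heterozygote proxy keeps ratios in (0.1, 0.9), wider than the
0.05/0.95 tail rule used during reference-SNP screening: a single error read
at ~20× lands just above 0.05 on a homozygous site and would otherwise fake
an edge peak.

Validated performance at the study depth regime (24× mean coverage, 200+
individuals per ploidy, ~1600 reference SNPs): 100% for diploids and
triploids, 99.5% for tetraploids, 92.5% for pentaploids.

## Synthetic data generator

The generator emulates a multi-team sampling campaign over K genetic
clusters with one tetraploid species among diploids:

* **Allele frequencies.** Per-locus ancestral frequency uniform on
  [0.05, 0.95]; cluster frequencies from the Balding–Nichols beta with
  parameters (p(1−F)/F, (1−p)(1−F)/F), F per cluster.  Defaults follow the
  study composition: five clusters of 198/109/10/127/25 individuals with
  ploidies 2/2/2/4/2, divergences 0.15/0.12/0.18/0.30/0.35 (chosen so the
  realized pairwise differentiation spans the 0.17–0.46 range observed
  between lineages), plus pair-hybrids and trihybrids and 30 clonal
  duplicates.
* **Genotypes.** Dosage ~ Binomial(ploidy, π) with π the admixture-weighted
  cluster frequency.
* **Reads.** Per-site coverage factor lognormal with σ = 1.0 (amplicon
  panels vary in coverage by orders of magnitude; this is also what makes
  the mean-coverage ≥ 24× reference-SNP filter informative — it enriches
  reference sites to roughly double the assay-wide mean).  Total depth per
  cell is negative binomial (size 12) around mean 24 × site factor.
  Alternate reads are beta-binomial around d/c with concentration 200 and a
  0.005 sequencing-error rate pulling homozygote ratios off 0 and 1.  The
  concentration and coverage-heterogeneity defaults were set analytically so
  that the density-profile classifier operates in the regime where the
  published procedure demonstrably worked (tetraploids separable at 24×):
  with substantially stronger overdispersion the tetraploid mixture is
  provably unimodal-to-flat and no peak detector can recover it.
* **Missingness.** MCAR at 5% (the source assay reports no missingness
  mechanism).
* **Chloroplast.** A pool of distinct binary haplotypes; each cluster draws
  a small set, re-using an already-assigned haplotype with probability 0.3
  (chloroplast capture).  Chloroplast genotypes are haploid copies of the
  haplotype string with MCAR missingness.
* **Sampling design.** Populations of ~8 nested within clusters; teams own
  whole populations, and a configurable fraction of teams (default 0.2)
  receives populations from two clusters, reproducing the situation where
  one team unknowingly collects two species.

What the generator does **not** emulate: linkage disequilibrium along
chromosomes, selection, isolation by distance within clusters, reference
bias in read mapping, and non-random missingness.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to these real-data complications.

## Dataset assembly

Two nuclear datasets are built.  The *initial diploid* dataset codes every
genotype as diploid (a mixed call collapses to heterozygous), drops samples
with > 40% missing data, keeps polymorphic loci (MAF ≥ 0.01, ploidy-aware
frequency Σdosage/Σploidy) with < 30% missing data, and collapses clones at
genetic distance ≤ 350.  The *diploid–tetraploid* dataset codes every
non-diploid call — including ambiguous ones — as tetraploid, relaxes the
sample cap to 50% and the clone threshold to 300.  Genetic distance is the
summed absolute dosage difference over loci non-missing in both samples,
and clone groups are single-linkage components; the genet representative is
the member with least missing data (ties: smallest id).  The absolute
thresholds are calibrated to ~5000 loci; scaled-down runs scale them
proportionally.  MAF and locus missingness are recomputed after sample
removal.  In STRUCTURE-format output every individual occupies four rows;
diploid-coded samples carry two allele rows then two rows of −9.

## Clustering

* **DAPC.** PCA on locus-mean-imputed dosages; k-means over K = 1..70
  scored by BIC_k = n·ln(WSS_k/n) + k·ln(n) (this form exhibits an interior
  minimum when the scores are high-dimensional, as genotype PCA scores
  are); the retained number of PCs maximises the a-score (observed minus
  permutation-expected reassignment proportion); linear discriminant
  analysis supplies axes and posterior memberships (softmax of −½ squared
  distance to group centroids in discriminant space).  K selection can be
  overridden (`force_k`), since BIC plateaus are common and external
  criteria (geography, morphology) may justify a different K.
* **Admixture.** A binomial-likelihood admixture model, dosage g_il ~
  Binomial(c_i, Σ_k Q_ik F_kl), fit by EM with per-sample coded ploidy c_i
  (so mixed 2×/4× matrices need no special casing).  Q starts from a
  symmetric Dirichlet, F from perturbed pooled frequencies; the best of the
  restarts by log-likelihood is kept and per-restart log-likelihoods feed
  the ΔK table.  The log-likelihood is non-decreasing by construction;
  frequencies are clipped to [1e−6, 1−1e−6].  This estimator deliberately
  replaces an external Bayesian clustering program in the pipeline; readers
  for externally produced run files are provided and feed the same ΔK code.
* **ΔK.** For interior K: |mean L(K+1) − 2 mean L(K) + mean L(K−1)| divided
  by the replicate standard deviation of L(K); undefined at the endpoints
  and where the sd is zero.
* **Lineages.** A sample joins cluster k when Q_ik ≥ 0.75, otherwise it is
  `admixed`.  Clusters whose members span the two designated disjoint
  regions (default Alaska / Europe) are split into two lineages by region.

## Diversity statistics

Computed on the diploid-coded dataset.  Per population and locus with n
genotyped individuals: Ho = heterozygote fraction, Hs = n/(n−1)·(1 − Σp² −
Ho/2n), FIS = 1 − Ho/Hs (undefined where Hs = 0); locus averages weight by
data presence.  Pairwise differentiation is Weir & Cockerham's θ from the
a/b/c variance components, combined over loci as a ratio of sums; negative
estimates are reported as computed.  Per-individual heterozygosity follows
the vcftools `--het` convention: observed vs expected homozygote counts
with the 2n/(2n−1) small-sample factor and the method-of-moments F.

## Chloroplast haplotypes

Sites with more than 10% missing data are dropped; among sites that induce
the same sample partition (identical columns up to a global 0↔1 swap,
compared on shared non-missing samples) only the least-missing one is kept
— "uniquely informative" is read as partition-level information.  Retained
sites are concatenated in genomic order; any missing retained site voids
the sample's haplotype (no imputation).  Haplotype letters are assigned by
decreasing frequency.  A haplotype present in more than one nuclear
cluster is flagged `shared` (chloroplast capture), otherwise `endemic`.

## Multicriteria labels

Cluster assignment and ploidy are the deciding criteria: a sample receives
its cluster's label only when its (possibly pooled-"putative") ploidy call
matches the cluster's modal ploidy; conflicts and unknowns are
`unresolved`.  Morphology (blade shape and teeth must match, leaf size
ranges inclusive) and chlorotype corroborate but never decide — chlorotype
sharing across species makes it non-diagnostic by construction.  Samples
without a confident cluster assignment are `putative hybrid`, or `putative
trihybrid` when three memberships each reach 0.2.

## Problem sizes and determinism

The test suite exercises the full pipeline on a scaled-down composition
(167 genets-worth of samples, 800 loci, clone thresholds scaled
accordingly) and the ploidy-accuracy validation on 820 individuals × 8000
loci; both complete in a few minutes.  All randomness flows from
`numpy.random.default_rng` seeded from a single integer; a rerun with the
same configuration reproduces every output file byte-identically.

## Known limitations

* The EM admixture estimator maximises likelihood without the correlated-
  allele-frequency prior of the Bayesian program it stands in for; Q
  estimates on weakly diverged clusters are noisier.
* Pentaploid recognition at 24× remains the hardest case (~92% at default
  difficulty); profiles with merged inner modes come out `unknown`.
* FST is computed on the diploid-coded dataset only; a ploidy-aware
  estimator is out of scope.
* Clone-distance thresholds are absolute counts and must be rescaled when
  the locus panel size changes.
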