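# Methods

## The problem and the model

Many cultivated citrus varieties are interspecific mosaics of two
ancestral gene pools — *C. reticulata* (mandarins, "RET" throughout the
package) and *C. maxima* (pummelos, "MAX").  Given a biallelic genotype
matrix over a set of reference accessions of both taxa plus admixed
query varieties, the pipeline (i) selects polymorphisms diagnostic of
the two-taxon differentiation and (ii) paints each query genome as a
mosaic of ancestral states ("phylogenomic karyotype") with genome-wide
admixture proportions.

All genotypes are unordered diploid allele pairs; a call at a biallelic
locus is fully described by its alt-allele dosage x ∈ {0, 1, 2} (−1 for
missing), which is the internal representation everywhere.  No phasing
or imputation is attempted.  Coordinates are 1-based inclusive.

## Estimators

With p the frequency of an allele in a (sub)population:

* expected heterozygosity  He = 1 − Σᵢ pᵢ² (= 2p(1−p) biallelic);
* observed heterozygosity  Ho = heterozygote fraction of non-missing calls;
* fixation index           Fw = 1 − Ho/He (undefined at He = 0) —
  heterozygote excess gives Fw < 0;
* Nei differentiation      G_ST = (He_tot − (He_ret + He_max)/2) / He_tot,
  with the total population built by *equal-weight* pooling
  p_tot = (p_ret + p_max)/2, so the 11-vs-6 panel asymmetry does not
  bias the estimate.  G_ST ∈ [0, 1]; 1 means the taxa are fixed for
  alternative alleles.  Values are clamped to [0, 1] with tolerance 1e−12.
* simple-matching dissimilarity d = 1 − (1/L) Σ m_l/2, with
  m_l ∈ {0, 1, 2} the alleles shared at locus l (dosage form
  m = 2 − |xᵢ − xⱼ|), over pairwise-complete loci only;
* Euclidean dissimilarity √Σ (xᵢₖ − xⱼₖ)², same completeness rule;
* centroid similarity of an individual with alleles (a, b) to a
  reference set with allele-frequency profile p_c:
  S = (p_c(a) + p_c(b))/2 — the expected allele-matching rate.  The
  formula is not standard anywhere; it was chosen because it reduces
  exactly to the simple-matching similarity 1 − d when the centroid is
  a single *homozygous* genotype (for a heterozygous centroid call the
  expected matching rate is 0.5 while identity matching would give 1 —
  an inherent difference between expectation and identity scoring).

Undefined statistics (no observations, monomorphic denominators)
propagate as NaN, never as zeros.  Aggregated statistics are unweighted
means over defined loci.

## Filtering

Defaults mirror a GBS post-calling cleanup: calls with fewer than 5
supporting reads become missing; loci with more than 50% missing calls
or minor-allele frequency below 0.05 (boundary retained) are dropped,
both computed over all samples; finally only loci with fewer than 30%
missing calls among the 17 reference accessions are kept.  Filters are
idempotent and never alter surviving calls.

## Introgression scan of the references

Reference accessions may themselves be introgressed, which corrupts the
taxon allele frequencies.  Two moving-average tracks are computed per
reference and chromosome, in marker-index space:

* heterozygosity, windows of 120 markers stepped by 40;
* similarity to the RET and MAX centroids, windows of 60 markers
  stepped by 20, restricted to loci informative for the differentiation
  (first-pass G_ST > 0.5).

A window is flagged when Ho > 0.40 (intraspecific combinations sit
around ≤ 0.30; the (0.30, 0.40] gap is deliberately not flagged by this
condition) **or** when similarity to the other taxon's centroid ≥
similarity to the own centroid — the second condition catches
*homozygous* introgressions invisible to Ho.  Runs of consecutive
flagged windows become bp intervals (first to last marker of the run);
intervals from both tracks are unioned.  The two-condition rule is this
package's explicit codification of what is otherwise a judgment call on
track discontinuities; both thresholds are configurable.

Terminal window convention (used by every scan): full windows
[k·step, k·step + win); a terminal remainder forms its own partial
window when it holds ≥ win/2 markers, otherwise it merges into the last
full window; a chromosome with < win/2 markers becomes one whole-window
with a warning.

Masked calls are set to missing per reference; query samples are never
masked.

## Diagnostic polymorphisms and painting

Taxon frequencies are re-estimated on the masked references and loci
with G_ST ≥ 0.9 are selected (the comparator is ≥, exposed as a
parameter).  Only anchor positions of Indels enter the panel, so one
multi-position Indel contributes one marker.  Each panel entry is
oriented by the per-taxon major allele; loci with coinciding or tied
majors are dropped with a warning (orientation is needed for painting
even though selection alone would not require it).

Painting reduces each sample's panel genotypes to RET-homozygous,
MAX-homozygous, heterozygous or missing, then calls successive
non-overlapping windows of 20 DPs: a window is assigned its most
frequent configuration when best/second ≥ 2 (a zero runner-up with a
non-zero best counts as satisfied; an exact tie never calls), and is
undetermined otherwise or when fewer than 10 DPs are scored
(min_scored = 10 is this package's guard for windows gutted by missing
data; it is configurable).  Runs of identical window states merge
losslessly into segments whose bp span runs from the first to the last
DP observed; gaps between segments are left unpainted rather than
imputed.  Genome-wide admixture is counted directly over scored DP
alleles: prop_max = (2·n_max_hom + n_het)/(2·n_scored).

## Synthetic data

The generator emulates the target data regime: 9 chromosomes of 30 Mb,
~4,340 loci each (~39,000 genome-wide), a fraction prop_fixed = 0.285
of loci fixed for alternative alleles (mirroring the observed ratio of
diagnostic to total markers), remaining loci with independent
symmetric Beta(0.5) per-taxon frequencies, 11 + 6 reference accessions,
and 12.6% missing calls injected uniformly at random — all overridable.
Within a taxon genotypes are drawn in HWE and loci are in linkage
equilibrium; ancestry blocks, not LD, carry the spatial signal, which
suffices because every statistic in the pipeline is single-locus or a
window mean.  Admixed queries are per-homolog block mosaics: F1, BC(n)
(n explicit meioses against the recurrent parent, one uniform-random
crossover per chromosome per meiosis, making the expected donor
fraction exactly 0.5^(n+1)), or arbitrary explicit blocks.  Missing
data can be accompanied by a read-depth matrix in which exactly the
missing cells carry < 5 reads, so a depth-threshold pass reproduces
the pattern.

What the generator does **not** emulate: linkage disequilibrium within
taxa, non-uniform marker density (real GBS markers cluster in genic
regions), locus-specific missingness (real missingness is depth- and
variety-correlated), genotyping error, and recombination-rate
variation.  Passing recovery tests therefore demonstrate correctness of
the algorithms under the stated statistical regime, not robustness to
those real-data artifacts.

## Verification and problem sizes

The test suite checks every estimator against closed forms or
independent brute-force recomputations on ≤ 1,000-locus fixtures, and
runs the full pipeline at the default scale (~39,000 loci, 21 samples)
once: diagnostic-marker recall on fixed-difference loci, karyotype
window accuracy against block truth, breakpoint localisation within ±1
window, and admixture-proportion error are measured end to end.
Recall is defined at the selection stage — selected / fixed-difference
loci surviving QC — because the QC missingness filter removes ~1.4% of
all loci by chance under the 12.6% missingness regime regardless of
their diagnostic value, just as any real panel is defined relative to
its QC-passed marker set.  Monte-Carlo checks (backcross dilution,
binomial missingness) use explicit seed-controlled generators and
standard-error-scaled tolerances.  `scripts/acceptance.py` re-runs all
of this from scratch at a user-supplied seed; the sizes above keep it
within a few minutes on one CPU.

## Known limitations

* The introgression rule is threshold-based, not probabilistic: no
  significance testing or HMM smoothing of tracks.
* Painting assumes exactly two source taxa; varieties carrying a third
  ancestry would be mis-assigned or undetermined.
* Reference accessions can be painted against a panel derived from
  their own masked data — a mild circularity retained deliberately to
  match standard practice.
* Segment bp extents stop at observed DP positions; true breakpoints
  lie somewhere in the unpainted gap between adjacent segments.
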