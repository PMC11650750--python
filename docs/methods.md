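# Methods

## Scope and model

`chloropop` analyses the population genetics of coral-associated
Symbiodiniaceae from chloroplast minicircle genes. The unit of
observation is a coral colony; the genetic state attributed to it is the
*dominant* symbiont haplotype over 11 protein-coding genes, treated as a
single haploid, indel-free sequence colinear with a reference. Three
simplifications define the model:

1. **Haploidy.** Within a colony one symbiont strain usually dominates;
   the consensus base at each site is taken as that strain's allele.
   Minor strains are not genotyped — they are only *detected*, from
   credible second bases at diagnostic sites.
2. **Colinearity.** Consensus sequences are reference-colinear by
   construction (pileups are per-reference-position), so no multiple
   alignment is performed anywhere; concatenation in fixed alphabetical
   gene order replaces alignment. Indels are out of scope.
3. **Profiles as haplotype classes.** Population-level analyses operate
   on profile labels (e.g. U1, U2, U3, L, O1, O2), not full sequences,
   mirroring how such studies code haplotypes for AMOVA.

## Consensus calling and SNP discovery

At each site with depth ≥ `min_depth` (default 5, matching the depth
cutoff used for diagnostic-site informativeness) the base with the
highest count is called. Ties that include the reference base resolve to
the reference — the prior of a reference-based caller; ties among
non-reference bases resolve in fixed order A<C<G<T. Sites below the
cutoff or uncovered are N. A SNP is any site with ≥ 2 distinct non-N
alleles across colonies; a site where all but one colony is N is not
variable.

Per-gene summaries report: the SNP count; the mean number of
non-reference calls per colony ("SNPs per genome" is counted against the
reference, not the major allele — the reference-relative framing is the
one the site names use); and nucleotide diversity π as the average over
colony pairs of (differences at sites non-N in both) / (sites non-N in
both) — pairwise deletion, the standard treatment for missing data. π
here is a per-site per-pair average; it is *not* comparable to
definitions that average over all sites including missing ones.

## Profile assignment and mixed-infection detection

A diagnostic panel lists ~10 sites (named `gene.position`, 1-based) and
each profile's expected base at each. A colony is assigned the unique
profile consistent with all its non-N panel bases; several consistent
profiles → AMBIGUOUS; none → the nearest profile by mismatch count (ties
→ AMBIGUOUS), with the mismatch count reported. If more than
`max_missing` panel sites are N (default: half the panel — enough
missingness that most profile contrasts are unobserved) the colony is
UNCALLED.

Mixed infection: a panel site *flags* a colony when depth > `min_depth`
and the second base has count ≥ `min_minor_count` (default 2) and
fraction ≥ `min_minor_fraction` (default 0.10). The defaults are chosen
so that a 30% minor strain at ~35x depth is detected with sensitivity
≥ 0.9 while uniform sequencing error at 0.5% per base yields a
false-positive rate ≤ 0.05 (both verified by simulation in the test
suite). The (dominant, secondary) profile pair is reported when the major
bases identify a unique dominant profile and the minor bases at flagged
sites identify a unique distinct secondary; otherwise no pair is named.

## Trees

Unique concatenated haplotypes (exact string deduplication; N is a
distinct character, so missing data never merges haplotypes) are related
by p-distance (mismatches / sites non-N in both; a pair with no
comparable sites is an error) and clustered by UPGMA. Merge height is
half the average-linkage distance, so the tree is ultrametric by
construction and branch lengths are in substitutions per site. Ties are
broken by the lexicographically smallest pair of cluster representatives,
making output deterministic.

## AMOVA

Sums of squares come from the squared-distance identity
`SS(group) = (1/n) Σ_{i<j∈group} d²_ij`. With the default `mismatch01`
distance (0 same profile / 1 different; note d² = d) the SS depend only
on per-group profile counts, which is also what makes 999-permutation
tests cheap. The three-level nested decomposition (regions / reefs /
colonies) solves variance components from the expected mean squares with
the standard unbalanced-design coefficients:

    n'   = (N − Σ_g Σ_{p∈g} n_p²/n_g) / (P − R)
    n''  = (Σ_g Σ_{p∈g} n_p²/n_g − Σ_p n_p²/N) / (R − 1)
    n''' = (N − Σ_g n_g²/N) / (R − 1)

    σ²_c = MS_within,  σ²_b = (MS_reef − σ²_c)/n',
    σ²_a = (MS_region − σ²_c − n''·σ²_b)/n'''

Permutation schemes follow convention per statistic: Φ_PT permutes
colonies across all reefs, Φ_PR permutes colonies among reefs within
their region, Φ_RT permutes whole reefs among regions. p-values use the
+1-corrected estimator, so the floor is 1/(n_perm+1). Negative variance
components are reported as computed; a `clamp_negative` option floors
them at zero before percentages (different AMOVA implementations differ
here, so both policies are available). If all colonies share one profile
every SS is zero and the Φ statistics are undefined: they are reported
as NaN with an explicit degenerate flag, never silently zeroed. Pairwise
reef Φ_PT is the two-level special case per reef pair; a pair with zero
total SS (both reefs fixed for the same profile) is reported as 0 (no
molecular variation implies no differentiation).

## Reef-level distances, PCoA, IBD, Mantel

The reef-level genetic distance defaults to pairwise Φ_PT floored at
zero (so it is a proper dissimilarity); a Euclidean distance between reef
profile-frequency vectors is available as an alternative, since coded-
haplotype distance conventions differ between implementations. PCoA is
the Gower double-centering −½JD²J with eigendecomposition; coordinates
are eigenvectors scaled by √λ for positive eigenvalues, and axis
percentages (the scale-invariant quantity) are each λ over the positive
total. Isolation by distance uses half-open bins (0,1], (1,2], then 2-km
bins to ≥88 km; same-reef (zero-distance) pairs are excluded; ordinary
least squares of bin mean genetic distance on bin midpoint gives slope,
R² and p. Mantel tests correlate lower-triangle entries (Pearson) with a
one-tailed (positive association) permutation null from joint row/column
shuffles, matching common usage for IBD confirmation. Thermal distances
are Euclidean in (mean reef temperature °C, SD of daily fluctuation °C),
unstandardized by default because both dimensions are already in °C;
standardization is a flag.

Fisher's exact test (two-sided, probability-based) and the Pearson
chi-squared independence test (no continuity correction) are delegated to
scipy.stats; the test suite checks the 2×2 case against a full
hypergeometric enumeration.

## Transplant analysis

Ramets are named `transplantReef-nursery-colony`. A switch is a ramet
whose post-transplant dominant profile differs from its native call;
ramets without a usable post call (dead or UNCALLED) are excluded from
both numerator and denominator, and the denominator is reported alongside
the fraction. Switches are counted per ramet, with a per-colony rollup
also available. Destination classification uses the precedence
LOCAL_DOMINANT > PANEL_NEIGHBOR > NATIVE_PRESENT > NOVEL, keeping all
satisfied evidence flags: "local dominant" is the modal dominant profile
among surveyed colonies of the transplant reef; "panel neighbour" is grid
adjacency on the nursery panel (8-neighbourhood by default, configurable
to 4 or a wider radius — "nearby" has no canonical definition); "native
present" means the profile occurs in the native reef's surveyed pool.
Survival summaries report survivors/deployed × 100 per transplant reef,
native region and native profile.

## Synthetic data generator

The generator emulates the statistical structure of a fine-scale
archipelago study:

- **References**: 11 genes with nucleotide lengths equal to their
  amino-acid lengths × 3 (13,821 nt concatenated), random sequence.
- **Profiles**: four ingroup profiles (U1/U2/U3/L) differing only at a
  10-site panel — five sites split U from L, one extra site each defines
  U2 and U3 — plus two outgroup profiles (O1/O2) carrying panel sites of
  their own and, by default, 30 extra random substitutions outside the
  panel (the divergent-outgroup condition).
- **Reef mosaic** (`example_layout`): 39 reefs in 7 regions over ~90 km,
  with region-structured frequencies — a second upper profile only in the
  two northern regions, U1-dominated mid-lagoon, a forereef transect with
  an outgroup cline rising 5%→90%, and southern reefs split between U3-
  and L-dominated clusters. The exact frequencies are the package's own
  choice of a realistic mosaic; they are fixed, not fitted to anything.
- **Pileups**: per-site depth Poisson with mean 35.4 (a fixed-depth
  option exists for exact tests), reads drawn from the colony's one- or
  two-profile mixture, and uniform sequencing error (rate 0.005) to one
  of the three other bases — the simplest symmetric null error process.
  Mixed colonies carry exactly two profiles (pairs are what such studies
  report), with default incidence 16.5% and minor fraction 0.3.
- **Transplant**: 79 source colonies × 10 ramets, two per site across
  five sites (nurseries 1 and 2; four 25-position 5×5 panels per
  nursery). Survival is two-stage: immediate survival of transplant
  stress (default 633/790 ≈ 0.80) followed by site-specific one-year
  survival of immediate survivors at rates (0.48, 0.42, 0.09, 0.16,
  0.21). The two-stage reading is deliberate: per-site survival
  percentages of that magnitude are mutually consistent with a ~170/790
  one-year survivor count only if they condition on surviving the
  transplant itself. A surviving ramet yields a usable post-transplant
  genotype with probability 91/170, and switches dominant profile with
  probability 0.13, adopting the transplant reef's modal profile or a
  differing panel neighbour's native profile (equal mixture by default).
  When no differing profile is available nearby the switch is
  unobservable, so the realized switch fraction sits marginally below the
  nominal rate.

All draws derive from `SimulationConfig.seed`; identical seed and config
reproduce outputs exactly.

### What synthetic validation does and does not show

Passing tests demonstrate internal correctness (calling, classification
and statistics recover planted truth; estimators are calibrated under
the generator's assumptions). They do not demonstrate robustness to
features real data have and the generator lacks: mapping artefacts and
reference bias, non-uniform and correlated sequencing error, depth
heterogeneity beyond Poisson, within-profile sequence variation (real
profile classes contain many distinct haplotypes), more than two strains
per colony, and temporal change. Quantities that depend on those
features — notably total SNP counts and unique-haplotype counts — are
not reproduced at realistic values by simulation and are reported only
as synthetic analogues.

## Numerical and interface choices

- Coordinates are 1-based and inclusive everywhere; SNP and panel sites
  are named `gene.position`.
- Consensus/haplotype concatenation order is alphabetical by gene id,
  fixed for reproducibility.
- PCoA eigenvalues below `1e-10 × max|λ|` are treated as null axes.
- Permutation tests require an explicit seed for reproducibility in the
  CLI; library calls default to fresh entropy when no seed is given.
- The GenAlEx-style haplotype reader maps integer codes to profile
  labels through an externalized code map (default 1→U1 … 5→O), because
  code legends vary between exports; declared population sizes are
  validated against actual row counts.
- Every CLI run writes a manifest (config echo, package version, input
  MD5 checksums) sufficient to reproduce outputs byte-identically.

## Problem sizes used in validation

The bundled validation runs at desk scale, chosen so the entire suite
completes in about a minute on one CPU: full-genome genotyping on cohorts
of 40–60 colonies, population statistics on the full 273-colony mosaic,
permutation-calibration studies of 500 replicate datasets at 999
permutations (with the counts-based AMOVA kernel each replicate costs
milliseconds), and 100–500 replicate transplant experiments. Larger runs
scale linearly in colonies × sites.

## Known limitations

- The AMOVA kernel operates on profile labels; sequence-level AMOVA with
  per-site distances is out of scope, as is any mixed-effect survival
  modelling (a plain chi-squared independence test on survival tables is
  provided instead).
- `detect_mixed` reports at most one secondary profile; three-strain
  colonies would be flagged but their pair left unresolved.
- IBD bin means ignore the varying number of pairs per bin (the
  regression is unweighted, matching the conventional presentation);
  the OLS interval is exact only when bin means are homoscedastic.
- UPGMA assumes a clock; deep outgroup divergence distorts ingroup
  heights as in any average-linkage tree, which is why profile calls come
  from the panel and the tree is confirmatory.
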