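# Methods

This note documents the statistical procedures `ednadiv` implements, the
choices made where conventions diverge, and what the bundled and
synthetic data can and cannot establish.

## Data model

The central object is an integer taxa-by-samples count matrix with
per-sample metadata (river section, technical replicate). Counts are
stored exactly as integers; relative abundances (read ratios) are always
derived on demand and never stored, so no precision is lost and every
downstream quantity is reproducible from the counts alone. Taxon traits
— taxonomy, the three guild axes and status flags — live in separate
records keyed by an opaque taxon id, so synthetic taxa need no Latin
binomials and display names stay free of markup.

The bundled reference survey covers 97 fish species over 12
dam-separated river sections (one pooled column per section, in the
source table's column order, which places WJD before SFY although the
sampling design lists them the other way; the table's order is kept and
noted in the fixture metadata). The file is checksum-verified at load
time. Two caveats are recorded in its metadata sidecar rather than
silently corrected: five of the 97 published per-species dominance
values are internally inconsistent with the published counts (each
corresponds to an occurrence frequency off by exactly one section); and
two genera share the abbreviated binomial "S. sinensis", so species
display names are unique only as (genus, species) pairs.

## OTU pipeline

Retention follows the standard annotation screen: identity ≥ 0.97,
E-value ≤ 10⁻⁵, target class only, and cluster size strictly over 10
reads, read as total ≥ 11. The size threshold is exposed as a parameter
because "over 10" is ambiguous in common usage. Filtering is idempotent
and preserves row order; an empty result is legal (logged, not raised).

Rarefaction draws without replacement — each sample's rarefied vector
is multivariate hypergeometric given its counts and the target depth —
so rarefied counts never exceed the originals and column totals equal
the depth exactly. `depth="min"` (the smallest sample total) never
fails on a valid matrix. A seed is mandatory; there is no hidden global
state. Whether to rarefy before or after pooling replicates is the
caller's choice: the survey literature does not pin the order, both are
supported, and the CLI logs which was used. Pooling is by summation.

## Alpha diversity and dominance

* **Chao1** uses the bias-corrected form `S_obs + n₁(n₁−1)/(2(n₂+1))`,
  finite when no doubletons exist; the classic `n₁²/(2n₂)` form is
  available behind a flag and raises on n₂ = 0.
* **Shannon** is the standard negative entropy `−Σ pᵢ ln pᵢ` in natural
  log; the base is an option. Pielou evenness `J = H/ln S_obs` is
  base-invariant by construction; it is undefined (reported as NaN in
  tables, an error as a scalar call) for single-species samples.
* **Simpson** is the finite-sample concentration
  `Σ nᵢ(nᵢ−1)/(N(N−1))` on integer counts — the probability that two
  reads drawn without replacement are conspecific, so higher means less
  diverse. The probability form `Σ pᵢ²` is provided separately for
  proportion inputs and is not identical at finite N.
* **Good's coverage** is `1 − n₁/N`. On species-level tables with
  near-million read depths it is ~1 by construction; published coverage
  ranges from OTU-level replicate data cannot be recomputed from a
  species-by-section table and are not asserted anywhere.
* **McNaughton dominance** is `Yᵢ = (nᵢ/N)·fᵢ` with N the grand total
  over the whole matrix and fᵢ the fraction of columns where the taxon
  occurs. For the bundled survey, the columns are the 12 pooled
  sections; this convention reproduces 92 of the 97 published dominance
  values to all 8 printed decimals (the other 5 are the internally
  inconsistent ones noted above). The dominance call is strict,
  Y > 0.02.

## Group comparison

Diversity indices are compared across sections on technical-replicate
values. The parametric path (one-way ANOVA, Tukey HSD) is taken only
when a normality and a homogeneity screen both pass at α = 0.05;
otherwise the tie-corrected Kruskal–Wallis test is used with Dunn's
pairwise rank z-tests under Holm correction. Dunn's test is implemented
in-package (mean-rank differences with the `Σ(t³−t)/(12(N−1))` tie
term) since no installed library provides it.

The normality screen defaults to a single Shapiro–Wilk test on the
pooled within-group-centered residuals, alongside the median-centered
Levene test. The alternative — requiring every group to pass
Shapiro–Wilk individually — is available (`rule="per_group"`) but not
the default: with a dozen groups the per-group rule rejects about half
of genuinely normal datasets at α = 0.05 (its family-wise pass rate is
roughly 0.95¹²), which would route most well-behaved data to the
nonparametric path for no reason. Groups with fewer than 3 observations
or zero variance are untestable and conservatively fail the screen
under either rule. With 3 replicates per group either normality test
has little power; the selection should be read as a safeguard, not an
inference.

Compact letter displays use the insert-and-absorb algorithm on the
adjusted pairwise p-value matrix: starting from one column holding all
groups, every significantly different pair sharing a column splits it,
subset columns are absorbed, and letters are assigned in order of
descending group mean. Two groups share a letter exactly when their
adjusted pairwise p exceeds α. Group SEMs (sample SD over √n) accompany
the letters for error bars.

Under the global null (12 normal groups of 3), the selected test's
measured rejection rate is at the nominal 5 % level; the calibration is
asserted over 1000 simulations in the test suite.

## Beta diversity

Bray–Curtis dissimilarity `1 − 2Σ min(xᵢ,yᵢ)/(Σx + Σy)` is computed on
per-sample relative abundances by default (the read-ratio basis; on
equal-total columns the count and relative bases coincide). Species
level is the default; genus-level aggregation is an option.

PCoA Gower-centers `−d²/2` and takes the symmetric eigendecomposition.
Bray–Curtis matrices are generally non-Euclidean, so negative
eigenvalues occur; they are reported, not corrected, and proportions of
explained variation are computed over the positive eigenvalues only.
Lingoes and Cailliez corrections are available as options. For the
bundled survey the first three axes carry 66.7 % of the variation
(one small negative eigenvalue). Axis signs are fixed by making each
axis's largest-magnitude coordinate positive, so output is reproducible
run to run. On a genuinely Euclidean input the embedding reproduces the
distances to numerical precision (asserted via Procrustes in tests).

The dendrogram uses UPGMA (average linkage) — the community-ecology
default when no linkage is named — with node heights at half the merge
distance, giving an ultrametric Newick tree; other scipy linkages are
accepted for sensitivity checks. One known limit: on the bundled
per-section table, the pair of sections that merges first differs from
the pair reported in the original survey, whose tree was built from
replicate-level rarefied data that is not published; the published
sister pair only emerges from this table if distances are computed on
raw pooled counts, which weight sections by sequencing depth and
contradict the read-ratio basis, so the package does not adopt that.

## Composition and checklist comparison

Guild composition is computed per section on each of the three axes,
either by presence (a taxon counts once if its reads there are nonzero
— "number of species") or by sequence abundance; proportions sum to 1
within a section. Presence-based proportions are invariant to scaling a
section's counts; abundance-based proportions respond to the mix.
Family composition is species counts per family over the record list.

Checklist comparison matches by exact species name when the checklist
carries entries, else by the shared-with-history flag; the two
conventions agree on data where both are available. The detection rate
is detected richness over checklist richness; alien/indigenous/endemic
tallies come from the status flags (indigenous = not alien). The
shared-OTU fraction counts OTUs with nonzero reads in every section
(replicates pool into sections first).

## Synthetic data

The generator emulates the target survey design: 12 sections × 3
technical replicates by default, per-replicate depth drawn uniformly in
roughly the half-million-read range observed in such surveys
(625 000 ± 120 000 by default), a log-normal species-abundance
distribution (σ = 2, a typical community shape), per-(species, section)
log-normal multipliers (σ = 0.75) to create compositional differences
between sections, species split over 1–3 OTUs, and 10 % extra OTUs
whose annotation is built to fail exactly one retention threshold.
Status-flag fractions default to the bundled survey's composition
(alien 12/97, endemic 13/97, protected 4/97), guild probabilities to
its observed guild frequencies, and the checklist is sized so the
planted detection rate is 97/193. Deterministic margins use the
rounding rule `floor(f·n + 0.5)`. Randomness is split into one child
stream per component (abundance, section effects, depth, annotation,
traits, checklist) from a single seed, so output is byte-reproducible
and adding a component does not disturb the others.

What the generator does *not* emulate: sequence-level error (PCR bias,
chimeras, index hopping), correlated replicate structure beyond shared
section composition, taxonomic mis-assignment (annotation noise is
threshold-failure only), and spatial autocorrelation between adjacent
sections. Pipeline tests passing on synthetic data therefore establish
the arithmetic and the bookkeeping, not robustness to those artifacts.

## Numerical conventions

Counts are int64 throughout; thousands separators are accepted on
input. Proportions are kept at full double precision internally and
rounded only at formatting time. Distance matrices must be symmetric
within 1e-12 with zero diagonal. Tests pin scalar examples to hand
computations, cross-check Chao1/Shannon/coverage, Bray–Curtis and PCoA
eigenvalues against scikit-bio, and treat closed-form cases (two-point
PCoA, ANOVA ≡ t² for two groups, Dunn ≡ Kruskal–Wallis for two groups)
as oracles. Test problem sizes (200-seed calibrations, 1000 null
simulations, depth-1000 multinomials) are chosen so the whole suite
runs in well under a minute while keeping Monte-Carlo standard errors
far below the asserted tolerances.
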