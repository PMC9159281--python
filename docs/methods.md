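# Methods

This note describes the models and procedures implemented in `multimerge`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data generator does and does not emulate.

## Problem setting

Multi-crystal experiments (small-wedge cryo collections, in situ
room-temperature series) produce tens to hundreds of individually
integrated, severely incomplete data sets that must be combined into one
merged set of intensities. Four obstacles recur: the consensus symmetry is
unknown and, when the lattice symmetry exceeds the crystal symmetry,
each crystal's indexing is ambiguous; data sets differ by scale, overall B
factor and radiation damage; some crystals are non-isomorphous or simply
bad; and preferential orientation can leave systematic holes in reciprocal
space. The package addresses each stage on a common in-memory model of
unmerged observations (Miller index, intensity, sigma, image number) plus
per-crystal metadata (cell, orientation, scan, wavelength).

## Lattice symmetry search

Candidate two-fold axes are enumerated as integer direct/reciprocal row
pairs (u, h) with u·h in {1, 2}; the corresponding rotation is
2·u hᵀ/(u·h) − I. Each candidate is scored by its obliquity — the angle
between the direct-space axis u and the reciprocal-space axis h in
Cartesian coordinates — and accepted when this delta is within the angular
tolerance (default 5°, reported per operation). Accepted two-folds that
preserve the lattice centring are closed under composition; composite
operations inherit the worst generator delta. Rhombohedral lattices are
handled in the hexagonal setting throughout. Group naming goes through
gemmi's tabulated settings; a subgroup in a non-conventional basis that has
no tabulated name is labelled by its order.

The tolerance deliberately admits *pseudo*-symmetry: a monoclinic cell with
β ≈ 100.4° and a near-coincident C-centred orthorhombic metric gains the
pseudo two-folds at ~0.9° delta, which the correlation analysis below then
accepts or rejects on the intensities themselves.

## Symmetry analysis by correlation embedding

Each of the n data sets is represented m times, once per operation of the
maximum lattice group. The (n·m)² matrix r of pairwise Pearson correlations
between normalized intensities (per-dataset mean normalization within
resolution bins, removing Wilson falloff) is approximated by inner products
of d-dimensional vectors x via L-BFGS minimisation of

    F(x) = Σ_{a<b} (r_ab − x_a·x_b)²  +  Σ_a max(0, |x_a|² − 1)² ,

with coordinates initialised uniformly in [0, 1) (seeded), at most 100
iterations and gradient tolerance 1e-5. The hinge term encodes the model's
meaning — |x| estimates CC*, which cannot exceed 1 — and removes a flat
degeneracy of the pair terms alone (dot products of vectors longer than 1
do not pin down directions). Pairs with fewer than `min_common` (default 3)
common reflections contribute r = 0.

Two implementation points matter at small reflection counts:

* **General-position filtering.** A reflection fixed (up to Friedel) by
  some non-identity lattice operation matches a symmetry copy of itself
  under any indexing, so it correlates copies that the embedding model
  treats as orthogonal. All correlations are therefore computed over
  general-position reflections only. With realistically large reflection
  counts the special zones are a negligible fraction and this choice is
  immaterial; at a few hundred unique reflections it is the difference
  between a clean and a washed-out cluster structure.
* **Flip-invariant element scores.** The mean cos-angle estimating CC for
  operation S is averaged over copy pairs of the *same* data set, where any
  unknown per-dataset indexing choice cancels in the relative operation.

The embedding dimension is chosen by minimising F for d = 2..m and taking
the elbow of the functional-vs-dimension curve: the point of maximum
perpendicular distance from the chord joining the endpoints, with the x
axis normalised to [0, 1] and the y axis to units of the initial
functional. Extra dimensions always absorb some noise, so the curve is
gently convex even without structure; if no point bends away from the
chord by more than 10% of the initial misfit the curve is declared
elbow-free and the most parsimonious d = 2 is used.

Symmetry elements are scored by a two-model likelihood: p(CC; S) is a
Lorentzian centred at 1 truncated to [−1, 1], p(CC; ¬S) the same shape
centred at 0, both with width γ = 0.1 (the conventional lower bound on
σ(CC) — many reflections contribute indirectly to every angle), and equal
priors. Patterson-group candidates are all subgroups of the lattice
rotation group; each multiplies the "present" density over its member
elements and the "absent" density over the rest, the posterior being
normalised across candidates (ties broken toward higher symmetry). Z-CC is
reported as 10·CC, and per-candidate Zcc+/Zcc− are mean z-scores of member
and non-member elements. Re-indexing operations are assigned per data set
by picking the highest-density coordinate as a cluster seed and taking, for
each data set, the coset representative (lattice over chosen group) whose
copy lies nearest the seed; the assignment is determined up to one global
re-indexing applied to all data sets, which is unobservable in principle.

With m = 1 the same machinery is the non-isomorphism mode: the n×n
correlation matrix of consistently indexed, ASU-merged intensities is
embedded, vector lengths estimate each set's signal (inversely related to
its random error) and angles between vectors estimate systematic
differences.

## Clustering and filtering

* **Unit cells** are clustered (Ward) on (a, b, c, angles in radians scaled
  by the mean edge). The default cut looks for the first large gap in the
  sorted merge heights (a jump by more than 5× beyond an absolute ~1 Å
  floor); members outside the largest cluster at the cut are rejected. A
  median-based relative cut was tried first and found to misbehave: with
  near-identical cells the median merge height is at measurement noise, and
  any multiple of it slices the main population arbitrarily.
* **Intensity clustering** uses average linkage on 1 − r (pairwise
  dataset CC over common ASU reflections) or 1 − cos∠(x_i, x_j) from the
  non-isomorphism embedding; every internal dendrogram node is reported
  with its completeness and multiplicity, and clusters can be selected by
  maximum count, minimum completeness or minimum multiplicity.
* **ΔCC½ filtering** iterates: compute overall CC½ (seeded random split of
  each symmetry-equivalent group into half sets), the jackknife deltas
  ΔCC½_i = CC½(without i) − CC½(all), standardise them robustly and remove
  data sets above the cutoff (default 3σ), then repeat until no outliers or
  the cycle limit (6). The σ estimate is max(1.4826·MAD, sample SD): the
  MAD alone is noisy at the typical 10–100-dataset scale and the sample-SD
  floor suppresses false removals while leaving gross outliers (which move
  CC½ by an order of magnitude more than the clean spread) clearly above
  any cutoff. The filter never removes more than half of the input and is
  idempotent on its own output.

## Scaling

The physical-model correction per data set is
g(φ, s) = k(φ)·exp(−2·B(φ)·s) with s = sin²θ/λ², where k and B are
Gaussian-kernel interpolations of control values spaced every 15° of
rotation (a single constant for smaller wedges). Model selection is
automatic: wedges under 60° get scale+B only; larger wedges add a
per-dataset even-order real spherical-harmonic absorption surface on the
scattering direction, at low/medium/high strength (harmonic order 4/6/8
with decreasing quadratic restraint). Refinement alternates (i) reference
update — inverse-variance weighted group means of corrected intensities,
(ii) per-dataset weighted linear fits of log(I/I_ref) in the control-value
basis, (iii) rejection of observations deviating more than 6σ from their
group mean (at most 5 rounds), and (iv) refinement of a single error model
σ'² = a²(σ² + (b·I)²) shared by all data sets, fit so standardized
within-group deviations have unit variance across intensity bins. Only
relative scales are determinable, so the mean log-scale and mean B over
data sets are fixed to zero; planted-truth comparisons must apply the same
gauge. Friedel pairs are kept separate throughout when anomalous mode is
requested.

## Merging statistics and resolution

Merged intensities are inverse-variance weighted means per unique index
under the Patterson group (canonical representative: the lexicographically
greatest orbit member, a fixed deterministic convention — the conventional
per-group ASU shapes are not needed for internal consistency). R_merge,
R_meas and R_pim use the standard unmerged sums over groups with
multiplicity ≥ 2 and are reported as undefined (not zero) when no such
group exists; the multiplicity identities R_meas/R_merge = √(n/(n−1)) and
R_pim/R_merge = 1/√(n−1) hold exactly per group and are tested exactly.
CC½ uses a seeded random split of the observations of each group; CC_anom
correlates half-set anomalous differences. Statistics come overall and in
20 bins of equal volume in 1/d³, with the highest shell reported
separately; completeness is measured against the full theoretically
observable unique set (centring absences excluded) within the data's
resolution range.

The resolution cutoff fits CC½(s) with c₀/2·(1 − tanh((s − s₀)/r)),
initialised at the half-maximum bin, and returns the d where the fitted
curve crosses the cutoff (default CC½ = 0.3), falling back to the data edge
when the curve never crosses and to the last bin above the cutoff if the
fit fails. The pipeline then re-scales at the cutoff before final
statistics.

## Space-group assignment from absences

For each principal axis the rotation order in the Patterson group fixes the
candidate screws (2₁; 3₁; 4₂ and 4₁; 6₃, 6₂, 6₁); the expected-absent class
of each candidate is the axial reflections whose index is not divisible by
the screw period (skipped when centring already extinguishes the class).
The test statistic is z = ⟨I/σ⟩ of the merged expected-absent reflections
times √count, which is N(0, 1) when the screw is present. The likelihood of
the screw weighs this null against an empirical alternative
z ~ N(z_ref, max(1, z_ref/2)) with z_ref the identical statistic on the
screw-allowed axial class. (A pure logistic mapping of z alone was tried
first and proved fragile: with only ~7 unique axial reflections a ~3σ noise
fluctuation in a genuinely absent class could flip the call even though
present reflections in the same data score z of 30–85.) When the allowed
class is unmeasured the logistic fallback (midpoint 3, scale 3) applies,
and an unmeasured absent class scores an uninformative 0.5. Among
candidates supported on an axis the largest period wins (a genuine 4₁ also
passes the 4₂ test, not vice versa); enantiomorphic screws are
indistinguishable from absences and reported as the low-index member. The
final symbol substitutes the winning screws into the acentric symmorphic
Hermann–Mauguin symbol.

## Radiation damage and coverage diagnostics

Image number is the dose proxy (constant dose per image assumed). The
cumulative pairwise R factor R_cp(j) is the merging R over all observations
with image ≤ j; per-image scale and R_merge curves and cumulative
completeness versus dose come from the same pass. Crystal orientations are
projected stereographically (beam along +z into the page; directions
folded to the beam hemisphere and projected from the antipode, so a point
at the origin means the axis is parallel to the beam), optionally with
symmetry-equivalent copies. Isotropy is tested with the Bingham statistic
on the scatter matrix of the axial directions, T = (15n/2)(tr S² − 1/3),
asymptotically χ²₅ under uniformity, flagged at α = 0.01 (chosen
conservatively so that isotropic experiments are essentially never
flagged). Missing-region analysis generates the complete index set to the
cutoff in the primitive setting (centred cells are reduced so lattice
absences do not fragment regions), expands the observed unique set to the
full sphere, groups unobserved points by 26-connectivity
(max(|Δh|,|Δk|,|Δl|) = 1) with scipy.ndimage labelling, merges components
that map to the same unique reflections (symmetry copies of one physical
region), and reports each region's unique members, count, percentage of
the total unique set and resolution span, sorted by size.

## Synthetic data

The generator plants every effect the pipeline is meant to recover:

* true intensities are acentric-Wilson (exponential) via complex Gaussian
  structure factors, with ⟨I⟩(d) ∝ exp(−B_w/2d²) (default B_w = 20 Å²);
  centric statistics are not modelled (noted deviation — no statistic
  exercised here distinguishes them);
* each data set observes the Ewald-sphere crossings of its wedge (default
  10°, rotation about the lab x axis, random or concentrated orientation),
  or a random subsample at a configured multiplicity when geometric realism
  is not the point of a test;
* per-dataset scale (default range 0.5–2.0) and B (0–10 Å²), optional
  per-image B growth for radiation damage, Gaussian noise calibrated to a
  target ⟨I/σ⟩ (default 10; either proportional to the local Wilson mean,
  giving uniform I/σ, or flat in absolute terms so I/σ and CC½ genuinely
  fall off with resolution), screw-axis absences with exactly zero true
  intensity, permuted-intensity outlier data sets, and an optional
  indexing ambiguity applied to a subset of data sets;
* non-isomorphous subpopulations share structure factors with amplitude
  weight α: for unit complex Gaussians, corr(|F₁|², |F₂|²) = α², so
  α = √ρ plants an intensity correlation of exactly ρ (verified by Monte
  Carlo).

What it does not emulate: partiality (each crossing yields one full
observation), detector and background effects, absorption anisotropy,
centric zones, and unit-cell drift within a data set. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not robustness to every pathology of real detector
data.

Problem sizes in the test and acceptance runs are scaled to the desk: a few
hundred unique reflections and 8–24 data sets for most scenarios (the
symmetry-recovery condition is 20 data sets, ~300 unique reflections,
⟨I/σ⟩ ≈ 10, with per-dataset counts chosen to preserve realistic pairwise
overlap at that unique count), ~2000+ unique for scaling recovery where
B-factor leverage needs a real resolution range.

## Known limitations

* Subgroup re-indexing operators to *conventional* settings are not
  derived; candidates found in a non-conventional basis keep the identity
  basis change and, lacking a tabulated name, are labelled by group order.
* Screw enantiomorphs (4₁ vs 4₃ etc.) are inherently indistinguishable
  from absences; the low-index member is reported.
* The per-axis absence test uses axial reflection classes only; zonal
  classes (glide planes) are out of scope, as is any twinning analysis.
* The ΔCC½ image-range variant (excluding trailing image windows rather
  than whole data sets) is available through the damage curves but whole-
  dataset exclusion is the only automated filter.
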