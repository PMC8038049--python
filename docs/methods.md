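# Methods

## The analysis

`gmnet` builds single-subject grey-matter (GM) similarity networks from
segmented T1 partial-volume maps and asks two questions about their
small-world topology: does it differ between a patient group and a control
group, and does it track anhedonia severity?

**Network construction.** A GM partial-volume map on an isotropic 2 mm grid
is tiled into non-overlapping 3×3×3-voxel cubes anchored at the array
origin. A cube becomes a graph node if at least `min_gm_voxels_per_cube`
(default 1) of its 27 voxels exceed `gm_voxel_threshold` (default 0.1).
The similarity of two nodes is the maximum Pearson correlation between one
cube's 27 intensities and all rigid rotations of the other's — by default
the 24 proper rotations of the cube, optionally all 48 symmetries including
reflections. Rotation maximisation makes locally mirrored or rotated
cortical folds comparable. A correlation involving a zero-variance cube is
defined as 0.

**Thresholding.** Each of the n(n−1)/2 candidate edges receives a one-sided
empirical p-value against a permutation null: `n_perm` (default 100,000)
random node pairs are drawn with replacement, the 27 entries of each member
are independently permuted, and the rotation-maximised correlation of the
permuted pair is recorded. p-values use add-one smoothing,
p = (1 + #{null ≥ v}) / (n_perm + 1). Benjamini–Hochberg at q = 0.05 over
the subject's whole edge family determines the surviving edges. The null is
estimated per subject, and BH is applied per subject; the observed
similarity only enters through its rank against the null, so the procedure
adapts to each subject's node count and intensity distribution.

**Small-worldness.** For a binary network, the clustering coefficient CC is
the mean Watts–Strogatz local clustering (vertices of degree < 2 contribute
0), and the characteristic path length L is the mean breadth-first shortest
path over vertex pairs within the largest connected component (the covered
vertex fraction is recorded as `component_fraction` so fragmented networks
can be filtered downstream). Twenty degree-preserving random reference
networks are generated by Maslov–Sneppen double-edge swaps
(`swap_attempts = 10 × |E|` attempted swaps each; swaps creating self-loops
or duplicate edges are rejected, so the degree sequence is preserved
exactly). Then

    gamma = CC / mean(CC_random),  lambda = L / mean(L_random),
    sigma = gamma / lambda.

sigma > 1 indicates small-world topology. If an ensemble mean is 0 (for
example a star graph, which admits no alternative degree-preserving
realisation and has zero clustering), sigma is reported as undefined with an
explicit status rather than divided silently.

**Local scale.** The identical construction is repeated on atlas-masked
node subsets at two levels: the 7 intrinsic connectivity networks
(ICNs: DMN, CCN, SVN, DAN, LN, SMN, VN; unions of atlas regions sharing a
grouping) and individual regions of an AAL-style parcellation. Each cube is
assigned to the region holding the majority of its 27 voxel labels
(background excluded; ties break to the smallest region id). Per-region
null models are re-estimated within the region's node pool. Regions whose
mean node count across all subjects falls below 30 are omitted from
statistical analysis — sigma on very small networks is unstable — and the
retained set is shared by both groups.

**Statistics.** Demographics use Welch's unequal-variance t-test
(continuous variables) and a Yates-corrected chi-square (sex). The group
comparison of sigma is an ANCOVA: OLS of sigma on an intercept, a group
indicator, and total GM volume; the F statistic for the group term (equal to
the squared t of the group coefficient) has (1, n − p) degrees of freedom.
Education is deliberately not a covariate. Anhedonia correlations are
partial correlations (residual method) between sigma and the Chapman
physical (PAS, 0–61) and social (SAS, 0–40) anhedonia scales, controlling
total GM volume in controls and additionally illness duration and
antipsychotic dose in patients; rows with missing SAS drop listwise. The
group difference of coefficients uses the Fisher r-to-z test,

    z = (atanh(r1) − atanh(r2)) / sqrt(1/(n1−3−k1) + 1/(n2−3−k2)),

with the covariate count k subtracted from each group's effective df.
BH-FDR is applied within each test family (the 7 ICN ANCOVAs; the retained
regional ANCOVAs; the correlation comparisons per scale and scope), and
results with adjusted p in (0.05, 0.1] are tagged as trends, never counted
as significant.

## The synthetic cohort generator

No imaging data ship with the package; the generator produces the full
input stack — per-subject GM volumes, an atlas aligned to the grid, and a
covariate table — with the statistical structure the analysis assumes.

**Geometry.** The GM region is a cube-aligned ellipsoidal blob: the union
of tiling cubes whose centres fall inside an ellipsoid rescaled so the
total GM volume matches the subject's drawn target within 5% (a final
multiplicative intensity rescale closes the gap). The blob is cube-aligned
on purpose: a smooth voxel-level boundary would give shell cubes a shared
radial ramp shape that correlates strongly under rotation maximisation and
swamps the designed covariance. Per-cube profile scaling and offsets leave
within-cube correlations untouched, so the gentle radial taper applied per
cube is cosmetic. The atlas is a Lloyd-relaxed Voronoi parcellation of the
reference ellipsoid (roughly equal-sized, contiguous regions), with regions
mapped round-robin onto the 7 ICN groupings.

**Latent covariance and the regularity axis.** Each atlas region carries a
latent 27-voxel pattern; a cube's intensities are its region's pattern plus
idiosyncratic pattern noise and voxel noise. Region patterns are mixes of
per-region basis factors along a cohort-fixed small-world region graph (a
ring with rewiring probability 0.15). The per-subject scalar
`regularity` ∈ [0, 1] interpolates two regimes:

* regularity → 0 (diffuse): wide neighbour mixing (weight 0.70) and low
  cube noise (0.30) spread moderate correlations widely. The thresholded
  graph is dense and disorganised, and sigma is low.
* regularity → 1 (concentrated): narrow mixing (0.35) and higher cube noise
  (0.55) concentrate the covariance into crisp local neighbourhoods. The
  thresholded graph is sparse and clustered, and sigma is high.

Both knobs vary linearly with regularity, so sigma is a smooth monotone
function of it (verified at six regularity points in the tests). Two
design points deserve explanation:

* *Generative, not prescriptive, covariance.* Early designs that prescribed
  a sparse target correlation matrix with strong entries failed:
  correlation matrices obey transitivity (two variables strongly correlated
  with a third cannot be uncorrelated with each other), so sparse strong
  couplings are infeasible and PSD projection silently destroys them. The
  mixing construction is generative and therefore always consistent.
* *Exact-Gram cohort template.* The basis factors are rows of an exact
  orthonormal matrix (orthogonal to the constant vector, so per-cube mean
  removal preserves correlations), shared by the cohort; each subject
  perturbs them by a fraction 0.25 in sd units. With only 27 dimensions, a
  Gaussian template's realised correlations would carry sd ≈ 0.1 sampling
  noise — enough to make the thresholded topology, and hence sigma, a
  lottery from cohort to cohort. The exact basis removes that noise while
  the subject perturbation keeps realistic inter-subject variability.

**Covariates.** Group sizes default to 121 patients / 160 controls. Age,
sex, education, total GM volume, PAS, SAS, illness duration, and
antipsychotic dose are drawn from per-group normal distributions (clipped
to their scales) whose default means and SDs are the reference cohort's
summary values; SAS is missing for a configurable fraction per group
(defaults reproduce 77 / 104 observed). Patient-only fields are absent for
controls. The default volume shape (64, 76, 64) at 2 mm emulates a
whole-brain grid so GM volumes near 586 / 600 cm³ are attainable; the test
suite uses 24³ grids with proportionally reduced GM-volume means
(≈ 28 cm³).

**Anhedonia coupling.** SAS is a linear function of the subject's
standardised regularity plus independent noise — never of the constructed
sigma, so the sigma–SAS correlation is induced through the shared latent
trait rather than imposed. Because measured sigma tracks regularity with
correlation ≈ 0.81 at the reduced test scale (the regularity→sigma
fidelity, a measured calibration constant), the coupling weight is the
configured target divided by 0.81; the realised sigma–SAS correlation then
approaches the configured target as the cohort grows.

**What the generator does not emulate.** No scanner physics, bias fields,
motion, segmentation error, registration error, cortical folding, or
anatomically realistic region shapes. Passing tests show the analysis
machinery is correct and well calibrated under the stated statistical
structure — they say nothing about segmentation quality or atlas
registration on real MRI, which this package deliberately leaves upstream.

## Numerical and implementation choices

* Cube symmetries are enumerated exactly on the 3×3×3 grid (24 proper
  rotations; 48 with reflections, behind one flag). The canonical
  flattening is x-fastest (index = x + 3y + 9z), documented and fixed.
* The all-pairs similarity matrix is computed as an elementwise maximum of
  24 matrix products of standardised intensity rows; exact symmetry is
  enforced by a final max with the transpose (the rotation group is closed
  under inverses, so the two triangles agree up to floating-point max
  ordering).
* Graph primitives (local transitivity, shortest paths, Maslov–Sneppen
  rewiring) run through python-igraph's C core; networkx implementations
  serve as independent oracles in the tests. Rewiring is deterministic
  given the seed (igraph draws from Python's `random`, which is seeded and
  restored around each call).
* Every stochastic stage derives its seed deterministically from the master
  seed and the subject/region identifier (SHA-256 based), so full pipeline
  runs are reproducible bit-for-bit and subjects can be processed in any
  order.
* Degenerate inputs yield explicit statuses, not silent numbers: empty
  networks (sigma missing), regions with fewer than 2 nodes, undefined
  sigma (zero reference means), failed demographics tests on tiny groups.
* Test and acceptance runs use reduced problem sizes — 24³ volumes,
  permutation nulls of 1,000–20,000 draws, 2–20 random references, and the
  replicate counts stated in each test — chosen so the whole suite
  exercises the full chain end to end at desk scale.

## Known limitations

* Sigma on sparse or fragmented networks is unstable; the package reports
  `component_fraction` and leaves filtering to the analyst, and the
  generator's operating band is chosen to keep networks connected.
* The empirical null treats a cube's 27 intensities as exchangeable under
  permutation; intensity fields with strong within-cube spatial
  autocorrelation beyond the generated kind would make the null slightly
  conservative or liberal depending on direction.
* The regularity→sigma fidelity constant is measured at the reduced test
  scale; at other scales the induced sigma–SAS correlation will deviate
  from the configured target in proportion to the fidelity difference.
* Only sigma-type small-worldness is implemented (no lattice-normalised
  omega variants), and only binary undirected networks.
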