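# Methods

`optirad` implements the quantitative machinery for assessing surgical
disconnection of the optic radiations in (paediatric) epilepsy surgery:
tract visitation maps and tract-weighted microstructural metrics, a
cross-sectional resection-overlap score, a mixed-effects group comparison,
and clinical concordance summaries — together with a synthetic-data layer
that generates every input with known ground truth.

## Coordinate conventions

All volumes carry a 4×4 affine mapping voxel indices to world RAS
millimetres (NIfTI-1 convention). "Anterior–posterior" always means world
Y; "posterior" is −Y. Streamlines are polylines in world mm and are read
and written as TCK through `nibabel.streamlines`.

## Synthetic data layer

### Geometry phantoms (`phantom`)

A phantom is a tube of streamlines around a parametric centreline whose
default course — anterior swing followed by a posterior sweep — mimics the
anterior loop of the optic radiation (Meyer's loop), the segment most at
risk in temporal-lobe resections. Each streamline is the centreline plus a
constant radial offset in the local perpendicular frame; the offset radius
is half-normal with sd = `tract_radius/2`, truncated at `tract_radius`, so
containment within the tube is guaranteed by construction. Streamlines are
generated directly rather than tracked: fibre-orientation estimation and
probabilistic tracking are external, upstream steps, and the phantom's job
is to exercise everything downstream of them.

The accompanying label volume places a "thalamus" box at the anterior end
of the curve, three adjacent occipital parcels (lingual, pericalcarine,
lateral occipital, FreeSurfer label ids) at the posterior end, and a
contralateral grey-matter block; the resection is an axis-aligned ellipsoid
at a configurable centre. Defaults use a 48×64×32 grid at 2 mm — the
in-plane resolution of the acquisition the pipeline targets.

### Diffusion signal simulator (`signal_sim`)

Voxels contain identical axisymmetric microdomains (diffusivities
λ∥ ≥ λ⊥) whose orientations follow a Watson distribution with
concentration κ about a per-voxel mean axis. Watson is used because it is
the standard antipodally-symmetric, axisymmetric dispersion model and
exposes a single concentration parameter for monotonicity checks. The
signal is the orientation average of exp(−b(λ⊥+(λ∥−λ⊥)(g·n)²)), evaluated
by fixed spherical quadrature (1024 Fibonacci orientations), normalised to
b0 = 1, then corrupted with Rician noise of scale 1/SNR (magnitude-MRI
convention; SNR is defined on the b0 signal). The construction makes the
per-shell direction average independent of κ and of the mean axis — the
premise the spherical mean technique rests on — and the simulator is the
generative oracle for all microstructure-fitting tests.

The default protocol matches the targeted acquisition: shells at b = 1000
and 2200 s/mm² with 60 directions each plus 13 interleaved b = 0 volumes.
Per-shell direction sets are built by antipodal electrostatic repulsion
(L-BFGS minimisation of the Coulomb energy of the 60 point pairs from a
Fibonacci start), the standard construction for gradient tables; with this
set the 60-direction shell average matches the analytic spherical mean to
~3×10⁻⁴ even for near-coherent fibres.

Default ground truth is λ∥ = 1.7×10⁻³ mm²/s, λ⊥ = 0.3×10⁻³ mm²/s — typical
coherent white matter — with SNR 30, a realistic b0 SNR for 2 mm paediatric
EPI.

### Cohort simulator (`cohort_sim`)

One row per subject × timepoint × hemisphere × metric, for nine metrics
(MD, AD, RD, FA, μMD, Long, Trans, μFA, ODEntropy). Default composition
mirrors the study cohort: 43 patients (two timepoints, hemispheres coded
ipsi/contra) and 50 controls (baseline only, left/right), ages uniform on
5–19 years, male fractions 22/43 and 30/50. Metric intercepts default to
the published group-level values; planted fixed effects default to the
published effect magnitudes with the signs of the significant-change
summary (the source's coefficient table prints group estimates whose signs
contradict its own t statistics; the qualitative summary table is taken as
authoritative).

The spec-level noise scales (`subject_sd`, `hemisphere_sd`, `residual_sd`)
are *fractions of each metric's intercept* (defaults 0.03/0.01/0.02),
because the metrics span four orders of magnitude and a single absolute sd
cannot be meaningful across them. Age effects are planted about the cohort
median age (11 y) so the intercept keeps its interpretation.

## Microstructure models

### DTI (`dti`)

Log-linear weighted least squares (weights = squared signal, the usual
variance stabilisation for log-transformed Rician data), batched over
voxels; eigendecomposition gives FA/MD/AD/RD. Negative eigenvalues from
noisy fits are clamped to zero before scalars are computed and flagged.
Requires ≥ 6 unique directions and a full-rank design; voxels with
non-positive signal are excluded and flagged, not fitted. On noise-free
single-tensor signals the fit is exact to numerical precision (the
log-linear system is then consistent).

### Spherical mean technique (`smt`)

Per-shell spherical means ē(b) (arithmetic mean of b0-normalised signals
over a shell's directions; normaliser is the mean of all b = 0 volumes)
are fit with the axisymmetric-microdomain closed form

    ē(b) = exp(−b λ⊥) √π erf(√(b(λ∥−λ⊥))) / (2 √(b(λ∥−λ⊥)))

with a second-order series expansion below b(λ∥−λ⊥) = 10⁻⁸ so the
isotropic limit exp(−b λ∥) and b = 0 → 1 are handled smoothly. Fitting is
a 32×32 multi-start grid over the feasible triangle
0 ≤ λ⊥ ≤ λ∥ ≤ 3×10⁻³ mm²/s followed by bounded least-squares refinement in
the (λ∥, λ⊥/λ∥) parameterisation; boundary or non-converged fits are
flagged but keep their boundary estimate. μMD = (λ∥+2λ⊥)/3 and
μFA = |λ∥−λ⊥|/√(λ∥²+2λ⊥²) follow. Note that two shells give two
observations for two parameters; the multi-start grid exists because the
objective is non-convex near the isotropy edge.

### Orientation dispersion entropy (`odentropy`)

The directional signal is deconvolved with the voxel's fitted axisymmetric
kernel in an even real spherical-harmonic basis (default order 8): by the
Funk–Hecke theorem each degree l is scaled by the kernel's Legendre
coefficient, so the FOD coefficients are recovered by a per-voxel
regularised least squares (Laplace–Beltrami penalty, relative weight
10⁻³ — the standard stabiliser for truncated-basis spherical
deconvolution). The FOD is clipped to non-negative values, renormalised to
unit mass, and summarised as the normalised negentropy
ODEntropy = 1 − H/ln 4π ∈ [0,1]: zero for a uniform orientation
distribution (grey matter, CSF), rising toward one for coherent bundles.
Voxels whose kernel degree-2/degree-0 ratio falls below 10⁻³ (near
isotropic — deconvolution ill posed) are flagged and set to 0.

The exact published definition of this scalar is not public; the
implementation is isolated behind one function and its tested contract is
the published behaviour only — monotone increase with orientation
coherence, and lower values for fibre crossings than for single bundles.

## Regions of interest (`roi`)

The LGN seed surrogate is the posterior half of the thalamus parcel: voxels
strictly posterior (world Y, so oblique affines behave) to the unweighted
voxel centroid; centroid-plane ties count as anterior, making the split
deterministic. The target is the union of lingual, pericalcarine and
lateral occipital parcels (missing parcels warn and are skipped; all three
missing is an error). Exclusion masks combine the contralateral
grey-matter parcel with axis-aligned world-space half-spaces and slabs —
an explicit, reproducible parameterisation of what is in practice a
hand-drawn, subjective step.

## Visitation maps and tract-weighted averages (`tractmap`)

Streamline filtering keeps exactly the polylines that touch both seed and
target and never the exclusion mask (point-in-voxel by world-to-voxel
rounding); the operation is idempotent. Visitation maps count *distinct*
streamlines per voxel (so step size does not bias weights), with segments
resampled at half the smallest voxel edge so no traversed voxel is
skipped, divided by the total streamline count. Thresholding at fraction q
(default 0.05) uses ≥, and the denominator is the total selected
streamline count; thresholding relative to the map maximum is available as
a mode because "5%" is ambiguous between the two readings. Tract-weighted
metric averages use the visitation fractions as weights, excluding
non-finite metric voxels from numerator and denominator; an unweighted
mean over the support is available as an option.

## Disconnection score (`disconnect`)

The thresholded tract map's principal axis (first PC of voxel-centre world
coordinates, sign-oriented anterior→posterior, ties toward +X then +Z) is
rotated about the tract centroid onto the anterior–posterior axis by the
minimal-angle rotation; the identical rigid transform is applied to the
resection (and any other volumes). Masks resample nearest-neighbour,
continuous maps trilinearly; a transform that empties a non-empty volume
is an error. Collinear masks are accepted (a perfect line has a
well-defined first PC); only < 3 voxels or zero covariance raise.

After alignment, for every coronal slice s the intersection count
n_s = |tract ∩ resection in s| is computed and two scores are defined:

* `whole_volume` (default): max_s n_s / |tract| — the fraction of the
  whole tract removed at the worst coronal level;
* `slice`: max_s n_s / |tract in s| — the per-slice disconnection
  percentage (1.0 means some level is completely transected).

Both are reported with the argmax slice (ties → smallest index) and the
full per-slice profile; presence/absence of overlap is score > 0. The two
denominators correspond to two readings of the source description, which
are genuinely in tension; neither is declared "the" truth and results name
their mode.

## Group statistics (`stats`)

Per metric: value ~ age + gender + group + timepoint with a random
intercept per subject and a random hemisphere-within-subject intercept,
fit by REML (statsmodels `MixedLM`, L-BFGS optimiser). Coding: F=0/M=1,
control=0/patient=1, baseline=0/after=1. Hemisphere enters only through
the random term (ipsi/contra in patients, left/right in controls). When
the hemisphere component makes the fit singular it is dropped and the
result flagged. Significance uses the Wald statistic with a normal
reference — statsmodels provides no Satterthwaite degrees of freedom; at
the cohort sizes involved the normal reference is equivalent to the |t|>2
convention and is mildly liberal (measured pooled type-I rate ≈ 0.058 at
nominal 0.05 on null simulations). `sign_pattern` classifies each
group/timepoint effect as up/down/"–" at a chosen alpha. For exact
recovery checks of a planted pattern a stricter alpha (10⁻³) is used:
strongly planted effects have p-values many orders below it, while null
cells would otherwise trip the nominal 5% false-positive rate in roughly
one run out of four.

## Clinical fixtures (`clinical`)

The 43-row cohort table and the 12-patient overlap/visual-field table ship
as TSV inside the package, transcribed verbatim — including "No data" and
"Unavailable" strings, an en-dash medication entry, and two known internal
inconsistencies of the source (21 transcribed males vs a reported 22;
seizure freedom 25/36 ≈ 69% vs a reported 75%), which are preserved rather
than silently corrected. Concordance restricts to complete pre- and
post-operative assessments, counts acquired deficits (normal before,
HH/HSQ/abnormal after) accompanied by overlap, and verifies the exact
overlap ⇔ deficit correspondence. Ages in the transcription are integers,
so the summary's median age (11.0) differs in the decimals from the
source's 10.70.

## Problem sizes and numerical choices

Test and acceptance runs use scaled problem sizes chosen to make each
check statistically meaningful: 1000 random 24³ mask pairs for exact
oracle equivalence; 50 rigid motions (≤30°, ≤8 mm — head-motion scale) on
a ≥500-voxel tract with the 0.02 absolute score tolerance that this
support size warrants; 1000 simulated voxels for noisy SMT recovery; 200
replicate null cohorts of 30+30 subjects for type-I control. The
acceptance script uses the same machinery at somewhat smaller replicate
counts and reports every quantity with its problem size.

## Limitations

The synthetic layer exercises the pipeline's mathematics, not scanner
physics: no susceptibility/eddy artifacts, no motion, no partial volume,
no spatially varying noise, single-fibre-population voxels (crossings are
simulated only as explicit mixtures), and phantom geometry far simpler
than real anatomy. Passing tests therefore demonstrate correctness of the
implemented operations and estimators under the stated generative models,
not performance on clinical data. Registration estimation, resection
segmentation, FOD tracking and cortical parcellation are consumed, never
produced. Brain shift between pre- and post-surgical scans is not
modelled.
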