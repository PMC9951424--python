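# Methods

`alphamicro` models the dosimetry and radiobiology of an in vitro
alpha-emitter radiopharmaceutical therapy (αRPT) experiment: adherent
HER2-positive cells on a well bottom, incubated with a ²¹²Pb-labelled
antibody, whose clonogenic survival is read against the absorbed dose their
nuclei actually receive. Because alpha tracks are 50–100 µm long and sparse
at assay activities, the dose to a single nucleus is a stochastic quantity;
the package estimates its full distribution per cell and propagates it into
survival and RBE estimates, alongside the classical mean-dose treatment.

## Synthetic populations

No public imaging or survival data accompany the original experiments, so
the package generates populations with the statistical structure the
analysis depends on.

**Positions.** A Thomas cluster process (Poisson parents, Poisson offspring
with isotropic Gaussian displacement, torus-wrapped) reproduces the tight
clustering of adherent cells, which is the property that drives cross-dose.
In the σ → well-size limit the process reduces to complete spatial
randomness; the test suite verifies the mean nearest-neighbour distance
1/(2√λ) in that limit against a brute-force uniform sampler.

**Shapes.** Cells are the upper halves of flattened ellipsoids resting on
the well bottom (height = 0.85 × lateral radius); nuclei are ellipsoids with
an axial/lateral ratio of 0.6. Nuclear volumes are log-normal with the
median fixed at the volume of a 10 µm sphere (523.6 µm³) and a 30% CV — the
median matches the measured calibration point, while the dispersion and
eccentricity are not reported anywhere and are exposed as configuration.
Masks are voxelized at confocal resolution (0.101 × 0.101 × 0.159 µm by
default; tests use coarser isotropic grids to stay fast). When a drawn
nucleus does not fit its drawn cell body the cell is scaled up (preserving
the nucleus-volume distribution and hence the calibration); a required
linear scale above 4× raises an error.

**Compartments.** The cytosol is the cell mask eroded by 0.2 µm (the lower
end of the 0.2–0.3 µm range used on the real segmentations; implemented by
thresholding the anisotropic Euclidean distance transform so sub-voxel
depths work at confocal resolution); the membrane is the distance-transform
expansion of the cell minus the cytosol. On grids too coarse to represent
0.2 µm the membrane falls back to a one-voxel shell so the compartment
never vanishes.

**Antibody phases.** Membrane signal is uniform over membrane voxels.
Internalized signal is a set of Gaussian endosome puncta seeded uniformly in
the cytosol whose centroids drift deterministically toward the nucleus
surface and merge pairwise when closer than one endosome radius —
reproducing the perinuclear pooling phase qualitatively without asserting a
trafficking model. Per-frame compartment sums are renormalized to the
supplied counts exactly, so activity is conserved by construction.

**Photobleaching.** Time-lapse signal decays as the normalized
double-exponential a·e^(−p₁n) + (1−a)·e^(−p₂n) in the number of laser
passes n. The fitter uses data-driven multi-starts plus an explicit
single-exponential boundary candidate (a = 1), so the nested single-model
case can never fit worse than its own sub-model. Note a caveat found while
validating: over 60 passes a slow rate p₂ ≈ 0.005 only decays ~26%, so p₂
is weakly identified at 1% noise even at the global least-squares optimum;
the fast component and mixing fraction recover within 10%, p₂ only within
a factor ~2.

## Binding kinetics

The five-rate surface model (association k_on, dissociation k_off,
internalization k_int, degradation k_deg, recycling k_rec, receptor number
R_total, ambient concentration C held constant — antibody excess) is the
minimal mass-action realization of the membrane/endosome compartment
diagram:

    dB/dt      =  k_on·C·R_free − (k_off + k_int)·B
    dI/dt      =  k_int·B − k_deg·I
    dR_free/dt = −k_on·C·R_free + k_off·B + k_rec·I

The system is linear; trajectories are computed by eigendecomposition with
a stiff-solver fallback. R_free + B + I is conserved exactly when
k_deg = k_rec = 0 (with recycling active, receptors return to the surface
while antibody remains counted in the internal pool — the model is
antibody-centric). Defaults encode the reported R_total = 1.72 × 10⁵
binding sites and K_D = 0.98 nM; the trafficking rates are not reported and
are set once to typical antibody values (k_int = 5 × 10⁻³ min⁻¹ ≈ 2.3 h
internalization half-time, k_deg = 10⁻³ min⁻¹, k_rec = 2 × 10⁻³ min⁻¹).
K_D values transfer between labels through the immunoreactive-fraction
ratio (only the immunoreactive part binds), e.g. 0.98 nM × 0.95/0.55 =
1.69 nM.

The ensemble fit minimizes, with a Nelder–Mead simplex in log-parameter
space, the squared differences between predicted and measured
antibodies/cell jointly over all concentrations, durations and compartments,
each compartment scaled by its mean so membrane and internalized counts
contribute comparably. Synthetic assays replicate the saturation
(0.25–30 nM) and kinetic (5 min–24 h at 10 nM) designs in triplicate with
log-normal noise, and cell numbers grow with the 26 h doubling time.

**Expected decays.** Bound antibody converts to expected ²¹²Pb primary
events in Δt = 1 min steps: ⟨n⟩ = λ·N(t)·SA·e^(−λt)·Δt, with λ from the
10.64 h half-life and the e^(−λt) factor accounting for physical decay of
the label (unavoidable even though unstated in most assay descriptions).
The specific activity default, 10⁻⁴ isotopes per antibody, is chosen so
that expected decays per cell land in the few-per-assay regime in which
zero-hit fractions exceed 50% for the lower half of the concentration
range — the regime the microdosimetric argument is about.

## Alpha transport

A primary event is one ²¹²Pb chain decayed in situ; the chain emits exactly
one alpha, either the ²¹²Bi line (35.94%, collapsed fine structure at
6.06 MeV) or the ²¹²Po line (64.06%, 8.785 MeV). Beta, recoil and secondary
electron dose are not scored: alpha LET dominates nuclear energy deposition
at cellular geometry, and this is a documented simplification relative to a
full transport code — absolute doses here carry a small systematic deficit.

Tracks are straight (CSDA; scattering and straggling of alphas are
negligible at µm scale). The range–energy relation is a Bragg–Kleeman power
law R = 2.04·E^1.75 µm tabulated on a fine grid, anchored to published CSDA
ranges in liquid water (≈40/48/91 µm at 5.49/6.06/8.785 MeV) and
interpolated piecewise-linearly through the same nodes in both directions,
which makes E(R(E)) exact to machine precision — the property that lets a
fully contained track deposit exactly its branch energy. Deposited energy
between path depths a and b is E(R₀−a) − E(R₀−b) with residual ranges
clipped at zero; the sampled-midpoint implementation telescopes exactly
within contiguous in-mask runs, so non-convex voxel masks with multi-segment
chords need no special casing. Sampling step is half the smallest voxel
edge. Validation: ray-traced chords agree with analytic sphere chords
within two voxel diagonals, and the mean chord under uniform isotropic
irradiation matches Cauchy's 4V/S within 2%.

Decay locations are drawn per voxel proportionally to antibody intensity
and uniformly within the voxel. Events are stratified per target cell:
membrane (its own membrane map), cytosol (its own internalized map), and
cross (all other activity in the laterally 3×3-tiled field; the target's
own center-tile signal is excluded, while its periodic images are kept — in
a torus geometry they stand for distinct neighbours). Desk-scale campaigns
default to 10³–10⁴ events per compartment; the statistics scale like any
Monte Carlo, so larger runs only sharpen the spectra.

## Microdosimetry bootstrap

Per-cell dose is compound Poisson: the event count per compartment is
Poisson with the PK-derived mean, each event contributing a score resampled
from the simulated per-event pool. Per-time-step Poisson draws are
aggregated into one draw with the summed mean — distribution-identical by
Poisson additivity because the pool is time-invariant within a compartment.
Zero-score events cannot change a fold sum, so the process is thinned to the
nonzero sub-pool (rate × nonzero fraction), again distribution-exact and
essential for cross-dose pools where ~99.9% of primaries miss.

Fold sums are histogrammed in K = 250 equal bins over [0, 1.1 × pilot max]
(the pilot is 10³ folds; overshooting sums accumulate in the last bin so
mass is conserved), with the zero-dose mass tracked explicitly and a
companion track-length distribution. A "hit" is a positive total track
length, so a grazing traversal with negligible energy still counts as a
hit. Desk-scale default is 10⁴–10⁵ folds (the analysis-scale reference is
10⁶); degenerate single-value pools reproduce the compound-Poisson closed
forms e^(−⟨n⟩), ⟨n⟩z₁, ⟨n⟩z₁² within Monte-Carlo error, which the test
suite asserts at 3σ.

## Selection-bias correction

Manually selected high-resolution fields oversample dense clusters. Each
acquired cell contributes its histogram of distances to the other cells in
its field; nonnegative per-cell weights c_j are fitted so the normalized
reweighted histogram matches an unbiased reference built the same way from
automated overview tiles (in the synthetic setting: from the full
population). The objective is the L2 distance between normalized
histograms; optimization is a Powell search (derivative-free, as in the
original analysis) warm-started from the nonnegative least-squares solution
of the underlying linear system, with a uniform-weight fallback that
guarantees reweighting never fits worse than no reweighting. Weights are
normalized to mean 1 and enter every population average (Σc_j v_j / Σc_j):
mean doses, colony survival, zero-hit fractions. Binning and norm are
configurable since neither is prescribed.

## Survival models and RBE

With per-cell specific-energy distributions f(z) in hand, the
microdosimetric survival probability is P(S) = Σᵢ wᵢ e^(−z₀ zᵢ) with
frequency weights wᵢ = f(zᵢ)/Σf(zᵢ); the explicit zero-dose mass
contributes e⁰ = 1 exactly rather than at the first bin's center. (A
printed variant of the weights, wᵢ = zᵢ/Σf(zᵢ), is dimensionally
inconsistent and not normalized; it is available behind `literal_weights=True`
for comparison but never used.) The colony surviving fraction is the
bias-weighted average of per-cell P(S). The classical comparator is
SF = e^(−κ·D̄) in the bias-corrected mean dose. Both sensitivities are
fitted by Nelder–Mead on the sum of squared SF errors; when every cell's
distribution is a zero-hit-free point mass, the micro model reduces exactly
to the classical one (fitted z₀ = κ), a degenerate-equivalence check in the
suite.

**Uncertainty.** 95% CIs use a percentile bootstrap with 500 refits.
Two resampling units are provided: experimental conditions (the default,
mirroring the original analysis) and multiplicative residuals at fixed
design. Condition resampling is known to undercover at realistic condition
counts — measured here at 86–91% across n = 8–16 designs — because
variance estimates from so few resampled design points are unstable;
residual resampling keeps the full dose design in every pseudo-sample and
attains ≈95–98% coverage in the same designs. Coverage claims in the test
suite are made for the residual scheme; users quoting condition-resampled
CIs should treat them as slightly anticonservative.

**RBE.** The external-beam reference is the linear-quadratic response with
α = 0.169 Gy⁻¹, β = 0.056 Gy⁻² (taken as inputs, not refit). RBE at a
survival level is D_EBRT/D_αRPT at that level: the LQ dose comes from the
positive quadratic root, the classical alpha dose from −ln(SF)/κ, and the
microdosimetric dose by monotone log-SF interpolation of the predicted
⟨SF⟩-vs-D̄ curve along the condition axis (the two model variants then share
an abscissa). With κ = 5.0 Gy⁻¹ the worked values at 37% and 50% survival
are 14.9 and 16.7, i.e. within 2% of the published 14.7 and 16.5 — the
residual is consistent with κ being printed to two significant figures.
The mean inactivation dose is the trapezoidal area under SF-vs-D̄. The
scale-free "RBE₂" metric is not implemented: no reproducible definition is
available.

**Model comparison.** SSE of the two models' SF predictions, with a
permutation test that randomly swaps the models' squared residuals within
each condition (statistic SSE_A − SSE_B, two-sided, 10⁴ permutations,
exact enumeration of all 2ⁿ swap patterns when feasible). Identical
predictions give p = 1 by construction.

## Reference geometric model

The classical idealization: every cell two concentric spheres (18 µm cell,
10 µm nucleus), on a hexagonal lattice whose pitch is maximized by bisection
on lattice capacity so the requested cell count is "maximally spaced" in the
well, with uniform activity per compartment (membrane = one-voxel shell at
the outer radius, since a two-sphere model has no membrane thickness). It
runs through the same transport/microdosimetry stack, and the comparison
report lists geometric vs realistic per-compartment mean doses side by side
without asserting a direction — the sign of the cross-dose difference
depends on how tightly the realistic population clusters relative to the
maximally spread lattice, which the pitch sweep in the test suite shows
directly (cross dose is monotone non-increasing in pitch).

## Pipeline

`alphamicro run -c config.yaml` executes population → PK → transport →
microdosimetry → survival/RBE → geometric comparison from one YAML config.
One global seed is expanded into independent per-stage streams via
`SeedSequence`, so reruns are byte-identical and stages are individually
reproducible. Every artifact (CSV/JSON) is hashed into `manifest.json`
together with config, seeds, timings and per-stage errors; a stage failure
skips its dependents but still writes the manifest. When no measured
surviving-fraction table is supplied, the survival stage synthesizes one
from the microdosimetric model at a configured true z₀ (default
30.1 Gy⁻¹) with 2% multiplicative noise, so the full loop is exercisable
without external data; supplying `survival.sf_table` (CSV:
`condition_nM, sf`) replaces it.

Default desk-scale problem sizes — tens of cells, 0.4 µm test grids,
10³–10⁴ transport events per compartment, 2 × 10⁴ bootstrap folds, 500
bootstrap refits — are the package's chosen operating point for interactive
use; all of them are single config keys, and the estimators' convergence in
each of these sizes is what the property tests pin down.

## What the synthetic data does and does not establish

The generator reproduces: clustered positions with controllable acquisition
bias, the measured nucleus-size calibration point, the three antibody
phases, assay tables from a known kinetic truth, and bleaching decay. It
does not attempt: microscope point-spread functions or detection noise,
real segmentation artifacts (over/under-segmentation tails in the volume
histogram), cell-cycle or morphology correlations, or daughter-isotope
diffusion (assumed in situ, as in the reference analysis). Passing tests
therefore demonstrate that the estimators recover known truths under the
stated statistical structure — not that the defaults quantitatively match
any particular cell line; with measured inputs (NRRD activity maps, STL
nucleus surfaces, CSV survival tables) the same machinery runs on real
data.

## Numerical choices

- Voxel grids are 0-based; world coordinates are voxel centers; all masks of
  a cell share one local grid.
- Range table nodes are shared by R(E) and E(R), making round trips exact;
  residual ranges clip at zero.
- Ray sampling step ≤ half the smallest voxel edge; per-sample deposits
  telescope within in-mask runs.
- Histogram ranges are frozen from a pilot pass; overflow mass goes to the
  last bin (conservation over resolution in the extreme tail).
- Nelder–Mead searches run in log-parameter space (positivity without
  constraints); best-so-far objective traces are recorded and are
  non-increasing by construction.
- Powell weight fits: tolerance 10⁻⁶ on the objective, ≤10⁴ evaluations,
  NNLS warm start, uniform fallback.
- Degenerate bootstrap resamples (fewer than two distinct conditions) are
  skipped and counted, never silently refit.
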