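"""Cell-survival models, sensitivity fitting, bootstrap CIs, RBE and model
comparison.

Two response models are compared.  The microdosimetric model applies an
intrinsic sensitivity z₀ bin-wise to each cell's specific-energy
distribution, P(S) = Σᵢ wᵢ·e^(−z₀·zᵢ) with frequency weights
wᵢ = f(zᵢ)/Σf(zᵢ), so cells in the zero-dose mass survive with probability 1
— the mechanism that raises apparent sensitivity estimates when zero-hit
fractions are large.  The classical (mean-dose / S-value) model is a
monoexponential in the bias-corrected average dose, SF = e^(−κ·D̄).  Colony
surviving fractions are selection-bias-weighted averages of per-cell
survival probabilities.  RBE at a survival level is the ratio of the
external-beam (linear-quadratic) dose to the alpha-therapy dose producing
the same surviving fraction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .bias import weighted_mean
from .microdose import SpectrumDistribution


# ---------------------------------------------------------------------------
# survival models
# ---------------------------------------------------------------------------

def survival_probability_micro(
    dist: SpectrumDistribution, z0: float, literal_weights: bool = False
) -> float:
    """Microdosimetric single-cell survival probability Σ wᵢ e^(−z₀ zᵢ).

    ``literal_weights`` switches to the unnormalized weights wᵢ = zᵢ/Σf(zᵢ)
    (a printed variant that is not a probability; provided for comparison
    only — the default frequency weights are the consistent reading).
    """
    if z0 < 0:
        raise ValueError("z0 must be nonnegative")
    f = dist.frequencies.copy()
    z = dist.bin_centers
    total = f.sum()
    if total <= 0:
        raise ValueError("empty distribution")
    if literal_weights:
        w = z / total
        return float(np.dot(w, np.exp(-z0 * z)))
    # the explicit zero-dose mass survives with probability exactly 1; the
    # remaining first-bin mass is evaluated at the bin center like every bin
    n_zero = dist.zero_mass * total
    f[0] = max(f[0] - n_zero, 0.0)
    return float((n_zero + np.dot(f, np.exp(-z0 * z))) / total)


def colony_sf(per_cell_ps: np.ndarray, weights: np.ndarray) -> float:
    """Bias-weighted colony surviving fraction ⟨SF⟩ = Σ cⱼ P(Sⱼ) / Σ cⱼ."""
    return weighted_mean(np.asarray(per_cell_ps, dtype=float), weights)


def classical_sf(mean_dose_gy: float, kappa: float) -> float:
    """Monoexponential mean-dose survival SF = e^(−κ·D̄)."""
    if mean_dose_gy < 0 or kappa < 0:
        raise ValueError("dose and kappa must be nonnegative")
    return float(np.exp(-kappa * mean_dose_gy))


def mean_dose(per_cell_doses: np.ndarray, weights: np.ndarray) -> float:
    """Selection-bias-free average dose D̄ = Σ cⱼ ⟨D⟩ⱼ / Σ cⱼ."""
    return weighted_mean(np.asarray(per_cell_doses, dtype=float), weights)


# ---------------------------------------------------------------------------
# sensitivity fitting
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    parameter: float           # κ (classical) or z₀ (micro), Gy⁻¹
    model: str                 # "classical" | "micro"
    sse: float
    converged: bool
    ci_low: float | None = None
    ci_high: float | None = None
    ci_folds: int = 0
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _predict_sf(
    sensitivity: float,
    model: str,
    mean_doses: np.ndarray | None,
    distributions: list | None,
    weight_sets: list | None,
) -> np.ndarray:
    if model == "classical":
        return np.exp(-sensitivity * mean_doses)
    preds = []
    for dists, w in zip(distributions, weight_sets):
        ps = np.array([survival_probability_micro(d, sensitivity) for d in dists])
        preds.append(colony_sf(ps, w))
    return np.asarray(preds)


def fit_sensitivity(
    measured_sf: np.ndarray,
    model: str = "classical",
    mean_doses: np.ndarray | None = None,
    distributions: list | None = None,
    bias_weights: list | None = None,
    x0: float = 1.0,
    maxfev: int = 4000,
) -> SurvivalFit:
    """Fit κ or z₀ by Nelder–Mead minimization of the SSE against measured SF.

    ``model="classical"`` needs per-condition mean doses D̄ (Gy);
    ``model="micro"`` needs per-condition lists of per-cell specific-energy
    distributions (and optional per-condition bias weights).  The sensitivity
    is searched in log space to keep it nonnegative.
    """
    y = np.asarray(measured_sf, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 conditions")
    if model == "classical":
        if mean_doses is None or len(mean_doses) != len(y):
            raise ValueError("classical fit needs one mean dose per condition")
        mean_doses = np.asarray(mean_doses, dtype=float)
        weight_sets = None
    elif model == "micro":
        if distributions is None or len(distributions) != len(y):
            raise ValueError("micro fit needs per-condition distributions")
        if bias_weights is None:
            bias_weights = [np.ones(len(d)) for d in distributions]
        weight_sets = bias_weights
    else:
        raise ValueError("model must be 'classical' or 'micro'")

    trace: list[float] = []

    def objective(theta: np.ndarray) -> float:
        s = float(np.exp(theta[0]))
        pred = _predict_sf(s, model, mean_doses, distributions, weight_sets)
        sse = float(np.sum((pred - y) ** 2))
        trace.append(sse)
        return sse

    res = optimize.minimize(
        objective,
        np.array([np.log(max(x0, 1e-9))]),
        method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 1e-10, "fatol": 1e-14},
    )
    if not res.success:
        warnings.warn("sensitivity fit did not converge; returning best-so-far")
    return SurvivalFit(
        parameter=float(np.exp(res.x[0])),
        model=model,
        sse=float(res.fun),
        converged=bool(res.success),
        objective_trace=np.minimum.accumulate(np.asarray(trace)),
    )


def bootstrap_ci(
    fit_func,
    n_conditions: int,
    folds: int = 500,
    rng: np.random.Generator | int | None = None,
    level: float = 0.95,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI of a fitted parameter.

    ``fit_func(indices) -> float`` refits on a resampled condition index
    vector.  Degenerate resamples (those raising ``ValueError`` or returning
    NaN) are skipped and counted.  Returns (low, high, n_skipped).
    """
    rng = np.random.default_rng(rng)
    estimates = []
    skipped = 0
    for _ in range(folds):
        idx = rng.integers(0, n_conditions, size=n_conditions)
        if len(np.unique(idx)) < 2:
            skipped += 1
            continue
        try:
            est = fit_func(idx)
        except ValueError:
            skipped += 1
            continue
        if not np.isfinite(est):
            skipped += 1
            continue
        estimates.append(est)
    if not estimates:
        raise RuntimeError("all bootstrap resamples degenerate")
    a = (1 - level) / 2
    lo, hi = np.quantile(estimates, [a, 1 - a])
    return float(lo), float(hi), skipped


def residual_bootstrap_ci(
    fit_on_sf,
    measured_sf: np.ndarray,
    predicted_sf: np.ndarray,
    folds: int = 500,
    rng: np.random.Generator | int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile CI from resampling multiplicative residuals at fixed design.

    Surviving fractions carry multiplicative (log-normal) error, so the
    centered log-residuals of the fitted curve are resampled with
    replacement onto the fitted predictions and the parameter refit on each
    pseudo-dataset: ``fit_on_sf(sf*) -> float``.  Because every pseudo-sample
    spans the full dose design, the interval stays close to its nominal level
    even with few conditions, where condition resampling
    (:func:`bootstrap_ci`) is known to undercover.
    """
    y = np.asarray(measured_sf, dtype=float)
    pred = np.clip(np.asarray(predicted_sf, dtype=float), 1e-300, None)
    if y.shape != pred.shape:
        raise ValueError("measured and predicted SF must align")
    rng = np.random.default_rng(rng)
    log_res = np.log(np.clip(y, 1e-300, None) / pred)
    log_res = log_res - log_res.mean()
    n = len(y)
    estimates = np.empty(folds)
    for b in range(folds):
        sf_star = pred * np.exp(log_res[rng.integers(0, n, size=n)])
        estimates[b] = fit_on_sf(sf_star)
    a = (1 - level) / 2
    lo, hi = np.quantile(estimates, [a, 1 - a])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# linear-quadratic reference and RBE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LQParameters:
    """External-beam photon linear-quadratic response SF = e^(−αD−βD²)."""

    alpha: float = 0.169  # Gy⁻¹
    beta: float = 0.056   # Gy⁻²

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")


def lq_sf(dose_gy, params: LQParameters):
    """Linear-quadratic surviving fraction."""
    d = np.asarray(dose_gy, dtype=float)
    return np.exp(-params.alpha * d - params.beta * d * d)


def lq_dose_at_sf(sf: float, params: LQParameters) -> float:
    """Invert the LQ model: dose at which SF is reached (positive root)."""
    if not 0.0 < sf <= 1.0:
        raise ValueError("SF must be in (0, 1]")
    if sf == 1.0:
        return 0.0
    c = -np.log(sf)
    if params.beta == 0:
        if params.alpha == 0:
            raise ValueError("degenerate LQ parameters")
        return float(c / params.alpha)
    disc = params.alpha**2 + 4 * params.beta * c
    return float((-params.alpha + np.sqrt(disc)) / (2 * params.beta))


@dataclass
class RBEResult:
    level: float
    rbe: float
    model: str  # "geometric" | "non-stochastic" | "microdosimetric" | free label


def rbe_at_sf(
    level: float,
    lq: LQParameters,
    kappa: float | None = None,
    micro_curve: tuple[np.ndarray, np.ndarray] | None = None,
    model_label: str = "non-stochastic",
) -> RBEResult:
    """RBE = D_EBRT(level) / D_αRPT(level) at a surviving-fraction level.

    The classical (mean-dose) alpha arm inverts SF = e^(−κD) directly.  The
    microdosimetric arm supplies ``micro_curve = (mean_doses, sf)`` sampled
    along the condition axis (conditions ordered by their bias-corrected D̄);
    the dose at the requested level is found by monotone interpolation in
    log-SF, with an extrapolation warning outside the fitted range.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("survival level must be in (0, 1)")
    d_ref = lq_dose_at_sf(level, lq)
    if kappa is not None:
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        d_alpha = -np.log(level) / kappa
    elif micro_curve is not None:
        doses, sfs = (np.asarray(a, dtype=float) for a in micro_curve)
        order = np.argsort(doses)
        doses, sfs = doses[order], sfs[order]
        log_sf = np.log(np.clip(sfs, 1e-300, None))
        target = np.log(level)
        if target < log_sf.min() or target > log_sf.max():
            warnings.warn("survival level outside fitted range; extrapolating")
        # log-SF decreases with dose; interpolate dose as function of -logSF
        d_alpha = float(np.interp(-target, -log_sf, doses))
    else:
        raise ValueError("provide kappa or micro_curve")
    if d_alpha <= 0:
        raise ValueError("alpha-therapy dose at level is nonpositive")
    return RBEResult(level=level, rbe=float(d_ref / d_alpha), model=model_label)


def mean_inactivation_dose(doses_gy: np.ndarray, sf: np.ndarray) -> float:
    """Trapezoidal area under the SF-versus-dose curve, Gy."""
    d = np.asarray(doses_gy, dtype=float)
    s = np.asarray(sf, dtype=float)
    if d.shape != s.shape or d.size < 2:
        raise ValueError("need >= 2 (dose, SF) points")
    if np.any(np.diff(d) < 0):
        warnings.warn("dose axis unsorted; sorting before integration")
        order = np.argsort(d)
        d, s = d[order], s[order]
    return float(np.trapezoid(s, d))


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    sse_a: float
    sse_b: float
    sse_a_ci: tuple[float, float]
    sse_b_ci: tuple[float, float]
    p_value: float
    permutations: int
    exact: bool


def compare_models(
    predictions_a: np.ndarray,
    predictions_b: np.ndarray,
    measured_sf: np.ndarray,
    permutations: int = 10_000,
    bootstrap_folds: int = 500,
    rng: np.random.Generator | int | None = None,
) -> ModelComparison:
    """Permutation comparison of two models' squared prediction errors.

    The statistic is SSE_A − SSE_B; the null is generated by randomly
    swapping the two models' squared residuals within each condition (exact
    enumeration of all 2ⁿ swap patterns when fewer than 4 conditions, or
    whenever 2ⁿ ≤ ``permutations``).  Two-sided p-value; equal predictions
    give p = 1.  SSE confidence intervals come from a condition-resampling
    bootstrap.
    """
    a = np.asarray(predictions_a, dtype=float)
    b = np.asarray(predictions_b, dtype=float)
    y = np.asarray(measured_sf, dtype=float)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("condition sets must align")
    rng = np.random.default_rng(rng)
    ra, rb = (a - y) ** 2, (b - y) ** 2
    n = len(y)
    observed = float(ra.sum() - rb.sum())
    diff = ra - rb  # swap within a condition flips the sign of its term

    exact = n < 4 or 2**n <= permutations
    if exact:
        stats = np.array(
            [
                np.dot(signs, diff)
                for signs in itertools.product((1.0, -1.0), repeat=n)
            ]
        )
    else:
        signs = rng.choice([1.0, -1.0], size=(permutations, n))
        stats = signs @ diff
    tol = 1e-12 * max(1.0, np.abs(diff).sum())
    p = float(np.mean(np.abs(stats) >= np.abs(observed) - tol))

    def sse_ci(resid: np.ndarray) -> tuple[float, float]:
        sums = np.array(
            [
                resid[rng.integers(0, n, size=n)].sum()
                for _ in range(bootstrap_folds)
            ]
        )
        return tuple(np.quantile(sums, [0.025, 0.975]))

    return ModelComparison(
        sse_a=float(ra.sum()),
        sse_b=float(rb.sum()),
        sse_a_ci=sse_ci(ra),
        sse_b_ci=sse_ci(rb),
        p_value=p,
        permutations=len(stats) if exact else permutations,
        exact=exact,
    )
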