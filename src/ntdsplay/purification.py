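"""In-silico purification: fit and subtract a fractal-aggregate term.

Small-angle scattering samples of large membrane-protein complexes are
often contaminated by a small fraction of aggregates that dominate the
low-q signal. Ensemble-refinement methods assume a homogeneous sample,
so the aggregate contribution must be removed first. The protocol here:

1. model the aggregates as mass fractals of the tetramer itself, via
   the Teixeira fractal structure factor S(q; D, xi, r0);
2. fit the measured curve as
   I_fit(q) = c_tet*P_tet(q) + c_a*P_tet(q)*S(q) + background;
3. subtract only the fitted aggregate term:
   I_filtered(q) = I_original(q) - I_aggregate,fit(q).

A Bayesian indirect Fourier transform (IFT) provides the model-free
chi^2_r floor that any structural model of the filtered curve can aim
for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn

from .beads import guinier_rg
from .curves import ScatteringCurve

__all__ = [
    "AggregateParams",
    "AggregateFitResult",
    "PrCurve",
    "fractal_structure_factor",
    "fit_composite",
    "subtract_aggregate",
    "ift_chi2_floor",
]


@dataclass
class AggregateParams:
    """Mass-fractal aggregate model parameters.

    fraction_scale : aggregate intensity scale c_a (intensity units).
    fractal_dimension : D, 1 < D <= 3 (2 for the default diffusion-limited
        sheet-like aggregates).
    correlation_length : xi (A), overall aggregate size cutoff.
    building_block_radius : r0 (A), radius of the aggregating unit (the
        tetramer itself in this model).
    """

    fraction_scale: float
    fractal_dimension: float = 2.0
    correlation_length: float = 300.0
    building_block_radius: float = 40.0

    def __post_init__(self) -> None:
        if self.fraction_scale < 0:
            raise ValueError("fraction_scale must be >= 0")
        if not (1.0 < self.fractal_dimension <= 3.0):
            raise ValueError("fractal_dimension must be in (1, 3]")
        if not (self.correlation_length > self.building_block_radius > 0):
            raise ValueError("require correlation_length > building_block_radius > 0")


@dataclass
class AggregateFitResult:
    """Result of the composite tetramer + aggregate + background fit."""

    c_tet: float
    aggregate: AggregateParams
    background: float
    chi2_reduced: float
    covariance: np.ndarray  # over (c_tet, c_a, xi, background)
    q: np.ndarray
    aggregate_intensity: np.ndarray  # fitted I_agg on the data grid
    converged: bool = True


def fractal_structure_factor(q_grid, D: float, xi: float, r0: float) -> np.ndarray:
    """Teixeira structure factor of a mass-fractal aggregate (S >= 1).

    S(q) = 1 + D*Gamma(D-1) * sin((D-1)*arctan(q*xi))
               / ((q*r0)^D * (1 + 1/(q*xi)^2)^((D-1)/2))

    with the analytic q = 0 limit S(0) = 1 + Gamma(D+1)*(xi/r0)^D. For
    D = 2 this reduces to the closed form 1 + 2*(xi/r0)^2/(1 + q^2*xi^2).
    """
    if D <= 1.0:
        raise ValueError("fractal dimension must exceed 1 (Gamma(D-1) diverges)")
    if not (xi >= r0 > 0):
        raise ValueError("require xi >= r0 > 0")
    q = np.asarray(q_grid, dtype=float)
    S = np.empty_like(q)
    zero = q == 0
    S[zero] = 1.0 + gamma_fn(D + 1.0) * (xi / r0) ** D
    qq = q[~zero]
    qxi = qq * xi
    S[~zero] = 1.0 + (
        D
        * gamma_fn(D - 1.0)
        * np.sin((D - 1.0) * np.arctan(qxi))
        / ((qq * r0) ** D * (1.0 + 1.0 / qxi**2) ** ((D - 1.0) / 2.0))
    )
    return S


def fit_composite(
    data: ScatteringCurve,
    tetramer_form: ScatteringCurve,
    init: AggregateParams,
    fix_dimension: float | None = 2.0,
    max_iter: int = 500,
) -> AggregateFitResult:
    """Weighted least-squares fit of tetramer + aggregate + background.

    Free parameters: (c_tet, c_a, xi, background). The fractal dimension
    is fixed (default 2) and the building-block radius is fixed to the
    tetramer form factor's sphere-equivalent Guinier radius
    r0 = sqrt(5/3)*Rg. The aggregate intensity is modelled as
    I_agg(q) = c_a * P_tet(q) * S(q) — aggregates of tetramers.
    """
    if not data.same_grid(tetramer_form):
        raise ValueError("data and tetramer form must share the q grid")
    if data.sigma is None:
        raise ValueError("data must carry uncertainties")
    D = init.fractal_dimension if fix_dimension is None else float(fix_dimension)
    r0 = np.sqrt(5.0 / 3.0) * guinier_rg(tetramer_form)
    q, I, sig = data.q, data.I, data.sigma
    P = tetramer_form.I

    def model(c_tet, c_a, xi, bkg):
        return c_tet * P + c_a * P * fractal_structure_factor(q, D, xi, r0) + bkg

    def residuals(p):
        return (model(*p) - I) / sig

    p_max = float(np.max(np.abs(P))) or 1.0
    c_tet0 = max(float(np.max(I)) / p_max, 1e-12)
    xi0 = max(init.correlation_length, 1.05 * r0)
    p0 = [c_tet0, max(init.fraction_scale, 1e-6 * c_tet0), xi0, float(np.min(I))]
    lb = [0.0, 0.0, 1.01 * r0, -np.inf]
    ub = [np.inf, np.inf, np.inf, np.inf]
    sol = least_squares(
        residuals,
        p0,
        bounds=(lb, ub),
        method="trf",
        max_nfev=max_iter * 10,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        x_scale=[c_tet0, c_tet0, xi0, max(abs(p0[3]), 1e-6)],
    )
    c_tet, c_a, xi, bkg = sol.x
    if not sol.success:
        warnings.warn(
            f"composite fit did not converge: {sol.message}; reporting last iterate"
        )
    scale_ref = max(abs(c_tet), abs(c_a), 1e-30)
    if c_a <= 1e-9 * scale_ref or (
        getattr(sol, "active_mask", None) is not None and sol.active_mask[1] == -1
    ):
        warnings.warn("best-fit aggregate scale hit zero (clipped at the bound)")
        c_a = 0.0
    chi2 = float(np.sum(sol.fun**2))
    dof = max(len(data) - 4, 1)
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = np.full((4, 4), np.nan)
    S = fractal_structure_factor(q, D, xi, r0) if c_a > 0 else np.ones_like(q)
    return AggregateFitResult(
        c_tet=float(c_tet),
        aggregate=AggregateParams(float(c_a), D, float(xi), float(r0)),
        background=float(bkg),
        chi2_reduced=chi2 / dof,
        covariance=cov,
        q=q.copy(),
        aggregate_intensity=c_a * P * S,
        converged=bool(sol.success),
    )


def subtract_aggregate(data: ScatteringCurve, fit: AggregateFitResult) -> ScatteringCurve:
    """I_filtered = I_original - I_aggregate,fit, pointwise.

    The constant background is NOT subtracted (it remains part of any
    later fit), and sigma is copied unchanged: the subtracted term is a
    smooth fitted model treated as noise-free.
    """
    if fit.q.shape != data.q.shape or not np.allclose(fit.q, data.q, rtol=1e-9, atol=0):
        raise ValueError("fit was derived on a different q grid")
    return ScatteringCurve(
        data.q.copy(),
        data.I - fit.aggregate_intensity,
        None if data.sigma is None else data.sigma.copy(),
        label=(data.label or "") + " [aggregate-subtracted]",
    )


# ---------------------------------------------------------------------------
# Bayesian indirect Fourier transform (chi^2_r floor)


@dataclass
class PrCurve:
    """Regularized pair-distance distribution from the IFT."""

    r: np.ndarray  # A
    p: np.ndarray  # arbitrary units
    d_max: float
    alpha: float
    background: float
    n_good: float  # effective number of free parameters
    chi2_reduced: float


def _ift_design(q, d_max, n_r):
    dr = d_max / n_r
    r = (np.arange(n_r) + 0.5) * dr
    B = np.sinc(np.outer(q, r) / np.pi)
    # second-difference smoothness operator with implicit zero boundaries
    L = np.zeros((n_r + 2, n_r))
    for j in range(n_r):
        L[j, j] += 1.0
        L[j + 1, j] += -2.0
        L[j + 2, j] += 1.0
    return r, B, L


def _ift_solve(q, I, sigma, d_max, alpha, n_r):
    """Ridge solution of p(r) (+ free constant background) at fixed alpha."""
    r, B, L = _ift_design(q, d_max, n_r)
    w = 1.0 / sigma
    Bw = np.column_stack([B, np.ones_like(q)]) * w[:, None]
    dw = I * w
    P = np.zeros((n_r + 1, n_r + 1))
    P[:n_r, :n_r] = L.T @ L
    P[n_r, n_r] = 1e-12  # near-flat prior on the background
    A = Bw.T @ Bw + alpha * P
    rhs = Bw.T @ dw
    coef = np.linalg.solve(A, rhs)
    p, bkg = coef[:n_r], coef[n_r]
    resid = dw - Bw @ coef
    chi2 = float(resid @ resid)
    smooth = float(p @ (L.T @ L) @ p)
    # Laplace-approximation log evidence (alpha-dependent terms only)
    sign, logdetA = np.linalg.slogdet(A)
    log_ev = -0.5 * chi2 - 0.5 * alpha * smooth + 0.5 * n_r * np.log(alpha) - 0.5 * logdetA
    # effective number of parameters actually determined by the data
    n_good = float(np.trace(np.linalg.solve(A, Bw.T @ Bw)))
    return r, p, float(bkg), chi2, log_ev, n_good


def ift_chi2_floor(
    data: ScatteringCurve,
    d_max_init: float,
    n_r: int = 60,
    alpha_grid=None,
    refine_dmax: bool = True,
):
    """Model-free chi^2_r floor via a Bayesian smoothness-regularized IFT.

    A free-form p(r) on [0, D_max] is fitted to the curve (with a free
    constant background); the regularization weight alpha is chosen by
    maximizing a Laplace-approximation evidence over a log-spaced grid
    (1e-2 ... 1e18, 41 points), and D_max is refined by golden-section
    search around the initial guess. The resulting chi^2_r — computed
    with the effective number of determined parameters removed from the
    degrees of freedom — is the floor any structural model can aim for.

    Returns ``(chi2_reduced_floor, PrCurve)``.
    """
    if data.sigma is None:
        raise ValueError("data must carry uncertainties")
    if d_max_init <= 0:
        raise ValueError("d_max_init must be positive")
    q, I, sigma = data.q, data.I, data.sigma
    if alpha_grid is None:
        alpha_grid = np.logspace(-2, 18, 41)

    def best_at(d_max):
        best = None
        for alpha in alpha_grid:
            out = _ift_solve(q, I, sigma, d_max, alpha, n_r)
            if best is None or out[4] > best[1][4]:
                best = (alpha, out)
        return best

    d_max = float(d_max_init)
    if refine_dmax:
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = 0.5 * d_max_init, 1.5 * d_max_init
        c, d = b - gr * (b - a), a + gr * (b - a)
        fc, fd = best_at(c)[1][4], best_at(d)[1][4]
        for _ in range(20):
            if fc > fd:
                b, d, fd = d, c, fc
                c = b - gr * (b - a)
                fc = best_at(c)[1][4]
            else:
                a, c, fc = c, d, fd
                d = a + gr * (b - a)
                fd = best_at(d)[1][4]
            if abs(b - a) < 1e-3 * d_max_init:
                break
        d_max = 0.5 * (a + b)

    alpha, (r, p, bkg, chi2, _, n_good) = best_at(d_max)
    tail = p[int(0.9 * n_r) :]
    if p.max() > 0 and np.mean(np.abs(tail)) > 0.1 * np.abs(p).max():
        warnings.warn(
            "p(r) piles up at D_max: the assumed maximum dimension is smaller "
            "than the data's resolvable extent"
        )
    dof = max(len(data) - n_good, 1.0)
    chi2r = chi2 / dof
    pr = PrCurve(r, p, d_max, float(alpha), bkg, n_good, chi2r)
    return chi2r, pr
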