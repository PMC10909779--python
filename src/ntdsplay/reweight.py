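"""Bayesian/maximum-entropy (BME) ensemble reweighting against SANS data.

A biased simulation provides prior frame weights w0 (from the final
bias potential, w0_i proportional to exp(+V_bias,i/kT)); BME then finds
posterior weights minimizing

    Q(w) = chi^2_r(w) - theta * S_REL(w),    S_REL = -sum_i w_i ln(w_i/w0_i)

where chi^2_r measures the misfit of the weighted ensemble-average
scattering to the data and S_REL <= 0 penalizes divergence from the
prior. The problem is solved in its convex dual: the optimum has the
Gibbs form w_i proportional to w0_i * exp(-sum_q lambda_q I_i(q)), and
the dual function over lambda is minimized by damped Newton with the
analytic Hessian. The Lagrange-multiplier trade-off theta is chosen
from a scan, at the knee of the chi^2_r vs phi_eff curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .beads import fit_scale_background
from .curves import ScatteringCurve

__all__ = [
    "BiasTrace",
    "BMEResult",
    "ThetaSelection",
    "bias_to_weights",
    "bme_optimize",
    "theta_scan",
    "select_theta",
    "kish_phi_eff",
    "splayed_fraction",
]


@dataclass
class BiasTrace:
    """Per-frame collective variable and bias energy of a biased run.

    cv : NTD distance per frame (nm).
    bias_energy : V_bias per frame (kJ/mol).
    kT : thermal energy (kJ/mol).
    """

    cv: np.ndarray
    bias_energy: np.ndarray
    kT: float

    def __post_init__(self) -> None:
        self.cv = np.asarray(self.cv, dtype=float)
        self.bias_energy = np.asarray(self.bias_energy, dtype=float)
        if self.cv.shape != self.bias_energy.shape:
            raise ValueError("cv and bias_energy must have the same length")


@dataclass
class BMEResult:
    """Posterior weights and fit diagnostics at one value of theta."""

    theta: float
    weights: np.ndarray
    chi2_reduced: float
    S_rel: float  # -sum w ln(w/w0), <= 0, equality iff w = w0
    phi_eff: float  # Kish effective sample fraction exp(S_rel)
    scale: float = 1.0
    background: float = 0.0
    converged: bool = True
    grad_norm: float = 0.0


def bias_to_weights(trace: BiasTrace) -> np.ndarray:
    """Prior frame weights from the final bias: w0_i ~ exp(+V_bias,i/kT).

    Frames that the bias had to push hardest to visit are the ones the
    unbiased ensemble favours; inverting the bias recovers them. The
    exponent is max-shifted before exponentiation for overflow safety,
    which also makes the result invariant to any constant added to V.
    """
    if trace.kT <= 0:
        raise ValueError("kT must be positive")
    v = trace.bias_energy
    if not np.all(np.isfinite(v)):
        raise ValueError("bias energies must be finite")
    x = v / trace.kT
    w = np.exp(x - x.max())
    return w / w.sum()


def _frame_matrix(frame_curves, data: ScatteringCurve) -> np.ndarray:
    frames = list(frame_curves)
    if not frames:
        raise ValueError("no frame curves")
    for f in frames:
        if not data.same_grid(f):
            raise ValueError("frame curves must share the data q grid")
    return np.vstack([f.I for f in frames])


def _solve_dual(A, d, ln_w0, th, nu0, tol, max_iter):
    """Damped-Newton minimization of the convex BME dual.

    Variables are residual-scaled multipliers nu_q = lambda_q*sigma_q;
    with A_iq = I_i(q)/sigma_q and d_q the data/sigma_q,

        G(nu) = th*ln sum_i w0_i exp(-(A nu)_i/th) + nu.d + 0.5*|nu|^2.

    The minimizer gives w_i ~ w0_i exp(-(A nu)_i/th); the gradient
    -w@A + d + nu vanishes exactly when nu equals the weighted-average
    residual, i.e. the Gibbs-form stationarity of Q.
    """
    nu = nu0.copy()
    n_q = d.size

    def value_state(nu):
        expo = ln_w0 - (A @ nu.T if nu.ndim > 1 else A @ nu) / th
        lz = logsumexp(expo)
        w = np.exp(expo - lz)
        g = th * lz + nu @ d + 0.5 * nu @ nu
        return g, w

    g, w = value_state(nu)
    grad = -(w @ A) + d + nu
    gnorm = float(np.linalg.norm(grad, ord=np.inf))
    for _ in range(max_iter):
        if gnorm < tol:
            break
        wa = w @ A
        H = (A.T * w) @ A
        H -= np.outer(wa, wa)
        H /= th
        H[np.diag_indices(n_q)] += 1.0
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = -grad
        # backtracking line search on the convex dual
        t = 1.0
        for _ in range(60):
            g_new, w_new = value_state(nu + t * step)
            if g_new <= g + 1e-4 * t * (grad @ step):
                break
            t *= 0.5
        nu = nu + t * step
        g, w = g_new, w_new
        grad = -(w @ A) + d + nu
        gnorm = float(np.linalg.norm(grad, ord=np.inf))
    return nu, w, gnorm


def bme_optimize(
    frame_curves,
    data: ScatteringCurve,
    w0,
    theta: float,
    scale: float | None = None,
    background: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    max_outer: int = 50,
) -> BMEResult:
    """Minimize Q = chi^2_r - theta*S_REL over the weight simplex.

    The global scale and constant background entering chi^2 are
    profile-refitted (closed-form weighted LSQ against the current
    weighted average) in alternation with the weight update, so every
    chi^2 evaluation sees the best global parameters for its weights;
    pass ``scale``/``background`` to freeze them instead. chi^2_r uses
    n_q - 2 degrees of freedom (scale and background are fitted).

    For fixed global parameters the problem is solved in its convex
    dual (one multiplier per data point, damped Newton, analytic
    Hessian); the optimum has the maximum-entropy Gibbs form
    w_i ~ w0_i exp(-sum_q lambda_q I_i(q)). Non-convergence (gradient
    norm above ``tol`` after ``max_iter`` Newton steps) is reported via
    ``converged``/``grad_norm`` on the result.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if data.sigma is None or np.any(data.sigma <= 0):
        raise ValueError("data must carry strictly positive uncertainties")
    w0 = np.asarray(w0, dtype=float)
    w0 = w0 / w0.sum()
    I = _frame_matrix(frame_curves, data)
    if I.shape[0] != w0.size:
        raise ValueError("one prior weight per frame required")
    n_q = len(data)
    m = n_q - 2
    if m < 1:
        raise ValueError("need more than 2 data points")

    fixed_sb = scale is not None and background is not None
    if not fixed_sb:
        prior_avg = ScatteringCurve(data.q, w0 @ I)
        scale, background, _ = fit_scale_background(prior_avg, data)

    sig = data.sigma
    th = theta * m / 2.0
    ln_w0 = np.log(w0)
    d = data.I / sig
    w = w0.copy()
    nu = np.zeros(n_q)
    gnorm = np.inf
    for _ in range(max_outer):
        A = (scale * I + background) / sig
        nu, w, gnorm = _solve_dual(A, d, ln_w0, th, nu, tol, max_iter)
        if fixed_sb:
            break
        avg = ScatteringCurve(data.q, w @ I)
        new_scale, new_background, _ = fit_scale_background(avg, data)
        if abs(new_scale - scale) <= 1e-12 * max(abs(scale), 1.0) and abs(
            new_background - background
        ) <= 1e-12 * max(abs(background), 1.0):
            scale, background = new_scale, new_background
            break
        scale, background = new_scale, new_background

    avg = scale * (w @ I) + background
    chi2r = float(np.sum(((avg - data.I) / sig) ** 2)) / m
    s_rel = _relative_entropy(w, w0)
    return BMEResult(
        theta=float(theta),
        weights=w / w.sum(),
        chi2_reduced=chi2r,
        S_rel=s_rel,
        phi_eff=float(np.exp(s_rel)),
        scale=float(scale),
        background=float(background),
        converged=gnorm < max(100 * tol, 1e-5),
        grad_norm=float(gnorm),
    )


def _relative_entropy(w, w0) -> float:
    """S_REL = -sum w ln(w/w0) (<= 0; 0 iff w = w0)."""
    w = np.asarray(w, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    pos = w > 0
    if np.any(w0[pos] <= 0):
        raise ValueError("posterior weight on a frame with zero prior weight")
    return float(-np.sum(w[pos] * np.log(w[pos] / w0[pos])))


def theta_scan(frame_curves, data: ScatteringCurve, w0, theta_grid=None, **kw):
    """Run bme_optimize across a theta grid (default 1e-3...1e3, 25 points).

    Results are returned in the order of the grid; chi^2_r is
    non-increasing as theta decreases (the optimizations are nested),
    up to optimizer tolerance.
    """
    if theta_grid is None:
        theta_grid = np.logspace(-3, 3, 25)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ValueError("empty theta grid")
    return [bme_optimize(frame_curves, data, w0, th, **kw) for th in theta_grid]


@dataclass
class ThetaSelection:
    """Outcome of the theta scan: the knee, plus the floor crossing."""

    theta: float  # maximum-curvature (knee) point of chi^2_r vs phi_eff
    result: BMEResult
    theta_at_floor: float | None = None  # largest theta with chi2r <= floor
    result_at_floor: BMEResult | None = None


def select_theta(results, chi2_floor: float | None = None) -> ThetaSelection:
    """Pick theta at the knee of the chi^2_r vs phi_eff trade-off curve.

    The knee is the point of maximum distance from the chord joining the
    endpoints of the (phi_eff, chi^2_r) curve (both axes normalized) —
    past it, further fit improvement costs disproportionate effective
    sample size. When ``chi2_floor`` is supplied (from the IFT), the
    smallest theta whose chi^2_r reaches the floor is also reported.
    """
    results = list(results)
    if not results:
        raise ValueError("no scan results")
    if len(results) == 1:
        sel = ThetaSelection(results[0].theta, results[0])
    else:
        ordered = sorted(results, key=lambda r: r.theta)
        phi = np.array([r.phi_eff for r in ordered])
        chi = np.array([max(r.chi2_reduced, 1e-12) for r in ordered])
        log_chi = np.log(chi)
        span_p = phi.max() - phi.min()
        span_c = log_chi.max() - log_chi.min()
        if span_p < 1e-9 or span_c < 1e-6:
            # flat trade-off: nothing to gain from reweighting; keep the
            # most prior-preserving theta
            k = len(ordered) - 1
        else:
            x = (phi - phi.min()) / span_p
            y = (log_chi - log_chi.min()) / span_c
            v = np.array([x[-1] - x[0], y[-1] - y[0]])
            nv = np.linalg.norm(v) or 1.0
            dist = np.abs(v[0] * (y - y[0]) - v[1] * (x - x[0])) / nv
            k = int(np.argmax(dist))
        sel = ThetaSelection(ordered[k].theta, ordered[k])
    if chi2_floor is not None:
        ok = [r for r in results if r.chi2_reduced <= chi2_floor]
        if ok:
            # least perturbation that reaches the floor: the largest such
            # theta (chi^2_r is monotone along the scan)
            best = max(ok, key=lambda r: r.theta)
            sel.theta_at_floor = best.theta
            sel.result_at_floor = best
    return sel


def kish_phi_eff(weights, w0) -> float:
    """Kish effective sample fraction phi_eff = exp(S_REL), in (0, 1]."""
    return float(np.exp(_relative_entropy(weights, w0)))


def splayed_fraction(ensemble_or_cv, weights, cv_cutoff: float) -> float:
    """Total posterior weight of frames with CV (NTD distance, nm) > cutoff."""
    cv = getattr(ensemble_or_cv, "cv", ensemble_or_cv)
    cv = np.asarray(cv, dtype=float)
    w = np.asarray(weights, dtype=float)
    if cv.shape != w.shape:
        raise ValueError("weights and CV must have the same length")
    return float(w[cv > cv_cutoff].sum())
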