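"""Seeded 1-D Metropolis sampler shared by the synthetic-data generators.

Chains are run in parallel across "walkers" (one per umbrella window,
or a single walker for an unbiased ensemble). The proposal step is
auto-tuned during burn-in toward a 30-50% acceptance rate; the first
10% of the requested samples are always discarded as burn-in, so the
retained samples satisfy detailed balance for the final step size.
Samples along one chain are correlated (no thinning is applied); the
downstream estimators assume this only inflates variance, not bias.
"""

from __future__ import annotations

import numpy as np

__all__ = ["metropolis"]


def metropolis(
    potential,
    x0,
    n_samples: int,
    kT: float,
    rng: np.random.Generator,
    step: float = 0.1,
    burn_frac: float = 0.1,
    tune: bool = True,
    thin: int = 1,
):
    """Sample x ~ exp(-potential(x)/kT) with a Gaussian random walk.

    Parameters
    ----------
    potential : callable
        Vectorized energy function (same units as kT).
    x0 : float or (m,) array
        Start point(s); one chain per entry.
    n_samples : int
        Retained samples per chain (after burn-in).
    kT : float
        Thermal energy.
    rng : numpy Generator
        Source of all randomness.
    step : float
        Initial proposal standard deviation.
    burn_frac : float
        Burn-in fraction, discarded; step tuning happens only here.
    tune : bool
        Auto-tune the step toward 30-50% acceptance during burn-in.
    thin : int
        Keep every ``thin``-th post-burn-in step (reduces serial
        correlation at proportional cost).

    Returns
    -------
    samples : (n_samples,) or (n_samples, m) array
    acceptance_rate : float or (m,) array (post-burn-in)
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if kT <= 0:
        raise ValueError("kT must be positive")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    scalar_chain = np.ndim(x0) == 0
    m = x.size
    n_keep_steps = n_samples * thin
    n_burn = max(int(np.ceil(burn_frac * n_keep_steps)), 10 if tune else 0)
    n_total = n_burn + n_keep_steps

    u = potential(x)
    if not np.all(np.isfinite(u)):
        raise ValueError("potential is not finite at the start point")
    steps = np.full(m, float(step))
    samples = np.empty((n_samples, m))
    accepted = np.zeros(m)
    tune_acc = np.zeros(m)
    tune_count = 0

    for i in range(n_total):
        prop = x + steps * rng.standard_normal(m)
        u_prop = potential(prop)
        du = u_prop - u
        ok = np.isfinite(u_prop) & (
            (du <= 0) | (rng.random(m) < np.exp(-np.clip(du / kT, 0, 700)))
        )
        x = np.where(ok, prop, x)
        u = np.where(ok, u_prop, u)
        if i < n_burn:
            if tune:
                tune_acc += ok
                tune_count += 1
                if tune_count == 50:  # adapt every 50 burn-in steps
                    rate = tune_acc / tune_count
                    steps = np.where(rate > 0.5, steps * 1.5, steps)
                    steps = np.where(rate < 0.3, steps * 0.6, steps)
                    tune_acc[:] = 0.0
                    tune_count = 0
        else:
            j = i - n_burn
            if j % thin == thin - 1:
                samples[j // thin] = x
            accepted += ok

    acc = accepted / n_keep_steps
    if scalar_chain:
        return samples[:, 0], float(acc[0])
    return samples, acc
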