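"""Small-angle scattering curves and their plain-text serialization.

A :class:`ScatteringCurve` is the package's exchange format between the
forward model, the aggregate-subtraction step, and the ensemble
reweighting: a momentum-transfer grid ``q`` (1/Angstrom), intensities
``I`` (arbitrary units), and optionally one standard error per point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScatteringCurve", "read_dat", "write_dat"]


@dataclass
class ScatteringCurve:
    """A measured or computed small-angle scattering profile.

    Parameters
    ----------
    q : array of float
        Momentum transfer, 1/Angstrom, strictly increasing. ``q = 0`` is
        permitted only as the first point of a *computed* curve (the
        forward-scattering anchor); measured curves start at q > 0.
    I : array of float
        Scattering intensity, arbitrary units.
    sigma : array of float, optional
        Standard error of I, same units; required by every fitting step.
    label : str, optional
        Free-form tag carried through the pipeline.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.I.shape != self.q.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if self.q.size and np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.q.size and self.q[0] < 0:
            raise ValueError("q must be non-negative")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return self.q.size

    def same_grid(self, other: "ScatteringCurve", rtol: float = 1e-9) -> bool:
        return self.q.shape == other.q.shape and np.allclose(
            self.q, other.q, rtol=rtol, atol=0.0
        )

    def copy(self) -> "ScatteringCurve":
        return ScatteringCurve(
            self.q.copy(),
            self.I.copy(),
            None if self.sigma is None else self.sigma.copy(),
            self.label,
        )


def read_dat(path) -> ScatteringCurve:
    """Read a 3-column whitespace ``.dat`` curve (``#`` comment lines)."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (q, I)")
    sigma = arr[:, 2] if arr.shape[1] >= 3 else None
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma, label=str(path))


def write_dat(path, curve: ScatteringCurve, header: str = "") -> None:
    """Write a curve as whitespace columns q[1/A] I sigma with # header."""
    cols = [curve.q, curve.I]
    names = "q[1/A] I"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        names += " sigma"
    head = (header + "\n" if header else "") + names
    np.savetxt(path, np.column_stack(cols), header=head)
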