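"""Smooth-component building blocks: cubic B-spline age basis and the
constrained second-order random-walk (RW2) time structure.

Both the synthetic generator and the fitted model share these structures so
that the generator produces exactly the surfaces the model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = ["build_age_basis", "center_basis", "Rw2Structure", "build_rw2"]


def build_age_basis(ages: np.ndarray, knots: "list[float] | np.ndarray",
                    degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix over an age grid.

    Boundary knots are clamped at the grid edges so the basis is a partition
    of unity: every row sums to exactly 1.  ``knots`` are the interior knots
    and must lie strictly inside the age domain (an empty list yields a plain
    cubic polynomial basis).

    Returns an ``(len(ages), len(knots) + degree + 1)`` matrix.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    knots = np.asarray(sorted(knots), dtype=float)
    lo, hi = float(ages.min()), float(ages.max())
    if lo == hi:
        # Degenerate single-age domain: widen infinitesimally so the spline
        # machinery is well posed; the basis still sums to 1.
        hi = lo + 1e-6
    if knots.size and (knots.min() <= lo or knots.max() >= hi):
        raise ValueError(
            f"interior knots {knots.tolist()} must lie strictly inside ({lo}, {hi})"
        )
    t = np.concatenate([
        np.repeat(lo, degree + 1), knots, np.repeat(hi, degree + 1)
    ])
    k = len(knots) + degree + 1
    basis = BSpline.design_matrix(
        np.clip(ages, lo, hi), t, degree, extrapolate=False
    ).toarray()
    assert basis.shape == (len(ages), k)
    return basis


def center_basis(basis: np.ndarray) -> np.ndarray:
    """Remove the grid-mean of each column so the spline curve has zero mean
    over the evaluation grid (the model's intercept carries the level)."""
    return basis - basis.mean(axis=0, keepdims=True)


@dataclass(frozen=True)
class Rw2Structure:
    """Constrained RW2 over ``n_times`` grid points.

    The non-linear trend is ``u = Z @ w`` where the columns of ``Z`` span the
    orthogonal complement of {constant, linear} — so any ``u`` is orthogonal
    to the intercept and slope by construction (identifiability).  The RW2
    smoothness prior on ``u`` induces ``w ~ N(0, sigma^2 * M^{-1})`` with
    ``M = Z' D'D Z`` and ``D`` the second-difference operator.
    """

    z: np.ndarray            # (n_times, n_times - 2), orthonormal columns
    penalty: np.ndarray      # M, (n_times-2, n_times-2), positive definite
    chol_penalty: np.ndarray  # upper Cholesky factor R with R'R = M

    @property
    def n_times(self) -> int:
        return self.z.shape[0]

    @property
    def dim(self) -> int:
        return self.z.shape[1]

    def sample_w(self, scale: float, rng: np.random.Generator) -> np.ndarray:
        """Draw w with marginal u = Z w having RW2 innovation scale ``scale``."""
        if scale == 0:
            return np.zeros(self.dim)
        from scipy.linalg import solve_triangular
        zvec = rng.standard_normal(self.dim)
        return scale * solve_triangular(self.chol_penalty, zvec, lower=False)

    def curve(self, w: np.ndarray) -> np.ndarray:
        return self.z @ w


def build_rw2(n_times: int) -> Rw2Structure:
    """Build the constrained RW2 structure for a grid of ``n_times`` points.

    Requires at least 3 points (second differences are undefined otherwise).
    """
    if n_times < 3:
        raise ValueError(f"RW2 needs >= 3 time points, got {n_times}")
    t = np.arange(n_times, dtype=float)
    t = (t - t.mean()) / (t.std() if n_times > 1 else 1.0)
    constraints = np.vstack([np.ones(n_times), t])
    z = null_space(constraints)  # (n_times, n_times-2), orthonormal
    d = np.zeros((n_times - 2, n_times))
    for i in range(n_times - 2):
        d[i, i:i + 3] = (1.0, -2.0, 1.0)
    m = z.T @ (d.T @ d) @ z
    m = 0.5 * (m + m.T)
    r = np.linalg.cholesky(m).T
    return Rw2Structure(z=z, penalty=m, chol_penalty=r)
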