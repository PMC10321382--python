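"""Cubic regression spline basis with a second-derivative penalty.

The basis is parameterized by the function values at the knots: the m basis
functions are the natural-cubic-spline cardinal functions, so evaluating the
basis at the knots gives the identity matrix, and the penalty is the exact
integrated squared second derivative of the interpolating spline.  This is
the standard "cr" construction used by penalized-GAM software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CRSplineBasis", "build_crs_basis", "sum_to_zero_constraint"]


@dataclass(frozen=True)
class CRSplineBasis:
    """Cubic regression spline basis on a fixed knot sequence.

    Attributes
    ----------
    knots : ndarray, shape (m,)
        Strictly increasing knot locations.
    penalty : ndarray, shape (m, m)
        Symmetric PSD penalty matrix (integrated squared second
        derivative); its null space is spanned by linear functions.
    """

    knots: np.ndarray
    penalty: np.ndarray
    _F: np.ndarray = field(repr=False)  # maps knot values -> knot 2nd derivs

    @property
    def dim(self) -> int:
        return len(self.knots)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the m basis functions at points ``x``.

        Points outside the knot range are extended linearly (the natural
        spline has zero second derivative beyond the boundary knots).

        Returns
        -------
        ndarray, shape (len(x), m)
        """
        x = np.asarray(x, dtype=float).ravel()
        k = self.knots
        m = len(k)
        # clamp to the boundary, remember offsets for linear extension
        below = x < k[0]
        above = x > k[-1]
        xc = np.clip(x, k[0], k[-1])
        j = np.clip(np.searchsorted(k, xc, side="right") - 1, 0, m - 2)
        h = k[j + 1] - k[j]
        dl = k[j + 1] - xc
        dr = xc - k[j]
        a_minus = dl / h
        a_plus = dr / h
        c_minus = (dl**3 / h - h * dl) / 6.0
        c_plus = (dr**3 / h - h * dr) / 6.0
        X = np.zeros((len(x), m))
        rows = np.arange(len(x))
        np.add.at(X, (rows, j), a_minus)
        np.add.at(X, (rows, j + 1), a_plus)
        X += c_minus[:, None] * self._F[j, :]
        X += c_plus[:, None] * self._F[j + 1, :]
        if below.any() or above.any():
            eps = 1e-6 * (k[-1] - k[0])
            for mask, x0 in ((below, k[0]), (above, k[-1])):
                if mask.any():
                    b0 = self.evaluate(np.array([x0]))
                    b1 = self.evaluate(np.array([x0 + (eps if x0 == k[0] else -eps)]))
                    slope = (b1 - b0) / (eps if x0 == k[0] else -eps)
                    X[mask, :] = b0 + (x[mask, None] - x0) * slope
        return X


def build_crs_basis(times: np.ndarray, dim: int) -> CRSplineBasis:
    """Build a cubic regression spline basis with knots at quantiles.

    Parameters
    ----------
    times : array-like
        Observed time values; knots are placed at the quantiles of the
        distinct values so every inter-knot interval carries data.
    dim : int
        Basis dimension (number of knots), at least 3.

    Raises
    ------
    ValueError
        If ``dim < 3`` or there are fewer than ``dim`` distinct times.
    """
    if dim < 3:
        raise ValueError(f"basis dimension must be >= 3; got {dim}")
    uniq = np.unique(np.asarray(times, dtype=float))
    if len(uniq) < dim:
        raise ValueError(
            f"need at least {dim} distinct time values, found {len(uniq)}"
        )
    probs = np.linspace(0.0, 1.0, dim)
    knots = np.quantile(uniq, probs)
    knots = np.unique(knots)
    if len(knots) < dim:  # heavy ties in the quantiles: fall back to spread
        knots = np.linspace(uniq[0], uniq[-1], dim)
    return crs_from_knots(knots)


def crs_from_knots(knots: np.ndarray) -> CRSplineBasis:
    """Construct the basis and penalty for given strictly increasing knots."""
    k = np.asarray(knots, dtype=float)
    m = len(k)
    if m < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(k) <= 0):
        raise ValueError("knots must be strictly increasing")
    h = np.diff(k)  # length m-1
    # Banded system for natural-spline second derivatives: B delta = D beta
    D = np.zeros((m - 2, m))
    B = np.zeros((m - 2, m - 2))
    for i in range(m - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < m - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    Binv_D = np.linalg.solve(B, D)
    F = np.zeros((m, m))
    F[1:-1, :] = Binv_D  # second derivative is zero at the boundary knots
    S = D.T @ Binv_D
    S = (S + S.T) / 2.0
    return CRSplineBasis(knots=k, penalty=S, _F=F)


def sum_to_zero_constraint(X: np.ndarray) -> np.ndarray:
    """Orthonormal null-space basis of the column-sum constraint ``1'X q = 0``.

    Returns Q of shape (m, m-1); reparameterizing by ``X @ Q`` makes the
    smooth orthogonal to the intercept over the observed rows, which
    identifies a separate constant term in the model.
    """
    c = X.sum(axis=0)[:, None]  # (m, 1)
    q, _ = np.linalg.qr(c, mode="complete")
    return q[:, 1:]
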