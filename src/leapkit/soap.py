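"""SOAP power-spectrum vectors for local neighbor environments.

The Smooth Overlap of Atomic Positions representation expands a Gaussian
neighbor density around each center in an orthonormal radial basis times
spherical harmonics, and contracts the expansion coefficients over the
magnetic index m into the rotationally invariant power spectrum

    p(n, n', l) = sum_m c_{nlm} conj(c_{n'lm}),  n <= n'.

The radial basis is the polynomial set phi_alpha(r) = (rcut - r)^(alpha+2),
alpha = 1..n_max, orthonormalized with the analytic overlap integral.  The
coefficient integrals use the closed-form angular part of a Gaussian placed
at distance r_j (an exponentially scaled modified spherical Bessel function,
so no overflow at small sigma) and Gauss–Legendre quadrature radially.

Only the neighbor density is expanded — the center itself contributes no
density, so a center with zero neighbors has an exactly zero (flagged)
vector.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.linalg import eigh
from scipy.special import ive, sph_harm_y

__all__ = ["SoapCalculator"]

_N_QUAD = 96


@lru_cache(maxsize=32)
def _radial_basis(n_max: int, rcut: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quadrature nodes/weights and orthonormal radial basis on the nodes.

    Returns ``(r_nodes, weights, G)`` with ``G[n, q] = g_n(r_q)`` and the
    weights already including the ``r^2`` volume element.
    """
    x, w = np.polynomial.legendre.leggauss(_N_QUAD)
    r = 0.5 * rcut * (x + 1.0)
    w = 0.5 * rcut * w * r**2
    alphas = np.arange(1, n_max + 1)
    # overlap S_ab = ∫_0^rcut (rcut-r)^(a+b+4) r^2 dr, exact
    p = alphas[:, None] + alphas[None, :] + 4
    S = rcut ** (p + 3.0) * 2.0 / ((p + 1.0) * (p + 2.0) * (p + 3.0))
    vals, vecs = eigh(S)
    W = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T  # S^{-1/2}
    phi = (rcut - r)[None, :] ** (alphas[:, None] + 2)
    return r, w, W @ phi


class SoapCalculator:
    """Computes L2-normalizable SOAP power-spectrum vectors.

    Parameters
    ----------
    rcut : float
        Environment cutoff radius.
    n_max, l_max : int
        Number of radial channels and maximum angular momentum.
    sigma : float, optional
        Gaussian width of the neighbor density; defaults to ``rcut / 8``.
    cutoff_width : float, optional
        Width of the smooth cosine taper at the edge of the sphere
        (default ``rcut / 4``).  Each neighbor's density is weighted by a
        cutoff function that decays continuously to zero at ``rcut``, so a
        neighbor drifting across the boundary enters and leaves the
        environment smoothly instead of discontinuously.
    """

    def __init__(self, rcut: float, n_max: int = 8, l_max: int = 8,
                 sigma: float | None = None, cutoff_width: float | None = None):
        if not rcut > 0:
            raise ValueError("rcut must be positive")
        if n_max < 1 or l_max < 0:
            raise ValueError("n_max >= 1 and l_max >= 0 required")
        self.rcut = float(rcut)
        self.n_max = int(n_max)
        self.l_max = int(l_max)
        self.sigma = float(sigma) if sigma is not None else self.rcut / 8.0
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        self.cutoff_width = (float(cutoff_width) if cutoff_width is not None
                             else self.rcut / 4.0)
        if not 0 < self.cutoff_width <= self.rcut:
            raise ValueError("cutoff_width must lie in (0, rcut]")
        self._r, self._w, self._G = _radial_basis(self.n_max, self.rcut)

    def _fcut(self, r: np.ndarray) -> np.ndarray:
        inner = self.rcut - self.cutoff_width
        w = 0.5 * (1.0 + np.cos(np.pi * (r - inner) / self.cutoff_width))
        return np.where(r <= inner, 1.0, np.where(r >= self.rcut, 0.0, w))

    @property
    def n_features(self) -> int:
        return (self.l_max + 1) * self.n_max * (self.n_max + 1) // 2

    def power_spectrum(self, rel_positions: np.ndarray) -> np.ndarray:
        """Power spectrum of the neighbor density at one center.

        ``rel_positions`` are neighbor coordinates relative to the center,
        shape ``(n_neighbors, 3)``.  Returns the un-normalized feature
        vector; all-zero when there are no neighbors.
        """
        rel = np.atleast_2d(np.asarray(rel_positions, dtype=float))
        return self.batch_power_spectra(rel, np.array([rel.shape[0]]))[0]

    def batch_power_spectra(self, rel: np.ndarray, counts: np.ndarray) -> np.ndarray:
        """Power spectra for many centers at once.

        ``rel`` stacks the center-relative neighbor coordinates of all
        centers, shape ``(sum(counts), 3)``; ``counts[c]`` neighbors belong
        to center ``c``.  The expensive transcendental evaluations are
        shared across centers.  Returns ``(len(counts), n_features)``;
        centers with zero neighbors get all-zero rows.
        """
        counts = np.asarray(counts, dtype=int)
        out = np.zeros((len(counts), self.n_features))
        rel = np.asarray(rel, dtype=float)
        if rel.shape[0] == 0:
            return out
        rj = np.clip(np.linalg.norm(rel, axis=1), 1e-12, None)
        theta = np.arccos(np.clip(rel[:, 2] / rj, -1.0, 1.0))
        phi = np.arctan2(rel[:, 1], rel[:, 0])
        s2 = self.sigma**2
        r, w, G = self._r, self._w, self._G
        x = np.clip(r[:, None] * rj[None, :] / s2, 1e-12, None)  # (nq, N)
        # 4π e^{-(r²+rj²)/2σ²} i_l(x) with i_l via scaled Bessel: no overflow
        log_env = x - (r[:, None] ** 2 + rj[None, :] ** 2) / (2.0 * s2)
        env = 4.0 * np.pi * np.sqrt(np.pi / (2.0 * x)) * np.exp(log_env)
        env *= self._fcut(rj)[None, :]
        Gw = G * w
        bounds = np.concatenate([[0], np.cumsum(counts)])
        iu = np.triu_indices(self.n_max)
        pos = 0
        for l in range(self.l_max + 1):
            I = Gw @ (env * ive(l + 0.5, x))  # (n_max, N)
            ms = np.arange(-l, l + 1)
            Yc = np.conjugate(
                sph_harm_y(l, ms[:, None], theta[None, :], phi[None, :])
            )  # (2l+1, N)
            pref = np.pi * np.sqrt(8.0 / (2.0 * l + 1.0))
            width = len(iu[0])
            for c in range(len(counts)):
                lo, hi = bounds[c], bounds[c + 1]
                if lo == hi:
                    continue
                cc = I[:, lo:hi] @ Yc[:, lo:hi].T  # (n_max, 2l+1)
                P = np.real(cc @ np.conjugate(cc).T)
                out[c, pos:pos + width] = pref * P[iu]
            pos += width
        return out
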