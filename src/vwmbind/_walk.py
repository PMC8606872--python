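"""Direction densities of spike-count population decodes.

The ML decode of a conjunctive population code with product von Mises tuning
reduces, per feature dimension, to the direction of the resultant vector of
the spikes' preferred values (see :mod:`vwmbind.popmodel`).  Conditional on a
spike count ``k``, each spike's preferred value is (to lattice-quadrature
accuracy) an independent von Mises draw centered on the encoded feature.  The
decoded direction is therefore distributed as the direction of a ``k``-step
von Mises random walk.

Because the von Mises density is an exponential tilt of the uniform one, the
resultant vector of ``k`` von Mises(0, kappa) unit steps has density

    p(r, theta)  proportional to  exp(kappa * r * cos(theta)) * w_k(r)

where ``w_k`` is the radial density of the classical *uniform* (Pearson)
random walk with ``k`` unit steps — a fixed, kappa-independent family.  This
module computes ``w_k`` once by an exact distributional recursion (adding one
uniform unit step at a time, k = 2 analytic) and caches it; direction
densities for any kappa then follow by a radial quadrature with the
exponential tilt, carried out in log space.

For large ``k`` (> ``K_EXACT``) the direction density is replaced by its
asymptotic limit: the decoded direction is the MLE of the mean direction of
``k`` von Mises observations, with Fisher information ``k * kappa * A(kappa)``
per sample (``A = I1/I0``), i.e. a von Mises law with that concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e, i1e, logsumexp

K_EXACT = 80  # exact Pearson-walk tables up to this step count
_NGRID = 512  # radial resolution of the recursion
_NODES = 128  # condensed radial nodes used in the tilted quadrature

# caches: step count k -> radial representation
_full: dict[int, np.ndarray] = {}  # masses on linspace(0, k, _NGRID+1) cells
_condensed: dict[int, tuple[np.ndarray, np.ndarray]] = {}  # (nodes, masses)


def bessel_ratio(kappa: float) -> float:
    """A(kappa) = I1(kappa) / I0(kappa), the mean resultant of a von Mises."""
    return float(i1e(kappa) / i0e(kappa))


def _uniform_step_cdf(r: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(|rho*e_x + unit uniform step| <= r), shape (len(r), len(rho))."""
    r = r[:, None]
    rho = rho[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (r**2 - rho**2 - 1.0) / (2.0 * rho)
    x = np.clip(np.where(np.isfinite(x), x, -1.0), -1.0, 1.0)
    return 1.0 - np.arccos(x) / np.pi


def _ensure_exact(k: int) -> None:
    """Fill the exact-mass cache for step counts up to k (k >= 2)."""
    if k in _full:
        return
    if 2 not in _full:
        edges = np.linspace(0.0, 2.0, _NGRID + 1)
        # two unit steps: |resultant| = 2|cos(phi/2)|, CDF analytic
        cdf = 1.0 - np.arccos(np.clip((edges**2 - 2.0) / 2.0, -1.0, 1.0)) / np.pi
        _full[2] = np.diff(cdf)
    kk = max(_full)
    while kk < k:
        edges_prev = np.linspace(0.0, float(kk), _NGRID + 1)
        rho = 0.5 * (edges_prev[:-1] + edges_prev[1:])
        m = _full[kk]
        edges = np.linspace(0.0, float(kk + 1), _NGRID + 1)
        cdf = _uniform_step_cdf(edges, rho) @ m
        _full[kk + 1] = np.maximum(np.diff(cdf), 0.0)
        kk += 1


def radial_masses(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Radial node positions and probability masses of the k-step walk.

    Valid for 2 <= k <= K_EXACT; the condensed representation has ``_NODES``
    nodes at mass-weighted positions.  Satisfies sum(m) = 1 and
    sum(m * rho^2) = k (the exact second moment of a uniform walk).
    """
    if not 2 <= k <= K_EXACT:
        raise ValueError(f"radial_masses: k={k} outside [2, {K_EXACT}]")
    if k not in _condensed:
        _ensure_exact(k)
        m = _full[k]
        edges = np.linspace(0.0, float(k), _NGRID + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        group = _NGRID // _NODES
        mg = m.reshape(_NODES, group)
        mass = mg.sum(axis=1)
        with np.errstate(invalid="ignore"):
            nodes = (mg * mid.reshape(_NODES, group)).sum(axis=1) / mass
        nodes = np.where(mass > 0, nodes, mid.reshape(_NODES, group).mean(axis=1))
        _condensed[k] = (nodes, mass / mass.sum())
    return _condensed[k]


@dataclass
class DirectionTables:
    """Tabulated decode-direction densities, one row per spike count.

    ``theta`` is a uniform closed grid over [-pi, pi] (first and last point
    identical by periodicity); ``pdf``/``cdf`` have shape (len(ks), len(theta)).
    Row ``i`` is the density of the decoded direction (relative to the encoded
    feature value) given ``ks[i]`` spikes; ``ks[i] == 0`` is the uniform
    guessing row.
    """

    kappa: float
    ks: np.ndarray
    theta: np.ndarray
    pdf: np.ndarray
    cdf: np.ndarray

    @property
    def h(self) -> float:
        return float(self.theta[1] - self.theta[0])

    def _locate(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # x must lie in [-pi, pi); returns (index, fraction) on the grid
        t = (x + np.pi) / self.h
        idx = np.clip(t.astype(int), 0, len(self.theta) - 2)
        return idx, t - idx

    def pdf_rows_at(self, x: np.ndarray) -> np.ndarray:
        """Evaluate every spike-count row at angles x; shape (nk,) + x.shape."""
        idx, frac = self._locate(x)
        return self.pdf[:, idx] * (1.0 - frac) + self.pdf[:, idx + 1] * frac

    def locate_ext(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Periodic-extension lookup: (winding, grid index, fraction)."""
        winding = np.floor((y + np.pi) / (2.0 * np.pi))
        x = np.clip(y - winding * 2.0 * np.pi, -np.pi, np.pi - 1e-12)
        idx, frac = self._locate(x)
        return winding, idx, frac

    def cdf_rows_ext(self, y: np.ndarray) -> np.ndarray:
        """Periodically extended CDF at arbitrary y; shape (nk,) + y.shape."""
        winding, idx, frac = self.locate_ext(y)
        vals = self.cdf[:, idx] * (1.0 - frac) + self.cdf[:, idx + 1] * frac
        return vals + winding


def direction_tables(kappa: float, ks, half_points: int = 257) -> DirectionTables:
    """Decode-direction pdf/cdf tables for the given spike counts.

    Parameters
    ----------
    kappa
        Tuning concentration of the feature dimension (> 0).
    ks
        Iterable of spike counts (nonnegative ints, typically the support of
        the per-item Poisson count distribution).
    half_points
        Grid points on [0, pi]; the full circle uses ``2*half_points - 1``.
    """
    if kappa <= 0:
        raise ValueError("direction_tables: kappa must be positive")
    ks = np.asarray(sorted(set(int(k) for k in ks)), int)
    if np.any(ks < 0):
        raise ValueError("direction_tables: negative spike count")
    th_half = np.linspace(0.0, np.pi, half_points)
    cos_half = np.cos(th_half)
    logpdf_half = np.empty((len(ks), half_points))
    A = bessel_ratio(kappa)
    exact = [i for i, k in enumerate(ks) if 2 <= k <= K_EXACT]
    if exact:
        nodes = np.stack([radial_masses(int(ks[i]))[0] for i in exact])
        mass = np.stack([radial_masses(int(ks[i]))[1] for i in exact])
        expo = kappa * nodes[:, :, None] * cos_half[None, None, :]
        logpdf_half[exact] = logsumexp(expo, axis=1, b=mass[:, :, None])
    for i, k in enumerate(ks):
        if k == 0:
            logpdf_half[i] = -np.log(2.0 * np.pi)
        elif k == 1:
            logpdf_half[i] = (
                kappa * cos_half - np.log(2.0 * np.pi) - np.log(i0e(kappa)) - kappa
            )
        elif k > K_EXACT:  # asymptotic von Mises, matched Fisher information
            kk = k * kappa * A
            logpdf_half[i] = (
                kk * cos_half - np.log(2.0 * np.pi) - np.log(i0e(kk)) - kk
            )
    # mirror to the full circle [-pi, pi] and normalize by trapezoid rule
    logpdf = np.concatenate([logpdf_half[:, :0:-1], logpdf_half], axis=1)
    theta = np.concatenate([-th_half[:0:-1], th_half])
    logpdf -= logpdf.max(axis=1, keepdims=True)
    pdf = np.exp(logpdf)
    h = theta[1] - theta[0]
    norm = np.trapezoid(pdf, dx=h, axis=1)
    pdf /= norm[:, None]
    inc = 0.5 * h * (pdf[:, :-1] + pdf[:, 1:])
    cdf = np.concatenate([np.zeros((len(ks), 1)), np.cumsum(inc, axis=1)], axis=1)
    cdf /= cdf[:, -1:]
    return DirectionTables(kappa=float(kappa), ks=ks, theta=theta, pdf=pdf, cdf=cdf)
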