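"""Neural population binding model for cued recall from multi-item arrays.

Each pair of bound feature dimensions (e.g. color x location) is represented
by an idealized conjunctive population code: a lattice of ``M`` neurons with
preferred value pairs covering the 2-torus, product von Mises tuning with
per-dimension concentrations, and a global expected spike budget ``gamma``
shared equally by the ``N`` array items.  Spiking is independent Poisson;
recall decodes every item's feature pair by maximum likelihood from its
spikes, selects the item whose decoded cue feature is closest to the
presented cue, and reports that item's decoded report feature.

Three binding architectures are distinguished by which conjunctive
populations exist and how retrieval chains through them:

``spatial``
    separate color x location and orientation x location populations; every
    nonspatial feature is bound to the others only via shared location.
``via_color`` / ``via_orientation``
    a direct color x orientation population exists, and one reported feature
    is retrieved using the other (or the cue) as an intermediary.

For a product-von-Mises code the spike log-likelihood separates by dimension
and the ML decode is the circular mean of the spiking neurons' preferred
values; the decoded direction given ``k`` spikes is therefore the direction
of a ``k``-step von Mises random walk (see :mod:`vwmbind._walk`).  The
response likelihood is computed from these exact conditional laws by mixing
over the Poisson spike-count distribution and the item-selection event — a
deterministic quadrature rather than a Monte Carlo estimate, which makes
fits reproducible and fast.  Chained architectures condition the second
retrieval stage on the observed intermediary report, which the model treats
as identical to the decoded intermediary value.

All model variants have four free parameters: ``gamma`` and one tuning
concentration per feature dimension, shared across the conjunctive
populations of the variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._walk import DirectionTables, bessel_ratio, direction_tables
from .circstats import wrap
from .dataset import Dataset

logger = logging.getLogger(__name__)

VARIANTS = ("spatial", "via_color", "via_orientation")

__all__ = [
    "VARIANTS",
    "PopulationParams",
    "PopulationGrid",
    "PopFitResult",
    "retrieval_plan",
    "mean_rates",
    "sample_spikes",
    "ml_decode_item",
    "simulate_reports",
    "simulate_report",
    "conditional_density",
    "response_log_likelihood",
    "decoding_sd",
    "fit_popmodel",
    "compare_variants",
    "PopulationBindingModel",
]


# ---------------------------------------------------------------------------
# parameters and grid
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PopulationParams:
    """Global spike budget and per-dimension tuning concentrations.

    ``gamma`` is the expected total spike count of a population per retrieval
    episode (the decoding interval is fixed at 1, so rate and count
    coincide); it is shared equally by the N encoded items.
    """

    gamma: float
    kappa_loc: float
    kappa_col: float
    kappa_ori: float

    def __post_init__(self):
        for name in ("gamma", "kappa_loc", "kappa_col", "kappa_ori"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"PopulationParams.{name} must be positive")

    def kappa(self, dim: str) -> float:
        return {
            "location": self.kappa_loc,
            "color": self.kappa_col,
            "orientation": self.kappa_ori,
        }[dim]

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.gamma, self.kappa_loc, self.kappa_col, self.kappa_ori]
        )


@dataclass(frozen=True)
class PopulationGrid:
    """Square lattice of preferred value pairs over the 2-torus."""

    m_side: int = 32

    def __post_init__(self):
        if self.m_side < 2:
            raise ValueError("m_side must be >= 2")

    @property
    def M(self) -> int:
        return self.m_side**2

    @property
    def axis(self) -> np.ndarray:
        return -np.pi + 2.0 * np.pi * np.arange(self.m_side) / self.m_side

    def preferred(self) -> tuple[np.ndarray, np.ndarray]:
        """Preferred (psi', theta') of all M neurons, each shape (M,)."""
        a = self.axis
        P, T = np.meshgrid(a, a, indexing="ij")
        return P.ravel(), T.ravel()


DEFAULT_GRID = PopulationGrid(32)


# ---------------------------------------------------------------------------
# retrieval plans
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Stage:
    """One retrieval step through a conjunctive population.

    ``cue_dim``/``report_dim`` name the population (cue side first).
    ``cue_stage`` is None for the external cue, or the index of the earlier
    stage whose decoded output acts as intermediary cue.  ``slot`` is the
    index in the dataset's report order that this stage's output fills.
    """

    cue_dim: str
    report_dim: str
    cue_stage: int | None
    slot: int


def retrieval_plan(
    variant: str, cue_dim: str, report_dims: tuple[str, str]
) -> list[Stage]:
    """Stages, in generation order, for a binding variant and task."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown binding variant {variant!r}")
    key = (cue_dim, tuple(report_dims))
    plans = {
        ("location", ("color", "orientation")): {
            "spatial": [
                Stage("location", "color", None, 0),
                Stage("location", "orientation", None, 1),
            ],
            "via_color": [
                Stage("location", "color", None, 0),
                Stage("color", "orientation", 0, 1),
            ],
            "via_orientation": [
                Stage("location", "orientation", None, 1),
                Stage("orientation", "color", 0, 0),
            ],
        },
        ("orientation", ("color", "location")): {
            "spatial": [
                Stage("orientation", "location", None, 1),
                Stage("location", "color", 0, 0),
            ],
            "via_color": [
                Stage("orientation", "color", None, 0),
                Stage("color", "location", 0, 1),
            ],
            "via_orientation": [
                Stage("orientation", "color", None, 0),
                Stage("orientation", "location", None, 1),
            ],
        },
    }
    if key not in plans:
        raise ValueError(
            f"no retrieval plan for cue {cue_dim!r} with reports {report_dims!r}"
        )
    return plans[key][variant]


# ---------------------------------------------------------------------------
# encoding, spiking, decoding (lattice level)
# ---------------------------------------------------------------------------
def _lattice_probs(value: float, kappa: float, axis: np.ndarray) -> np.ndarray:
    w = np.exp(kappa * (np.cos(axis - value) - 1.0))
    return w / w.sum()


def mean_rates(
    item: tuple[float, float],
    params: PopulationParams,
    grid: PopulationGrid,
    n_items: int,
    dims: tuple[str, str],
) -> np.ndarray:
    """Expected spike counts of all M neurons for one encoded item.

    Tuning is the product of von Mises profiles in the two dimensions,
    normalized so that each of the N items contributes exactly ``gamma / N``
    expected spikes; summed over items the population expects ``gamma``.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    psi, theta = item
    p1 = _lattice_probs(float(psi), params.kappa(dims[0]), grid.axis)
    p2 = _lattice_probs(float(theta), params.kappa(dims[1]), grid.axis)
    return (params.gamma / n_items) * np.outer(p1, p2).ravel()


def sample_spikes(rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson spike counts with the given means."""
    rates = np.asarray(rates, float)
    if np.any(rates < 0):
        raise ValueError("negative rate")
    return rng.poisson(rates)


def ml_decode_item(
    counts: np.ndarray,
    params: PopulationParams,
    grid: PopulationGrid,
    dims: tuple[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Maximum-likelihood feature pair from one item's spike counts.

    The spike log-likelihood ``sum_i r_i log rbar_i(psi, theta)`` separates
    into per-dimension cosine sums, so the exact maximizer is the circular
    mean of the spiking neurons' preferred values in each dimension.  With
    zero spikes (or an exactly vanishing resultant) the decode is an
    uninformative uniform random draw.
    """
    counts = np.asarray(counts)
    if counts.shape != (grid.M,):
        raise ValueError("counts shape does not match grid")
    if rng is None:
        rng = np.random.default_rng()
    pref_psi, pref_theta = grid.preferred()
    out = []
    for pref in (pref_psi, pref_theta):
        z = np.sum(counts * np.exp(1j * pref))
        if counts.sum() == 0 or np.abs(z) < 1e-12:
            out.append(float(rng.uniform(-np.pi, np.pi)))
        else:
            out.append(float(np.angle(z)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# batched simulation
# ---------------------------------------------------------------------------
def _decode_dim_batch(
    feats: np.ndarray,  # (T, N) encoded feature values
    counts: np.ndarray,  # (T, N) spike counts per item
    kappa: float,
    grid: PopulationGrid,
    rng: np.random.Generator,
) -> np.ndarray:
    """Decoded values (T, N) for one feature dimension of all items.

    Exploits two exact reductions: (i) given an item's total count, its
    spikes' preferred indices in the two lattice dimensions are independent,
    so each dimension can be sampled on its own marginal lattice; (ii) the ML
    decode is the resultant direction of the spikes' preferred values.
    """
    T, N = feats.shape
    m = grid.m_side
    axis = grid.axis
    unit = np.exp(1j * axis)
    # lattice probabilities per (trial, item): shift profile to each feature
    w = np.exp(kappa * (np.cos(axis[None, None, :] - feats[:, :, None]) - 1.0))
    w /= w.sum(axis=2, keepdims=True)
    cat = rng.multinomial(counts.ravel(), w.reshape(-1, m))  # (T*N, m)
    z = cat.astype(float) @ unit
    z = z.reshape(T, N)
    dec = np.angle(z)
    lost = (counts == 0) | (np.abs(z).reshape(T, N) < 1e-12)
    if lost.any():
        dec = np.where(lost, rng.uniform(-np.pi, np.pi, size=(T, N)), dec)
    return dec


def _simulate_stage(
    cue_vals: np.ndarray,  # (T,)
    cue_feats: np.ndarray,  # (T, N)
    rep_feats: np.ndarray,  # (T, N)
    kappa_cue: float,
    kappa_rep: float,
    gamma: float,
    grid: PopulationGrid,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One retrieval episode per trial; returns (responses, selected_index)."""
    T, N = cue_feats.shape
    counts = rng.poisson(gamma / N, size=(T, N))
    dec_cue = _decode_dim_batch(cue_feats, counts, kappa_cue, grid, rng)
    dec_rep = _decode_dim_batch(rep_feats, counts, kappa_rep, grid, rng)
    dev = np.abs(wrap(dec_cue - cue_vals[:, None]))
    sel = np.argmin(dev, axis=1)
    rows = np.arange(T)
    return dec_rep[rows, sel], sel


def simulate_reports(
    dataset: Dataset,
    params: PopulationParams,
    variant: str,
    rng: np.random.Generator,
    grid: PopulationGrid = DEFAULT_GRID,
    return_details: bool = False,
):
    """Simulate one pair of reports per trial under a binding variant.

    Returns a response array ``(n_trials, 2)`` in the dataset's report
    order; with ``return_details`` also a dict with the per-stage selected
    item indices (``(n_trials, n_stages)``).
    """
    plan = retrieval_plan(variant, dataset.cue_dim, dataset.report_dims)
    T = dataset.n_trials
    responses = np.empty((T, 2))
    outputs: list[np.ndarray] = []
    selected = np.empty((T, len(plan)), int)
    for s, stage in enumerate(plan):
        if stage.cue_stage is None:
            cue_vals = dataset.cue_values()
        else:
            cue_vals = outputs[stage.cue_stage]
        resp, sel = _simulate_stage(
            cue_vals,
            dataset.features(stage.cue_dim),
            dataset.features(stage.report_dim),
            params.kappa(stage.cue_dim),
            params.kappa(stage.report_dim),
            params.gamma,
            grid,
            rng,
        )
        outputs.append(resp)
        selected[:, s] = sel
        responses[:, stage.slot] = resp
    if return_details:
        return responses, {"selected": selected, "plan": plan}
    return responses


def simulate_report(
    dataset: Dataset,
    trial_index: int,
    params: PopulationParams,
    variant: str,
    rng: np.random.Generator,
    grid: PopulationGrid = DEFAULT_GRID,
) -> tuple[float, float]:
    """Simulate the response pair of a single trial."""
    resp = simulate_reports(
        dataset.subset(np.array([trial_index])), params, variant, rng, grid
    )
    return float(resp[0, 0]), float(resp[0, 1])


# ---------------------------------------------------------------------------
# response likelihood (deterministic quadrature)
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class LikelihoodConfig:
    """Numerical resolution of the response-density quadrature."""

    half_points: int = 257  # minimum circular grid points on [0, pi]
    max_half_points: int = 4097  # resolution ceiling for concentrated decodes
    d_bins: int = 64  # bins of the selection-distance integral
    poisson_tol: float = 1e-9  # truncation of the spike-count distribution
    density_floor: float = 1e-150  # floor for zero-density responses
    chunk: int = 256  # trial chunk size (memory control)


DEFAULT_LIK = LikelihoodConfig()


def _poisson_support(lam: float, tol: float) -> tuple[np.ndarray, np.ndarray]:
    hi = int(np.ceil(lam + 8.0 * np.sqrt(lam) + 8.0))
    ks = np.arange(0, hi + 1)
    pmf = stats.poisson.pmf(ks, lam)
    keep = (pmf > tol) | (ks == 0)
    ks, pmf = ks[keep], pmf[keep]
    return ks, pmf / pmf.sum()


def _stage_logdensity(
    cue_vals: np.ndarray,
    resp_vals: np.ndarray | None,
    cue_feats: np.ndarray,
    rep_feats: np.ndarray,
    cue_tab: DirectionTables,
    rep_tab: DirectionTables,
    pmf: np.ndarray,
    cfg: LikelihoodConfig,
    eval_grid: np.ndarray | None = None,
):
    """Per-trial log density of the stage report (or density on a grid).

    Implements the exact decomposition
    ``p(report | cue) = sum_{j,k} P(select item j, K_j = k) g_k(report -
    theta_j)`` where the selection probabilities follow from the independent
    per-item decode-deviation distributions, integrated over the selection
    distance on a binned grid.
    """
    T, N = cue_feats.shape
    # selection-distance bins concentrated near zero, where the competition
    # between precisely decoded cue features is resolved
    edges = np.pi * (np.linspace(0.0, 1.0, cfg.d_bins + 1)) ** 2
    E = cfg.d_bins
    G1 = len(cue_tab.theta)
    out = np.empty(T) if eval_grid is None else None
    grid_out = None
    cdf_marg = pmf @ cue_tab.cdf  # (G+1,) marginal deviation CDF per item
    marg_tab = DirectionTables(
        kappa=cue_tab.kappa,
        ks=np.array([0]),
        theta=cue_tab.theta,
        pdf=cdf_marg[None, :],  # unused; placeholder
        cdf=cdf_marg[None, :],
    )
    for lo in range(0, T, cfg.chunk):
        sl = slice(lo, min(lo + cfg.chunk, T))
        mu = wrap(cue_feats[sl] - cue_vals[sl, None])  # (t, N)
        t = mu.shape[0]
        hi_arg = edges[None, None, :] - mu[:, :, None]  # (t, N, E+1)
        lo_arg = -edges[None, None, :] - mu[:, :, None]
        # marginal CDF of the absolute cue deviation of each item
        Fbar = (
            marg_tab.cdf_rows_ext(hi_arg) - marg_tab.cdf_rows_ext(lo_arg)
        )[0]
        S = np.clip(1.0 - Fbar, 0.0, 1.0)  # (t, N, E+1) survival at edges
        Smid = 0.5 * (S[:, :, :-1] + S[:, :, 1:])  # at bin midpoints
        # leave-one-out products via prefix/suffix (stable at S -> 0)
        L = np.ones_like(Smid)
        R = np.ones_like(Smid)
        L[:, 1:] = np.cumprod(Smid[:, :-1], axis=1)
        R[:, :-1] = np.cumprod(Smid[:, :0:-1], axis=1)[:, ::-1]
        H = L * R  # (t, N, E) prob all other items farther than d
        # Selection weights W[k, t, j] = sum_bins (F_{j,k}(d_{e+1}) -
        # F_{j,k}(d_e)) * H_j(mid_e) with F the per-count deviation CDF.
        # Summation by parts turns this into a fixed linear functional of
        # the CDF table rows: scatter per-(trial, item) coefficients onto
        # the table grid once, then contract with all count rows at once.
        Gc = np.empty((t, N, E + 1))
        Gc[:, :, 0] = -H[:, :, 0]
        Gc[:, :, 1:E] = H[:, :, : E - 1] - H[:, :, 1:]
        Gc[:, :, E] = H[:, :, E - 1]
        const = np.zeros((t, N))
        rowbase = np.arange(t * N)[:, None] * G1
        flats = []
        vals = []
        for arg, sign in ((hi_arg, 1.0), (lo_arg, -1.0)):
            wind, idx, frac = cue_tab.locate_ext(arg)
            coeff = sign * Gc
            flat = (rowbase + idx.reshape(t * N, E + 1)).ravel()
            flats += [flat, flat + 1]
            vals += [(coeff * (1.0 - frac)).reshape(-1), (coeff * frac).reshape(-1)]
            const += (coeff * wind).sum(axis=2)
        Q = np.bincount(
            np.concatenate(flats), np.concatenate(vals), minlength=t * N * G1
        ).reshape(t * N, G1)
        w = cue_tab.cdf @ Q.T  # (nk, t*N)
        w = w.reshape(-1, t, N) + const[None, :, :]
        np.clip(w, 0.0, None, out=w)
        w *= pmf[:, None, None]
        tot = w.sum(axis=(0, 2), keepdims=True)
        w /= np.maximum(tot, 1e-300)
        if eval_grid is None:
            dev = wrap(resp_vals[sl, None] - rep_feats[sl])  # (t, N)
            gk = rep_tab.pdf_rows_at(dev)  # (nk, t, N)
            out[sl] = np.log(
                np.maximum(np.einsum("ktn,ktn->t", w, gk), cfg.density_floor)
            )
        else:
            dev = wrap(eval_grid[None, None, :] - rep_feats[sl][:, :, None])
            gk = rep_tab.pdf_rows_at(dev)  # (nk, t, N, G)
            dens = np.einsum("ktn,ktng->tg", w, gk)
            grid_out = dens if grid_out is None else np.vstack([grid_out, dens])
    return out if eval_grid is None else grid_out


def _tables_for(
    params: PopulationParams,
    dims: set[str],
    n_items: int,
    cfg: LikelihoodConfig,
) -> tuple[dict[str, DirectionTables], np.ndarray]:
    lam = params.gamma / n_items
    ks, pmf = _poisson_support(lam, cfg.poisson_tol)
    tabs = {}
    for d in dims:
        kap = params.kappa(d)
        # resolve the most concentrated row (effective concentration
        # k_max * kappa * A(kappa)) with ~6 grid points per SD
        keff = max(float(ks.max()) * kap * bessel_ratio(kap), 1.0)
        hp = int(
            np.clip(
                np.ceil(6.0 * np.pi * np.sqrt(keff)) + 1,
                cfg.half_points,
                cfg.max_half_points,
            )
        )
        tabs[d] = direction_tables(kap, ks, hp)
    return tabs, pmf


def response_log_likelihood(
    dataset: Dataset,
    params: PopulationParams,
    variant: str,
    cfg: LikelihoodConfig = DEFAULT_LIK,
) -> float:
    """Total log-likelihood of the observed response pairs under a variant.

    The joint density factorizes per the variant's retrieval chain; for
    chained stages the intermediary cue of the second factor is the observed
    intermediary report.
    """
    if dataset.responses is None:
        raise ValueError("dataset has no responses")
    plan = retrieval_plan(variant, dataset.cue_dim, dataset.report_dims)
    dims = {s.cue_dim for s in plan} | {s.report_dim for s in plan}
    tabs, pmf = _tables_for(params, dims, dataset.n_items, DEFAULT_LIK if cfg is None else cfg)
    total = 0.0
    n_floored = 0
    for stage in plan:
        if stage.cue_stage is None:
            cue_vals = dataset.cue_values()
        else:
            cue_vals = dataset.responses[:, plan[stage.cue_stage].slot]
        ll = _stage_logdensity(
            cue_vals,
            dataset.responses[:, stage.slot],
            dataset.features(stage.cue_dim),
            dataset.features(stage.report_dim),
            tabs[stage.cue_dim],
            tabs[stage.report_dim],
            pmf,
            cfg,
        )
        n_floored += int(np.sum(ll <= np.log(cfg.density_floor) + 1e-9))
        total += float(ll.sum())
    if n_floored:
        logger.warning("response_log_likelihood: %d densities floored", n_floored)
    return total


def conditional_density(
    params: PopulationParams,
    cue_pop: tuple[str, str],
    cue_value: float,
    trial: Dataset,
    grid_resolution: int = 256,
    cfg: LikelihoodConfig = DEFAULT_LIK,
) -> tuple[np.ndarray, np.ndarray]:
    """Density of one population's report feature given a cue value.

    ``cue_pop`` names (cue_dim, report_dim); ``trial`` is a single-trial
    dataset supplying the item set.  Returns (grid, density) with the grid
    uniform over [-pi, pi); the density integrates to 1.
    """
    if grid_resolution < 32:
        raise ValueError("grid_resolution must be >= 32")
    if trial.n_trials != 1:
        raise ValueError("conditional_density expects a single trial")
    cue_dim, rep_dim = cue_pop
    tabs, pmf = _tables_for(params, {cue_dim, rep_dim}, trial.n_items, cfg)
    grid = -np.pi + 2.0 * np.pi * np.arange(grid_resolution) / grid_resolution
    dens = _stage_logdensity(
        np.array([float(cue_value)]),
        None,
        trial.features(cue_dim),
        trial.features(rep_dim),
        tabs[cue_dim],
        tabs[rep_dim],
        pmf,
        cfg,
        eval_grid=grid,
    )[0]
    return grid, dens


def decoding_sd(
    params: PopulationParams,
    dim: str,
    n_items: int = 6,
    cfg: LikelihoodConfig = DEFAULT_LIK,
) -> float:
    """Circular SD of the decoding error of one feature dimension.

    Marginalizes the decode-direction density over the Poisson spike count
    of a single item (the model's per-feature decoding precision).
    """
    lam = params.gamma / n_items
    ks, pmf = _poisson_support(lam, cfg.poisson_tol)
    tab = direction_tables(params.kappa(dim), ks, cfg.half_points)
    dens = pmf @ tab.pdf
    R = float(np.trapezoid(dens * np.cos(tab.theta), tab.theta))
    if R <= 0:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(R)))


# ---------------------------------------------------------------------------
# fitting and comparison
# ---------------------------------------------------------------------------
@dataclass
class PopFitResult:
    """Maximum-likelihood fit of one binding variant."""

    params: PopulationParams
    log_likelihood: float
    variant: str
    n_trials: int
    converged: bool = True
    n_evaluations: int = 0
    n_params: int = 4

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    @property
    def bic(self) -> float:
        return self.n_params * np.log(self.n_trials) - 2.0 * self.log_likelihood


_LOG_BOUNDS = np.log(
    np.array([[0.05, 2000.0], [0.05, 100.0], [0.05, 100.0], [0.05, 100.0]])
)


def _objective(x: np.ndarray, dataset: Dataset, variant: str, cfg) -> float:
    xc = np.clip(x, _LOG_BOUNDS[:, 0], _LOG_BOUNDS[:, 1])
    penalty = 1e4 * float(np.sum((x - xc) ** 2))
    g, kl, kc, ko = np.exp(xc)
    params = PopulationParams(g, kl, kc, ko)
    return -response_log_likelihood(dataset, params, variant, cfg) + penalty


def fit_popmodel(
    dataset: Dataset,
    variant: str,
    n_restarts: int = 5,
    max_fev: int = 120,
    polish_fev: int = 150,
    seed: int = 0,
    cfg: LikelihoodConfig = DEFAULT_LIK,
) -> PopFitResult:
    """Maximum-likelihood fit of one binding variant by simplex search.

    Parameters are log-transformed (gamma and three concentrations);
    ``n_restarts`` dispersed starting points are run with a bounded
    function-evaluation budget and the best is polished.  The likelihood is
    deterministic, so fits are exactly reproducible for a given seed.
    """
    if dataset.n_trials == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    base = np.log(np.array([50.0, 8.0, 4.0, 4.0]))
    starts = [base]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(base + rng.normal(0.0, np.array([1.0, 0.7, 0.7, 0.7])))
    best = None
    nev = 0
    for x0 in starts:
        res = optimize.minimize(
            _objective,
            x0,
            args=(dataset, variant, cfg),
            method="Nelder-Mead",
            options={"maxfev": max_fev, "xatol": 1e-3, "fatol": 1e-3},
        )
        nev += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    res = optimize.minimize(
        _objective,
        best.x,
        args=(dataset, variant, cfg),
        method="Nelder-Mead",
        options={"maxfev": polish_fev, "xatol": 1e-4, "fatol": 1e-4},
    )
    nev += res.nfev
    if res.fun > best.fun:
        res = best
    converged = bool(res.success) or res.fun <= best.fun + 1e-6
    if not converged:
        logger.warning("fit_popmodel(%s): optimizer did not converge", variant)
    x = np.clip(res.x, _LOG_BOUNDS[:, 0], _LOG_BOUNDS[:, 1])
    g, kl, kc, ko = np.exp(x)
    params = PopulationParams(g, kl, kc, ko)
    ll = response_log_likelihood(dataset, params, variant, cfg)
    return PopFitResult(
        params=params,
        log_likelihood=ll,
        variant=variant,
        n_trials=dataset.n_trials,
        converged=converged,
        n_evaluations=nev,
    )


def compare_variants(
    dataset: Dataset,
    fits: dict[str, PopFitResult],
    mixture_fit=None,
):
    """Comparison table of binding-variant fits (and optionally a mixture fit).

    Delta log-likelihoods are taken against the spatial variant; AIC/BIC
    deltas against the joint mixture model when provided (positive deltas
    favor the population model).
    """
    import pandas as pd

    n = dataset.n_trials
    for v, f in fits.items():
        if f.n_trials != n:
            raise ValueError(f"fit for {v!r} used a different trial set")
    ll_spatial = fits["spatial"].log_likelihood if "spatial" in fits else np.nan
    rows = []
    for v, f in fits.items():
        row = {
            "model": v,
            "log_likelihood": f.log_likelihood,
            "n_params": f.n_params,
            "aic": f.aic,
            "bic": f.bic,
            "delta_ll_vs_spatial": f.log_likelihood - ll_spatial,
        }
        if mixture_fit is not None:
            mix_aic = 2.0 * mixture_fit.n_params - 2.0 * mixture_fit.log_likelihood_
            mix_bic = (
                mixture_fit.n_params * np.log(n) - 2.0 * mixture_fit.log_likelihood_
            )
            row["delta_aic_vs_mixture"] = mix_aic - f.aic
            row["delta_bic_vs_mixture"] = mix_bic - f.bic
        rows.append(row)
    if mixture_fit is not None:
        rows.append(
            {
                "model": "joint_mixture",
                "log_likelihood": mixture_fit.log_likelihood_,
                "n_params": mixture_fit.n_params,
                "aic": 2.0 * mixture_fit.n_params - 2.0 * mixture_fit.log_likelihood_,
                "bic": mixture_fit.n_params * np.log(n)
                - 2.0 * mixture_fit.log_likelihood_,
                "delta_ll_vs_spatial": np.nan,
            }
        )
    table = pd.DataFrame(rows)
    variants_only = table[table["model"].isin(VARIANTS)]
    table.attrs["winner_ll"] = variants_only.loc[
        variants_only["log_likelihood"].idxmax(), "model"
    ]
    return table


class PopulationBindingModel(BaseEstimator):
    """Neural binding model estimator with a scikit-learn interface.

    Parameters
    ----------
    variant : {"spatial", "via_color", "via_orientation"}
        Binding architecture.
    n_restarts, max_fev, polish_fev, seed
        Simplex-search budget (see :func:`fit_popmodel`).

    Attributes
    ----------
    gamma_, kappa_loc_, kappa_col_, kappa_ori_ : float
        Fitted spike budget and tuning concentrations.
    log_likelihood_ : float
        Log-likelihood at the fitted parameters.
    result_ : PopFitResult
    """

    def __init__(
        self,
        variant: str = "spatial",
        n_restarts: int = 5,
        max_fev: int = 120,
        polish_fev: int = 150,
        seed: int = 0,
    ):
        self.variant = variant
        self.n_restarts = n_restarts
        self.max_fev = max_fev
        self.polish_fev = polish_fev
        self.seed = seed

    def fit(self, X: Dataset, y=None):
        res = fit_popmodel(
            X,
            self.variant,
            n_restarts=self.n_restarts,
            max_fev=self.max_fev,
            polish_fev=self.polish_fev,
            seed=self.seed,
        )
        self.result_ = res
        self.gamma_ = res.params.gamma
        self.kappa_loc_ = res.params.kappa_loc
        self.kappa_col_ = res.params.kappa_col
        self.kappa_ori_ = res.params.kappa_ori
        self.log_likelihood_ = res.log_likelihood
        self.converged_ = res.converged
        return self

    def score(self, X: Dataset, y=None) -> float:
        """Log-likelihood of a dataset at the fitted parameters."""
        return response_log_likelihood(X, self.result_.params, self.variant)

    def simulate(self, X: Dataset, rng: np.random.Generator) -> np.ndarray:
        """Posterior-predictive responses for the trials of ``X``."""
        return simulate_reports(X, self.result_.params, self.variant, rng)
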