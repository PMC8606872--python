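"""Von Mises mixture models for dual-report response errors.

The descriptive counterpart of the population binding model: each report is
a mixture of a target component (von Mises around the true target feature),
optionally a nontarget component (von Mises around a nontarget's feature,
same concentration as the target component), and a uniform guessing
component.  The *joint* models estimate proportions over response-type
pairs across the two reports — the central quantity for measuring whether
the two features of the cued item succeed or fail together.

Joint two-component model: proportions over {TT, TU, UT, UU}, one
concentration per report; 5 free parameters.  Joint three-component model:
adds nontarget responses, with the both-nontarget case split into matched
(same nontarget item both reports, NNs) and mismatched (two different
items, NNd) swaps; 11 free parameters.

Fitting is by expectation-maximization over an atom expansion (every
(source item, source item) pair is an atom within its component), with the
concentration updated by inverting the Bessel ratio A(kappa) = I1/I0 on
the responsibility-weighted mean resultant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import i0e, i1e
from sklearn.base import BaseEstimator

from .circstats import circ_dist
from .dataset import Dataset

KAPPA_MIN, KAPPA_MAX = 1e-3, 1e4

LABELS2 = ("TT", "TU", "UT", "UU")
LABELS3 = ("TT", "TN", "TU", "NT", "NNs", "NNd", "NU", "UT", "UN", "UU")

__all__ = [
    "LABELS2",
    "LABELS3",
    "JointVonMisesMixture",
    "SingleVonMisesMixture",
    "ResponseClassification",
    "fit_joint2",
    "fit_joint3",
    "predict_independent",
    "predict_correlated",
    "phi_squared",
    "classify_responses",
    "conditional_error_distributions",
    "vonmises_logpdf",
    "a_inv",
]


def vonmises_logpdf(x: np.ndarray, kappa: float) -> np.ndarray:
    """log density of a von Mises centered at 0 (exponentially scaled I0)."""
    return kappa * (np.cos(x) - 1.0) - np.log(2.0 * np.pi * i0e(kappa))


def a_inv(r: float) -> float:
    """Invert the Bessel ratio A(kappa) = I1(kappa)/I0(kappa).

    Piecewise initial approximation followed by Newton steps; clipped to
    [KAPPA_MIN, KAPPA_MAX].
    """
    r = float(np.clip(r, 0.0, 1.0 - 1e-12))
    if r < 1e-9:
        return KAPPA_MIN
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    for _ in range(4):
        a = i1e(k) / i0e(k)
        da = 1.0 - a * a - a / k  # derivative of A
        if da <= 0:
            break
        k -= (a - r) / da
        if k <= 0:
            k = KAPPA_MIN
            break
    return float(np.clip(k, KAPPA_MIN, KAPPA_MAX))


# ---------------------------------------------------------------------------
# atom expansion shared by all mixture fits
# ---------------------------------------------------------------------------
def _sources(n_items: int, with_nontargets: bool):
    """Per-report response sources: target, nontargets (array order), uniform."""
    src = [("T", -1)]
    if with_nontargets:
        src += [("N", j) for j in range(n_items - 1)]
    src += [("U", -1)]
    return src


def _pair_label(s1, s2) -> str:
    t1, j1 = s1
    t2, j2 = s2
    if t1 == "N" and t2 == "N":
        return "NNs" if j1 == j2 else "NNd"
    return t1 + t2


def _source_logdens(
    dataset: Dataset, report: int, kappa: float, with_nontargets: bool
) -> np.ndarray:
    """(n_trials, n_sources) log density of the response under each source."""
    dim = dataset.report_dims[report]
    resp = dataset.responses[:, report]
    cols = [vonmises_logpdf(circ_dist(resp, dataset.target_feature(dim)), kappa)]
    if with_nontargets:
        nt = dataset.nontarget_features(dim)
        dev = circ_dist(resp[:, None], nt)
        for j in range(dataset.n_items - 1):
            cols.append(vonmises_logpdf(dev[:, j], kappa))
    cols.append(np.full(dataset.n_trials, -np.log(2.0 * np.pi)))
    return np.stack(cols, axis=1)


@dataclass
class _JointSpec:
    labels: tuple
    atoms: list  # (source-index report 1, source-index report 2, group index)
    group_weight: np.ndarray  # 1 / multiplicity within group
    sources: list
    with_nontargets: bool


def _joint_spec(n_items: int, three_component: bool) -> _JointSpec:
    labels = LABELS3 if three_component else LABELS2
    src = _sources(n_items, three_component)
    atoms = []
    counts = {lab: 0 for lab in labels}
    for a1, s1 in enumerate(src):
        for a2, s2 in enumerate(src):
            lab = _pair_label(s1, s2)
            atoms.append((a1, a2, labels.index(lab)))
            counts[lab] += 1
    gw = np.array([1.0 / counts[labels[g]] for (_, _, g) in atoms])
    return _JointSpec(labels, atoms, gw, src, three_component)


def _em_joint(
    dataset: Dataset,
    three_component: bool,
    kappa0: tuple[float, float],
    alpha0: np.ndarray,
    max_iter: int,
    tol: float,
) -> dict:
    spec = _joint_spec(dataset.n_items, three_component)
    n = dataset.n_trials
    src = _sources(dataset.n_items, three_component)
    n_src = len(src)
    a1_idx = np.array([a for (a, _, _) in spec.atoms])
    a2_idx = np.array([a for (_, a, _) in spec.atoms])
    grp = np.array([g for (_, _, g) in spec.atoms])
    circ1 = np.array([src[a][0] != "U" for a in a1_idx])
    circ2 = np.array([src[a][0] != "U" for a in a2_idx])
    # deviations per source (for the kappa update); uniform column unused
    def devs(report):
        dim = dataset.report_dims[report]
        resp = dataset.responses[:, report]
        d = [circ_dist(resp, dataset.target_feature(dim))]
        if three_component:
            nt = dataset.nontarget_features(dim)
            d += [circ_dist(resp, nt[:, j]) for j in range(dataset.n_items - 1)]
        d.append(np.zeros(n))
        return np.stack(d, axis=1)

    dev1, dev2 = devs(0), devs(1)
    kappa1, kappa2 = kappa0
    alphas = alpha0.copy()
    ll_prev = -np.inf
    for it in range(max_iter):
        ld1 = _source_logdens(dataset, 0, kappa1, three_component)
        ld2 = _source_logdens(dataset, 1, kappa2, three_component)
        log_atom = (
            np.log(np.maximum(alphas[grp] * spec.group_weight, 1e-300))[None, :]
            + ld1[:, a1_idx]
            + ld2[:, a2_idx]
        )
        m = log_atom.max(axis=1, keepdims=True)
        p = np.exp(log_atom - m)
        denom = p.sum(axis=1, keepdims=True)
        resp = p / denom
        ll = float(np.sum(m[:, 0] + np.log(denom[:, 0])))
        # M step
        for g in range(len(spec.labels)):
            alphas[g] = resp[:, grp == g].sum() / n
        alphas = np.maximum(alphas, 0.0)
        alphas /= alphas.sum()
        w1 = resp[:, circ1]
        c1 = np.sum(w1 * np.cos(dev1[:, a1_idx[circ1]])) / max(w1.sum(), 1e-300)
        w2 = resp[:, circ2]
        c2 = np.sum(w2 * np.cos(dev2[:, a2_idx[circ2]])) / max(w2.sum(), 1e-300)
        kappa1, kappa2 = a_inv(c1), a_inv(c2)
        if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            ll_prev = ll
            break
        ll_prev = ll
    return {
        "kappa1": kappa1,
        "kappa2": kappa2,
        "alphas": dict(zip(spec.labels, alphas)),
        "log_likelihood": ll_prev,
        "n_iter": it + 1,
    }


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------
class JointVonMisesMixture(BaseEstimator):
    """Joint mixture model over the response-type pairs of the two reports.

    Parameters
    ----------
    n_components : {2, 3}
        2 for target/uniform (proportions over TT/TU/UT/UU, 5 free
        parameters); 3 adds nontarget responses with matched/mismatched
        both-swap components (11 free parameters).
    n_restarts, seed, max_iter, tol
        EM control; restarts draw random initial proportions.

    Attributes
    ----------
    kappa1_, kappa2_ : float
        Concentrations of the circular components per report (shared
        between target and nontarget components).
    alphas_ : dict
        Mixture proportions keyed by component label.
    log_likelihood_ : float
    """

    def __init__(
        self,
        n_components: int = 2,
        n_restarts: int = 3,
        seed: int = 0,
        max_iter: int = 400,
        tol: float = 1e-8,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    @property
    def n_params(self) -> int:
        return 5 if self.n_components == 2 else 11

    def fit(self, X: Dataset, y=None):
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        if X.responses is None:
            raise ValueError("dataset has no responses")
        if X.n_trials < 20:
            raise ValueError("need at least 20 trials with both responses")
        if self.n_components == 3 and X.n_items < 3:
            raise ValueError("three-component joint model needs >= 3 items")
        three = self.n_components == 3
        labels = LABELS3 if three else LABELS2
        rng = np.random.default_rng(self.seed)
        # moment-style start: kappa from overall error resultant
        k0 = tuple(
            a_inv(min(float(np.mean(np.cos(X.errors(r)))), 1.0 - 1e-9))
            if np.mean(np.cos(X.errors(r))) > 0
            else 1.0
            for r in (0, 1)
        )
        starts = [(k0, np.full(len(labels), 1.0 / len(labels)))]
        for _ in range(max(0, self.n_restarts - 1)):
            starts.append(
                (
                    (rng.uniform(1, 20), rng.uniform(1, 20)),
                    rng.dirichlet(np.ones(len(labels))),
                )
            )
        best = None
        for kap, al in starts:
            res = _em_joint(X, three, kap, al, self.max_iter, self.tol)
            if best is None or res["log_likelihood"] > best["log_likelihood"]:
                best = res
        if best["kappa1"] >= KAPPA_MAX or best["kappa2"] >= KAPPA_MAX:
            warnings.warn("degenerate data: concentration capped at KAPPA_MAX")
        self.kappa1_ = best["kappa1"]
        self.kappa2_ = best["kappa2"]
        self.alphas_ = best["alphas"]
        self.log_likelihood_ = best["log_likelihood"]
        self.n_iter_ = best["n_iter"]
        return self

    @property
    def phi_squared_(self) -> float:
        """Mean-square contingency of the fitted 2x2 T/U proportion table."""
        if self.n_components != 2:
            raise AttributeError("phi_squared_ is defined for the 2-component fit")
        return phi_squared(self.alphas_)

    def marginals(self) -> tuple[float, float]:
        """(alpha_T., alpha_.T): target proportions per report."""
        a = self.alphas_
        if self.n_components == 2:
            return a["TT"] + a["TU"], a["TT"] + a["UT"]
        t1 = a["TT"] + a["TN"] + a["TU"]
        t2 = a["TT"] + a["NT"] + a["UT"]
        return t1, t2


class SingleVonMisesMixture(BaseEstimator):
    """Single-feature mixture model for one report (target/[nontarget]/uniform).

    Used to classify individual responses; ``n_components`` is 2 (T, U) or
    3 (T, N, U).
    """

    def __init__(
        self,
        report: int = 0,
        n_components: int = 2,
        n_restarts: int = 3,
        seed: int = 0,
        max_iter: int = 400,
        tol: float = 1e-8,
    ):
        self.report = report
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def _atom_logdens(self, X: Dataset, kappa: float) -> np.ndarray:
        return _source_logdens(X, self.report, kappa, self.n_components == 3)

    def fit(self, X: Dataset, y=None):
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        if X.responses is None:
            raise ValueError("dataset has no responses")
        three = self.n_components == 3
        n = X.n_trials
        n_nt = X.n_items - 1 if three else 0
        labels = ("T", "N", "U") if three else ("T", "U")
        grp = np.array([0] + [1] * n_nt + [1 + (1 if three else 0)])
        gw = np.array([1.0] + [1.0 / n_nt] * n_nt + [1.0]) if three else np.ones(2)
        dim = X.report_dims[self.report]
        resp = X.responses[:, self.report]
        dev_cols = [circ_dist(resp, X.target_feature(dim))]
        if three:
            nt = X.nontarget_features(dim)
            dev_cols += [circ_dist(resp, nt[:, j]) for j in range(n_nt)]
        dev_cols.append(np.zeros(n))
        dev = np.stack(dev_cols, axis=1)
        circ = np.array([True] * (1 + n_nt) + [False])
        rng = np.random.default_rng(self.seed)
        r0 = float(np.mean(np.cos(dev[:, 0])))
        starts = [
            (a_inv(r0) if r0 > 0 else 1.0, np.full(len(labels), 1.0 / len(labels)))
        ]
        for _ in range(max(0, self.n_restarts - 1)):
            starts.append((rng.uniform(1, 20), rng.dirichlet(np.ones(len(labels)))))
        best = None
        for kappa, alphas in starts:
            alphas = alphas.copy()
            ll_prev = -np.inf
            for it in range(self.max_iter):
                ld = self._atom_logdens(X, kappa)
                log_atom = (
                    np.log(np.maximum(alphas[grp] * gw, 1e-300))[None, :] + ld
                )
                m = log_atom.max(axis=1, keepdims=True)
                p = np.exp(log_atom - m)
                denom = p.sum(axis=1, keepdims=True)
                r = p / denom
                ll = float(np.sum(m[:, 0] + np.log(denom[:, 0])))
                for g in range(len(labels)):
                    alphas[g] = r[:, grp == g].sum() / n
                alphas = np.maximum(alphas, 0.0)
                alphas /= alphas.sum()
                wc = r[:, circ]
                c = np.sum(wc * np.cos(dev[:, circ])) / max(wc.sum(), 1e-300)
                kappa = a_inv(c)
                if abs(ll - ll_prev) < self.tol * (1.0 + abs(ll)):
                    ll_prev = ll
                    break
                ll_prev = ll
            cand = {
                "kappa": kappa,
                "alphas": dict(zip(labels, alphas)),
                "ll": ll_prev,
            }
            if best is None or cand["ll"] > best["ll"]:
                best = cand
        self.kappa_ = best["kappa"]
        self.alphas_ = best["alphas"]
        self.log_likelihood_ = best["ll"]
        self.labels_ = labels
        return self

    def predict_proba(self, X: Dataset) -> np.ndarray:
        """(n_trials, n_components) posterior over components per response."""
        three = self.n_components == 3
        n_nt = X.n_items - 1 if three else 0
        grp = np.array([0] + [1] * n_nt + [1 + (1 if three else 0)])
        gw = (
            np.array([1.0] + [1.0 / n_nt] * n_nt + [1.0])
            if three
            else np.ones(2)
        )
        al = np.array([self.alphas_[lab] for lab in self.labels_])
        ld = self._atom_logdens(X, self.kappa_)
        log_atom = np.log(np.maximum(al[grp] * gw, 1e-300))[None, :] + ld
        m = log_atom.max(axis=1, keepdims=True)
        p = np.exp(log_atom - m)
        post = np.zeros((X.n_trials, self.n_components))
        for g in range(self.n_components):
            post[:, g] = p[:, grp == g].sum(axis=1)
        post /= post.sum(axis=1, keepdims=True)
        self._last_atom_post_ = p / p.sum(axis=1, keepdims=True)
        return post


@dataclass
class ResponseClassification:
    """Per-trial posteriors and hard labels of both reports.

    ``labels`` holds "T"/"N"/"U" strings of shape (n_trials, 2);
    ``nontarget_index`` the winning nontarget (array order among
    nontargets) for N-labeled responses, else -1.
    """

    posteriors: tuple[np.ndarray, np.ndarray]
    labels: np.ndarray
    nontarget_index: np.ndarray
    component_labels: tuple


def classify_responses(
    dataset: Dataset,
    fits: tuple[SingleVonMisesMixture, SingleVonMisesMixture],
) -> ResponseClassification:
    """Classify each response with separate single-feature mixture fits.

    Separate per-report fits ensure that classifying one feature cannot
    bias the classification of the other.  Hard labels are the argmax of
    the component posterior; for nontarget labels the winning nontarget
    item is recorded.
    """
    posts = []
    labels = np.empty((dataset.n_trials, 2), dtype=object)
    nt_idx = np.full((dataset.n_trials, 2), -1)
    for r, fit in enumerate(fits):
        if fit.report != r:
            raise ValueError("fit/report order mismatch")
        post = fit.predict_proba(dataset)
        posts.append(post)
        hard = np.argmax(post, axis=1)
        labels[:, r] = np.array(fit.labels_, dtype=object)[hard]
        if fit.n_components == 3:
            atom_post = fit._last_atom_post_
            nt_cols = atom_post[:, 1 : dataset.n_items]  # nontarget atoms
            nt_idx[:, r] = np.where(
                labels[:, r] == "N", np.argmax(nt_cols, axis=1), -1
            )
    return ResponseClassification(
        posteriors=(posts[0], posts[1]),
        labels=labels,
        nontarget_index=nt_idx,
        component_labels=tuple(f.labels_ for f in fits),
    )


# ---------------------------------------------------------------------------
# analytic predictions and correlation measure
# ---------------------------------------------------------------------------
def _check_marginal(a):
    if not 0.0 <= a <= 1.0:
        raise ValueError("marginal proportion outside [0, 1]")


def predict_independent(alpha_t1: float, alpha_t2: float) -> dict:
    """Expected joint proportions for completely independent recall.

    Outer product of the per-report (target, uniform) marginals.
    """
    _check_marginal(alpha_t1)
    _check_marginal(alpha_t2)
    return {
        "TT": alpha_t1 * alpha_t2,
        "TU": alpha_t1 * (1.0 - alpha_t2),
        "UT": (1.0 - alpha_t1) * alpha_t2,
        "UU": (1.0 - alpha_t1) * (1.0 - alpha_t2),
    }


def predict_correlated(alpha_t1: float, alpha_t2: float) -> dict:
    """Expected joint proportions for perfectly correlated recall."""
    _check_marginal(alpha_t1)
    _check_marginal(alpha_t2)
    att = 0.5 * (alpha_t1 + alpha_t2)
    return {"TT": att, "TU": 0.0, "UT": 0.0, "UU": 1.0 - att}


def phi_squared(alphas: dict) -> float:
    """Mean-square contingency of a 2x2 T/U proportion table.

    0 for independent, 1 for perfectly correlated response types.  Returns
    0 (with a warning) when a margin is degenerate.
    """
    att, atu = alphas["TT"], alphas["TU"]
    aut, auu = alphas["UT"], alphas["UU"]
    m1t, m1u = att + atu, aut + auu
    m2t, m2u = att + aut, atu + auu
    denom = m1t * m1u * m2t * m2u
    if denom <= 0:
        warnings.warn("phi_squared: degenerate margin; returning 0")
        return 0.0
    return float((att * auu - atu * aut) ** 2 / denom)


# ---------------------------------------------------------------------------
# conditional error distributions
# ---------------------------------------------------------------------------
def conditional_error_distributions(
    dataset: Dataset,
    classification: ResponseClassification,
    conditioning_report: int,
    relative_to: str = "target",
    bins: int = 37,
) -> dict:
    """Error histograms of one report, split by the other report's class.

    For each hard label of ``conditioning_report``, histograms the signed
    errors of the other report; with ``relative_to="selected_nontarget"``
    errors are taken relative to the other-report feature of the nontarget
    item identified in the conditioning report's classification (only
    meaningful for its N class).
    """
    if relative_to not in ("target", "selected_nontarget"):
        raise ValueError("relative_to must be 'target' or 'selected_nontarget'")
    other = 1 - conditioning_report
    dim = dataset.report_dims[other]
    resp = dataset.responses[:, other]
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    out = {}
    for lab in classification.component_labels[conditioning_report]:
        mask = classification.labels[:, conditioning_report] == lab
        if relative_to == "target":
            ref = dataset.target_feature(dim)
        else:
            nt = dataset.nontarget_features(dim)
            idx = classification.nontarget_index[:, conditioning_report]
            safe = np.maximum(idx, 0)
            ref = nt[np.arange(dataset.n_trials), safe]
            mask = mask & (idx >= 0)
        err = circ_dist(resp[mask], ref[mask])
        counts, _ = np.histogram(err, bins=edges)
        out[lab] = {
            "bin_edges": edges,
            "counts": counts,
            "errors": err,
            "n": int(mask.sum()),
            "empty": bool(mask.sum() == 0),
        }
    return out


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------
def fit_joint2(dataset: Dataset, **kwargs) -> JointVonMisesMixture:
    """Fit the two-component joint mixture model."""
    return JointVonMisesMixture(n_components=2, **kwargs).fit(dataset)


def fit_joint3(dataset: Dataset, **kwargs) -> JointVonMisesMixture:
    """Fit the three-component joint mixture model (with swap components)."""
    return JointVonMisesMixture(n_components=3, **kwargs).fit(dataset)
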