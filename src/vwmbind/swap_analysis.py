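"""Model-free swap-error statistics.

Swap errors — reporting a feature of a non-cued array item — show up as a
clustering of responses around nontarget feature values.  Because stimulus
arrays enforce minimum feature separations, the distribution of
response-to-nontarget deviations is not flat even without swaps; all
statistics here are therefore corrected against a shuffling null that
pairs each trial's response error (relative to its target) with nontarget
configurations drawn from other trials of the same delay condition.  This
preserves the response-error marginal and the separation structure while
destroying any genuine response-nontarget association.

The summary statistic is the mean absolute deviation (MAD) of responses
from nontarget feature values; its chance level is pi/2 for uniform
responses, and values below the shuffling expectation signal swaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import circ_dist, wrap
from .dataset import Dataset
from .taskgen import MIN_SEP_DEFAULT

__all__ = [
    "NontargetDeviationSet",
    "ShuffleNull",
    "nontarget_deviations",
    "shuffle_null",
    "mad_test",
    "MadTestResult",
    "binned_mad_by_cue_distance",
]

DEFAULT_BINS = 37


@dataclass
class NontargetDeviationSet:
    """Signed deviations of each response from every nontarget feature."""

    deviations: np.ndarray  # (n_trials, n_items - 1)
    report: int
    dim: str


def nontarget_deviations(dataset: Dataset, report: int) -> NontargetDeviationSet:
    """Deviation of the response from each nontarget's report feature."""
    if dataset.responses is None:
        raise ValueError("dataset has no responses")
    dim = dataset.report_dims[report]
    nt = dataset.nontarget_features(dim)
    dev = circ_dist(dataset.responses[:, report][:, None], nt)
    return NontargetDeviationSet(deviations=dev, report=report, dim=dim)


@dataclass
class ShuffleNull:
    """Shuffling-based expectation of nontarget deviations without swaps."""

    bin_edges: np.ndarray
    expected_hist: np.ndarray  # mean count per bin per shuffle replicate
    hist_std: np.ndarray  # across shuffle replicates
    expected_mad: float
    mad_std: float
    n_shuffles: int
    n_trials: int


def _null_offsets(dataset: Dataset, report: int) -> np.ndarray:
    """(n, N-1) target-to-nontarget offsets in the report dimension."""
    dim = dataset.report_dims[report]
    return circ_dist(
        dataset.nontarget_features(dim), dataset.target_feature(dim)[:, None]
    )


def _condition_groups(dataset: Dataset) -> list[np.ndarray]:
    return [
        np.flatnonzero(dataset.delay == lev)
        for lev in np.unique(dataset.delay.astype(str))
    ]


def shuffle_null(
    dataset: Dataset,
    report: int,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    bins: int = DEFAULT_BINS,
) -> ShuffleNull:
    """Expected nontarget-deviation distribution in the absence of swaps.

    Each shuffle permutes the nontarget offset configurations (relative to
    the target) across trials within the same delay condition and
    recombines them with the actual per-trial response errors; histograms
    and MADs are averaged over replicates.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    if dataset.n_trials < 2:
        raise ValueError("need at least 2 trials")
    if rng is None:
        rng = np.random.default_rng()
    err = dataset.errors(report)
    offsets = _null_offsets(dataset, report)
    groups = _condition_groups(dataset)
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    hists = np.empty((n_shuffles, bins))
    mads = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = np.arange(dataset.n_trials)
        for g in groups:
            perm[g] = g[rng.permutation(len(g))]
        dev = wrap(err[:, None] + offsets[perm])
        hists[s] = np.histogram(dev, bins=edges)[0]
        mads[s] = np.mean(np.abs(dev))
    return ShuffleNull(
        bin_edges=edges,
        expected_hist=hists.mean(axis=0),
        hist_std=hists.std(axis=0, ddof=1),
        expected_mad=float(mads.mean()),
        mad_std=float(mads.std(ddof=1)),
        n_shuffles=n_shuffles,
        n_trials=dataset.n_trials,
    )


@dataclass
class MadTestResult:
    """Observed vs expected MAD of nontarget deviations."""

    observed_mad: float
    expected_mad: float
    difference: float  # observed - expected; negative signals swaps
    mad_std: float
    observed_hist: np.ndarray
    corrected_hist: np.ndarray  # observed - expected counts per bin
    bin_edges: np.ndarray


def mad_test(dataset: Dataset, report: int, null: ShuffleNull) -> MadTestResult:
    """Compare the actual nontarget-deviation MAD with the shuffle null."""
    if null.n_trials != dataset.n_trials:
        raise ValueError("null was computed on a different trial set")
    dev = nontarget_deviations(dataset, report).deviations
    observed = float(np.mean(np.abs(dev)))
    obs_hist = np.histogram(dev, bins=null.bin_edges)[0].astype(float)
    return MadTestResult(
        observed_mad=observed,
        expected_mad=null.expected_mad,
        difference=observed - null.expected_mad,
        mad_std=null.mad_std,
        observed_hist=obs_hist,
        corrected_hist=obs_hist - null.expected_hist,
        bin_edges=null.bin_edges,
    )


def binned_mad_by_cue_distance(
    dataset: Dataset,
    report: int,
    n_bins: int = 8,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    min_sep: float | None = None,
) -> pd.DataFrame:
    """MAD of responses from nontarget features, binned by cue-feature distance.

    Nontargets are assigned to ``n_bins`` equal-width bins of absolute
    cue-dimension distance to the target, spanning [minimum separation, pi].
    Swap errors driven by cue similarity depress the MAD below its shuffle
    expectation in the near bins only.  Returns a tidy frame with one row
    per bin (empty bins are flagged, not errors).
    """
    if dataset.n_items < 2:
        raise ValueError("need at least 2 items")
    if rng is None:
        rng = np.random.default_rng()
    if min_sep is None:
        min_sep = dataset.meta.get("min_sep", {}).get(
            dataset.cue_dim, MIN_SEP_DEFAULT
        )
    edges = np.linspace(min_sep, np.pi, n_bins + 1)
    err = dataset.errors(report)
    offsets = _null_offsets(dataset, report)
    dev = nontarget_deviations(dataset, report).deviations
    cue_off = np.abs(
        circ_dist(
            dataset.nontarget_features(dataset.cue_dim),
            dataset.target_feature(dataset.cue_dim)[:, None],
        )
    )
    which = np.clip(np.digitize(cue_off, edges) - 1, 0, n_bins - 1)
    obs_mad = np.full(n_bins, np.nan)
    obs_n = np.zeros(n_bins, int)
    for b in range(n_bins):
        m = which == b
        obs_n[b] = int(m.sum())
        if obs_n[b]:
            obs_mad[b] = float(np.mean(np.abs(dev[m])))
    groups = _condition_groups(dataset)
    exp_sum = np.zeros(n_bins)
    exp_sq = np.zeros(n_bins)
    exp_cnt = np.zeros(n_bins)
    for s in range(n_shuffles):
        perm = np.arange(dataset.n_trials)
        for g in groups:
            perm[g] = g[rng.permutation(len(g))]
        dev_null = wrap(err[:, None] + offsets[perm])
        which_null = which[perm]
        for b in range(n_bins):
            m = which_null == b
            if m.any():
                v = float(np.mean(np.abs(dev_null[m])))
                exp_sum[b] += v
                exp_sq[b] += v * v
                exp_cnt[b] += 1
    with np.errstate(invalid="ignore"):
        exp_mad = exp_sum / np.maximum(exp_cnt, 1)
        exp_std = np.sqrt(
            np.maximum(exp_sq / np.maximum(exp_cnt, 1) - exp_mad**2, 0.0)
        )
    return pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "lo": edges[:-1],
            "hi": edges[1:],
            "n_deviations": obs_n,
            "observed_mad": obs_mad,
            "expected_mad": np.where(exp_cnt > 0, exp_mad, np.nan),
            "expected_std": np.where(exp_cnt > 0, exp_std, np.nan),
            "empty": obs_n == 0,
        }
    )
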