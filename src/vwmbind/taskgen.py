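"""Synthetic dual-report experiments.

Generates stimulus arrays matching the task design the analyses expect —
six-item arrays of colored oriented bars on an invisible circle, with
minimum angular separations within each feature dimension (20 degrees for
color and location, 10 degrees for native orientation, i.e. 20 degrees in
doubled orientation space), two retention-interval conditions randomly
interleaved and balanced within blocks, and 216 trials per participant —
and simulates responses from either a descriptive mixture-model ground
truth or the generative neural binding model.

Orientations are handled in doubled space throughout, so the default
minimum separation is pi/9 radians in every dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circstats import wrap
from .dataset import DELAY_LEVELS, Dataset

MIN_SEP_DEFAULT = np.pi / 9.0  # 20 degrees (10 degrees native orientation)
MAX_REJECTION_ATTEMPTS = 10_000

__all__ = [
    "ExperimentDesign",
    "MixtureGroundTruth",
    "exp1_design",
    "exp2_design",
    "generate_array",
    "generate_experiment",
    "generate_multi_participant",
    "simulate_responses_mixture",
    "simulate_responses_popmodel",
    "inject_cue_nearest_swaps",
    "DEFAULT_POPULATION_PARAMS",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Stimulus/task design of one dual-report experiment."""

    cue_dim: str
    report_dims: tuple[str, str]
    n_items: int = 6
    n_trials: int = 216
    trials_per_block: int = 36
    min_sep: dict = field(
        default_factory=lambda: {
            "location": MIN_SEP_DEFAULT,
            "color": MIN_SEP_DEFAULT,
            "orientation": MIN_SEP_DEFAULT,  # doubled space
        }
    )
    delay_levels: tuple[str, ...] = DELAY_LEVELS
    delay_props: tuple[float, ...] = (0.5, 0.5)

    def __post_init__(self):
        for dim, sep in self.min_sep.items():
            if self.n_items * sep >= 2.0 * np.pi:
                raise ValueError(
                    f"infeasible design: {self.n_items} items with minimum "
                    f"separation {sep:.4f} rad in {dim} exceed the circle"
                )
        if abs(sum(self.delay_props) - 1.0) > 1e-9:
            raise ValueError("delay proportions must sum to 1")


def exp1_design(**overrides) -> ExperimentDesign:
    """Location-cue task: report color then orientation."""
    return ExperimentDesign(
        cue_dim="location", report_dims=("color", "orientation"), **overrides
    )


def exp2_design(**overrides) -> ExperimentDesign:
    """Orientation-cue task: report color then location."""
    return ExperimentDesign(
        cue_dim="orientation", report_dims=("color", "location"), **overrides
    )


@dataclass(frozen=True)
class MixtureGroundTruth:
    """Generative mixture over response-type pairs.

    ``proportions`` maps labels over {T, N, U} pairs (with the both-nontarget
    case split into matched ``NNs`` and mismatched ``NNd``) to probabilities.
    T responses are von Mises around the target feature, N responses von
    Mises around a uniformly chosen nontarget's feature (same concentration),
    U responses uniform.
    """

    kappa1: float
    kappa2: float
    proportions: dict

    _LABELS = ("TT", "TN", "TU", "NT", "NNs", "NNd", "NU", "UT", "UN", "UU")

    def __post_init__(self):
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("concentrations must be positive")
        bad = set(self.proportions) - set(self._LABELS)
        if bad:
            raise ValueError(f"unknown component labels {bad}")
        p = np.array([self.proportions.get(k, 0.0) for k in self._LABELS])
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")

    def vector(self) -> np.ndarray:
        return np.array([self.proportions.get(k, 0.0) for k in self._LABELS])


from .popmodel import PopulationParams  # noqa: E402  (avoid cycle at import)

#: Canonical generative parameters used for model-based synthetic studies.
DEFAULT_POPULATION_PARAMS = PopulationParams(
    gamma=100.0, kappa_loc=8.0, kappa_col=4.0, kappa_ori=4.0
)


def _sample_separated(
    n_items: int, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform angles conditioned on pairwise separation, by rejection."""
    for _ in range(MAX_REJECTION_ATTEMPTS):
        a = np.sort(rng.uniform(-np.pi, np.pi, n_items))
        gaps = np.diff(np.concatenate([a, [a[0] + 2.0 * np.pi]]))
        if n_items == 1 or np.min(gaps) >= min_sep:
            return rng.permutation(a)
    raise RuntimeError(
        f"rejection sampling failed after {MAX_REJECTION_ATTEMPTS} attempts"
    )


def generate_array(design: ExperimentDesign, rng: np.random.Generator) -> Dataset:
    """One stimulus array (single-trial dataset, no responses)."""
    feats = {
        dim: _sample_separated(design.n_items, design.min_sep[dim], rng)
        for dim in ("location", "color", "orientation")
    }
    return Dataset(
        locations=feats["location"][None, :],
        colors=feats["color"][None, :],
        orientations=feats["orientation"][None, :],
        cue_dim=design.cue_dim,
        report_dims=design.report_dims,
        target_index=np.array([rng.integers(design.n_items)]),
        delay=np.array([design.delay_levels[0]], dtype=object),
        meta={"min_sep": dict(design.min_sep)},
    )


def generate_experiment(
    design: ExperimentDesign,
    rng: np.random.Generator,
    participant: int = 0,
) -> Dataset:
    """A full experiment for one participant (no responses).

    Delay conditions are balanced and randomly interleaved within each
    block.  Each trial uses its own child random stream (spawned from
    ``rng``), so the generated stimuli do not depend on trial order.
    """
    if design.n_trials % design.trials_per_block != 0:
        raise ValueError("n_trials must be divisible by trials_per_block")
    counts = [
        design.trials_per_block * p for p in design.delay_props
    ]
    if any(abs(c - round(c)) > 1e-9 for c in counts):
        raise ValueError("delay proportions do not balance within a block")
    n_blocks = design.n_trials // design.trials_per_block
    struct_rng = rng.spawn(1)[0]
    trial_rngs = rng.spawn(design.n_trials)
    delays, blocks = [], []
    for b in range(n_blocks):
        lab = np.repeat(
            np.array(design.delay_levels, dtype=object),
            [int(round(c)) for c in counts],
        )
        struct_rng.shuffle(lab)
        delays.append(lab)
        blocks.append(np.full(design.trials_per_block, b))
    delays = np.concatenate(delays)
    blocks = np.concatenate(blocks)
    targets = struct_rng.integers(design.n_items, size=design.n_trials)
    loc = np.empty((design.n_trials, design.n_items))
    col = np.empty_like(loc)
    ori = np.empty_like(loc)
    for t, trng in enumerate(trial_rngs):
        loc[t] = _sample_separated(design.n_items, design.min_sep["location"], trng)
        col[t] = _sample_separated(design.n_items, design.min_sep["color"], trng)
        ori[t] = _sample_separated(design.n_items, design.min_sep["orientation"], trng)
    return Dataset(
        locations=loc,
        colors=col,
        orientations=ori,
        cue_dim=design.cue_dim,
        report_dims=design.report_dims,
        target_index=targets,
        delay=delays,
        participant=np.full(design.n_trials, participant),
        block=blocks,
        meta={"min_sep": dict(design.min_sep)},
    )


def generate_multi_participant(
    design: ExperimentDesign, n_participants: int, rng: np.random.Generator
) -> Dataset:
    """Concatenated experiments for several participants."""
    parts = [
        generate_experiment(design, child, participant=p)
        for p, child in enumerate(rng.spawn(n_participants))
    ]
    return Dataset.concatenate(parts)


def simulate_responses_mixture(
    dataset: Dataset, truth: MixtureGroundTruth, rng: np.random.Generator
) -> Dataset:
    """Draw responses from a mixture-model ground truth."""
    n, N = dataset.n_trials, dataset.n_items
    labels = np.array(truth._LABELS)
    if truth.proportions.get("NNd", 0.0) > 0 and N < 3:
        raise ValueError("NNd components require at least 3 items")
    comp = rng.choice(len(labels), size=n, p=truth.vector())
    resp = np.empty((n, 2))
    nt1 = dataset.nontarget_features(dataset.report_dims[0])
    nt2 = dataset.nontarget_features(dataset.report_dims[1])
    tgt1 = dataset.target_feature(dataset.report_dims[0])
    tgt2 = dataset.target_feature(dataset.report_dims[1])
    # pre-draw nontarget picks: shared index, and a distinct second index
    j1 = rng.integers(N - 1, size=n)
    j2 = (j1 + 1 + rng.integers(N - 2, size=n)) % (N - 1) if N >= 3 else j1
    lab = labels[comp]
    for r, (kappa, tgt, nt) in enumerate(
        [(truth.kappa1, tgt1, nt1), (truth.kappa2, tgt2, nt2)]
    ):
        # response-type letter for this report ("NNs"/"NNd" both read as N)
        code = np.array([la[0] if r == 0 else la[1] for la in lab])
        noise = rng.vonmises(0.0, kappa, size=n)
        uni = rng.uniform(-np.pi, np.pi, size=n)
        if r == 0:
            nt_pick = nt[np.arange(n), j1]
        else:
            idx = np.where(lab == "NNd", j2, j1)
            nt_pick = nt[np.arange(n), idx]
        resp[:, r] = np.where(
            code == "T",
            wrap(tgt + noise),
            np.where(code == "N", wrap(nt_pick + noise), uni),
        )
    return dataset.with_responses(resp)


def simulate_responses_popmodel(
    dataset: Dataset,
    params: PopulationParams | None = None,
    variant: str = "spatial",
    rng: np.random.Generator | None = None,
    grid=None,
) -> Dataset:
    """Draw responses from the neural binding model."""
    from . import popmodel

    if params is None:
        params = DEFAULT_POPULATION_PARAMS
    if rng is None:
        rng = np.random.default_rng()
    kwargs = {} if grid is None else {"grid": grid}
    resp = popmodel.simulate_reports(dataset, params, variant, rng, **kwargs)
    return dataset.with_responses(resp)


def inject_cue_nearest_swaps(
    dataset: Dataset,
    fraction: float,
    kappa: float,
    rng: np.random.Generator,
    report: int = 0,
) -> Dataset:
    """Replace a fraction of responses with cue-nearest-nontarget swaps.

    Calibration utility: in the chosen trials, the response of ``report``
    is redrawn as a von Mises around the report feature of the nontarget
    whose cue-dimension feature is closest to the target's — the signature
    of cue-similarity-driven swap errors.
    """
    if dataset.responses is None:
        raise ValueError("dataset has no responses")
    n = dataset.n_trials
    pick = rng.random(n) < fraction
    cue_t = dataset.target_feature(dataset.cue_dim)
    cue_nt = dataset.nontarget_features(dataset.cue_dim)
    nearest = np.argmin(np.abs(wrap(cue_nt - cue_t[:, None])), axis=1)
    rep_nt = dataset.nontarget_features(dataset.report_dims[report])
    swap_val = rep_nt[np.arange(n), nearest]
    resp = dataset.responses.copy()
    resp[pick, report] = wrap(swap_val[pick] + rng.vonmises(0.0, kappa, pick.sum()))
    return dataset.with_responses(resp)
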