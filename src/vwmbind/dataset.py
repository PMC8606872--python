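"""Trial-level container for dual-report working-memory experiments.

A :class:`Dataset` holds one or more participants' trials from a single task
configuration: arrays of item feature angles (location, color, orientation —
orientation in doubled space), the cue dimension, the target index, the delay
condition, and (optionally) the two continuous reports in report order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .circstats import circ_dist, wrap

FEATURE_DIMS = ("location", "color", "orientation")
DELAY_LEVELS = ("short", "long")

__all__ = ["Dataset", "FEATURE_DIMS", "DELAY_LEVELS"]


@dataclass
class Dataset:
    """Trials of a dual-report experiment.

    Parameters
    ----------
    locations, colors, orientations
        ``(n_trials, n_items)`` feature angles in radians, wrapped to
        ``[-pi, pi)``.  Orientations are stored in doubled space (native
        orientation times two).
    cue_dim
        Feature dimension used to indicate the target (``"location"`` for
        the location-cue task, ``"orientation"`` for the orientation-cue
        task).
    report_dims
        The two reported dimensions in report order, e.g.
        ``("color", "orientation")``.
    target_index
        ``(n_trials,)`` 0-based index of the cued item.
    delay
        ``(n_trials,)`` array of ``"short"`` / ``"long"`` labels.
    responses
        ``(n_trials, 2)`` reported values in report order (doubled space for
        orientation reports), or ``None`` for stimulus-only datasets.
    """

    locations: np.ndarray
    colors: np.ndarray
    orientations: np.ndarray
    cue_dim: str
    report_dims: tuple[str, str]
    target_index: np.ndarray
    delay: np.ndarray
    responses: np.ndarray | None = None
    participant: np.ndarray | None = None
    block: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.locations = wrap(np.atleast_2d(np.asarray(self.locations, float)))
        self.colors = wrap(np.atleast_2d(np.asarray(self.colors, float)))
        self.orientations = wrap(np.atleast_2d(np.asarray(self.orientations, float)))
        n, N = self.locations.shape
        if self.colors.shape != (n, N) or self.orientations.shape != (n, N):
            raise ValueError("feature arrays must share shape (n_trials, n_items)")
        if self.cue_dim not in FEATURE_DIMS:
            raise ValueError(f"unknown cue dimension {self.cue_dim!r}")
        self.report_dims = tuple(self.report_dims)
        if len(self.report_dims) != 2 or any(
            d not in FEATURE_DIMS for d in self.report_dims
        ):
            raise ValueError(f"invalid report dimensions {self.report_dims!r}")
        self.target_index = np.asarray(self.target_index, int)
        if self.target_index.shape != (n,):
            raise ValueError("target_index must have shape (n_trials,)")
        if np.any((self.target_index < 0) | (self.target_index >= N)):
            raise ValueError("target_index out of range")
        self.delay = np.asarray(self.delay, dtype=object)
        if self.delay.shape != (n,):
            raise ValueError("delay must have shape (n_trials,)")
        bad = set(self.delay) - set(DELAY_LEVELS)
        if bad:
            raise ValueError(f"unknown delay levels {bad}")
        if self.responses is not None:
            self.responses = wrap(np.asarray(self.responses, float))
            if self.responses.shape != (n, 2):
                raise ValueError("responses must have shape (n_trials, 2)")
        if self.participant is None:
            self.participant = np.zeros(n, int)
        else:
            self.participant = np.asarray(self.participant, int)
        if self.block is None:
            self.block = np.zeros(n, int)
        else:
            self.block = np.asarray(self.block, int)

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.locations.shape[0]

    @property
    def n_items(self) -> int:
        return self.locations.shape[1]

    def features(self, dim: str) -> np.ndarray:
        """(n_trials, n_items) feature angles for one dimension."""
        return {
            "location": self.locations,
            "color": self.colors,
            "orientation": self.orientations,
        }[dim]

    def target_feature(self, dim: str) -> np.ndarray:
        """(n_trials,) target feature value in one dimension."""
        f = self.features(dim)
        return f[np.arange(self.n_trials), self.target_index]

    def nontarget_features(self, dim: str) -> np.ndarray:
        """(n_trials, n_items - 1) nontarget feature values, array order."""
        f = self.features(dim)
        n, N = f.shape
        mask = np.ones((n, N), bool)
        mask[np.arange(n), self.target_index] = False
        return f[mask].reshape(n, N - 1)

    def cue_values(self) -> np.ndarray:
        return self.target_feature(self.cue_dim)

    # -- responses ------------------------------------------------------
    def errors(self, report: int) -> np.ndarray:
        """(n_trials,) signed response error of report 0 or 1 w.r.t. target."""
        if self.responses is None:
            raise ValueError("dataset has no responses")
        dim = self.report_dims[report]
        return circ_dist(self.responses[:, report], self.target_feature(dim))

    def with_responses(self, responses: np.ndarray) -> "Dataset":
        return replace(self, responses=np.asarray(responses, float))

    # -- slicing --------------------------------------------------------
    def subset(self, mask) -> "Dataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Dataset(
            locations=self.locations[idx],
            colors=self.colors[idx],
            orientations=self.orientations[idx],
            cue_dim=self.cue_dim,
            report_dims=self.report_dims,
            target_index=self.target_index[idx],
            delay=self.delay[idx],
            responses=None if self.responses is None else self.responses[idx],
            participant=self.participant[idx],
            block=self.block[idx],
            meta=dict(self.meta),
        )

    def by_participant(self):
        """Yield (participant_id, sub-dataset) in id order."""
        for pid in np.unique(self.participant):
            yield int(pid), self.subset(self.participant == pid)

    def by_delay(self):
        for level in DELAY_LEVELS:
            mask = self.delay == level
            if mask.any():
                yield level, self.subset(mask)

    @staticmethod
    def concatenate(datasets: list["Dataset"]) -> "Dataset":
        first = datasets[0]
        for d in datasets[1:]:
            if d.cue_dim != first.cue_dim or d.report_dims != first.report_dims:
                raise ValueError("cannot concatenate datasets from different tasks")
        has_resp = all(d.responses is not None for d in datasets)
        return Dataset(
            locations=np.concatenate([d.locations for d in datasets]),
            colors=np.concatenate([d.colors for d in datasets]),
            orientations=np.concatenate([d.orientations for d in datasets]),
            cue_dim=first.cue_dim,
            report_dims=first.report_dims,
            target_index=np.concatenate([d.target_index for d in datasets]),
            delay=np.concatenate([d.delay for d in datasets]),
            responses=(
                np.concatenate([d.responses for d in datasets]) if has_resp else None
            ),
            participant=np.concatenate([d.participant for d in datasets]),
            block=np.concatenate([d.block for d in datasets]),
            meta=dict(first.meta),
        )
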