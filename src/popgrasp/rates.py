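"""Smoothed, event-aligned firing-rate tensors.

Spike trains are converted to firing rates by summing a Gaussian kernel
(SD 57 ms by default) over spikes, evaluated on a regular grid in each of
three alignments: cue onset, movement onset and reward.  The kernel is
truncated at +/-4 SD and renormalized (mass loss < 0.01%); spikes are drawn
from an extended window so smoothing carries no boundary bias.  The three
alignment axes are kept separate and concatenated only explicitly — clusters
and components never silently bridge the variable-length gaps between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import N_CONDITIONS, SpikeDataset, condition_table

_EVENT_COLUMNS = {
    "cue_onset": "t_cue_on_ms",
    "movement_onset": "t_move_on_ms",
    "reward": "t_reward_ms",
}


@dataclass(frozen=True)
class AlignmentSpec:
    """A window (pre_ms, post_ms) around a trial event, sampled every step_ms."""

    event: str
    pre_ms: float
    post_ms: float
    step_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.event not in _EVENT_COLUMNS:
            raise ValueError(f"unknown alignment event {self.event!r}")
        if self.pre_ms >= self.post_ms:
            raise ValueError("pre_ms must be < post_ms")
        if self.step_ms <= 0:
            raise ValueError("step_ms must be positive")

    @property
    def event_column(self) -> str:
        return _EVENT_COLUMNS[self.event]

    def time_grid(self) -> np.ndarray:
        return np.arange(self.pre_ms, self.post_ms + 0.5 * self.step_ms, self.step_ms)


def default_alignments(step_ms: float = 10.0) -> list[AlignmentSpec]:
    """Cue [-300, +1100], movement [-500, +500], reward [-300, +500] ms."""
    return [
        AlignmentSpec("cue_onset", -300.0, 1100.0, step_ms),
        AlignmentSpec("movement_onset", -500.0, 500.0, step_ms),
        AlignmentSpec("reward", -300.0, 500.0, step_ms),
    ]


def smooth_unit_rate(
    spike_times_ms: np.ndarray,
    t_grid_ms: np.ndarray,
    kernel_sd_ms: float = 57.0,
    truncate_sd: float = 4.0,
) -> np.ndarray:
    """Firing rate (Hz) at grid times from one spike train.

    rate(t) = sum_spikes N(t - t_spike; sd), with the Gaussian truncated at
    +/- ``truncate_sd`` SD and renormalized.  An empty spike list yields an
    all-zero rate.
    """
    t = np.asarray(t_grid_ms, dtype=float)
    s = np.asarray(spike_times_ms, dtype=float)
    if s.size == 0:
        return np.zeros_like(t)
    from scipy.special import erf

    mass = erf(truncate_sd / np.sqrt(2.0))  # kernel mass inside +/-trunc SD
    d = (t[None, :] - s[:, None]) / kernel_sd_ms
    k = np.exp(-0.5 * d * d)
    k[np.abs(d) > truncate_sd] = 0.0
    norm = 1000.0 / (kernel_sd_ms * np.sqrt(2.0 * np.pi) * mass)  # per-ms -> Hz
    return norm * k.sum(axis=0)


@dataclass
class RateTensor:
    """Smoothed firing rates over the concatenated alignment axes.

    ``values`` is (n_units, n_trials, T) in single-trial mode or
    (n_units, 20, T) trial-averaged, with T the total sample count over the
    alignments.  ``segments`` holds the (start, stop) column range of each
    alignment; operations that scan time (cluster extraction, decoding
    contiguity) respect these boundaries.
    """

    values: np.ndarray
    alignments: list
    unit_ids: np.ndarray
    mode: str  # "single_trial" | "trial_averaged"
    trial_conditions: np.ndarray | None = None  # condition per trial row
    trial_ids: np.ndarray | None = None
    conditions: pd.DataFrame = field(default_factory=condition_table)

    def __post_init__(self) -> None:
        if self.mode not in ("single_trial", "trial_averaged"):
            raise ValueError("mode must be single_trial or trial_averaged")

    # -------------------------------------------------------------- axes
    @property
    def time_grids(self) -> list[np.ndarray]:
        return [a.time_grid() for a in self.alignments]

    @property
    def time_ms(self) -> np.ndarray:
        return np.concatenate(self.time_grids)

    @property
    def segments(self) -> list[tuple[int, int]]:
        bounds, start = [], 0
        for g in self.time_grids:
            bounds.append((start, start + len(g)))
            start += len(g)
        return bounds

    @property
    def n_time(self) -> int:
        return self.values.shape[-1]

    @property
    def step_ms(self) -> float:
        return float(self.alignments[0].step_ms)

    # ------------------------------------------------------- conversions
    def average_conditions(self) -> "RateTensor":
        """Average single-trial rates within each of the 20 conditions."""
        if self.mode == "trial_averaged":
            return self
        vals = np.empty((self.values.shape[0], N_CONDITIONS, self.n_time))
        for c in range(N_CONDITIONS):
            m = self.trial_conditions == c
            if not m.any():
                row = self.conditions.loc[c]
                raise ValueError(
                    f"condition {c} ({row['hand']}, {row['grip']}, "
                    f"{row['orientation_deg']} deg) has zero trials"
                )
            vals[:, c, :] = self.values[:, m, :].mean(axis=1)
        return RateTensor(
            values=vals,
            alignments=self.alignments,
            unit_ids=self.unit_ids,
            mode="trial_averaged",
            conditions=self.conditions,
        )

    def as_matrix(self) -> np.ndarray:
        """Trial-averaged data as (units, conditions*time) — the matrix X."""
        if self.mode != "trial_averaged":
            raise ValueError("as_matrix requires a trial-averaged tensor")
        n_u = self.values.shape[0]
        return self.values.reshape(n_u, -1)

    def condition_tensor(self) -> np.ndarray:
        """Trial-averaged data reshaped to (units, 2, 2, 5, T)."""
        if self.mode != "trial_averaged":
            raise ValueError("condition_tensor requires a trial-averaged tensor")
        n_u = self.values.shape[0]
        return self.values.reshape(n_u, 2, 2, 5, self.n_time)

    # --------------------------------------------------------------- I/O
    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=self.values)
            fh.create_dataset("unit_ids", data=np.asarray(self.unit_ids))
            fh.attrs["mode"] = self.mode
            for i, a in enumerate(self.alignments):
                grp = fh.create_group(f"alignment/{i}")
                grp.attrs.update(
                    event=a.event, pre_ms=a.pre_ms, post_ms=a.post_ms, step_ms=a.step_ms
                )
            if self.trial_conditions is not None:
                fh.create_dataset("trial_conditions", data=self.trial_conditions)
            if self.trial_ids is not None:
                fh.create_dataset("trial_ids", data=np.asarray(self.trial_ids))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "RateTensor":
        with h5py.File(path, "r") as fh:
            aligns = []
            for i in sorted(fh["alignment"], key=int):
                at = fh[f"alignment/{i}"].attrs
                aligns.append(
                    AlignmentSpec(
                        str(at["event"]),
                        float(at["pre_ms"]),
                        float(at["post_ms"]),
                        float(at["step_ms"]),
                    )
                )
            return cls(
                values=fh["values"][()],
                alignments=aligns,
                unit_ids=fh["unit_ids"][()],
                mode=str(fh.attrs["mode"]),
                trial_conditions=fh["trial_conditions"][()]
                if "trial_conditions" in fh
                else None,
                trial_ids=fh["trial_ids"][()] if "trial_ids" in fh else None,
            )


# --------------------------------------------------------------------------
# building tensors from spikes
# --------------------------------------------------------------------------
class _SpikeIndex:
    """Spikes sorted by (unit, trial) with O(1) slice lookup."""

    def __init__(self, dataset: SpikeDataset):
        sp = dataset.spikes
        self.units = np.asarray(dataset.unit_ids)
        self.trial_ids = dataset.trials["trial_id"].to_numpy()
        u_idx = np.searchsorted(np.sort(self.units), sp["unit_id"].to_numpy())
        u_order = np.argsort(self.units)
        # map sorted-position back to canonical unit position
        u_pos = np.empty_like(u_order)
        u_pos[np.arange(len(u_order))] = u_order
        t_sorter = np.argsort(self.trial_ids, kind="stable")
        t_idx = t_sorter[
            np.searchsorted(self.trial_ids[t_sorter], sp["trial_id"].to_numpy())
        ]
        n_tr = len(self.trial_ids)
        key = u_pos[u_idx] * n_tr + t_idx
        order = np.lexsort((sp["spike_time_ms"].to_numpy(), key))
        self.key = key[order]
        self.times = sp["spike_time_ms"].to_numpy()[order]
        self.n_tr = n_tr

    def spikes_of(self, unit_pos: int, trial_pos: int) -> np.ndarray:
        k = unit_pos * self.n_tr + trial_pos
        lo = np.searchsorted(self.key, k, "left")
        hi = np.searchsorted(self.key, k, "right")
        return self.times[lo:hi]

    def unit_slice(self, unit_pos: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.key, unit_pos * self.n_tr, "left")
        hi = np.searchsorted(self.key, (unit_pos + 1) * self.n_tr, "left")
        return self.key[lo:hi] - unit_pos * self.n_tr, self.times[lo:hi]


def unit_rate_matrix(
    index: "_SpikeIndex | SpikeDataset",
    dataset: SpikeDataset,
    unit_pos: int,
    alignments: list[AlignmentSpec],
    kernel_sd_ms: float = 57.0,
    truncate_sd: float = 4.0,
) -> np.ndarray:
    """Single-trial rates (n_trials, T_total) for one unit.

    Vectorized over trials: per alignment, spikes of all trials are pooled
    relative to the trial event and smoothed in one pass.
    """
    if isinstance(index, SpikeDataset):
        index = _SpikeIndex(index)
    from scipy.special import erf

    mass = erf(truncate_sd / np.sqrt(2.0))
    norm = 1000.0 / (kernel_sd_ms * np.sqrt(2.0 * np.pi) * mass)
    pad = truncate_sd * kernel_sd_ms
    n_tr = len(dataset.trials)
    trial_keys, times = index.unit_slice(unit_pos)

    blocks = []
    for a in alignments:
        grid = a.time_grid()
        events = dataset.trials[a.event_column].to_numpy()
        rate = np.zeros((n_tr, len(grid)))
        ev = events[trial_keys]
        rel = times - ev
        m = (rel >= a.pre_ms - pad) & (rel <= a.post_ms + pad)
        rel, keys = rel[m], trial_keys[m]
        if len(rel):
            d = (grid[None, :] - rel[:, None]) / kernel_sd_ms
            k = np.exp(-0.5 * d * d)
            k[np.abs(d) > truncate_sd] = 0.0
            # spikes are ordered by trial; segment-sum rows per trial
            bounds = np.flatnonzero(np.r_[True, np.diff(keys) != 0])
            sums = np.add.reduceat(k, bounds, axis=0)
            rate[keys[bounds]] = norm * sums
        blocks.append(rate)
    return np.concatenate(blocks, axis=1)


def build_rate_tensor(
    dataset: SpikeDataset,
    alignments: list[AlignmentSpec] | None = None,
    mode: str = "single_trial",
    kernel_sd_ms: float = 57.0,
) -> RateTensor:
    """Smooth a spike dataset into a RateTensor.

    Trial-averaged mode averages single-trial rates within each of the 20
    conditions and raises if any condition has zero trials.
    """
    if alignments is None:
        alignments = default_alignments()
    for a in alignments:
        if dataset.trials[a.event_column].isna().any():
            raise ValueError(f"missing event times for alignment {a.event!r}")
    index = _SpikeIndex(dataset)
    n_units = dataset.n_units
    t_total = sum(len(a.time_grid()) for a in alignments)
    values = np.empty((n_units, len(dataset.trials), t_total))
    for u in range(n_units):
        values[u] = unit_rate_matrix(index, dataset, u, alignments, kernel_sd_ms)
    tensor = RateTensor(
        values=values,
        alignments=list(alignments),
        unit_ids=np.asarray(dataset.unit_ids),
        mode="single_trial",
        trial_conditions=dataset.condition_of_trials(),
        trial_ids=dataset.trials["trial_id"].to_numpy(),
    )
    if mode == "trial_averaged":
        return tensor.average_conditions()
    return tensor


def exclude_unstable(dataset: SpikeDataset, min_trials: int = 5) -> SpikeDataset:
    """Keep only units recorded for >= min_trials in every condition.

    Implements the stable-recording inclusion gate: a unit enters the
    database only with at least 5 trials in each of the 20 conditions.
    """
    cond = dataset.condition_of_trials()
    keep = []
    for uid in dataset.unit_ids:
        t = dataset.trials_of_unit(uid)
        if len(t) == 0:
            continue
        c = dataset.condition_of_trials(t)
        counts = np.bincount(c, minlength=N_CONDITIONS)
        if (counts >= min_trials).all():
            keep.append(uid)
    keep_arr = np.asarray(keep, dtype=np.asarray(dataset.unit_ids).dtype)
    spikes = dataset.spikes[dataset.spikes["unit_id"].isin(keep_arr)]
    return SpikeDataset(
        spikes=spikes.reset_index(drop=True),
        trials=dataset.trials,
        unit_ids=keep_arr,
        hemisphere=dataset.hemisphere,
        unit_trials=None
        if dataset.unit_trials is None
        else {u: dataset.unit_trials[u] for u in keep},
    )
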