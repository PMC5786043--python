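"""Single-trial decoding of task factors along demixed component axes.

Units are not recorded simultaneously, so test "trials" are pseudo-trials:
one held-out trial per unit per condition stitched into a population vector.
Each of the (default 100) Monte-Carlo iterations holds out one random trial
per unit/condition, averages the rest into a training set, fits dPCA on the
training averages and uses the factor's leading demixed axis as a linear
classifier: a test pseudo-trial is projected on the axis at every time point
and assigned to the class whose training-mean projection is nearest.

Chance is estimated from (default 100) shuffles in which each unit's trials
are permuted across conditions (respecting the per-condition trial counts)
before the identical pipeline is re-run.  Decoding is significant where the
real accuracy exceeds every shuffle value on all iterations for at least
200 ms contiguously (within one alignment window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import N_CONDITIONS, condition_table
from .dpca import DemixedPCA
from .rates import RateTensor


def factor_classes(factor: str) -> np.ndarray:
    """Class index of each of the 20 conditions for a (compound) factor.

    ``factor`` is a marginalization-style tag: "hand", "grip",
    "orientation", or a compound like "hand:orientation" decoded as the
    product classes.
    """
    table = condition_table()
    cols = {
        "hand": table["hand"],
        "grip": table["grip"],
        "orientation": table["orientation_deg"],
    }
    parts = factor.split(":")
    for p in parts:
        if p not in cols:
            raise ValueError(f"unknown factor {p!r}")
    keys = list(zip(*[cols[p] for p in parts]))
    uniq = sorted(set(keys), key=lambda k: keys.index(k))
    return np.array([uniq.index(k) for k in keys])


def split_pseudotrials(
    tensor: RateTensor, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One stratified Monte-Carlo leave-group-out split.

    Returns ``X_train`` (units, 20, T) — the average of the non-held-out
    trials — and ``X_test`` (units, 20, T) — one held-out trial per unit and
    condition — plus the held-out trial row index per (unit, condition).
    """
    if tensor.mode != "single_trial":
        raise ValueError("split requires single-trial rates")
    vals = tensor.values
    conds = tensor.trial_conditions
    n_units, _, T = vals.shape
    X_train = np.empty((n_units, N_CONDITIONS, T))
    X_test = np.empty((n_units, N_CONDITIONS, T))
    held = np.empty((n_units, N_CONDITIONS), dtype=int)
    for c in range(N_CONDITIONS):
        idx = np.flatnonzero(conds == c)
        if len(idx) < 2:
            row = tensor.conditions.loc[c]
            raise ValueError(
                f"condition {c} ({row['hand']}, {row['grip']}, "
                f"{row['orientation_deg']} deg) has < 2 trials"
            )
        choice = rng.integers(0, len(idx), size=n_units)
        for u in range(n_units):
            hold = idx[choice[u]]
            rest = idx[idx != hold]
            held[u, c] = hold
            X_test[u, c] = vals[u, hold]
            X_train[u, c] = vals[u, rest].mean(axis=0)
    return X_train, X_test, held


def classify_on_component(
    axis: np.ndarray,
    X_train_c: np.ndarray,
    X_test_c: np.ndarray,
    classes: np.ndarray,
) -> np.ndarray:
    """Nearest-training-mean classification along one decoder axis.

    Inputs are centered tensors (units, 20, T); returns the per-time-point
    accuracy (T,) over the 20 test pseudo-trial conditions.  Distance ties
    resolve to the lowest class index.
    """
    p_train = np.einsum("u,uct->ct", axis, X_train_c)
    p_test = np.einsum("u,uct->ct", axis, X_test_c)
    n_classes = classes.max() + 1
    means = np.stack(
        [p_train[classes == k].mean(axis=0) for k in range(n_classes)]
    )  # (K, T)
    dist = np.abs(p_test[None, :, :] - means[:, None, :])  # (K, C, T)
    pred = np.argmin(dist, axis=0)
    return (pred == classes[:, None]).mean(axis=0)


def _one_iteration(
    tensor: RateTensor,
    factor: str,
    classes: np.ndarray,
    reg: float,
    rng: np.random.Generator,
) -> np.ndarray:
    X_train, X_test, _ = split_pseudotrials(tensor, rng)
    model = DemixedPCA(X_train, marginalizations=[factor])
    res = model.fit(n_components=1, reg=reg)
    means = res.unit_means[:, None, None]
    return classify_on_component(
        res.decoder[0], X_train - means, X_test - means, classes
    )


def decode_timecourse(
    tensor: RateTensor,
    factor: str,
    n_iter: int = 100,
    reg: float = 1e-6,
    seed: int = 0,
) -> np.ndarray:
    """Held-out accuracy time-series, one row per Monte-Carlo iteration."""
    classes = factor_classes(factor)
    out = np.empty((n_iter, tensor.n_time))
    for it in range(n_iter):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, it)))
        out[it] = _one_iteration(tensor, factor, classes, reg, rng)
    return out


def _shuffled_tensor(tensor: RateTensor, rng: np.random.Generator) -> RateTensor:
    """Independently permute each unit's trials across conditions."""
    vals = tensor.values.copy()
    n_units, n_trials, _ = vals.shape
    for u in range(n_units):
        vals[u] = vals[u, rng.permutation(n_trials)]
    return RateTensor(
        values=vals,
        alignments=tensor.alignments,
        unit_ids=tensor.unit_ids,
        mode="single_trial",
        trial_conditions=tensor.trial_conditions,
        trial_ids=tensor.trial_ids,
        conditions=tensor.conditions,
    )


def shuffle_null(
    tensor: RateTensor,
    factor: str,
    n_shuffles: int = 100,
    reg: float = 1e-6,
    seed: int = 0,
) -> np.ndarray:
    """Chance accuracy distribution from condition-label shuffles.

    Each shuffle permutes every unit's trials over conditions (trial counts
    per condition are untouched) and re-runs one full split/fit/classify
    pass.  Rows are (n_shuffles, T).
    """
    classes = factor_classes(factor)
    out = np.empty((n_shuffles, tensor.n_time))
    for sh in range(n_shuffles):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, sh)))
        shuffled = _shuffled_tensor(tensor, rng)
        out[sh] = _one_iteration(shuffled, factor, classes, reg, rng)
    return out


def significant_intervals(
    accuracy: np.ndarray,
    null: np.ndarray,
    time_ms: np.ndarray,
    step_ms: float,
    segments: list[tuple[int, int]] | None = None,
    min_duration_ms: float = 200.0,
) -> list[tuple[float, float]]:
    """Maximal runs where decoding beats chance on all iterations >= 200 ms.

    A sample counts when the minimum real accuracy across iterations exceeds
    the maximum shuffle accuracy; runs are confined to alignment segments
    and kept only if they span at least ``min_duration_ms``.
    """
    above = accuracy.min(axis=0) > null.max(axis=0)
    T = len(above)
    if segments is None:
        segments = [(0, T)]
    min_samples = int(np.ceil(min_duration_ms / step_ms))
    intervals = []
    for s, e in segments:
        i = s
        while i < e:
            if above[i]:
                j = i
                while j < e and above[j]:
                    j += 1
                if j - i >= min_samples:
                    intervals.append((float(time_ms[i]), float(time_ms[j - 1])))
                i = j
            else:
                i += 1
    return intervals


@dataclass
class DecodeRun:
    """Full decoding analysis for one factor."""

    factor: str
    accuracy: np.ndarray  # (n_iter, T)
    null: np.ndarray  # (n_shuffles, T)
    intervals: list = field(default_factory=list)
    time_ms: np.ndarray | None = None
    seed: int = 0

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    @property
    def chance_level(self) -> float:
        return float(self.null.mean())


def decode_factor(
    tensor: RateTensor,
    factor: str,
    n_iter: int = 100,
    n_shuffles: int = 100,
    reg: float = 1e-6,
    seed: int = 0,
    min_duration_ms: float = 200.0,
) -> DecodeRun:
    """Decode a factor end to end: accuracy, shuffle null, intervals."""
    acc = decode_timecourse(tensor, factor, n_iter, reg, seed)
    null = shuffle_null(tensor, factor, n_shuffles, reg, seed)
    intervals = significant_intervals(
        acc, null, tensor.time_ms, tensor.step_ms, tensor.segments, min_duration_ms
    )
    return DecodeRun(
        factor=factor,
        accuracy=acc,
        null=null,
        intervals=intervals,
        time_ms=tensor.time_ms,
        seed=seed,
    )
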