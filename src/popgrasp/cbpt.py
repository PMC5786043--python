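"""Cluster-based permutation test (CBPT) for per-unit factor tuning.

For each unit and task factor the test compares single-trial rate
time-courses between two trial groups: the two hands, the two grips, or the
preferred vs. non-preferred orientation (of the five orientations, the ones
with the highest/lowest across-trial mean activity between cue onset and
reward).  A pooled-variance independent-samples t-statistic is computed at
every time sample; contiguous sign-homogeneous runs whose |t| exceeds the
two-sided critical value at alpha form clusters, scored by the sum of |t|
(cluster mass).  The null distribution of the *largest* cluster mass is
built by randomly re-partitioning trials (1000 partitions by default); a
cluster is significant when its mass exceeds the (1 - p) null quantile.
Because orientation groups are themselves selected from the data, the
orientation null re-applies the preferred/non-preferred selection inside
every permutation, keeping the statistic exchangeable under the null.

The per-factor significance level is Bonferroni-divided by the number of
factors tested, so the family-wise false-positive rate over all factors and
time points stays below the designated level.  Clusters never span the
boundary between alignment windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import FACTORS, SpikeDataset
from .rates import AlignmentSpec, _SpikeIndex, default_alignments, unit_rate_matrix

_FACTOR_COLUMNS = {"hand": "hand", "grip": "grip", "orientation": "orientation_deg"}


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------
@dataclass
class Cluster:
    start: int  # sample index, inclusive
    stop: int  # sample index, exclusive
    start_ms: float
    stop_ms: float
    mass: float
    sign: int
    p_value: float = np.nan


@dataclass
class PreferredLevels:
    factor: str
    preferred: object
    non_preferred: object
    tie: bool = False


@dataclass
class ClusterTestResult:
    factor: str
    clusters: list = field(default_factory=list)
    threshold_t: float = np.nan
    alpha: float = 0.05
    cluster_p: float = 0.05
    corrected_level: float = 0.05
    n_perm: int = 1000
    seed: int | None = None
    preferred: PreferredLevels | None = None

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c.p_value < self.corrected_level]

    @property
    def significant(self) -> bool:
        return len(self.significant_clusters) > 0

    def coverage(self, n_time: int) -> np.ndarray:
        """Boolean time mask covered by significant clusters."""
        cov = np.zeros(n_time, dtype=bool)
        for c in self.significant_clusters:
            cov[c.start : c.stop] = True
        return cov


# --------------------------------------------------------------------------
# elementary statistics
# --------------------------------------------------------------------------
def pointwise_tstat(trials_a: np.ndarray, trials_b: np.ndarray) -> np.ndarray:
    """Pooled-variance independent-samples t at each time sample.

    Both inputs are (n_trials, T).  Where both groups have zero variance the
    t value is defined as 0.
    """
    a = np.atleast_2d(np.asarray(trials_a, dtype=float))
    b = np.atleast_2d(np.asarray(trials_b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 trials per group")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def cluster_threshold(alpha: float, df: int) -> float:
    """Two-sided critical t value forming clusters."""
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def extract_clusters(
    t_series: np.ndarray,
    threshold: float,
    segments: list[tuple[int, int]] | None = None,
    time_ms: np.ndarray | None = None,
) -> list[Cluster]:
    """Maximal contiguous sign-homogeneous runs with |t| above threshold.

    A sign flip inside a super-threshold stretch splits the run into two
    clusters.  Runs never cross alignment-segment boundaries.
    """
    t = np.asarray(t_series, dtype=float)
    if segments is None:
        segments = [(0, len(t))]
    if time_ms is None:
        time_ms = np.arange(len(t), dtype=float)
    out: list[Cluster] = []
    for s, e in segments:
        i = s
        while i < e:
            if abs(t[i]) > threshold:
                sign = 1 if t[i] > 0 else -1
                j = i
                mass = 0.0
                while j < e and abs(t[j]) > threshold and (t[j] > 0) == (sign > 0):
                    mass += abs(t[j])
                    j += 1
                out.append(
                    Cluster(
                        start=i,
                        stop=j,
                        start_ms=float(time_ms[i]),
                        stop_ms=float(time_ms[j - 1]),
                        mass=mass,
                        sign=sign,
                    )
                )
                i = j
            else:
                i += 1
    return out


def _max_cluster_masses(
    t: np.ndarray, threshold: float, segments: list[tuple[int, int]]
) -> np.ndarray:
    """Largest sign-homogeneous cluster mass per row of a (P, T) t array."""
    P = t.shape[0]
    best = np.zeros(P)
    cur_p = np.zeros(P)
    cur_n = np.zeros(P)
    for s, e in segments:
        cur_p[:] = 0.0
        cur_n[:] = 0.0
        for i in range(s, e):
            col = t[:, i]
            cur_p = np.where(col > threshold, cur_p + col, 0.0)
            cur_n = np.where(col < -threshold, cur_n - col, 0.0)
            np.maximum(best, cur_p, out=best)
            np.maximum(best, cur_n, out=best)
    return best


def _perm_tstats(X, Xsq, mask_a, mask_b, na, nb):
    """t (P, T) from group-membership masks (float 0/1 matrices)."""
    sa = mask_a @ X
    qa = mask_a @ Xsq
    sb = mask_b @ X
    qb = mask_b @ Xsq
    ma = sa / na
    mb = sb / nb
    va = np.maximum(qa - sa * ma, 0.0) / (na - 1)
    vb = np.maximum(qb - sb * mb, 0.0) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0), 0.0)


def permutation_null(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    segments: list[tuple[int, int]] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of the largest cluster mass for a two-group test.

    Trials are pooled and randomly re-partitioned (preserving group sizes)
    ``n_perm`` times; each partition contributes its largest cluster mass
    (0 when no cluster forms).
    """
    a = np.atleast_2d(np.asarray(trials_a, dtype=float))
    b = np.atleast_2d(np.asarray(trials_b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    if na + nb < 4:
        raise ValueError("need at least 4 trials in total")
    X = np.vstack([a, b])
    if segments is None:
        segments = [(0, X.shape[1])]
    if rng is None:
        rng = np.random.default_rng()
    thr = cluster_threshold(alpha, na + nb - 2)
    Xsq = X * X
    n = na + nb
    perm = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    rows = np.arange(n_perm)[:, None]
    mask_a = np.zeros((n_perm, n))
    mask_a[rows, perm[:, :na]] = 1.0
    mask_b = 1.0 - mask_a
    t = _perm_tstats(X, Xsq, mask_a, mask_b, na, nb)
    return _max_cluster_masses(t, thr, segments)


def _orientation_perm_null(
    X: np.ndarray,
    labels: np.ndarray,
    selection: np.ndarray,
    n_perm: int,
    alpha: float,
    segments: list[tuple[int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Max-cluster-mass null for the preferred/non-preferred orientation test.

    Orientation labels are permuted over all trials (respecting level
    counts); the preferred and non-preferred levels are re-selected from the
    permuted cue-to-reward means before the t/cluster statistic is formed,
    so the extreme-level selection is part of the permuted statistic.
    """
    levels, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    if len(levels) < 2:
        raise ValueError("orientation test needs at least two levels")
    if not (counts == counts[0]).all():
        raise ValueError("orientation permutation requires balanced level counts")
    cnt = int(counts[0])
    n = len(labels)
    n_lev = len(levels)
    thr = cluster_threshold(alpha, 2 * cnt - 2)
    Xsq = X * X
    perm = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    # block b of each permuted order plays the role of orientation level b
    sel_perm = selection[perm].reshape(n_perm, n_lev, cnt)
    block_means = sel_perm.mean(axis=2)
    hi = np.argmax(block_means, axis=1)
    lo = np.argmin(block_means, axis=1)
    clash = hi == lo  # constant selection values; pick a distinct level
    lo[clash] = (hi[clash] + 1) % n_lev
    rows = np.arange(n_perm)[:, None]
    cols = np.arange(cnt)[None, :]
    idx_a = perm[rows, hi[:, None] * cnt + cols]
    idx_b = perm[rows, lo[:, None] * cnt + cols]
    mask_a = np.zeros((n_perm, n))
    mask_b = np.zeros((n_perm, n))
    mask_a[rows, idx_a] = 1.0
    mask_b[rows, idx_b] = 1.0
    t = _perm_tstats(X, Xsq, mask_a, mask_b, cnt, cnt)
    return _max_cluster_masses(t, thr, segments)


# --------------------------------------------------------------------------
# preferred levels
# --------------------------------------------------------------------------
def preferred_levels(
    selection_stat: np.ndarray, labels: np.ndarray, factor: str
) -> PreferredLevels:
    """Preferred / non-preferred level of a factor for one unit.

    ``selection_stat`` is the per-trial mean activity between cue onset and
    reward onset; it is averaged within each level, and the levels with the
    highest and lowest mean are preferred and non-preferred.  Ties resolve
    to the lowest level index and are flagged.
    """
    levels = list(FACTORS[factor])
    sel = np.asarray(selection_stat, dtype=float)
    means = np.full(len(levels), -np.inf)
    for i, lev in enumerate(levels):
        m = labels == lev
        if not m.any():
            raise ValueError(f"factor {factor!r} level {lev!r} has no trials")
        means[i] = sel[m].mean()
    hi = int(np.argmax(means))
    lo = int(np.argmin(means))
    tie = bool(np.isclose(means.max(), means.min()))
    if hi == lo:
        hi, lo = 0, 1
    return PreferredLevels(factor, levels[hi], levels[lo], tie=tie)


def cue_to_reward_mean(
    dataset: SpikeDataset, index: _SpikeIndex, unit_pos: int
) -> np.ndarray:
    """Per-trial mean firing rate (Hz) between cue onset and reward onset."""
    t0 = dataset.trials["t_cue_on_ms"].to_numpy()
    t1 = dataset.trials["t_reward_ms"].to_numpy()
    keys, times = index.unit_slice(unit_pos)
    counts = np.zeros(len(t0))
    inwin = (times >= t0[keys]) & (times < t1[keys])
    np.add.at(counts, keys[inwin], 1.0)
    return 1000.0 * counts / (t1 - t0)


# --------------------------------------------------------------------------
# the composed test
# --------------------------------------------------------------------------
def cbpt_test(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    alpha: float = 0.05,
    cluster_p: float = 0.05,
    n_factors: int = 1,
    n_perm: int = 1000,
    seed: int | None = None,
    segments: list[tuple[int, int]] | None = None,
    time_ms: np.ndarray | None = None,
    factor: str = "",
    null_masses: np.ndarray | None = None,
) -> ClusterTestResult:
    """Two-group CBPT: observed clusters scored against the max-mass null.

    The effective cluster significance level is ``cluster_p / n_factors``
    (Bonferroni over the factors tested per unit).
    """
    a = np.atleast_2d(np.asarray(trials_a, dtype=float))
    b = np.atleast_2d(np.asarray(trials_b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    thr = cluster_threshold(alpha, na + nb - 2)
    t_obs = pointwise_tstat(a, b)
    clusters = extract_clusters(t_obs, thr, segments, time_ms)
    if null_masses is None:
        rng = np.random.default_rng(seed)
        null_masses = permutation_null(a, b, n_perm, alpha, segments, rng)
    for c in clusters:
        c.p_value = (1.0 + np.sum(null_masses >= c.mass)) / (1.0 + len(null_masses))
    level = cluster_p / n_factors
    return ClusterTestResult(
        factor=factor,
        clusters=clusters,
        threshold_t=thr,
        alpha=alpha,
        cluster_p=cluster_p,
        corrected_level=level,
        n_perm=len(null_masses),
        seed=seed,
    )


def factor_tuning(
    rate_matrix: np.ndarray,
    labels: np.ndarray,
    factor: str,
    selection_stat: np.ndarray | None = None,
    alpha: float = 0.05,
    cluster_p: float = 0.05,
    n_factors: int = 3,
    n_perm: int = 1000,
    seed: int | None = None,
    segments: list[tuple[int, int]] | None = None,
    time_ms: np.ndarray | None = None,
) -> ClusterTestResult:
    """CBPT for one unit and one factor.

    ``rate_matrix`` is the unit's single-trial rates (n_trials, T); ``labels``
    the factor level of each trial.  Two-level factors compare their levels
    directly; orientation compares preferred vs non-preferred trials, with
    the selection re-applied inside the permutation null.
    """
    levels = list(FACTORS[factor])
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if factor == "orientation":
        if selection_stat is None:
            raise ValueError("orientation tuning requires selection_stat")
        pref = preferred_levels(selection_stat, labels, factor)
        a = rate_matrix[labels == pref.preferred]
        b = rate_matrix[labels == pref.non_preferred]
        null = _orientation_perm_null(
            np.asarray(rate_matrix, dtype=float),
            labels,
            np.asarray(selection_stat, dtype=float),
            n_perm,
            alpha,
            segments or [(0, rate_matrix.shape[1])],
            rng,
        )
        res = cbpt_test(
            a, b, alpha, cluster_p, n_factors, n_perm, seed, segments, time_ms,
            factor=factor, null_masses=null,
        )
        res.preferred = pref
        return res
    present = [lev for lev in levels if (labels == lev).any()]
    if len(present) < 2:
        raise ValueError(f"factor {factor!r}: need both levels present")
    a = rate_matrix[labels == levels[0]]
    b = rate_matrix[labels == levels[1]]
    null = permutation_null(
        a, b, n_perm, alpha, segments or [(0, rate_matrix.shape[1])], rng
    )
    return cbpt_test(
        a, b, alpha, cluster_p, n_factors, n_perm, seed, segments, time_ms,
        factor=factor, null_masses=null,
    )


def task_related(results: dict[str, ClusterTestResult]) -> bool:
    """A unit is task-related if any factor has a significant cluster."""
    return any(r.significant for r in results.values())


# --------------------------------------------------------------------------
# population-level runners
# --------------------------------------------------------------------------
def run_population_cbpt(
    dataset: SpikeDataset,
    alignments: list[AlignmentSpec] | None = None,
    factors: tuple[str, ...] = ("hand", "grip", "orientation"),
    trial_subset: str = "all",
    alpha: float = 0.05,
    cluster_p: float = 0.05,
    n_perm: int = 1000,
    kernel_sd_ms: float = 57.0,
    seed: int = 0,
) -> list[dict[str, ClusterTestResult]]:
    """Run the factor-corrected CBPT for every unit of a dataset.

    ``trial_subset`` restricts to contra- or ipsi-lateral trials (relative
    to the recorded hemisphere); the hand factor is then unavailable and is
    dropped from the factor list with the correction adjusted accordingly.
    Units are processed one at a time, so memory stays flat in population
    size.
    """
    if alignments is None:
        alignments = default_alignments()
    trials = dataset.trials
    keep = np.ones(len(trials), dtype=bool)
    factors = tuple(factors)
    if trial_subset != "all":
        contra = dataset.contra_hand()
        want = contra if trial_subset == "contra" else (
            "left" if contra == "right" else "right"
        )
        keep = (trials["hand"] == want).to_numpy()
        if not keep.any():
            raise ValueError(f"trial subset {trial_subset!r} is empty")
        factors = tuple(f for f in factors if f != "hand")
    index = _SpikeIndex(dataset)
    grids = [a.time_grid() for a in alignments]
    time_ms = np.concatenate(grids)
    segments, start = [], 0
    for g in grids:
        segments.append((start, start + len(g)))
        start += len(g)
    n_factors = len(factors)
    out = []
    for u in range(dataset.n_units):
        rates = unit_rate_matrix(index, dataset, u, alignments, kernel_sd_ms)[keep]
        sel = cue_to_reward_mean(dataset, index, u)[keep]
        res: dict[str, ClusterTestResult] = {}
        for fi, factor in enumerate(factors):
            labels = trials.loc[keep, _FACTOR_COLUMNS[factor]].to_numpy()
            sub_seed = int(
                np.random.SeedSequence(seed, spawn_key=(u, fi)).generate_state(1)[0]
                % (2**31)
            )
            res[factor] = factor_tuning(
                rates,
                labels,
                factor,
                selection_stat=sel,
                alpha=alpha,
                cluster_p=cluster_p,
                n_factors=n_factors,
                n_perm=n_perm,
                seed=sub_seed,
                segments=segments,
                time_ms=time_ms,
            )
        out.append(res)
    return out


def tuning_fraction(
    population_results: list[dict[str, ClusterTestResult]],
    factor: str,
    n_time: int,
    task_related_only: bool = False,
) -> np.ndarray:
    """Percent of units significantly tuned for a factor at each sample.

    With ``task_related_only`` the denominator is restricted to units that
    are task-related (significant for any factor), matching figures drawn
    from a task-related subpopulation; the default denominator is every unit
    in ``population_results``.
    """
    units = [
        r
        for r in population_results
        if (not task_related_only) or task_related(r)
    ]
    if not units:
        return np.zeros(n_time)
    cov = np.zeros(n_time)
    for r in units:
        if factor in r:
            cov += r[factor].coverage(n_time)
    return 100.0 * cov / len(units)
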