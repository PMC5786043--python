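"""Synthetic spiking populations with planted factorial structure.

Each dataset emulates one animal of a delayed grasping study: 20 conditions
(2 hand x 2 grip x 5 orientation), at least 5 trials per condition, epochs
fixation (700-1100 ms) -> cue (800 ms) -> memory (700-1100 ms) -> go ->
reaction -> movement -> hold (300 ms) -> reward.  Firing is an inhomogeneous
Poisson process whose intensity is a rectified sum of a baseline and planted
latent components.  Every component is tagged with exactly one task-factor
marginalization (condition-independent, hand, grip, orientation, or one of
the pairwise interactions), its condition pattern is zero-mean in every
factor it excludes, so the planted structure lands exactly in the matching
marginalization of the trial-averaged data.

An optional "artifact" component emulates a transient, cue/memory-confined
hand signal present in one dataset only (e.g. caused by small premature hand
movements of one animal); it is what the shared-component selection stage is
designed to discard.

Randomness is split into one counter-based stream per (dataset, unit, trial)
so that simulation results do not depend on iteration order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .core import N_CONDITIONS, ORIENTATIONS, SpikeDataset, condition_table

MARGINALIZATIONS = (
    "time",
    "hand",
    "grip",
    "orientation",
    "hand:grip",
    "hand:orientation",
    "grip:orientation",
)

#: latent time-course shape attached to each marginalization by default
DEFAULT_PROFILES = {
    "time": "movement",
    "hand": "memory_sustained",
    "grip": "memory_sustained",
    "orientation": "cue_sustained",
    "hand:grip": "movement",
    "hand:orientation": "late_cue_sustained",
    "grip:orientation": "movement",
}

#: planted component amplitudes in Hz; condition-independent structure
#: dominates, single factors are intermediate, interactions are small.
DEFAULT_AMPLITUDES = {
    "time": 8.0,
    "hand": 4.0,
    "grip": 4.0,
    "orientation": 4.0,
    "hand:grip": 1.5,
    "hand:orientation": 1.5,
    "grip:orientation": 1.5,
}


# --------------------------------------------------------------------------
# epoch schedule
# --------------------------------------------------------------------------
@dataclass
class EpochSchedule:
    """Event times (ms, absolute trial clock starting at fixation onset)."""

    fixation_ms: float
    cue_ms: float
    memory_ms: float
    reaction_ms: float
    movement_ms: float
    hold_ms: float = 300.0
    post_reward_ms: float = 800.0

    def __post_init__(self) -> None:
        for name in ("fixation_ms", "cue_ms", "memory_ms", "reaction_ms",
                     "movement_ms", "hold_ms", "post_reward_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def t_cue_on(self) -> float:
        return self.fixation_ms

    @property
    def t_cue_off(self) -> float:
        return self.t_cue_on + self.cue_ms

    @property
    def t_go(self) -> float:
        return self.t_cue_off + self.memory_ms

    @property
    def t_move_on(self) -> float:
        return self.t_go + self.reaction_ms

    @property
    def t_hold_on(self) -> float:
        return self.t_move_on + self.movement_ms

    @property
    def t_reward(self) -> float:
        return self.t_hold_on + self.hold_ms

    @property
    def t_end(self) -> float:
        return self.t_reward + self.post_reward_ms

    @classmethod
    def sample(cls, rng: np.random.Generator, config: "SynthConfig") -> "EpochSchedule":
        """Draw one trial's epoch durations."""
        return cls(
            fixation_ms=rng.uniform(700.0, 1100.0),
            cue_ms=800.0,
            memory_ms=rng.uniform(700.0, 1100.0),
            reaction_ms=max(120.0, rng.normal(config.rt_median_ms, config.rt_sd_ms)),
            movement_ms=max(150.0, rng.normal(config.mt_median_ms, config.mt_sd_ms)),
            hold_ms=300.0,
            post_reward_ms=config.post_reward_ms,
        )

    @classmethod
    def reference(cls, config: "SynthConfig") -> "EpochSchedule":
        """Deterministic schedule at the mean epoch durations (oracle use)."""
        return cls(
            fixation_ms=900.0,
            cue_ms=800.0,
            memory_ms=900.0,
            reaction_ms=config.rt_median_ms,
            movement_ms=config.mt_median_ms,
            hold_ms=300.0,
            post_reward_ms=config.post_reward_ms,
        )


# --------------------------------------------------------------------------
# latent time-courses
# --------------------------------------------------------------------------
def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40.0, 40.0)))


def latent_profile(name: str, t_ms: np.ndarray, sched: EpochSchedule) -> np.ndarray:
    """Evaluate a named latent time-course (range [0, 1]) on a time grid.

    Shapes are smooth epoch-anchored bumps and plateaus:

    - ``cue_phasic``:        Gaussian bump shortly after cue onset
    - ``cue_sustained``:     rises at cue onset, sustained until reward
    - ``late_cue_sustained``: rises late in the cue, sustained until reward
    - ``memory_sustained``:  rises entering memory, sustained until reward
    - ``movement``:          Gaussian bump around movement onset
    - ``cue_transient``:     bump after cue onset, forced to zero after the
      go cue (the artifact shape, confined to the cue/memory window)
    """
    t = np.asarray(t_ms, dtype=float)
    if name == "cue_phasic":
        return np.exp(-0.5 * ((t - (sched.t_cue_on + 250.0)) / 120.0) ** 2)
    if name == "cue_sustained":
        return _sigmoid((t - (sched.t_cue_on + 150.0)) / 60.0) * _sigmoid(
            ((sched.t_reward + 100.0) - t) / 80.0
        )
    if name == "late_cue_sustained":
        return _sigmoid((t - (sched.t_cue_off - 150.0)) / 60.0) * _sigmoid(
            ((sched.t_reward + 100.0) - t) / 80.0
        )
    if name == "memory_sustained":
        return _sigmoid((t - (sched.t_cue_off + 100.0)) / 60.0) * _sigmoid(
            ((sched.t_reward + 100.0) - t) / 80.0
        )
    if name == "movement":
        return np.exp(-0.5 * ((t - (sched.t_move_on + 100.0)) / 150.0) ** 2)
    if name == "cue_transient":
        bump = np.exp(-0.5 * ((t - (sched.t_cue_on + 300.0)) / 150.0) ** 2)
        return bump * (t < sched.t_go)
    raise ValueError(f"unknown latent profile {name!r}")


def condition_pattern(tag: str) -> np.ndarray:
    """Signed condition weights (2, 2, 5) for a marginalization tag.

    Each pattern is zero-mean along every factor axis that the tag excludes,
    so a component contributes variance to its own marginalization only.
    The hand x orientation pattern is mirror-symmetric (body-centric):
    value(left, theta) == value(right, -theta).
    """
    h = np.array([1.0, -1.0])  # left, right
    g = np.array([1.0, -1.0])  # power, precision
    o = np.asarray(ORIENTATIONS, dtype=float) / 50.0  # -1 .. +1
    ones_h, ones_g, ones_o = np.ones(2), np.ones(2), np.ones(5)
    factors = {
        "time": (ones_h, ones_g, ones_o),
        "hand": (h, ones_g, ones_o),
        "grip": (ones_h, g, ones_o),
        "orientation": (ones_h, ones_g, o),
        "hand:grip": (h, g, ones_o),
        "hand:orientation": (h, ones_g, o),
        "grip:orientation": (ones_h, g, o),
    }
    if tag not in factors:
        raise ValueError(f"unknown marginalization tag {tag!r}")
    a, b, c = factors[tag]
    return np.einsum("i,j,k->ijk", a, b, c)


# --------------------------------------------------------------------------
# configuration and ground truth
# --------------------------------------------------------------------------
@dataclass
class ArtifactSpec:
    """A transient hand component planted in exactly one dataset.

    The time-course is confined to the cue/memory window (zero after the go
    cue), emulating a premature-movement artifact carried by one animal.
    """

    dataset_index: int = 0
    amplitude_hz: float = 4.0
    profile: str = "cue_transient"


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study design: 20 conditions, 10 trials per
    condition (200 trials, inside the reported 100-260 range), reaction and
    movement times near the reported medians, and two datasets so the
    cross-dataset selection stage can be exercised.
    """

    n_units: int = 50
    n_datasets: int = 2
    trials_per_condition: int = 10
    baseline_hz: float = 20.0
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    artifact: ArtifactSpec | None = None
    rt_median_ms: float = 230.0
    rt_sd_ms: float = 20.0
    mt_median_ms: float = 305.0
    mt_sd_ms: float = 30.0
    post_reward_ms: float = 800.0
    hemispheres: tuple = ("left", "right")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be at least 1")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be at least 1")
        if self.trials_per_condition < 5:
            raise ValueError(
                "trials_per_condition must be >= 5 (unit inclusion requires "
                "at least 5 trials per condition)"
            )
        if self.baseline_hz < 0:
            raise ValueError("baseline_hz must be non-negative")
        for tag, amp in self.amplitudes.items():
            if tag not in MARGINALIZATIONS:
                raise ValueError(f"unknown marginalization tag {tag!r}")
            if amp < 0:
                raise ValueError(f"amplitude for {tag!r} must be >= 0")
        if self.artifact is not None and not isinstance(self.artifact, ArtifactSpec):
            self.artifact = ArtifactSpec(**dict(self.artifact))

    @classmethod
    def null(cls, **kwargs) -> "SynthConfig":
        """A configuration with no condition dependence (all amplitudes 0)."""
        kwargs.setdefault("amplitudes", {tag: 0.0 for tag in MARGINALIZATIONS})
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "hemispheres" in data:
            data["hemispheres"] = tuple(data["hemispheres"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["hemispheres"] = list(self.hemispheres)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GroundTruthComponent:
    """One planted latent component.

    ``loadings`` maps dataset index -> per-unit weight vector (dimensionless,
    standard normal).  The rate contribution of the component to unit *u* of
    dataset *d* in condition *c* at time *t* is
    ``amplitude_hz * loadings[d][u] * pattern[c] * profile(t)``.
    """

    tag: str
    amplitude_hz: float
    profile: str
    pattern: np.ndarray  # (2, 2, 5)
    loadings: dict  # dataset index -> (n_units,)
    artifact: bool = False

    def rate_contribution(
        self, dataset_index: int, t_ms: np.ndarray, sched: EpochSchedule
    ) -> np.ndarray:
        """Contribution in Hz, shaped (n_units, 20, len(t_ms))."""
        load = self.loadings.get(dataset_index)
        if load is None:
            return np.zeros((0, N_CONDITIONS, len(t_ms)))
        prof = latent_profile(self.profile, t_ms, sched)
        pat = self.pattern.reshape(-1)
        return (
            self.amplitude_hz
            * load[:, None, None]
            * pat[None, :, None]
            * prof[None, None, :]
        )

    def to_jsonable(self) -> dict:
        return {
            "tag": self.tag,
            "amplitude_hz": self.amplitude_hz,
            "profile": self.profile,
            "pattern": self.pattern.tolist(),
            "loadings": {str(d): v.tolist() for d, v in self.loadings.items()},
            "artifact": self.artifact,
        }


def build_ground_truth(config: SynthConfig) -> list[GroundTruthComponent]:
    """Construct the planted components: one per marginalization tag, plus
    the optional single-dataset artifact.

    Deterministic given ``config.seed``; unit loadings are standard-normal
    draws from a dedicated stream per (component, dataset).
    """
    comps: list[GroundTruthComponent] = []
    for ci, tag in enumerate(MARGINALIZATIONS):
        amp = float(config.amplitudes.get(tag, 0.0))
        loadings = {}
        for d in range(config.n_datasets):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(900, ci, d))
            )
            loadings[d] = rng.standard_normal(config.n_units)
        comps.append(
            GroundTruthComponent(
                tag=tag,
                amplitude_hz=amp,
                profile=config.profiles.get(tag, DEFAULT_PROFILES[tag]),
                pattern=condition_pattern(tag),
                loadings=loadings,
            )
        )
    if config.artifact is not None:
        art = config.artifact
        if not 0 <= art.dataset_index < config.n_datasets:
            raise ValueError("artifact dataset_index out of range")
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(901, art.dataset_index))
        )
        comps.append(
            GroundTruthComponent(
                tag="hand",
                amplitude_hz=art.amplitude_hz,
                profile=art.profile,
                pattern=condition_pattern("hand"),
                loadings={art.dataset_index: rng.standard_normal(config.n_units)},
                artifact=True,
            )
        )
    return comps


def write_ground_truth(comps: list[GroundTruthComponent], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_jsonable() for c in comps], fh)


def planted_condition_profiles(
    comps: list[GroundTruthComponent],
    dataset_index: int,
    sched: EpochSchedule,
    t_ms: np.ndarray,
    include_baseline: float = 0.0,
    rectify: bool = False,
) -> np.ndarray:
    """Noise-free planted intensity (n_units, 20, T) on a reference schedule.

    This is the test oracle: with rectify=False it is the exact
    pre-rectification intensity (baseline + sum of contributions).
    """
    total = None
    for comp in comps:
        contrib = comp.rate_contribution(dataset_index, t_ms, sched)
        if contrib.shape[0] == 0:
            continue
        total = contrib if total is None else total + contrib
    if total is None:
        raise ValueError("no component carries loadings for this dataset")
    total = total + include_baseline
    if rectify:
        total = np.maximum(total, 0.0)
    return total


# --------------------------------------------------------------------------
# spike simulation
# --------------------------------------------------------------------------
def _sample_poisson_spikes(
    rng: np.random.Generator, intensity_hz: np.ndarray | float, duration_ms: float
) -> np.ndarray:
    """Spike times (ms) of an (in)homogeneous Poisson process by thinning.

    ``intensity_hz`` is either a scalar (homogeneous) or a piecewise-constant
    intensity sampled on a 1 ms grid; thinning against the grid maximum is
    exact for such intensities.
    """
    if np.isscalar(intensity_hz):
        lam = float(intensity_hz)
        if lam <= 0:
            return np.empty(0)
        n = rng.poisson(lam * duration_ms / 1000.0)
        return np.sort(rng.uniform(0.0, duration_ms, n))
    intensity = np.asarray(intensity_hz, dtype=float)
    lam_max = float(intensity.max(initial=0.0))
    if lam_max <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * duration_ms / 1000.0)
    times = rng.uniform(0.0, duration_ms, n)
    u = rng.uniform(0.0, lam_max, n)
    idx = np.minimum(times.astype(int), len(intensity) - 1)
    return np.sort(times[u < intensity[idx]])


def simulate_dataset(
    config: SynthConfig,
    dataset_index: int,
    components: list[GroundTruthComponent] | None = None,
) -> SpikeDataset:
    """Simulate one dataset (one synthetic animal).

    The trial table covers the 20 conditions x ``trials_per_condition`` in
    pseudorandom order; every unit shares the trial table but has its own
    independent spiking stream per trial.  Byte-identical across runs with
    the same config.
    """
    if not 0 <= dataset_index < config.n_datasets:
        raise ValueError("dataset_index out of range")
    if components is None:
        components = build_ground_truth(config)

    cond = condition_table()
    n_trials = N_CONDITIONS * config.trials_per_condition
    order_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(dataset_index, 2))
    )
    cond_of_trial = order_rng.permutation(
        np.repeat(np.arange(N_CONDITIONS), config.trials_per_condition)
    )

    # per-component (amplitude * pattern) weights for this dataset
    active = [
        c
        for c in components
        if c.amplitude_hz > 0 and dataset_index in c.loadings
    ]
    if active:
        pat = np.stack([c.amplitude_hz * c.pattern.reshape(-1) for c in active])
        loads = np.stack([c.loadings[dataset_index] for c in active])  # (K, U)

    trial_rows = []
    unit_col, trial_col, time_col = [], [], []
    for tr in range(n_trials):
        sched_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(dataset_index, 0, tr))
        )
        sched = EpochSchedule.sample(sched_rng, config)
        dur = sched.t_end
        c = int(cond_of_trial[tr])
        row = cond.loc[c]
        trial_rows.append(
            (
                tr,
                row["hand"],
                row["grip"],
                int(row["orientation_deg"]),
                sched.t_cue_on,
                sched.t_move_on,
                sched.t_reward,
                sched.t_end,
            )
        )
        if active:
            t_grid = np.arange(int(np.ceil(dur)), dtype=float) + 0.5
            profs = np.stack(
                [latent_profile(comp.profile, t_grid, sched) for comp in active]
            )  # (K, T)
            # (K,) condition weights for this trial
            w_cond = pat[:, c]
        for u in range(config.n_units):
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    config.seed, spawn_key=(dataset_index, 1, u, tr)
                )
            )
            if active:
                coeff = loads[:, u] * w_cond  # (K,)
                if np.any(coeff != 0.0):
                    intensity = np.maximum(
                        config.baseline_hz + coeff @ profs, 0.0
                    )
                else:
                    intensity = config.baseline_hz
            else:
                intensity = config.baseline_hz
            st = _sample_poisson_spikes(rng, intensity, dur)
            if len(st):
                unit_col.append(np.full(len(st), u))
                trial_col.append(np.full(len(st), tr))
                time_col.append(st)

    import pandas as pd

    spikes = pd.DataFrame(
        {
            "unit_id": np.concatenate(unit_col) if unit_col else np.empty(0, int),
            "trial_id": np.concatenate(trial_col) if trial_col else np.empty(0, int),
            "spike_time_ms": np.concatenate(time_col) if time_col else np.empty(0),
        }
    )
    trials = pd.DataFrame(
        trial_rows,
        columns=[
            "trial_id",
            "hand",
            "grip",
            "orientation_deg",
            "t_cue_on_ms",
            "t_move_on_ms",
            "t_reward_ms",
            "t_end_ms",
        ],
    )
    hemi = config.hemispheres[dataset_index % len(config.hemispheres)]
    return SpikeDataset(
        spikes=spikes,
        trials=trials,
        unit_ids=np.arange(config.n_units),
        hemisphere=hemi,
    )
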