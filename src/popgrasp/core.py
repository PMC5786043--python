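"""Task design constants and the spike-dataset container.

The delayed grasping task has a balanced 2 x 2 x 5 factorial design:
hand (left/right, cued by an auditory tone), grip (power/precision, cued
visually) and handle orientation (-50, -25, 0, +25, +50 degrees), giving
20 conditions presented in pseudorandom order.  Units are recorded
non-simultaneously, so a dataset is a collection of per-unit spike trains
tied to a common trial table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HANDS = ("left", "right")
GRIPS = ("power", "precision")
ORIENTATIONS = (-50, -25, 0, 25, 50)

#: factor name -> ordered levels
FACTORS = {"hand": HANDS, "grip": GRIPS, "orientation": ORIENTATIONS}

#: shape of the balanced condition grid (hand, grip, orientation)
CONDITION_SHAPE = (len(HANDS), len(GRIPS), len(ORIENTATIONS))
N_CONDITIONS = int(np.prod(CONDITION_SHAPE))


def condition_table() -> pd.DataFrame:
    """The 20 task conditions in canonical (hand, grip, orientation) order.

    Returns a DataFrame with columns ``hand``, ``grip``, ``orientation_deg``
    and a ``condition`` index 0..19.  Canonical order is row-major over the
    (2, 2, 5) grid; every tensor in this package uses it.
    """
    rows = [
        (h, g, o)
        for h in HANDS
        for g in GRIPS
        for o in ORIENTATIONS
    ]
    df = pd.DataFrame(rows, columns=["hand", "grip", "orientation_deg"])
    df.index.name = "condition"
    return df


def condition_index(hand: str, grip: str, orientation_deg: int) -> int:
    """Map factor levels to the canonical condition index 0..19."""
    h = HANDS.index(hand)
    g = GRIPS.index(grip)
    o = ORIENTATIONS.index(int(orientation_deg))
    return (h * len(GRIPS) + g) * len(ORIENTATIONS) + o


@dataclass
class SpikeDataset:
    """Spike events plus trial metadata for one (pseudo-)population.

    Attributes
    ----------
    spikes : pandas.DataFrame
        Columns ``unit_id``, ``trial_id``, ``spike_time_ms``.  Times are on
        an absolute per-trial clock starting at fixation onset.
    trials : pandas.DataFrame
        One row per trial: ``trial_id``, ``hand``, ``grip``,
        ``orientation_deg``, ``t_cue_on_ms``, ``t_move_on_ms``,
        ``t_reward_ms``, ``t_end_ms``.
    unit_ids : ndarray of int
        All units in the dataset (a unit may have zero spikes).
    hemisphere : str
        Recorded hemisphere, used to resolve contra-/ipsi-lateral trials.
    unit_trials : dict or None
        Optional map unit_id -> array of trial_ids during which the unit was
        stably recorded.  ``None`` means every unit saw every trial.
    """

    spikes: pd.DataFrame
    trials: pd.DataFrame
    unit_ids: np.ndarray
    hemisphere: str = "left"
    unit_trials: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        self.trials = self.trials.reset_index(drop=True)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trials_of_unit(self, unit_id) -> pd.DataFrame:
        if self.unit_trials is None:
            return self.trials
        keep = self.trials["trial_id"].isin(self.unit_trials[unit_id])
        return self.trials.loc[keep]

    def condition_of_trials(self, trial_table: pd.DataFrame | None = None) -> np.ndarray:
        """Canonical condition index (0..19) for each trial row."""
        t = self.trials if trial_table is None else trial_table
        return np.array(
            [
                condition_index(h, g, o)
                for h, g, o in zip(t["hand"], t["grip"], t["orientation_deg"])
            ]
        )

    def contra_hand(self) -> str:
        """The hand contra-lateral to the recorded hemisphere."""
        return "right" if self.hemisphere == "left" else "left"

    def unit_spikes(self, unit_id, trial_id=None) -> np.ndarray:
        """Sorted spike times (ms) of one unit, optionally for one trial."""
        m = self.spikes["unit_id"] == unit_id
        if trial_id is not None:
            m &= self.spikes["trial_id"] == trial_id
        return np.sort(self.spikes.loc[m, "spike_time_ms"].to_numpy())

    # ---------------------------------------------------------------- I/O
    def write(self, out_dir: str | Path, prefix: str = "dataset") -> None:
        """Write spike events and trial metadata as delimited text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spikes.to_csv(out / f"{prefix}_spikes.csv", index=False)
        meta = self.trials.copy()
        meta.to_csv(out / f"{prefix}_trials.csv", index=False)
        pd.DataFrame({"unit_id": self.unit_ids}).assign(
            hemisphere=self.hemisphere
        ).to_csv(out / f"{prefix}_units.csv", index=False)

    @classmethod
    def read(cls, out_dir: str | Path, prefix: str = "dataset") -> "SpikeDataset":
        out = Path(out_dir)
        spikes = pd.read_csv(out / f"{prefix}_spikes.csv")
        trials = pd.read_csv(out / f"{prefix}_trials.csv")
        units = pd.read_csv(out / f"{prefix}_units.csv")
        hemisphere = str(units["hemisphere"].iloc[0]) if len(units) else "left"
        return cls(
            spikes=spikes,
            trials=trials,
            unit_ids=units["unit_id"].to_numpy(),
            hemisphere=hemisphere,
        )
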