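"""Trial schedule generation for the force-field adaptation session.

A session alternates strictly between trained (270 degree) and untrained
(90 degree) reaches, because the endpoint of each movement is the start of
the next.  The session has five phases:

baseline
    360 null reaches (174 trained + 186 untrained), with 12 trained-direction
    error-clamp (EC) probes pseudo-randomly interspersed in the second half
    to measure each subject's baseline lateral force.
adapt_transition
    124 movements: 30 nulls, then abrupt force-field (FF) onset.  Trained
    reaches run 3 FF : 2 EC for the first 10 movements and 5 FF : 1 EC for
    the remaining 84.  Once the field is on, every untrained reach is an EC.
adaptation
    two 96-movement blocks; trained reaches keep the exact 5 FF : 1 EC ratio
    (8 EC probes per block, 16 total).
decay_transition
    26 movements of training with increasing probe density (first 12 at
    5 FF : 1 EC, last 14 at 4 FF : 3 EC) to pin down the final adaptation
    level.
decay
    120 consecutive EC trials (60 trained) during which adaptation decays
    with no error feedback.

The training index counts trained-direction FF trials from field onset; EC
trials are measurements and do not advance it.  Trained EC trials during the
decay period additionally carry a 1-based decay index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .kinematics import FORCE_FIELD_TYPES

__all__ = ["TrialSpec", "Schedule", "build_schedule", "trained_trial_index"]

BLOCKS = ("baseline", "adapt_transition", "adaptation", "decay_transition", "decay")

TRAINED_DIRECTION = 270
UNTRAINED_DIRECTION = 90


@dataclass(frozen=True)
class TrialSpec:
    """One movement of the session."""

    index: int  # 1-based position in the session
    block: str
    direction: int  # 270 trained / 90 untrained
    trial_type: str  # "null" | "FF" | "EC"
    training_index: int  # trained FF counter; EC/null inherit the current value
    decay_index: int = 0  # 1..60 for trained EC trials of the decay period


@dataclass
class Schedule:
    """Ordered trial list for one subject session."""

    trials: list[TrialSpec]
    ff_type: str
    seed: int

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [tr.index for tr in self.trials],
                "block": [tr.block for tr in self.trials],
                "direction": [tr.direction for tr in self.trials],
                "trial_type": [tr.trial_type for tr in self.trials],
                "training_index": [tr.training_index for tr in self.trials],
                "decay_index": [tr.decay_index for tr in self.trials],
            }
        )

    def counts(self) -> dict[str, int]:
        """Summary counts used throughout the analysis and its checks."""
        df = self.to_frame()
        base = df[df.block == "baseline"]
        decay = df[df.block == "decay"]
        adapt = df[df.block == "adaptation"]
        return {
            "total_movements": len(df),
            "baseline_null": int((base.trial_type == "null").sum()),
            "baseline_trained_ec": int(
                ((base.trial_type == "EC") & (base.direction == TRAINED_DIRECTION)).sum()
            ),
            "adapt_transition_movements": int((df.block == "adapt_transition").sum()),
            "adaptation_trained_ec": int(
                ((adapt.trial_type == "EC") & (adapt.direction == TRAINED_DIRECTION)).sum()
            ),
            "decay_transition_movements": int(
                ((df.block == "decay_transition") | (df.block == "decay")).sum()
            ),
            "decay_ec_total": int((decay.trial_type == "EC").sum()),
            "decay_ec_trained": int(
                ((decay.trial_type == "EC") & (decay.direction == TRAINED_DIRECTION)).sum()
            ),
            "trained_ff_trials": int(
                ((df.trial_type == "FF") & (df.direction == TRAINED_DIRECTION)).sum()
            ),
        }


def _ratio_block(
    rng: np.random.Generator, n_ff: int, n_ec: int, forbid_first: bool = False
) -> list[str]:
    """Pseudo-random order of n_ff FF and n_ec EC trials (exact ratio)."""
    n = n_ff + n_ec
    slots = np.arange(1 if forbid_first else 0, n)
    ec_slots = rng.choice(slots, size=n_ec, replace=False)
    out = ["FF"] * n
    for s in ec_slots:
        out[int(s)] = "EC"
    return out


def _baseline_trained(rng: np.random.Generator) -> list[str]:
    """Trained-direction baseline sequence: 174 nulls + 12 EC probes.

    Probes go in the second half (the last two blocks, trained slots
    81..186), 6 per block, never on a block's first trained slot.
    """
    seq = ["null"] * 186
    for start in (80, 133):  # 0-based starts of the last two blocks (53 slots each)
        slots = rng.choice(np.arange(start + 1, start + 53), size=6, replace=False)
        for s in slots:
            seq[int(s)] = "EC"
    return seq


def build_schedule(ff_type: str, seed: int) -> Schedule:
    """Build the full session schedule for one subject.

    The schedule is a pure function of ``(ff_type, seed)``; the seed only
    moves the pseudo-random EC probe placements within their exact ratios.
    """
    if ff_type not in FORCE_FIELD_TYPES:
        raise ValueError(f"ff_type must be one of {FORCE_FIELD_TYPES}, got {ff_type!r}")
    rng = np.random.default_rng(seed)

    # (block, trained-direction trial type) in session order
    trained: list[tuple[str, str]] = []
    trained += [("baseline", t) for t in _baseline_trained(rng)]
    trained += [("adapt_transition", "null")] * 15
    trained += [("adapt_transition", t) for t in _ratio_block(rng, 3, 2, forbid_first=True)]
    for _ in range(7):
        trained += [("adapt_transition", t) for t in _ratio_block(rng, 5, 1)]
    for block in range(2):
        for sub in range(8):
            trained += [
                ("adaptation", t)
                for t in _ratio_block(rng, 5, 1, forbid_first=(sub == 0))
            ]
    trained += [("decay_transition", t) for t in _ratio_block(rng, 5, 1, forbid_first=True)]
    trained += [("decay_transition", t) for t in _ratio_block(rng, 4, 3)]
    trained += [("decay", "EC")] * 60

    trials: list[TrialSpec] = []
    session_index = 0
    training_counter = 0
    decay_counter = 0
    field_on = False
    for block, ttype in trained:
        if ttype == "FF":
            field_on = True
            training_counter += 1
        session_index += 1
        if block == "decay":
            decay_counter += 1
        trials.append(
            TrialSpec(
                index=session_index,
                block=block,
                direction=TRAINED_DIRECTION,
                trial_type=ttype,
                training_index=training_counter,
                decay_index=decay_counter if block == "decay" else 0,
            )
        )
        # return movement in the untrained direction; EC once the field is on
        session_index += 1
        trials.append(
            TrialSpec(
                index=session_index,
                block=block,
                direction=UNTRAINED_DIRECTION,
                trial_type="EC" if field_on else "null",
                training_index=training_counter,
            )
        )
    return Schedule(trials=trials, ff_type=ff_type, seed=seed)


def trained_trial_index(schedule: Schedule | Iterable[TrialSpec]) -> dict[int, int]:
    """Map session index -> trained-direction training-trial count.

    The counter advances on trained-direction FF trials only; EC probes (and
    nulls) are assigned the count of the most recent FF trial, so that a
    probe between FF trials n and n+1 measures the state after trial n.
    """
    trials = schedule.trials if isinstance(schedule, Schedule) else list(schedule)
    return {tr.index: tr.training_index for tr in trials}
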