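"""State space of the illness-death model.

Three ordered states — healthy, ill, dead — with death absorbing and no
remission (ill never returns to healthy).  The "ill" state is defined
relative to a condition pair: a person-month is ill when both conditions
of the pair are present, irrespective of any other conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEALTHY, ILL, DEAD = 0, 1, 2
STATE_LABELS = ("healthy", "ill", "dead")
STATE_CODES = {label: code for code, label in enumerate(STATE_LABELS)}

N_STATES = 3


@dataclass(frozen=True)
class StateSpace:
    """Ordered three-state space with an optional condition-pair illness rule.

    Parameters
    ----------
    condition_pair : tuple of str, optional
        When the panel carries per-condition flag columns rather than a
        ``state`` column, a person-month is *ill* iff both named flags
        are set.  Death always takes precedence.
    """

    states: tuple = field(default=STATE_LABELS)
    condition_pair: tuple | None = None

    def __post_init__(self):
        if tuple(self.states) != STATE_LABELS:
            raise ValueError(
                f"state space must be exactly {STATE_LABELS}, got {self.states}"
            )
        if self.condition_pair is not None and len(self.condition_pair) != 2:
            raise ValueError("condition_pair must name exactly two conditions")

    def encode(self, panel: pd.DataFrame) -> np.ndarray:
        """Return integer state codes for each panel row.

        Accepts either a ``state`` column with literal labels
        healthy|ill|dead, or (with ``condition_pair`` set) a ``dead``
        0/1 column plus one 0/1 column per condition.
        """
        if "state" in panel.columns:
            codes = panel["state"].map(STATE_CODES)
            if codes.isna().any():
                bad = sorted(set(panel.loc[codes.isna(), "state"]))
                raise ValueError(f"unknown state labels in panel: {bad}")
            return codes.to_numpy(dtype=np.int8)
        if self.condition_pair is None:
            raise ValueError(
                "panel has no 'state' column and no condition_pair was given"
            )
        a, b = self.condition_pair
        for col in ("dead", a, b):
            if col not in panel.columns:
                raise ValueError(f"panel lacks required column {col!r}")
        dead = panel["dead"].to_numpy(dtype=bool)
        ill = panel[a].to_numpy(dtype=bool) & panel[b].to_numpy(dtype=bool)
        out = np.zeros(len(panel), dtype=np.int8)
        out[ill] = ILL
        out[dead] = DEAD
        return out
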