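"""Reading and writing the package's tabular interchange formats.

Panels and snapshots travel as header-bearing CSV (or Parquet, by file
suffix); counts/matrices and burden metrics as long-format CSV; run
configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .states import STATE_LABELS
from .transitions import AgeTransitionMatrices, TransitionCountTensor
from .metrics import BurdenMetrics

PANEL_COLUMNS = ["person_id", "month_index", "age_years", "state"]


def _is_parquet(path) -> bool:
    return str(path).endswith((".parquet", ".pq"))


def read_panel(path) -> pd.DataFrame:
    """Read a person-month panel (CSV or Parquet by suffix)."""
    if _is_parquet(path):
        panel = pd.read_parquet(path)
    else:
        panel = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel file {path} lacks columns {sorted(missing)}")
    bad = ~panel["state"].isin(STATE_LABELS)
    if bad.any():
        lines = (panel.index[bad][:5] + 2).tolist()  # +2: header + 1-basing
        raise ValueError(f"panel file {path} has invalid state values "
                         f"(first offending lines: {lines})")
    return panel


def write_panel(panel: pd.DataFrame, path) -> None:
    if _is_parquet(path):
        panel.to_parquet(path, index=False)
    else:
        panel.to_csv(path, index=False)


def read_snapshot(path) -> pd.DataFrame:
    """Read a cross-sectional snapshot (person_id, age_years, sex, flags)."""
    snap = pd.read_parquet(path) if _is_parquet(path) else pd.read_csv(path)
    missing = {"person_id", "age_years", "sex"} - set(snap.columns)
    if missing:
        raise ValueError(f"snapshot file {path} lacks columns {sorted(missing)}")
    return snap


def write_snapshot(snapshot: pd.DataFrame, path) -> None:
    if _is_parquet(path):
        snapshot.to_parquet(path, index=False)
    else:
        snapshot.to_csv(path, index=False)


def matrices_frame(counts: TransitionCountTensor,
                   matrices: AgeTransitionMatrices) -> pd.DataFrame:
    """Long-format table: one row per (age, origin, destination)."""
    rows = []
    yearly = matrices.yearly
    for a in range(counts.age_cap + 1):
        for i, oi in enumerate(STATE_LABELS):
            for j, oj in enumerate(STATE_LABELS):
                rows.append({
                    "age": a, "origin_state": oi, "destination_state": oj,
                    "count": int(counts.counts[i, j, a]),
                    "monthly_probability": matrices.monthly[a, i, j],
                    "yearly_probability": (yearly[a, i, j]
                                           if yearly is not None else np.nan),
                })
    return pd.DataFrame(rows)


def write_matrices(counts: TransitionCountTensor,
                   matrices: AgeTransitionMatrices, path) -> None:
    matrices_frame(counts, matrices).to_csv(path, index=False)


BURDEN_COLUMNS = ["combination_label", "sex_stratum", "L_r", "a_median",
                  "Y_LW", "Y_LL", "age_at_death", "C_YLW", "C_YLL"]


def burden_row(label: str, sex_stratum: str, metrics: BurdenMetrics) -> dict:
    return {"combination_label": label, "sex_stratum": sex_stratum,
            **metrics.as_dict()}


def write_burden_table(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=BURDEN_COLUMNS).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a nested key-value YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
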