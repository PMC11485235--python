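"""Cross-sectional prevalence analytics.

Point prevalence, joint (dual-combination) prevalence with its
observed-minus-expected excess over the independence expectation, and
the distribution of condition counts by age band, sex and index-condition
status (the Fig.-1-style table: among people with the index condition
the count includes the index condition itself; the comparator group is
people without it who have at least one of the other conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default 5-year adult age bands: 20-24 ... 80-84, then 85+
DEFAULT_AGE_BANDS = [(lo, lo + 4) for lo in range(20, 85, 5)] + [(85, 200)]


class EmptyStratumError(ValueError):
    """The requested stratum contains no persons; prevalence is undefined."""


@dataclass(frozen=True)
class ExcessPrevalence:
    """Observed vs expected-under-independence joint prevalence of a pair."""

    condition_a: str
    condition_b: str
    observed: float
    expected: float

    @property
    def excess(self) -> float:
        return self.observed - self.expected


def round_percent(x: float, decimals: int = 1) -> float:
    """Percentage rounding, half away from zero (presentation rule)."""
    if math.isnan(x):
        return x
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _stratum(snapshot: pd.DataFrame, age_range=None, sex=None) -> pd.DataFrame:
    out = snapshot
    if age_range is not None:
        lo, hi = age_range
        out = out[(out["age_years"] >= lo) & (out["age_years"] <= hi)]
    if sex is not None:
        out = out[out["sex"] == sex]
    return out


def point_prevalence(snapshot: pd.DataFrame, condition: str,
                     age_range: tuple[int, int] | None = None,
                     sex: str | None = None) -> float:
    """Proportion of the stratum with the condition flag set."""
    if condition not in snapshot.columns:
        raise KeyError(f"condition {condition!r} not in snapshot")
    sub = _stratum(snapshot, age_range, sex)
    if len(sub) == 0:
        raise EmptyStratumError("empty stratum: prevalence is not computable")
    return float(sub[condition].astype(bool).mean())


def observed_minus_expected(snapshot: pd.DataFrame, condition_a: str,
                            condition_b: str,
                            age_range: tuple[int, int] | None = None,
                            sex: str | None = None) -> ExcessPrevalence:
    """Joint prevalence of a pair minus the product of its marginals.

    Computed crude over the (optionally filtered) population: expected
    is the product of the two marginal prevalences irrespective of each
    other's status.
    """
    for c in (condition_a, condition_b):
        if c not in snapshot.columns:
            raise KeyError(f"condition {c!r} not in snapshot")
    sub = _stratum(snapshot, age_range, sex)
    if len(sub) == 0:
        raise EmptyStratumError("empty stratum: prevalence is not computable")
    a = sub[condition_a].astype(bool)
    b = sub[condition_b].astype(bool)
    observed = float((a & b).mean())
    expected = float(a.mean()) * float(b.mean())
    return ExcessPrevalence(condition_a, condition_b, observed, expected)


def _band_label(lo: int, hi: int) -> str:
    return f"{lo}+" if hi >= 150 else f"{lo}-{hi}"


def mltc_count_distribution(snapshot: pd.DataFrame,
                            conditions: list[str] | None = None,
                            index_condition: str = "diabetes",
                            age_bands: list[tuple[int, int]] | None = None,
                            by_sex: bool = True,
                            max_k: int = 6) -> pd.DataFrame:
    """Proportion of persons with >= k conditions, by stratum and group.

    Two groups per stratum: persons with the index condition (their
    count *includes* it) and, as comparator, persons without it who have
    at least one of the other conditions (count over the other
    conditions only).  k runs 1..max_k, the last bin meaning >= max_k.

    Returns a long DataFrame with columns ``age_band``, ``sex`` (if
    ``by_sex``), ``group``, ``k``, ``proportion``, ``n`` — ``proportion``
    is NaN where the stratum group is empty.
    """
    if conditions is None:
        conditions = [c for c in snapshot.columns
                      if c not in ("person_id", "age_years", "sex")]
    if index_condition not in conditions:
        raise KeyError(f"index condition {index_condition!r} not among "
                       "snapshot conditions")
    others = [c for c in conditions if c != index_condition]
    age_bands = age_bands if age_bands is not None else DEFAULT_AGE_BANDS

    flags = snapshot[conditions].astype(bool)
    has_index = flags[index_condition].to_numpy()
    n_other = flags[others].sum(axis=1).to_numpy() if others else np.zeros(len(snapshot), dtype=int)
    count_with_index = n_other + has_index.astype(int)

    sexes = sorted(snapshot["sex"].unique()) if by_sex else [None]
    rows = []
    age = snapshot["age_years"].to_numpy()
    sex_col = snapshot["sex"].to_numpy() if by_sex else None
    for lo, hi in age_bands:
        in_band = (age >= lo) & (age <= hi)
        for sex in sexes:
            mask = in_band if sex is None else in_band & (sex_col == sex)
            groups = {
                index_condition: (mask & has_index, count_with_index),
                f"no_{index_condition}": (mask & ~has_index & (n_other >= 1),
                                          n_other),
            }
            for group, (gmask, counts) in groups.items():
                denom = int(gmask.sum())
                for k in range(1, max_k + 1):
                    prop = (float((counts[gmask] >= k).mean())
                            if denom else math.nan)
                    row = {"age_band": _band_label(lo, hi), "group": group,
                           "k": k, "proportion": prop, "n": denom}
                    if by_sex:
                        row["sex"] = sex
                    rows.append(row)
    cols = ["age_band"] + (["sex"] if by_sex else []) + ["group", "k",
                                                         "proportion", "n"]
    return pd.DataFrame(rows)[cols]
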