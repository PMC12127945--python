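"""Dataset-level curation: inclusion filtering, one-image-per-patient
selection, age handling, and stratified train/tune/test partitioning.

The partitioner stratifies jointly over manufacturer, deviation-index
tercile, sex, age decade and ethnicity (with fallback coarsening for tiny
strata) and allocates split sizes by largest-remainder (Hamilton)
rounding, then rebalances single rows between strata so the global split
sizes match the largest-remainder targets exactly while every stratum
stays within one row of its ideal quota.
"""

from __future__ import annotations

import math
import re
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

STRATIFICATION_FIELDS = ("manufacturer", "deviation_index", "sex", "age", "ethnicity")
SPLITS = ("train", "tune", "test")
DEFAULT_FRACTIONS = (0.64, 0.16, 0.20)

_RANGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*-\s*(\d+(?:\.\d+)?)\s*$")
_YEARS_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*Y?\s*$", re.IGNORECASE)


def age_midpoint(age_field: Union[str, float, int, None]) -> Optional[float]:
    """Resolve an age field to numeric years.

    Numbers pass through; a range ``"A-B"`` resolves to its midpoint;
    anything unparseable returns None (missing), never raises.
    """
    if age_field is None:
        return None
    if isinstance(age_field, (int, float, np.integer, np.floating)):
        return None if (isinstance(age_field, float) and math.isnan(age_field)) \
            else float(age_field)
    s = str(age_field).strip()
    if not s:
        return None
    m = _RANGE_RE.match(s)
    if m:
        return (float(m.group(1)) + float(m.group(2))) / 2.0
    m = _YEARS_RE.match(s)
    if m:
        return float(m.group(1))
    return None


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and not v.strip():
        return True
    return pd.isna(v)


def apply_inclusion_filters(table: pd.DataFrame
                            ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows with any missing stratification field.

    Returns (retained table with an added numeric ``age_years`` column,
    exclusion log with columns image_id, missing_field — the first missing
    field in canonical order).
    """
    table = table.copy()
    table["age_years"] = table["age"].map(age_midpoint)
    excluded = []
    keep_mask = np.ones(len(table), dtype=bool)
    for i, (_, row) in enumerate(table.iterrows()):
        for f in STRATIFICATION_FIELDS:
            value = row["age_years"] if f == "age" else row[f]
            if _is_missing(value):
                excluded.append({"image_id": row["image_id"], "missing_field": f})
                keep_mask[i] = False
                break
    log = pd.DataFrame(excluded, columns=["image_id", "missing_field"])
    return table[keep_mask].reset_index(drop=True), log


def select_one_per_patient(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep exactly one uniformly random image per patient (seeded)."""
    rng = np.random.default_rng(seed)
    table = table.sort_values("image_id").reset_index(drop=True)
    keep_ids = []
    for patient in sorted(table["patient_id"].unique()):
        rows = table.index[table["patient_id"] == patient]
        keep_ids.append(rows[rng.integers(len(rows))])
    return table.loc[sorted(keep_ids)].reset_index(drop=True)


def largest_remainder(n: int, fractions: Sequence[float]) -> List[int]:
    """Hamilton apportionment of ``n`` units to the given fractions.

    Ties in the remainders are broken toward the earlier fraction.
    """
    quotas = [n * f for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    leftover = n - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def _stratum_keys(table: pd.DataFrame, strata: Sequence[str]) -> pd.Series:
    """Joint stratum key with continuous-field binning (age decades,
    deviation-index terciles) and coarsening of strata smaller than 3 rows
    (drop the deviation bin first, then the age bin)."""
    parts: Dict[str, pd.Series] = {}
    for f in strata:
        if f == "age":
            years = table["age_years"] if "age_years" in table else table["age"].map(age_midpoint)
            parts[f] = (years // 10).astype(int).astype(str).radd("age")
        elif f == "deviation_index":
            di = pd.to_numeric(table[f])
            edges = np.quantile(di, [1 / 3, 2 / 3])
            parts[f] = pd.Series(np.searchsorted(edges, di), index=table.index
                                 ).astype(str).radd("di")
        else:
            parts[f] = table[f].astype(str)

    def joint(fields: Sequence[str]) -> pd.Series:
        key = pd.Series("", index=table.index)
        for f in fields:
            key = key + "|" + parts[f]
        return key

    drop_order = [list(strata)]
    if "deviation_index" in strata:
        drop_order.append([f for f in strata if f != "deviation_index"])
    if "age" in strata:
        drop_order.append([f for f in drop_order[-1] if f != "age"])
    drop_order.append([])  # fully pooled

    keys = joint(drop_order[0])
    for level, fields in enumerate(drop_order[1:], start=1):
        counts = keys.value_counts()
        small = keys.isin(counts.index[counts < 3])
        if not small.any():
            break
        coarse = joint(fields) if fields else pd.Series("|pooled", index=table.index)
        keys = keys.where(~small, f"L{level}" + coarse)
    return keys


def stratified_partition(table: pd.DataFrame,
                         fractions: Sequence[float] = DEFAULT_FRACTIONS,
                         strata: Sequence[str] = STRATIFICATION_FIELDS,
                         seed: int = 0) -> pd.Series:
    """Assign each row to train/tune/test.

    Within each stratum rows are shuffled (seeded) and allocated
    contiguously by largest-remainder counts; single-row transfers then
    make the global split sizes match the global largest-remainder targets
    exactly, keeping every stratum within +/- 1 row of its ideal quota.
    Returns a Series mapping image_id -> split name.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if table["image_id"].duplicated().any():
        raise ValueError("image IDs must be unique")
    n = len(table)
    n_splits = len(fractions)
    rng = np.random.default_rng(seed)
    keys = _stratum_keys(table, strata)

    # Cumulative controlled rounding: per stratum take the floor of each
    # quota, then hand the leftover rows to the splits with the largest
    # running deficit (cumulative quota minus cumulative allocation). With
    # many small strata this self-balances — a naive per-stratum largest
    # remainder would systematically favor whichever split happens to have
    # the biggest remainder at the common stratum size.
    global_target = largest_remainder(n, fractions)
    strata_sorted = sorted(keys.unique())
    alloc: Dict[str, List[int]] = {}
    floors: Dict[str, List[int]] = {}
    cum_quota = np.zeros(n_splits)
    cum_alloc = np.zeros(n_splits, dtype=int)
    for key in strata_sorted:
        n_i = int((keys == key).sum())
        quotas = [n_i * f for f in fractions]
        base = [int(math.floor(q)) for q in quotas]
        floors[key] = list(base)
        leftover = n_i - sum(base)
        cum_quota += quotas
        deficit = cum_quota - (cum_alloc + base)
        order = sorted(range(n_splits), key=lambda s: (-deficit[s], s))
        a = list(base)
        for s in order[:leftover]:
            a[s] += 1
        alloc[key] = a
        cum_alloc += a

    # final correction (at most one unit per split) to hit the global
    # largest-remainder target exactly
    totals = list(cum_alloc)
    while totals != global_target:
        s_over = next(s for s in range(n_splits) if totals[s] > global_target[s])
        s_under = next(s for s in range(n_splits) if totals[s] < global_target[s])
        donor = next(k for k in strata_sorted
                     if alloc[k][s_over] > floors[k][s_over]
                     and alloc[k][s_under] <= floors[k][s_under])
        alloc[donor][s_over] -= 1
        alloc[donor][s_under] += 1
        totals[s_over] -= 1
        totals[s_under] += 1

    assignment: Dict[str, str] = {}
    for key in strata_sorted:
        ids = sorted(table.loc[keys == key, "image_id"])
        rng.shuffle(ids)
        start = 0
        for split, count in zip(SPLITS, alloc[key]):
            for image_id in ids[start:start + count]:
                assignment[image_id] = split
            start += count

    result = pd.Series(assignment, name="split").reindex(table["image_id"])
    _assert_patient_disjoint(table, result)
    return result


def _assert_patient_disjoint(table: pd.DataFrame, assignment: pd.Series) -> None:
    if "patient_id" not in table:
        return
    merged = table[["image_id", "patient_id"]].merge(
        assignment.rename("split"), left_on="image_id", right_index=True)
    per_patient = merged.groupby("patient_id")["split"].nunique()
    if (per_patient > 1).any():
        bad = per_patient.index[per_patient > 1][0]
        raise ValueError(
            f"patient {bad!r} spans multiple splits; deduplicate with "
            "select_one_per_patient before partitioning")
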