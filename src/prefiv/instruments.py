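"""Surrogate instruments from physicians' prescription histories.

A physician's latent preference for one drug over another cannot be
observed, but the prescriptions they issued to earlier patients can.  Three
surrogate instruments are supported: the most recent prior prescription (one
binary column), the count of comparator prescriptions over the previous
``depth`` patients, and a set of ``depth`` most-recent-first indicator
columns.

"Prior prescriptions" are first-time (index) prescriptions of earlier
patients at the same physician; the current patient's own records never
contribute, and no instrument ever uses a prescription dated on or after the
row's index date (only strictly earlier dates qualify; same-date earlier
history entries are ordered among themselves by patient id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["InstrumentSpec", "build_instrument", "instrument_coverage"]


@dataclass(frozen=True)
class InstrumentSpec:
    """Form and depth of a surrogate instrument.

    ``most_recent`` requires ``depth == 1``; ``count`` and ``indicators``
    require ``depth >= 2``.
    """

    depth: int = 1
    form: str = "most_recent"

    def __post_init__(self):
        if self.form not in ("most_recent", "count", "indicators"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "most_recent" and self.depth != 1:
            raise ValueError("most_recent requires depth=1")
        if self.form in ("count", "indicators") and self.depth < 2:
            raise ValueError(f"{self.form} requires depth >= 2")

    @property
    def columns(self) -> list:
        if self.form == "most_recent":
            return ["Z1"]
        if self.form == "count":
            return [f"Z_count{self.depth}"]
        return [f"Z_ind{self.depth}_{j}" for j in range(1, self.depth + 1)]


def _comparator_indicator(hist: pd.DataFrame, contrast: str) -> np.ndarray:
    if contrast == "tca-ssri":
        return (hist["drug_class"] == "TCA").to_numpy(np.float64)
    if contrast == "parox-ssri":
        return (hist["drug_name"] == "paroxetine").to_numpy(np.float64)
    raise ValueError(f"unknown contrast {contrast!r}")


def build_instrument(cohort, prescriptions, spec: InstrumentSpec, contrast: str = "tca-ssri"):
    """Append instrument column(s) to the cohort.

    For each cohort row, the physician's previous ``depth`` qualifying
    prescriptions (first prescriptions of distinct earlier patients, strictly
    before the index date, the current patient excluded) are located.  Rows
    whose physician lacks ``depth`` priors are dropped and counted.

    Returns ``(cohort_with_columns, coverage)`` where ``coverage`` is the
    ``(loss, percent)`` pair of :func:`instrument_coverage`.
    """
    k = spec.depth
    hist = prescriptions.loc[
        prescriptions["date"].notna() & prescriptions["physician_id"].notna(),
        ["patient_id", "physician_id", "date", "drug_class", "drug_name"],
    ].copy()
    # per-patient first prescription = that patient's index event
    hist = hist.sort_values(["patient_id", "date"], kind="stable")
    hist = hist.drop_duplicates("patient_id", keep="first")
    hist = hist.sort_values(["physician_id", "date", "patient_id"], kind="stable")
    hist["z"] = _comparator_indicator(hist, contrast)

    # lag j = j-th most recent history entry at or before each history row;
    # one extra lag so a self-match can be skipped
    g = hist.groupby("physician_id", sort=False)
    lag_z, lag_pid = [], []
    for j in range(k + 1):
        lag_z.append(g["z"].shift(j))
        lag_pid.append(g["patient_id"].shift(j))
    for j in range(k + 1):
        hist[f"_z{j}"] = lag_z[j]
        hist[f"_p{j}"] = lag_pid[j]

    cohort = cohort.reset_index(drop=True)
    cand = cohort[["patient_id", "physician_id", "index_date"]].copy()
    cand["physician_id"] = cand["physician_id"].astype(np.float64)
    hist["physician_id"] = hist["physician_id"].astype(np.float64)
    cand["_row"] = np.arange(len(cand))
    zcols = [f"_z{j}" for j in range(k + 1)] + [f"_p{j}" for j in range(k + 1)]
    merged = pd.merge_asof(
        cand.sort_values("index_date", kind="stable").reset_index(drop=True),
        hist[["physician_id", "date"] + zcols].sort_values("date", kind="stable").reset_index(drop=True),
        left_on="index_date",
        right_on="date",
        by="physician_id",
        allow_exact_matches=False,
        direction="backward",
    ).sort_values("_row", kind="stable")

    z = np.column_stack([merged[f"_z{j}"].to_numpy(np.float64) for j in range(k + 1)])
    pid = np.column_stack([merged[f"_p{j}"].to_numpy(np.float64) for j in range(k + 1)])
    own = merged["patient_id"].to_numpy(np.float64)[:, None]
    is_self = pid == own
    # drop the (at most one) self entry, shifting deeper lags forward
    out = np.full((len(merged), k), np.nan)
    has_self = is_self.any(axis=1)
    s = np.where(has_self, is_self.argmax(axis=1), k + 1)
    for j in range(k):
        out[:, j] = np.where(j < s, z[:, j], z[:, j + 1])

    complete = ~np.isnan(out).any(axis=1)
    kept = cohort[complete].copy()
    vals = out[complete]
    if spec.form == "most_recent":
        kept["Z1"] = vals[:, 0].astype(np.int8)
    elif spec.form == "count":
        kept[spec.columns[0]] = vals.sum(axis=1).astype(np.int64)
    else:
        for j, col in enumerate(spec.columns):
            kept[col] = vals[:, j].astype(np.int8)
    coverage = instrument_coverage(cohort, kept)
    return kept.reset_index(drop=True), coverage


def instrument_coverage(cohort_before, cohort_after):
    """Rows lost to insufficient physician history, as (count, percent)."""
    n_before = cohort_before if isinstance(cohort_before, (int, np.integer)) else len(cohort_before)
    n_after = cohort_after if isinstance(cohort_after, (int, np.integer)) else len(cohort_after)
    if n_after > n_before:
        raise ValueError("cohort_after larger than cohort_before")
    loss = n_before - n_after
    pct = 100.0 * loss / n_before if n_before else 0.0
    return loss, pct
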