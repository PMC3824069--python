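"""Cohort construction: index prescriptions, exclusions, covariates, outcome.

The analysis cohort holds one row per patient at their first ("index")
antidepressant prescription.  Construction follows the usual primary-care
database workflow: clean invalid prescription records, keep each patient's
earliest remaining prescription, apply the cohort exclusion rules in a fixed
documented order while logging attrition, code the exposure contrast, attach
baseline covariates, and link the rare outcome within a short post-index
window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import COVARIATES

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionRules",
    "AttritionLog",
    "EXCLUSION_ORDER",
    "select_index_prescriptions",
    "apply_exclusions",
    "attach_outcome",
    "filter_low_dose_amitriptyline",
    "filter_bmi_range",
    "physician_prior_counts",
]

#: Default order of the cohort exclusion rules.
EXCLUSION_ORDER = [
    "within_12_months_of_registration",
    "outside_study_window",
    "non_physician_prescriber",
    "missing_physician_id",
    "age_under_10",
    "missing_birth_year",
    "fewer_than_10_prior_prescriptions",
]


@dataclass
class ExclusionRules:
    """Configuration of the exclusion rules and the exposure contrast.

    ``contrast`` is ``"tca-ssri"`` (exposure 1 = TCA) or ``"parox-ssri"``
    (exposure 1 = paroxetine, TCA patients dropped).  ``prior_count_mode``
    chooses whether a physician's "prior prescriptions" are counted over
    first-time (index) prescriptions per patient (``"index"``) or over all
    prescription events (``"all"``).
    """

    contrast: str = "tca-ssri"
    window_start: str = "1995-01-01"
    window_end: str = "2010-06-30"
    min_registration_days: int = 365
    min_age: int = 10
    min_prior_prescriptions: int = 10
    prior_count_mode: str = "index"
    order: list = field(default_factory=lambda: list(EXCLUSION_ORDER))

    def validate(self):
        if pd.Timestamp(self.window_start) >= pd.Timestamp(self.window_end):
            raise ValueError("calendar window inverted")
        unknown = set(self.order) - set(EXCLUSION_ORDER)
        if unknown:
            raise ValueError(f"unknown rule name(s): {sorted(unknown)}")
        if self.contrast not in ("tca-ssri", "parox-ssri"):
            raise ValueError(f"unknown contrast {self.contrast!r}")


class AttritionLog:
    """Ordered record of rows removed by each rule.

    Invariant: input count minus the sum of removals equals the final count.
    """

    def __init__(self, n_start: int):
        self.n_start = int(n_start)
        self.rows: list[dict] = []

    def record(self, rule: str, removed: int) -> None:
        remaining = (self.rows[-1]["remaining"] if self.rows else self.n_start) - removed
        self.rows.append({"rule": rule, "removed": int(removed), "remaining": int(remaining)})
        logger.info("exclusion %-40s removed %7d remaining %8d", rule, removed, remaining)

    def removed(self, rule: str) -> int:
        return sum(r["removed"] for r in self.rows if r["rule"] == rule)

    @property
    def final_remaining(self) -> int:
        return self.rows[-1]["remaining"] if self.rows else self.n_start

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rule", "removed", "remaining"])


def select_index_prescriptions(prescriptions, patients):
    """Pick each patient's earliest valid prescription.

    Records are dropped (and counted) if they are missing a date, predate the
    patient's registration, or postdate the registration end.  Only patients
    present in the patient table are candidates.  Same-date ties are broken
    by (drug_class, drug_name, record id).

    Returns ``(candidates, record_log)`` where ``record_log`` maps the three
    record-level rules to counts.
    """
    rx = prescriptions.reset_index(drop=True).copy()
    rx["record_id"] = np.arange(len(rx))
    reg = patients[["patient_id", "registration_start", "registration_end"]]
    rx = rx.merge(reg, on="patient_id", how="inner")

    dup = rx.duplicated(["patient_id", "date", "drug_name"], keep=False) & rx["date"].notna()
    n_dup = int(dup.sum())
    if n_dup:
        warnings.warn(f"{n_dup} exact duplicate (patient, date, drug) prescription rows")

    missing = rx["date"].isna()
    pre_reg = rx["date"].notna() & (rx["date"] < rx["registration_start"])
    post_dereg = (
        rx["date"].notna()
        & rx["registration_end"].notna()
        & (rx["date"] > rx["registration_end"])
    )
    record_log = {
        "missing_date_record": int(missing.sum()),
        "pre_registration_record": int(pre_reg.sum()),
        "post_deregistration_record": int(post_dereg.sum()),
    }
    rx = rx[~(missing | pre_reg | post_dereg)]

    rx = rx.sort_values(
        ["patient_id", "date", "drug_class", "drug_name", "record_id"], kind="stable"
    )
    cand = rx.drop_duplicates("patient_id", keep="first").copy()
    cand = cand.rename(columns={"date": "index_date"})
    cand["index_year"] = cand["index_date"].dt.year
    cols = [
        "patient_id",
        "physician_id",
        "practice_id",
        "prescriber_is_physician",
        "index_date",
        "index_year",
        "drug_class",
        "drug_name",
        "dose_mg",
    ]
    if "practice_linked" in cand.columns:
        cols.insert(3, "practice_linked")
    return cand[cols].reset_index(drop=True), record_log


def physician_prior_counts(candidates, prescriptions, mode="index"):
    """Count each physician's prescriptions issued strictly before each
    candidate's index date, excluding the candidate's own records.

    Returns a DataFrame aligned with ``candidates`` holding ``n_prior``,
    ``n_prior_ssri``, ``n_prior_tca`` and ``n_prior_paroxetine``.
    """
    hist = prescriptions.loc[
        prescriptions["date"].notna() & prescriptions["physician_id"].notna(),
        ["patient_id", "physician_id", "date", "drug_class", "drug_name"],
    ].copy()
    if mode == "index":
        hist = hist.sort_values(["patient_id", "date"], kind="stable")
        hist = hist.drop_duplicates("patient_id", keep="first")
    elif mode != "all":
        raise ValueError(f"unknown prior_count_mode {mode!r}")
    hist = hist.sort_values(["physician_id", "date", "patient_id"], kind="stable")
    g = hist.groupby("physician_id", sort=False)
    hist["n_cum"] = g.cumcount() + 1
    hist["is_ssri"] = (hist["drug_class"] == "SSRI").astype(np.int64)
    hist["is_tca"] = (hist["drug_class"] == "TCA").astype(np.int64)
    hist["is_parox"] = (hist["drug_name"] == "paroxetine").astype(np.int64)
    for c in ("is_ssri", "is_tca", "is_parox"):
        hist["cum_" + c[3:]] = g[c].cumsum()

    cand = candidates[["patient_id", "physician_id", "index_date", "drug_class", "drug_name"]].copy()
    cand["physician_id"] = cand["physician_id"].astype(np.float64)
    hist["physician_id"] = hist["physician_id"].astype(np.float64)
    cand["_row"] = np.arange(len(cand))
    merged = pd.merge_asof(
        cand.sort_values("index_date", kind="stable").reset_index(drop=True),
        hist[["physician_id", "date", "n_cum", "cum_ssri", "cum_tca", "cum_parox"]]
        .sort_values("date", kind="stable")
        .reset_index(drop=True),
        left_on="index_date",
        right_on="date",
        by="physician_id",
        allow_exact_matches=False,
        direction="backward",
    )
    merged = merged.sort_values("_row", kind="stable")
    out = pd.DataFrame(
        {
            "n_prior": merged["n_cum"].fillna(0).to_numpy(np.int64),
            "n_prior_ssri": merged["cum_ssri"].fillna(0).to_numpy(np.int64),
            "n_prior_tca": merged["cum_tca"].fillna(0).to_numpy(np.int64),
            "n_prior_paroxetine": merged["cum_parox"].fillna(0).to_numpy(np.int64),
        }
    )

    # a candidate's own earlier record (if any) must not count toward their
    # physician's prior prescriptions
    own = hist[["patient_id", "date", "drug_class", "drug_name"]].rename(
        columns={"date": "own_first_date", "drug_class": "own_class", "drug_name": "own_name"}
    )
    cand2 = cand.sort_values("_row", kind="stable").merge(own, on="patient_id", how="left")
    self_prior = (
        cand2["own_first_date"].notna()
        & (cand2["own_first_date"] < cand2["index_date"].to_numpy())
    ).to_numpy()
    out.loc[self_prior, "n_prior"] -= 1
    out.loc[self_prior & (cand2["own_class"] == "SSRI").to_numpy(), "n_prior_ssri"] -= 1
    out.loc[self_prior & (cand2["own_class"] == "TCA").to_numpy(), "n_prior_tca"] -= 1
    out.loc[self_prior & (cand2["own_name"] == "paroxetine").to_numpy(), "n_prior_paroxetine"] -= 1
    out.index = candidates.index
    return out


def _assemble_covariates(cand, patients):
    pat = patients.set_index("patient_id").drop(columns=["registration_start", "registration_end"])
    overlap = [c for c in pat.columns if c in cand.columns]
    joined = cand.drop(columns=overlap).join(pat, on="patient_id")
    joined["age_at_index"] = joined["index_year"] - joined["birth_year"]
    joined["age_over_40"] = (joined["age_at_index"] > 40).astype(float)
    joined.loc[joined["birth_year"].isna(), "age_over_40"] = np.nan
    joined["male"] = (joined["sex"] == "M").astype(float)
    joined["bmi_over_25"] = np.where(
        joined["bmi"].notna(), (joined["bmi"] > 25).astype(float), np.nan
    )
    return joined


def apply_exclusions(candidates, patients, prescriptions, rules: ExclusionRules):
    """Apply the cohort exclusion rules in order; return (cohort, AttritionLog).

    A row violating several rules is counted under the first rule in
    ``rules.order`` that catches it.  Contrast-specific rules (no prior
    prescription of the compared classes; for the paroxetine contrast, TCA
    patients) are applied after the seven generic rules.
    """
    rules.validate()
    cand = candidates.reset_index(drop=True).copy()
    reg = patients[["patient_id", "registration_start", "registration_end", "birth_year"]]
    cand = cand.merge(reg, on="patient_id", how="left", suffixes=("", "_pat"))
    if "birth_year_pat" in cand.columns:
        cand["birth_year"] = cand["birth_year_pat"]
    priors = physician_prior_counts(cand, prescriptions, mode=rules.prior_count_mode)
    cand = cand.drop(columns=[c for c in priors.columns if c in cand.columns])
    cand = pd.concat([cand, priors], axis=1)

    w0, w1 = pd.Timestamp(rules.window_start), pd.Timestamp(rules.window_end)
    age = cand["index_year"] - cand["birth_year"]
    masks = {
        "within_12_months_of_registration": (
            cand["index_date"] - cand["registration_start"]
        ).dt.days < rules.min_registration_days,
        "outside_study_window": (cand["index_date"] < w0) | (cand["index_date"] > w1),
        "non_physician_prescriber": ~cand["prescriber_is_physician"].astype(bool),
        "missing_physician_id": cand["physician_id"].isna(),
        "age_under_10": cand["birth_year"].notna() & (age < rules.min_age),
        "missing_birth_year": cand["birth_year"].isna(),
        "fewer_than_10_prior_prescriptions": cand["n_prior"] < rules.min_prior_prescriptions,
    }

    log = AttritionLog(len(cand))
    keep = np.ones(len(cand), dtype=bool)
    for rule in rules.order:
        hit = masks[rule].to_numpy() & keep
        log.record(rule, hit.sum())
        keep &= ~hit

    if rules.contrast == "tca-ssri":
        hit = ((cand["n_prior_tca"] + cand["n_prior_ssri"]) == 0).to_numpy() & keep
        log.record("physician_no_prior_tca_or_ssri", hit.sum())
        keep &= ~hit
    else:
        hit = (cand["drug_class"] == "TCA").to_numpy() & keep
        log.record("tca_index_prescription", hit.sum())
        keep &= ~hit
        hit = (cand["n_prior_ssri"] == 0).to_numpy() & keep
        log.record("physician_no_prior_ssri", hit.sum())
        keep &= ~hit

    cohort = cand[keep].copy()
    cohort = _assemble_covariates(cohort, patients)
    if rules.contrast == "tca-ssri":
        cohort["X"] = (cohort["drug_class"] == "TCA").astype(np.int8)
    else:
        cohort["X"] = (cohort["drug_name"] == "paroxetine").astype(np.int8)
    cohort["physician_id"] = cohort["physician_id"].astype(np.int64)
    if "practice_linked" in cohort.columns:
        cohort["linked"] = cohort["practice_linked"].astype(bool)
    keep_cols = [
        "patient_id",
        "physician_id",
        "practice_id",
        "prescriber_is_physician",
        "index_date",
        "index_year",
        "drug_class",
        "drug_name",
        "dose_mg",
        "registration_start",
        "registration_end",
        "birth_year",
        "bmi",
        "X",
        "n_prior",
        "n_prior_ssri",
        "n_prior_tca",
        "n_prior_paroxetine",
    ] + COVARIATES
    if "linked" in cohort.columns:
        keep_cols.append("linked")
    if "practice_linked" in cohort.columns:
        keep_cols.append("practice_linked")
    return cohort[keep_cols].reset_index(drop=True), log


def attach_outcome(
    cohort,
    outcome_events,
    window_days: int = 91,
    drop_prior_self_harm: bool = False,
    linked_only: bool = False,
):
    """Attach the binary outcome Y within ``(index, index + window_days]``.

    Events on the index date itself are excluded (they may be the indication
    for treatment rather than a consequence); the right end of the window is
    closed.  Returns ``(cohort, info)`` with the number of rows dropped for a
    pre-index self-harm admission and for lack of outcome linkage.
    """
    if window_days < 0:
        raise ValueError("window_days must be nonnegative")
    out = cohort.copy()
    info = {"n_prior_self_harm_dropped": 0, "n_unlinked_dropped": 0}
    if linked_only and "linked" in out.columns:
        n0 = len(out)
        out = out[out["linked"]]
        info["n_unlinked_dropped"] = n0 - len(out)

    ev = outcome_events.merge(
        out[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    if drop_prior_self_harm:
        prior = ev[(ev["event_type"] == "self_harm") & (ev["event_date"] <= ev["index_date"])]
        bad = set(prior["patient_id"])
        info["n_prior_self_harm_dropped"] = int(out["patient_id"].isin(bad).sum())
        out = out[~out["patient_id"].isin(bad)]
        ev = ev[~ev["patient_id"].isin(bad)]

    in_window = (ev["event_date"] > ev["index_date"]) & (
        ev["event_date"] <= ev["index_date"] + pd.Timedelta(days=window_days)
    )
    hits = set(ev.loc[in_window, "patient_id"])
    out["Y"] = out["patient_id"].isin(hits).astype(np.int8)
    return out.reset_index(drop=True), info


def filter_low_dose_amitriptyline(cohort, prescriptions=None, threshold_mg: float = 13.0):
    """Drop rows whose index prescription is amitriptyline below ``threshold_mg``.

    Rows with a missing dose are retained and counted.  Returns
    ``(cohort, n_removed, n_missing_dose_retained)``.
    """
    if threshold_mg <= 0:
        raise ValueError("threshold_mg must be positive")
    is_ami = cohort["drug_name"] == "amitriptyline"
    missing = is_ami & cohort["dose_mg"].isna()
    low = is_ami & (cohort["dose_mg"] < threshold_mg)
    n_removed = int(low.sum())
    if missing.any():
        logger.info("%d amitriptyline rows with missing dose retained", int(missing.sum()))
    return cohort[~low].reset_index(drop=True), n_removed, int(missing.sum())


def filter_bmi_range(patients, low: float = 15.0, high: float = 100.0):
    """Set BMI values outside ``[low, high]`` to missing (likely data errors).

    Boundary values (exactly ``low`` or ``high``) are retained.  Returns
    ``(patients, n_set_missing)``.
    """
    if low >= high:
        raise ValueError("low must be below high")
    out = patients.copy()
    bad = out["bmi"].notna() & ((out["bmi"] < low) | (out["bmi"] > high))
    out.loc[bad, "bmi"] = np.nan
    return out, int(bad.sum())
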