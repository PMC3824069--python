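"""Synthetic physician-clustered prescribing data with known latent structure.

The generator emulates the situation in which preference-based instrumental
variables are used: physicians hold a latent, continuous preference for one
antidepressant class over another; each new patient's prescription is driven
by that preference, by observed case-mix covariates, by an unmeasured
confounder, and by a secular trend; and a rare binary outcome (self-harm
admission or suicide) may occur within a short window after the index
prescription.  Because the latent quantities (per-physician preference, the
patient-level confounder, the true risk difference) are returned alongside
the observable tables, estimator bias and instrument validity can be checked
against ground truth.

Drug choice is Bernoulli on the log-odds scale,

    logit P(X=1) = intercept_rx + alpha_phys + drift*t + sum_c beta_c C_c
                   + gamma_rx * U + trend_rx * t,

with ``alpha_phys ~ N(0, preference_sd^2)`` the physician preference and
``t`` years since the calendar start.  The outcome is a clipped linear
probability model,

    P(Y=1) = clip(baseline_risk + tau*X/100 + gamma_y*U/100, 0, 1),

so that the risk-difference estimand equals the configured ``tau`` exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATES",
    "DEFAULT_PREVALENCES",
    "DEFAULT_COVARIATE_EFFECTS",
    "SimulationConfig",
    "LatentTruth",
    "generate_population",
    "make_messy_fixture",
    "MESSY_RULES",
    "write_tables",
    "read_tables",
]

#: The twelve binary baseline covariates carried through every balance table.
COVARIATES = [
    "bmi_over_25",
    "hospitalized_prior_year",
    "consultations_over_13",
    "age_over_40",
    "prescriptions_over_5",
    "male",
    "ever_smoked",
    "prior_depression",
    "prior_self_harm",
    "prior_hypnotic",
    "prior_antipsychotic",
    "charlson_gt_0",
]

# Marginal prevalences of the covariates in a UK primary-care antidepressant
# cohort (pooled over both exposure arms).
DEFAULT_PREVALENCES = {
    "bmi_over_25": 0.545,
    "hospitalized_prior_year": 0.004,
    "consultations_over_13": 0.685,
    "age_over_40": 0.623,
    "prescriptions_over_5": 0.610,
    "male": 0.386,
    "ever_smoked": 0.481,
    "prior_depression": 0.517,
    "prior_self_harm": 0.058,
    "prior_hypnotic": 0.148,
    "prior_antipsychotic": 0.022,
    "charlson_gt_0": 0.382,
}

# Log-odds effects of each covariate on receiving the comparator drug.  Signs
# and rough magnitudes mirror the imbalance pattern seen in routine data:
# older, heavily-consulting, multimorbid patients are steered toward TCAs,
# smokers and patients with a recorded depression diagnosis toward SSRIs.
DEFAULT_COVARIATE_EFFECTS = {
    "bmi_over_25": 0.30,
    "hospitalized_prior_year": 0.10,
    "consultations_over_13": 0.75,
    "age_over_40": 0.90,
    "prescriptions_over_5": 0.90,
    "male": -0.08,
    "ever_smoked": -0.65,
    "prior_depression": -0.80,
    "prior_self_harm": 0.0,
    "prior_hypnotic": 0.20,
    "prior_antipsychotic": 0.15,
    "charlson_gt_0": 0.40,
}

# Drug names used when materializing the binary choice as prescription rows.
_TCA_NAMES = ["amitriptyline", "dosulepin", "lofepramine"]
_SSRI_OTHER_NAMES = ["fluoxetine", "citalopram", "sertraline"]
_TCA_DOSES = [75.0, 100.0, 150.0]  # mg; deliberately above low-dose cutoffs


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return math.log(p / (1.0 - p))


@dataclass
class SimulationConfig:
    """Parameters of the data-generating process.

    ``treatment_effect`` and ``confounder_effect_y`` are risk differences per
    100 patients; preference and covariate effects are on the log-odds scale.
    """

    n_physicians: int = 500
    patients_per_physician: int = 100
    preference_sd: float = 1.0
    preference_drift: float = 0.0
    covariate_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    casemix_sd: float = 0.05
    confounder_effect_rx: float = 0.5
    covariate_effects_rx: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    trend_rx: float = -0.05
    baseline_risk: float = 0.0015
    treatment_effect: float = -0.05
    confounder_effect_y: float = 0.2
    calendar_start: int = 1995
    calendar_end: int = 2010
    seed: int = 0
    # ---- plumbing knobs -------------------------------------------------
    intercept_rx: float = -0.8  # with the default covariate effects: ~55% comparator share
    history_per_physician: int = 10
    physicians_per_practice: int = 5
    linked_fraction: float = 0.5
    contrast: str = "tca-ssri"
    paroxetine_share: float = 0.5  # share of paroxetine among warm-up SSRIs (contrast B)
    outcome_window_days: int = 91

    def validate(self) -> None:
        if self.n_physicians <= 0 or self.patients_per_physician <= 0:
            raise ValueError("n_physicians and patients_per_physician must be positive")
        if self.preference_sd < 0 or self.casemix_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0 < self.baseline_risk < 1:
            raise ValueError("baseline_risk must be in (0, 1)")
        for name, p in self.covariate_prevalences.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence of {name!r} must be in (0, 1)")
        if self.calendar_start >= self.calendar_end:
            raise ValueError("calendar_start must precede calendar_end")
        if self.contrast not in ("tca-ssri", "parox-ssri"):
            raise ValueError(f"unknown contrast {self.contrast!r}")


@dataclass
class LatentTruth:
    """Hidden quantities of a generated population, for recovery tests."""

    physician_preferences: dict
    patient_confounders: dict
    true_effect: float


def _comparator_names(contrast: str):
    if contrast == "tca-ssri":
        return _TCA_NAMES, "TCA", _SSRI_OTHER_NAMES, "SSRI"
    return ["paroxetine"], "SSRI", _SSRI_OTHER_NAMES, "SSRI"


def generate_population(config: SimulationConfig):
    """Generate (prescriptions, patients, outcomes, LatentTruth).

    Each physician issues ``history_per_physician`` warm-up prescriptions (to
    pseudo-patients with negative ids, present only in the prescription
    table) followed by ``patients_per_physician`` index prescriptions in
    strict date order.  Identical configs produce byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_phys = config.n_physicians
    n_pat = config.patients_per_physician
    n = n_phys * n_pat

    phys_ids = np.arange(1, n_phys + 1)
    practice_ids = (phys_ids - 1) // config.physicians_per_practice + 1
    n_practices = int(practice_ids.max())
    practice_linked = rng.random(n_practices) < config.linked_fraction
    alpha = rng.normal(0.0, config.preference_sd, n_phys)

    # --- patients ---------------------------------------------------------
    pat_phys = np.repeat(phys_ids, n_pat)
    pat_practice = np.repeat(practice_ids, n_pat)
    patient_id = np.arange(1, n + 1)

    start = pd.Timestamp(f"{config.calendar_start}-01-01")
    end = pd.Timestamp(f"{config.calendar_end}-06-30")
    span_days = (end - start).days
    offsets = rng.integers(0, span_days + 1, n)
    # order patients by arrival within physician (ties broken by patient id,
    # which is the stable sort order here)
    offsets = np.sort(offsets.reshape(n_phys, n_pat), axis=1).ravel()
    index_date = start + pd.to_timedelta(offsets, unit="D")
    t_years = offsets / 365.25

    # covariates: physician-level random shift on the log-odds scale induces
    # case-mix clustering shared by all of a physician's patients
    cov = {}
    for name in COVARIATES:
        p = config.covariate_prevalences[name]
        shift = rng.normal(0.0, config.casemix_sd, n_phys)
        prob = _sigmoid(_logit(p) + np.repeat(shift, n_pat))
        cov[name] = (rng.random(n) < prob).astype(np.int8)

    u = (rng.random(n) < 0.5).astype(np.int8)

    # --- drug choice ------------------------------------------------------
    logits = (
        config.intercept_rx
        + np.repeat(alpha, n_pat)
        + config.preference_drift * t_years
        + config.confounder_effect_rx * u
        + config.trend_rx * t_years
    )
    for name in COVARIATES:
        beta = config.covariate_effects_rx.get(name, 0.0)
        if beta:
            logits = logits + beta * cov[name]
    x = (rng.random(n) < _sigmoid(logits)).astype(np.int8)

    # --- outcome (clipped linear risk model) ------------------------------
    risk_raw = (
        config.baseline_risk
        + config.treatment_effect * x / 100.0
        + config.confounder_effect_y * u / 100.0
    )
    n_clipped = int(((risk_raw < 0) | (risk_raw > 1)).sum())
    if n_clipped > 0.01 * n:
        raise ValueError(
            f"linear risk model clipped on {n_clipped}/{n} rows (>1%): "
            "configuration inconsistent with a linear risk difference"
        )
    y = (rng.random(n) < np.clip(risk_raw, 0.0, 1.0)).astype(np.int8)

    # --- materialize raw patient fields consistent with the indicators ----
    index_year = index_date.year.to_numpy()
    age = np.where(
        cov["age_over_40"] == 1,
        rng.integers(41, 81, n),
        rng.integers(11, 41, n),
    )
    birth_year = index_year - age
    sex = np.where(cov["male"] == 1, "M", "F")
    bmi = np.where(
        cov["bmi_over_25"] == 1,
        np.round(rng.uniform(25.1, 40.0, n), 1),
        np.round(rng.uniform(15.5, 25.0, n), 1),
    )
    reg_lag = rng.integers(400, 3000, n)  # days; always > 12 months
    registration_start = index_date - pd.to_timedelta(reg_lag, unit="D")

    comp_names, comp_class, ref_names, ref_class = _comparator_names(config.contrast)
    drug_name = np.where(
        x == 1,
        np.asarray(comp_names)[rng.integers(0, len(comp_names), n)],
        np.asarray(ref_names)[rng.integers(0, len(ref_names), n)],
    )
    drug_class = np.where(x == 1, comp_class, ref_class)
    dose = np.where(
        np.isin(drug_name, _TCA_NAMES),
        np.asarray(_TCA_DOSES)[rng.integers(0, len(_TCA_DOSES), n)],
        20.0,
    )

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "birth_year": birth_year.astype(float),
            "sex": sex,
            "registration_start": registration_start,
            "registration_end": pd.NaT,
            "bmi": bmi,
            **{
                name: cov[name]
                for name in COVARIATES
                if name not in ("bmi_over_25", "age_over_40", "male")
            },
        }
    )

    prescriptions = pd.DataFrame(
        {
            "patient_id": patient_id,
            "physician_id": pat_phys.astype(float),
            "practice_id": pat_practice,
            "practice_linked": practice_linked[pat_practice - 1],
            "prescriber_is_physician": True,
            "date": index_date,
            "drug_class": drug_class,
            "drug_name": drug_name,
            "dose_mg": dose,
        }
    )

    # --- warm-up history --------------------------------------------------
    n_hist = config.history_per_physician
    if n_hist > 0:
        h_phys = np.repeat(phys_ids, n_hist)
        nh = n_phys * n_hist
        h_logits = config.intercept_rx + np.repeat(alpha, n_hist)
        h_x = (rng.random(nh) < _sigmoid(h_logits)).astype(np.int8)
        h_name = np.where(
            h_x == 1,
            np.asarray(comp_names)[rng.integers(0, len(comp_names), nh)],
            np.asarray(ref_names)[rng.integers(0, len(ref_names), nh)],
        )
        if config.contrast == "tca-ssri":
            # some warm-up SSRIs are paroxetine so contrast-B history exists
            parox = (h_x == 0) & (rng.random(nh) < config.paroxetine_share)
            h_name = np.where(parox, "paroxetine", h_name)
        h_class = np.where(np.isin(h_name, _TCA_NAMES), "TCA", "SSRI")
        h_dose = np.where(
            np.isin(h_name, _TCA_NAMES),
            np.asarray(_TCA_DOSES)[rng.integers(0, len(_TCA_DOSES), nh)],
            20.0,
        )
        # spread warm-ups over the year before the calendar window
        k = np.tile(np.arange(n_hist), n_phys)
        h_date = start - pd.to_timedelta((n_hist - k) * 30, unit="D")
        history = pd.DataFrame(
            {
                "patient_id": -np.arange(1, nh + 1),
                "physician_id": h_phys.astype(float),
                "practice_id": practice_ids[h_phys - 1],
                "practice_linked": practice_linked[practice_ids[h_phys - 1] - 1],
                "prescriber_is_physician": True,
                "date": h_date,
                "drug_class": h_class,
                "drug_name": h_name,
                "dose_mg": h_dose,
            }
        )
        prescriptions = pd.concat([history, prescriptions], ignore_index=True)

    # --- outcome events ---------------------------------------------------
    hit = np.flatnonzero(y == 1)
    lag = rng.integers(1, config.outcome_window_days + 1, hit.size)
    outcomes = pd.DataFrame(
        {
            "patient_id": patient_id[hit],
            "event_date": index_date[hit] + pd.to_timedelta(lag, unit="D"),
            "event_type": np.where(rng.random(hit.size) < 0.9, "self_harm", "suicide"),
        }
    ).sort_values(["patient_id"], kind="stable", ignore_index=True)

    truth = LatentTruth(
        physician_preferences={int(p): float(a) for p, a in zip(phys_ids, alpha)},
        patient_confounders={int(i): int(v) for i, v in zip(patient_id, u)},
        true_effect=float(config.treatment_effect),
    )
    return prescriptions, patients, outcomes, truth


# ---------------------------------------------------------------------------
# messy fixtures
# ---------------------------------------------------------------------------

#: Rule names accepted by :func:`make_messy_fixture`.  The first seven are the
#: cohort exclusion rules, the next three are record-level cleaning rules, and
#: the last three exercise the sensitivity filters.
MESSY_RULES = [
    "within_12_months_of_registration",
    "outside_study_window",
    "non_physician_prescriber",
    "missing_physician_id",
    "age_under_10",
    "missing_birth_year",
    "fewer_than_10_prior_prescriptions",
    "pre_registration_record",
    "missing_date_record",
    "post_deregistration_record",
    "bmi_out_of_range",
    "amitriptyline_under_13",
    "amitriptyline_13_to_70",
]


def make_messy_fixture(config: SimulationConfig, violation_counts: dict):
    """Inject exactly-counted rule violations into a clean population.

    Returns ``(prescriptions, patients, outcomes, expected_log)`` where
    ``expected_log`` maps every rule in :data:`MESSY_RULES` to the number of
    rows the corresponding cleaning step should remove (or, for
    ``bmi_out_of_range``, set missing).  Patients are drawn without
    replacement so no row violates two rules at once.
    """
    for key in violation_counts:
        if key not in MESSY_RULES:
            raise ValueError(f"unknown rule {key!r}")
    prescriptions, patients, outcomes, truth = generate_population(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 915]))
    expected = {rule: int(violation_counts.get(rule, 0)) for rule in MESSY_RULES}

    n_needed = sum(
        v
        for k, v in expected.items()
        if k != "fewer_than_10_prior_prescriptions"
    )
    if n_needed > len(patients):
        raise ValueError("requested violations exceed population size")
    victims = rng.choice(patients["patient_id"].to_numpy(), n_needed, replace=False)
    pool = iter(victims)

    def take(k):
        return np.array([next(pool) for _ in range(k)], dtype=int)

    patients = patients.set_index("patient_id", drop=False)
    rx_index = prescriptions.set_index("patient_id", drop=False)

    def idx_date(pid):
        return rx_index.loc[pid, "date"]

    # (1) index within 12 months of joining the practice
    for pid in take(expected["within_12_months_of_registration"]):
        patients.loc[pid, "registration_start"] = idx_date(pid) - pd.Timedelta(days=100)
    # (2) index outside the study window
    window_end = pd.Timestamp("2010-06-30")
    for pid in take(expected["outside_study_window"]):
        mask = prescriptions["patient_id"] == pid
        prescriptions.loc[mask, "date"] = window_end + pd.Timedelta(days=30)
    # (3) prescriber not a physician
    for pid in take(expected["non_physician_prescriber"]):
        prescriptions.loc[prescriptions["patient_id"] == pid, "prescriber_is_physician"] = False
    # (4) missing physician id
    for pid in take(expected["missing_physician_id"]):
        prescriptions.loc[prescriptions["patient_id"] == pid, "physician_id"] = np.nan
    # (5) younger than 10 at index
    for pid in take(expected["age_under_10"]):
        patients.loc[pid, "birth_year"] = float(idx_date(pid).year - 5)
    # (6) missing birth year
    for pid in take(expected["missing_birth_year"]):
        patients.loc[pid, "birth_year"] = np.nan
    # (7) physician with <10 prior prescriptions: fresh physicians with one
    # patient each and no warm-up history
    k7 = expected["fewer_than_10_prior_prescriptions"]
    if k7:
        max_phys = int(np.nanmax(prescriptions["physician_id"]))
        max_pid = int(patients["patient_id"].max())
        new_rows, new_pat = [], []
        for j in range(k7):
            pid = max_pid + 1 + j
            phys = max_phys + 1 + j
            date = pd.Timestamp("2005-06-15") + pd.Timedelta(days=int(j))
            new_rows.append(
                {
                    "patient_id": pid,
                    "physician_id": float(phys),
                    "practice_id": int(prescriptions["practice_id"].max()) + 1 + j,
                    "practice_linked": True,
                    "prescriber_is_physician": True,
                    "date": date,
                    "drug_class": "SSRI",
                    "drug_name": "fluoxetine",
                    "dose_mg": 20.0,
                }
            )
            new_pat.append(
                {
                    "patient_id": pid,
                    "birth_year": 1960.0,
                    "sex": "F",
                    "registration_start": date - pd.Timedelta(days=900),
                    "registration_end": pd.NaT,
                    "bmi": 24.0,
                    **{
                        c: 0
                        for c in COVARIATES
                        if c not in ("bmi_over_25", "age_over_40", "male")
                    },
                }
            )
        prescriptions = pd.concat(
            [prescriptions, pd.DataFrame(new_rows)], ignore_index=True
        )
        patients = pd.concat(
            [patients, pd.DataFrame(new_pat).set_index("patient_id", drop=False)]
        )

    # record-level rules: extra prescription rows for existing patients,
    # dated before the index so they would otherwise *be* the index
    extra = []
    for pid in take(expected["pre_registration_record"]):
        extra.append(
            {
                "patient_id": pid,
                "physician_id": float(rx_index.loc[pid, "physician_id"]),
                "practice_id": rx_index.loc[pid, "practice_id"],
                "practice_linked": rx_index.loc[pid, "practice_linked"],
                "prescriber_is_physician": True,
                "date": patients.loc[pid, "registration_start"] - pd.Timedelta(days=50),
                "drug_class": "SSRI",
                "drug_name": "fluoxetine",
                "dose_mg": 20.0,
            }
        )
    for pid in take(expected["missing_date_record"]):
        extra.append(
            {
                "patient_id": pid,
                "physician_id": float(rx_index.loc[pid, "physician_id"]),
                "practice_id": rx_index.loc[pid, "practice_id"],
                "practice_linked": rx_index.loc[pid, "practice_linked"],
                "prescriber_is_physician": True,
                "date": pd.NaT,
                "drug_class": "SSRI",
                "drug_name": "citalopram",
                "dose_mg": 20.0,
            }
        )
    for pid in take(expected["post_deregistration_record"]):
        d0 = idx_date(pid)
        patients.loc[pid, "registration_end"] = d0 + pd.Timedelta(days=200)
        extra.append(
            {
                "patient_id": pid,
                "physician_id": float(rx_index.loc[pid, "physician_id"]),
                "practice_id": rx_index.loc[pid, "practice_id"],
                "practice_linked": rx_index.loc[pid, "practice_linked"],
                "prescriber_is_physician": True,
                "date": d0 + pd.Timedelta(days=300),
                "drug_class": "SSRI",
                "drug_name": "sertraline",
                "dose_mg": 20.0,
            }
        )
    if extra:
        prescriptions = pd.concat([prescriptions, pd.DataFrame(extra)], ignore_index=True)

    # sensitivity-filter rules
    for i, pid in enumerate(take(expected["bmi_out_of_range"])):
        patients.loc[pid, "bmi"] = 101.5 if i % 2 == 0 else 14.2
    for pid in take(expected["amitriptyline_under_13"]):
        mask = prescriptions["patient_id"] == pid
        prescriptions.loc[mask, ["drug_class", "drug_name", "dose_mg"]] = (
            "TCA",
            "amitriptyline",
            10.0,
        )
    for pid in take(expected["amitriptyline_13_to_70"]):
        mask = prescriptions["patient_id"] == pid
        prescriptions.loc[mask, ["drug_class", "drug_name", "dose_mg"]] = (
            "TCA",
            "amitriptyline",
            25.0,
        )

    patients = patients.reset_index(drop=True)
    return prescriptions, patients, outcomes, expected


# ---------------------------------------------------------------------------
# delimited I/O
# ---------------------------------------------------------------------------

_DATE_COLS = {
    "prescriptions": ["date"],
    "patients": ["registration_start", "registration_end"],
    "outcomes": ["event_date"],
}


def write_tables(outdir, prescriptions, patients, outcomes, truth=None):
    """Write the three tables as comma-separated text with ISO-8601 dates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prescriptions.to_csv(outdir / "prescriptions.csv", index=False, date_format="%Y-%m-%d")
    patients.to_csv(outdir / "patients.csv", index=False, date_format="%Y-%m-%d")
    outcomes.to_csv(outdir / "outcomes.csv", index=False, date_format="%Y-%m-%d")
    if truth is not None:
        (outdir / "latent_truth.json").write_text(
            json.dumps(dataclasses.asdict(truth), sort_keys=True)
        )


def read_tables(outdir):
    """Read tables written by :func:`write_tables`."""
    outdir = Path(outdir)
    prescriptions = pd.read_csv(outdir / "prescriptions.csv", parse_dates=_DATE_COLS["prescriptions"])
    patients = pd.read_csv(outdir / "patients.csv", parse_dates=_DATE_COLS["patients"])
    outcomes = pd.read_csv(outdir / "outcomes.csv", parse_dates=_DATE_COLS["outcomes"])
    truth = None
    tf = outdir / "latent_truth.json"
    if tf.exists():
        d = json.loads(tf.read_text())
        truth = LatentTruth(
            physician_preferences={int(k): v for k, v in d["physician_preferences"].items()},
            patient_confounders={int(k): v for k, v in d["patient_confounders"].items()},
            true_effect=d["true_effect"],
        )
    return prescriptions, patients, outcomes, truth
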