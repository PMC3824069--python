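"""Covariate balance diagnostics for instrument validity assessment.

An instrument is only useful if it is less associated with patient
characteristics than the actual prescription is.  This module quantifies
that comparison three ways: adjusted risk differences of each covariate by
exposure and by instrument (per 100, physician-clustered CIs), the
Mahalanobis distance between group covariate-mean vectors with the percent
reduction achieved by the instrument, and the prevalence difference ratio
(PDR) with its bias-comparison rule: when |PDR| exceeds the first-stage
strength E(X|Z=1) - E(X|Z=0), the instrumented analysis may carry *more*
bias from that covariate than the conventional one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import first_stage_diagnostics, ols_cluster, year_controls
from .simulate import COVARIATES

__all__ = [
    "BalanceRow",
    "ImbalanceSummary",
    "adjusted_risk_difference",
    "mahalanobis_imbalance",
    "imbalance_reduction",
    "prevalence_difference_ratio",
    "joint_covariate_association",
    "balance_table",
    "PDR_UNSTABLE_THRESHOLD",
]

#: Exposure risk differences smaller than this (per 100) make the PDR
#: denominator unstable; the ratio is then reported as missing.
PDR_UNSTABLE_THRESHOLD = 0.1


@dataclass
class BalanceRow:
    covariate: str
    rd_by_exposure: float
    rd_exposure_ci: tuple
    rd_by_instrument: float
    rd_instrument_ci: tuple
    pdr: float  # NaN when unstable
    pdr_flag: object  # True/False, or None when the PDR is unstable


@dataclass
class ImbalanceSummary:
    d_exposure: float
    d_instrument: float
    reduction_pct: float


def adjusted_risk_difference(cohort, covariate, group_col, controls=("index_year",)):
    """Risk difference of a covariate between groups, per 100, year-adjusted.

    Least-squares coefficient of ``group_col`` from ``covariate ~ group +
    year indicators`` on the rows where the covariate is observed, with a
    physician-clustered CI.
    """
    sub = cohort[cohort[covariate].notna()]
    y = sub[covariate].to_numpy(np.float64)
    if y.min() == y.max():
        raise ValueError(f"covariate {covariate!r} is constant")
    ctrl = None
    if controls and "index_year" in controls:
        ctrl = year_controls(sub["index_year"]).to_numpy()
    res = ols_cluster(y, sub[group_col].to_numpy(np.float64), ctrl, sub["physician_id"].to_numpy())
    return res.rd_per_100, (res.ci_low, res.ci_high), res.se


def mahalanobis_imbalance(cohort, covariate_set, group_col):
    """Mahalanobis distance between the group covariate-mean vectors, x100.

    Uses the pooled within-group covariance; affine rescaling of the
    covariates leaves the distance unchanged.
    """
    covariate_set = list(covariate_set)
    if len(covariate_set) < 2:
        raise ValueError("need at least 2 covariates")
    sub = cohort.dropna(subset=covariate_set + [group_col])
    g1 = sub[sub[group_col] == 1][covariate_set].to_numpy(np.float64)
    g0 = sub[sub[group_col] == 0][covariate_set].to_numpy(np.float64)
    n1, n0 = len(g1), len(g0)
    diff = g1.mean(axis=0) - g0.mean(axis=0)
    S = ((n1 - 1) * np.cov(g1, rowvar=False) + (n0 - 1) * np.cov(g0, rowvar=False)) / (
        n1 + n0 - 2
    )
    try:
        sol = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError:
        corr = np.corrcoef(sub[covariate_set].to_numpy(np.float64), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "singular pooled covariance; most collinear pair: "
            f"{covariate_set[i]!r} and {covariate_set[j]!r}"
        ) from None
    return 100.0 * float(np.sqrt(max(diff @ sol, 0.0)))


def imbalance_reduction(d_exposure, d_instrument):
    """Percent reduction in Mahalanobis distance achieved by the instrument.

    Rounded to the nearest integer for display; negative when the instrument
    is more imbalanced than the exposure.
    """
    if d_exposure == 0:
        raise ValueError("d_exposure must be positive")
    return round(100.0 * (1.0 - d_instrument / d_exposure))


def prevalence_difference_ratio(rd_instrument, rd_exposure, first_stage_strength):
    """PDR = covariate imbalance by instrument over imbalance by exposure.

    ``first_stage_strength`` is E(X|Z=1) - E(X|Z=0) on the probability scale
    (in (0, 1]).  Returns ``(pdr, flag)``; the flag is True when |PDR|
    exceeds the strength, i.e. when the instrumented analysis may be the more
    biased one for this covariate.  Near-zero exposure imbalance
    (|rd_exposure| < 0.1 per 100) makes the ratio unstable: ``(nan, None)``.
    """
    if not 0 < first_stage_strength <= 1:
        raise ValueError("first_stage_strength must be in (0, 1]")
    if abs(rd_exposure) < PDR_UNSTABLE_THRESHOLD:
        return float("nan"), None
    pdr = rd_instrument / rd_exposure
    return pdr, bool(abs(pdr) > first_stage_strength)


def joint_covariate_association(cohort, covariate, instrument_cols, controls=("index_year",)):
    """Cluster-robust joint F-test of all instrument coefficients being zero
    in ``covariate ~ instruments + year indicators``.

    Returns ``(F, q, p)``.  With a single instrument F equals the squared
    cluster-robust t of :func:`adjusted_risk_difference`.
    """
    instrument_cols = list(instrument_cols)
    sub = cohort[cohort[covariate].notna()]
    Z = sub[instrument_cols].to_numpy(np.float64)
    if np.linalg.matrix_rank(Z - Z.mean(axis=0)) < Z.shape[1]:
        raise ValueError("collinear instrument set")
    ctrl = None
    if controls and "index_year" in controls:
        ctrl = year_controls(sub["index_year"]).to_numpy()
    fs = first_stage_diagnostics(
        sub[covariate].to_numpy(np.float64), Z, ctrl, sub["physician_id"].to_numpy()
    )
    return fs.partial_f, Z.shape[1], fs.partial_f_p


def balance_table(cohort, instrument_col="Z1", exposure_col="X", covariates=None,
                  adjust_pdr_for_year=True):
    """Full balance table: one :class:`BalanceRow` per covariate plus an
    :class:`ImbalanceSummary`, mirroring the standard reporting layout.

    ``adjust_pdr_for_year`` selects whether the PDR numerator/denominator
    come from year-adjusted (default) or crude risk differences.
    """
    covariates = list(covariates) if covariates is not None else list(COVARIATES)
    fs = first_stage_diagnostics(
        cohort[exposure_col].to_numpy(np.float64),
        cohort[instrument_col].to_numpy(np.float64),
        year_controls(cohort["index_year"]).to_numpy(),
        cohort["physician_id"].to_numpy(),
    )
    strength = fs.first_stage_rd / 100.0
    controls = ("index_year",) if adjust_pdr_for_year else ()
    rows = []
    for cov in covariates:
        rd_x, ci_x, _ = adjusted_risk_difference(cohort, cov, exposure_col, controls)
        rd_z, ci_z, _ = adjusted_risk_difference(cohort, cov, instrument_col, controls)
        pdr, flag = prevalence_difference_ratio(rd_z, rd_x, strength)
        rows.append(BalanceRow(cov, rd_x, ci_x, rd_z, ci_z, pdr, flag))
    usable = [c for c in covariates if cohort[c].notna().all()]
    d_x = mahalanobis_imbalance(cohort, usable, exposure_col)
    d_z = mahalanobis_imbalance(cohort, usable, instrument_col)
    summary = ImbalanceSummary(d_x, d_z, imbalance_reduction(d_x, d_z))
    return rows, summary


def balance_frame(rows, summary=None) -> pd.DataFrame:
    """Render balance rows (and optionally the distance summary) as a table."""
    df = pd.DataFrame(
        {
            "covariate": [r.covariate for r in rows],
            "rd_by_exposure": [r.rd_by_exposure for r in rows],
            "rd_by_instrument": [r.rd_by_instrument for r in rows],
            "pdr": [r.pdr for r in rows],
            "pdr_flag": [r.pdr_flag for r in rows],
        }
    )
    if summary is not None:
        df.attrs["mahalanobis_exposure"] = summary.d_exposure
        df.attrs["mahalanobis_instrument"] = summary.d_instrument
        df.attrs["reduction_pct"] = summary.reduction_pct
    return df
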