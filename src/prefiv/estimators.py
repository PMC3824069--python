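"""Effect estimators and specification tests for physician-clustered data.

All estimators report risk differences per 100 patients with variance from
the physician-clustered sandwich.  The small-sample factor is the Stata
convention ``G/(G-1) * (N-1)/(N-k)``, and confidence intervals and p-values
use a t/F reference distribution with ``G-1`` degrees of freedom.

Two-stage least squares is implemented directly (single or multiple
instruments, plain 2SLS): the clustered variance uses the *structural*
residuals ``y - X @ beta``, never the second-stage plug-in residuals.  The
Durbin-Wu-Hausman test takes the control-function form (first-stage residual
appended to the outcome regression, coefficient tested with a cluster-robust
Wald test), which remains well defined under clustering where the classical
variance-difference form can fail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EstimateResult",
    "FirstStageDiagnostics",
    "ols_cluster",
    "tsls",
    "wald_ratio",
    "first_stage_diagnostics",
    "lm_added_instruments",
    "hausman_dwh",
    "fe_tsls",
    "ps_match_rd",
    "year_controls",
]


@dataclass
class EstimateResult:
    """One estimator's risk difference per 100 with cluster-robust uncertainty."""

    name: str
    rd_per_100: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_clusters: int
    diagnostics: dict = field(default_factory=dict)


@dataclass
class FirstStageDiagnostics:
    first_stage_rd: float  # per 100 (single instrument) or NaN for blocks
    partial_f: float
    partial_f_p: float
    partial_r2: float
    n: int
    n_clusters: int


def _as_2d(a):
    a = np.asarray(a, dtype=np.float64)
    return a[:, None] if a.ndim == 1 else a


def year_controls(index_year) -> pd.DataFrame:
    """Indicator controls for calendar year of first prescription.

    One column per year, first year dropped as reference; prescribing trends
    are markedly nonlinear so a linear year term is not used.
    """
    d = pd.get_dummies(pd.Series(np.asarray(index_year), name="year"), prefix="year", dtype=np.float64)
    return d.iloc[:, 1:]


def _design(x, controls):
    x = _as_2d(x)
    parts = [x]
    if controls is not None and np.size(controls):
        parts.append(_as_2d(np.asarray(controls, dtype=np.float64)))
    parts.append(np.ones((x.shape[0], 1)))
    return np.hstack(parts)


def _cluster_meat(scores: np.ndarray, clusters) -> np.ndarray:
    s = pd.DataFrame(scores).groupby(np.asarray(clusters), sort=False).sum().to_numpy()
    return s.T @ s


def _small_sample_factor(n, g, k):
    return (g / (g - 1)) * ((n - 1) / (n - k))


def ols_cluster(y, x, controls=None, clusters=None, name="ols") -> EstimateResult:
    """Least-squares coefficient of ``x`` (x100) with clustered sandwich SE.

    With every observation its own cluster the SE reduces to HC1.
    """
    y = np.asarray(y, dtype=np.float64)
    X = _design(x, controls)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    clusters = np.asarray(clusters)
    g = len(np.unique(clusters))
    if g < 2:
        raise ValueError("need at least 2 clusters")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    u = y - X @ beta
    meat = _cluster_meat(X * u[:, None], clusters)
    V = _small_sample_factor(n, g, k) * XtX_inv @ meat @ XtX_inv
    se = float(np.sqrt(max(V[0, 0], 0.0)))
    tcrit = stats.t.ppf(0.975, g - 1)
    b = float(beta[0])
    return EstimateResult(
        name, 100 * b, 100 * se, 100 * (b - tcrit * se), 100 * (b + tcrit * se), n, g
    )


def wald_ratio(y, x, z) -> float:
    """Just-identified IV oracle: reduced form over first stage, x100."""
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    z = np.asarray(z)
    m1, m0 = z == 1, z == 0
    denom = x[m1].mean() - x[m0].mean()
    if denom == 0:
        raise ValueError("zero first-stage difference")
    return 100.0 * (y[m1].mean() - y[m0].mean()) / denom


def _tsls_core(y, X, Z, clusters, k_absorbed=0):
    n, k = X.shape
    Pi, *_ = np.linalg.lstsq(Z, X, rcond=None)
    Xhat = Z @ Pi
    if Z.shape[1] == k:
        # just-identified: beta solves Z'X beta = Z'y exactly (no projection
        # round-off), matching the hand-computed Wald ratio to machine precision
        A = Z.T @ X
        rhs = Z.T @ y
    else:
        A = Xhat.T @ X
        rhs = Xhat.T @ y
    if np.linalg.matrix_rank(A) < k:
        raise ValueError("rank-deficient 2SLS system")
    beta = np.linalg.solve(A, rhs)
    A = Xhat.T @ X  # bread for the sandwich in both cases
    u = y - X @ beta  # structural residuals
    bread = np.linalg.inv(A)
    clusters = np.asarray(clusters)
    g = len(np.unique(clusters))
    if g < 2:
        raise ValueError("need at least 2 clusters")
    meat = _cluster_meat(Xhat * u[:, None], clusters)
    c = _small_sample_factor(n, g, k + k_absorbed)
    V = c * bread @ meat @ bread.T
    return beta, V, g


def tsls(y, x, instruments, controls=None, clusters=None, name="iv"):
    """Two-stage least squares, coefficient of ``x`` per 100 patients.

    Returns ``(EstimateResult, FirstStageDiagnostics)``.  A weak first stage
    (partial F below 10) triggers a warning, not a failure.
    """
    y = np.asarray(y, dtype=np.float64)
    X = _design(x, controls)
    Z = _design(instruments, controls)
    beta, V, g = _tsls_core(y, X, Z, clusters)
    fs = first_stage_diagnostics(x, instruments, controls, clusters)
    if fs.partial_f < 10:
        warnings.warn(f"weak first stage: partial F = {fs.partial_f:.2f} < 10")
    se = float(np.sqrt(max(V[0, 0], 0.0)))
    tcrit = stats.t.ppf(0.975, g - 1)
    b = float(beta[0])
    est = EstimateResult(
        name,
        100 * b,
        100 * se,
        100 * (b - tcrit * se),
        100 * (b + tcrit * se),
        X.shape[0],
        g,
        diagnostics={"partial_f": fs.partial_f, "partial_r2": fs.partial_r2},
    )
    return est, fs


def first_stage_diagnostics(x, instruments, controls=None, clusters=None) -> FirstStageDiagnostics:
    """Strength of the instrument block in the first-stage regression.

    Partial F is the cluster-robust Wald test of the instrument coefficients
    divided by their number; partial r-squared is the squared (multiple)
    partial correlation of exposure and instruments given the controls.
    """
    x = np.asarray(x, dtype=np.float64)
    Zb = _as_2d(instruments)
    q = Zb.shape[1]
    X = _design(Zb, controls)
    n, k = X.shape
    clusters = np.asarray(clusters)
    g = len(np.unique(clusters))
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ x)
    u = x - X @ beta
    meat = _cluster_meat(X * u[:, None], clusters)
    V = _small_sample_factor(n, g, k) * XtX_inv @ meat @ XtX_inv
    bz, Vz = beta[:q], V[:q, :q]
    try:
        wald = float(bz @ np.linalg.solve(Vz, bz))
    except np.linalg.LinAlgError:
        # zero sampling variance (e.g. exposure exactly reproduced by the
        # instruments in a tiny sample): strength is effectively unbounded
        wald = float("inf") if float(bz @ bz) > 0 else 0.0
    partial_f = wald / q
    p = float(stats.f.sf(partial_f, q, g - 1))

    # partial r2: residualize x and instruments on the controls
    C = _design(np.empty((n, 0)), controls)  # controls + intercept
    bx, *_ = np.linalg.lstsq(C, x, rcond=None)
    ex = x - C @ bx
    bZ, *_ = np.linalg.lstsq(C, Zb, rcond=None)
    eZ = Zb - C @ bZ
    bb, *_ = np.linalg.lstsq(eZ, ex, rcond=None)
    ssr = float(((ex - eZ @ bb) ** 2).sum())
    sst = float((ex**2).sum())
    partial_r2 = 1.0 - ssr / sst if sst > 0 else 0.0

    rd = 100 * float(beta[0]) if q == 1 else float("nan")
    return FirstStageDiagnostics(rd, partial_f, p, partial_r2, n, g)


def lm_added_instruments(x, base_instrument, added_instruments, controls=None):
    """Score test that extra instruments explain additional exposure variance.

    Regress the base first-stage residuals on the added instruments plus
    controls; ``N * R^2`` is chi-square with one degree of freedom per added
    instrument under the null of no added explanatory power.
    """
    x = np.asarray(x, dtype=np.float64)
    B = _as_2d(base_instrument)
    A = _as_2d(added_instruments)
    for j in range(A.shape[1]):
        for i in range(B.shape[1]):
            if np.array_equal(A[:, j], B[:, i]):
                raise ValueError("added instruments overlap the base set")
    Xb = _design(B, controls)
    bb, *_ = np.linalg.lstsq(Xb, x, rcond=None)
    e = x - Xb @ bb
    Xa = _design(A, controls)
    ba, *_ = np.linalg.lstsq(Xa, e, rcond=None)
    resid = e - Xa @ ba
    sst = float(((e - e.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    n = len(x)
    stat = n * r2
    df = A.shape[1]
    return stat, df, float(stats.chi2.sf(stat, df))


def hausman_dwh(y, x, instruments, controls=None, clusters=None):
    """Durbin-Wu-Hausman endogeneity test, control-function form.

    The first-stage residual is appended to the outcome regression and its
    coefficient tested with a cluster-robust Wald test; under the null the
    OLS and IV estimands coincide.  Returns ``(statistic, p)`` where the
    statistic is the squared cluster-robust t of the residual term.
    """
    x = np.asarray(x, dtype=np.float64)
    Zm = _design(instruments, controls)
    bz, *_ = np.linalg.lstsq(Zm, x, rcond=None)
    v = x - Zm @ bz
    if float(v @ v) < 1e-12 * max(1.0, float(x @ x)):
        raise ValueError("degenerate test: exposure is an exact function of the instruments")
    # outcome regression: y ~ x + v + controls
    rhs = np.hstack([_as_2d(x), _as_2d(v)])
    if controls is not None and np.size(controls):
        rhs = np.hstack([rhs, _as_2d(np.asarray(controls, dtype=np.float64))])
    X = np.hstack([rhs, np.ones((len(x), 1))])
    yv = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    clusters = np.asarray(clusters)
    g = len(np.unique(clusters))
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ yv)
    u = yv - X @ beta
    meat = _cluster_meat(X * u[:, None], clusters)
    V = _small_sample_factor(n, g, k) * XtX_inv @ meat @ XtX_inv
    t2 = float(beta[1] ** 2 / V[1, 1])
    p = float(stats.f.sf(t2, 1, g - 1))
    return t2, p


def fe_tsls(y, x, instruments, controls=None, physician_ids=None, name="fe-iv"):
    """2SLS with physician fixed effects, probing a direct physician effect.

    All variables are demeaned within physician before 2SLS (no constant);
    clusters are the physicians.  Physicians whose instrument never varies
    contribute nothing to identification.
    """
    ids = np.asarray(physician_ids)
    y = np.asarray(y, dtype=np.float64)
    X = _as_2d(x)
    Zb = _as_2d(instruments)
    parts = [X, Zb] + ([_as_2d(np.asarray(controls, dtype=np.float64))] if controls is not None and np.size(controls) else [])
    M = np.hstack([_as_2d(y)] + parts)
    df = pd.DataFrame(M)
    dem = (df - df.groupby(ids, sort=False).transform("mean")).to_numpy()
    yd = dem[:, 0]
    Xd = dem[:, 1 : 1 + X.shape[1]]
    Zd = dem[:, 1 + X.shape[1] : 1 + X.shape[1] + Zb.shape[1]]
    Cd = dem[:, 1 + X.shape[1] + Zb.shape[1] :]
    if float((Zd**2).sum()) < 1e-12:
        raise ValueError("no within-physician instrument variation")
    Xm = np.hstack([Xd, Cd]) if Cd.size else Xd
    Zm = np.hstack([Zd, Cd]) if Cd.size else Zd
    g = len(np.unique(ids))
    beta, V, g = _tsls_core(yd, Xm, Zm, ids, k_absorbed=g)
    se = float(np.sqrt(max(V[0, 0], 0.0)))
    tcrit = stats.t.ppf(0.975, g - 1)
    b = float(beta[0])
    return EstimateResult(
        name, 100 * b, 100 * se, 100 * (b - tcrit * se), 100 * (b + tcrit * se), len(yd), g
    )


def ps_match_rd(
    y,
    x,
    covariates,
    caliper: float = 0.01,
    with_replacement: bool = True,
    name="psm",
) -> EstimateResult:
    """Propensity-score matched risk difference (ATT), per 100 patients.

    Logistic propensity model on the supplied covariates; each exposed
    patient is matched to the nearest control within ``caliper`` on the
    score, sampling controls with replacement.  Matching proceeds in
    descending order of the exposed scores; equidistant ties go to the
    control with the smaller id.  The variance treats re-used controls via
    frequency weights.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.int64)
    C = _as_2d(np.asarray(covariates, dtype=np.float64))
    if not with_replacement:
        raise NotImplementedError("only matching with replacement is supported")
    logit = sm.Logit(x, sm.add_constant(C)).fit(disp=0, maxiter=200)
    ps = np.asarray(logit.predict(sm.add_constant(C)))

    t_idx = np.flatnonzero(x == 1)
    c_idx = np.flatnonzero(x == 0)
    if len(t_idx) == 0 or len(c_idx) == 0:
        raise ValueError("need both exposed and control units")
    order = t_idx[np.argsort(-ps[t_idx], kind="stable")]
    c_sorted = c_idx[np.lexsort((c_idx, ps[c_idx]))]
    c_ps = ps[c_sorted]

    matches = np.full(len(order), -1, dtype=np.int64)
    pos = np.searchsorted(c_ps, ps[order])
    for i, (ti, p0) in enumerate(zip(order, pos)):
        cands = []
        if p0 < len(c_ps):
            cands.append(p0)
        if p0 > 0:
            cands.append(p0 - 1)
        best, best_d = -1, np.inf
        for c in cands:
            d = abs(c_ps[c] - ps[ti])
            if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and 0 <= best and c_sorted[c] < c_sorted[best]):
                best, best_d = c, d
        if best >= 0 and best_d <= caliper:
            matches[i] = c_sorted[best]
    matched = matches >= 0
    if not matched.any():
        raise ValueError("no exposed unit found a control within the caliper")

    t_used = order[matched]
    c_used = matches[matched]
    yt = y[t_used]
    ids, w = np.unique(c_used, return_counts=True)
    yc = y[ids]
    wsum = w.sum()
    mt, mc = yt.mean(), float((w * yc).sum() / wsum)
    rd = mt - mc
    var_t = yt.var(ddof=1) / len(yt) if len(yt) > 1 else 0.0
    mc_w = mc
    var_c = float((w.astype(float) ** 2 * (yc - mc_w) ** 2).sum() / wsum**2)
    se = float(np.sqrt(var_t + var_c))
    z = stats.norm.ppf(0.975)
    return EstimateResult(
        name,
        100 * rd,
        100 * se,
        100 * (rd - z * se),
        100 * (rd + z * se),
        int(len(yt) + len(ids)),
        int(len(ids)),
        diagnostics={"n_matched_exposed": int(len(yt)), "n_distinct_controls": int(len(ids))},
    )
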