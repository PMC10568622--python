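"""Risk-factor analysis: group comparisons (rank-sum / chi-square) between
admissions with and without an ADE, and a binary logistic regression of ADE
occurrence on utilisation covariates.

The logistic fit is a maximum-likelihood fit computed by iteratively
reweighted least squares (IRLS) with Wald standard errors; confidence
intervals for odds ratios are exp(beta +/- 1.96 * SE). Quasi-complete
separation is detected and flagged rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError

#: Covariates entered simultaneously in the default regression.
DEFAULT_COVARIATES = ("length_of_stay", "n_diagnoses", "n_medications",
                      "antibacterial_use", "antibacterial_hours")

CONTINUOUS = ("age", "length_of_stay", "n_diagnoses", "n_medications",
              "antibacterial_hours")
CATEGORICAL = ("sex_female", "antibacterial_use")


def assemble_covariates(cohort, ades) -> pd.DataFrame:
    """One complete-case row per admission: outcome + utilisation covariates.

    n_medications counts distinct drug names; antibacterial_hours sums the
    administered durations of antibacterial orders (an order with no stop
    runs to discharge).
    """
    ade_ids = {a.admission_id for a in ades}
    med = cohort.medications
    rows = []
    for _, adm in cohort.admissions.iterrows():
        aid = adm["admission_id"]
        sub = med.loc[med["admission_id"] == aid]
        anti = sub.loc[sub["drug_class"] == "antibacterial"]
        hours = 0.0
        for _, m in anti.iterrows():
            stop = m["stop_ts"] if not pd.isna(m["stop_ts"]) else adm["discharge_ts"]
            hours += max((stop - m["start_ts"]).total_seconds() / 3600.0, 0.0)
        rows.append({
            "admission_id": aid,
            "ade_occurred": int(aid in ade_ids),
            "age": int(adm["age"]),
            "sex_female": int(adm["sex"] == "female"),
            "length_of_stay": int(adm["length_of_stay"]),
            "n_diagnoses": int(adm["n_diagnoses"]),
            "n_medications": int(sub["drug_name"].nunique()),
            "antibacterial_use": int(len(anti) > 0),
            "antibacterial_hours": hours,
        })
    return pd.DataFrame(rows)


def compare_groups(cov: pd.DataFrame, continuity_correction: bool = False
                   ) -> pd.DataFrame:
    """Compare ADE vs no-ADE admissions covariate by covariate.

    Continuous covariates use the two-sample rank-sum (Mann-Whitney) test;
    binary covariates use the chi-square test on the 2x2 table (Yates
    continuity correction off by default).
    """
    g1 = cov.loc[cov["ade_occurred"] == 1]
    g0 = cov.loc[cov["ade_occurred"] == 0]
    if g1.empty or g0.empty:
        raise ComputationError("both outcome groups must be non-empty")
    rows = []
    for var in CONTINUOUS:
        a, b = g1[var].to_numpy(float), g0[var].to_numpy(float)
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"variable": var, "test": "rank_sum",
                     "ade_mean": a.mean(), "no_ade_mean": b.mean(), "p_value": p})
    for var in CATEGORICAL:
        table = np.array([
            [int(g1[var].sum()), int(len(g1) - g1[var].sum())],
            [int(g0[var].sum()), int(len(g0) - g0[var].sum())],
        ])
        if table.sum(axis=0).min() == 0:  # constant column: no association testable
            p = 1.0
        else:
            p = float(stats.chi2_contingency(
                table, correction=continuity_correction)[1])
        rows.append({"variable": var, "test": "chi_square",
                     "ade_mean": g1[var].mean(), "no_ade_mean": g0[var].mean(),
                     "p_value": p})
    return pd.DataFrame(rows)


@dataclass
class LogisticFit:
    covariates: tuple
    beta: np.ndarray            # includes intercept at position 0
    se: np.ndarray
    converged: bool
    separation: bool
    n_iter: int
    n: int
    log_likelihood: float
    table: pd.DataFrame = field(init=False)

    def __post_init__(self):
        names = ("intercept",) + tuple(self.covariates)
        z = np.divide(self.beta, self.se, out=np.full_like(self.beta, np.nan),
                      where=self.se > 0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        self.table = pd.DataFrame({
            "variable": names,
            "beta": self.beta,
            "se": self.se,
            "odds_ratio": np.exp(self.beta),
            "p_value": pvals,
            "ci_low": np.exp(self.beta - 1.96 * self.se),
            "ci_high": np.exp(self.beta + 1.96 * self.se),
        })


def _log_likelihood(y, eta):
    # log-lik of Bernoulli with logit link, numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(cov: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                 outcome: str = "ade_occurred", tol: float = 1e-8,
                 max_iter: int = 50) -> LogisticFit:
    """Binary logistic regression by IRLS.

    Requires at least 10 events and a full-rank design. Stops when the change
    in log-likelihood falls below ``tol``; separation or non-convergence is
    flagged on the returned fit rather than raised.
    """
    covariates = tuple(covariates)
    y = cov[outcome].to_numpy(float)
    if int(y.sum()) < 10:
        raise ComputationError(
            f"need >= 10 events for a stable fit, got {int(y.sum())}")
    X = np.column_stack([np.ones(len(cov))]
                        + [cov[c].to_numpy(float) for c in covariates])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ComputationError("design matrix is rank deficient")
    beta = np.zeros(X.shape[1])
    ll_old = _log_likelihood(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        ll_new = _log_likelihood(y, X @ beta)
        if abs(ll_new - ll_old) < tol:
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = X.T @ (X * w[:, None])
    try:
        cov_beta = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full_like(beta, np.nan)
    # quasi-complete separation: fitted probabilities pinned at the outcome
    separation = bool(np.max(np.abs(y - mu)) < 1e-4) or bool(
        np.max(np.abs(beta)) > 15.0) or not converged
    return LogisticFit(covariates=covariates, beta=beta, se=se,
                       converged=converged, separation=separation,
                       n_iter=it, n=len(y), log_likelihood=ll_old)
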