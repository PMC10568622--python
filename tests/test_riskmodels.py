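"""Group comparisons and the IRLS logistic regression (statsmodels as the
independent reference implementation)."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from gtt_ade import assemble_covariates, compare_groups, fit_logistic
from gtt_ade.errors import ComputationError


def _cov_frame(rng, n, beta_meds=0.0, intercept=-2.0):
    meds = np.clip(np.rint(rng.normal(18.26, 6.42, n)), 5, 40)
    los = np.clip(np.rint(rng.normal(8.95, 4.57, n)), 2, 27)
    dx = np.clip(np.rint(rng.normal(5.38, 2.8, n)), 1, 19)
    anti = (rng.random(n) < 0.3083).astype(int)
    hours = anti * rng.exponential(50, n)
    eta = intercept + beta_meds * meds
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame({
        "admission_id": [f"A{i}" for i in range(n)], "ade_occurred": y,
        "age": np.clip(np.rint(rng.normal(72.6, 5.9, n)), 65, 91),
        "sex_female": (rng.random(n) < 0.456).astype(int),
        "length_of_stay": los, "n_diagnoses": dx, "n_medications": meds,
        "antibacterial_use": anti, "antibacterial_hours": hours,
    })


def test_identical_groups_give_p_one():
    base = _cov_frame(np.random.default_rng(0), 60)
    half = base.iloc[:30].copy()
    dup = pd.concat([half.assign(ade_occurred=0), half.assign(ade_occurred=1)],
                    ignore_index=True)
    table = compare_groups(dup)
    cont = table.loc[table["test"] == "rank_sum", "p_value"].to_numpy()
    assert np.allclose(cont, 1.0, atol=1e-9)
    cat = table.loc[table["test"] == "chi_square", "p_value"].to_numpy()
    assert np.allclose(cat, 1.0, atol=1e-9)


def _shift_detection_rate(n_ade, n_total, reps=100, alpha=0.01):
    detected = 0
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        cov = _cov_frame(rng, n_total)
        cov["ade_occurred"] = 0
        cov.loc[: n_ade - 1, "ade_occurred"] = 1
        cov.loc[cov["ade_occurred"] == 1, "n_medications"] += 3
        table = compare_groups(cov)
        p = table.set_index("variable").loc["n_medications", "p_value"]
        detected += p < alpha
    return detected / reps


def test_planted_medication_shift_is_detected():
    """A +3 shift in medications for the ADE group at n=480.

    With the cohort's unbalanced 51/429 split the rank-sum power at
    alpha=0.01 is ~0.72 (normal-approximation check: SE of the mean
    difference is 6.42*sqrt(1/51+1/429)=0.95, z=3/0.95=3.16, power
    Phi(3.16-2.576)=0.72); with balanced groups the same shift is detected
    in >= 95% of replicates."""
    assert 0.55 <= _shift_detection_rate(51, 480) <= 0.88
    assert _shift_detection_rate(240, 480) >= 0.93


def test_antibacterial_contingency_not_significant():
    table = np.array([[17, 29], [131, 298]])
    p = chi2_contingency(table, correction=False)[1]
    assert p > 0.05


def test_group_comparison_invariant_to_row_order_and_label_swap():
    rng = np.random.default_rng(5)
    cov = _cov_frame(rng, 300, beta_meds=0.08)
    if cov["ade_occurred"].sum() in (0, len(cov)):
        pytest.skip("degenerate draw")
    t1 = compare_groups(cov)
    shuffled = cov.sample(frac=1.0, random_state=1).reset_index(drop=True)
    t2 = compare_groups(shuffled)
    pd.testing.assert_frame_equal(t1, t2)
    swapped = cov.assign(ade_occurred=1 - cov["ade_occurred"])
    t3 = compare_groups(swapped)
    np.testing.assert_allclose(t1["p_value"], t3["p_value"], atol=1e-9)


def test_empty_group_raises():
    cov = _cov_frame(np.random.default_rng(2), 50)
    cov["ade_occurred"] = 0
    with pytest.raises(ComputationError):
        compare_groups(cov)


def test_irls_matches_statsmodels_to_1e6():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(42)
    cov = _cov_frame(rng, 400, beta_meds=0.087)
    fit = fit_logistic(cov)
    X = sm.add_constant(cov[list(fit.covariates)].astype(float))
    ref = sm.GLM(cov["ade_occurred"], X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.beta, ref.params.to_numpy(), atol=1e-6)
    np.testing.assert_allclose(fit.se, ref.bse.to_numpy(), rtol=1e-4)
    assert fit.converged and not fit.separation


def test_fit_table_invariants():
    rng = np.random.default_rng(7)
    fit = fit_logistic(_cov_frame(rng, 500, beta_meds=0.087))
    t = fit.table
    np.testing.assert_allclose(t["odds_ratio"], np.exp(t["beta"]))
    assert ((t["ci_low"] <= t["odds_ratio"]) & (t["odds_ratio"] <= t["ci_high"])).all()


def test_null_model_type_one_error_calibration():
    """Outcome independent of covariates: |z| < 1.96 for the medications
    coefficient in roughly 95% of replicates."""
    inside = 0
    reps = 100
    for seed in range(reps):
        rng = np.random.default_rng(1000 + seed)
        cov = _cov_frame(rng, 400, beta_meds=0.0, intercept=-1.5)
        fit = fit_logistic(cov)
        row = fit.table.set_index("variable").loc["n_medications"]
        inside += bool(abs(row["beta"] / row["se"]) < 1.96)
    assert inside >= 85


def test_perfect_separation_is_flagged():
    rng = np.random.default_rng(3)
    cov = _cov_frame(rng, 200)
    cov["n_medications"] = cov["ade_occurred"] * 30.0 + 5.0
    cov["antibacterial_hours"] = rng.normal(size=200)
    fit = fit_logistic(cov, covariates=("n_medications",))
    assert fit.separation


def test_too_few_events_rejected():
    rng = np.random.default_rng(4)
    cov = _cov_frame(rng, 100)
    cov["ade_occurred"] = 0
    cov.loc[:3, "ade_occurred"] = 1
    with pytest.raises(ComputationError):
        fit_logistic(cov)


def test_coefficient_bias_shrinks_with_n():
    """Self-generated data: the medications log-OR estimate approaches the
    truth as n grows."""
    truth = 0.087
    errs = []
    for n in (500, 2000, 8000):
        est = []
        for seed in range(8):
            rng = np.random.default_rng(seed * 7919 + n)
            cov = _cov_frame(rng, n, beta_meds=truth, intercept=-3.6)
            fit = fit_logistic(cov)
            est.append(fit.table.set_index("variable").loc["n_medications", "beta"])
        errs.append(abs(np.mean(est) - truth))
    assert errs[-1] < 0.01
    assert errs[-1] <= errs[0] + 0.005


def test_assemble_covariates_counts_distinct_drugs_and_hours(synth_cohort):
    cohort, truth = synth_cohort
    cov = assemble_covariates(cohort, truth.ades)
    assert len(cov) == cohort.n_admissions
    assert cov.notna().all().all()
    aid = cohort.admissions.iloc[0]["admission_id"]
    sub = cohort.medications
    expected = sub.loc[sub["admission_id"] == aid, "drug_name"].nunique()
    assert cov.set_index("admission_id").loc[aid, "n_medications"] == expected
    assert (cov.loc[cov["antibacterial_use"] == 0, "antibacterial_hours"] == 0).all()
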