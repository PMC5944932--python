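"""Agreement statistics: CCC, correlations, Bland-Altman, R^2 decomposition."""

import numpy as np
import pandas as pd
import pytest

from ihcphantom import (
    AgreementError,
    bland_altman,
    ccc,
    evaluate_panel,
    pearson,
    regression_decomposition,
    spearman,
)
from ihcphantom.agreement import agreement_report, panel_summary_table


def test_ccc_perfect_concordance():
    est, lo, hi = ccc([10.0, 50.0, 90.0], [10.0, 50.0, 90.0])
    assert est == pytest.approx(1.0)
    assert lo == pytest.approx(est) and hi == pytest.approx(est)


def test_ccc_closed_form_shifted_line():
    # cov = 2/3, both variances 2/3, mean shift 1 -> 2*(2/3) / (4/3 + 1) = 4/7
    est, lo, hi = ccc([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert est == pytest.approx(4.0 / 7.0, abs=1e-12)
    assert lo <= est <= hi


def test_ccc_perfect_reversal():
    x = np.array([-2.0, 0.0, 2.0])
    assert ccc(x, -x)[0] == pytest.approx(-1.0)


def test_ccc_errors():
    with pytest.raises(AgreementError, match="length"):
        ccc([1.0, 2.0, 3.0], [1.0, 2.0])
    with pytest.raises(AgreementError, match="constant"):
        ccc([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])


def test_ccc_not_above_pearson_for_positive_correlation():
    rng = np.random.default_rng(8)
    for _ in range(20):
        x = rng.uniform(0, 100, 25)
        y = x + rng.normal(3.0, 5.0, 25)
        c, p = ccc(x, y)[0], pearson(x, y)[0]
        assert c <= p + 1e-12


def test_correlation_cis_bracket_estimates():
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 100, 40)
    y = x + rng.normal(0, 10, 40)
    for stat in (ccc, pearson, spearman):
        est, lo, hi = stat(x, y)
        assert lo <= est <= hi
        assert -1.0 <= lo and hi <= 1.0


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(10)
    x = rng.uniform(1, 99, 30)
    y = x + rng.normal(0, 10, 30)
    base = spearman(x, y)[0]
    assert spearman(np.exp(x / 25.0), y)[0] == pytest.approx(base, abs=1e-12)
    assert spearman(x, np.sqrt(y - y.min() + 1))[0] == pytest.approx(base, abs=1e-12)


def test_bland_altman_trivial_cases():
    t = np.array([10.0, 40.0, 70.0])
    ba = bland_altman(t, t)
    assert ba.bias == 0.0 and ba.sd == 0.0
    assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)
    ba5 = bland_altman(t, t + 5.0)
    assert ba5.bias == pytest.approx(5.0) and ba5.sd == pytest.approx(0.0)
    assert np.allclose(ba5.means, t + 2.5)


def test_regression_decomposition_exact_predictors():
    rng = np.random.default_rng(11)
    rn = rng.uniform(0, 100, 30)
    ra = rn + rng.normal(0, 5, 30)
    dec = regression_decomposition(rn, rn, ra)
    assert dec.total_r2 == pytest.approx(1.0)
    assert dec.r2_rn == pytest.approx(1.0)
    assert dec.semipartial_r2_ra == pytest.approx(0.0, abs=1e-10)
    dec2 = regression_decomposition(ra, rn, ra)
    assert dec2.r2_ra == pytest.approx(1.0)
    # semi-partials are total minus the other predictor's R^2 by definition
    assert dec2.semipartial_r2_rn == pytest.approx(dec2.total_r2 - dec2.r2_ra, abs=1e-12)


def test_regression_decomposition_null_response():
    rng = np.random.default_rng(13)
    rn = rng.uniform(0, 100, 100)
    ra = rn + rng.normal(0, 8, 100)
    noise = rng.normal(0, 1, 100)
    dec = regression_decomposition(noise, rn, ra)
    assert dec.total_r2 <= 0.5 and dec.r2_rn <= 0.5 and dec.r2_ra <= 0.5


def test_regression_decomposition_collinear_errors():
    rn = np.arange(10.0)
    with pytest.raises(AgreementError, match="collinear"):
        regression_decomposition(rn, rn, 2.0 * rn + 1.0)


def _truth_df(rng, n=42):
    rn = rng.uniform(0, 100, n)
    return pd.DataFrame(
        {
            "image_id": [f"img_{i:03d}" for i in range(n)],
            "r_n": rn,
            "r_a": np.clip(rn + rng.normal(0, 2, n), 0, 100),
            "r_t": rn * 0.25,
        }
    )


def test_evaluate_panel_perfect_reader():
    truth = _truth_df(np.random.default_rng(14))
    est = pd.DataFrame(
        {
            "image_id": truth["image_id"],
            "reader_id": "r1",
            "r_n_est": truth["r_n"],
            "r_t_est": truth["r_t"],
        }
    )
    reports = evaluate_panel(truth, est)
    assert reports[("r1", "r_n")].ccc[0] == pytest.approx(1.0)
    assert reports[("r1", "r_t")].ccc[0] == pytest.approx(1.0)


def test_evaluate_panel_noisy_reader_high_ccc():
    rng = np.random.default_rng(15)
    truth = _truth_df(rng)
    est = pd.DataFrame(
        {
            "image_id": truth["image_id"],
            "reader_id": "r1",
            "r_n_est": np.clip(truth["r_n"] + rng.normal(0, 2, len(truth)), 0, 100),
            "r_t_est": truth["r_t"],
        }
    )
    reports = evaluate_panel(truth, est)
    assert reports[("r1", "r_n")].ccc[0] >= 0.98
    table = panel_summary_table(reports)
    assert len(table) == 3  # one reader x three ratio types
    assert set(table["ratio_type"]) == {"r_n", "r_t", "r_a"}


def test_evaluate_panel_missing_images_error():
    truth = _truth_df(np.random.default_rng(16))
    est = pd.DataFrame(
        {
            "image_id": truth["image_id"][:21],
            "reader_id": "r1",
            "r_n_est": truth["r_n"][:21],
            "r_t_est": truth["r_t"][:21],
        }
    )
    with pytest.raises(AgreementError, match="missing images"):
        evaluate_panel(truth, est)


def test_agreement_report_bias_matches_means():
    rng = np.random.default_rng(17)
    truth = rng.uniform(0, 100, 30)
    est = truth + rng.normal(2, 4, 30)
    rep = agreement_report(truth, est)
    assert rep.bias_sd[0] == pytest.approx(est.mean() - truth.mean(), abs=1e-12)
    assert rep.ccc[1] <= rep.ccc[0] <= rep.ccc[2]
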