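"""Agreement statistics for scoring readers and algorithms against truth.

The phantom's exact ground truth turns evaluation into a measurement-
agreement problem: for each reader (human or algorithm) and each ratio
type we report mean +- SD, bias +- SD, Lin's concordance correlation
coefficient (CCC), and Pearson and Spearman correlations, each with a
95% confidence interval, plus Bland-Altman difference series.

Lin's CCC combines precision and accuracy:

    CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2)

with population (1/n) moments; its CI uses Lin's asymptotic variance on
the Fisher z scale.  Pearson and Spearman CIs use the Fisher transform
with the standard 1/(n-3) variance.  Bias rows use the sample (n-1) SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import AgreementError

_Z95 = 1.959963984540054

RATIO_TYPES = ("r_n", "r_t", "r_a")


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AgreementError(f"vectors must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if x.size < min_n:
        raise AgreementError(f"need at least {min_n} observations, got {x.size}")
    return x, y


def _fisher_ci(r: float, n: int) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0 - 1e-12:
        return (r, r) if abs(r) >= 1.0 - 1e-12 else (-1.0, 1.0)
    z = np.arctanh(r)
    half = _Z95 / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def ccc(x, y) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with a 95% CI.

    Returns (estimate, ci_low, ci_high).  Undefined when both vectors
    are constant.
    """
    x, y = _check_pair(x, y)
    n = x.size
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n) moments
    if vx == 0.0 and vy == 0.0:
        raise AgreementError("CCC undefined: both vectors are constant")
    sxy = ((x - mx) * (y - my)).mean()
    est = float(2.0 * sxy / (vx + vy + (mx - my) ** 2))
    if vx == 0.0 or vy == 0.0:
        return est, est, est  # degenerate: no correlation structure to propagate
    r = float(sxy / np.sqrt(vx * vy))
    if abs(est) >= 1.0 - 1e-12 or abs(r) < 1e-12 or n <= 2:
        return est, est, est
    # Lin's asymptotic variance of the Fisher z-transformed CCC
    u2 = (mx - my) ** 2 / np.sqrt(vx * vy)
    p2 = est**2
    var_z = (
        (1.0 - r**2) * p2 / ((1.0 - p2) * r**2)
        + 2.0 * est**3 * (1.0 - est) * u2 / (r * (1.0 - p2) ** 2)
        - est**4 * u2**2 / (2.0 * r**2 * (1.0 - p2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = np.arctanh(est)
    half = _Z95 * np.sqrt(var_z)
    return est, float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson(x, y) -> tuple[float, float, float]:
    """Pearson correlation with a Fisher-z 95% CI."""
    x, y = _check_pair(x, y)
    if x.std() == 0.0 or y.std() == 0.0:
        raise AgreementError("Pearson undefined: constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    lo, hi = _fisher_ci(r, x.size)
    return r, lo, hi


def spearman(x, y) -> tuple[float, float, float]:
    """Spearman rank correlation with a Fisher-z 95% CI."""
    x, y = _check_pair(x, y)
    if x.std() == 0.0 or y.std() == 0.0:
        raise AgreementError("Spearman undefined: constant vector")
    r = float(stats.spearmanr(x, y).statistic)
    lo, hi = _fisher_ci(r, x.size)
    return r, lo, hi


@dataclass
class BlandAltmanSeries:
    """Difference-vs-mean series with 95% limits of agreement."""

    means: np.ndarray  # per-image mean of (truth, estimate)
    differences: np.ndarray  # estimate - truth
    bias: float
    sd: float  # sample SD of the differences
    loa_low: float
    loa_high: float


def bland_altman(truth, estimate) -> BlandAltmanSeries:
    """Bland-Altman analysis of estimate vs truth.

    Differences are estimate - truth; limits of agreement are
    bias +- 1.96 x sample SD of the differences.
    """
    truth, estimate = _check_pair(truth, estimate, min_n=2)
    diffs = estimate - truth
    bias = float(diffs.mean())
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanSeries(
        means=(truth + estimate) / 2.0,
        differences=diffs,
        bias=bias,
        sd=sd,
        loa_low=bias - _Z95 * sd,
        loa_high=bias + _Z95 * sd,
    )


def bland_altman_plot(series: BlandAltmanSeries, path, title: str = "Bland-Altman"):
    """Write a Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(series.means, series.differences, s=18, color="tab:blue")
    for yv, style in ((series.bias, "-"), (series.loa_low, "--"), (series.loa_high, "--")):
        ax.axhline(yv, color="tab:red", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of truth and estimate (%)")
    ax.set_ylabel("estimate - truth (%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class RegressionDecomposition:
    """Variance decomposition of a response over the two predictors r_n, r_a."""

    total_r2: float
    r2_rn: float
    semipartial_r2_rn: float
    r2_ra: float
    semipartial_r2_ra: float


def regression_decomposition(response, r_n, r_a) -> RegressionDecomposition:
    """Total and semi-partial R^2 of a response regressed on r_n and r_a.

    The semi-partial R^2 of a predictor is the additional variance it
    explains beyond the other predictor: total R^2 minus the other
    predictor's single-predictor R^2.
    """
    y, rn = _check_pair(response, r_n, min_n=4)
    _, ra = _check_pair(response, r_a, min_n=4)
    if rn.std() == 0.0 or ra.std() == 0.0:
        raise AgreementError("constant predictor")
    if abs(np.corrcoef(rn, ra)[0, 1]) > 1.0 - 1e-10:
        raise AgreementError("predictors r_n and r_a are perfectly collinear")
    full = sm.OLS(y, sm.add_constant(np.column_stack([rn, ra]))).fit()
    only_rn = sm.OLS(y, sm.add_constant(rn)).fit()
    only_ra = sm.OLS(y, sm.add_constant(ra)).fit()
    total = float(full.rsquared)
    return RegressionDecomposition(
        total_r2=total,
        r2_rn=float(only_rn.rsquared),
        semipartial_r2_rn=total - float(only_ra.rsquared),
        r2_ra=float(only_ra.rsquared),
        semipartial_r2_ra=total - float(only_rn.rsquared),
    )


@dataclass
class AgreementReport:
    """One reader x ratio-type row of the evaluation tables."""

    n: int
    mean_sd: tuple[float, float]  # mean and sample SD of the estimates
    bias_sd: tuple[float, float]  # mean and sample SD of estimate - truth
    ccc: tuple[float, float, float]
    pearson: tuple[float, float, float]
    spearman: tuple[float, float, float]


def agreement_report(truth, estimate) -> AgreementReport:
    truth, estimate = _check_pair(truth, estimate)
    ba = bland_altman(truth, estimate)
    return AgreementReport(
        n=truth.size,
        mean_sd=(float(estimate.mean()), float(np.std(estimate, ddof=1))),
        bias_sd=(ba.bias, ba.sd),
        ccc=ccc(truth, estimate),
        pearson=pearson(truth, estimate),
        spearman=spearman(truth, estimate),
    )


def evaluate_panel(
    truth_ratios: pd.DataFrame, estimates: pd.DataFrame
) -> dict[tuple[str, str], AgreementReport]:
    """Score every reader against truth for all three ratio types.

    ``truth_ratios`` needs columns image_id, r_n, r_a, r_t; ``estimates``
    needs image_id, reader_id, r_n_est, r_t_est.  Each reader must cover
    every truth image.  Readers are scored on r_n and r_t directly; for
    r_a the reader's r_n estimate is used as a surrogate, probing whether
    an area fraction is what is really being judged when a count ratio
    is requested.
    """
    for col in ("image_id", "r_n", "r_a", "r_t"):
        if col not in truth_ratios.columns:
            raise AgreementError(f"truth table missing column {col}")
    truth = truth_ratios.set_index("image_id").sort_index()
    reports: dict[tuple[str, str], AgreementReport] = {}
    for reader_id, sub in estimates.groupby("reader_id"):
        missing = sorted(set(truth.index) - set(sub["image_id"]))
        if missing:
            raise AgreementError(f"reader {reader_id} missing images: {missing}")
        sub = sub.set_index("image_id").loc[truth.index]
        for ratio_type, est_col in (("r_n", "r_n_est"), ("r_t", "r_t_est"), ("r_a", "r_n_est")):
            reports[(str(reader_id), ratio_type)] = agreement_report(
                truth[ratio_type].to_numpy(), sub[est_col].to_numpy()
            )
    return reports


def panel_summary_table(reports: Mapping[tuple[str, str], AgreementReport]) -> pd.DataFrame:
    """Flatten panel reports into one tidy row per reader x ratio type."""
    rows = []
    for (reader_id, ratio_type), rep in reports.items():
        rows.append(
            {
                "reader_id": reader_id,
                "ratio_type": ratio_type,
                "n": rep.n,
                "mean": rep.mean_sd[0],
                "sd": rep.mean_sd[1],
                "bias": rep.bias_sd[0],
                "bias_sd": rep.bias_sd[1],
                "ccc": rep.ccc[0],
                "ccc_lo": rep.ccc[1],
                "ccc_hi": rep.ccc[2],
                "pearson": rep.pearson[0],
                "pearson_lo": rep.pearson[1],
                "pearson_hi": rep.pearson[2],
                "spearman": rep.spearman[0],
                "spearman_lo": rep.spearman[1],
                "spearman_hi": rep.spearman[2],
            }
        )
    return pd.DataFrame(rows)
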