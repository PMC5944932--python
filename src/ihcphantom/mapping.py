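"""Quadratic area-to-count calibration.

The count ratio r_n is the clinical quantity, but nuclear *areas* are
far cheaper to measure than nucleus counts.  On phantoms the difference

    D = r_a - r_n              (both in percent)

is a smooth function of r_a, small when a field is homogeneous (r_a near
0 or 100) and largest at intermediate mixing.  It is approximated by a
second-degree polynomial

    Psi(r_a) = a * r_a**2 + b * r_a + c

fitted by ordinary least squares of the observed D against the
polynomial basis, giving the estimator

    r_n  ~=  r_a - Psi(r_a),   clamped to [0, 100].

``heldout_protocol`` evaluates the calibration the way it is meant to be
used: hold one image out of each ratio bin, fit on the rest, and report
the sample SD of the prediction error on the held-out images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ProtocolError
from .phantom import TABLE1_BINS, bin_index


@dataclass
class MappingModel:
    """Coefficients of Psi plus fit diagnostics.

    ``residual_sd`` is the sample (n-1) standard deviation of the
    training residuals D - Psi(r_a).  The private normal-equations
    inverse and residual variance support the 95% prediction band.
    """

    a: float
    b: float
    c: float
    residual_sd: float
    n_train: int
    _xtx_inv: np.ndarray | None = field(default=None, repr=False, compare=False)
    _sigma2: float = field(default=0.0, repr=False, compare=False)

    def psi(self, r_a):
        r_a = np.asarray(r_a, dtype=float)
        return self.a * r_a**2 + self.b * r_a + self.c

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "residual_sd": self.residual_sd,
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MappingModel":
        return cls(
            a=float(d["a"]),
            b=float(d["b"]),
            c=float(d["c"]),
            residual_sd=float(d["residual_sd"]),
            n_train=int(d["n_train"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "MappingModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_mapping(train: Sequence[tuple[float, float]]) -> MappingModel:
    """Least-squares fit of Psi to D = r_a - r_n over (r_a, r_n) pairs.

    Requires at least three pairs (three coefficients) and a full-rank
    quadratic design (at least three distinct r_a values).
    """
    arr = np.asarray(train, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FitError("train must be a sequence of (r_a, r_n) pairs")
    n = arr.shape[0]
    if n < 3:
        raise FitError(f"need at least 3 training pairs, got {n}")
    r_a, r_n = arr[:, 0], arr[:, 1]
    d = r_a - r_n
    X = np.column_stack([r_a**2, r_a, np.ones(n)])
    coef, _, rank, _ = np.linalg.lstsq(X, d, rcond=None)
    if rank < 3:
        raise FitError("rank-deficient quadratic design (r_a values degenerate)")
    resid = d - X @ coef
    residual_sd = float(np.std(resid, ddof=1)) if n > 1 else 0.0
    df = n - 3
    sigma2 = float(resid @ resid / df) if df > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    return MappingModel(
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        residual_sd=residual_sd,
        n_train=n,
        _xtx_inv=xtx_inv,
        _sigma2=sigma2,
    )


def predict_rn(model: MappingModel, r_a):
    """Estimate the count ratio: r_a - Psi(r_a), clamped to [0, 100] percent."""
    out = np.clip(np.asarray(r_a, dtype=float) - model.psi(r_a), 0.0, 100.0)
    return float(out) if out.ndim == 0 else out


def prediction_band(model: MappingModel, r_a, level: float = 0.95):
    """Pointwise prediction interval for D at new r_a values.

    Uses the usual OLS formula sd = sqrt(sigma2 * (1 + x' (X'X)^-1 x))
    with a Student-t quantile on n_train - 3 degrees of freedom.
    """
    if model._xtx_inv is None:
        raise FitError("prediction band requires a model produced by fit_mapping")
    df = model.n_train - 3
    if df <= 0:
        raise FitError("prediction band requires n_train > 3")
    r_a = np.atleast_1d(np.asarray(r_a, dtype=float))
    X = np.column_stack([r_a**2, r_a, np.ones(r_a.size)])
    lever = np.einsum("ij,jk,ik->i", X, model._xtx_inv, X)
    se = np.sqrt(model._sigma2 * (1.0 + lever))
    t = stats.t.ppf(0.5 + level / 2.0, df)
    center = model.psi(r_a)
    return center - t * se, center + t * se


@dataclass
class HeldoutReport:
    """Per-test-image predictions and the SD of the prediction error."""

    table: pd.DataFrame  # columns: bin, r_a, r_n, rn_hat
    sd: float


def heldout_protocol(
    images: Sequence[tuple[float, float]],
    bins: Sequence[tuple[float, float]] = TABLE1_BINS,
    seed: int = 0,
) -> tuple[MappingModel, HeldoutReport]:
    """One-image-per-bin held-out evaluation of the calibration.

    ``images`` are (r_a, r_n) pairs in percent; each image is assigned to
    a ratio bin by its true r_n.  One image per bin is held out at
    random, Psi is fitted on the remainder, and the report carries the
    held-out predictions and the sample SD of r_n - rn_hat.
    """
    arr = np.asarray(images, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ProtocolError("images must be a sequence of (r_a, r_n) pairs")
    assignments: list[list[int]] = [[] for _ in bins]
    for i, (_, r_n) in enumerate(arr):
        assignments[bin_index(r_n, bins)].append(i)
    empty = [k for k, members in enumerate(assignments) if not members]
    if empty:
        raise ProtocolError(f"empty ratio bin(s) {empty}: cannot hold out one image each")
    rng = np.random.default_rng(seed)
    test_idx = [members[int(rng.integers(len(members)))] for members in assignments]
    train_idx = [i for i in range(len(arr)) if i not in set(test_idx)]
    model = fit_mapping(arr[train_idx])
    r_a, r_n = arr[test_idx, 0], arr[test_idx, 1]
    rn_hat = predict_rn(model, r_a)
    table = pd.DataFrame(
        {"bin": list(range(len(bins))), "r_a": r_a, "r_n": r_n, "rn_hat": rn_hat}
    )
    sd = float(np.std(r_n - rn_hat, ddof=1)) if len(test_idx) > 1 else 0.0
    return model, HeldoutReport(table=table, sd=sd)
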