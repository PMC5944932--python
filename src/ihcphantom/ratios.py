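"""The three ratios of a Ki-67 field, all in percent.

- ``r_n`` -- positive nuclei / total nuclei x 100: the count ratio, the
  clinically reported labeling index.
- ``r_a`` -- positive nuclear area / total nuclear area x 100.
- ``r_t`` -- positive nuclear area / image area x 100.

Areas come from the class-labelled pixel mask, so a pixel shared by
overlapping nuclei is counted once, attributed to the object on top;
double counting would let ``r_a`` exceed 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .errors import RatioError
from .phantom import GroundTruth, NEGATIVE, POSITIVE

Source = Literal["truth", "reader", "algorithm"]

READER_COLUMNS = ("image_id", "reader_id", "r_n_est", "r_t_est")


@dataclass(frozen=True)
class RatioSet:
    """(r_n, r_a, r_t) in percent for one image, tagged with their source."""

    r_n: float
    r_a: float
    r_t: float
    source: Source = "truth"


def ratios_from_truth(truth: GroundTruth) -> RatioSet:
    """Exact ratios of a phantom's reference standard.

    ``r_n`` uses the exact nucleus counts; ``r_a`` and ``r_t`` count
    class-mask pixels (overlaps resolved by z-order, counted once); the
    ``r_t`` denominator is the full canvas area.
    """
    total = truth.total_nuclei
    if total == 0:
        raise RatioError("r_n is undefined for zero total nuclei")
    pos_px = int((truth.class_mask == POSITIVE).sum())
    neg_px = int((truth.class_mask == NEGATIVE).sum())
    nuclear_px = pos_px + neg_px
    r_n = 100.0 * truth.n_positive_nuclei / total
    r_a = 100.0 * pos_px / nuclear_px if nuclear_px else 0.0
    r_t = 100.0 * pos_px / truth.class_mask.size
    return RatioSet(r_n=r_n, r_a=r_a, r_t=r_t, source="truth")


def truth_table(truths: Iterable[GroundTruth], image_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-image ground-truth summary: counts and all three ratios."""
    rows = []
    truths = list(truths)
    ids = list(image_ids) if image_ids is not None else [f"img_{i:03d}" for i in range(len(truths))]
    for image_id, truth in zip(ids, truths):
        rs = ratios_from_truth(truth)
        rows.append(
            {
                "image_id": image_id,
                "positive_pct": truth.spec.positive_pct,
                "n_positive_nuclei": truth.n_positive_nuclei,
                "n_negative_nuclei": truth.n_negative_nuclei,
                "r_n": rs.r_n,
                "r_a": rs.r_a,
                "r_t": rs.r_t,
            }
        )
    return pd.DataFrame(rows)


def read_reader_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV of reader estimates (image_id, reader_id, r_n_est, r_t_est).

    Estimates are percentages; any value outside [0, 100] is rejected
    with its row number.  An empty file yields an empty table with a
    warning rather than an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty reader table", stacklevel=2)
        return pd.DataFrame(columns=list(READER_COLUMNS))
    missing = [c for c in READER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty reader table", stacklevel=2)
        return df[list(READER_COLUMNS)]
    for col in ("r_n_est", "r_t_est"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0) | (vals > 100)]
        if len(bad):
            # +2: header line plus 1-based numbering, i.e. the file line number
            raise ValueError(
                f"{path}: {col} out of [0, 100] or non-numeric at file line(s) "
                f"{[int(i) + 2 for i in bad]}"
            )
        df[col] = vals
    return df[list(READER_COLUMNS) + [c for c in df.columns if c not in READER_COLUMNS]]
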