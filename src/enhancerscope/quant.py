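"""Expression and reporter quantitation conventions.

Comparative (2^-ddCt) relative expression against a normalizer gene and a
calibrator sample; log-linear standard-curve fitting and absolute
quantitation for nuclear/cytoplasmic fractions; and dual-luciferase
normalization (firefly/renilla) with fold over a control construct.

Replicates are combined by arithmetic mean of Ct before dCt; replicate SD
is propagated in quadrature to a reported range 2^-(ddCt +/- sd).
Comparative mode assumes perfect doubling per cycle (base 2), matching the
2^ convention; an efficiency-corrected base can be supplied from a fitted
standard curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "gene", "replicate", "Ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(df["Ct"]).all():
        raise ValueError("Ct table contains non-finite Ct values")
    return df


def _mean_sd(table: pd.DataFrame, sample: str, gene: str) -> tuple[float, float]:
    sub = table[(table["sample"] == sample) & (table["gene"] == gene)]
    if sub.empty:
        raise ValueError(f"no Ct rows for sample={sample!r}, gene={gene!r}")
    return float(sub["Ct"].mean()), float(sub["Ct"].std(ddof=1)) if len(sub) > 1 else 0.0


def comparative_quantitation(
    table: pd.DataFrame,
    target: str,
    normalizer: str,
    calibrator: str,
    base: float = 2.0,
) -> pd.DataFrame:
    """Relative expression of ``target`` by the comparative (2^-ddCt) method.

    dCt_s = mean Ct(target, s) - mean Ct(normalizer, s);
    relative expression = base^-(dCt_s - dCt_calibrator), so the calibrator
    sample is exactly 1. Output columns: sample, delta_ct, rel_expr,
    rel_expr_low, rel_expr_high where the range is base^-(ddCt +/- sd) with
    sd = sqrt(sd_target^2 + sd_normalizer^2) over replicates.
    """
    samples = list(dict.fromkeys(table["sample"]))
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} absent from table")
    dct: dict[str, tuple[float, float]] = {}
    for s in samples:
        mt, sdt = _mean_sd(table, s, target)
        mn, sdn = _mean_sd(table, s, normalizer)
        dct[s] = (mt - mn, float(np.hypot(sdt, sdn)))
    dct_cal = dct[calibrator][0]
    rows = []
    for s in samples:
        ddct = dct[s][0] - dct_cal
        sd = dct[s][1]
        rows.append(
            {
                "sample": s,
                "delta_ct": dct[s][0],
                "rel_expr": base ** -ddct,
                "rel_expr_low": base ** -(ddct + sd),
                "rel_expr_high": base ** -(ddct - sd),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StandardCurve:
    """Least-squares fit of Ct on log10(quantity)."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency, 10^(-1/slope) - 1 (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(points) -> StandardCurve:
    """Fit a standard curve from (quantity, Ct) pairs (>= 3, quantities spread)."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (quantity, Ct) points")
    q, ct = arr[:, 0], arr[:, 1]
    if (q <= 0).any():
        raise ValueError("quantities must be > 0")
    logq = np.log10(q)
    if np.allclose(logq, logq[0]):
        raise ValueError("degenerate design: all quantities equal")
    fit = stats.linregress(logq, ct)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def absolute_quantitation(ct: float, curve: StandardCurve) -> float:
    """Quantity (in curve units) read off the standard curve: 10^((Ct - b)/m)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def luciferase_normalize(readings: pd.DataFrame, control_construct: str) -> pd.DataFrame:
    """Firefly/renilla normalization and fold over the control construct.

    ``readings`` columns: construct, firefly, renilla (and optionally
    sample/replicate). Rows with renilla <= 0 are excluded with a warning.
    Output per construct: mean normalized activity, its SD over replicates,
    and fold = mean(construct)/mean(control); the control's fold is 1.
    """
    required = {"construct", "firefly", "renilla"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"reporter table missing columns: {sorted(missing)}")
    bad = readings["renilla"] <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} reporter row(s) with non-positive renilla",
            stacklevel=2,
        )
        readings = readings[~bad]
    if control_construct not in set(readings["construct"]):
        raise ValueError(f"control construct {control_construct!r} absent (or all rows invalid)")
    norm = readings.assign(normalized=readings["firefly"] / readings["renilla"])
    grouped = norm.groupby("construct", sort=False)["normalized"]
    summary = grouped.agg(mean_normalized="mean", sd_normalized="std").reset_index()
    summary["sd_normalized"] = summary["sd_normalized"].fillna(0.0)
    control_mean = float(
        summary.loc[summary["construct"] == control_construct, "mean_normalized"].iloc[0]
    )
    summary["fold_over_control"] = summary["mean_normalized"] / control_mean
    return summary
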