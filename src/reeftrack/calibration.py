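"""Calibration of the positioning system's unitless precision score to metres.

Hyperbolic (time-difference-of-arrival) positioning systems emit a
unitless horizontal-precision score (HPE) per fix.  Receivers with
surveyed GPS coordinates are themselves positioned by the system, so
their fixes carry known deviations from truth.  Binning those deviations
by HPE and computing 2DRMS — twice the root of the summed mean-squared
deviations in X and Y, approximately the 95%-containment radius of
bivariate normal error — gives an empirical precision-to-accuracy map.
An ordinary least-squares line of 2DRMS on bin midpoints converts any
animal fix's HPE to an estimated metric error at the 95% level
(``hpe_m``), which is then thresholded (10 m for movement analyses, 5 m
for fine-scale distance-to-reef work).

Order of operations: exclude the upper 5% of HPE values, bin and fit on
receiver fixes, apply to animal fixes, threshold-filter.  Calibration is
fitted per dataset (per receiver-retrieval batch).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CalibrationError

logger = logging.getLogger(__name__)

#: Minimum dataset size for the upper-tail HPE exclusion to be meaningful.
MIN_FIXES_FOR_EXCLUSION = 20


def exclude_extreme_hpe(
    fixes: pd.DataFrame, quantile: float = 0.95, min_n: int = MIN_FIXES_FOR_EXCLUSION
) -> tuple[pd.DataFrame, float]:
    """Drop fixes in the upper tail of the HPE distribution.

    Extremely uncertain fixes are removed before any calibration so they
    cannot influence the 2DRMS fit.  The cutoff is the ``quantile``-th
    percentile of HPE, computed with linear interpolation between order
    statistics; fixes with ``hpe`` strictly above it are dropped.

    Returns the retained fixes and the cutoff.  With fewer than ``min_n``
    fixes a warning is issued and nothing is excluded (cutoff = NaN).
    """
    if len(fixes) == 0:
        raise CalibrationError("exclude_extreme_hpe: empty input")
    if len(fixes) < min_n:
        warnings.warn(
            f"only {len(fixes)} fixes (< {min_n}); skipping upper-tail HPE exclusion",
            stacklevel=2,
        )
        return fixes, float("nan")
    cutoff = float(np.quantile(fixes["hpe"].to_numpy(), quantile, method="linear"))
    kept = fixes[fixes["hpe"] <= cutoff]
    logger.info(
        "HPE exclusion: cutoff %.4g (q=%.3g), dropped %d of %d fixes",
        cutoff, quantile, len(fixes) - len(kept), len(fixes),
    )
    return kept.reset_index(drop=True), cutoff


def compute_2drms_bins(
    receiver_fixes: pd.DataFrame, bin_width: float = 1.0
) -> pd.DataFrame:
    """Bin receiver self-fix deviations by HPE and compute 2DRMS per bin.

    ``receiver_fixes`` must carry ``hpe`` and deviations ``dx, dy``
    (estimate minus surveyed truth, m).  Bins are ``[k*w, (k+1)*w)`` with
    midpoint ``(k + 0.5)*w``; per bin, ``2DRMS = 2 * sqrt(mean(dx^2) +
    mean(dy^2))`` pooled over all surveyed receivers — a mean squared
    deviation about known truth (accuracy), not about the bin mean.
    Empty bins are omitted.
    """
    for col in ("hpe", "dx", "dy"):
        if col not in receiver_fixes.columns:
            raise CalibrationError(f"receiver fixes lack column {col!r}")
    if len(receiver_fixes) == 0:
        raise CalibrationError(
            "no surveyed receiver fixes: calibration impossible"
        )
    hpe = receiver_fixes["hpe"].to_numpy(dtype=float)
    k = np.floor(hpe / bin_width).astype(int)
    rows = []
    for kk in np.unique(k):
        sel = k == kk
        mse_x = float(np.mean(receiver_fixes.loc[sel, "dx"] ** 2))
        mse_y = float(np.mean(receiver_fixes.loc[sel, "dy"] ** 2))
        rows.append(
            {
                "bin_lo": kk * bin_width,
                "bin_mid": (kk + 0.5) * bin_width,
                "n": int(sel.sum()),
                "twodrms": 2.0 * np.sqrt(mse_x + mse_y),
            }
        )
    return pd.DataFrame(rows).sort_values("bin_mid").reset_index(drop=True)


@dataclass
class HpeCalibrationResults:
    """Fitted HPE -> metric-error map with its provenance.

    ``predict``/``apply`` map HPE scores through ``slope * hpe +
    intercept`` (clamped at zero from below).
    """

    slope: float
    intercept: float
    hpe_cutoff: float
    bin_table: pd.DataFrame
    r_squared: float = float("nan")

    def predict(self, hpe):
        raw = self.slope * np.asarray(hpe, dtype=float) + self.intercept
        return np.maximum(raw, 0.0)

    def apply(self, fixes: pd.DataFrame) -> pd.DataFrame:
        return apply_calibration(fixes, self)

    def filter(self, fixes: pd.DataFrame, threshold_m: float):
        return filter_positions(fixes, threshold_m)

    def summary(self) -> str:
        lines = [
            "HPE calibration (receiver 2DRMS regression)",
            "-" * 44,
            f"slope       {self.slope:12.4f}  m per HPE unit",
            f"intercept   {self.intercept:12.4f}  m",
            f"HPE cutoff  {self.hpe_cutoff:12.4f}  (95th pct exclusion)",
            f"R^2         {self.r_squared:12.4f}",
            f"bins        {len(self.bin_table):6d}",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "hpe_cutoff": self.hpe_cutoff,
            "r_squared": self.r_squared,
            "bin_table": self.bin_table.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HpeCalibrationResults":
        payload = json.loads(Path(path).read_text())
        return cls(
            slope=payload["slope"],
            intercept=payload["intercept"],
            hpe_cutoff=payload["hpe_cutoff"],
            r_squared=payload.get("r_squared", float("nan")),
            bin_table=pd.DataFrame(payload["bin_table"]),
        )


def fit_hpe_regression(
    bin_table: pd.DataFrame, hpe_cutoff: float = float("nan")
) -> HpeCalibrationResults:
    """Ordinary least squares of 2DRMS on HPE bin midpoints (unweighted)."""
    if len(bin_table) < 2:
        raise CalibrationError(
            f"need >= 2 non-empty HPE bins to fit, got {len(bin_table)}"
        )
    x = bin_table["bin_mid"].to_numpy(dtype=float)
    y = bin_table["twodrms"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if np.any(fitted < 0):
        warnings.warn(
            "fitted 2DRMS is negative within the observed HPE range; "
            "predictions will be clamped at 0",
            stacklevel=2,
        )
    return HpeCalibrationResults(
        slope=float(slope),
        intercept=float(intercept),
        hpe_cutoff=hpe_cutoff,
        bin_table=bin_table.copy(),
        r_squared=r2,
    )


class HpeCalibration:
    """End-to-end calibration model: receiver fixes in, fitted map out.

    Parameters
    ----------
    receiver_fixes : DataFrame with ``hpe, dx, dy`` — self-fixes of
        surveyed receivers with deviations from truth in metres.
    bin_width : HPE bin width (default 1.0 HPE unit).
    exclude_upper : upper HPE tail fraction removed before binning
        (default 0.05, i.e. keep up to the 95th percentile).
    """

    def __init__(
        self,
        receiver_fixes: pd.DataFrame,
        bin_width: float = 1.0,
        exclude_upper: float = 0.05,
    ) -> None:
        self.receiver_fixes = receiver_fixes
        self.bin_width = bin_width
        self.exclude_upper = exclude_upper

    def fit(self) -> HpeCalibrationResults:
        kept, cutoff = exclude_extreme_hpe(
            self.receiver_fixes, quantile=1.0 - self.exclude_upper
        )
        bins = compute_2drms_bins(kept, bin_width=self.bin_width)
        return fit_hpe_regression(bins, hpe_cutoff=cutoff)


def apply_calibration(
    fixes: pd.DataFrame, model: HpeCalibrationResults
) -> pd.DataFrame:
    """Attach ``hpe_m`` = slope*hpe + intercept to every fix (clamped >= 0)."""
    out = fixes.copy()
    raw = model.slope * out["hpe"].to_numpy(dtype=float) + model.intercept
    n_clamped = int((raw < 0).sum())
    if n_clamped:
        warnings.warn(
            f"{n_clamped} fixes had negative predicted error; clamped to 0 m",
            stacklevel=2,
        )
    out["hpe_m"] = np.maximum(raw, 0.0)
    return out


@dataclass
class FilterReport:
    """Bookkeeping for one error-threshold filtering pass."""

    threshold_m: float
    n_in: int
    n_out: int

    @property
    def retention(self) -> float:
        return self.n_out / self.n_in if self.n_in else float("nan")

    def __str__(self) -> str:
        return (
            f"filter at {self.threshold_m:g} m: kept {self.n_out}/{self.n_in} "
            f"({100 * self.retention:.1f}%)"
        )


def filter_positions(
    fixes: pd.DataFrame, threshold_m: float
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop fixes whose estimated error exceeds ``threshold_m``.

    Standard thresholds: 10 m for movement analyses (reef use, home
    range, height above bottom), 5 m for fine-scale distance-to-reef.
    """
    if not threshold_m > 0:
        raise CalibrationError(f"threshold must be > 0 m, got {threshold_m}")
    if "hpe_m" not in fixes.columns:
        raise CalibrationError("fixes lack 'hpe_m'; run apply_calibration first")
    kept = fixes[fixes["hpe_m"] <= threshold_m].reset_index(drop=True)
    report = FilterReport(threshold_m=threshold_m, n_in=len(fixes), n_out=len(kept))
    if report.n_in and report.n_out == 0:
        warnings.warn(
            f"no fixes retained at {threshold_m:g} m threshold", stacklevel=2
        )
    logger.info("%s", report)
    return kept, report


def drift_test_error(
    vps_fixes: pd.DataFrame,
    gps_track: pd.DataFrame,
    region_of=None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Absolute error of positioning fixes against a towed GPS track.

    A transmitter towed slowly (~0.25 m/s) through the array is
    positioned by the system while a GPS logs truth.  Each fix's error is
    its Euclidean distance to the GPS position linearly interpolated to
    the fix time.  Fixes outside the GPS time span are excluded with a
    logged count.

    ``region_of(x, y) -> label`` optionally assigns each fix to a region
    (e.g. centre vs edge); per-region mean errors are then returned.
    """
    if len(gps_track) < 2:
        raise CalibrationError("GPS track needs >= 2 points to interpolate")
    gps = gps_track.sort_values("t")
    gt = gps["t"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    vt = vps_fixes["t"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    inside = (vt >= gt[0]) & (vt <= gt[-1])
    n_excluded = int((~inside).sum())
    if n_excluded == len(vps_fixes):
        raise CalibrationError("no temporal overlap between fixes and GPS track")
    if n_excluded:
        logger.info("drift_test_error: %d fixes outside GPS time span", n_excluded)
    sel = vps_fixes[inside].reset_index(drop=True)
    gx = np.interp(vt[inside], gt, gps["x"].to_numpy(dtype=float))
    gy = np.interp(vt[inside], gt, gps["y"].to_numpy(dtype=float))
    err = np.hypot(sel["x"].to_numpy(dtype=float) - gx,
                   sel["y"].to_numpy(dtype=float) - gy)
    out = sel.assign(error_m=err, gps_x=gx, gps_y=gy)
    means = None
    if region_of is not None:
        out["region"] = [
            region_of(x, y) for x, y in zip(out["gps_x"], out["gps_y"])
        ]
        means = out.groupby("region")["error_m"].mean()
    return out, means
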