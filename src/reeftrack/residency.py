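"""Release-reef residency: Kaplan–Meier estimation and site-fidelity algebra.

The quantity of interest is the proportion of tagged fish still resident
at the reef where they were released, as a function of days since
release.  A fish *departs* (event) when it is first observed visiting a
different reef or when it emigrates from the array; fish lost to
predation, tag shedding, harvest, surface mortality, or with unknown /
at-large dispositions are right-censored at their fate time.  Only fish
alive and present for at least 4 days post-release enter the analysis
(to exclude capture/release mortality).

Under simple exponential decay of release-reef occupancy,

    S(t) = N_t / N_0 = exp(-t * R_E),

with ``R_E`` the daily emigration rate, site fidelity over an interval
``t_SF`` is ``SF = exp(-t_SF * R_E)`` and the median residency is
``t_50 = t_SF * ln(0.5) / ln(SF)``.  Annual fidelity AF is the
``t_SF = 365`` special case.  :func:`convert_fidelity` completes any
sufficient subset of these parameters and keeps them mutually
consistent.

The Kaplan–Meier estimator is implemented natively: S(t) is the product
of (1 - d_i/n_i) over event times, with Greenwood variance and
confidence intervals on the complementary log-log scale (which keeps
bounds inside [0, 1]).  At tied times, events precede censorings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Fates that right-censor a residency record rather than score a departure.
CENSORING_FATES = frozenset(
    {"predation", "tag_loss", "harvest", "surface_mortality", "unknown", "at_large"}
)

#: Minimum days alive and present post-release to enter the analysis.
MIN_DAYS_PRESENT = 4.0


def build_residency_records(
    visits: pd.DataFrame,
    fates: pd.DataFrame,
    release_reef: dict | pd.Series,
    release_time: dict | pd.Series,
    last_time: dict | pd.Series,
    min_days: float = MIN_DAYS_PRESENT,
) -> pd.DataFrame:
    """Score one (duration, event) residency record per eligible fish.

    Parameters
    ----------
    visits : visit-event frame from :func:`reeftrack.reefs.detect_visits`.
    fates : frame with ``fish_id, fate, t`` (one row per fish).
    release_reef, release_time, last_time : per-fish mappings giving the
        reef of release, the release timestamp, and the last time the
        fish was observed inside the array.

    Event time is the first departure from the release reef: the start of
    the first visit event at a different reef, or the emigration fate
    time, whichever is earlier.  Otherwise the fish is censored at its
    fate time (or its last observation for fish still at large).  Fish
    present for fewer than ``min_days`` days are excluded.
    """
    fates_by_fish = fates.set_index("fish_id") if len(fates) else pd.DataFrame()
    records = []
    for fish_id in release_time.keys() if hasattr(release_time, "keys") else release_time.index:
        if fish_id not in release_reef or pd.isna(release_reef[fish_id]):
            raise ValueError(f"fish {fish_id!r} has no release reef")
        t0 = pd.Timestamp(release_time[fish_id])
        t_last = pd.Timestamp(last_time[fish_id])
        present_days = (t_last - t0).total_seconds() / 86400.0
        if present_days < min_days:
            continue

        event_time = None
        fish_visits = visits[visits["fish_id"] == fish_id].sort_values("t_start")
        away = fish_visits[fish_visits["reef_id"] != release_reef[fish_id]]
        if len(away):
            event_time = pd.Timestamp(away["t_start"].iloc[0])

        censor_time = t_last
        if fish_id in getattr(fates_by_fish, "index", []):
            fate = fates_by_fish.loc[fish_id, "fate"]
            fate_t = pd.Timestamp(fates_by_fish.loc[fish_id, "t"])
            if fate == "emigration" and (event_time is None or fate_t < event_time):
                event_time = fate_t
            elif fate in CENSORING_FATES:
                censor_time = fate_t

        if event_time is not None and event_time <= censor_time:
            duration = (event_time - t0).total_seconds() / 86400.0
            event = True
        else:
            duration = (censor_time - t0).total_seconds() / 86400.0
            event = False
        records.append(
            {"fish_id": fish_id, "duration": max(duration, 1e-9), "event": event}
        )
    return pd.DataFrame(records, columns=["fish_id", "duration", "event"])


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass
class MedianResidency:
    t50: float
    ci_lower: float
    ci_upper: float
    reached: bool

    def __str__(self) -> str:
        if not self.reached:
            return "median residency: not reached"
        return (
            f"median residency: {self.t50:g} d "
            f"(95% CI {self.ci_lower:g}-{self.ci_upper:g} d)"
        )


class KaplanMeierResults:
    """Fitted release-reef survival curve.

    Attributes
    ----------
    table : DataFrame with one row per distinct event/censor time:
        ``t, n_risk, n_events, n_censored, survival, ci_lower, ci_upper``.
    median_ : :class:`MedianResidency`
    """

    def __init__(self, table: pd.DataFrame, alpha: float, n: int) -> None:
        self.table = table
        self.alpha = alpha
        self.nobs = n
        self.median_ = self._median()

    def survival_at(self, t):
        """Step-function S(t) (right-continuous) at arbitrary times."""
        t = np.asarray(t, dtype=float)
        times = self.table["t"].to_numpy()
        surv = self.table["survival"].to_numpy()
        idx = np.searchsorted(times, t, side="right") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    def _band_cross(self, col: str) -> float:
        """Smallest event time where ``col`` drops to <= 0.5."""
        ev = self.table[self.table["n_events"] > 0]
        hit = ev[ev[col] <= 0.5]
        return float(hit["t"].iloc[0]) if len(hit) else float("nan")

    def _median(self) -> MedianResidency:
        t50 = self._band_cross("survival")
        lo = self._band_cross("ci_lower")
        hi = self._band_cross("ci_upper")
        return MedianResidency(
            t50=t50, ci_lower=lo, ci_upper=hi, reached=not np.isnan(t50)
        )

    def summary(self) -> str:
        n_events = int(self.table["n_events"].sum())
        lines = [
            "Kaplan-Meier release-reef residency",
            "-" * 36,
            f"n fish      {self.nobs}",
            f"departures  {n_events}",
            f"censored    {self.nobs - n_events}",
            str(self.median_),
            "",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        """Step plot of S(t) with its confidence band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.table["t"].to_numpy()])
        s = np.concatenate([[1.0], self.table["survival"].to_numpy()])
        lo = np.concatenate([[1.0], self.table["ci_lower"].to_numpy()])
        hi = np.concatenate([[1.0], self.table["ci_upper"].to_numpy()])
        ax.step(t, s, where="post", **kwargs)
        ax.fill_between(t, lo, hi, step="post", alpha=0.2)
        ax.set_xlabel("days since release")
        ax.set_ylabel("proportion at release reef")
        ax.set_ylim(0, 1.02)
        return ax


class KaplanMeier:
    """Nonparametric survival model for residency durations.

    Parameters
    ----------
    durations : array of days from release to departure or censoring (> 0).
    events : boolean array; True = departed (event), False = censored.
    alpha : two-sided CI level complement (default 0.05 for 95% bands).
    """

    def __init__(self, durations, events, alpha: float = 0.05) -> None:
        self.durations = np.asarray(durations, dtype=float)
        self.events = np.asarray(events, dtype=bool)
        if self.durations.shape != self.events.shape:
            raise ValueError("durations and events must have the same length")
        if len(self.durations) == 0:
            raise ValueError("need at least one record")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be > 0")
        self.alpha = alpha

    @classmethod
    def from_records(cls, records: pd.DataFrame, alpha: float = 0.05) -> "KaplanMeier":
        return cls(records["duration"], records["event"], alpha=alpha)

    def fit(self) -> KaplanMeierResults:
        from scipy.stats import norm

        t = self.durations
        e = self.events
        order = np.argsort(t, kind="mergesort")
        t, e = t[order], e[order]
        n = len(t)
        times = np.unique(t)

        rows = []
        surv = 1.0
        greenwood = 0.0  # running sum d / (n (n - d))
        at_risk = n
        z = norm.ppf(1 - self.alpha / 2)
        for ti in times:
            here = t == ti
            d = int(np.sum(here & e))
            c = int(np.sum(here & ~e))
            if d > 0:
                surv *= 1.0 - d / at_risk
                if at_risk > d:
                    greenwood += d / (at_risk * (at_risk - d))
                else:
                    greenwood = np.inf
            if 0 < surv < 1 and np.isfinite(greenwood):
                # CI on the complementary log-log scale
                se = np.sqrt(greenwood) / abs(np.log(surv))
                lo = surv ** np.exp(z * se)
                hi = surv ** np.exp(-z * se)
            elif surv == 0.0:
                lo = hi = 0.0
            else:
                lo = hi = surv
            rows.append(
                {
                    "t": ti,
                    "n_risk": at_risk,
                    "n_events": d,
                    "n_censored": c,
                    "survival": surv,
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
            at_risk -= d + c
        table = pd.DataFrame(rows)
        if not e.any():
            warnings.warn("no departure events: survival curve is degenerate (S=1)",
                          stacklevel=2)
        return KaplanMeierResults(table, alpha=self.alpha, n=n)


def km_estimate(records: pd.DataFrame, alpha: float = 0.05) -> KaplanMeierResults:
    """Functional wrapper: Kaplan–Meier curve from a residency-record frame."""
    return KaplanMeier.from_records(records, alpha=alpha).fit()


def median_residency(curve: KaplanMeierResults) -> MedianResidency:
    """Median residency (smallest event time with S <= 0.5) and its CI.

    The CI bounds are the first event times at which the lower and upper
    confidence bands drop to 0.5 (band-intersection construction).  If
    S never reaches 0.5 the median is flagged as not reached.
    """
    return curve.median_


# ---------------------------------------------------------------------------
# site-fidelity algebra


@dataclass
class FidelityParams:
    """Mutually consistent exponential-decay site-fidelity parameters.

    ``sf`` is the proportion remaining after ``t_sf`` days, ``r_e`` the
    daily emigration rate, ``t50`` the median residency in days, and
    ``af`` the annual (365-day) fidelity.
    """

    sf: float
    t_sf: float
    r_e: float
    t50: float
    af: float

    def summary(self) -> str:
        return (
            f"SF = {self.sf:.6g} over t_SF = {self.t_sf:g} d | "
            f"R_E = {self.r_e:.6g} /d | t50 = {self.t50:.6g} d | "
            f"AF = {self.af:.6g}"
        )


def convert_fidelity(
    sf: float | None = None,
    t_sf: float | None = None,
    r_e: float | None = None,
    t50: float | None = None,
) -> FidelityParams:
    """Complete the exponential-decay fidelity parameter set.

    Accepts any sufficient subset: (``sf`` and ``t_sf``), ``r_e`` alone,
    or ``t50`` alone (optionally with ``t_sf`` to also report SF over
    that interval; default ``t_sf`` = 365 d, making SF = AF).

    Uses R_E = -ln(SF)/t_SF, t50 = t_SF ln(0.5)/ln(SF) = ln(2)/R_E and
    AF = exp(-365 R_E).  SF = 1 means no emigration: R_E = 0 and the
    median is infinite (a warning flags it).  SF <= 0 or SF > 1 is an
    error.
    """
    ln2 = np.log(2.0)
    if sf is not None:
        if not 0 < sf <= 1:
            raise ValueError(f"SF must be in (0, 1], got {sf}")
        if t_sf is None or not t_sf > 0:
            raise ValueError("SF requires a positive t_SF interval")
        if sf == 1.0:
            warnings.warn("SF = 1: zero emigration, median residency is infinite",
                          stacklevel=2)
            r_e = 0.0
            t50 = np.inf
        else:
            r_e = -np.log(sf) / t_sf
            t50 = t_sf * np.log(0.5) / np.log(sf)
    elif r_e is not None:
        if r_e < 0:
            raise ValueError(f"R_E must be >= 0, got {r_e}")
        t_sf = 365.0 if t_sf is None else t_sf
        t50 = ln2 / r_e if r_e > 0 else np.inf
        sf = float(np.exp(-t_sf * r_e))
    elif t50 is not None:
        if not t50 > 0:
            raise ValueError(f"t50 must be > 0, got {t50}")
        t_sf = 365.0 if t_sf is None else t_sf
        r_e = ln2 / t50
        sf = float(np.exp(t_sf * np.log(0.5) / t50))
    else:
        raise ValueError("provide (sf, t_sf), r_e, or t50")
    af = float(np.exp(-365.0 * r_e))
    return FidelityParams(sf=float(sf), t_sf=float(t_sf), r_e=float(r_e),
                          t50=float(t50), af=af)
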