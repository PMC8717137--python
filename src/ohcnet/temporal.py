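"""Posting-activity profiles by weekday and hour of day, and their rank correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .distfit import DescriptiveStats, describe

__all__ = [
    "ActivityProfile",
    "CorrelationResult",
    "activity_profile",
    "correlate_profiles",
    "monthly_weekday_stats",
    "plot_profile",
]

_GRANULARITY_BINS = {"weekday": 7, "hour": 24}
_KINDS = ("all_posts", "threads", "replies")


@dataclass(frozen=True)
class ActivityProfile:
    granularity: str  # "weekday" (7 bins, Monday first) or "hour" (24 bins)
    kind: str  # "all_posts", "threads" or "replies"
    percentages: tuple[float, ...]  # sums to 100

    def top_bins(self, k: int) -> list[int]:
        order = np.argsort(self.percentages, kind="stable")[::-1]
        return [int(i) for i in order[:k]]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _timestamps(posts, kind: str) -> list:
    if kind == "all_posts":
        return [p.timestamp for p in posts]
    if kind == "threads":
        return [p.timestamp for p in posts if p.is_thread_root]
    if kind == "replies":
        return [p.timestamp for p in posts if not p.is_thread_root]
    raise ValueError(f"unknown kind: {kind!r}")


def activity_profile(posts, granularity: str, kind: str = "all_posts") -> ActivityProfile:
    """Share of posts per weekday (Monday first) or per hour, as percentages.

    Hours bucket by truncation: a post at 09:59 falls in bin 9.
    """
    if granularity not in _GRANULARITY_BINS:
        raise ValueError(f"unknown granularity: {granularity!r}")
    stamps = _timestamps(posts, kind)
    if not stamps:
        raise ValueError(f"no posts of kind {kind!r}")
    nbins = _GRANULARITY_BINS[granularity]
    if granularity == "weekday":
        idx = np.array([t.weekday() for t in stamps])
    else:
        idx = np.array([t.hour for t in stamps])
    counts = np.bincount(idx, minlength=nbins).astype(float)
    pct = 100.0 * counts / counts.sum()
    return ActivityProfile(
        granularity=granularity, kind=kind, percentages=tuple(float(p) for p in pct)
    )


def correlate_profiles(a: ActivityProfile, b: ActivityProfile) -> CorrelationResult:
    """Spearman rank correlation between two same-granularity profiles.

    Ties receive average ranks; the p-value is two-tailed.
    """
    if a.granularity != b.granularity:
        raise ValueError(
            f"granularity mismatch: {a.granularity!r} vs {b.granularity!r}"
        )
    res = scipy.stats.spearmanr(a.percentages, b.percentages)
    return CorrelationResult(
        rho=float(res.statistic), p_value=float(res.pvalue), n=len(a.percentages)
    )


def monthly_weekday_stats(posts) -> pd.DataFrame:
    """Distribution of monthly posting counts per weekday.

    For each weekday the posting count is tallied within every calendar month
    the data span, and the per-month counts are summarized with the same
    five-number summary used elsewhere.  Requires data spanning at least two
    calendar months.
    """
    stamps = [p.timestamp for p in posts]
    if not stamps:
        raise ValueError("no posts")
    frame = pd.DataFrame(
        {
            "month": [pd.Period(t, freq="M") for t in stamps],
            "weekday": [t.weekday() for t in stamps],
        }
    )
    months = pd.period_range(frame["month"].min(), frame["month"].max(), freq="M")
    if len(months) < 2:
        raise ValueError("monthly_weekday_stats requires data spanning >= 2 months")
    counts = (
        frame.groupby(["weekday", "month"], observed=False).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=range(7), columns=months, fill_value=0)
    rows = []
    for wd in range(7):
        st: DescriptiveStats = describe(counts.loc[wd].to_numpy())
        rows.append(
            {
                "weekday": wd,
                "min": st.min,
                "q1": st.q1,
                "median": st.median,
                "q3": st.q3,
                "max": st.max,
                "mean": st.mean,
            }
        )
    return pd.DataFrame(rows).set_index("weekday")


def plot_profile(profile: ActivityProfile, path=None, ax=None):
    """Simple line rendering of a profile; saves to ``path`` when given."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    nbins = len(profile.percentages)
    ax.plot(range(nbins), profile.percentages, marker="o", ms=3)
    if profile.granularity == "weekday":
        ax.set_xticks(range(7), ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"])
    else:
        ax.set_xlabel("hour of day")
    ax.set_ylabel(f"% of {profile.kind.replace('_', ' ')}")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
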