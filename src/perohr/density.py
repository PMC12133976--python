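"""Minimum number known alive (MNKA) density index.

MNKA is a classical capture-mark-recapture abundance index: an individual is
"known alive" on every sampling event between its first and last capture at a
plot, and the event's MNKA is the count of such individuals (all Peromyscus
pooled, since field species identifications are unreliable).  Each focal
individual's density covariate, meanMNKA, averages the plot's MNKA over the
events spanning the focal animal's own capture window.

A sampling event is a distinct trap-night date at a plot — the finest
resolution the records support; per-bout granularity is obtained upstream by
aggregating dates before calling in here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def enumerate_events(dates) -> pd.DatetimeIndex:
    """Distinct trap-night dates, ordered: one sampling event each."""
    d = pd.DatetimeIndex(pd.to_datetime(pd.Series(list(dates)).dropna().unique()))
    return d.sort_values()


def mnka(df: pd.DataFrame) -> pd.DataFrame:
    """Per-plot, per-event MNKA series.

    Expects a capture frame with ``plot_id``, ``collect_date``, ``tag_id``.
    Events at a plot are its distinct capture dates present in the records.
    """
    out = []
    for plot, sub in df.groupby("plot_id"):
        events = enumerate_events(sub["collect_date"])
        spans = sub.groupby("tag_id")["collect_date"].agg(["min", "max"])
        counts = np.zeros(len(events), dtype=int)
        for first, last in spans.itertuples(index=False):
            counts += ((events >= first) & (events <= last)).astype(int)
        out.append(pd.DataFrame({
            "plot_id": plot, "event_date": events, "mnka": counts,
        }))
    if not out:
        return pd.DataFrame(columns=["plot_id", "event_date", "mnka"])
    return pd.concat(out, ignore_index=True)


def mean_mnka(first, last, series: pd.DataFrame, plot_id: str) -> float:
    """Mean MNKA at ``plot_id`` over events in the inclusive window [first, last]."""
    sub = series[series["plot_id"] == plot_id]
    win = sub[(sub["event_date"] >= first) & (sub["event_date"] <= last)]
    if win.empty:
        raise ValueError(f"no sampling events for plot {plot_id!r} in window")
    return float(win["mnka"].mean())


def mean_mnka_per_individual(df: pd.DataFrame, home_plots: pd.Series,
                             series: pd.DataFrame | None = None) -> pd.Series:
    """meanMNKA for every individual, scoped to its home plot.

    ``home_plots`` maps tag_id -> plot; the window is the individual's first
    to last capture at that plot.
    """
    if series is None:
        series = mnka(df)
    vals = {}
    for tag, plot in home_plots.items():
        sub = df[(df["tag_id"] == tag) & (df["plot_id"] == plot)]
        if sub.empty:
            vals[tag] = np.nan
            continue
        vals[tag] = mean_mnka(sub["collect_date"].min(), sub["collect_date"].max(),
                              series, plot)
    return pd.Series(vals, name="mean_mnka")
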