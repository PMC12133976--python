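"""Kernel home-range estimation on trap-grid relocations.

An animal's utilization distribution (UD) is estimated by a fixed-bandwidth
bivariate Gaussian kernel density over its adult-capture trap positions, with
the reference ("href") bandwidth h = sigma_pooled * n^(-1/6).  The home range
is the 50% isopleth: the area of the smallest set of highest-density grid
cells holding half the UD mass.  A minimum convex polygon (MCP) estimator is
provided for comparison, and a rarefaction routine quantifies how both
estimators degrade as relocations are subsampled.

Relocations from live trapping are few and duplicated (trap re-use); the
eligibility rule — at least five adult captures from at least three unique
traps — is the gate the rarefaction analysis supports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

logger = logging.getLogger(__name__)

MIN_CAPTURES = 5
MIN_UNIQUE_LOCATIONS = 3
DEFAULT_LEVEL = 0.50
DEFAULT_CELL_M = 1.0
MIN_PAD_M = 15.0

#: 50% highest-density-region area of a circular bivariate normal with
#: standard deviation sigma is 2*pi*sigma^2*ln 2.
GAUSSIAN_AREA_FACTOR = 2.0 * np.pi * np.log(2.0)


def gaussian_area50(sigma: float) -> float:
    """Closed-form 50% isopleth area of a circular Gaussian UD (m^2)."""
    return GAUSSIAN_AREA_FACTOR * sigma ** 2


def sigma_from_area50(area50: float) -> float:
    return np.sqrt(area50 / GAUSSIAN_AREA_FACTOR)


def eligibility(points: np.ndarray,
                min_captures: int = MIN_CAPTURES,
                min_unique: int = MIN_UNIQUE_LOCATIONS) -> tuple[bool, str]:
    """Gate an individual's relocations for home-range estimation.

    Accept iff there are at least ``min_captures`` relocations from at least
    ``min_unique`` distinct trap positions; the reason is recorded on reject.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    n_unique = len(np.unique(pts, axis=0)) if n else 0
    if n < min_captures:
        return False, f"only {n} adult capture(s); need >= {min_captures}"
    if n_unique < min_unique:
        return False, f"only {n_unique} unique location(s); need >= {min_unique}"
    return True, "eligible"


def href_bandwidth(points: np.ndarray) -> float:
    """Reference bandwidth: sqrt(0.5*(var x + var y)) * n^(-1/6), n-1 variances."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two points for a bandwidth")
    v = 0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1))
    if v <= 0:
        raise ValueError("all points identical: bandwidth undefined")
    return float(np.sqrt(v) * len(pts) ** (-1.0 / 6.0))


@dataclass
class UDGrid:
    """Discretized utilization distribution.

    ``mass[i, j]`` is the probability mass of the cell centred at
    ``(x0 + j*cell, y0 + i*cell)``; the grid sums to one.
    """
    x0: float
    y0: float
    cell: float
    mass: np.ndarray = field(repr=False)
    bandwidth_h: float

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


def kde_ud(points: np.ndarray, h: float | None = None,
           cell: float = DEFAULT_CELL_M, pad: float | None = None) -> UDGrid:
    """Gaussian-kernel UD over a regular grid covering the data.

    The grid extends ``max(3h, 15 m)`` beyond the data bounding box so the
    kernel tails are captured; densities are evaluated at cell centres and
    normalized to unit total mass.  Duplicate points are retained as-is —
    kernel smoothing handles multiplicity.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty point set")
    if h is None:
        h = href_bandwidth(pts)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if cell > h:
        warnings.warn(f"grid cell ({cell} m) coarser than bandwidth ({h:.2f} m)")
    if pad is None:
        pad = max(3.0 * h, MIN_PAD_M)
    x0 = pts[:, 0].min() - pad
    x1 = pts[:, 0].max() + pad
    y0 = pts[:, 1].min() - pad
    y1 = pts[:, 1].max() + pad
    xs = np.arange(x0 + cell / 2.0, x1, cell)
    ys = np.arange(y0 + cell / 2.0, y1, cell)
    dens = np.zeros((len(ys), len(xs)))
    inv2h2 = 1.0 / (2.0 * h * h)
    # chunk over points to bound the (cells x points) temporary
    step = max(1, int(2e6 // (len(xs) * len(ys)) + 1))
    dx2 = None
    for i in range(0, len(pts), step):
        chunk = pts[i:i + step]
        dx2 = (xs[None, :, None] - chunk[:, 0]) ** 2
        dy2 = (ys[:, None, None] - chunk[:, 1]) ** 2
        dens += np.exp(-(dx2 + dy2) * inv2h2).sum(axis=-1)
    total = dens.sum()
    if total <= 0:
        raise ValueError("degenerate UD: zero total density")
    return UDGrid(x0=xs[0] - cell / 2.0, y0=ys[0] - cell / 2.0, cell=cell,
                  mass=dens / total, bandwidth_h=float(h))


def isopleth_area(ud: UDGrid, level: float = DEFAULT_LEVEL) -> float:
    """Area (m^2) of the smallest highest-density cell set holding ``level`` mass.

    Cells are accumulated in decreasing density order until the cumulative
    mass reaches the level; cells tied with the last-included density are all
    included.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    srt = np.sort(ud.mass.ravel())[::-1]
    cum = np.cumsum(srt)
    k = int(np.searchsorted(cum, level * cum[-1]))
    thr = srt[min(k, len(srt) - 1)]
    n_cells = int((ud.mass >= thr).sum())
    return n_cells * ud.cell ** 2


def kde_area(points: np.ndarray, level: float = DEFAULT_LEVEL,
             cell: float = DEFAULT_CELL_M, h: float | None = None) -> float:
    """Convenience: fit the UD and return the isopleth area in m^2."""
    return isopleth_area(kde_ud(points, h=h, cell=cell), level)


def mcp_area(points: np.ndarray, percent: float = 100.0) -> float:
    """Minimum-convex-polygon area (m^2) of the ``percent`` points closest
    to the centroid.  Fewer than three unique retained points give area 0
    with a warning (a degenerate hull)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        return 0.0
    if percent < 100.0:
        c = pts.mean(axis=0)
        d = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        keep = max(3, int(np.ceil(len(pts) * percent / 100.0)))
        pts = pts[np.argsort(d, kind="stable")[:keep]]
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        warnings.warn("fewer than 3 unique points: MCP area is 0")
        return 0.0
    area = float(MultiPoint(uniq).convex_hull.area)
    if area == 0.0:
        warnings.warn("degenerate (colinear) hull: MCP area is 0")
    return area


def home_range_table(df: pd.DataFrame,
                     levels: tuple[float, ...] = (DEFAULT_LEVEL,),
                     cell: float = DEFAULT_CELL_M,
                     min_captures: int = MIN_CAPTURES,
                     min_unique: int = MIN_UNIQUE_LOCATIONS,
                     include_mcp: bool = False) -> pd.DataFrame:
    """Per-individual home-range estimates from adult captures with positions.

    Expects columns ``tag_id``, ``x``, ``y`` (adult captures only, missing
    positions already excluded).  Ineligible individuals appear with missing
    areas and the rejection reason.
    """
    rows = []
    for tag, sub in df.groupby("tag_id"):
        pts = sub[["x", "y"]].dropna().to_numpy(float)
        ok, reason = eligibility(pts, min_captures, min_unique)
        row = {
            "tag_id": tag,
            "n_captures": len(pts),
            "n_unique": len(np.unique(pts, axis=0)) if len(pts) else 0,
            "eligible": ok,
            "reason": reason,
            "bandwidth_h": np.nan,
        }
        for lv in levels:
            row[f"area{int(round(lv * 100))}_m2"] = np.nan
        if include_mcp:
            row["mcp_area_m2"] = np.nan
        if ok:
            ud = kde_ud(pts, cell=cell)
            row["bandwidth_h"] = ud.bandwidth_h
            for lv in levels:
                row[f"area{int(round(lv * 100))}_m2"] = isopleth_area(ud, lv)
            if include_mcp:
                row["mcp_area_m2"] = mcp_area(pts)
        rows.append(row)
    return pd.DataFrame(rows)


def write_ud_ascii(ud: UDGrid, path) -> None:
    """Dump a UD grid as an ESRI ASCII raster for inspection."""
    ny, nx = ud.mass.shape
    header = (f"ncols {nx}\nnrows {ny}\nxllcorner {ud.x0}\nyllcorner {ud.y0}\n"
              f"cellsize {ud.cell}\nNODATA_value -9999\n")
    with open(path, "w") as fh:
        fh.write(header)
        for row in ud.mass[::-1]:
            fh.write(" ".join(f"{v:.6e}" for v in row) + "\n")


def rarefaction(points_by_tag: dict[str, np.ndarray],
                k_min: int = 10,
                reps: int = 500,
                estimators: tuple[str, ...] = ("kde", "mcp"),
                level: float = DEFAULT_LEVEL,
                cell: float = DEFAULT_CELL_M,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Subsampling analysis of estimator stability.

    For every reference individual with at least ``k_min`` relocations and
    each subsample size j = 3 .. k_min-1, draw j relocations without
    replacement ``reps`` times (split across individuals), recompute the area,
    and record the relative error against that individual's full-data area.
    Returns a tidy frame per (estimator, j): the signed median relative error
    with quartiles, and the median absolute relative error.
    """
    if rng is None:
        rng = np.random.default_rng()
    refs = {t: np.asarray(p, float) for t, p in points_by_tag.items()
            if len(p) >= k_min and len(np.unique(p, axis=0)) >= MIN_UNIQUE_LOCATIONS}
    if not refs:
        raise ValueError(f"no reference individuals with >= {k_min} relocations")
    per_ind = max(1, int(np.ceil(reps / len(refs))))
    errs: dict[tuple[str, int], list[float]] = {}
    for tag, pts in refs.items():
        full = {}
        if "kde" in estimators:
            full["kde"] = kde_area(pts, level=level, cell=cell)
        if "mcp" in estimators:
            full["mcp"] = mcp_area(pts)
        for j in range(3, k_min):
            for _ in range(per_ind):
                sub = pts[rng.choice(len(pts), size=j, replace=False)]
                uniq = len(np.unique(sub, axis=0))
                for est in estimators:
                    if est == "kde":
                        if uniq < 2:
                            continue
                        a = kde_area(sub, level=level, cell=cell)
                    else:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            a = mcp_area(sub)
                    ref = full[est]
                    if ref > 0:
                        errs.setdefault((est, j), []).append(a / ref - 1.0)
    rows = []
    for (est, j), e in sorted(errs.items()):
        e = np.asarray(e)
        rows.append({
            "estimator": est, "n_subsample": j, "n_draws": len(e),
            "median_rel_err": float(np.median(e)),
            "q25_rel_err": float(np.quantile(e, 0.25)),
            "q75_rel_err": float(np.quantile(e, 0.75)),
            "median_abs_rel_err": float(np.median(np.abs(e))),
        })
    return pd.DataFrame(rows)


def stable_subsample_size(rarefaction_table: pd.DataFrame,
                          estimator: str = "kde",
                          tolerance: float = 0.10) -> int | None:
    """Smallest subsample size whose |median relative error| is below tolerance."""
    sub = rarefaction_table[rarefaction_table["estimator"] == estimator]
    for _, row in sub.sort_values("n_subsample").iterrows():
        if abs(row["median_rel_err"]) < tolerance:
            return int(row["n_subsample"])
    return None
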