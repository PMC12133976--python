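"""Reading, validation and cleaning of NEON-dialect small-mammal capture tables.

The NEON small-mammal data product records one row per trap-night capture on a
1-ha grid of 100 Sherman traps at 10 m spacing.  This module reads that dialect
into a standardized :class:`pandas.DataFrame`, converts trap coordinates
(letter row A-J, column 1-10) to metric positions, applies the genus-level
taxon filters, the implausible-measurement rules, and the NLCD-to-macrohabitat
grouping used throughout the analysis.

All cleaning steps log what they removed; nothing is dropped silently.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standardized internal column names.
COLUMNS = [
    "site_id", "plot_id", "trap_coordinate", "collect_date", "tag_id",
    "taxon", "sex", "pregnancy_status", "life_stage_raw",
    "mass_g", "hindfoot_mm", "nlcd_class", "latitude",
]

#: Default mapping from NEON mam_pertrapnight column names to internal names.
NEON_COLUMN_MAP = {
    "siteID": "site_id",
    "plotID": "plot_id",
    "trapCoordinate": "trap_coordinate",
    "collectDate": "collect_date",
    "tagID": "tag_id",
    "taxonID": "taxon",
    "sex": "sex",
    "pregnancyStatus": "pregnancy_status",
    "lifeStage": "life_stage_raw",
    "weight": "mass_g",
    "hindfootLength": "hindfoot_mm",
    "nlcdClass": "nlcd_class",
    "decimalLatitude": "latitude",
}

#: Peromyscus species that exhibit social/genetic monogamy; removed because
#: monogamy inverts the sex-difference predictions for space use.
MONOGAMOUS_SPECIES = frozenset({"californicus", "eremicus", "polionotus"})

#: NLCD vegetation classes grouped into three macrohabitat categories.
NLCD_TO_HABITAT = {
    "deciduousForest": "forest",
    "mixedForest": "forest",
    "evergreenForest": "forest",
    "woodyWetlands": "forest",
    "grasslandHerbaceous": "grassland",
    "cultivatedCrops": "grassland",
    "pastureHay": "grassland",
    "shrubScrub": "shrubland",
}

_TRAP_RE = re.compile(r"^([A-J])(10|[1-9])$")

MASS_OUTLIER_G = 50.0
HINDFOOT_OUTLIER_MM = 28.0
IMPLAUSIBLE_ADULT_MASS_G = 10.0


class ColumnError(ValueError):
    """A mandatory input column is absent."""


class EmptyInputError(ValueError):
    """The input file contains no data rows."""


class HabitatError(KeyError):
    """An NLCD class has no macrohabitat mapping."""


def trap_to_xy(coord: str) -> tuple[float, float]:
    """Convert a trap coordinate like ``"E5"`` to metres (x east, y north).

    The letter indexes the row (A=0 at the origin), the number the column;
    traps sit on a 10 m lattice, so ``"A1" -> (0, 0)`` and ``"J10" -> (90, 90)``.
    Any consistent convention yields identical areas downstream.
    """
    m = _TRAP_RE.match(str(coord).strip())
    if not m:
        raise ValueError(f"malformed trap coordinate: {coord!r}")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2)) - 1
    return (10.0 * col, 10.0 * row)


def is_valid_trap(coord) -> bool:
    return isinstance(coord, str) and bool(_TRAP_RE.match(coord.strip()))


def add_trap_xy(df: pd.DataFrame) -> pd.DataFrame:
    """Append metric ``x``/``y`` columns (NaN where the coordinate is missing)."""
    xs, ys = [], []
    for c in df["trap_coordinate"]:
        if isinstance(c, str) and _TRAP_RE.match(c.strip()):
            x, y = trap_to_xy(c)
        else:
            x, y = np.nan, np.nan
        xs.append(x)
        ys.append(y)
    out = df.copy()
    out["x"] = xs
    out["y"] = ys
    return out


def read_captures(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a NEON-dialect capture CSV into the standardized frame.

    Comma-separated, UTF-8; literal ``"NA"`` or empty cells are missing.
    Unparseable numeric fields become missing, never zero.  Rows whose trap
    coordinate is present but not on the A-J / 1-10 grid are excluded with a
    logged warning; rows with a *missing* coordinate are kept (they still
    count for density and phenotypes, just not for home ranges).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(NEON_COLUMN_MAP if column_map is None else column_map)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=["", "NA"])
    if raw.empty:
        raise EmptyInputError(f"no data rows in {path}")
    missing = [src for src in cmap if src not in raw.columns]
    if missing:
        raise ColumnError(f"missing mandatory column(s): {', '.join(sorted(missing))}")
    df = raw[list(cmap)].rename(columns=cmap)
    for col in ("mass_g", "hindfoot_mm", "latitude"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["collect_date"] = pd.to_datetime(df["collect_date"], errors="coerce")

    bad = df["trap_coordinate"].notna() & ~df["trap_coordinate"].map(is_valid_trap)
    if bad.any():
        logger.warning("excluding %d record(s) with invalid trap coordinates: %s",
                       int(bad.sum()), sorted(df.loc[bad, "trap_coordinate"].unique()))
        df = df[~bad]
    return df.reset_index(drop=True)


def write_captures(df: pd.DataFrame, path) -> None:
    """Write the standardized frame back to CSV (round-trips exactly)."""
    out = df.copy()
    if "collect_date" in out:
        out["collect_date"] = pd.to_datetime(out["collect_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="NA")


def parse_taxon(taxon) -> tuple[bool, frozenset[str]]:
    """Parse a field taxon string.

    Returns ``(is_peromyscus, candidate_epithets)``; the candidate set is
    empty for genus-only identifications ("Peromyscus sp.").  Ambiguity codes
    such as ``"Peromyscus leucopus/maniculatus"`` yield both epithets.
    """
    if not isinstance(taxon, str) or not taxon.strip():
        return False, frozenset()
    t = taxon.strip()
    if not t.lower().startswith("peromyscus"):
        return False, frozenset()
    rest = t[len("peromyscus"):].strip().rstrip(".")
    if not rest or rest.lower() in {"sp", "spp"}:
        return True, frozenset()
    eps = frozenset(e.strip().lower() for e in rest.split("/") if e.strip())
    return True, eps


def filter_taxa(df: pd.DataFrame) -> pd.DataFrame:
    """Keep Peromyscus records, dropping the monogamous species.

    Non-Peromyscus captures are dropped with a logged count.  Records
    field-identified (unambiguously) as *californicus*, *eremicus* or
    *polionotus* are removed; genus-only and cross-species ambiguity codes
    among the retained species are kept.
    """
    parsed = df["taxon"].map(parse_taxon)
    is_pero = np.array([p[0] for p in parsed], dtype=bool)
    mono = np.array([bool(p[1]) and p[1] <= MONOGAMOUS_SPECIES for p in parsed],
                    dtype=bool)
    n_other = int((~is_pero).sum())
    n_mono = int((is_pero & mono).sum())
    if n_other:
        logger.info("dropped %d non-Peromyscus record(s)", n_other)
    if n_mono:
        logger.info("removed %d record(s) of monogamous Peromyscus species", n_mono)
    return df[is_pero & ~mono].reset_index(drop=True)


def drop_untagged(df: pd.DataFrame) -> pd.DataFrame:
    """Drop records without an individual tag (logged count)."""
    miss = df["tag_id"].isna() | (df["tag_id"].astype(str).str.strip() == "")
    if miss.any():
        logger.info("dropped %d record(s) lacking a tag identifier", int(miss.sum()))
    return df[~miss].reset_index(drop=True)


def _inconsistent_pregnancy(sub: pd.DataFrame, max_gap_days: int) -> bool:
    """Detect day-to-day alternation pregnant -> nonpregnant -> pregnant."""
    s = sub.sort_values("collect_date")
    s = s[s["pregnancy_status"].isin(["pregnant", "nonpregnant"])]
    status = s["pregnancy_status"].to_numpy()
    dates = pd.to_datetime(s["collect_date"]).to_numpy()
    for i in range(len(status) - 2):
        if (status[i] == "pregnant" and status[i + 1] == "nonpregnant"
                and status[i + 2] == "pregnant"):
            span = (dates[i + 2] - dates[i]) / np.timedelta64(1, "D")
            if span <= 2 * max_gap_days:
                return True
    return False


def apply_outlier_rules(
    df: pd.DataFrame,
    mass_outlier_g: float = MASS_OUTLIER_G,
    hindfoot_outlier_mm: float = HINDFOOT_OUTLIER_MM,
    implausible_mass_g: float = IMPLAUSIBLE_ADULT_MASS_G,
    pregnancy_gap_days: int = 1,
) -> pd.DataFrame:
    """Apply the implausible-measurement rules.

    Masses above 50 g and hindfeet above 28 mm are unrealistic for these
    species: the values are set missing but the records kept, so they still
    inform home ranges while staying out of the body-condition regression.
    Individuals whose every recorded mass is below 10 g (implausibly light
    throughout) and individuals with day-to-day alternating pregnancy status
    are removed outright.  All removals are logged with counts.
    """
    df = df.copy()
    n_mass = int((df["mass_g"] > mass_outlier_g).sum())
    n_hf = int((df["hindfoot_mm"] > hindfoot_outlier_mm).sum())
    df.loc[df["mass_g"] > mass_outlier_g, "mass_g"] = np.nan
    df.loc[df["hindfoot_mm"] > hindfoot_outlier_mm, "hindfoot_mm"] = np.nan
    if n_mass or n_hf:
        logger.info("set missing: %d mass value(s) > %g g, %d hindfoot value(s) > %g mm",
                    n_mass, mass_outlier_g, n_hf, hindfoot_outlier_mm)

    drop_tags = set()
    for tag, sub in df.groupby("tag_id"):
        masses = sub["mass_g"].dropna()
        if len(masses) and (masses < implausible_mass_g).all():
            drop_tags.add(tag)
    if drop_tags:
        logger.info("removed %d individual(s) with only implausibly low (<%g g) masses",
                    len(drop_tags), implausible_mass_g)

    preg_tags = set()
    for tag, sub in df.groupby("tag_id"):
        if tag in drop_tags:
            continue
        if _inconsistent_pregnancy(sub, pregnancy_gap_days):
            preg_tags.add(tag)
    if preg_tags:
        logger.info("removed %d individual(s) with inconsistent pregnancy status",
                    len(preg_tags))

    bad = drop_tags | preg_tags
    return df[~df["tag_id"].isin(bad)].reset_index(drop=True)


def group_habitat(nlcd_class: str) -> str:
    """Map an NLCD vegetation class to forest / grassland / shrubland."""
    try:
        return NLCD_TO_HABITAT[nlcd_class]
    except KeyError:
        raise HabitatError(f"unmapped NLCD class: {nlcd_class!r}") from None


def add_habitat(df: pd.DataFrame) -> pd.DataFrame:
    """Append a ``habitat`` column; raises on any unmapped NLCD class."""
    unknown = sorted(set(df["nlcd_class"].dropna()) - set(NLCD_TO_HABITAT))
    if unknown:
        raise HabitatError(f"unmapped NLCD class(es): {unknown}")
    out = df.copy()
    out["habitat"] = df["nlcd_class"].map(NLCD_TO_HABITAT)
    return out
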