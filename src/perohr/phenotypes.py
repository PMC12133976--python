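"""Per-individual phenotypes: sex, size class, life stage and body condition.

Field records of small mammals are noisy: sex is occasionally misrecorded,
juveniles grow past the adult threshold mid-study, and mass is sometimes not
taken.  The rules here resolve each individual's phenotype from its full
capture history:

* **Sex** — majority vote over recorded sexes, with any pregnancy record
  overriding to female; strict ties (or no usable records) give "unknown".
* **Size class** — field species fall into typically-small (*maniculatus*
  sensu lato, *leucopus*) and typically-large (*keeni*, *truei*, *gossypinus*,
  *attwateri*, *boylii*) groups with different adult mass thresholds.
* **Life stage** — mass-threshold rule (16 g small / 19 g large, inclusive)
  with forward propagation: once an individual has been recorded at or above
  the adult threshold, all later captures are adult, covering missing masses
  and mass loss.
* **Body condition** — residual of mean mass on mean hindfoot length, fitted
  by OLS separately within each size class; pregnant and unknown-pregnancy
  captures are excluded from the means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SMALL_SPECIES = frozenset({"maniculatus", "leucopus"})
LARGE_SPECIES = frozenset({"keeni", "truei", "gossypinus", "attwateri", "boylii"})

ADULT_MASS_G = {"small": 16.0, "large": 19.0}


class ConditionError(ValueError):
    """Too few individuals for the body-condition regression."""


def assign_sex(sex_records, pregnancy_records) -> str:
    """Resolve one individual's sex from its capture records.

    Any pregnancy record forces "female" regardless of recorded sex; otherwise
    the sex noted on the strict majority of captures wins (missing and "U"
    entries do not vote).  A strict tie, or no usable votes, gives "unknown".
    """
    preg = [p for p in pregnancy_records if isinstance(p, str)]
    if any(p == "pregnant" for p in preg):
        return "female"
    votes = [s for s in sex_records if isinstance(s, str) and s in ("M", "F")]
    n_m = votes.count("M")
    n_f = votes.count("F")
    if n_m > n_f:
        return "male"
    if n_f > n_m:
        return "female"
    return "unknown"


def assign_size_class(taxa, fallback: str = "small") -> str:
    """Resolve "small" vs "large" from the field taxa across captures.

    Cross-class ambiguity codes (e.g. gossypinus/leucopus), genus-only
    identifications, and mixed evidence fall back to ``fallback`` (default
    "small": >80% of captures are of small species).
    """
    from .neon_io import parse_taxon

    classes = set()
    for t in taxa:
        is_pero, eps = parse_taxon(t) if isinstance(t, str) else (False, frozenset())
        if not is_pero or not eps:
            continue
        if eps <= SMALL_SPECIES:
            classes.add("small")
        elif eps <= LARGE_SPECIES:
            classes.add("large")
        else:  # spans both classes
            classes.add("mixed")
    if classes == {"small"}:
        return "small"
    if classes == {"large"}:
        return "large"
    if classes:
        logger.debug("ambiguous size-class evidence %s -> fallback %r", classes, fallback)
    return fallback


def assign_life_stage(masses, size_class: str) -> list[str]:
    """Per-capture life stage for one individual's date-ordered masses.

    A capture is adult iff its mass meets the class threshold (inclusive) or
    it occurs on/after the individual's earliest at-threshold capture; earlier
    captures with missing mass are subadult.
    """
    thr = ADULT_MASS_G[size_class]
    masses = np.asarray([np.nan if m is None else m for m in masses], dtype=float)
    adult_seen = False
    stages = []
    for m in masses:
        if not np.isnan(m) and m >= thr:
            adult_seen = True
        stages.append("adult" if adult_seen else "subadult")
    return stages


def add_life_stage(df: pd.DataFrame, size_classes: pd.Series) -> pd.DataFrame:
    """Append a ``life_stage`` column to a capture frame.

    ``size_classes`` maps tag_id -> "small"/"large".  Captures are processed
    in date order within each individual.
    """
    out = df.copy()
    out["life_stage"] = "subadult"
    for tag, sub in out.groupby("tag_id"):
        order = sub.sort_values("collect_date", kind="stable").index
        stages = assign_life_stage(out.loc[order, "mass_g"].to_numpy(),
                                   size_classes[tag])
        out.loc[order, "life_stage"] = stages
    return out


def build_profiles(df: pd.DataFrame, fallback_size_class: str = "small") -> pd.DataFrame:
    """Derive the per-individual profile table from cleaned captures.

    Means of mass and hindfoot are taken over **adult** captures excluding
    those with pregnancy status pregnant or unknown (the analysis population
    is adults, and pregnancy temporarily inflates mass).  The home plot is
    the plot with the most captures (ties broken by first use).
    """
    rows = []
    for tag, sub in df.groupby("tag_id"):
        sub = sub.sort_values("collect_date", kind="stable")
        sex = assign_sex(sub["sex"], sub["pregnancy_status"])
        size_class = assign_size_class(sub["taxon"], fallback=fallback_size_class)
        stages = assign_life_stage(sub["mass_g"].to_numpy(), size_class)
        sub = sub.assign(life_stage=stages)
        adult = sub[sub["life_stage"] == "adult"]
        nonpreg = adult[~adult["pregnancy_status"].isin(["pregnant", "unknown"])]
        plot_counts = sub.groupby("plot_id", sort=False).size()
        home_plot = plot_counts.idxmax()
        first_adult = adult["collect_date"].min() if len(adult) else pd.NaT
        rows.append({
            "tag_id": tag,
            "assigned_sex": sex,
            "size_class": size_class,
            "home_plot": home_plot,
            "site_id": sub["site_id"].iloc[0],
            "latitude": sub["latitude"].iloc[0],
            "nlcd_class": sub["nlcd_class"].iloc[0],
            "n_captures": len(sub),
            "n_adult_captures": int(len(adult)),
            "mean_mass": nonpreg["mass_g"].mean(),
            "mean_hindfoot": nonpreg["hindfoot_mm"].mean(),
            "first_adult_year": (first_adult.year if pd.notna(first_adult) else np.nan),
        })
    return pd.DataFrame(rows)


def compute_condition(profiles: pd.DataFrame, min_per_class: int = 3) -> pd.DataFrame:
    """Fill the ``condition`` column: OLS residual of mean mass on mean hindfoot.

    Regressions run separately within each size class; individuals lacking
    either mean get missing condition.  Fewer than ``min_per_class`` usable
    individuals in a class present in the data is an error — the regression
    is meaningless at that size.
    """
    out = profiles.copy()
    out["condition"] = np.nan
    for cls, sub in out.groupby("size_class"):
        ok = sub["mean_mass"].notna() & sub["mean_hindfoot"].notna()
        n = int(ok.sum())
        if n == 0:
            continue
        if n < min_per_class:
            raise ConditionError(
                f"only {n} individual(s) with both means in size class {cls!r}; "
                f"need >= {min_per_class} for the condition regression")
        x = sub.loc[ok, "mean_hindfoot"].to_numpy(float)
        y = sub.loc[ok, "mean_mass"].to_numpy(float)
        X = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        out.loc[sub.index[ok], "condition"] = y - X @ coef
    return out
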