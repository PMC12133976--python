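"""End-to-end orchestration: clean -> phenotype -> density -> home range -> model.

One :class:`RunConfig` drives the whole chain; every stage writes its CSV and
logs a records-in/records-out line, and a manifest captures the config hash
and library versions so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import density, glmm, neon_io, phenotypes, space_use

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the study's settings."""
    input_csv: str = ""
    output_dir: str = "results/run"
    column_map: dict | None = None
    mass_outlier_g: float = 50.0
    hindfoot_outlier_mm: float = 28.0
    adult_mass_small_g: float = 16.0
    adult_mass_large_g: float = 19.0
    min_captures: int = 5
    min_unique_locations: int = 3
    isopleth_level: float = 0.50
    cell_size_m: float = 1.0
    fallback_size_class: str = "small"
    standardize_predictors: bool = True
    fit_models: bool = True
    include_mcp: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_analysis_table(cleaned: pd.DataFrame, profiles: pd.DataFrame,
                         home_ranges: pd.DataFrame,
                         mean_mnka: pd.Series,
                         level: float = 0.50) -> pd.DataFrame:
    """Join per-individual pieces into the modelling table (complete cases).

    Rows are eligible animals of known sex with area, condition, habitat,
    latitude, density (meanMNKA) and a first-adult-capture year; individuals
    of unknown sex keep their home range but are excluded from the model.
    """
    area_col = f"area{int(round(level * 100))}_m2"
    hr = home_ranges.loc[home_ranges["eligible"],
                         ["tag_id", area_col, "n_captures"]]
    hr = hr.rename(columns={"n_captures": "n_relocations"})
    prof = profiles.copy()
    prof["density"] = prof["tag_id"].map(mean_mnka)
    prof["habitat"] = prof["nlcd_class"].map(neon_io.NLCD_TO_HABITAT)
    tab = hr.merge(prof, on="tag_id", how="inner")
    tab = tab.rename(columns={"assigned_sex": "sex", "first_adult_year": "year"})
    tab = tab[tab["sex"].isin(["male", "female"])]
    keep = ["tag_id", area_col, "sex", "condition", "habitat", "latitude",
            "density", "site_id", "year", "n_relocations"]
    tab = tab[keep]
    n0 = len(tab)
    tab = tab.dropna()
    if n0 - len(tab):
        logger.info("dropped %d incomplete row(s) from the analysis table",
                    n0 - len(tab))
    tab["year"] = tab["year"].astype(int)
    return tab.reset_index(drop=True)


def run_all(config: RunConfig) -> dict:
    """Run every stage, writing CSVs, a run log and a manifest to output_dir.

    Returns the results bundle: stage DataFrames, fitted models and paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    root = logging.getLogger("perohr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage_counts = {}
    bundle: dict = {"config": config, "output_dir": str(out)}
    try:
        raw = neon_io.read_captures(config.input_csv, config.column_map)
        stage_counts["read"] = len(raw)
        logger.info("read: %d records", len(raw))

        df = neon_io.filter_taxa(raw)
        df = neon_io.drop_untagged(df)
        df = neon_io.apply_outlier_rules(
            df, config.mass_outlier_g, config.hindfoot_outlier_mm)
        df = neon_io.add_habitat(df)
        df = neon_io.add_trap_xy(df)
        stage_counts["clean"] = len(df)
        logger.info("clean: %d -> %d records", len(raw), len(df))
        neon_io.write_captures(df.drop(columns=["habitat", "x", "y"]),
                               out / "cleaned_captures.csv")
        bundle["cleaned"] = df

        phenotypes.ADULT_MASS_G["small"] = config.adult_mass_small_g
        phenotypes.ADULT_MASS_G["large"] = config.adult_mass_large_g
        profiles = phenotypes.build_profiles(df, config.fallback_size_class)
        profiles = phenotypes.compute_condition(profiles)
        stage_counts["individuals"] = len(profiles)
        logger.info("phenotypes: %d individuals", len(profiles))
        bundle["profiles"] = profiles

        series = density.mnka(df)
        home_plots = profiles.set_index("tag_id")["home_plot"]
        mean_mnka = density.mean_mnka_per_individual(df, home_plots, series)
        series.to_csv(out / "mnka.csv", index=False)
        prof_out = profiles.copy()
        prof_out["mean_mnka"] = prof_out["tag_id"].map(mean_mnka)
        prof_out.to_csv(out / "phenotypes.csv", index=False)
        bundle["mnka"] = series
        bundle["mean_mnka"] = mean_mnka

        size_classes = profiles.set_index("tag_id")["size_class"]
        staged = phenotypes.add_life_stage(df, size_classes)
        adult = staged[(staged["life_stage"] == "adult") & staged["x"].notna()]
        stage_counts["adult_captures"] = len(adult)
        logger.info("home ranges: %d adult captures with positions", len(adult))
        hr = space_use.home_range_table(
            adult, levels=(config.isopleth_level,), cell=config.cell_size_m,
            min_captures=config.min_captures,
            min_unique=config.min_unique_locations,
            include_mcp=config.include_mcp)
        stage_counts["eligible"] = int(hr["eligible"].sum())
        logger.info("home ranges: %d of %d individuals eligible",
                    int(hr["eligible"].sum()), len(hr))
        hr.to_csv(out / "home_ranges.csv", index=False)
        bundle["home_ranges"] = hr

        tab = build_analysis_table(df, profiles, hr, mean_mnka,
                                   config.isopleth_level)
        stage_counts["analysis_rows"] = len(tab)
        tab.to_csv(out / "analysis_table.csv", index=False)
        bundle["analysis_table"] = tab

        if config.fit_models and len(tab) >= 50 \
                and tab["site_id"].nunique() >= 2 and tab["year"].nunique() >= 2:
            area_col = f"area{int(round(config.isopleth_level * 100))}_m2"
            fits = []
            for spec in glmm.build_model_set():
                fits.append(glmm.fit_glmm(
                    tab, spec, response=area_col,
                    standardize=config.standardize_predictors))
            comparison = glmm.aic_weights(fits)
            comparison.to_csv(out / "model_comparison.csv", index=False)
            best = max(fits, key=lambda f: -f.aic)
            anova = glmm.wald_anova(best)
            anova.to_csv(out / "deviance_table.csv", index=False)
            bundle.update(fits=fits, comparison=comparison, best_fit=best,
                          anova=anova)
            if "habitat" in best.term_slices:
                contrasts = glmm.habitat_contrasts(best)
                contrasts.to_csv(out / "habitat_contrasts.csv", index=False)
                bundle["contrasts"] = contrasts
            bundle["predictions"] = prediction_curves(best, tab)
            bundle["predictions"].to_csv(out / "prediction_curves.csv", index=False)
        elif config.fit_models:
            logger.warning("analysis table too small for model fitting "
                           "(%d rows); skipping models", len(tab))

        manifest = {
            "config_digest": config.digest(),
            "config": asdict(config),
            "stage_counts": stage_counts,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        bundle["manifest"] = manifest
        bundle["stage_counts"] = stage_counts
    finally:
        root.removeHandler(handler)
        handler.close()
    return bundle


def prediction_curves(fit, tab: pd.DataFrame, n_grid: int = 25) -> pd.DataFrame:
    """Density-response curves per habitat at low/mid/high latitude, plus a
    condition curve per sex, all within observed covariate ranges."""
    frames = []
    lat_pts = glmm.latitude_tertile_points(tab["latitude"].to_numpy())
    den = np.linspace(tab["density"].min(), tab["density"].max(), n_grid)
    for hab in sorted(tab["habitat"].unique()):
        for label, lat in lat_pts.items():
            nd = pd.DataFrame({
                "density": den, "latitude": lat, "habitat": hab,
                "sex": "female", "condition": tab["condition"].mean(),
            })
            pred = glmm.predict_response(fit, nd)
            pred.insert(0, "curve", f"density|habitat={hab},latitude={label}")
            frames.append(pred)
    cond = np.linspace(tab["condition"].min(), tab["condition"].max(), n_grid)
    for sex in ("female", "male"):
        nd = pd.DataFrame({
            "condition": cond, "sex": sex,
            "habitat": "forest", "latitude": tab["latitude"].mean(),
            "density": tab["density"].mean(),
        })
        pred = glmm.predict_response(fit, nd)
        pred.insert(0, "curve", f"condition|sex={sex}")
        frames.append(pred)
    return pd.concat(frames, ignore_index=True)


def report(bundle: dict) -> str:
    """Human-readable summary mirroring the analysis' results structure."""
    lines = ["Pipeline summary", "================"]
    counts = bundle.get("stage_counts", {})
    for k, v in counts.items():
        lines.append(f"{k:>16}: {v}")
    prof = bundle.get("profiles")
    if prof is not None:
        by_sex = prof["assigned_sex"].value_counts().to_dict()
        lines.append(f"individuals by sex: {by_sex}")
    hr = bundle.get("home_ranges")
    tab = bundle.get("analysis_table")
    if hr is not None and hr["eligible"].any():
        area_cols = [c for c in hr.columns if c.startswith("area")]
        a = hr.loc[hr["eligible"], area_cols[0]]
        lines.append(f"home-range area ({area_cols[0]}): mean {a.mean():.1f}, "
                     f"SD {a.std():.1f}, range {a.min():.1f}-{a.max():.1f} m^2")
    if tab is not None and len(tab):
        d = tab["density"]
        lines.append(f"meanMNKA: mean {d.mean():.2f}, SD {d.std():.2f}, "
                     f"range {d.min():.1f}-{d.max():.1f}")
    comp = bundle.get("comparison")
    if comp is not None:
        lines.append("model comparison (AIC):")
        for _, row in comp.iterrows():
            lines.append(f"  {row['model']:<22} AIC {row['aic']:10.1f}  "
                         f"dAIC {row['delta_aic']:8.1f}  w {row['weight']:.3f}")
    anova = bundle.get("anova")
    if anova is not None:
        lines.append("deviance table of the best model:")
        for _, row in anova.iterrows():
            lines.append(f"  {row['term']:<28} chisq {row['chisq']:9.3f}  "
                         f"df {int(row['df'])}  p {row['p_value']:.4g}")
    contrasts = bundle.get("contrasts")
    if contrasts is not None:
        letters = contrasts.attrs.get("letters", {})
        lines.append(f"habitat groups (shared letter = not distinguishable): {letters}")
    if "fits" not in bundle:
        lines.append("no model fitted")
    return "\n".join(lines)
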