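"""Synthetic NEON-dialect capture studies with known ground truth.

Every downstream stage — cleaning, phenotyping, MNKA, kernel home ranges, the
gamma mixed model — is exercised against data whose generating process is
known.  The generator mirrors the sampling design of the NEON small-mammal
protocol: sites spanning the study's latitude band, each with a handful of
1-ha 10x10 trap grids sampled in 4-6 short bouts per year (1-night "diversity"
or 3-night "pathogen" grids).  Individuals carry a circular-Gaussian
utilization distribution whose 50%-isopleth area is drawn from the same gamma
log-link linear predictor the analysis fits (sex, condition, habitat,
latitude, density, the sex x condition and habitat x latitude x density
interaction structure, plus site and year random intercepts).

Movement is i.i.d. draws from the utilization distribution — the kernel
estimator's own assumption — with each capture assigned to a trap by a
multinomial over the 100 trap positions weighted by the UD.  Field noise is
layered on top: juvenile growth across the adult mass threshold, pregnancy
episodes, occasional sex misrecordings, missing masses, and a sprinkle of
non-target and monogamous-species captures for the filters to remove.

Two entry points:

* :func:`simulate_analysis_table` — the model-level generator (covariates and
  gamma areas only), used for estimator-calibration checks.
* :func:`generate_study` — the full capture-record generator returning a
  NEON-dialect capture table plus a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .space_use import gaussian_area50, sigma_from_area50

#: Centering constants for the generator's linear predictor: effects are
#: defined at mid-latitude and typical density, so the intercept is the log
#: area of a reference animal (female, forest, average condition) there.
LATITUDE_CENTER = 37.6
DENSITY_CENTER = 22.0

#: Default true coefficients, keyed by design column names (centered basis,
#: log-m^2 scale).  Signs and magnitudes follow the field expectations the
#: analysis is built to detect: males larger; condition raising male but
#: lowering female areas; forest smallest and grassland largest; areas growing
#: with latitude and shrinking with density; and a three-way structure in
#: which the density decline steepens at high latitude in grasslands but at
#: low latitude in forests, while shrubland areas are larger at low latitude.
DEFAULT_COEFFICIENTS = {
    "(Intercept)": float(np.log(1200.0)),
    "sex[male]": 0.25,
    "condition": -0.05,
    "habitat[grassland]": 0.35,
    "habitat[shrubland]": 0.18,
    "latitude": 0.020,
    "density": -0.015,
    "sex[male]:condition": 0.10,
    "habitat[grassland]:latitude": -0.010,
    "habitat[shrubland]:latitude": -0.030,
    "latitude:density": 0.0004,
    "habitat[grassland]:density": 0.002,
    "habitat[shrubland]:density": 0.005,
    "habitat[grassland]:latitude:density": -0.0012,
    "habitat[shrubland]:latitude:density": -0.0004,
}

SPECIES_MIX = {
    "Peromyscus leucopus": 0.415,
    "Peromyscus maniculatus": 0.36,
    "Peromyscus gossypinus": 0.10,
    "Peromyscus boylii": 0.045,
    "Peromyscus truei": 0.025,
    "Peromyscus keeni": 0.012,
    "Peromyscus attwateri": 0.001,
    "Peromyscus leucopus/maniculatus": 0.022,
    "Peromyscus gossypinus/leucopus": 0.005,
    "Peromyscus sp.": 0.015,
}

LARGE_EPITHETS = {"gossypinus", "boylii", "truei", "keeni", "attwateri"}

NLCD_BY_HABITAT = {
    "forest": ["deciduousForest", "mixedForest", "evergreenForest", "woodyWetlands"],
    "grassland": ["grasslandHerbaceous", "cultivatedCrops", "pastureHay"],
    "shrubland": ["shrubScrub"],
}

OTHER_GENUS_SPECIES = ["Microtus pennsylvanicus", "Tamias striatus",
                       "Blarina brevicauda", "Zapus hudsonius"]

TRAPS = np.array([(10.0 * c, 10.0 * r) for r in range(10) for c in range(10)])
TRAP_NAMES = [f"{chr(ord('A') + r)}{c + 1}" for r in range(10) for c in range(10)]


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Defaults are the package's reference study conditions: 8 sites of 3 plots
    across the 28-47.2 degree latitude band, two years of five bouts, sized to
    yield roughly 400-500 home-range-eligible animals with plot densities in
    the observed MNKA range.
    """
    n_sites: int = 8
    plots_per_site: int = 3
    years: int = 3
    start_year: int = 2019
    bouts_per_year: int = 5
    pathogen_nights: int = 3
    diversity_plot_fraction: float = 0.25
    latitude_range: tuple[float, float] = (28.0, 47.2)
    habitat_probs: dict = field(default_factory=lambda: {
        "forest": 0.60, "grassland": 0.25, "shrubland": 0.15})
    mean_abundance: float = 20.0
    abundance_shape: float = 4.0
    p_capture: float = 0.45
    min_residency_bouts: int = 3
    male_fraction: float = 0.525
    condition_sd: float = 1.3
    juvenile_fraction: float = 0.20
    pregnancy_episode_rate: float = 0.30
    unknown_pregnancy_rate: float = 0.05
    sex_misrecord_rate: float = 0.02
    sex_unknown_rate: float = 0.01
    missing_mass_rate: float = 0.08
    missing_hindfoot_rate: float = 0.05
    other_genus_rate: float = 0.04
    monogamous_rate: float = 0.003
    center_pad_m: float = 20.0
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    sigma_site: float = 0.30
    sigma_year: float = 0.15
    gamma_shape: float = 2.0

    def __post_init__(self):
        for name in ("p_capture", "male_fraction", "juvenile_fraction",
                     "pregnancy_episode_rate", "unknown_pregnancy_rate",
                     "sex_misrecord_rate", "sex_unknown_rate",
                     "missing_mass_rate", "missing_hindfoot_rate",
                     "other_genus_rate", "monogamous_rate",
                     "diversity_plot_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_sites < 1 or self.plots_per_site < 1 or self.years < 1:
            raise ValueError("study design must have >= 1 site, plot and year")
        if not 4 <= self.bouts_per_year <= 6:
            raise ValueError("bouts_per_year must be 4-6")

    def to_dict(self) -> dict:
        return asdict(self)


def _linear_predictor(coefficients: dict, sex_male, condition, habitat,
                      lat_c, den_c) -> np.ndarray:
    """Evaluate the generator's fixed-effect predictor on centered covariates."""
    g = (habitat == "grassland").astype(float)
    s = (habitat == "shrubland").astype(float)
    base = {
        "(Intercept)": 1.0,
        "sex[male]": sex_male,
        "condition": condition,
        "habitat[grassland]": g,
        "habitat[shrubland]": s,
        "latitude": lat_c,
        "density": den_c,
    }
    eta = np.zeros(np.broadcast(sex_male, lat_c).shape or (1,), dtype=float)
    for name, coef in coefficients.items():
        v = np.ones_like(eta)
        for part in name.split(":"):
            v = v * np.asarray(base[part], dtype=float)
        eta = eta + coef * v
    return eta


def simulate_analysis_table(
    n: int = 2000,
    n_sites: int = 30,
    n_years: int = 10,
    coefficients: dict | None = None,
    sigma_site: float = 0.30,
    sigma_year: float = 0.15,
    shape: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Model-level draw: covariates plus gamma areas, no capture process.

    Continuous covariates are emitted already centered (latitude about the
    mid-study latitude, density about typical MNKA), so an unstandardized fit
    of the full model estimates exactly the returned truth coefficients.
    Returns ``(table, truth)`` where truth maps design column names to the
    generating values.
    """
    rng = np.random.default_rng(rng)
    coefficients = dict(DEFAULT_COEFFICIENTS if coefficients is None else coefficients)
    site_lat = rng.uniform(28.0, 47.2, n_sites) - LATITUDE_CENTER
    site_eff = rng.normal(0.0, sigma_site, n_sites)
    year_eff = rng.normal(0.0, sigma_year, n_years)
    site = rng.integers(0, n_sites, n)
    year = rng.integers(0, n_years, n)
    sex_male = rng.binomial(1, 0.525, n).astype(float)
    condition = rng.normal(0.0, 1.3, n)
    habitat = rng.choice(np.array(["forest", "grassland", "shrubland"]),
                         size=n, p=[0.60, 0.25, 0.15])
    # plot-level latitude jitter around the site's latitude
    lat_c = site_lat[site] + rng.normal(0.0, 0.05, n)
    den_c = np.clip(rng.gamma(2.7, 8.0, n), 1.4, 80.0) - DENSITY_CENTER
    eta = _linear_predictor(coefficients, sex_male, condition, habitat, lat_c, den_c)
    eta = eta + site_eff[site] + year_eff[year]
    area = rng.gamma(shape, np.exp(eta) / shape)
    df = pd.DataFrame({
        "area50_m2": area,
        "sex": np.where(sex_male > 0, "male", "female"),
        "condition": condition,
        "habitat": habitat,
        "latitude": lat_c,
        "density": den_c,
        "site_id": [f"S{i:02d}" for i in site],
        "year": 2013 + year,
    })
    truth = dict(coefficients)
    truth.update({"sigma_site": sigma_site, "sigma_year": sigma_year,
                  "shape": shape})
    return df, truth


def simulate_relocations(n_individuals: int = 20,
                         n_captures: int = 10,
                         area_log_mean: float = float(np.log(1200.0)),
                         area_log_sd: float = 0.6,
                         rng: np.random.Generator | int | None = None,
                         ) -> dict[str, np.ndarray]:
    """Trap-grid relocation sets for Gaussian movers (no field noise).

    Each individual gets a circular-Gaussian utilization with a lognormal
    50%-isopleth area and a center on the 1-ha grid; every relocation is a
    multinomial draw over the 100 trap positions weighted by the UD.  Useful
    for estimator-only studies such as rarefaction.
    """
    rng = np.random.default_rng(rng)
    out = {}
    made = 0
    while made < n_individuals:
        area = float(np.exp(rng.normal(area_log_mean, area_log_sd)))
        sigma = sigma_from_area50(area)
        center = rng.uniform(10.0, 80.0, 2)
        w = np.exp(-((TRAPS - center) ** 2).sum(axis=1) / (2.0 * sigma ** 2))
        w = w / w.sum()
        pts = TRAPS[rng.choice(100, size=n_captures, p=w)]
        if len(np.unique(pts, axis=0)) < 3:
            continue
        out[f"m{made:03d}"] = pts
        made += 1
    return out


def _bout_schedule(rng, year: int, bouts: int, nights: int) -> list[pd.Timestamp]:
    """Trap-night dates: ``bouts`` sessions of ``nights`` consecutive days,
    spread over the field season (roughly April-October)."""
    starts = np.sort(rng.choice(np.arange(95, 290, 7), size=bouts, replace=False))
    dates = []
    for s in starts:
        for k in range(nights):
            dates.append(pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=int(s + k)))
    return dates


def generate_study(config: SimConfig | None = None,
                   seed: int | np.random.Generator = 0,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one full synthetic study.

    Returns ``(captures, truth)``: a NEON-dialect capture table (one row per
    trap-night capture, NEON column names) and a per-individual truth table
    with the generating center, sigma, area, covariates and realized random
    effects.  Identical config and seed give byte-identical tables.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    species_names = list(SPECIES_MIX)
    species_p = np.array(list(SPECIES_MIX.values()))
    species_p = species_p / species_p.sum()
    habitat_names = list(cfg.habitat_probs)
    habitat_p = np.array(list(cfg.habitat_probs.values()), float)
    habitat_p /= habitat_p.sum()

    lo, hi = cfg.latitude_range
    site_ids = [f"S{i:02d}" for i in range(cfg.n_sites)]
    site_lat = np.round(rng.uniform(lo, hi, cfg.n_sites), 4)
    site_eff = rng.normal(0.0, cfg.sigma_site, cfg.n_sites)
    years = list(range(cfg.start_year, cfg.start_year + cfg.years))
    year_eff = rng.normal(0.0, cfg.sigma_year, cfg.years)

    plots = []
    for si, sid in enumerate(site_ids):
        for j in range(cfg.plots_per_site):
            hab = habitat_names[rng.choice(len(habitat_names), p=habitat_p)]
            nlcd = NLCD_BY_HABITAT[hab][rng.integers(len(NLCD_BY_HABITAT[hab]))]
            nights = (1 if rng.random() < cfg.diversity_plot_fraction
                      else cfg.pathogen_nights)
            plots.append(dict(site_idx=si, plot_id=f"{sid}_P{j + 1}", habitat=hab,
                              nlcd=nlcd, nights=nights))

    cap_rows: list[dict] = []
    truth_rows: list[dict] = []

    def record_capture(plot, date, tag, taxon, sex_rec, preg, mass, hindfoot,
                       trap_name, stage):
        cap_rows.append({
            "siteID": site_ids[plot["site_idx"]],
            "plotID": plot["plot_id"],
            "trapCoordinate": trap_name,
            "collectDate": date.strftime("%Y-%m-%d"),
            "tagID": tag,
            "taxonID": taxon,
            "sex": sex_rec,
            "pregnancyStatus": preg,
            "lifeStage": stage,
            "weight": mass,
            "hindfootLength": hindfoot,
            "nlcdClass": plot["nlcd"],
            "decimalLatitude": site_lat[plot["site_idx"]],
        })

    for plot in plots:
        si = plot["site_idx"]
        for yi, year in enumerate(years):
            bouts = _bout_schedule(rng, year, cfg.bouts_per_year, plot["nights"])
            bout_groups = [bouts[k * plot["nights"]:(k + 1) * plot["nights"]]
                           for k in range(cfg.bouts_per_year)]
            lam = rng.gamma(cfg.abundance_shape,
                            cfg.mean_abundance / cfg.abundance_shape)
            n_ind = int(rng.poisson(lam))
            den_c = n_ind - DENSITY_CENTER
            lat_c = site_lat[si] - LATITUDE_CENTER
            for idx in range(n_ind):
                tag = f"{plot['plot_id']}_{year}_{idx:03d}"
                taxon = species_names[rng.choice(len(species_names), p=species_p)]
                eps = taxon.removeprefix("Peromyscus").strip().rstrip(".")
                large = (bool(eps) and eps not in ("sp", "spp")
                         and all(e in LARGE_EPITHETS for e in eps.split("/")))
                thr = 19.0 if large else 16.0
                male = rng.random() < cfg.male_fraction
                condition = rng.normal(0.0, cfg.condition_sd)
                eta = float(np.ravel(_linear_predictor(
                    cfg.coefficients, np.array(float(male)), np.array(condition),
                    np.array(plot["habitat"]), np.array(lat_c),
                    np.array(float(den_c))))[0])
                eta += site_eff[si] + year_eff[yi]
                area = float(rng.gamma(cfg.gamma_shape, np.exp(eta) / cfg.gamma_shape))
                sigma = sigma_from_area50(area)
                center = rng.uniform(-cfg.center_pad_m, 90.0 + cfg.center_pad_m, 2)

                hf_mean, hf_sd = (22.0, 0.9) if large else (19.5, 0.8)
                a0, b0 = (-18.0, 2.0) if large else (-15.0, 1.8)
                hindfoot = rng.normal(hf_mean, hf_sd)
                adult_mass = a0 + b0 * hindfoot + condition + rng.normal(0.0, 0.3)
                adult_mass = max(adult_mass, thr + 0.5)

                juvenile = rng.random() < cfg.juvenile_fraction
                min_res = min(cfg.min_residency_bouts, cfg.bouts_per_year)
                start_bout = int(rng.integers(0, cfg.bouts_per_year - min_res + 1))
                length = int(rng.integers(min_res,
                                          cfg.bouts_per_year - start_bout + 1))
                window = [d for g in bout_groups[start_bout:start_bout + length]
                          for d in g]
                birth_mass = rng.uniform(9.0, thr - 1.0) if juvenile else adult_mass
                growth = rng.uniform(0.15, 0.35)  # g per day

                w = np.exp(-((TRAPS - center) ** 2).sum(axis=1) / (2.0 * sigma ** 2))
                if w.sum() <= 0:
                    continue
                w = w / w.sum()
                cap_dates = [d for d in window if rng.random() < cfg.p_capture]
                # pregnancy episode: a contiguous date span for adult females
                ep_span = (None, None)
                if (not male) and cap_dates and rng.random() < cfg.pregnancy_episode_rate:
                    e0 = cap_dates[rng.integers(len(cap_dates))]
                    ep_span = (e0, e0 + pd.Timedelta(days=21))
                for d in cap_dates:
                    days = (d - window[0]).days
                    mass_now = (min(adult_mass, birth_mass + growth * days)
                                if juvenile else adult_mass)
                    stage = "adult" if mass_now >= thr else "subadult"
                    preg = np.nan
                    if not male:
                        if (ep_span[0] is not None and ep_span[0] <= d <= ep_span[1]
                                and mass_now >= thr):
                            preg = "pregnant"
                            mass_now += 3.0
                        elif rng.random() < cfg.unknown_pregnancy_rate:
                            preg = "unknown"
                        else:
                            preg = "nonpregnant"
                    true_letter = "M" if male else "F"
                    if rng.random() < cfg.sex_unknown_rate:
                        sex_rec = "U"
                    elif rng.random() < cfg.sex_misrecord_rate:
                        sex_rec = "F" if male else "M"
                    else:
                        sex_rec = true_letter
                    mass_rec = (np.nan if rng.random() < cfg.missing_mass_rate
                                else round(mass_now + rng.normal(0.0, 0.3), 1))
                    hf_rec = (np.nan if rng.random() < cfg.missing_hindfoot_rate
                              else round(hindfoot + rng.normal(0.0, 0.2), 1))
                    trap_idx = int(rng.choice(100, p=w))
                    record_capture(plot, d, tag, taxon, sex_rec, preg, mass_rec,
                                   hf_rec, TRAP_NAMES[trap_idx], stage)
                truth_rows.append({
                    "tag_id": tag, "site_id": site_ids[si], "plot_id": plot["plot_id"],
                    "year": year, "true_x": center[0], "true_y": center[1],
                    "true_sigma": sigma, "true_area50_m2": area,
                    "sex": "male" if male else "female", "condition": condition,
                    "size_class": "large" if large else "small",
                    "habitat": plot["habitat"], "latitude": site_lat[si],
                    "density": n_ind, "site_effect": site_eff[si],
                    "year_effect": year_eff[yi], "gamma_shape": cfg.gamma_shape,
                    "n_captures": len(cap_dates), "juvenile_start": juvenile,
                })
            # bycatch: non-target genera and rare monogamous Peromyscus
            n_other = rng.poisson(cfg.other_genus_rate * max(n_ind, 1))
            n_mono = rng.poisson(cfg.monogamous_rate * max(n_ind, 1))
            for k in range(n_other + n_mono):
                taxon = ("Peromyscus californicus" if k >= n_other else
                         OTHER_GENUS_SPECIES[rng.integers(len(OTHER_GENUS_SPECIES))])
                tag = f"{plot['plot_id']}_{year}_X{k:02d}"
                for d in bouts:
                    if rng.random() < cfg.p_capture * 0.5:
                        record_capture(
                            plot, d, tag, taxon,
                            "M" if rng.random() < 0.5 else "F", np.nan,
                            round(rng.uniform(15.0, 45.0), 1),
                            round(rng.uniform(17.0, 26.0), 1),
                            TRAP_NAMES[int(rng.integers(100))], "adult")

    captures = pd.DataFrame(cap_rows)
    if len(captures):
        captures = captures.sort_values(
            ["plotID", "collectDate", "tagID"], kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return captures, truth


def write_study(captures: pd.DataFrame, truth: pd.DataFrame,
                captures_path, truth_path) -> None:
    captures.to_csv(captures_path, index=False, na_rep="NA")
    truth.to_csv(truth_path, index=False, na_rep="NA")


def recovery_report(truth: pd.DataFrame,
                    home_ranges: pd.DataFrame | None = None,
                    profiles: pd.DataFrame | None = None,
                    fit=None,
                    true_coefficients: dict | None = None,
                    ) -> tuple[dict, pd.DataFrame | None]:
    """Compare pipeline outputs against the generating truth.

    Returns ``(metrics, coef_table)``: summary metrics (area relative errors,
    sex-assignment confusion) and, when a fitted model and true coefficients
    are supplied, a per-coefficient table of bias, 95% Wald coverage and sign
    agreement.
    """
    metrics: dict = {}
    if home_ranges is not None:
        m = home_ranges[home_ranges["eligible"]].merge(
            truth[["tag_id", "true_area50_m2"]], on="tag_id")
        rel = (m["area50_m2"] - m["true_area50_m2"]) / m["true_area50_m2"]
        metrics["n_eligible_matched"] = int(len(m))
        metrics["area_median_rel_err"] = float(rel.median())
        metrics["area_median_abs_rel_err"] = float(rel.abs().median())
    if profiles is not None:
        m = profiles.merge(truth[["tag_id", "sex"]], on="tag_id",
                           suffixes=("_assigned", "_true"))
        known = m[m["assigned_sex"] != "unknown"]
        metrics["n_sex_assigned"] = int(len(known))
        metrics["sex_accuracy"] = float(
            (known["assigned_sex"] == known["sex"]).mean()) if len(known) else np.nan
    coef_table = None
    if fit is not None and true_coefficients is not None:
        ci = fit.wald_ci()
        rows = []
        for name, true_val in true_coefficients.items():
            if name not in ci.index:
                continue
            est, se, lo, hi = ci.loc[name]
            rows.append({
                "coefficient": name, "true": true_val, "estimate": est,
                "bias": est - true_val, "covered": bool(lo <= true_val <= hi),
                "sign_agrees": bool(np.sign(est) == np.sign(true_val))
                if true_val != 0 else np.nan,
            })
        coef_table = pd.DataFrame(rows)
    return metrics, coef_table
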