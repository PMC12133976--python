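import numpy as np
import pandas as pd
import pytest

from perohr import pipeline
from perohr.synthetic import SimConfig, generate_study, write_study


def make_captures(rows, **overrides):
    """Build a standardized capture frame from compact row tuples:
    (tag, date, trap, sex, pregnancy, mass, hindfoot)."""
    recs = []
    for tag, date, trap, sex, preg, mass, hf in rows:
        recs.append({
            "site_id": overrides.get("site_id", "S00"),
            "plot_id": overrides.get("plot_id", "S00_P1"),
            "trap_coordinate": trap,
            "collect_date": pd.Timestamp(date),
            "tag_id": tag,
            "taxon": overrides.get("taxon", "Peromyscus leucopus"),
            "sex": sex,
            "pregnancy_status": preg,
            "life_stage_raw": np.nan,
            "mass_g": mass,
            "hindfoot_mm": hf,
            "nlcd_class": overrides.get("nlcd_class", "deciduousForest"),
            "latitude": overrides.get("latitude", 38.0),
        })
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared across tests."""
    captures, truth = generate_study(SimConfig(), seed=0)
    return captures, truth


@pytest.fixture(scope="session")
def study_run(default_study, tmp_path_factory):
    """Full pipeline run on the default synthetic study."""
    captures, truth = default_study
    d = tmp_path_factory.mktemp("study")
    write_study(captures, truth, d / "captures.csv", d / "truth.csv")
    cfg = pipeline.RunConfig(input_csv=str(d / "captures.csv"),
                             output_dir=str(d / "run"))
    bundle = pipeline.run_all(cfg)
    bundle["truth"] = truth
    bundle["captures_csv"] = str(d / "captures.csv")
    return bundle
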