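"""Clean the raw capture table.

Reads results/synthetic/captures.csv (NEON dialect), applies the taxon
filters (Peromyscus only, monogamous species removed), drops untagged
records, applies the implausible-measurement rules, and attaches macrohabitat
and metric trap positions.  Writes results/cleaned_captures.csv and prints
the records-in/records-out accounting.
"""

import argparse
import logging
from pathlib import Path

from perohr import neon_io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")

    res = Path(args.results)
    raw = neon_io.read_captures(res / "synthetic" / "captures.csv")
    print(f"read {len(raw)} records")
    df = neon_io.filter_taxa(raw)
    print(f"after taxon filters: {len(df)} ({len(raw) - len(df)} removed)")
    df = neon_io.drop_untagged(df)
    df = neon_io.apply_outlier_rules(df)
    print(f"after outlier rules: {len(df)}")
    df = neon_io.add_habitat(df)
    neon_io.write_captures(df.drop(columns=["habitat"]),
                           res / "cleaned_captures.csv")
    print(f"habitat mix: {df['habitat'].value_counts().to_dict()}")
    print(f"wrote {res/'cleaned_captures.csv'}")


if __name__ == "__main__":
    main()
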