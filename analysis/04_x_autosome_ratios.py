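#!/usr/bin/env python
"""X:Autosome expression ratios across cohorts.

Computes per-sample X:Autosome mean-intensity ratios for the bulk cohort
and the pure neuron/microglia cohorts, then runs the pairwise pooled
Student t-tests (neurons vs whole tissue, whole tissue vs microglia).

Writes results/ratios/ratios.tsv and comparisons.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

import chromowave as cw

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    data = ROOT / "scratch" / "synthetic_studies"
    out = ROOT / "results" / "ratios"
    out.mkdir(parents=True, exist_ok=True)

    tables = {}
    for name in ("cohort", "neurons", "microglia"):
        study = cw.median_normalize(cw.read_study(data / name))
        tables[name] = cw.x_autosome_ratio(study)
        mean = tables[name]["x_autosome_ratio"].mean()
        sd = tables[name]["x_autosome_ratio"].std()
        print(f"{name}: mean X:Autosome ratio {mean:.3f} +/- {sd:.3f} "
              f"(n={len(tables[name])})")
    pd.concat(tables, names=["cohort"]).to_csv(out / "ratios.tsv", sep="\t")

    rows = []
    for a, b in (("neurons", "cohort"), ("cohort", "microglia")):
        t = cw.compare_ratio_groups(tables[a], tables[b])
        rows.append((a, b, t.group_means[0], t.group_means[1], t.t, t.df, t.p))
        print(f"{a} vs {b}: t = {t.t:.2f}, df = {t.df}, p = {t.p:.1e}")
    pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_a", "mean_b", "t", "df", "p"]
    ).to_csv(out / "comparisons.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
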