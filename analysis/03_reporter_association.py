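#!/usr/bin/env python
"""Associate the chromosome X case loadings with cell-type reporter genes.

Builds neuronal and astrocytic reporter patterns (first SVD component of
each >20-fold reporter gene set), correlates them with the X-pattern case
loadings, tests the disease/control loading difference (all subjects and
male-only), and asks by forward stepwise regression whether the astrocytic
pattern adds information beyond the neuronal one.

Writes results/association/associations.tsv and prints the statistics.
"""

import argparse
from pathlib import Path

import pandas as pd

import chromowave as cw

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    data = ROOT / "scratch" / "synthetic_studies" / "cohort"
    out = ROOT / "results" / "association"
    out.mkdir(parents=True, exist_ok=True)

    study = cw.median_normalize(cw.read_study(data))
    loadings = (
        pd.read_csv(ROOT / "results" / "x_pattern" / "loadings.tsv", sep="\t")
        .set_index("sample_id")
        .loc[study.matrix.columns, "loading"]
        .to_numpy()
    )
    reference = pd.read_csv(data / "reporter_reference.tsv", sep="\t")

    rows, patterns = [], {}
    for cell_type in ("neuron", "astrocyte"):
        rset = cw.select_reporters(reference, study, cell_type)
        patterns[cell_type] = cw.reporter_pattern(study, rset)
        assoc = cw.correlate_loadings(loadings, patterns[cell_type])
        rows.append((cell_type, len(rset.probes), assoc.r, assoc.p, assoc.n))
        print(f"{cell_type} reporters ({len(rset.probes)} probes): "
              f"r = {assoc.r:.3f}, p = {assoc.p:.2e}")
    pd.DataFrame(
        rows, columns=["cell_type", "n_probes", "r", "p", "n"]
    ).to_csv(out / "associations.tsv", sep="\t", index=False)

    truth = cw.correlate_loadings(loadings, study.samples["frac_neuron"].to_numpy())
    print(f"loadings vs true neuron fraction: r = {truth.r:.3f}")

    for sex_filter in ("none", "male_only"):
        t = cw.compare_loading_groups(loadings, study.samples, sex_filter=sex_filter)
        print(f"disease vs control loadings ({sex_filter}): "
              f"t = {t.t:.2f}, df = {t.df}, p = {t.p:.2e}")

    sw = cw.stepwise_add(loadings, patterns["neuron"], patterns["astrocyte"])
    verdict = "adds" if sw.added_is_significant else "does not add"
    print(f"stepwise: astrocytic pattern {verdict} information beyond neuronal "
          f"(partial F = {sw.partial_F:.2f}, p = {sw.partial_p:.3f})")


if __name__ == "__main__":
    main()
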