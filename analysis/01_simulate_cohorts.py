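#!/usr/bin/env python
"""Simulate the study's cohorts: a two-group bulk brain cohort plus
pure-cell-type cohorts (laser-dissected-neuron and cultured-microglia
analogues), all from one shared probe annotation and one set of cell-type
profiles.

Writes results/data/{cohort,neurons,microglia}/ as TSV studies plus the
reporter reference table.  Downstream scripts (02-04) read these.
"""

import argparse
from pathlib import Path

import chromowave as cw

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    out = ROOT / "scratch" / "synthetic_studies"

    ann = cw.generate_annotation(6000, 600, escape_fraction=0.15, seed=args.seed)
    profiles = cw.generate_cell_profiles(ann, x_factor_neuron=1.3, seed=args.seed + 1)

    cohort = cw.generate_cohort(cw.CohortDesign(seed=args.seed + 2), profiles, ann)
    cw.write_study(cohort, out / "cohort")
    profiles.reference.to_csv(
        out / "cohort" / "reporter_reference.tsv", sep="\t", index=False
    )

    neurons = cw.generate_pure_cohort(
        "neuron", 8, profiles, ann, noise_sd_log2=0.25, seed=args.seed + 3
    )
    cw.write_study(neurons, out / "neurons")

    microglia = cw.generate_pure_cohort(
        "microglia", 4, profiles, ann, noise_sd_log2=0.25, seed=args.seed + 4
    )
    cw.write_study(microglia, out / "microglia")

    print(f"cohort: {cohort.n_probes} probes x {cohort.n_samples} samples "
          f"(mean neuron fraction: control "
          f"{cohort.samples.loc[cohort.samples.group == 'control', 'frac_neuron'].mean():.2f}, "
          f"disease "
          f"{cohort.samples.loc[cohort.samples.group == 'disease', 'frac_neuron'].mean():.2f})")
    print(f"pure cohorts: {neurons.n_samples} neuron, {microglia.n_samples} microglia")
    print(f"written under {out}")


if __name__ == "__main__":
    main()
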