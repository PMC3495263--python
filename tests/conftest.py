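"""Shared fixtures: small synthetic studies and the 10-seed default cohort run.

The default-cohort pipeline (12 controls + 12 disease, 6000 autosomal +
600 X probes, neuronal X factor 1.3, log2 noise sd 0.25) is expensive
enough to compute once per session; several recovery tests read from the
same run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import chromowave as cw

N_SEEDS = 10
DEFAULT_N_AUTOSOMAL = 6000
DEFAULT_N_X = 600


@dataclass
class PipelineRun:
    """Everything the recovery tests need from one seeded cohort run."""

    seed: int
    study: cw.ExpressionStudy
    result: cw.PatternResult
    is_escape: np.ndarray  # aligned with the X slice's probe order
    neuronal_loadings: np.ndarray
    astro_loadings: np.ndarray
    r_neuronal: float
    r_astro: float
    r_true_fraction: float


def run_default_pipeline(seed: int, independent_astrocyte: bool = False) -> PipelineRun:
    ann = cw.generate_annotation(DEFAULT_N_AUTOSOMAL, DEFAULT_N_X, 0.15, seed=seed)
    profiles = cw.generate_cell_profiles(ann, x_factor_neuron=1.3, seed=seed + 10_000)
    design = cw.CohortDesign(
        seed=seed + 20_000, independent_astrocyte=independent_astrocyte
    )
    study = cw.generate_cohort(design, profiles, ann)
    norm = cw.median_normalize(study)
    x_slice = cw.chromosome_slice(norm, "X")
    result = cw.extract_pattern(x_slice)

    neuronal = cw.reporter_pattern(
        norm, cw.select_reporters(profiles.reference, norm, "neuron")
    )
    astro = cw.reporter_pattern(
        norm, cw.select_reporters(profiles.reference, norm, "astrocyte")
    )
    truth = study.samples["frac_neuron"].to_numpy()
    return PipelineRun(
        seed=seed,
        study=study,
        result=result,
        is_escape=ann.loc[x_slice.probe_ids, "is_escape"].to_numpy(),
        neuronal_loadings=neuronal,
        astro_loadings=astro,
        r_neuronal=cw.correlate_loadings(result.case_loadings, neuronal).r,
        r_astro=cw.correlate_loadings(result.case_loadings, astro).r,
        r_true_fraction=cw.correlate_loadings(result.case_loadings, truth).r,
    )


@pytest.fixture(scope="session")
def default_runs() -> list[PipelineRun]:
    """The default synthetic cohort pipeline over 10 seeds."""
    return [run_default_pipeline(seed) for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def independent_astro_runs() -> list[PipelineRun]:
    """Same pipeline with astrocyte fraction independent of neuron fraction."""
    return [
        run_default_pipeline(seed, independent_astrocyte=True)
        for seed in range(N_SEEDS)
    ]


# -- small fixtures ---------------------------------------------------------


@pytest.fixture
def small_annotation() -> pd.DataFrame:
    return cw.generate_annotation(100, 50, escape_fraction=0.15, seed=1)


@pytest.fixture
def small_profiles(small_annotation) -> cw.CellProfiles:
    return cw.generate_cell_profiles(
        small_annotation,
        x_factor_neuron=1.3,
        reporter_config={"neuron": (8, 25.0), "astrocyte": (8, 25.0)},
        seed=2,
    )


@pytest.fixture
def small_study(small_annotation, small_profiles) -> cw.ExpressionStudy:
    design = cw.CohortDesign(n_control=5, n_disease=5, noise_sd_log2=0.2, seed=3)
    return cw.generate_cohort(design, small_profiles, small_annotation)
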