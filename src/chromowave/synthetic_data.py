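"""Synthetic bulk brain-tissue expression cohorts.

Bulk brain samples are modelled as mixtures of three cell types (neurons,
astrocytes, microglia).  Each cell type has its own positive linear
expression profile; neurons additionally up-regulate chromosome X by a
multiplicative factor, except for a contiguous escape zone at the telomeric
Xp end which stays at baseline (mirroring genes that escape
X-inactivation).  A set of autosomal "reporter" genes is strongly
(>20-fold) enriched in one cell type and proxies its abundance in bulk
tissue.  Disease cohorts differ from controls by a lower mean neuronal
fraction — the composition shift that confounds case/control expression
studies and that the downstream pattern extraction is meant to recover.

Observed intensities are the fraction-weighted mixture of the cell-type
profiles with multiplicative log-normal measurement noise:

    intensity[g, i] = (sum_c fraction[i, c] * profile[c, g]) * 2**eps,
    eps ~ Normal(0, noise_sd_log2**2)

Pure-cell-type cohorts (laser-dissected neurons, cultured microglia) are
the degenerate mixtures with a single fraction equal to one.

All generation is driven by :class:`numpy.random.Generator` seeds and is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "CELL_TYPES",
    "CellProfiles",
    "CohortDesign",
    "ExpressionStudy",
    "generate_annotation",
    "generate_cell_profiles",
    "generate_cohort",
    "generate_pure_cohort",
    "write_study",
]

CELL_TYPES = ("neuron", "astrocyte", "microglia")

#: Baseline linear intensity law: log2-intensity ~ Normal(6, 1) per probe,
#: identical for X and autosomal probes so the null X:Autosome ratio is 1.
#: The base is shared by all cell types: the generator is deliberately
#: mechanism-minimal, so cell types differ only through the modelled
#: effects (neuronal X up-regulation, reporter enrichment) and every
#: deviation downstream is attributable to one of them.
BASE_LOG2_MEAN = 6.0
BASE_LOG2_SD = 1.0

ANNOTATION_COLUMNS = ["gene_symbol", "chromosome", "start_bp", "is_escape"]
SAMPLE_COLUMNS = [
    "group",
    "sex",
    "age",
    "frac_neuron",
    "frac_astrocyte",
    "frac_microglia",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CellProfiles:
    """Per-cell-type linear expression profiles plus reporter bookkeeping.

    Attributes
    ----------
    base_intensity:
        probes x cell-types DataFrame of positive linear intensities with
        the neuronal X factor and reporter enrichment already applied.
    x_factor_neuron:
        Multiplicative ChrX up-regulation applied to neuron intensities on
        non-escape X probes.
    reporter_fold:
        Enrichment of a reporter probe in its own cell type over every
        other cell type (strictly > 20 by construction).
    reporters:
        cell type -> list of reporter gene symbols (autosomal only).
    reference:
        Tidy reference table (gene_symbol, cell_type, fold_change,
        chromosome) in the layout reporter selection consumes.
    """

    base_intensity: pd.DataFrame
    x_factor_neuron: float
    reporter_fold: float
    reporters: dict[str, list[str]]
    reference: pd.DataFrame


@dataclass
class CohortDesign:
    """Sampling design of a two-group (control/disease) bulk cohort.

    Cell-type fractions are Dirichlet on the 3-simplex around per-group
    mean compositions; ``concentration`` controls the within-group spread
    (larger = tighter).  With ``independent_astrocyte`` the neuron and
    astrocyte fractions are instead drawn as independent Betas (microglia
    takes the remainder), which decouples astrocyte abundance from
    neuronal loss — the null scenario for the stepwise-regression control.
    """

    n_control: int = 12
    n_disease: int = 12
    control_fractions: tuple[float, float, float] = (0.60, 0.25, 0.15)
    disease_fractions: tuple[float, float, float] = (0.30, 0.40, 0.30)
    concentration: float = 40.0
    independent_astrocyte: bool = False
    noise_sd_log2: float = 0.25
    detection_quantile: float = 0.0
    seed: int = 0


@dataclass
class ExpressionStudy:
    """A probe x sample expression study with detection calls and metadata.

    ``matrix`` and ``detection`` share the probe index (matching
    ``annotation``) and sample columns (matching ``samples``).  ``scale``
    is ``"linear"`` for raw positive intensities, ``"log2"`` after
    normalization.
    """

    matrix: pd.DataFrame
    detection: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise InputError(f"unknown scale {self.scale!r}")
        if not self.matrix.index.equals(self.annotation.index):
            raise InputError("matrix probe axis does not match annotation")
        if not self.matrix.columns.equals(self.samples.index):
            raise InputError("matrix sample axis does not match sample metadata")
        if not self.matrix.index.is_unique:
            raise InputError("duplicate probe_ids")
        if not self.matrix.columns.is_unique:
            raise InputError("duplicate sample_ids")
        if self.scale == "linear" and not (self.matrix.to_numpy() > 0).all():
            raise InputError("linear-scale intensities must be positive")

    @property
    def n_probes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_annotation(
    n_autosomal: int,
    n_x: int,
    escape_fraction: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a probe annotation table with an Xp escape zone.

    Autosomal probes are spread round-robin over chromosomes 1-22 with
    random positions; X probes are sorted by position and the lowest-
    coordinate ``ceil(escape_fraction * n_x)`` of them form the contiguous
    escape zone (``is_escape=True``).

    Returns a DataFrame indexed by probe_id with columns
    gene_symbol, chromosome, start_bp, is_escape.
    """
    if n_autosomal < 1 or n_x < 1:
        raise InputError("probe counts must be >= 1")
    if not 0.0 <= escape_fraction < 1.0:
        raise InputError("escape_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    auto = pd.DataFrame(
        {
            "probe_id": [f"A{i:06d}_at" for i in range(n_autosomal)],
            "gene_symbol": [f"AGENE{i:05d}" for i in range(n_autosomal)],
            "chromosome": [str(i % 22 + 1) for i in range(n_autosomal)],
            "start_bp": rng.integers(1, 250_000_000, size=n_autosomal),
            "is_escape": False,
        }
    )
    x_pos = np.sort(rng.integers(1, 155_000_000, size=n_x))
    n_escape = math.ceil(escape_fraction * n_x)
    x = pd.DataFrame(
        {
            "probe_id": [f"X{j:06d}_at" for j in range(n_x)],
            "gene_symbol": [f"XGENE{j:05d}" for j in range(n_x)],
            "chromosome": "X",
            "start_bp": x_pos,
            "is_escape": np.arange(n_x) < n_escape,
        }
    )
    ann = pd.concat([auto, x], ignore_index=True).set_index("probe_id")
    ann["start_bp"] = ann["start_bp"].astype(int)
    ann["is_escape"] = ann["is_escape"].astype(bool)
    return ann


def generate_cell_profiles(
    annotation: pd.DataFrame,
    x_factor_neuron: float = 1.3,
    reporter_config: dict[str, tuple[int, float]] | None = None,
    seed: int = 0,
) -> CellProfiles:
    """Draw cell-type profiles with neuronal X up-regulation and reporters.

    Parameters
    ----------
    x_factor_neuron:
        Factor applied to neuron intensities on non-escape X probes only.
    reporter_config:
        cell type -> (number of reporter genes, fold enrichment).  Default
        60 genes each for neurons and astrocytes at 25-fold.  Reporter
        probes are drawn from disjoint autosomal probes; the reporter's
        own-cell-type intensity is set to ``fold x`` the maximum intensity
        of the other cell types, so the fold-change guarantee holds
        probe-wise.
    """
    if x_factor_neuron <= 0:
        raise InputError("x_factor_neuron must be > 0")
    if reporter_config is None:
        reporter_config = {"neuron": (60, 25.0), "astrocyte": (60, 25.0)}
    for ct, (k, fold) in reporter_config.items():
        if ct not in CELL_TYPES:
            raise InputError(f"unknown cell type {ct!r}")
        if fold <= 20:
            raise InputError("reporter fold enrichment must exceed 20")

    rng = np.random.default_rng(seed)
    probes = annotation.index
    gene_level = rng.normal(BASE_LOG2_MEAN, BASE_LOG2_SD, size=(len(probes), 1))
    base = pd.DataFrame(
        np.repeat(2.0**gene_level, 3, axis=1),
        index=probes,
        columns=list(CELL_TYPES),
    )

    on_x = annotation["chromosome"] == "X"
    uplift = on_x & ~annotation["is_escape"]
    base.loc[uplift, "neuron"] *= x_factor_neuron

    autosomal = annotation.index[~on_x & (annotation["chromosome"] != "Y")]
    n_needed = sum(k for k, _ in reporter_config.values())
    if n_needed > len(autosomal):
        raise InputError(
            f"{n_needed} reporter genes requested but only "
            f"{len(autosomal)} autosomal probes available"
        )
    chosen = rng.choice(autosomal, size=n_needed, replace=False)

    reporters: dict[str, list[str]] = {}
    ref_rows = []
    offset = 0
    min_fold = np.inf
    for ct, (k, fold) in reporter_config.items():
        ct_probes = chosen[offset : offset + k]
        offset += k
        # Markers are expressed at ordinary levels in their own cell type and
        # near-silent elsewhere: enrichment comes from suppressing the other
        # cell types, so reporters do not distort chromosome-wide means.
        others = [c for c in CELL_TYPES if c != ct]
        own = base.loc[ct_probes, ct]
        cap = own / (fold * (1.0 + 1e-9))  # margin keeps the fold strictly met in FP
        for other in others:
            base.loc[ct_probes, other] = np.minimum(
                base.loc[ct_probes, other].to_numpy(), cap.to_numpy()
            )
        genes = annotation.loc[ct_probes, "gene_symbol"].tolist()
        reporters[ct] = genes
        min_fold = min(min_fold, fold)
        for p, g in zip(ct_probes, genes):
            ref_rows.append((g, ct, fold, annotation.loc[p, "chromosome"]))

    reference = pd.DataFrame(
        ref_rows, columns=["gene_symbol", "cell_type", "fold_change", "chromosome"]
    )
    return CellProfiles(
        base_intensity=base,
        x_factor_neuron=x_factor_neuron,
        reporter_fold=float(min_fold) if ref_rows else float("nan"),
        reporters=reporters,
        reference=reference,
    )


def _draw_fractions(
    rng: np.random.Generator,
    n: int,
    means: tuple[float, float, float],
    concentration: float,
    independent_astrocyte: bool,
) -> np.ndarray:
    means_arr = np.asarray(means, dtype=float)
    if means_arr.min() < 0 or abs(means_arr.sum() - 1.0) > 1e-9:
        raise InputError("mean fractions must be non-negative and sum to 1")
    if not independent_astrocyte:
        return rng.dirichlet(concentration * means_arr, size=n)
    # Independent neuron/astrocyte Betas; microglia takes the remainder.
    # Rejection keeps the draw on the open simplex.
    out = np.empty((n, 3))
    for i in range(n):
        for _ in range(1000):
            f_n = rng.beta(concentration * means_arr[0], concentration * (1 - means_arr[0]))
            f_a = rng.beta(concentration * means_arr[1], concentration * (1 - means_arr[1]))
            if f_n + f_a < 0.98:
                break
        else:  # pragma: no cover - essentially unreachable at sane means
            raise InputError("could not draw fractions on the simplex")
        out[i] = (f_n, f_a, 1.0 - f_n - f_a)
    return out


def _mix(
    fractions: np.ndarray,
    profiles: CellProfiles,
    annotation: pd.DataFrame,
    sample_ids: list[str],
    noise_sd_log2: float,
    rng: np.random.Generator,
    detection_quantile: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if noise_sd_log2 < 0:
        raise InputError("noise_sd_log2 must be >= 0")
    if not np.allclose(fractions.sum(axis=1), 1.0) or fractions.min() < 0:
        raise InputError("cell-type fractions must lie on the simplex")
    if not profiles.base_intensity.index.equals(annotation.index):
        raise InputError("profiles do not cover the annotation's probes")

    clean = profiles.base_intensity.to_numpy() @ fractions.T  # probes x samples
    if noise_sd_log2 > 0:
        clean = clean * 2.0 ** rng.normal(0.0, noise_sd_log2, size=clean.shape)
    matrix = pd.DataFrame(clean, index=annotation.index, columns=sample_ids)
    if detection_quantile > 0:
        floor = matrix.quantile(detection_quantile, axis=0)
        detection = matrix.gt(floor, axis=1)
    else:
        detection = pd.DataFrame(True, index=matrix.index, columns=matrix.columns)
    return matrix, detection


def generate_cohort(
    design: CohortDesign,
    profiles: CellProfiles,
    annotation: pd.DataFrame,
) -> ExpressionStudy:
    """Generate a two-group bulk cohort from the mixture model."""
    if design.n_control < 1 or design.n_disease < 1:
        raise InputError("group sizes must be >= 1")
    rng = np.random.default_rng(design.seed)

    frac_c = _draw_fractions(
        rng, design.n_control, design.control_fractions,
        design.concentration, design.independent_astrocyte,
    )
    frac_d = _draw_fractions(
        rng, design.n_disease, design.disease_fractions,
        design.concentration, design.independent_astrocyte,
    )
    fractions = np.vstack([frac_c, frac_d])
    sample_ids = [f"ctrl{i:02d}" for i in range(design.n_control)] + [
        f"dis{i:02d}" for i in range(design.n_disease)
    ]
    groups = ["control"] * design.n_control + ["disease"] * design.n_disease
    sexes = [("M", "F")[i % 2] for i in range(len(sample_ids))]
    ages = np.round(rng.normal(75, 6, size=len(sample_ids)), 1)

    matrix, detection = _mix(
        fractions, profiles, annotation, sample_ids,
        design.noise_sd_log2, rng, design.detection_quantile,
    )
    samples = pd.DataFrame(
        {
            "group": groups,
            "sex": sexes,
            "age": ages,
            "frac_neuron": fractions[:, 0],
            "frac_astrocyte": fractions[:, 1],
            "frac_microglia": fractions[:, 2],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionStudy(matrix, detection, annotation.copy(), samples)


def generate_pure_cohort(
    cell_type: str,
    n: int,
    profiles: CellProfiles,
    annotation: pd.DataFrame,
    noise_sd_log2: float = 0.25,
    seed: int = 0,
) -> ExpressionStudy:
    """Generate a pure-cell-type cohort (e.g. laser-dissected neurons)."""
    if cell_type not in CELL_TYPES:
        raise InputError(f"unknown cell type {cell_type!r}")
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    onehot = np.zeros((n, 3))
    onehot[:, CELL_TYPES.index(cell_type)] = 1.0
    sample_ids = [f"{cell_type}{i:02d}" for i in range(n)]
    matrix, detection = _mix(
        onehot, profiles, annotation, sample_ids, noise_sd_log2, rng
    )
    samples = pd.DataFrame(
        {
            "group": cell_type,
            "sex": [("M", "F")[i % 2] for i in range(n)],
            "age": np.round(rng.normal(70, 8, size=n), 1),
            "frac_neuron": onehot[:, 0],
            "frac_astrocyte": onehot[:, 1],
            "frac_microglia": onehot[:, 2],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionStudy(matrix, detection, annotation.copy(), samples)


# ---------------------------------------------------------------------------
# writers (the TSV dialect io_preprocess.read_study consumes)
# ---------------------------------------------------------------------------


def write_study(study: ExpressionStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a study as four TSVs: expression, detection (P/A), annotation,
    samples.  Returns the paths keyed by table name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "detection": out / "detection.tsv",
        "annotation": out / "annotation.tsv",
        "samples": out / "samples.tsv",
    }
    study.matrix.rename_axis("probe_id").to_csv(paths["expression"], sep="\t")
    calls = pd.DataFrame(
        np.where(study.detection.to_numpy(), "P", "A"),
        index=study.detection.index,
        columns=study.detection.columns,
    )
    calls.rename_axis("probe_id").to_csv(paths["detection"], sep="\t")
    study.annotation.rename_axis("probe_id").to_csv(paths["annotation"], sep="\t")
    study.samples.rename_axis("sample_id").to_csv(paths["samples"], sep="\t")
    return paths
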