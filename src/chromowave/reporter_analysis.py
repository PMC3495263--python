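"""Cell-type reporter genes and their association with case loadings.

Reporter genes are autosomal genes with > 20-fold enrichment in one cell
type (neurons or astrocytes) in a cell-type transcriptome reference; ChrX
genes are excluded a priori so the reporter signal cannot trivially
correlate with a ChrX pattern.  The aggregate expression of a reporter set
proxies the abundance of its cell type in bulk tissue.  The per-sample
summary is the first SVD component of the centered log2 reporter-probe
matrix — more robust than a plain average, whose direction is used only to
orient the component's sign.

Association of chromosomal case loadings with reporter patterns uses
two-tailed Pearson correlation; whether a second (astrocytic) predictor
adds information beyond the first (neuronal) is a forward partial-F test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ComputationError, InputError
from .synthetic_data import ExpressionStudy

__all__ = [
    "ReporterGeneSet",
    "AssociationResult",
    "StepwiseResult",
    "select_reporters",
    "reporter_pattern",
    "correlate_loadings",
    "stepwise_add",
]


@dataclass
class ReporterGeneSet:
    cell_type: str
    genes: dict[str, float]  # gene symbol -> fold change (> threshold)
    probes: list[str]  # all study probes mapping to those genes


@dataclass
class AssociationResult:
    r: float
    p: float
    n: int


@dataclass
class StepwiseResult:
    base_predictor: str
    added_predictor: str
    partial_F: float
    partial_p: float
    added_is_significant: bool
    alpha: float


def select_reporters(
    reference,
    study: ExpressionStudy,
    cell_type: str,
    fold_threshold: float = 20.0,
) -> ReporterGeneSet:
    """Select reporter genes for ``cell_type`` and attach study probes.

    ``reference`` is a DataFrame with columns gene_symbol, cell_type,
    fold_change, chromosome.  Rules: matching cell type, fold change
    strictly above ``fold_threshold``, chromosome != X.  Every probe in the
    study whose gene symbol matches a selected gene is attached.
    """
    required = {"gene_symbol", "cell_type", "fold_change", "chromosome"}
    missing = required - set(reference.columns)
    if missing:
        raise InputError(f"reference table missing columns {sorted(missing)}")
    rows = reference[
        (reference["cell_type"] == cell_type)
        & (reference["fold_change"] > fold_threshold)
        & (reference["chromosome"].astype(str) != "X")
    ]
    genes = dict(zip(rows["gene_symbol"], rows["fold_change"].astype(float)))
    probes = study.annotation.index[
        study.annotation["gene_symbol"].isin(genes)
    ].tolist()
    if not probes:
        raise ComputationError(f"no reporters found for cell type {cell_type!r}")
    return ReporterGeneSet(cell_type=cell_type, genes=genes, probes=probes)


def reporter_pattern(
    study: ExpressionStudy, reporters: ReporterGeneSet
) -> np.ndarray:
    """Per-sample loading of the primary reporter expression pattern.

    First SVD component of the row-centered log2 reporter matrix, scaled
    by the singular value; sign oriented so loadings correlate positively
    with the per-sample mean reporter expression.
    """
    if study.scale != "log2":
        raise InputError("reporter_pattern expects a log2-scale study")
    if study.n_samples < 3:
        raise InputError("need at least 3 samples")
    if len(reporters.probes) < 2:
        raise InputError("need at least 2 reporter probes")
    mat = study.matrix.loc[reporters.probes].to_numpy(dtype=float)
    centered = mat - mat.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ComputationError("reporter matrix has no between-sample variance")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = s[0] * vt[0]
    sample_means = mat.mean(axis=0)
    if np.ptp(sample_means) > 0:
        r = np.corrcoef(loadings, sample_means)[0, 1]
        if np.isfinite(r) and r < 0:
            loadings = -loadings
    return loadings


def correlate_loadings(x: np.ndarray, y: np.ndarray) -> AssociationResult:
    """Two-tailed Pearson correlation between two loading vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("loading vectors must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise InputError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("non-finite loadings")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError("zero variance in a loading vector")
    res = stats.pearsonr(x, y)
    p = min(max(float(res.pvalue), np.nextafter(0, 1)), 1.0)
    return AssociationResult(r=float(res.statistic), p=p, n=n)


def stepwise_add(
    y: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    alpha: float = 0.05,
    base_name: str = "neuronal",
    added_name: str = "astrocytic",
) -> StepwiseResult:
    """Forward partial-F test: does ``x2`` add to the fit of ``y ~ x1``?

    Fits y ~ 1 + x1 and y ~ 1 + x1 + x2 by least squares;
    partial F = ((RSS1 - RSS2) / 1) / (RSS2 / (n - 3)), referred to
    F(1, n-3).
    """
    y, x1, x2 = (np.asarray(v, dtype=float) for v in (y, x1, x2))
    if not (y.shape == x1.shape == x2.shape) or y.ndim != 1:
        raise InputError("y, x1, x2 must be 1-D and equal length")
    n = y.size
    if n < 4:
        raise InputError("need n >= 4")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ComputationError("constant predictor")
    r12 = np.corrcoef(x1, x2)[0, 1]
    if abs(r12) >= 1.0 - 1e-12:
        raise ComputationError("collinear predictors")

    ones = np.ones(n)
    d1 = np.column_stack([ones, x1])
    d2 = np.column_stack([ones, x1, x2])
    rss1 = float(np.sum((y - d1 @ np.linalg.lstsq(d1, y, rcond=None)[0]) ** 2))
    rss2 = float(np.sum((y - d2 @ np.linalg.lstsq(d2, y, rcond=None)[0]) ** 2))
    df2 = n - 3
    tss = float(np.sum((y - y.mean()) ** 2))
    tol = 1e-12 * max(tss, 1.0)
    if rss1 <= tol:
        # base model already fits (numerically) perfectly: nothing to add
        partial_f, partial_p = 0.0, 1.0
    elif rss2 <= tol:
        partial_f, partial_p = np.inf, 0.0
    else:
        partial_f = max((rss1 - rss2) / (rss2 / df2), 0.0)
        partial_p = float(stats.f.sf(partial_f, 1, df2))
    return StepwiseResult(
        base_predictor=base_name,
        added_predictor=added_name,
        partial_F=float(partial_f),
        partial_p=partial_p,
        added_is_significant=bool(partial_p < alpha),
        alpha=alpha,
    )
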