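"""Study IO, median/present-call normalization, and chromosomal ordering.

Normalization follows the classic Affymetrix-era recipe: per sample,
divide every intensity by the median intensity of the probes flagged
"present" in that sample, then log2-transform.  A present-call median of 1
(0 on the log2 scale) anchors each sample, which is what makes per-sample
mean ratios comparable across arrays and platforms.

`chromosome_slice` produces the spatial axis the wavelet transform runs
over: probes of one chromosome sorted by genomic start (ties broken by
probe_id), equally spaced in rank order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ComputationError, FormatError, InputError
from .synthetic_data import ANNOTATION_COLUMNS, ExpressionStudy

__all__ = [
    "OrderedChromosomeSlice",
    "read_study",
    "median_normalize",
    "chromosome_slice",
]

logger = logging.getLogger(__name__)


@dataclass
class OrderedChromosomeSlice:
    """Log2 expression of one chromosome's probes in genomic order."""

    chromosome: str
    probe_ids: list[str]
    positions_bp: np.ndarray
    values: np.ndarray  # probes x samples, log2 scale
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.probe_ids) != self.values.shape[0]:
            raise InputError("probe axis does not match values")
        if len(self.positions_bp) != len(self.probe_ids):
            raise InputError("positions do not match probes")
        if np.any(np.diff(self.positions_bp) < 0):
            raise InputError("positions must be non-decreasing")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def _read_numeric_table(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{name}: duplicated probe_id(s) {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{name}: non-numeric value {df.iat[bad[0], bad[1]]!r} at "
            f"row {df.index[bad[0]]!r}, column {df.columns[bad[1]]!r}"
        )
    return numeric


def read_study(
    expression: str | Path,
    detection: str | Path | None = None,
    annotation: str | Path | None = None,
    samples: str | Path | None = None,
) -> ExpressionStudy:
    """Read a study from the four-TSV layout written by ``write_study``.

    If only a directory is given as ``expression``, the standard file names
    (expression/detection/annotation/samples .tsv) are assumed.  Probes in
    the expression table without an annotation row are dropped (count
    logged); probes lacking a detection call default to present.
    """
    expression = Path(expression)
    if expression.is_dir():
        d = expression
        expression = d / "expression.tsv"
        detection = detection or d / "detection.tsv"
        annotation = annotation or d / "annotation.tsv"
        samples = samples or d / "samples.tsv"
    if annotation is None or samples is None:
        raise InputError("annotation and samples paths are required")

    matrix = _read_numeric_table(expression, "expression")
    ann = pd.read_csv(annotation, sep="\t", index_col=0, dtype={"chromosome": str})
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise FormatError(f"annotation: missing columns {missing_cols}")
    if not ann.index.is_unique:
        raise FormatError("annotation: duplicated probe_id")
    ann["is_escape"] = ann["is_escape"].astype(bool)

    unannotated = matrix.index.difference(ann.index)
    if len(unannotated):
        logger.warning(
            "dropping %d expression probe(s) absent from annotation", len(unannotated)
        )
        matrix = matrix.drop(index=unannotated)
    ann = ann.loc[matrix.index]

    if detection is not None and Path(detection).exists():
        det_raw = pd.read_csv(detection, sep="\t", index_col=0, dtype=str)
        det = det_raw.reindex(index=matrix.index, columns=matrix.columns)
        detection_df = det.eq("P") | det.isna()  # missing call -> present
    else:
        detection_df = pd.DataFrame(True, index=matrix.index, columns=matrix.columns)

    samp = pd.read_csv(samples, sep="\t", index_col=0)
    samp = samp.loc[matrix.columns]
    return ExpressionStudy(matrix, detection_df, ann, samp, scale="linear")


def median_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Per-sample median normalization over present-call probes, then log2.

    Raises
    ------
    InputError if the study is already on the log2 scale;
    ComputationError if any sample has no present-call probe.
    """
    if study.scale != "linear":
        raise InputError("median_normalize expects linear-scale intensities")
    empty = ~study.detection.any(axis=0)
    if empty.any():
        raise ComputationError(
            f"sample(s) with zero present probes: {list(study.detection.columns[empty])}"
        )
    medians = study.matrix.where(study.detection).median(axis=0, skipna=True)
    log2 = np.log2(study.matrix.div(medians, axis=1))
    return ExpressionStudy(
        log2, study.detection.copy(), study.annotation.copy(),
        study.samples.copy(), scale="log2",
    )


def chromosome_slice(
    study: ExpressionStudy,
    chromosome: str,
    present_filter: str = "none",
) -> OrderedChromosomeSlice:
    """Extract one chromosome's probes in genomic order.

    ``present_filter``: ``none`` keeps all probes; ``all_samples`` keeps a
    probe only if it is present in every sample (the rule for
    laser-dissected data); ``any_sample`` requires at least one present
    call.
    """
    if study.scale != "log2":
        raise InputError("chromosome_slice expects a log2-scale study")
    if present_filter not in ("none", "all_samples", "any_sample"):
        raise InputError(f"unknown present_filter {present_filter!r}")
    mask = study.annotation["chromosome"] == str(chromosome)
    if not mask.any():
        raise InputError(f"chromosome {chromosome!r} absent from annotation")

    sub_ann = study.annotation.loc[mask]
    if present_filter == "all_samples":
        keep = study.detection.loc[mask].all(axis=1)
        sub_ann = sub_ann.loc[keep]
    elif present_filter == "any_sample":
        keep = study.detection.loc[mask].any(axis=1)
        sub_ann = sub_ann.loc[keep]
    order = sub_ann.assign(_pid=sub_ann.index).sort_values(
        ["start_bp", "_pid"], kind="mergesort"
    )
    return OrderedChromosomeSlice(
        chromosome=str(chromosome),
        probe_ids=order.index.tolist(),
        positions_bp=order["start_bp"].to_numpy(),
        values=study.matrix.loc[order.index].to_numpy(dtype=float),
        sample_ids=study.matrix.columns.tolist(),
    )
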