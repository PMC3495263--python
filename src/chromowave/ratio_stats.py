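"""X:Autosome expression ratios and the group comparisons built on them.

The per-sample ratio is the mean linear intensity over X-linked probes
divided by the mean over autosomal (chr 1-22) probes — Y probes are left
out of the denominator so it is comparable between sexes.  In a tissue
without X up-regulation the ratio is ~1 after median normalization; a
cell type that up-regulates X (neurons, in brain) pushes it above 1 in
proportion to that cell type's abundance in the sample.

Group comparisons are two-tailed pooled-variance Student t-tests, both on
ratios (pure cohorts vs mixed tissue) and on case loadings (disease vs
control, optionally restricted to male subjects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputError
from .synthetic_data import ExpressionStudy

__all__ = [
    "TTestResult",
    "x_autosome_ratio",
    "compare_ratio_groups",
    "compare_loading_groups",
]

AUTOSOMES = {str(i) for i in range(1, 23)}


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    group_means: tuple[float, float]


def x_autosome_ratio(
    study: ExpressionStudy, present_only: bool = True
) -> pd.DataFrame:
    """Per-sample X:Autosome mean-intensity ratio.

    Works on linear intensities; a log2-scale study is back-transformed
    first (the ratio is invariant to the per-sample median scaling).  With
    ``present_only`` each sample's means run over its present-call probes.

    Returns a DataFrame indexed by sample_id with columns group,
    x_autosome_ratio, n_x_probes, n_autosomal_probes.
    """
    chroms = study.annotation["chromosome"].astype(str)
    x_mask = (chroms == "X").to_numpy()
    auto_mask = chroms.isin(AUTOSOMES).to_numpy()

    values = study.matrix.to_numpy(dtype=float)
    if study.scale == "log2":
        values = 2.0**values

    rows = []
    for j, sample in enumerate(study.matrix.columns):
        det = study.detection.iloc[:, j].to_numpy() if present_only else np.ones(
            values.shape[0], dtype=bool
        )
        x_sel = x_mask & det
        a_sel = auto_mask & det
        if not x_sel.any() or not a_sel.any():
            raise ComputationError(
                f"sample {sample!r}: no X or no autosomal probes after filtering"
            )
        rows.append(
            (
                sample,
                study.samples.loc[sample, "group"],
                float(values[x_sel, j].mean() / values[a_sel, j].mean()),
                int(x_sel.sum()),
                int(a_sel.sum()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "x_autosome_ratio", "n_x_probes", "n_autosomal_probes"],
    ).set_index("sample_id")


def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> TTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ComputationError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t=float(res.statistic),
        p=float(min(max(res.pvalue, np.nextafter(0, 1)), 1.0)),
        df=a.size + b.size - 2,
        group_means=(float(a.mean()), float(b.mean())),
    )


def compare_ratio_groups(a: pd.DataFrame, b: pd.DataFrame) -> TTestResult:
    """Two-sample pooled-variance Student t-test between two RatioTables."""
    return _pooled_ttest(
        a["x_autosome_ratio"].to_numpy(), b["x_autosome_ratio"].to_numpy()
    )


def compare_loading_groups(
    loadings: np.ndarray,
    metadata: pd.DataFrame,
    groups: tuple[str, str] = ("control", "disease"),
    sex_filter: str = "none",
) -> TTestResult:
    """Student t-test on case loadings between two group labels.

    ``sex_filter="male_only"`` drops samples labelled F before testing
    (removing the second X chromosome's escape-zone contribution from the
    comparison).  group_means is ordered as ``groups``.
    """
    if sex_filter not in ("none", "male_only"):
        raise InputError(f"unknown sex_filter {sex_filter!r}")
    loadings = np.asarray(loadings, dtype=float)
    if loadings.size != len(metadata):
        raise InputError("loadings do not match sample metadata")
    keep = np.ones(loadings.size, dtype=bool)
    if sex_filter == "male_only":
        keep = (metadata["sex"] != "F").to_numpy()
    grp = metadata["group"].to_numpy()
    a = loadings[keep & (grp == groups[0])]
    b = loadings[keep & (grp == groups[1])]
    if a.size == 0 or b.size == 0:
        raise InputError("a group is empty after filtering")
    return _pooled_ttest(a, b)
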