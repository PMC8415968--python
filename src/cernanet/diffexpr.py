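"""Differential-expression classification of count matrices.

Counts are normalised to counts-per-million (CPM), features are scored
with a case/control fold change and a Welch t-test on log2(CPM+1), and
each feature is called ``up`` / ``down`` / ``ns`` under fold-change and
significance cutoffs.  The defaults reproduce the study-design cutoffs
common in EV transcriptomics screens: fold change strictly above 1.4 for
enrichment, strictly below 0.7 for depletion, p <= 0.05 for significance
on the raw (uncorrected) p-value, with an optional Benjamini-Hochberg
switch.

The Welch t-test is a deliberately transparent substitute for
pipeline-specific count engines (edgeR, MAPRSeq): the classification
contract is thresholds plus a p-value source, and the p-value source is
pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DomainError, ParameterError
from .io import GROUP_CASE, GROUP_CONTROL, ExpressionMatrix


@dataclass(frozen=True)
class DEThresholds:
    """Cutoffs for calling differential expression.

    ``fc_up``: upregulated requires fold change strictly greater (default 1.4).
    ``fc_down``: downregulated requires fold change strictly smaller (default 0.7).
    ``alpha``: significance level, inclusive p <= alpha (default 0.05).
    """

    fc_up: float = 1.4
    fc_down: float = 0.7
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ParameterError("thresholds must satisfy 0 < fc_down < 1 < fc_up")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie strictly between 0 and 1")


@dataclass(frozen=True)
class DESummary:
    """Per-kind tally of DE calls with percentages of the annotated total."""

    n_annotated: int
    n_up: int
    n_down: int
    n_de: int
    pct_up: float
    pct_down: float


def _round_half_up(x_num: int, x_den: int, decimals: int = 1) -> float:
    """100*x_num/x_den as a percentage, rounded half-up (5 rounds away from 0)."""
    q = Decimal(100 * x_num) / Decimal(x_den)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def de_summary(n_annotated: int, n_up: int, n_down: int) -> DESummary:
    """Tally DE calls against the annotated feature universe.

    Percentages are 100*n/n_annotated rounded half-up to one decimal.
    """
    if min(n_annotated, n_up, n_down) < 0:
        raise DomainError("counts must be non-negative")
    if n_up + n_down > n_annotated:
        raise DomainError("n_up + n_down exceeds n_annotated")
    if n_annotated == 0:
        if n_up + n_down:
            raise DomainError("nonzero DE count with zero annotated features")
        return DESummary(0, 0, 0, 0, 0.0, 0.0)
    return DESummary(
        n_annotated=n_annotated,
        n_up=n_up,
        n_down=n_down,
        n_de=n_up + n_down,
        pct_up=_round_half_up(n_up, n_annotated),
        pct_down=_round_half_up(n_down, n_annotated),
    )


def normalize_cpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample column to counts per million."""
    if matrix.scale != "counts":
        raise DataError(f"normalize_cpm expects a counts matrix, got {matrix.scale!r}")
    sums = matrix.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise DataError(f"sample {zero.index[0]!r} has zero library size")
    cpm = matrix.values.div(sums, axis=1) * 1e6
    return ExpressionMatrix(values=cpm, kind=matrix.kind, groups=matrix.groups, scale="cpm")


def log2cpm(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount); accepts counts (normalised first) or cpm."""
    if matrix.scale == "counts":
        matrix = normalize_cpm(matrix)
    if matrix.scale != "cpm":
        raise DataError(f"log2cpm expects counts or cpm, got {matrix.scale!r}")
    vals = np.log2(matrix.values + pseudocount)
    return ExpressionMatrix(values=vals, kind=matrix.kind, groups=matrix.groups, scale="log2cpm")


def _group_columns(matrix: ExpressionMatrix) -> tuple[list[str], list[str]]:
    control = matrix.samples_in_group(GROUP_CONTROL)
    case = matrix.samples_in_group(GROUP_CASE)
    if not control or not case:
        missing = GROUP_CONTROL if not control else GROUP_CASE
        raise DataError(f"group {missing!r} absent from matrix")
    return control, case


def fold_change(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-feature case/control fold change of group-mean CPM.

    FC = (mean case CPM + pseudocount) / (mean control CPM + pseudocount);
    the pseudocount keeps zero-expression features finite and at FC = 1.
    """
    if matrix.scale != "cpm":
        raise DataError(f"fold_change expects a cpm matrix, got {matrix.scale!r}")
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    control, case = _group_columns(matrix)
    mean_control = matrix.values[control].mean(axis=1)
    mean_case = matrix.values[case].mean(axis=1)
    fc = (mean_case + pseudocount) / (mean_control + pseudocount)
    return pd.DataFrame(
        {
            "mean_lean_cpm": mean_control,
            "mean_mets_cpm": mean_case,
            "fc": fc,
            "log2fc": np.log2(fc),
        }
    )


def welch_pvalues(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.Series:
    """Two-sided Welch t-test p per feature on log2(CPM + pseudocount).

    Degenerate features (zero within-group variance in both groups) get
    p = 1 when the group means are equal and p = 0 otherwise.
    """
    if matrix.scale == "cpm":
        matrix = log2cpm(matrix, pseudocount)
    if matrix.scale != "log2cpm":
        raise DataError(f"welch_pvalues expects cpm or log2cpm, got {matrix.scale!r}")
    control, case = _group_columns(matrix)
    if len(control) < 2 or len(case) < 2:
        raise DataError("need at least 2 samples per group for the t-test")
    a = matrix.values[case].to_numpy(float)
    b = matrix.values[control].to_numpy(float)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant features trigger a harmless precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return pd.Series(p, index=matrix.values.index, name="p")


def de_test(matrix: ExpressionMatrix, feature_id: str, pseudocount: float = 1.0) -> float:
    """Welch p-value for a single feature (convenience over :func:`welch_pvalues`)."""
    p = welch_pvalues(matrix, pseudocount)
    if feature_id not in p.index:
        raise DataError(f"feature {feature_id!r} not in matrix")
    return float(p[feature_id])


def classify_de(fc: float, p_value: float, thresholds: DEThresholds) -> str:
    """Call a feature up/down/ns; fold-change bounds are strict, alpha inclusive."""
    if p_value <= thresholds.alpha:
        if fc > thresholds.fc_up:
            return "up"
        if fc < thresholds.fc_down:
            return "down"
    return "ns"


def run_de(
    matrix: ExpressionMatrix,
    thresholds: DEThresholds | None = None,
    pseudocount: float = 1.0,
    bh_correction: bool = False,
) -> tuple[pd.DataFrame, DESummary]:
    """Full DE pass: CPM -> fold change -> Welch test -> classification.

    Returns the per-feature record table (columns feature_id, kind,
    mean_lean_cpm, mean_mets_cpm, fc, log2fc, p, direction) and a
    :class:`DESummary`.  With ``bh_correction`` the calls use the
    Benjamini-Hochberg adjusted p; the raw p stays in the table.
    """
    thresholds = thresholds or DEThresholds()
    if len(matrix.values) == 0:
        empty = pd.DataFrame(
            columns=["feature_id", "kind", "mean_lean_cpm", "mean_mets_cpm",
                     "fc", "log2fc", "p", "direction"]
        )
        return empty, de_summary(0, 0, 0)
    cpm = normalize_cpm(matrix) if matrix.scale == "counts" else matrix
    table = fold_change(cpm, pseudocount)
    table["p"] = welch_pvalues(cpm, pseudocount)
    p_for_call = table["p"].to_numpy()
    if bh_correction:
        p_for_call = multipletests(p_for_call, method="fdr_bh")[1]
    table["direction"] = [
        classify_de(fc, p, thresholds) for fc, p in zip(table["fc"], p_for_call)
    ]
    table.insert(0, "kind", matrix.kind)
    table = table.reset_index(names="feature_id")
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    return table, de_summary(len(table), n_up, n_down)


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"feature_id": str})
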