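"""Sponge-triplet screening and ceRNA network assembly.

A competing-endogenous-RNA (ceRNA) candidate is a (lncRNA, miRNA, mRNA)
triplet in which the lncRNA and the mRNA share the miRNA in the
interaction tables and all three members are differentially expressed.
A candidate passes the screen when, across all samples (both groups
pooled):

1. the lncRNA and mRNA are significantly positively correlated
   (r > 0.3, p < 0.05 by default),
2. the miRNA and mRNA are significantly negatively correlated
   (r < -0.3, p < 0.05), and
3. the miRNA and lncRNA are significantly negatively correlated
   (r < -0.3, p < 0.05).

Correlations are Pearson product-moment on log2(CPM+1) by default
(Spearman selectable); p comes from the two-sided t statistic
t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, with the limit
convention p = 0 at |r| = 1.  Passed triplets assemble into a typed
two-layer network: sponge edges lncRNA->miRNA and target edges
miRNA->mRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DegenerateFeatureError, ParameterError
from .io import (
    RELATION_SPONGES,
    RELATION_TARGETS,
    ExpressionMatrix,
    InteractionTable,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CeRNACriteria:
    """Correlation thresholds of the triplet screen (all strict)."""

    r_pos_min: float = 0.3
    r_neg_max: float = -0.3
    corr_alpha: float = 0.05
    method: str = "pearson"

    def __post_init__(self) -> None:
        if not (-1 <= self.r_neg_max < 0 < self.r_pos_min <= 1):
            raise ParameterError("need -1 <= r_neg_max < 0 < r_pos_min <= 1")
        if not (0 < self.corr_alpha < 1):
            raise ParameterError("corr_alpha must lie strictly between 0 and 1")
        if self.method not in ("pearson", "spearman"):
            raise ParameterError(f"unknown correlation method {self.method!r}")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class CeRNATriplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    corr_lnc_mrna: CorrelationResult
    corr_mir_mrna: CorrelationResult
    corr_mir_lnc: CorrelationResult
    passed: bool

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


@dataclass
class CeRNANetwork:
    """Typed two-layer graph: nodes carry (kind, DE direction); edges are
    (source, relation, target) with relation ``sponges`` or ``targets``."""

    nodes: dict[str, tuple[str, str]]
    edges: set[tuple[str, str, str]]

    def summary(self) -> dict[str, int]:
        kinds = [k for k, _d in self.nodes.values()]
        return {
            "n_lncRNA": kinds.count("lncRNA"),
            "n_miRNA": kinds.count("miRNA"),
            "n_mRNA": kinds.count("mRNA"),
            "n_sponge_edges": sum(1 for _s, r, _t in self.edges if r == RELATION_SPONGES),
            "n_target_edges": sum(1 for _s, r, _t in self.edges if r == RELATION_TARGETS),
        }


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Correlation coefficient with a small-sample t-based p-value.

    Pearson is the product-moment coefficient; Spearman applies the same
    computation to average ranks.  ``p`` is the two-sided tail of
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom; perfectly
    correlated input gets p = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("correlate expects two equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise DataError("need at least 3 paired samples for a correlation p-value")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("non-finite values in correlation input")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ParameterError(f"unknown correlation method {method!r}")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise DegenerateFeatureError("zero-variance vector in correlation")
    r = float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-14:
        r = float(np.sign(r))
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n)


def _de_ids(de_table: pd.DataFrame) -> set[str]:
    return set(de_table.loc[de_table["direction"] != "ns", "feature_id"])


def top_k_mirnas(de_lncrna: pd.DataFrame, mir_lncrna: InteractionTable, k: int) -> set[str]:
    """Top-k miRNAs ranked by number of distinct DE-lncRNA partners.

    Optional pre-filter mirroring a 'top N miRNAs targeted by the DE
    lncRNAs' selection; ties broken lexicographically by miRNA id.
    """
    de_lnc = _de_ids(de_lncrna)
    frame = mir_lncrna.frame
    frame = frame[frame["target_id"].isin(de_lnc)]
    counts = frame.groupby("mirna_id")["target_id"].nunique()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {m for m, _c in ranked[:k]}


def candidate_triplets(
    de_lncrna: pd.DataFrame,
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    mir_mrna: InteractionTable,
    mir_lncrna: InteractionTable,
    mirna_whitelist: set[str] | None = None,
) -> list[tuple[str, str, str]]:
    """All (lncRNA, miRNA, mRNA) triplets sharing a DE miRNA.

    A triplet qualifies when the (miRNA, mRNA) pair is in the mRNA
    interaction table, the (miRNA, lncRNA) pair is in the lncRNA table,
    and every member is differentially expressed.  The result is
    duplicate-free in deterministic lexicographic order.
    """
    for table, kind in ((mir_mrna, "mRNA"), (mir_lncrna, "lncRNA")):
        wrong = set(table.frame["target_kind"]) - {kind}
        if wrong:
            raise DataError(
                f"interaction table for {kind} targets contains target_kind {sorted(wrong)[0]!r}"
            )
    de_l, de_m, de_g = _de_ids(de_lncrna), _de_ids(de_mirna), _de_ids(de_mrna)
    if mirna_whitelist is not None:
        de_m = de_m & mirna_whitelist
    mrna_by_mir: dict[str, set[str]] = {}
    for m, g in mir_mrna.pairs():
        if m in de_m and g in de_g:
            mrna_by_mir.setdefault(m, set()).add(g)
    lnc_by_mir: dict[str, set[str]] = {}
    for m, l in mir_lncrna.pairs():
        if m in de_m and l in de_l:
            lnc_by_mir.setdefault(m, set()).add(l)
    out = {
        (l, m, g)
        for m in mrna_by_mir.keys() & lnc_by_mir.keys()
        for l in lnc_by_mir[m]
        for g in mrna_by_mir[m]
    }
    return sorted(out)


def _check_aligned(matrices: dict[str, ExpressionMatrix]) -> None:
    sample_sets = {kind: tuple(m.sample_ids) for kind, m in matrices.items()}
    ref = next(iter(sample_sets.values()))
    for kind, samples in sample_sets.items():
        if samples != ref:
            raise DataError(f"sample set of {kind} matrix differs from the others")


def screen_triplets(
    candidates: list[tuple[str, str, str]],
    expr_lncrna: ExpressionMatrix,
    expr_mirna: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    criteria: CeRNACriteria | None = None,
    bh_correction: bool = False,
    per_group: bool = False,
) -> list[CeRNATriplet]:
    """Annotate each candidate with its three correlations and pass flag.

    Expects log2cpm-scale matrices sharing one ordered sample set;
    correlations pool both groups.  With ``per_group`` the three criteria
    must additionally hold within each group separately.  Candidates
    containing a zero-variance feature are excluded and logged.  With
    ``bh_correction`` the pass decision uses Benjamini-Hochberg adjusted
    p-values pooled over all 3*len(candidates) correlation tests.
    """
    criteria = criteria or CeRNACriteria()
    matrices = {"lncRNA": expr_lncrna, "miRNA": expr_mirna, "mRNA": expr_mrna}
    for kind, m in matrices.items():
        if m.scale != "log2cpm":
            raise DataError(f"{kind} matrix must be log2cpm scale, got {m.scale!r}")
    _check_aligned(matrices)

    def _vec(matrix: ExpressionMatrix, fid: str, cols: list[str] | None) -> np.ndarray:
        if fid not in matrix.values.index:
            raise DataError(f"candidate feature {fid!r} missing from {matrix.kind} matrix")
        row = matrix.values.loc[fid]
        return (row[cols] if cols is not None else row).to_numpy(float)

    group_cols = None
    if per_group:
        ref = expr_lncrna
        group_cols = [ref.samples_in_group(g) for g in sorted(set(ref.groups))]

    results: list[CeRNATriplet] = []
    corr_rows: list[tuple[CorrelationResult, ...]] = []
    kept: list[tuple[str, str, str]] = []
    for l, m, g in candidates:
        try:
            lvec = _vec(expr_lncrna, l, None)
            mvec = _vec(expr_mirna, m, None)
            gvec = _vec(expr_mrna, g, None)
            c_lg = correlate(lvec, gvec, criteria.method)
            c_mg = correlate(mvec, gvec, criteria.method)
            c_ml = correlate(mvec, lvec, criteria.method)
        except DegenerateFeatureError:
            logger.info("excluding candidate (%s, %s, %s): zero-variance feature", l, m, g)
            continue
        kept.append((l, m, g))
        corr_rows.append((c_lg, c_mg, c_ml))

    # one shared p-value vector so BH (if requested) spans every test
    p_flat = np.array([c.p for row in corr_rows for c in row])
    p_eff = multipletests(p_flat, method="fdr_bh")[1] if (bh_correction and len(p_flat)) else p_flat

    for i, ((l, m, g), (c_lg, c_mg, c_ml)) in enumerate(zip(kept, corr_rows)):
        p_lg, p_mg, p_ml = p_eff[3 * i : 3 * i + 3]
        passed = (
            c_lg.r > criteria.r_pos_min
            and p_lg < criteria.corr_alpha
            and c_mg.r < criteria.r_neg_max
            and p_mg < criteria.corr_alpha
            and c_ml.r < criteria.r_neg_max
            and p_ml < criteria.corr_alpha
        )
        if passed and per_group and group_cols is not None:
            for cols in group_cols:
                try:
                    gc_lg = correlate(_vec(expr_lncrna, l, cols), _vec(expr_mrna, g, cols), criteria.method)
                    gc_mg = correlate(_vec(expr_mirna, m, cols), _vec(expr_mrna, g, cols), criteria.method)
                    gc_ml = correlate(_vec(expr_mirna, m, cols), _vec(expr_lncrna, l, cols), criteria.method)
                except DegenerateFeatureError:
                    passed = False
                    break
                if not (
                    gc_lg.r > criteria.r_pos_min and gc_lg.p < criteria.corr_alpha
                    and gc_mg.r < criteria.r_neg_max and gc_mg.p < criteria.corr_alpha
                    and gc_ml.r < criteria.r_neg_max and gc_ml.p < criteria.corr_alpha
                ):
                    passed = False
                    break
        results.append(
            CeRNATriplet(
                lncrna_id=l, mirna_id=m, mrna_id=g,
                corr_lnc_mrna=c_lg, corr_mir_mrna=c_mg, corr_mir_lnc=c_ml,
                passed=bool(passed),
            )
        )
    return results


def triplets_to_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    """Flatten triplets to the exportable TSV layout."""
    rows = [
        {
            "lncrna_id": t.lncrna_id,
            "mirna_id": t.mirna_id,
            "mrna_id": t.mrna_id,
            "r_lnc_mrna": t.corr_lnc_mrna.r,
            "p_lnc_mrna": t.corr_lnc_mrna.p,
            "r_mir_mrna": t.corr_mir_mrna.r,
            "p_mir_mrna": t.corr_mir_mrna.p,
            "r_mir_lnc": t.corr_mir_lnc.r,
            "p_mir_lnc": t.corr_mir_lnc.p,
            "passed": t.passed,
        }
        for t in triplets
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "mirna_id", "mrna_id",
            "r_lnc_mrna", "p_lnc_mrna", "r_mir_mrna", "p_mir_mrna",
            "r_mir_lnc", "p_mir_lnc", "passed",
        ],
    )


def build_network(
    triplets: list[CeRNATriplet],
    de_tables: dict[str, pd.DataFrame],
) -> CeRNANetwork:
    """Assemble the passed triplets into a deduplicated two-layer network.

    ``de_tables`` maps kind -> DE record table and supplies the per-node
    DE direction attribute.
    """
    direction: dict[tuple[str, str], str] = {}
    for kind, table in de_tables.items():
        for fid, d in zip(table["feature_id"], table["direction"]):
            direction[(kind, fid)] = d
    nodes: dict[str, tuple[str, str]] = {}
    edges: set[tuple[str, str, str]] = set()
    for t in triplets:
        if not t.passed:
            raise DataError("build_network expects only passed triplets")
        for fid, kind in ((t.lncrna_id, "lncRNA"), (t.mirna_id, "miRNA"), (t.mrna_id, "mRNA")):
            if (kind, fid) not in direction:
                raise DataError(f"triplet member {fid!r} missing from {kind} DE table")
            nodes[fid] = (kind, direction[(kind, fid)])
        edges.add((t.lncrna_id, RELATION_SPONGES, t.mirna_id))
        edges.add((t.mirna_id, RELATION_TARGETS, t.mrna_id))
    return CeRNANetwork(nodes=nodes, edges=edges)


def hub_rank(network: CeRNANetwork, kind: str) -> list[tuple[str, int]]:
    """Nodes of one kind by degree, descending; ties lexicographic by id."""
    degree: dict[str, int] = {n: 0 for n in network.nodes}
    for src, _rel, dst in network.edges:
        degree[src] += 1
        degree[dst] += 1
    ranked = [
        (n, degree[n]) for n, (k, _d) in network.nodes.items() if k == kind
    ]
    return sorted(ranked, key=lambda nd: (-nd[1], nd[0]))


def evaluate_recovery(
    passed_triplets: list[tuple[str, str, str]] | list[CeRNATriplet],
    planted_triplets: list[tuple[str, str, str]],
) -> tuple[float, float, float]:
    """Precision, recall and F1 of passed triplets against the planted set."""
    passed = {
        t.key if isinstance(t, CeRNATriplet) else tuple(t) for t in passed_triplets
    }
    planted = {tuple(t) for t in planted_triplets}
    hits = len(passed & planted)
    precision = hits / len(passed) if passed else (1.0 if not planted else 0.0)
    recall = hits / len(planted) if planted else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1
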