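"""Case/control differential expression and drug-target intersection.

The expression matrix is genes x samples with a case/control label per
sample.  Values are log2-transformed, then per-gene centered and scaled
(sample standard deviation, ddof=1) for visualisation and clustering;
the two-group test runs on the log2 values (Welch t by default, with a
pooled-variance option).  Genes below the significance cutoff are DEGs;
the analysis's final product is their intersection with candidate drug
targets, each annotated with the contributing drugs, plus per-group
box-plot summaries and hierarchical clustering of the intersection
genes (average linkage, correlation distance).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess",
    "differential_expression",
    "intersect_deg_targets",
    "group_expression_summary",
    "cluster_genes",
    "GroupDifferentialExpression",
    "DifferentialExpressionResults",
    "read_expression",
    "read_labels",
]


def preprocess(
    matrix: pd.DataFrame, pseudo_count: float = 0.0
) -> tuple[pd.DataFrame, list[str]]:
    """log2-transform, then center and scale each gene row.

    Returns the standardized matrix (row mean 0, row sd 1 with ddof=1)
    and the list of constant genes, whose scaled rows are set to 0.

    Raises
    ------
    ValidationError
        If any value is non-positive and no pseudo-count is supplied.
    """
    values = matrix.to_numpy(dtype=float) + pseudo_count
    if np.any(values <= 0):
        raise ValidationError(
            "expression values must be positive (or pass a pseudo_count)"
        )
    logged = np.log2(values)
    mean = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    scaled = (logged - mean) / sd
    scaled[constant] = 0.0
    flagged = list(matrix.index[constant])
    if flagged:
        logger.warning("preprocess: %d constant gene(s) scaled to 0", len(flagged))
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns), flagged


def _split_groups(
    matrix: pd.DataFrame, labels: Mapping[str, str] | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    lab = pd.Series(labels)
    case_cols = [c for c in matrix.columns if lab.get(c) == "case"]
    ctrl_cols = [c for c in matrix.columns if lab.get(c) == "control"]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (case={len(case_cols)}, "
            f"control={len(ctrl_cols)})"
        )
    return (
        matrix[case_cols].to_numpy(dtype=float),
        matrix[ctrl_cols].to_numpy(dtype=float),
    )


def differential_expression(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    method: str = "welch",
) -> pd.DataFrame:
    """Per-gene two-sided two-sample t-test, case vs control.

    ``method='welch'`` (default) uses unequal variances; ``'pooled'``
    the classic equal-variance test.  Direction is the sign of the
    case-minus-control mean difference; ``is_deg`` flags p strictly
    below ``alpha``.  Genes identical in both groups get statistic 0
    and p = 1.
    """
    if method not in ("welch", "pooled"):
        raise InvalidParameterError(f"unknown method {method!r}")
    case, ctrl = _split_groups(matrix, labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(case, ctrl, axis=1, equal_var=(method == "pooled"))
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    # zero-variance genes: no evidence either way when means agree
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate & (diff == 0), 0.0, t)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    out = pd.DataFrame(
        {
            "gene": matrix.index,
            "statistic": t,
            "p": p,
            "direction": np.where(diff >= 0, "up", "down"),
        }
    )
    out["is_deg"] = out["p"] < alpha
    return out.reset_index(drop=True)


def intersect_deg_targets(
    deg_records: pd.DataFrame,
    drug_target_map,
    alpha: float = 0.05,
    drug_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Genes significant at ``alpha`` that are targets of candidate drugs.

    ``drug_target_map`` is a :class:`~reposcreen.proximity.DrugTargetMap`;
    ``drug_ids`` restricts to a candidate subset (default: all drugs).
    Each intersection gene is annotated with the contributing drugs,
    comma-separated, sorted.
    """
    ids = sorted(drug_ids) if drug_ids is not None else sorted(
        drug_target_map.drugs
    )
    target_to_drugs: dict[str, list[str]] = {}
    for d in ids:
        for t in drug_target_map[d].targets:
            target_to_drugs.setdefault(t, []).append(d)
    sig = deg_records[deg_records["p"] < alpha]
    rows = []
    for rec in sig.itertuples(index=False):
        if rec.gene in target_to_drugs:
            rows.append(
                {
                    "gene": rec.gene,
                    "p": rec.p,
                    "direction": rec.direction,
                    "drugs": ",".join(sorted(target_to_drugs[rec.gene])),
                }
            )
    out = pd.DataFrame(rows, columns=["gene", "p", "direction", "drugs"])
    return out.sort_values(["p", "gene"]).reset_index(drop=True) if len(out) else out


def group_expression_summary(
    matrix: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Box-plot summaries (median, quartiles, 1.5*IQR whiskers, outliers).

    Quartiles use linear interpolation.  Whiskers extend to the most
    extreme data point inside median +/- ... i.e. within
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR]; values outside are listed as outliers.
    """
    unknown = [g for g in genes if g not in matrix.index]
    if unknown:
        raise ValidationError(f"unknown gene(s): {', '.join(map(str, unknown))}")
    lab = pd.Series(labels)
    rows = []
    for gene in genes:
        for group in ("case", "control"):
            cols = [c for c in matrix.columns if lab.get(c) == group]
            x = matrix.loc[gene, cols].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = x[(x >= lo_fence) & (x <= hi_fence)]
            outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "n": x.size,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": inside.min() if inside.size else np.nan,
                    "whisker_high": inside.max() if inside.size else np.nan,
                    "outliers": ",".join(f"{v:.6g}" for v in outliers),
                }
            )
    return pd.DataFrame(rows)


def cluster_genes(
    matrix: pd.DataFrame,
    genes: Sequence[str],
    n_clusters: int = 2,
) -> tuple[dict[str, int], list[str]]:
    """Hierarchical clustering of genes on standardized expression.

    Average linkage on correlation distance (1 - Pearson across
    samples), cut at ``n_clusters``.  Constant rows (undefined
    correlation) are excluded with a warning.  Genes are processed in
    sorted order and cluster labels renumbered by first occurrence, so
    the assignment is invariant to input order.  Returns the label map
    and the dendrogram leaf order.
    """
    from scipy.cluster import hierarchy

    genes = sorted(set(genes))
    if len(genes) < 2:
        raise InvalidParameterError("need at least 2 genes to cluster")
    unknown = [g for g in genes if g not in matrix.index]
    if unknown:
        raise ValidationError(f"unknown gene(s): {', '.join(map(str, unknown))}")
    data = matrix.loc[genes].to_numpy(dtype=float)
    sd = data.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g, k in zip(genes, keep) if not k]
    if dropped:
        logger.warning(
            "cluster_genes: excluded constant gene(s): %s", ", ".join(dropped)
        )
    genes = [g for g, k in zip(genes, keep) if k]
    data = data[keep]
    if len(genes) < 2:
        raise InvalidParameterError("fewer than 2 non-constant genes to cluster")
    data = (data - data.mean(axis=1, keepdims=True)) / data.std(
        axis=1, ddof=1, keepdims=True
    )
    n_clusters = min(n_clusters, len(genes))
    link = hierarchy.linkage(data, method="average", metric="correlation")
    raw = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for g, r in zip(genes, raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[g] = relabel[r]
    order = [genes[i] for i in hierarchy.leaves_list(link)]
    return labels, order


# ---------------------------------------------------------------------------
# Model / Results


class GroupDifferentialExpression:
    """Two-group expression model on a genes x samples matrix.

    Parameters
    ----------
    matrix
        Raw positive expression values (genes x samples).
    labels
        Sample -> 'case' / 'control'.
    pseudo_count
        Added before log2 when zeros are present.
    test_on
        'log2' (default) runs the test on log2 values; 'scaled' on
        centered/scaled values (scaling removes per-gene location, so
        this is mainly for sensitivity checks).
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        labels: Mapping[str, str] | pd.Series,
        pseudo_count: float = 0.0,
        test_on: str = "log2",
    ):
        if test_on not in ("log2", "scaled"):
            raise InvalidParameterError(f"unknown test_on {test_on!r}")
        self.matrix = matrix
        self.labels = pd.Series(labels)
        bad = set(self.labels.unique()) - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        values = matrix.to_numpy(dtype=float) + pseudo_count
        if np.any(values <= 0):
            raise ValidationError(
                "expression values must be positive (or pass a pseudo_count)"
            )
        self.log2 = pd.DataFrame(
            np.log2(values), index=matrix.index, columns=matrix.columns
        )
        self.scaled, self.constant_genes = preprocess(matrix, pseudo_count)
        self.test_on = test_on

    def fit(
        self, alpha: float = 0.05, method: str = "welch"
    ) -> "DifferentialExpressionResults":
        source = self.log2 if self.test_on == "log2" else self.scaled
        table = differential_expression(source, self.labels, alpha, method)
        return DifferentialExpressionResults(self, table, alpha=alpha, method=method)


class DifferentialExpressionResults:
    """Per-gene test statistics with DEG flags and downstream helpers."""

    def __init__(
        self,
        model: GroupDifferentialExpression,
        frame: pd.DataFrame,
        alpha: float,
        method: str,
    ):
        self.model = model
        self.frame = frame
        self.alpha = alpha
        self.method = method

    @property
    def degs(self) -> list[str]:
        return sorted(self.frame.loc[self.frame["is_deg"], "gene"])

    def intersect_targets(
        self, drug_target_map, drug_ids: Iterable[str] | None = None
    ) -> pd.DataFrame:
        return intersect_deg_targets(
            self.frame, drug_target_map, self.alpha, drug_ids
        )

    def group_summary(self, genes: Sequence[str]) -> pd.DataFrame:
        return group_expression_summary(self.model.log2, self.model.labels, genes)

    def cluster(self, genes: Sequence[str], n_clusters: int = 2):
        return cluster_genes(self.model.scaled, genes, n_clusters)

    def summary(self) -> str:
        n = len(self.frame)
        n_deg = int(self.frame["is_deg"].sum())
        lines = [
            "Two-group differential expression",
            "=" * 56,
            f"Genes tested: {n}   method: {self.method}   "
            f"alpha: {self.alpha}",
            f"DEGs (p < {self.alpha}): {n_deg} "
            f"({100 * n_deg / max(n, 1):.1f}%)",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# I/O


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column = gene symbols)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``sample group`` into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValidationError(
            f"{path}: expected header 'sample<TAB>group', got {list(df.columns)}"
        )
    return pd.Series(df["group"].to_numpy(), index=df["sample"], name="group")
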