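"""Per-subgroup feature vectors, Pearson correlation, hierarchical clustering.

Subgroups (not samples) are clustered: each subgroup is described by its
alteration-frequency column plus two expression means (CDK6 fold-change and
a proliferation score), features are z-scored across subgroups (percent and
fold units are mixed), and agglomerative clustering runs on the Pearson
correlation distance d = 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from . import _catalog as cat
from .classifier import SubgroupCall
from .cohort import Cohort, ExpressionProfile
from .pathways import CohortSummary

#: Single-gene rows below this whole-cohort frequency (percent) are dropped
#: from the default feature set as uninformative; composite rows are always
#: kept.
MIN_TOTAL_PCT = 10.0
COMPOSITE_ROWS = frozenset(
    name for name, kind, _ in cat.FEATURE_ROWS
    if kind in ("composite", "tert", "mgmt"))


@dataclass(frozen=True)
class ClusterConfig:
    linkage: str = "average"           # average | complete | single
    zscore: bool = True
    min_total_pct: float = MIN_TOTAL_PCT
    include_features: tuple[str, ...] | None = None  # explicit mask override
    expression_means: bool = True      # append CDK6 + proliferation means


def proliferation_score(expression: ExpressionProfile,
                        marker_genes: tuple[str, ...] = ("MKI67",)
                        ) -> float | None:
    """Compound proliferation parameter: mean fold-change over the marker
    genes (MKI67 by default); None when no marker is present."""
    folds = [expression.fold(g) for g in marker_genes
             if expression.fold(g) is not None]
    if not folds:
        return None
    return float(np.mean(folds))


def default_feature_mask(summary: CohortSummary,
                         config: ClusterConfig) -> list[str]:
    if config.include_features is not None:
        return list(config.include_features)
    wt_cols = [s for s in cat.IDH_WT_SUBGROUPS if s in summary.matrix.columns]
    num = summary.numerators[wt_cols].sum(axis=1)
    den = summary.denominators[wt_cols].sum(axis=1)
    total = 100.0 * num / den.where(den > 0)
    keep = []
    for name in summary.matrix.index:
        if name in COMPOSITE_ROWS or total[name] >= config.min_total_pct:
            keep.append(name)
    return keep


def build_feature_vectors(summary: CohortSummary,
                          cohort: Cohort | None = None,
                          subgroup_calls: dict[str, SubgroupCall] | None = None,
                          config: ClusterConfig = ClusterConfig()
                          ) -> pd.DataFrame:
    """Features x subgroups matrix: frequency rows plus (optionally) the
    mean CDK6 fold and mean proliferation score of each subgroup's
    expression-profiled cases."""
    mask = default_feature_mask(summary, config)
    vectors = summary.matrix.loc[mask].copy()
    if config.expression_means:
        if cohort is None or subgroup_calls is None:
            raise ValueError("expression means require cohort and calls")
        cdk6 = {}
        prolif = {}
        for label in vectors.columns:
            folds, scores = [], []
            for case in cohort:
                if subgroup_calls[case.case_id].label != label:
                    continue
                if case.expression is None:
                    continue
                f = case.expression.fold("CDK6")
                if f is not None:
                    folds.append(f)
                p = proliferation_score(case.expression)
                if p is not None:
                    scores.append(p)
            cdk6[label] = float(np.mean(folds)) if folds else np.nan
            prolif[label] = float(np.mean(scores)) if scores else np.nan
        vectors.loc["CDK6_mean_fold"] = pd.Series(cdk6)
        vectors.loc["proliferation_mean"] = pd.Series(prolif)
    if vectors.isna().any().any():
        bad = vectors.columns[vectors.isna().any()].tolist()
        raise ValueError(f"missing feature values for subgroups: {bad}")
    return vectors


def correlation_matrix(vectors: pd.DataFrame,
                       zscore: bool = True) -> pd.DataFrame:
    """Pearson correlation between subgroup feature vectors."""
    if vectors.shape[1] < 2 or vectors.shape[0] < 3:
        raise ValueError("need >= 2 subgroups and >= 3 features")
    sd = vectors.std(axis=1, ddof=0)
    flat = vectors.index[sd == 0].tolist()
    X = vectors.to_numpy(float)
    if zscore:
        if flat:
            raise ValueError(f"zero-variance features: {flat}")
        X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=0, keepdims=True)
    col_sd = X.std(axis=0, ddof=0)
    if (col_sd == 0).any():
        bad = vectors.columns[col_sd == 0].tolist()
        raise ValueError(f"zero-variance subgroup vector(s): {bad}")
    r = np.corrcoef(X.T)
    return pd.DataFrame(r, index=vectors.columns, columns=vectors.columns)


@dataclass
class Dendrogram:
    """Nested binary tree with merge heights over subgroup labels."""

    labels: list[str]
    linkage_matrix: np.ndarray
    method: str

    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage_matrix[:, 2]]

    def subtrees(self) -> set[frozenset]:
        """Every internal node's leaf set."""
        members: dict[int, frozenset] = {
            i: frozenset({lab}) for i, lab in enumerate(self.labels)}
        out: set[frozenset] = set()
        n = len(self.labels)
        for i, (a, b, _, _) in enumerate(self.linkage_matrix):
            m = members[int(a)] | members[int(b)]
            members[n + i] = m
            out.add(m)
        return out

    def to_newick(self) -> str:
        """Newick string with branch lengths = difference of merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + i] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + i] = h
        return node[n + len(self.linkage_matrix) - 1] + ";"


def cluster_subgroups(corr: pd.DataFrame,
                      linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering on d = 1 - r.

    Labels are canonicalized (lexicographic order) before linkage so the
    result is invariant to input permutation and deterministic under ties.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    labels = sorted(corr.columns)
    corr = corr.loc[labels, labels]
    d = 1.0 - corr.to_numpy(float)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    Z = sch.linkage(condensed, method=linkage)
    return Dendrogram(labels=list(labels), linkage_matrix=Z, method=linkage)
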