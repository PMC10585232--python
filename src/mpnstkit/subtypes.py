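"""Unsupervised transcriptomic subtype discovery.

Samples are clustered by consensus non-negative matrix factorization: the
variance-filtered log2 matrix is shifted to be non-negative, factorised at a
fixed rank over many restarts (each on a random 80% gene subsample with a
fresh random initialisation), and the per-restart sample labels (argmax of
the mixture coefficients) are accumulated into a sample x sample consensus
matrix.  The final partition is an average-linkage hierarchical cut of
``1 - consensus``; the cophenetic correlation of that dendrogram against the
consensus distances measures cluster stability.  Clusters are named by their
mean single-sample immune enrichment score: the lower-scoring cluster is the
immune-deficient subtype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from sklearn.decomposition import NMF

from .containers import ExpressionMatrix
from .errors import ArgumentError, DataError

ACTIVE = "immune_active"
DEFICIENT = "immune_deficient"


@dataclass
class SubtypeConfig:
    variance_threshold: float = 0.3
    rank: int = 2
    n_restarts: int = 50
    subsample_frac: float = 0.8
    max_iter: int = 400
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 2:
            raise ArgumentError("rank must be >= 2")
        if self.n_restarts < 2:
            raise ArgumentError("need >= 2 restarts")
        if self.tol <= 0:
            raise ArgumentError("tol must be > 0")


@dataclass
class SubtypeAssignment:
    labels: pd.Series              # sample -> cluster id (0-based ints)
    consensus: pd.DataFrame        # sample x sample co-clustering frequency
    cophenetic: float
    names: dict[int, str] = field(default_factory=dict)

    def named_labels(self) -> pd.Series:
        if not self.names:
            raise ArgumentError("subtypes have not been named yet")
        return self.labels.map(self.names)


def select_variable_genes(expr: ExpressionMatrix, threshold: float = 0.3,
                          samples: list[str] | None = None) -> list[str]:
    """Genes with sample variance strictly above ``threshold`` (log2 scale)."""
    values = expr.values[samples] if samples is not None else expr.values
    if values.shape[1] < 2:
        raise DataError("need at least two samples to compute variances")
    variances = values.var(axis=1, ddof=1)
    return list(variances.index[variances > threshold])


def nmf_consensus(expr: ExpressionMatrix, config: SubtypeConfig | None = None,
                  samples: list[str] | None = None) -> SubtypeAssignment:
    """Consensus-NMF partition of samples; deterministic given ``config.seed``."""
    cfg = config or SubtypeConfig()
    values = expr.values[samples] if samples is not None else expr.values
    sample_ids = list(values.columns)
    n = len(sample_ids)
    if n < cfg.rank:
        raise ArgumentError(f"{n} samples cannot support rank {cfg.rank}")
    x = values.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DataError("constant expression matrix: no structure to factorise")
    x = x - x.min()  # NMF requires non-negativity; log2 data is shifted by its minimum
    rng = np.random.default_rng(cfg.seed)
    co = np.zeros((n, n))
    n_sub = max(cfg.rank, int(round(cfg.subsample_frac * x.shape[0])))
    for _ in range(cfg.n_restarts):
        rows = rng.choice(x.shape[0], size=n_sub, replace=False)
        model = NMF(n_components=cfg.rank, init="random", solver="mu",
                    beta_loss="frobenius", max_iter=cfg.max_iter, tol=cfg.tol,
                    random_state=int(rng.integers(2**31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = model.fit(x[rows]).components_  # rank x samples
        lab = h.argmax(axis=0)
        co += lab[:, None] == lab[None, :]
    consensus = co / cfg.n_restarts
    np.fill_diagonal(consensus, 1.0)
    dist = squareform(1.0 - consensus, checks=False)
    linkage = average(dist)
    labels = fcluster(linkage, t=cfg.rank, criterion="maxclust") - 1
    if dist.std() == 0:
        coph = 0.0  # all consensus distances equal: stability undefined, report 0
    else:
        coph = float(cophenet(linkage, dist)[0])
    return SubtypeAssignment(
        labels=pd.Series(labels, index=sample_ids),
        consensus=pd.DataFrame(consensus, index=sample_ids, columns=sample_ids),
        cophenetic=coph,
    )


def name_subtypes(assignment: SubtypeAssignment, expr: ExpressionMatrix,
                  immune_sets: dict[str, list[str]]) -> SubtypeAssignment:
    """Attach immune_active / immune_deficient names by mean immune score.

    The cluster with the lower mean single-sample immune enrichment score is
    the deficient one; exact ties break toward the smaller cluster id with a
    warning.
    """
    from .enrichment import ssgsva  # local import to avoid a cycle

    usable = {name: [g for g in genes if g in expr.values.index]
              for name, genes in immune_sets.items()}
    usable = {k: v for k, v in usable.items() if len(v) >= 2}
    if not usable:
        raise DataError("immune gene sets share no genes with the expression matrix")
    samples = list(assignment.labels.index)
    scores = ssgsva(ExpressionMatrix(expr.values[samples],
                                     expr.groups.reindex(samples)), usable)
    immune_score = scores.mean(axis=0)
    cluster_ids = sorted(assignment.labels.unique())
    if len(cluster_ids) != 2:
        raise ArgumentError("naming requires exactly two clusters")
    means = {cid: immune_score[assignment.labels[assignment.labels == cid].index].mean()
             for cid in cluster_ids}
    if np.isclose(means[cluster_ids[0]], means[cluster_ids[1]]):
        warnings.warn("immune score tie between clusters; lower cluster id named deficient")
        deficient = cluster_ids[0]
    else:
        deficient = min(cluster_ids, key=lambda c: means[c])
    names = {cid: (DEFICIENT if cid == deficient else ACTIVE) for cid in cluster_ids}
    return SubtypeAssignment(labels=assignment.labels, consensus=assignment.consensus,
                             cophenetic=assignment.cophenetic, names=names)


@dataclass
class PCAResult:
    scores: pd.DataFrame           # samples x components
    loadings: pd.DataFrame         # genes x components
    explained_variance_ratio: np.ndarray
    separation_p: pd.Series | None = None  # per component, if groups were given


def pca_scores(expr: ExpressionMatrix, n_components: int = 5,
               groups: dict[str, list[str]] | None = None) -> PCAResult:
    """Sample PCA of the expression matrix (genes centred).

    Components are oriented so each one's largest-magnitude gene loading is
    positive.  When two sample groups are supplied, each component gets a
    two-sided rank-sum p-value for group separation along it.
    """
    values = expr.values
    if values.shape[1] < 3:
        raise ArgumentError("PCA needs at least three samples")
    x = values.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    if not np.any(x):
        raise DataError("zero-variance matrix: PCA undefined")
    k = min(n_components, min(x.shape) - 1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for c in range(k):  # sign convention: largest |loading| positive
        j = np.argmax(np.abs(u[:, c]))
        if u[j, c] < 0:
            u[:, c] *= -1
            vt[c] *= -1
    scores = pd.DataFrame((vt.T * s), index=values.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    loadings = pd.DataFrame(u, index=values.index, columns=scores.columns)
    evr = s**2 / np.sum(np.linalg.svd(x, compute_uv=False)**2)
    sep = None
    if groups is not None:
        if len(groups) != 2:
            raise ArgumentError("separation test needs exactly two groups")
        (ga, gb) = groups.values()
        ps = {}
        for pc in scores.columns:
            ps[pc] = float(mannwhitneyu(scores.loc[ga, pc], scores.loc[gb, pc],
                                        alternative="two-sided").pvalue)
        sep = pd.Series(ps)
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=evr, separation_p=sep)
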