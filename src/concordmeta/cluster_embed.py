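"""Study embedding (PCA) and hierarchical clustering with bootstrap support.

Studies are embedded by PCA of their signature-union feature matrices
(studies as observations, genes as features, optionally standardized).
Hierarchical clustering uses correlation distance, which depends only on
the direction of expression changes and so is not dominated by studies
with inflated fold-change magnitudes.  Cluster stability is assessed by
multiscale bootstrap resampling of gene columns: bootstrap probabilities
(BP) at several resample sizes are combined through a probit-scale fit
into approximately unbiased (AU) support values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform
from scipy.stats import norm

from concordmeta.signatures import FeatureMatrix
from concordmeta.study_io import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


@dataclass(frozen=True)
class EmbeddingResult:
    """PCA embedding of studies in signature space."""

    studies: tuple[str, ...]
    scores: np.ndarray          # studies x components
    loadings: np.ndarray        # genes x components
    variance_explained: np.ndarray
    genes: tuple[str, ...]


@dataclass(frozen=True)
class ClusterNode:
    """One internal node of the dendrogram."""

    leafset: frozenset[str]
    height: float
    bp: float | None = None
    au: float | None = None


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge tree over studies.

    ``merges`` is a (n-1, 2) array in scipy linkage convention: row k merges
    clusters ``merges[k, 0]`` and ``merges[k, 1]`` (ids < n are leaves,
    id n+k is the cluster created by row k) at ``heights[k]``.
    """

    studies: tuple[str, ...]
    merges: np.ndarray
    heights: np.ndarray
    linkage: str
    nodes: tuple[ClusterNode, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.linkage not in ("average", "complete"):
            raise ValidationError("linkage must be 'average' or 'complete'")

    def leafsets(self) -> list[frozenset[str]]:
        """Leafset of each internal node, in merge order."""
        n = len(self.studies)
        sets: list[frozenset[str]] = [frozenset([s]) for s in self.studies]
        out = []
        for a, b in self.merges.astype(int):
            merged = sets[a] | sets[b]
            sets.append(merged)
            out.append(merged)
        return out

    def cut(self, k: int) -> dict[str, int]:
        """Assign studies to k clusters by cutting the tree."""
        n = len(self.studies)
        if not (1 <= k <= n):
            raise ValidationError(f"k={k} not in [1, {n}]")
        z = np.column_stack(
            [self.merges.astype(float), self.heights, np.zeros(len(self.heights))]
        )
        # counts column required by scipy cut_tree
        sizes = np.ones(2 * n - 1)
        for row, (a, b) in enumerate(self.merges.astype(int)):
            sizes[n + row] = sizes[a] + sizes[b]
        z[:, 3] = sizes[n:]
        labels = _hier.cut_tree(z, n_clusters=k).ravel()
        return dict(zip(self.studies, labels.tolist()))

    def newick(self) -> str:
        """Newick export with AU support as internal node labels."""
        n = len(self.studies)
        reprs: list[str] = [s for s in self.studies]
        support = {i + n: node.au for i, node in enumerate(self.nodes)} if self.nodes else {}
        for row, (a, b) in enumerate(self.merges.astype(int)):
            label = ""
            au = support.get(row + n)
            if au is not None:
                label = f"{au:.3f}"
            reprs.append(f"({reprs[a]},{reprs[b]}){label}")
        return reprs[-1] + ";"


def pca_embed(
    fm: FeatureMatrix, center: bool = True, scale: bool = True
) -> EmbeddingResult:
    """PCA of the studies x genes feature matrix.

    Zero-variance gene columns are dropped before standardization.  The
    sign of each component is fixed so that its largest-|loading| gene has
    a positive loading, making the embedding reproducible.
    """
    if len(fm.studies) < 2:
        raise ValidationError("need at least two studies for PCA")
    x = fm.values.copy()
    variances = x.var(axis=0)
    keep = variances > 0
    if keep.sum() < 2:
        raise ValidationError("fewer than two non-constant gene columns")
    if (~keep).any():
        logger.info("PCA: dropped %d zero-variance gene columns", int((~keep).sum()))
    x = x[:, keep]
    genes = tuple(g for g, k in zip(fm.genes, keep) if k)
    if center:
        x = x - x.mean(axis=0)
    if scale:
        x = x / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate positive per component
    for comp in range(vt.shape[0]):
        pivot = int(np.argmax(np.abs(vt[comp])))
        if vt[comp, pivot] < 0:
            vt[comp] *= -1
            u[:, comp] *= -1
    scores = u * s
    total = float((s**2).sum())
    var_explained = s**2 / total if total > 0 else np.zeros_like(s)
    return EmbeddingResult(
        studies=fm.studies,
        scores=scores,
        loadings=vt.T,
        variance_explained=var_explained,
        genes=genes,
    )


def correlation_distance(fm: FeatureMatrix) -> np.ndarray:
    """Pairwise correlation distance d_ij = 1 - Pearson(row_i, row_j)."""
    x = fm.values
    if x.shape[0] < 2:
        raise ValidationError("need at least two studies")
    stds = x.std(axis=1)
    flat = np.nonzero(stds == 0)[0]
    if flat.size:
        raise ValidationError(
            f"constant feature row for study {fm.studies[flat[0]]!r}; "
            "correlation distance is undefined"
        )
    d = 1.0 - np.corrcoef(x)
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


def hierarchical_cluster(
    dist: np.ndarray,
    studies: tuple[str, ...] | list[str],
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of a study distance matrix.

    Backed by the standard linkage algorithm; average and complete linkage
    produce monotone (inversion-free) merge heights.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T, atol=1e-10):
        raise ValidationError("distance matrix must be square and symmetric")
    if n != len(studies):
        raise ValidationError("distance matrix does not match study list")
    if linkage not in ("average", "complete"):
        raise ValidationError("linkage must be 'average' or 'complete'")
    z = _hier.linkage(squareform(dist, checks=False), method=linkage)
    return ClusterTree(
        studies=tuple(studies),
        merges=z[:, :2].astype(int),
        heights=z[:, 2].copy(),
        linkage=linkage,
    )


def _bootstrap_counts(
    fm: FeatureMatrix,
    linkage: str,
    target_sets: list[frozenset[str]],
    n_cols: int,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """How often each target leafset reappears over n_boot gene resamples."""
    x = fm.values
    n_studies, n_genes = x.shape
    counts = np.zeros(len(target_sets), dtype=int)
    index = {s: i for i, s in enumerate(target_sets)}
    studies = fm.studies
    for _ in range(n_boot):
        cols = rng.integers(0, n_genes, size=n_cols)
        xb = x[:, cols]
        stds = xb.std(axis=1)
        if (stds == 0).any():
            # a study drew a constant resample: no defined correlation; the
            # replicate supports no cluster containing it
            ok = stds > 0
            if ok.sum() < 4:
                continue
            sub = xb[ok]
            d = np.clip(1.0 - np.corrcoef(sub), 0, 2)
            np.fill_diagonal(d, 0.0)
            z = _hier.linkage(squareform((d + d.T) / 2, checks=False), method=linkage)
            kept = [s for s, o in zip(studies, ok) if o]
        else:
            d = np.clip(1.0 - np.corrcoef(xb), 0, 2)
            np.fill_diagonal(d, 0.0)
            z = _hier.linkage(squareform((d + d.T) / 2, checks=False), method=linkage)
            kept = list(studies)
        m = len(kept)
        sets: list[frozenset[str]] = [frozenset([s]) for s in kept]
        for a, b in z[:, :2].astype(int):
            merged = sets[a] | sets[b]
            sets.append(merged)
            hit = index.get(merged)
            if hit is not None:
                counts[hit] += 1
    return counts


def multiscale_bootstrap(
    fm: FeatureMatrix,
    linkage: str = "average",
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot: int = 1000,
    seed: int | None = None,
) -> ClusterTree:
    """Cluster studies and attach multiscale-bootstrap AU/BP support values.

    For each scale r, round(r * n_genes) gene columns are resampled with
    replacement n_boot times; BP_r of an internal node is the fraction of
    replicates in which its exact leafset reappears.  Probit-transformed
    BP_r values (clamped away from 0/1) are fitted by weighted least
    squares to v*sqrt(r) + c/sqrt(r); the approximately unbiased support is
    AU = 1 - Phi(v - c).  Nodes saturated at BP 0 (never seen) or BP 1 at
    every scale fall back to that saturated value, as do nodes with fewer
    than two informative scales.
    """
    if len(fm.studies) < 4:
        raise ValidationError("need at least four studies for bootstrap support")
    if fm.values.shape[1] < 10:
        raise ValidationError("need at least ten feature columns for bootstrap support")
    if len(scales) < 2:
        raise ValidationError("need at least two scales")
    dist = correlation_distance(fm)
    tree = hierarchical_cluster(dist, fm.studies, linkage)
    target_sets = tree.leafsets()
    n_genes = fm.values.shape[1]
    rng = np.random.default_rng(seed)

    bp_by_scale = np.zeros((len(scales), len(target_sets)))
    for si, r in enumerate(scales):
        n_cols = max(2, int(round(r * n_genes)))
        counts = _bootstrap_counts(fm, linkage, target_sets, n_cols, n_boot, rng)
        bp_by_scale[si] = counts / n_boot

    aus, bps = _fit_au(bp_by_scale, np.asarray(scales, dtype=float), n_boot)
    nodes = tuple(
        ClusterNode(leafset=ls, height=float(h), bp=float(bp), au=float(au))
        for ls, h, bp, au in zip(target_sets, tree.heights, bps, aus)
    )
    return ClusterTree(
        studies=tree.studies,
        merges=tree.merges,
        heights=tree.heights,
        linkage=linkage,
        nodes=nodes,
    )


def _fit_au(
    bp_by_scale: np.ndarray, scales: np.ndarray, n_boot: int
) -> tuple[np.ndarray, np.ndarray]:
    """AU values from per-scale bootstrap probabilities.

    The probit fit uses only informative scales (0 < BP < 1); saturated
    nodes take their plain bootstrap probability at scale 1 instead.
    """
    n_nodes = bp_by_scale.shape[1]
    r1 = int(np.argmin(np.abs(scales - 1.0)))
    bp_at_1 = bp_by_scale[r1].copy()
    aus = np.empty(n_nodes)
    eps_lo, eps_hi = 1.0 / (n_boot + 1), n_boot / (n_boot + 1)
    sqrt_r = np.sqrt(scales)
    for node in range(n_nodes):
        bp = bp_by_scale[:, node]
        informative = (bp > 0) & (bp < 1)
        if informative.sum() < 2:
            # degenerate: the cluster (almost) always or never reappears, so
            # the probit fit has nothing to work with; report plain BP
            aus[node] = bp_at_1[node]
            logger.debug(
                "node %d: <2 informative scales, AU falls back to plain BP", node
            )
            continue
        bpc = np.clip(bp[informative], eps_lo, eps_hi)
        z = norm.ppf(1.0 - bpc)
        x1 = sqrt_r[informative]
        design = np.column_stack([x1, 1.0 / x1])
        weights = n_boot / (bpc * (1.0 - bpc))
        wsq = np.sqrt(weights)
        coef, *_ = np.linalg.lstsq(design * wsq[:, None], z * wsq, rcond=None)
        v, c = coef
        aus[node] = float(1.0 - norm.cdf(v - c))
    return aus, bp_at_1


def export_embedding_tsv(embedding: EmbeddingResult, path) -> None:
    """Write PCA scores with a trailing variance-explained row."""
    import pandas as pd

    k = embedding.scores.shape[1]
    cols = [f"PC{i+1}" for i in range(k)]
    frame = pd.DataFrame(embedding.scores, index=list(embedding.studies), columns=cols)
    frame.loc["__variance_explained__"] = embedding.variance_explained
    frame.to_csv(path, sep="\t", index_label="study_id")
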