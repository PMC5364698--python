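"""Pairwise and subgroup concordance of differential expression signatures.

Concordance between two studies is the Pearson correlation of their logFC
values (or their signs) over the union of the two studies' expression
signatures; both studies always carry a stored value for every support gene
because signatures are drawn from the shared universe.  Subgroup averages
A_S are tested against a resampling null: the 95th percentile of A_S over
randomly sampled subgroups of the same size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from concordmeta.signatures import ExpressionSignature
from concordmeta.study_io import DEProfile, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceMatrix:
    """Symmetric study x study matrix of pairwise concordances."""

    studies: tuple[str, ...]
    c: np.ndarray
    level: str = "gene"  # gene | sign | pathway

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        n = len(self.studies)
        if c.shape != (n, n):
            raise ValidationError(f"matrix shape {c.shape} != ({n}, {n})")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValidationError("concordance matrix is not symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValidationError("concordance matrix diagonal must be 1")
        if np.nanmax(np.abs(c)) > 1 + 1e-9:
            raise ValidationError("concordance values must lie in [-1, 1]")
        object.__setattr__(self, "c", c)

    def index_of(self, study_id: str) -> int:
        try:
            return self.studies.index(study_id)
        except ValueError:
            raise KeyError(f"unknown study {study_id!r}") from None

    def submatrix(self, subset: Sequence[str]) -> np.ndarray:
        idx = np.array([self.index_of(s) for s in subset])
        return self.c[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.c, index=list(self.studies), columns=list(self.studies))


@dataclass(frozen=True)
class SubgroupResult:
    """Significance call for one subgroup of studies."""

    label: str
    subset: tuple[str, ...]
    a_s: float
    a_i: dict[str, float]
    null_threshold: float
    n_null: int
    significant: bool
    seed: int | None = None


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson correlation; caller guarantees non-degenerate input."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc) / denom


def pairwise_concordance(
    profile_i: DEProfile,
    profile_j: DEProfile,
    sig_i: ExpressionSignature,
    sig_j: ExpressionSignature,
    mode: str = "logfc",
    support: str = "union",
) -> float:
    """Pearson correlation of two studies' logFC over their signature support.

    The support set is the union (default) or intersection of the two
    signatures' genes; each study contributes its own stored logFC for every
    support gene.  With ``mode='sign'`` the correlation is computed on the
    sign of the fold changes.  Degenerate supports (< 3 genes, or a constant
    vector) yield 0 with a logged warning, mirroring the convention used at
    the pathway level when information is absent.
    """
    if mode not in ("logfc", "sign"):
        raise ValueError("mode must be 'logfc' or 'sign'")
    if support == "union":
        genes = sorted(set(sig_i.genes) | set(sig_j.genes))
    elif support == "intersection":
        genes = sorted(set(sig_i.genes) & set(sig_j.genes))
    else:
        raise ValueError("support must be 'union' or 'intersection'")
    if len(genes) < 3:
        logger.warning(
            "%s vs %s: support of %d genes too small; concordance set to 0",
            profile_i.study_id, profile_j.study_id, len(genes),
        )
        return 0.0
    x = profile_i.logfc(genes)
    y = profile_j.logfc(genes)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError(
            f"{profile_i.study_id}/{profile_j.study_id}: signatures reference "
            "genes absent from a profile; were they drawn from the same universe?"
        )
    if mode == "sign":
        x, y = np.sign(x), np.sign(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning(
            "%s vs %s: constant vector on support; concordance set to 0",
            profile_i.study_id, profile_j.study_id,
        )
        return 0.0
    return _pearson(x, y)


def concordance_matrix(
    profiles: Sequence[DEProfile],
    signatures: Sequence[ExpressionSignature],
    mode: str = "logfc",
    support: str = "union",
) -> ConcordanceMatrix:
    """All-pairs concordance matrix (symmetric, unit diagonal)."""
    if len(profiles) < 2:
        raise ValidationError("need at least two studies")
    if [p.study_id for p in profiles] != [s.study_id for s in signatures]:
        raise ValidationError("profiles and signatures must align by study_id")
    n = len(profiles)
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            cij = pairwise_concordance(
                profiles[i], profiles[j], signatures[i], signatures[j],
                mode=mode, support=support,
            )
            c[i, j] = c[j, i] = cij
    level = "sign" if mode == "sign" else "gene"
    return ConcordanceMatrix(
        studies=tuple(p.study_id for p in profiles), c=c, level=level
    )


def _subset_average_from_sub(sub: np.ndarray) -> tuple[float, np.ndarray]:
    """(A_S, per-study A_i) from a subgroup's concordance submatrix."""
    m = sub.shape[0]
    a_i = (sub.sum(axis=1) - np.diag(sub)) / (m - 1)
    return float(a_i.mean()), a_i


def subset_average(
    matrix: ConcordanceMatrix, subset: Sequence[str]
) -> tuple[float, dict[str, float]]:
    """Average concordance A_S of a subgroup and its per-study averages A_i.

    A_i is study i's mean concordance with the other subgroup members; A_S
    is the mean of the A_i, which equals the mean off-diagonal entry of the
    subgroup's submatrix.
    """
    subset = list(subset)
    if len(subset) < 2:
        raise ValidationError("subset must contain at least two studies")
    if len(set(subset)) != len(subset):
        raise ValidationError("subset contains duplicate study ids")
    sub = matrix.submatrix(subset)
    a_s, a_i = _subset_average_from_sub(sub)
    return a_s, dict(zip(subset, a_i.tolist()))


def _sampled_subset_averages(
    c: np.ndarray, m: int, n_samples: int, rng: np.random.Generator,
    chunk: int = 20000,
) -> np.ndarray:
    """A_S values of ``n_samples`` uniform random m-subsets (with repetition
    across draws), computed in vectorized chunks."""
    n = c.shape[0]
    out = np.empty(n_samples)
    done = 0
    offdiag = m * (m - 1)
    while done < n_samples:
        b = min(chunk, n_samples - done)
        # first m columns of random permutations = uniform m-subsets
        idx = np.argsort(rng.random((b, n)), axis=1)[:, :m]
        sub = c[idx[:, :, None], idx[:, None, :]]
        totals = sub.sum(axis=(1, 2)) - m  # drop unit diagonal
        out[done:done + b] = totals / offdiag
        done += b
    return out


def _enumerated_subset_averages(c: np.ndarray, m: int) -> np.ndarray:
    """A_S over every m-subset of the studies, in combination order."""
    n = c.shape[0]
    combos = np.array(list(combinations(range(n), m)))
    sub = c[combos[:, :, None], combos[:, None, :]]
    return (sub.sum(axis=(1, 2)) - m) / (m * (m - 1))


def null_subset_averages(
    matrix: ConcordanceMatrix,
    subset_size: int,
    max_samples: int = 100_000,
    seed: int | None = None,
) -> np.ndarray:
    """Null distribution of A_S over random subgroups of a given size.

    All subgroups are enumerated when there are at most ``max_samples`` of
    them; otherwise ``max_samples`` subgroups are drawn uniformly at random
    (independently, duplicates allowed) from the seeded generator.
    """
    n = len(matrix.studies)
    m = subset_size
    if m < 2 or m > n:
        raise ValidationError(f"subset size {m} not in [2, {n}]")
    n_subsets = math.comb(n, m)
    if n_subsets <= max_samples:
        return _enumerated_subset_averages(matrix.c, m)
    rng = np.random.default_rng(seed)
    return _sampled_subset_averages(matrix.c, m, max_samples, rng)


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile of the ordered values (no interpolation)."""
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    ordered = np.sort(np.asarray(values, dtype=float))
    rank = max(1, math.ceil(q * len(ordered)))
    return float(ordered[rank - 1])


def null_threshold(
    matrix: ConcordanceMatrix,
    subset_size: int,
    q: float = 0.95,
    max_samples: int = 100_000,
    seed: int | None = None,
) -> tuple[float, int]:
    """Significance threshold for subgroup concordance at a given size.

    Returns ``(threshold, n_null)`` where the threshold is the nearest-rank
    q-quantile of the null A_S distribution; a subgroup is significant iff
    its A_S strictly exceeds it.  Smaller subgroups have wider nulls and
    hence higher thresholds.
    """
    values = null_subset_averages(matrix, subset_size, max_samples, seed)
    return nearest_rank_quantile(values, q), len(values)


def subgroup_significance(
    matrix: ConcordanceMatrix,
    subset: Sequence[str],
    label: str = "",
    q: float = 0.95,
    max_samples: int = 100_000,
    seed: int | None = None,
) -> SubgroupResult:
    """Test whether a subgroup's A_S beats the resampling null for its size."""
    a_s, a_i = subset_average(matrix, subset)
    threshold, n_null = null_threshold(
        matrix, len(subset), q=q, max_samples=max_samples, seed=seed
    )
    return SubgroupResult(
        label=label or "+".join(subset),
        subset=tuple(subset),
        a_s=a_s,
        a_i=a_i,
        null_threshold=threshold,
        n_null=n_null,
        significant=bool(a_s > threshold),
        seed=seed,
    )


def sample_size_regression(
    a_i: Mapping[str, float], sizes: Mapping[str, int]
) -> tuple[float, float, float, float]:
    """OLS of per-study average concordance on total sample size.

    Returns ``(slope, intercept, p_slope, r_squared)`` with a two-sided
    t-test p-value for the slope.  Used to ask whether smaller studies are
    systematically less concordant with the rest of the corpus.
    """
    studies = sorted(a_i)
    if len(studies) < 3:
        raise ValidationError("need at least three studies for the regression")
    missing = [s for s in studies if s not in sizes]
    if missing:
        raise ValidationError(f"no sample size for studies {missing[:5]}")
    y = np.array([a_i[s] for s in studies], dtype=float)
    x = np.array([sizes[s] for s in studies], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("sample sizes are constant; slope is undefined")
    if np.ptp(y) == 0:
        # flat response: slope 0 exactly, no linear trend to test
        return 0.0, float(y[0]), 1.0, 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue), float(res.rvalue**2)
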