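"""Preranked gene set enrichment analysis and pathway-level concordance.

Genes are ranked by signed log2 fold change; each pathway's enrichment
score (ES) is the maximal deviation of a weighted Kolmogorov-Smirnov
running sum over the ranked list (hits add their |score|^w share, misses
subtract a constant).  Significance comes from gene-label permutations of
the ranked list: the normalized enrichment score (NES) divides the ES by
the mean |null ES| of matching sign, nominal p-values are same-sign null
tail fractions, and FDR q-values follow the standard NES-pooling recipe.

Pathway-level concordance between two studies is the Pearson correlation
of NES values over pathways significant (FDR below a cutoff) in either
study, with 0 imputed where a study reports no score for a pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from concordmeta.study_io import DEProfile, PathwayDB, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GseaConfig:
    """Preranked GSEA parameters.

    n_perm: gene-label permutations for the null (1000 is conventional).
    min_size/max_size: pathway size bounds after intersection with the
        ranked list; small sets give unstable ES.
    weight_exponent: 0 gives the classic unweighted KS statistic, 1 weights
        hits by |score|.
    fdr_cutoff: significance cutoff on FDR q used downstream (0.25 is the
        conventional exploratory threshold).
    """

    n_perm: int = 1000
    min_size: int = 10
    max_size: int | None = None
    weight_exponent: float = 1.0
    fdr_cutoff: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.max_size is not None and self.max_size < self.min_size:
            raise ValueError("max_size must be >= min_size")


@dataclass(frozen=True)
class EnrichmentProfile:
    """One study's pathway enrichment table.

    ``rows`` is indexed by pathway_id with columns size, es, nes,
    p_nominal, fdr_q; only pathways passing the size filter appear.
    """

    study_id: str
    rows: pd.DataFrame = field(repr=False)
    db_fingerprint: int = 0

    def __post_init__(self) -> None:
        expected = ["size", "es", "nes", "p_nominal", "fdr_q"]
        if list(self.rows.columns) != expected:
            raise ValidationError(
                f"{self.study_id}: enrichment rows must have columns {expected}"
            )
        if len(self.rows):
            q = self.rows["fdr_q"].to_numpy()
            if (q < 0).any() or (q > 1).any():
                raise ValidationError(f"{self.study_id}: fdr_q outside [0, 1]")

    def __len__(self) -> int:
        return len(self.rows)

    def significant(self, fdr_cutoff: float) -> list[str]:
        return self.rows.index[self.rows["fdr_q"] < fdr_cutoff].tolist()


def rank_genes(profile: DEProfile) -> list[tuple[str, float]]:
    """Genes sorted by signed logFC descending; ties break lexicographically."""
    if len(profile) == 0:
        raise ValidationError(f"{profile.study_id}: empty profile cannot be ranked")
    items = [(g, float(v)) for g, v in profile.table["logfc"].items()]
    items.sort(key=lambda gv: (-gv[1], gv[0]))
    return items


def _es_from_positions(
    positions: np.ndarray, abs_weights: np.ndarray, n_total: int
) -> np.ndarray:
    """Signed enrichment scores for one or many hit-position vectors.

    ``positions``: (B, n) sorted 0-based ranks of the hits; ``abs_weights``:
    per-rank |score|^w over the full ranked list.  The running sum attains
    its positive extreme immediately after a hit and its negative extreme
    immediately before one, so only those 2n candidates are examined.  On an
    exact tie in magnitude the positive extreme is reported.
    """
    positions = np.atleast_2d(positions)
    b, n = positions.shape
    if n >= n_total:
        raise ValidationError("gene set covers the whole ranked list")
    w = abs_weights[positions]
    totals = w.sum(axis=1, keepdims=True)
    flat = totals[:, 0] == 0
    if flat.any():
        # all hit scores are zero: fall back to the unweighted statistic
        w[flat] = 1.0
        totals[flat] = n
    cum = np.cumsum(w, axis=1) / totals
    miss_step = 1.0 / (n_total - n)
    miss_count = positions - np.arange(n)  # misses strictly before each hit
    after = cum - miss_count * miss_step
    before = np.concatenate([np.zeros((b, 1)), cum[:, :-1]], axis=1) - miss_count * miss_step
    pos_peak = after.max(axis=1)
    neg_peak = before.min(axis=1)
    return np.where(pos_peak >= -neg_peak, pos_peak, neg_peak)


def enrichment_score(
    ranked: Sequence[tuple[str, float]],
    members: set[str] | frozenset[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score of a gene set against a ranked list.

    Returns ``(es, running_sum)`` where ``running_sum[p]`` is the value of
    the weighted KS walk after processing rank ``p`` and ``es`` is its
    extreme of maximal absolute deviation (positive preferred on ties).
    """
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    n_total = len(genes)
    hit = np.array([g in members for g in genes])
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValidationError("gene set has no overlap with the ranked list")
    if n_hits == n_total:
        raise ValidationError("gene set covers the whole ranked list")
    abs_w = np.abs(scores) ** weight_exponent
    hit_w = abs_w * hit
    total = hit_w.sum()
    if total == 0:
        hit_w = hit.astype(float)
        total = n_hits
    steps = hit_w / total - (~hit) / (n_total - n_hits)
    running = np.cumsum(steps)
    positions = np.nonzero(hit)[0]
    es = float(_es_from_positions(positions[None, :], abs_w, n_total)[0])
    return es, running


def _same_sign_stats(null_es: np.ndarray) -> tuple[float, float]:
    """Mean positive null ES and mean |negative null ES| (0 when empty)."""
    pos = null_es[null_es > 0]
    neg = null_es[null_es < 0]
    pos_mean = float(pos.mean()) if pos.size else 0.0
    neg_mean = float(-neg.mean()) if neg.size else 0.0
    return pos_mean, neg_mean


def preranked_gsea(
    profile: DEProfile,
    db: PathwayDB,
    config: GseaConfig = GseaConfig(),
) -> EnrichmentProfile:
    """Run preranked GSEA for one study against a pathway database.

    The permutation null permutes gene labels of the ranked list: one
    permutation per replicate, shared across pathways, which both matches
    sampling hit ranks without replacement per pathway and supports the
    pooled-NES FDR estimate.  Pathways whose null collapses entirely to
    zero are dropped (logged).
    """
    ranked = rank_genes(profile)
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    n_total = len(genes)
    abs_w = np.abs(scores) ** config.weight_exponent
    rank_of = {g: i for i, g in enumerate(genes)}

    eligible: list[tuple[str, np.ndarray]] = []
    for pid in sorted(db.pathways):
        positions = np.array(
            sorted(rank_of[g] for g in db.members(pid) if g in rank_of), dtype=int
        )
        size = len(positions)
        if size < config.min_size or size >= n_total:
            continue
        if config.max_size is not None and size > config.max_size:
            continue
        eligible.append((pid, positions))
    empty = pd.DataFrame(columns=["size", "es", "nes", "p_nominal", "fdr_q"])
    if not eligible:
        logger.warning("%s: no pathway passes the size filter", profile.study_id)
        return EnrichmentProfile(profile.study_id, empty, db.fingerprint())

    rng = np.random.default_rng(config.seed)
    b = config.n_perm
    # one gene-label permutation per replicate, shared by all pathways
    perms = np.argsort(rng.random((b, n_total)), axis=1)

    records = []
    pooled_null_nes: list[np.ndarray] = []
    for pid, positions in eligible:
        es = float(_es_from_positions(positions[None, :], abs_w, n_total)[0])
        null_pos = np.sort(perms[:, positions], axis=1)
        null_es = _es_from_positions(null_pos, abs_w, n_total)
        pos_mean, neg_mean = _same_sign_stats(null_es)
        norm = pos_mean if es >= 0 else neg_mean
        if norm == 0:
            norm = float(np.abs(null_es).mean())
        if norm == 0:
            logger.warning(
                "%s: pathway %s has a degenerate permutation null; dropped",
                profile.study_id, pid,
            )
            continue
        nes = es / norm
        same_sign = null_es[null_es >= 0] if es >= 0 else null_es[null_es < 0]
        if same_sign.size:
            p_nom = float((np.abs(same_sign) >= abs(es)).mean())
        else:
            p_nom = 0.0
        null_nes = np.where(
            null_es >= 0,
            null_es / (pos_mean if pos_mean else 1.0),
            null_es / (neg_mean if neg_mean else 1.0),
        )
        pooled_null_nes.append(null_nes)
        records.append((pid, len(positions), es, nes, p_nom))

    if not records:
        return EnrichmentProfile(profile.study_id, empty, db.fingerprint())

    rows = pd.DataFrame(
        records, columns=["pathway_id", "size", "es", "nes", "p_nominal"]
    ).set_index("pathway_id")
    rows["fdr_q"] = _pooled_fdr(rows["nes"].to_numpy(), np.concatenate(pooled_null_nes))
    rows = rows[["size", "es", "nes", "p_nominal", "fdr_q"]]
    return EnrichmentProfile(profile.study_id, rows, db.fingerprint())


def _pooled_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """FDR q-values from pooled permuted NES vs observed NES.

    For a positive NES*, q = [share of pooled null NES >= NES* among
    non-negative nulls] / [share of observed NES >= NES* among non-negative
    observed], clamped to [0, 1]; mirrored for negative scores.  q is then
    monotonized to be non-increasing in |NES| within each sign.
    """
    q = np.ones(len(obs_nes))
    pos_null = null_nes[null_nes >= 0]
    neg_null = null_nes[null_nes < 0]
    pos_obs = obs_nes[obs_nes >= 0]
    neg_obs = obs_nes[obs_nes < 0]
    for i, nes in enumerate(obs_nes):
        if nes >= 0:
            num = (pos_null >= nes).mean() if pos_null.size else 1.0
            den = (pos_obs >= nes).mean() if pos_obs.size else 1.0
        else:
            num = (neg_null <= nes).mean() if neg_null.size else 1.0
            den = (neg_obs <= nes).mean() if neg_obs.size else 1.0
        q[i] = 1.0 if den == 0 else min(1.0, num / den)
    # monotonize within each sign: larger |NES| never gets a larger q
    for mask in (obs_nes >= 0, obs_nes < 0):
        idx = np.nonzero(mask)[0]
        if idx.size:
            order = idx[np.argsort(np.abs(obs_nes[idx]), kind="stable")]
            q[order] = np.minimum.accumulate(q[order])
    return q


def pathway_concordance(
    ep_i: EnrichmentProfile,
    ep_j: EnrichmentProfile,
    fdr_cutoff: float = 0.25,
) -> float:
    """Pearson correlation of NES over pathways significant in either study.

    The support is the union of pathways with fdr_q below the cutoff in
    either profile.  Each study contributes its NES where it scored the
    pathway and 0 where the pathway is absent from its table (e.g. filtered
    by size there).  An empty or too-small support, or a constant vector,
    yields 0 — no evidence of agreement is scored as no agreement.
    """
    if ep_i.db_fingerprint != ep_j.db_fingerprint:
        raise ValidationError(
            f"{ep_i.study_id}/{ep_j.study_id}: enrichment profiles come from "
            "different pathway databases"
        )
    union = sorted(set(ep_i.significant(fdr_cutoff)) | set(ep_j.significant(fdr_cutoff)))
    if len(union) < 3:
        return 0.0
    x = ep_i.rows["nes"].reindex(union).fillna(0.0).to_numpy()
    y = ep_j.rows["nes"].reindex(union).fillna(0.0).to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    xc, yc = x - x.mean(), y - y.mean()
    return float(xc @ yc) / float(np.sqrt((xc @ xc) * (yc @ yc)))


def pathway_concordance_matrix(
    enrichments: Sequence[EnrichmentProfile],
    fdr_cutoff: float = 0.25,
):
    """All-pairs pathway-level concordance matrix."""
    from concordmeta.concordance import ConcordanceMatrix

    n = len(enrichments)
    if n < 2:
        raise ValidationError("need at least two enrichment profiles")
    c = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            c[i, j] = c[j, i] = pathway_concordance(
                enrichments[i], enrichments[j], fdr_cutoff
            )
    return ConcordanceMatrix(
        studies=tuple(e.study_id for e in enrichments), c=c, level="pathway"
    )


def export_enrichment_tsv(enrichments: Sequence[EnrichmentProfile], path) -> None:
    """Write enrichment profiles as one long TSV."""
    frames = []
    for ep in enrichments:
        frame = ep.rows.reset_index().rename(columns={"index": "pathway_id"})
        frame.insert(0, "study_id", ep.study_id)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
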