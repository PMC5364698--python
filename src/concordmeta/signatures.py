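"""Differential expression signatures and signature-union feature matrices.

A study's expression signature is its top-k genes by absolute log2 fold
change among genes significant at p < alpha, restricted to the corpus'
shared gene universe.  Ranking by fold change (rather than p-value) yields
more reproducible gene lists across studies.  Feature matrices over the
union of signatures feed the embedding/clustering stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from concordmeta.study_io import DEProfile, GeneUniverse, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureConfig:
    """Signature extraction parameters.

    k: signature size (top genes by |logFC|).
    alpha: p-value cutoff for eligibility.
    mode: 'logfc' keeps magnitudes; 'sign' keeps only direction downstream.
    adjust: 'none' applies alpha to raw p-values; 'bh' to Benjamini-Hochberg
        adjusted ones.
    """

    k: int = 50
    alpha: float = 0.05
    mode: str = "logfc"
    adjust: str = "none"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.mode not in ("logfc", "sign"):
            raise ValueError("mode must be 'logfc' or 'sign'")
        if self.adjust not in ("none", "bh"):
            raise ValueError("adjust must be 'none' or 'bh'")


@dataclass(frozen=True)
class ExpressionSignature:
    """Top-k genes of one study, ordered by |logFC| descending."""

    study_id: str
    genes: tuple[str, ...]
    values: tuple[float, ...]  # logFC, aligned with genes

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.values):
            raise ValidationError(
                f"{self.study_id}: genes and values length mismatch"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.genes), name=self.study_id)


@dataclass(frozen=True)
class FeatureMatrix:
    """Studies x genes matrix of logFC (or sign) values."""

    studies: tuple[str, ...]
    genes: tuple[str, ...]
    values: np.ndarray  # shape (n_studies, n_genes)
    mode: str = "logfc"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.studies), len(self.genes)):
            raise ValidationError(
                f"feature matrix shape {vals.shape} != "
                f"({len(self.studies)}, {len(self.genes)})"
            )
        if not np.isfinite(vals).all():
            raise ValidationError("feature matrix contains non-finite values")
        object.__setattr__(self, "values", vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.studies), columns=list(self.genes)
        )


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def extract_signature(
    profile: DEProfile,
    universe: GeneUniverse,
    config: SignatureConfig = SignatureConfig(),
) -> ExpressionSignature:
    """Top-k universe genes by |logFC| among those with p < alpha.

    Ties on |logFC| break by smaller p-value, then by gene symbol, so the
    result is independent of input row order.  If fewer than k genes
    qualify, the signature is returned shorter (logged); if none qualify it
    is empty.
    """
    genes = list(universe.genes)
    missing = set(genes) - profile.genes
    if missing:
        raise ValidationError(
            f"{profile.study_id}: profile does not cover universe "
            f"(missing e.g. {sorted(missing)[:5]})"
        )
    lfc = profile.logfc(genes)
    pval = profile.pvalue(genes)
    if config.adjust == "bh":
        pval = _bh_adjust(pval)
    eligible = pval < config.alpha
    idx = np.nonzero(eligible)[0]
    if idx.size == 0:
        logger.warning("%s: no genes significant at alpha=%g; empty signature",
                       profile.study_id, config.alpha)
        return ExpressionSignature(profile.study_id, (), ())
    # sort eligible genes by (|logfc| desc, p asc, symbol asc)
    keys = sorted(
        idx, key=lambda i: (-abs(lfc[i]), pval[i], genes[i])
    )
    chosen = keys[: config.k]
    if len(chosen) < config.k:
        logger.info(
            "%s: only %d of k=%d genes significant; short signature",
            profile.study_id, len(chosen), config.k,
        )
    return ExpressionSignature(
        study_id=profile.study_id,
        genes=tuple(genes[i] for i in chosen),
        values=tuple(float(lfc[i]) for i in chosen),
    )


def union_signature_genes(
    signatures: Sequence[ExpressionSignature],
) -> tuple[str, ...]:
    """Sorted union of the member genes of all signatures."""
    if not signatures:
        raise ValidationError("no signatures given")
    union: set[str] = set()
    for sig in signatures:
        union.update(sig.genes)
    if not union:
        raise ValidationError("all signatures are empty; no union gene set")
    return tuple(sorted(union))


def feature_matrix(
    profiles: Sequence[DEProfile],
    genes: Sequence[str],
    mode: str = "logfc",
) -> FeatureMatrix:
    """Assemble the studies x genes matrix of stored logFC (or sign) values."""
    if mode not in ("logfc", "sign"):
        raise ValueError("mode must be 'logfc' or 'sign'")
    rows = []
    for prof in profiles:
        vals = prof.logfc(genes)
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise ValidationError(
                f"{prof.study_id}: gene {genes[bad[0]]!r} absent from profile"
            )
        rows.append(vals)
    values = np.vstack(rows) if rows else np.empty((0, len(genes)))
    if mode == "sign":
        values = np.sign(values)
    return FeatureMatrix(
        studies=tuple(p.study_id for p in profiles),
        genes=tuple(genes),
        values=values,
        mode=mode,
    )


def export_signatures_tsv(
    signatures: Sequence[ExpressionSignature],
    profiles: Sequence[DEProfile],
    path,
) -> None:
    """Write signatures as TSV (study_id, rank, gene, logfc, pvalue)."""
    by_id = {p.study_id: p for p in profiles}
    records = []
    for sig in signatures:
        prof = by_id[sig.study_id]
        for rank, (gene, lfc) in enumerate(zip(sig.genes, sig.values), start=1):
            records.append(
                {
                    "study_id": sig.study_id,
                    "rank": rank,
                    "gene": gene,
                    "logfc": lfc,
                    "pvalue": float(prof.pvalue([gene])[0]),
                }
            )
    pd.DataFrame.from_records(
        records, columns=["study_id", "rank", "gene", "logfc", "pvalue"]
    ).to_csv(path, sep="\t", index=False)
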