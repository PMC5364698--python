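"""Vote-counting meta-analysis of expression-signature membership.

A gene receives one vote from every study whose expression signature
contains it; genes with at least a threshold number of votes within a
study subset are called significant by the meta-analysis.  Vote counting
is deliberately coarse — it is the method of choice when between-study
agreement is too low for effect-size pooling — so only the direction of
regulation is carried along, not a pooled magnitude.  Significant gene
lists are scored by their overlap with a reference disease-gene list.

The packaged fixture ``table2_fixture.tsv`` transcribes a published
vote-count table for 33 Parkinson's disease microarray studies (43 genes;
vote counts over all studies, human studies, and substantia nigra
studies), used as a worked example and regression anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from concordmeta.signatures import ExpressionSignature
from concordmeta.study_io import ReferenceGeneList, ValidationError

ALL_STUDIES_LABEL = "all"


@dataclass(frozen=True)
class VoteTable:
    """Per-gene signature-membership counts, overall and per subset.

    ``table`` is indexed by gene with integer columns: one per subset label
    (including ``all``), plus ``up_votes``/``down_votes`` and a string
    ``direction`` in {up, down, conflict}.
    """

    table: pd.DataFrame = field(repr=False)
    subsets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    n_studies: int = 0

    def votes(self, subset_label: str = ALL_STUDIES_LABEL) -> pd.Series:
        if subset_label not in self.table.columns:
            raise KeyError(f"unknown subset label {subset_label!r}")
        return self.table[subset_label]


@dataclass(frozen=True)
class MetaResult:
    """Significant genes of a vote-counting meta-analysis, optionally scored
    against a reference list."""

    subset_label: str
    threshold: int
    significant_genes: tuple[str, ...]
    directions: dict[str, str]
    reference_name: str | None = None
    overlap: int | None = None
    enrichment_pct: float | None = None
    hypergeom_p: float | None = None

    def __len__(self) -> int:
        return len(self.significant_genes)


def vote_counts(
    signatures: Sequence[ExpressionSignature],
    subsets: Mapping[str, Sequence[str]] | None = None,
) -> VoteTable:
    """Count signature membership per gene, overall and per subset.

    Votes are counted regardless of direction; the per-study logFC sign is
    tallied separately into up/down votes and summarized as a direction
    (``conflict`` when a gene is up in some studies and down in others).
    """
    subsets = dict(subsets or {})
    all_ids = [s.study_id for s in signatures]
    if len(set(all_ids)) != len(all_ids):
        raise ValidationError("duplicate study ids among signatures")
    known = set(all_ids)
    for label, members in subsets.items():
        unknown = set(members) - known
        if unknown:
            raise ValidationError(
                f"subset {label!r} references unknown studies {sorted(unknown)[:5]}"
            )
        if label == ALL_STUDIES_LABEL:
            raise ValidationError(f"subset label {ALL_STUDIES_LABEL!r} is reserved")

    counts: dict[str, dict[str, int]] = {}
    up: dict[str, int] = {}
    down: dict[str, int] = {}
    membership = {label: set(members) for label, members in subsets.items()}
    for sig in signatures:
        for gene, value in zip(sig.genes, sig.values):
            row = counts.setdefault(gene, {ALL_STUDIES_LABEL: 0, **{l: 0 for l in subsets}})
            row[ALL_STUDIES_LABEL] += 1
            for label, members in membership.items():
                if sig.study_id in members:
                    row[label] += 1
            if value >= 0:
                up[gene] = up.get(gene, 0) + 1
            else:
                down[gene] = down.get(gene, 0) + 1

    genes = sorted(counts)
    cols = [ALL_STUDIES_LABEL, *subsets]
    table = pd.DataFrame(
        {label: [counts[g][label] for g in genes] for label in cols},
        index=pd.Index(genes, name="gene"),
    )
    table["up_votes"] = [up.get(g, 0) for g in genes]
    table["down_votes"] = [down.get(g, 0) for g in genes]
    table["direction"] = [
        "conflict" if up.get(g, 0) and down.get(g, 0)
        else ("up" if up.get(g, 0) else "down")
        for g in genes
    ]
    return VoteTable(
        table=table,
        subsets={label: tuple(members) for label, members in subsets.items()},
        n_studies=len(signatures),
    )


def significant_genes(
    votes: VoteTable,
    min_votes: int = 3,
    subset_label: str = ALL_STUDIES_LABEL,
) -> MetaResult:
    """Genes with at least ``min_votes`` votes within a subset.

    Ordered by votes descending, then gene symbol.  The published method
    text says "more than three studies", but its result table lists genes
    with exactly three votes and its headline counts match a >= 3 rule, so
    >= 3 is the default here (configurable).
    """
    if min_votes < 1:
        raise ValidationError("min_votes must be >= 1")
    col = votes.votes(subset_label)
    hits = votes.table[col >= min_votes]
    order = hits.sort_values(
        by=[subset_label], ascending=False, kind="stable"
    )
    order = order.loc[
        sorted(order.index, key=lambda g: (-order.at[g, subset_label], g))
    ]
    return MetaResult(
        subset_label=subset_label,
        threshold=min_votes,
        significant_genes=tuple(order.index),
        directions={g: order.at[g, "direction"] for g in order.index},
    )


def reference_enrichment(
    result: MetaResult,
    ref: ReferenceGeneList,
    universe_size: int | None = None,
    universe_overlap: int | None = None,
) -> MetaResult:
    """Score a significant gene list against a reference disease-gene list.

    Reports the overlap count and the percentage of significant genes found
    in the reference.  When the size of the gene universe and the number of
    reference genes inside it are supplied, a hypergeometric enrichment
    p-value is attached as supporting context.
    """
    if len(ref) == 0:
        raise ValidationError("empty reference list")
    sig = result.significant_genes
    if not sig:
        return MetaResult(
            subset_label=result.subset_label,
            threshold=result.threshold,
            significant_genes=sig,
            directions=result.directions,
            reference_name=ref.name,
            overlap=None,
            enrichment_pct=None,
        )
    overlap = sum(1 for g in sig if g in ref.genes)
    pct = 100.0 * overlap / len(sig)
    p = None
    if universe_size is not None:
        in_universe = universe_overlap if universe_overlap is not None else len(ref)
        p = float(
            hypergeom.sf(overlap - 1, universe_size, in_universe, len(sig))
        )
    return MetaResult(
        subset_label=result.subset_label,
        threshold=result.threshold,
        significant_genes=sig,
        directions=result.directions,
        reference_name=ref.name,
        overlap=overlap,
        enrichment_pct=pct,
        hypergeom_p=p,
    )


def load_table2_fixture() -> VoteTable:
    """Load the packaged 43-gene published vote-count table.

    Columns: ``all`` (33 studies), ``human`` (human studies), ``sn``
    (substantia nigra studies).  Per-study membership is not recoverable
    from the published table, so up/down votes are attributed entirely to
    the printed direction.
    """
    with resources.files("concordmeta.data").joinpath("table2_fixture.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t")
    table = raw.set_index("gene")[["all", "human", "sn"]].astype(int)
    table["up_votes"] = np.where(raw.set_index("gene")["direction"] == "up", table["all"], 0)
    table["down_votes"] = table["all"] - table["up_votes"]
    table["direction"] = raw.set_index("gene")["direction"]
    return VoteTable(table=table, subsets={"human": (), "sn": ()}, n_studies=33)


def export_vote_table_tsv(votes: VoteTable, path) -> None:
    """Write the vote table as TSV (gene, direction, counts per subset)."""
    cols = ["direction", ALL_STUDIES_LABEL, *votes.subsets, "up_votes", "down_votes"]
    votes.table[cols].to_csv(path, sep="\t", index_label="gene")
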