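"""End-to-end orchestration: ingest -> signatures -> concordance -> GSEA ->
clustering -> meta-analysis, from a single configuration.

The pipeline consumes either a directory of per-study DE tables plus a
metadata table, or a synthetic corpus preset.  Subgroups are defined by
small metadata queries (``species=human AND tissue=substantia_nigra``);
any query resolving to fewer than three studies is reported as skipped
rather than analyzed, since subgroup averages over one or two studies
carry no meaningful evidence.  All randomness derives from a single root
seed through named substreams, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from concordmeta.cluster_embed import (
    DEFAULT_SCALES,
    multiscale_bootstrap,
    pca_embed,
)
from concordmeta.concordance import (
    ConcordanceMatrix,
    concordance_matrix,
    null_threshold,
    sample_size_regression,
    subset_average,
)
from concordmeta.meta_vote import (
    export_vote_table_tsv,
    reference_enrichment,
    significant_genes,
    vote_counts,
)
from concordmeta.pathway_enrichment import (
    GseaConfig,
    export_enrichment_tsv,
    pathway_concordance_matrix,
    preranked_gsea,
)
from concordmeta.signatures import (
    SignatureConfig,
    export_signatures_tsv,
    extract_signature,
    feature_matrix,
    union_signature_genes,
)
from concordmeta.study_io import (
    DEProfile,
    ReferenceGeneList,
    StudyMetadata,
    ValidationError,
    read_de_table,
    read_gene_list,
    read_gmt,
    read_metadata_table,
    shared_universe,
)
from concordmeta import synthetic_data as synth

logger = logging.getLogger(__name__)

ALL_STAGES = ("concordance", "gsea", "cluster", "meta")


# ---------------------------------------------------------------------------
# metadata query language


class QueryError(ValueError):
    """Malformed subgroup query or unknown metadata field."""


_QUERY_FIELDS = (
    "study_id", "species", "tissue", "platform", "disease_model",
    "treatment", "n_case", "n_control",
)


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


def subgroup_query(
    metadata: Mapping[str, StudyMetadata], expression: str
) -> set[str]:
    """Evaluate a metadata query; returns the matching study ids.

    Grammar: ``field=value`` atoms combined with NOT, AND, OR (in that
    precedence) and parentheses.  Values match case-insensitively;
    ``treatment=none`` matches studies without a recorded treatment.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise QueryError("empty query")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> set[str]:
        result = parse_and()
        while peek() is not None and peek().upper() == "OR":
            advance()
            result = result | parse_and()
        return result

    def parse_and() -> set[str]:
        result = parse_not()
        while peek() is not None and peek().upper() == "AND":
            advance()
            result = result & parse_not()
        return result

    def parse_not() -> set[str]:
        if peek() is not None and peek().upper() == "NOT":
            advance()
            return set(metadata) - parse_not()
        return parse_atom()

    def parse_atom() -> set[str]:
        tok = peek()
        if tok is None:
            raise QueryError(f"unexpected end of query: {expression!r}")
        if tok == "(":
            advance()
            inner = parse_or()
            if peek() != ")":
                raise QueryError(f"missing ')' in query: {expression!r}")
            advance()
            return inner
        advance()
        if "=" not in tok:
            raise QueryError(f"expected field=value, got {tok!r}")
        fname, value = tok.split("=", 1)
        if fname not in _QUERY_FIELDS:
            raise QueryError(
                f"unknown field {fname!r}; known fields: {_QUERY_FIELDS}"
            )
        value = value.strip().lower()
        matched = set()
        for sid, md in metadata.items():
            actual = getattr(md, fname)
            if actual is None:
                actual = "none"
            if str(actual).lower() == value:
                matched.add(sid)
        return matched

    result = parse_or()
    if pos != len(tokens):
        raise QueryError(f"trailing tokens in query: {expression!r}")
    return result


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; see ``RunConfig.from_yaml``."""

    seed: int = 0
    synthetic_preset: str | None = "paper_like"
    synthetic_n_genes: int = 2500
    de_dir: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    reference_path: str | None = None
    signature: SignatureConfig = SignatureConfig()
    cluster_k: int = 10  # signature size for the clustering feature matrix
    gsea: GseaConfig = GseaConfig(n_perm=200)
    subgroups: dict[str, str] = field(default_factory=dict)
    q: float = 0.95
    max_null_samples: int = 100_000
    min_votes: int = 3
    linkage: str = "average"
    n_boot: int = 1000
    scales: tuple[float, ...] = DEFAULT_SCALES
    pathway_background: int = 30
    pathway_planted: dict[str, int] = field(default_factory=dict)
    reference_classes: tuple[str, ...] = ()

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: Mapping[str, Any]) -> "RunConfig":
        synth_cfg = raw.get("synthetic") or {}
        inputs = raw.get("inputs") or {}
        sig = raw.get("signature") or {}
        gsea = raw.get("gsea") or {}
        resampling = raw.get("resampling") or {}
        bootstrap = raw.get("bootstrap") or {}
        pathways = raw.get("pathways") or {}
        return RunConfig(
            seed=int(raw.get("seed", 0)),
            synthetic_preset=synth_cfg.get("preset") if synth_cfg else (
                None if inputs else "paper_like"
            ),
            synthetic_n_genes=int(synth_cfg.get("n_genes", 2500)),
            de_dir=inputs.get("de_dir"),
            metadata_path=inputs.get("metadata"),
            gmt_path=inputs.get("gmt"),
            reference_path=inputs.get("reference"),
            signature=SignatureConfig(
                k=int(sig.get("k", 50)),
                alpha=float(sig.get("alpha", 0.05)),
                adjust=sig.get("adjust", "none"),
            ),
            cluster_k=int(sig.get("cluster_k", 10)),
            gsea=GseaConfig(
                n_perm=int(gsea.get("n_perm", 200)),
                min_size=int(gsea.get("min_size", 10)),
                max_size=gsea.get("max_size"),
                weight_exponent=float(gsea.get("weight_exponent", 1.0)),
                fdr_cutoff=float(gsea.get("fdr_cutoff", 0.25)),
            ),
            subgroups=dict(raw.get("subgroups") or {}),
            q=float(resampling.get("q", 0.95)),
            max_null_samples=int(resampling.get("max_samples", 100_000)),
            min_votes=int(raw.get("min_votes", 3)),
            linkage=bootstrap.get("linkage", "average"),
            n_boot=int(bootstrap.get("n_boot", 1000)),
            scales=tuple(bootstrap.get("scales", DEFAULT_SCALES)),
            pathway_background=int(pathways.get("n_background", 30)),
            pathway_planted=dict(pathways.get("planted") or {}),
            reference_classes=tuple(raw.get("reference_classes") or ()),
        )


DEFAULT_SUBGROUPS = {
    "human": "species=human",
    "human_sn": "species=human AND tissue=substantia_nigra",
    "sn": "tissue=substantia_nigra",
    "blood": "tissue=blood",
    "mptp": "disease_model=neurotoxic_mptp",
    "mouse": "species=mouse",
    "basal_ganglia": "tissue=substantia_nigra OR tissue=striatum",
}


@dataclass
class SubgroupReportRow:
    label: str
    query: str
    studies: tuple[str, ...]
    skipped: bool
    a_s_gene: float | None = None
    a_s_sign: float | None = None
    a_s_pathway: float | None = None
    null_threshold: float | None = None
    significant: bool | None = None
    n_null: int | None = None


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    manifest: dict[str, Any]
    subgroups: list[SubgroupReportRow]
    regression: dict[str, float] | None
    meta: dict[str, Any]
    variance_explained: list[float] | None
    cluster_support: list[dict[str, Any]] | None
    artifacts: dict[str, str]

    def to_dict(self) -> dict[str, Any]:
        return {
            "manifest": self.manifest,
            "subgroups": [vars(r) | {"studies": list(r.studies)} for r in self.subgroups],
            "regression": self.regression,
            "meta": self.meta,
            "variance_explained": self.variance_explained,
            "cluster_support": self.cluster_support,
            "artifacts": self.artifacts,
        }


def _stage_seeds(root_seed: int) -> dict[str, int]:
    """Named integer substream seeds (< 2^31) derived from the root seed."""
    state = np.random.SeedSequence(root_seed).generate_state(8) % (2**31)
    names = ("corpus", "gsea", "null", "bootstrap", "pathways", "reference")
    return {name: int(state[i]) for i, name in enumerate(names)}


def _load_inputs(config: RunConfig, seeds: dict[str, int]):
    """Profiles, metadata, pathway db, reference list — real or synthetic."""
    if config.synthetic_preset:
        preset = config.synthetic_preset
        if preset == "paper_like":
            scfg = synth.paper_like_config(config.synthetic_n_genes, seeds["corpus"])
        elif preset == "two_class":
            scfg = synth.two_class_config(config.synthetic_n_genes, seed=seeds["corpus"])
        elif preset == "pure_noise":
            scfg = synth.pure_noise_config(config.synthetic_n_genes, seed=seeds["corpus"])
        else:
            raise ValidationError(f"unknown synthetic preset {preset!r}")
        profiles, metadata, truth = synth.generate_corpus(scfg)
        planted = config.pathway_planted or (
            {"human_sn_cortex": 4, "mptp": 3, "blood": 3}
            if preset == "paper_like" else {}
        )
        pathway_db = synth.generate_pathway_db(
            truth, n_background=config.pathway_background,
            planted=planted, seed=seeds["pathways"],
        )
        ref_classes = config.reference_classes or (
            ("human_sn_cortex", "general_neurodeg") if preset == "paper_like" else ()
        )
        reference = (
            synth.generate_reference_list(
                truth, ref_classes, contamination=0.3, seed=seeds["reference"]
            )
            if ref_classes else None
        )
        return profiles, metadata, pathway_db, reference
    if not config.de_dir or not config.metadata_path:
        raise ValidationError("need either a synthetic preset or de_dir + metadata")
    metadata = read_metadata_table(config.metadata_path)
    profiles = [
        read_de_table(Path(config.de_dir) / f"{sid}.tsv", sid)
        for sid in sorted(metadata)
    ]
    pathway_db = read_gmt(config.gmt_path) if config.gmt_path else None
    reference = read_gene_list(config.reference_path) if config.reference_path else None
    return profiles, metadata, pathway_db, reference


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages: Sequence[str] = ALL_STAGES,
) -> RunReport:
    """Run the configured stages and write all artifacts under ``out_dir``."""
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValidationError(f"unknown stages {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artifacts: dict[str, str] = {}

    profiles, metadata, pathway_db, reference = _load_inputs(config, seeds)
    universe = shared_universe(profiles)
    logger.info("corpus: %d studies, %d shared genes", len(profiles), len(universe))

    signatures = [extract_signature(p, universe, config.signature) for p in profiles]
    export_signatures_tsv(signatures, profiles, out / "signatures.tsv")
    artifacts["signatures"] = "signatures.tsv"

    subgroup_queries = config.subgroups or DEFAULT_SUBGROUPS
    resolved: dict[str, tuple[str, set[str]]] = {}
    for label, query in subgroup_queries.items():
        resolved[label] = (query, subgroup_query(metadata, query))

    # --- concordance stage -------------------------------------------------
    subgroup_rows: list[SubgroupReportRow] = []
    regression = None
    cm_gene = cm_sign = cm_path = None
    if "concordance" in stages:
        cm_gene = concordance_matrix(profiles, signatures, mode="logfc")
        cm_sign = concordance_matrix(profiles, signatures, mode="sign")
        cm_gene.to_frame().to_csv(out / "concordance_gene.tsv", sep="\t")
        cm_sign.to_frame().to_csv(out / "concordance_sign.tsv", sep="\t")
        artifacts["concordance_gene"] = "concordance_gene.tsv"
        artifacts["concordance_sign"] = "concordance_sign.tsv"

    if "gsea" in stages and pathway_db is not None and len(pathway_db):
        enrichments = []
        for i, prof in enumerate(profiles):
            gcfg = GseaConfig(
                n_perm=config.gsea.n_perm,
                min_size=config.gsea.min_size,
                max_size=config.gsea.max_size,
                weight_exponent=config.gsea.weight_exponent,
                fdr_cutoff=config.gsea.fdr_cutoff,
                seed=(seeds["gsea"] + i) % (2**31),
            )
            enrichments.append(preranked_gsea(prof, pathway_db, gcfg))
        export_enrichment_tsv(enrichments, out / "enrichment.tsv")
        artifacts["enrichment"] = "enrichment.tsv"
        cm_path = pathway_concordance_matrix(enrichments, config.gsea.fdr_cutoff)
        cm_path.to_frame().to_csv(out / "concordance_pathway.tsv", sep="\t")
        artifacts["concordance_pathway"] = "concordance_pathway.tsv"

    if cm_gene is not None:
        threshold_cache: dict[int, tuple[float, int]] = {}

        def threshold_for(size: int) -> tuple[float, int]:
            if size not in threshold_cache:
                threshold_cache[size] = null_threshold(
                    cm_gene, size, q=config.q,
                    max_samples=config.max_null_samples, seed=seeds["null"],
                )
            return threshold_cache[size]

        for label, (query, members) in sorted(resolved.items()):
            ordered = tuple(sorted(members))
            if len(ordered) < 3:
                logger.info("subgroup %s: %d studies, skipped", label, len(ordered))
                subgroup_rows.append(SubgroupReportRow(
                    label=label, query=query, studies=ordered, skipped=True,
                ))
                continue
            a_s, _ = subset_average(cm_gene, ordered)
            a_s_sign, _ = subset_average(cm_sign, ordered)
            a_s_path = None
            if cm_path is not None:
                a_s_path, _ = subset_average(cm_path, ordered)
            thr, n_null = threshold_for(len(ordered))
            subgroup_rows.append(SubgroupReportRow(
                label=label, query=query, studies=ordered, skipped=False,
                a_s_gene=a_s, a_s_sign=a_s_sign, a_s_pathway=a_s_path,
                null_threshold=thr, significant=bool(a_s > thr), n_null=n_null,
            ))

        _, a_i_full = subset_average(cm_gene, cm_gene.studies)
        sizes = {sid: md.n_total for sid, md in metadata.items()}
        try:
            slope, intercept, p_slope, r2 = sample_size_regression(a_i_full, sizes)
            regression = {
                "slope": slope, "intercept": intercept,
                "p_slope": p_slope, "r_squared": r2,
            }
        except ValidationError as exc:
            logger.warning("sample-size regression skipped: %s", exc)
            regression = None
        pd.DataFrame(
            [vars(r) | {"studies": ";".join(r.studies)} for r in subgroup_rows]
        ).to_csv(out / "subgroups.tsv", sep="\t", index=False)
        artifacts["subgroups"] = "subgroups.tsv"

    # --- embedding / clustering stage --------------------------------------
    variance_explained = None
    cluster_support = None
    if "cluster" in stages:
        union_50 = union_signature_genes(signatures)
        fm = feature_matrix(profiles, union_50, mode="logfc")
        embedding = pca_embed(fm)
        variance_explained = embedding.variance_explained.tolist()
        from concordmeta.cluster_embed import export_embedding_tsv

        export_embedding_tsv(embedding, out / "embedding.tsv")
        artifacts["embedding"] = "embedding.tsv"

        short_cfg = SignatureConfig(
            k=config.cluster_k, alpha=config.signature.alpha,
            adjust=config.signature.adjust,
        )
        short_sigs = [extract_signature(p, universe, short_cfg) for p in profiles]
        union_short = union_signature_genes(short_sigs)
        fm_short = feature_matrix(profiles, union_short, mode="logfc")
        tree = multiscale_bootstrap(
            fm_short, linkage=config.linkage, scales=config.scales,
            n_boot=config.n_boot, seed=seeds["bootstrap"],
        )
        (out / "tree.newick").write_text(tree.newick() + "\n", encoding="utf-8")
        artifacts["tree"] = "tree.newick"
        cluster_support = [
            {
                "leafset": sorted(node.leafset),
                "height": node.height,
                "bp": node.bp,
                "au": node.au,
            }
            for node in tree.nodes
        ]

    # --- meta-analysis stage ------------------------------------------------
    meta_report: dict[str, Any] = {}
    if "meta" in stages:
        vote_subsets = {
            label: tuple(sorted(members))
            for label, (_, members) in resolved.items()
            if len(members) >= 3
        }
        votes = vote_counts(signatures, vote_subsets)
        export_vote_table_tsv(votes, out / "votes.tsv")
        artifacts["votes"] = "votes.tsv"
        for label in ["all", *sorted(vote_subsets)]:
            result = significant_genes(votes, config.min_votes, label)
            entry: dict[str, Any] = {
                "n_significant": len(result),
                "genes": list(result.significant_genes),
            }
            if reference is not None:
                scored = reference_enrichment(
                    result, reference, universe_size=len(universe),
                    universe_overlap=sum(1 for g in reference.genes if g in universe),
                )
                entry["overlap"] = scored.overlap
                entry["enrichment_pct"] = scored.enrichment_pct
                entry["hypergeom_p"] = scored.hypergeom_p
            meta_report[label] = entry

    from concordmeta import __version__ as pkg_version

    manifest = {
        "version": pkg_version,
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_studies": len(profiles),
        "universe_size": len(universe),
        "signature_k": config.signature.k,
        "alpha": config.signature.alpha,
        "stages": list(stages),
        "synthetic_preset": config.synthetic_preset,
    }
    report = RunReport(
        manifest=manifest,
        subgroups=subgroup_rows,
        regression=regression,
        meta=meta_report,
        variance_explained=variance_explained,
        cluster_support=cluster_support,
        artifacts=artifacts,
    )
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return report
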