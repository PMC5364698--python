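"""Ingestion and harmonization of per-study differential expression tables.

Studies arrive as gene-level tables of (log2 fold change, p-value), typically
produced by a moderated linear-model fit on a normalized microarray matrix.
Before cross-study comparison they must be harmonized into a shared data
model: probe-level rows collapsed to one row per gene, animal-model gene
identifiers translated to their human orthologs, and the corpus reduced to
the gene universe measured by every study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SPECIES = frozenset({"human", "mouse", "rat", "macaque"})
VALID_DISEASE_MODELS = frozenset(
    {
        "human_pd",
        "neurotoxic_mptp",
        "neurotoxic_6ohda",
        "neurotoxic_other",
        "genetic",
        "disease_control",
    }
)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def _clean_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class StudyMetadata:
    """Descriptive metadata for one case/control study.

    ``n_case``/``n_control`` are sample counts after any quality filtering;
    both must be at least 2 for a differential contrast to be estimable.
    """

    study_id: str
    species: str
    tissue: str
    platform: str
    disease_model: str
    n_case: int
    n_control: int
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValidationError(
                f"{self.study_id}: unknown species {self.species!r}; "
                f"expected one of {sorted(VALID_SPECIES)}"
            )
        if self.disease_model not in VALID_DISEASE_MODELS:
            raise ValidationError(
                f"{self.study_id}: unknown disease_model {self.disease_model!r}"
            )
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError(
                f"{self.study_id}: need at least two samples per condition "
                f"(got n_case={self.n_case}, n_control={self.n_control})"
            )

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


@dataclass(frozen=True)
class DEProfile:
    """One study's gene-level differential expression profile.

    ``table`` is indexed by upper-cased gene symbol (unique, sorted) with
    float columns ``logfc`` and ``pvalue``.
    """

    study_id: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        tab = self.table
        if list(tab.columns) != ["logfc", "pvalue"]:
            raise ValidationError(
                f"{self.study_id}: profile table must have columns "
                f"['logfc', 'pvalue'], got {list(tab.columns)}"
            )
        if tab.index.has_duplicates:
            dupes = tab.index[tab.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(
                f"{self.study_id}: duplicate gene symbols {dupes}; "
                "collapse probes to genes first (collapse_probes)"
            )
        if len(tab) and not np.isfinite(tab["logfc"].to_numpy()).all():
            raise ValidationError(f"{self.study_id}: non-finite logfc values")
        pv = tab["pvalue"].to_numpy()
        if len(tab) and (not np.isfinite(pv).all() or (pv < 0).any() or (pv > 1).any()):
            raise ValidationError(f"{self.study_id}: p-values outside [0, 1]")
        if not tab.index.is_monotonic_increasing:
            object.__setattr__(self, "table", tab.sort_index())

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def logfc(self, genes: Sequence[str]) -> np.ndarray:
        """logFC values for ``genes``, in the given order."""
        return self.table["logfc"].reindex(genes).to_numpy()

    def pvalue(self, genes: Sequence[str]) -> np.ndarray:
        return self.table["pvalue"].reindex(genes).to_numpy()

    @staticmethod
    def from_entries(
        study_id: str, entries: Mapping[str, tuple[float, float]]
    ) -> "DEProfile":
        """Build a profile from a ``gene -> (logfc, pvalue)`` mapping."""
        idx = [_clean_symbol(g) for g in entries]
        tab = pd.DataFrame(
            {
                "logfc": [float(v[0]) for v in entries.values()],
                "pvalue": [float(v[1]) for v in entries.values()],
            },
            index=pd.Index(idx, name="gene"),
        )
        return DEProfile(study_id=study_id, table=tab)


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered set of gene symbols measured by every study in a corpus."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.genes) != sorted(set(self.genes)):
            object.__setattr__(self, "genes", tuple(sorted(set(self.genes))))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class PathwayDB:
    """Pathway/gene-set collection keyed by pathway id."""

    pathways: dict[str, tuple[str, frozenset[str]]]  # id -> (name, members)

    def __post_init__(self) -> None:
        for pid, (_, members) in self.pathways.items():
            if not members:
                raise ValidationError(f"pathway {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.pathways)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def fingerprint(self) -> int:
        """Order-independent hash of ids and membership, for compatibility checks."""
        return hash(
            frozenset((pid, members) for pid, (_, members) in self.pathways.items())
        )


@dataclass(frozen=True)
class ReferenceGeneList:
    """A named reference set of disease-associated gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"reference list {self.name!r} is empty")
        cleaned = frozenset(_clean_symbol(g) for g in self.genes)
        object.__setattr__(self, "genes", cleaned)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers


def read_de_table(path: str | Path, study_id: str) -> DEProfile:
    """Read a gene-level DE table (TSV with header gene/logfc/pvalue).

    Extra columns are ignored.  Duplicate gene rows are rejected: tables with
    several probes per gene must go through :func:`collapse_probes` first.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    missing = {"gene", "logfc", "pvalue"} - set(raw.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"found {list(raw.columns)}"
        )
    raw = raw[["gene", "logfc", "pvalue"]].copy()
    raw["gene"] = raw["gene"].map(_clean_symbol)

    for col in ("logfc", "pvalue"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy()))[0]
        if bad.size:
            rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
            raise ValidationError(
                f"{path}: non-numeric {col} on file line(s) {rows}"
            )
        raw[col] = vals
    out_of_range = np.nonzero(
        (raw["pvalue"].to_numpy() < 0) | (raw["pvalue"].to_numpy() > 1)
    )[0]
    if out_of_range.size:
        rows = ", ".join(str(i + 2) for i in out_of_range[:10])
        raise ValidationError(f"{path}: pvalue outside [0, 1] on file line(s) {rows}")
    if raw["gene"].duplicated().any():
        dupes = raw.loc[raw["gene"].duplicated(), "gene"].unique().tolist()[:5]
        raise ValidationError(
            f"{path}: duplicated gene symbol(s) {dupes}; run collapse_probes "
            "on the probe-level table first"
        )
    tab = raw.set_index("gene")[["logfc", "pvalue"]]
    tab.index.name = "gene"
    return DEProfile(study_id=study_id, table=tab)


def read_metadata_table(path: str | Path) -> dict[str, StudyMetadata]:
    """Read a study metadata table (one row per study) into StudyMetadata."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "study_id",
        "species",
        "tissue",
        "platform",
        "disease_model",
        "n_case",
        "n_control",
    }
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing column(s) {sorted(missing)}")
    out: dict[str, StudyMetadata] = {}
    for _, row in raw.iterrows():
        sid = str(row["study_id"])
        if sid in out:
            raise ValidationError(f"{path}: duplicate study_id {sid!r}")
        treatment = row.get("treatment")
        if treatment is not None and (pd.isna(treatment) or treatment == ""):
            treatment = None
        out[sid] = StudyMetadata(
            study_id=sid,
            species=str(row["species"]),
            tissue=str(row["tissue"]),
            platform=str(row["platform"]),
            disease_model=str(row["disease_model"]),
            n_case=int(row["n_case"]),
            n_control=int(row["n_control"]),
            treatment=treatment,
        )
    return out


def read_gmt(path: str | Path) -> PathwayDB:
    """Parse a GMT gene-set file (name, description, members...)."""
    path = Path(path)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, members...), got {len(fields)}"
                )
            pid, desc = fields[0].strip(), fields[1].strip()
            members = frozenset(
                _clean_symbol(g) for g in fields[2:] if g.strip()
            )
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {pid!r} has no members")
            if pid in pathways:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            pathways[pid] = (desc or pid, members)
    return PathwayDB(pathways=pathways)


def read_gene_list(path: str | Path, name: str | None = None) -> ReferenceGeneList:
    """Read a one-symbol-per-line reference gene list ('#' starts a comment)."""
    path = Path(path)
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(_clean_symbol(line))
    return ReferenceGeneList(name=name or path.stem, genes=frozenset(genes))


# ---------------------------------------------------------------------------
# harmonization

#: policies for picking one probe when several map to the same gene
COLLISION_POLICIES = ("worst_p", "best_p", "max_abs_lfc")


def _resolve_collision(
    rows: list[tuple[float, float]], policy: str
) -> tuple[float, float]:
    """Pick one (logfc, pvalue) pair among probes hitting the same gene."""
    if policy == "worst_p":
        # the least significant probe is retained; ties broken toward the
        # smaller |logfc| to stay conservative, then by input order
        return max(rows, key=lambda r: (r[1], -abs(r[0])))
    if policy == "best_p":
        return min(rows, key=lambda r: (r[1], -abs(r[0])))
    if policy == "max_abs_lfc":
        return max(rows, key=lambda r: (abs(r[0]), -r[1]))
    raise ValueError(f"unknown collision policy {policy!r}; use one of {COLLISION_POLICIES}")


def collapse_probes(
    probe_rows: Iterable[tuple[str, Sequence[str], float, float]],
    study_id: str = "study",
    collision: str = "worst_p",
) -> DEProfile:
    """Collapse probe-level rows to one (logfc, pvalue) pair per gene.

    Each row is ``(probe_id, gene_symbols, logfc, pvalue)``.  A probe
    annotated to several genes contributes its values to each of them, which
    maximizes the genes available for cross-platform comparison at the cost
    of some artificial inflation of between-study agreement.  Probes with no
    gene annotation are dropped.  When several probes hit one gene the
    default ``worst_p`` policy keeps the probe with the largest p-value.
    """
    per_gene: dict[str, list[tuple[float, float]]] = {}
    n_unannotated = 0
    for probe_id, symbols, logfc, pvalue in probe_rows:
        symbols = [_clean_symbol(s) for s in symbols if str(s).strip()]
        if not symbols:
            n_unannotated += 1
            continue
        for sym in symbols:
            per_gene.setdefault(sym, []).append((float(logfc), float(pvalue)))
    if n_unannotated:
        logger.info("%s: dropped %d unannotated probes", study_id, n_unannotated)
    entries = {
        gene: _resolve_collision(rows, collision) for gene, rows in per_gene.items()
    }
    return DEProfile.from_entries(study_id, entries)


def map_orthologs(
    profile: DEProfile,
    ortholog_map: Mapping[str, str],
    collision: str = "worst_p",
) -> DEProfile:
    """Relabel a profile's genes with their human orthologs.

    ``ortholog_map`` maps source-species symbols to human symbols (many-to-
    one).  Source genes without a mapping are dropped (count logged).  When
    two source genes map to the same human gene the collision is resolved
    with the same policy as probe collapsing.
    """
    if not ortholog_map:
        raise ValidationError("empty ortholog map")
    cleaned = {_clean_symbol(k): _clean_symbol(v) for k, v in ortholog_map.items()}
    per_human: dict[str, list[tuple[float, float]]] = {}
    n_unmapped = 0
    for gene, row in profile.table.iterrows():
        human = cleaned.get(gene)
        if human is None:
            n_unmapped += 1
            continue
        per_human.setdefault(human, []).append(
            (float(row["logfc"]), float(row["pvalue"]))
        )
    if n_unmapped:
        logger.info(
            "%s: dropped %d genes without a human ortholog", profile.study_id, n_unmapped
        )
    entries = {
        gene: _resolve_collision(rows, collision) for gene, rows in per_human.items()
    }
    return DEProfile.from_entries(profile.study_id, entries)


def shared_universe(profiles: Sequence[DEProfile]) -> GeneUniverse:
    """Intersection of gene sets over all profiles, lexicographically ordered."""
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles to define a shared universe")
    common: set[str] = set(profiles[0].genes)
    for prof in profiles[1:]:
        common &= prof.genes
    if not common:
        raise ValidationError(
            "profiles share no genes; the corpus is not comparable"
        )
    return GeneUniverse(genes=tuple(sorted(common)))
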