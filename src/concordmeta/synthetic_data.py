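"""Synthetic multi-study differential-expression corpora with planted structure.

Each latent class c owns a sparse signal vector mu_c over the gene
universe (nonzero on a random support, with random sign and
Normal(effect_mean, effect_sd) magnitude).  Study s mixes the class
signals with weights w_s, adds independent Gaussian noise with standard
deviation sigma_s, and scales the result by an inflation factor
lambda_s >= 1 that mimics studies reporting implausibly large fold
changes (inflation moves a study away from the others in Euclidean/PCA
space but leaves its correlations untouched):

    logFC_sg = lambda_s * (sum_c w_sc * mu_cg + eps_sg),  eps ~ N(0, sigma_s^2)

P-values come from a Gaussian z-approximation of a two-sample test at the
study's sample sizes, so larger |logFC| and larger samples give smaller p
without simulating raw intensity matrices.  A secondary mode does emit
case/control expression matrices and computes Welch t-tests, for
end-to-end demonstrations of sample-size effects.

Because the construction is analytic, the expected full-gene Pearson
correlation between any two studies is available in closed form and
serves as an oracle for the concordance pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from concordmeta.study_io import (
    DEProfile,
    GeneUniverse,
    PathwayDB,
    ReferenceGeneList,
    StudyMetadata,
    ValidationError,
)


@dataclass(frozen=True)
class ClassSpec:
    """One latent signal class: a sparse +/- Gaussian effect vector."""

    name: str
    support_size: int
    effect_mean: float = 1.0
    effect_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.support_size < 1:
            raise ValidationError(f"class {self.name!r}: support_size must be >= 1")

    def signal_variance(self, n_genes: int) -> float:
        """Per-gene variance contributed by this class over the universe."""
        frac = self.support_size / n_genes
        return frac * (self.effect_mean**2 + self.effect_sd**2)


@dataclass(frozen=True)
class StudySpec:
    """Simulation parameters plus metadata for one synthetic study."""

    study_id: str
    class_weights: tuple[float, ...]
    noise_sd: float = 1.0
    inflation: float = 1.0
    n_case: int = 6
    n_control: int = 6
    species: str = "human"
    tissue: str = "substantia_nigra"
    platform: str = "affymetrix_u133"
    disease_model: str = "human_pd"
    treatment: str | None = None
    dropout_fraction: float = 0.0  # platform emulation: genes missing from output

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError(f"{self.study_id}: noise_sd must be > 0")
        if self.inflation < 1:
            raise ValidationError(f"{self.study_id}: inflation must be >= 1")
        if any(w < 0 for w in self.class_weights):
            raise ValidationError(f"{self.study_id}: class weights must be >= 0")
        if not (0 <= self.dropout_fraction < 1):
            raise ValidationError(f"{self.study_id}: dropout_fraction must be in [0, 1)")

    def metadata(self) -> StudyMetadata:
        return StudyMetadata(
            study_id=self.study_id,
            species=self.species,
            tissue=self.tissue,
            platform=self.platform,
            disease_model=self.disease_model,
            n_case=self.n_case,
            n_control=self.n_control,
            treatment=self.treatment,
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full corpus recipe.  ``seed`` is mandatory: corpora are reproducible."""

    n_genes: int
    classes: tuple[ClassSpec, ...]
    studies: tuple[StudySpec, ...]
    seed: int
    kappa: float = 1.0  # p-value calibration constant

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValidationError("n_genes must be >= 10")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate study ids in config")
        for spec in self.studies:
            if len(spec.class_weights) != len(self.classes):
                raise ValidationError(
                    f"{spec.study_id}: {len(spec.class_weights)} weights for "
                    f"{len(self.classes)} classes"
                )
        for cls in self.classes:
            if cls.support_size > self.n_genes:
                raise ValidationError(
                    f"class {cls.name!r}: support exceeds the gene universe"
                )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated corpus, for oracles and planted recovery."""

    genes: tuple[str, ...]
    class_names: tuple[str, ...]
    mu: np.ndarray                     # classes x genes signal vectors
    supports: tuple[tuple[int, ...], ...]  # per-class gene indices
    weights: np.ndarray                # studies x classes
    noise_sd: np.ndarray
    inflation: np.ndarray
    study_ids: tuple[str, ...]
    class_variances: np.ndarray        # per-class per-gene signal variance

    def study_index(self, study_id: str) -> int:
        try:
            return self.study_ids.index(study_id)
        except ValueError:
            raise KeyError(f"unknown study {study_id!r}") from None

    def support_genes(self, class_name: str) -> tuple[str, ...]:
        c = self.class_names.index(class_name)
        return tuple(self.genes[i] for i in self.supports[c])


def _gene_names(n_genes: int) -> tuple[str, ...]:
    width = max(5, len(str(n_genes)))
    return tuple(f"G{i:0{width}d}" for i in range(n_genes))


def _zscore_pvalues(
    y: np.ndarray, spec: StudySpec, kappa: float
) -> np.ndarray:
    """Two-sided Gaussian p-values for observed logFC at the study's sizes."""
    se = (
        spec.inflation
        * spec.noise_sd
        * math.sqrt(1.0 / spec.n_case + 1.0 / spec.n_control)
        * kappa
    )
    z = np.abs(y) / se
    return np.clip(2.0 * (1.0 - stats.norm.cdf(z)), 0.0, 1.0)


def generate_corpus(
    config: SyntheticConfig, mode: str = "analytic"
) -> tuple[list[DEProfile], dict[str, StudyMetadata], SyntheticTruth]:
    """Generate per-study DE profiles, metadata, and the ground truth.

    ``mode='analytic'`` (default) emits logFC with z-approximation
    p-values; ``mode='ttest'`` simulates case/control expression matrices
    around the same true effects and computes Welch t-tests, making the
    p-values genuinely sample-size dependent.
    """
    if mode not in ("analytic", "ttest"):
        raise ValueError("mode must be 'analytic' or 'ttest'")
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    genes = _gene_names(g)

    n_classes = len(config.classes)
    mu = np.zeros((n_classes, g))
    supports: list[tuple[int, ...]] = []
    for c, cls in enumerate(config.classes):
        support = np.sort(rng.choice(g, size=cls.support_size, replace=False))
        signs = rng.choice([-1.0, 1.0], size=cls.support_size)
        mu[c, support] = signs * rng.normal(cls.effect_mean, cls.effect_sd, cls.support_size)
        supports.append(tuple(int(i) for i in support))

    profiles: list[DEProfile] = []
    metadata: dict[str, StudyMetadata] = {}
    weights = np.array([s.class_weights for s in config.studies], dtype=float)
    for s, spec in enumerate(config.studies):
        signal = weights[s] @ mu
        eps = rng.normal(0.0, spec.noise_sd, g)
        y = spec.inflation * (signal + eps)
        if mode == "analytic":
            pvals = _zscore_pvalues(y, spec, config.kappa)
        else:
            within_sd = spec.inflation * spec.noise_sd * config.kappa
            base = rng.normal(8.0, 1.0, g)
            cases = rng.normal(
                (base + y)[:, None], within_sd, (g, spec.n_case)
            )
            controls = rng.normal(base[:, None], within_sd, (g, spec.n_control))
            res = stats.ttest_ind(cases, controls, axis=1, equal_var=False)
            y = cases.mean(axis=1) - controls.mean(axis=1)
            pvals = np.nan_to_num(res.pvalue, nan=1.0)
        keep = np.ones(g, dtype=bool)
        if spec.dropout_fraction > 0:
            keep = rng.random(g) >= spec.dropout_fraction
        tab_genes = [genes[i] for i in np.nonzero(keep)[0]]
        profiles.append(
            DEProfile.from_entries(
                spec.study_id,
                {gn: (float(y[i]), float(pvals[i]))
                 for gn, i in zip(tab_genes, np.nonzero(keep)[0])},
            )
        )
        metadata[spec.study_id] = spec.metadata()

    truth = SyntheticTruth(
        genes=genes,
        class_names=tuple(c.name for c in config.classes),
        mu=mu,
        supports=tuple(supports),
        weights=weights,
        noise_sd=np.array([s.noise_sd for s in config.studies]),
        inflation=np.array([s.inflation for s in config.studies]),
        study_ids=tuple(s.study_id for s in config.studies),
        class_variances=np.array(
            [c.signal_variance(g) for c in config.classes]
        ),
    )
    return profiles, metadata, truth


def expected_pairwise_correlation(
    truth: SyntheticTruth, study_i: str, study_j: str
) -> float:
    """Analytic full-gene Pearson correlation implied by the generator.

    With per-class per-gene signal variances v_c and independent noise,
    rho_ij = (w_i . diag(v) . w_j) / sqrt((w_i.diag(v).w_i + sigma_i^2)
    (w_j.diag(v).w_j + sigma_j^2)); the inflation factors cancel.
    """
    i = truth.study_index(study_i)
    j = truth.study_index(study_j)
    if i == j:
        return 1.0
    v = truth.class_variances
    s_ij = float(truth.weights[i] * v @ truth.weights[j])
    s_ii = float(truth.weights[i] * v @ truth.weights[i]) + truth.noise_sd[i] ** 2
    s_jj = float(truth.weights[j] * v @ truth.weights[j]) + truth.noise_sd[j] ** 2
    return s_ij / math.sqrt(s_ii * s_jj)


def expected_correlation_matrix(truth: SyntheticTruth) -> np.ndarray:
    n = len(truth.study_ids)
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rho[i, j] = rho[j, i] = expected_pairwise_correlation(
                truth, truth.study_ids[i], truth.study_ids[j]
            )
    return rho


def generate_pathway_db(
    truth: SyntheticTruth,
    universe: GeneUniverse | None = None,
    n_background: int = 30,
    planted: Mapping[str, int] | None = None,
    set_size: tuple[int, int] = (20, 60),
    seed: int = 0,
) -> PathwayDB:
    """Random background gene sets plus gene sets planted in class supports.

    Planted sets are subsets of a class's signal support restricted to the
    coherently up-regulated (positive-effect) genes, mimicking real
    pathways whose members move together; studies weighted on that class
    therefore show genuine positive enrichment.  Background sets are
    uniform draws from the universe and should behave as null pathways.
    """
    rng = np.random.default_rng(seed)
    genes = list(universe.genes) if universe is not None else list(truth.genes)
    lo, hi = set_size
    if lo < 1 or hi < lo:
        raise ValidationError("set_size bounds must satisfy 1 <= lo <= hi")
    if hi > len(genes):
        raise ValidationError("requested set size exceeds the gene universe")
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for b in range(n_background):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(genes, size=size, replace=False).tolist())
        pid = f"PW_BG_{b:03d}"
        pathways[pid] = (f"background set {b}", members)
    gene_set = set(genes)
    for class_name, count in (planted or {}).items():
        c = truth.class_names.index(class_name)
        support = [
            truth.genes[i]
            for i in truth.supports[c]
            if truth.mu[c, i] > 0 and truth.genes[i] in gene_set
        ]
        if not support:
            support = [g for g in truth.support_genes(class_name) if g in gene_set]
        if not support:
            raise ValidationError(
                f"class {class_name!r} has no support genes inside the universe"
            )
        for k in range(count):
            size = int(rng.integers(lo, min(hi, len(support)) + 1))
            size = min(size, len(support))
            members = frozenset(rng.choice(support, size=size, replace=False).tolist())
            pid = f"PW_{class_name.upper()}_{k:03d}"
            pathways[pid] = (f"planted in {class_name} support", members)
    return PathwayDB(pathways=pathways)


def generate_reference_list(
    truth: SyntheticTruth,
    classes: Sequence[str],
    contamination: float = 0.0,
    seed: int = 0,
    name: str = "synthetic_reference",
) -> ReferenceGeneList:
    """Union of the chosen classes' supports plus random non-signal genes.

    ``contamination`` is the fraction of the final list made of random
    genes drawn outside every class support (must be < 1).
    """
    if not (0 <= contamination < 1):
        raise ValidationError("contamination must be in [0, 1)")
    base: set[str] = set()
    for class_name in classes:
        base.update(truth.support_genes(class_name))
    if not base:
        raise ValidationError("selected classes have an empty combined support")
    rng = np.random.default_rng(seed)
    signal_genes = {g for sup in truth.supports for g in (truth.genes[i] for i in sup)}
    nonsignal = sorted(set(truth.genes) - signal_genes)
    n_extra = int(round(len(base) * contamination / (1.0 - contamination)))
    n_extra = min(n_extra, len(nonsignal))
    extra = rng.choice(nonsignal, size=n_extra, replace=False).tolist() if n_extra else []
    return ReferenceGeneList(name=name, genes=frozenset(base | set(extra)))


# ---------------------------------------------------------------------------
# presets


def two_class_config(
    n_genes: int = 2000,
    n_per_class: int = 5,
    rho_within: float = 0.5,
    seed: int = 0,
) -> SyntheticConfig:
    """Two orthogonal study classes with a chosen within-class correlation.

    Solves sigma from rho = v / (v + sigma^2) for one-hot class weights,
    where v is the class signal variance over the universe.
    """
    if not (0 < rho_within < 1):
        raise ValidationError("rho_within must be in (0, 1)")
    # effect_sd is kept small relative to effect_mean so the realized
    # signal variance over the support concentrates near its ensemble
    # value and the closed-form correlation oracle is tight (within
    # sampling error ~3/sqrt(n_genes) of observed correlations)
    support = max(1, n_genes // 5)
    cls = [
        ClassSpec("class_a", support, effect_mean=1.0, effect_sd=0.3),
        ClassSpec("class_b", support, effect_mean=1.0, effect_sd=0.3),
    ]
    v = cls[0].signal_variance(n_genes)
    sigma = math.sqrt(v * (1.0 - rho_within) / rho_within)
    studies = []
    for c, (wname, weights) in enumerate([("a", (1.0, 0.0)), ("b", (0.0, 1.0))]):
        for i in range(n_per_class):
            studies.append(
                StudySpec(
                    study_id=f"study_{wname}{i:02d}",
                    class_weights=weights,
                    noise_sd=sigma,
                    tissue="substantia_nigra" if c == 0 else "blood",
                )
            )
    return SyntheticConfig(
        n_genes=n_genes, classes=tuple(cls), studies=tuple(studies), seed=seed
    )


def pure_noise_config(
    n_genes: int = 500, n_studies: int = 12, seed: int = 0
) -> SyntheticConfig:
    """Exchangeable null corpus: no shared signal, unit noise everywhere."""
    cls = (ClassSpec("null_class", support_size=1, effect_mean=0.0, effect_sd=0.0),)
    studies = tuple(
        StudySpec(
            study_id=f"noise_{i:02d}",
            class_weights=(0.0,),
            noise_sd=1.0,
            tissue="substantia_nigra",
        )
        for i in range(n_studies)
    )
    return SyntheticConfig(n_genes=n_genes, classes=cls, studies=studies, seed=seed)


def paper_like_config(n_genes: int = 2500, seed: int = 0) -> SyntheticConfig:
    """A 33-study corpus echoing the composition of the published PD corpus.

    Purely illustrative synthetic stand-in — not the published data.  Five
    latent classes (human nigral/cortical signal, a general
    neurodegeneration signal, a blood signal, an MPTP-model signal, and
    unallocated noise) are mixed to mirror the observed grouping: human
    substantia nigra and frontal cortex studies share a strong class, MPTP
    models share their own, blood studies theirs, and a few studies carry
    inflated fold-change magnitudes.
    """
    def sup(frac: float) -> int:
        return max(10, int(round(frac * n_genes)))

    classes = (
        ClassSpec("human_sn_cortex", support_size=sup(0.14), effect_mean=1.2, effect_sd=0.4),
        ClassSpec("general_neurodeg", support_size=sup(0.16), effect_mean=0.8, effect_sd=0.3),
        ClassSpec("blood", support_size=sup(0.10), effect_mean=0.9, effect_sd=0.3),
        ClassSpec("mptp", support_size=sup(0.12), effect_mean=0.9, effect_sd=0.3),
    )

    def w(sn=0.0, gen=0.0, blood=0.0, mptp=0.0):
        return (sn, gen, blood, mptp)

    studies: list[StudySpec] = []

    def add(sid, weights, sigma, species, tissue, model, n_case, n_control,
            inflation=1.0, platform="affymetrix_u133", treatment=None):
        studies.append(StudySpec(
            study_id=sid, class_weights=weights, noise_sd=sigma,
            inflation=inflation, n_case=n_case, n_control=n_control,
            species=species, tissue=tissue, platform=platform,
            disease_model=model, treatment=treatment,
        ))

    # human patients: substantia nigra (6), frontal cortex (2), striatum (1)
    for i in range(6):
        add(f"hum_sn_{i:02d}", w(sn=0.9, gen=0.35), 0.8, "human",
            "substantia_nigra", "human_pd", 8 + i % 4, 7 + i % 3,
            inflation=6.0 if i == 5 else 1.0,
            platform="agilent" if i == 5 else "affymetrix_u133")
    for i in range(2):
        add(f"hum_ctx_{i:02d}", w(sn=0.75, gen=0.4), 0.9, "human",
            "frontal_cortex", "human_pd", 6 + i, 6)
    add("hum_str_00", w(gen=0.6), 1.0, "human", "striatum", "human_pd", 6, 5)
    # human patients: blood (3), isolated dopaminergic neurons (3)
    for i in range(3):
        add(f"hum_blood_{i:02d}", w(blood=0.85, gen=0.2), 0.9, "human",
            "blood", "human_pd", 10 + 2 * i, 10 + i, platform="illumina")
    for i in range(3):
        add(f"hum_dan_{i:02d}", w(gen=0.5), 1.1, "human",
            "dopaminergic_neurons", "human_pd", 4 + i, 4)
    # human cell lines (4, one magnitude outlier)
    for i in range(4):
        add(f"hum_cell_{i:02d}", w(gen=0.3), 1.2, "human", "cell_line",
            "genetic", 3 + i % 2, 3, inflation=8.0 if i == 1 else 1.0)
    # mouse models: MPTP striatum (5), 6-OHDA (2, one outlier), genetic (2)
    for i in range(5):
        add(f"mouse_mptp_{i:02d}", w(mptp=0.75, gen=0.3), 1.0, "mouse",
            "striatum", "neurotoxic_mptp", 5 + i % 3, 5,
            platform="affymetrix_mouse430",
            treatment="l_dopa" if i == 4 else None)
    for i in range(2):
        add(f"mouse_6ohda_{i:02d}", w(gen=0.15), 1.3, "mouse", "striatum",
            "neurotoxic_6ohda", 4, 4, inflation=7.0 if i == 0 else 1.0,
            platform="affymetrix_mouse430")
    for i in range(2):
        add(f"mouse_gen_{i:02d}", w(gen=0.45), 1.1, "mouse", "whole_brain",
            "genetic", 5, 5, platform="affymetrix_mouse430")
    # rat models: one nigral study that tracks the human signal, three others
    add("rat_sn_00", w(sn=0.55, gen=0.3), 1.0, "rat", "substantia_nigra",
        "neurotoxic_other", 4, 4, platform="affymetrix_rat230")
    for i in range(3):
        add(f"rat_str_{i:02d}", w(gen=0.15), 1.3, "rat", "striatum",
            "neurotoxic_6ohda", 4 + i % 2, 4, platform="affymetrix_rat230",
            treatment="l_dopa" if i == 2 else None)
    # one macaque MPTP study of the substantia nigra
    add("mac_sn_00", w(sn=0.3, mptp=0.5, gen=0.25), 1.1, "macaque",
        "substantia_nigra", "neurotoxic_mptp", 4, 4)

    assert len(studies) == 33
    return SyntheticConfig(
        n_genes=n_genes, classes=classes, studies=tuple(studies), seed=seed
    )


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
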