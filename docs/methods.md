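# Methods

This note documents the statistical model behind `concordmeta`, the
conventions and numerical choices embedded in the code, what the
synthetic-data generator does and does not emulate, and known
limitations.

## Data model and harmonization

A corpus is a set of studies, each a gene-level differential expression
table (log2 fold change, p-value) with metadata (species, tissue,
platform, disease model, case/control sample counts, treatment).  Inputs
are expected to be the output of a standard microarray pipeline
(normalization and linear-model fitting are out of scope here).

Harmonization applies three rules before any comparison:

- **Probe collapsing.**  When several probes map to one gene, the probe
  with the *largest* p-value is retained by default (`collision=worst_p`).
  This least-significant-probe rule is deliberately conservative and is
  kept as the default for fidelity with the published procedure this
  package operationalizes; because it is surprising (most pipelines keep
  the most significant probe), `best_p` and `max_abs_lfc` are exposed as
  alternatives rather than silently substituted.  A probe annotated to
  several genes contributes to each of them, which maximizes the shared
  gene set across platforms at the cost of some artificial correlation
  between studies on related platforms; no correction is applied.
- **Ortholog mapping.**  Animal-model symbols are relabeled to human
  orthologs through a user-supplied many-to-one map; collisions reuse the
  probe-collapse policy, unmapped genes are dropped and counted.
- **Shared universe.**  All signature and concordance computations are
  restricted to the intersection of the gene sets of every study, in
  lexicographic order, so every downstream matrix is reproducible.
  Subgroup concordances reuse the full-corpus universe and signatures
  rather than re-deriving per-subgroup universes, so that subgroup
  averages are comparable across subsets of different size; recomputing
  per subset is possible by building a corpus from the subset alone.

## Expression signatures

A study's signature is its top-k genes by |log2FC| among universe genes
with p < α; defaults k = 50, α = 0.05 applied to raw p-values
(`adjust=bh` switches to Benjamini–Hochberg).  Fold change rather than
p-value is the ranking statistic because it yields more reproducible
lists across studies.  Ties on |logFC| break by smaller p, then gene
symbol, making extraction invariant to input row order.  If fewer than k
genes qualify the signature is simply shorter — padding would fabricate
evidence.

## Concordance

The pairwise concordance of studies i and j is the Pearson correlation of
their stored logFC values over the **union** of the two signatures (each
study always has a value for every support gene, since signatures come
from the shared universe).  The union convention is a deliberate choice:
the intersection of two top-50 lists is frequently near-empty, while the
union preserves both studies' evidence; `support=intersection` is
available for sensitivity analysis.  `mode=sign` correlates the signs of
the fold changes instead, discarding magnitude.  Degenerate cases —
support smaller than 3 genes, or a constant vector — score 0 with a
logged warning, mirroring the pathway-level convention that absent
information counts as no agreement.

Per-study averages A_i (mean concordance with the other members of a
subset) and the subgroup average A_S (mean of A_i, equal to the mean
off-diagonal entry of the subgroup submatrix) summarize subsets defined
by metadata queries.

**Significance.**  A_S of a subgroup of size m is compared to the null
distribution of A_S over random m-subsets of the corpus: exhaustively
enumerated when C(n, m) ≤ 100,000, otherwise 100,000 uniform independent
draws (duplicates allowed) from a seeded generator.  The threshold is the
nearest-rank 95th percentile of the ordered null values (no
interpolation), and a subgroup is significant iff A_S strictly exceeds
it.  Smaller subgroups have wider nulls, hence higher thresholds.  Under
an exchangeable null this rule fires on ≈ 5 % of random subgroups, which
the acceptance suite verifies by simulation.

**Sample-size regression.**  OLS of A_i on total sample size
(case + control) with a two-sided t-test on the slope asks whether small
studies are systematically discordant; constant sizes raise an error, a
constant response returns a zero slope with R² = 0.

## Pathway enrichment (preranked GSEA)

Genes are ranked by signed logFC (ties lexicographic).  For a gene set of
size n in a ranked list of N genes, the running sum adds
|score|^w / Σ_hits |score|^w at each member gene and subtracts
1/(N − n) at each non-member; the enrichment score ES is the extreme of
maximal absolute deviation (positive preferred on an exact tie; if all
hit scores are zero the statistic falls back to its unweighted form).
Defaults: weight w = 1, minimum set size 10 after intersection with the
ranked list, 1000 permutations.

The null permutes gene labels — the only exchangeable unit available in
preranked mode — with one permutation per replicate shared by all
pathways, which is what allows a pooled FDR.  Per pathway: NES = ES
divided by the mean |null ES| of matching sign (falling back to the
unsigned mean when a sign has no null mass, dropping the pathway if the
null is entirely degenerate); the nominal p is the same-sign null tail
fraction at |ES|.  FDR q follows the standard pooled-NES recipe — the
tail fraction of pooled permuted NES beyond the observed NES divided by
the tail fraction of observed NES beyond it, clamped to [0, 1] — then
monotonized so q never increases with |NES| within a sign.  The exact q
values of any particular GSEA implementation are version-dependent;
correctness here is established against the package's own oracles
(brute-force ES agreement, null p-value uniformity, planted-pathway
power) rather than value-matching an external tool.

Pathway-level concordance between two studies is the Pearson correlation
of NES over the union of pathways with q < 0.25 in either study, with 0
imputed where a study has no row for a pathway (it was size-filtered
there); an empty or too-small union, or a constant vector, scores 0.
Species-specific pathway databases can be supplied per study as long as
they share the pathway-id namespace.

## Embedding and clustering

PCA operates on the studies × genes matrix of logFC over the union of
signatures (k = 50 by default), centered and scaled per gene;
zero-variance columns are dropped first.  Component signs are fixed by
making each component's largest-|loading| gene positive.  Because fold
changes of a few "inflated" studies can dominate this space, a sign-mode
feature matrix (only the direction of regulation) is available as the
mitigation, in preference to ad-hoc outlier removal.

Clustering uses correlation distance d = 1 − r between study rows of the
top-10-signature-union matrix (magnitude-insensitive, unlike Euclidean
distance), with average linkage by default and complete linkage as an
option.  The merge tree comes from the standard agglomerative linkage
algorithm; the test suite validates it against a naive O(n³)
agglomeration oracle.

**Multiscale bootstrap support.**  For scales r ∈ {0.5, …, 1.4} (step
0.1), round(r·G) gene columns are resampled with replacement B = 1000
times per scale; BP_r of an internal node is the frequency with which its
exact leafset (no partial credit) reappears after reclustering.  The
approximately unbiased support fits Φ⁻¹(1 − BP_r), clamped to
[1/(B+1), B/(B+1)], by weighted least squares on (√r, 1/√r) with weights
B / (BP_r (1 − BP_r)), giving coefficients (v, c) and
AU = 1 − Φ(v − c); BP is reported at r = 1.  Nodes whose BP saturates at
0 or 1 in (almost) every scale leave the probit fit with fewer than two
informative points; such nodes fall back to their plain bootstrap
probability, which is the natural limit (a cluster reproduced in every
replicate at every scale has support 1).  A study whose resampled row is
constant has no defined correlation in that replicate and supports no
cluster containing it.  All bootstrap runs are bit-reproducible given
(seed, scales, B).

## Vote-counting meta-analysis

A gene receives a vote from each study whose signature contains it; genes
with ≥ 3 votes within a subset are significant.  The published method
this implements states the threshold as "more than three studies" while
its own result table and headline counts follow a ≥ 3 rule; the package
defaults to ≥ 3 (configurable) and records the discrepancy rather than
hiding it.  Direction is annotation only: up/down tallies are kept
per gene, and a gene regulated in both directions is labeled `conflict`
and excluded from direction-specific reporting but retained in the table.
Significant lists are scored by overlap count and percentage against a
reference gene list, with an optional hypergeometric p-value against the
corpus universe as supporting context (vote counting itself makes no
distributional claim — it is the method of last resort when agreement is
too low for effect-size pooling, which is precisely the regime here).

The packaged `table2_fixture.tsv` transcribes the published 43-gene vote
table (columns: all studies, human studies, substantia nigra studies)
and anchors the worked examples: 43 genes at ≥ 3 votes over all studies,
22 over human studies, maximum vote count 6.

## Synthetic corpus generator

Per study s and gene g:

    logFC_sg = λ_s · (Σ_c w_sc · μ_cg + ε_sg),   ε_sg ~ N(0, σ_s²)

where each latent class c has a sparse signal vector μ_c — nonzero on a
random support of chosen size, with random sign and
N(effect_mean, effect_sd) magnitude — and λ_s ≥ 1 is a fold-change
inflation factor that scales a study's magnitudes without changing any
of its correlations (mimicking the magnitude-dominated outlier studies
seen in real corpora).  P-values come from a two-sided Gaussian
z-approximation at the study's sample sizes,
p = 2(1 − Φ(|logFC| / (λ_s σ_s √(1/n_case + 1/n_control) κ))), keeping
the generator fully analytic; a secondary `ttest` mode simulates actual
case/control expression matrices and computes Welch t-tests when genuine
sample-size behaviour is wanted.  Optional per-study gene dropout
emulates platform differences and exercises the shared-universe
intersection.

The expected full-gene correlation between studies i and j is available
in closed form,

    ρ_ij = (w_i · diag(v) · w_j) / √((w_i·diag(v)·w_i + σ_i²)(w_j·diag(v)·w_j + σ_j²)),

with per-class per-gene signal variance v_c = (support/G)(mean² + sd²);
λ cancels.  This oracle is accurate to sampling error (≈ 3/√G) only when
the realized signal variance over a finite support concentrates near its
ensemble value, so preset classes keep effect_sd small relative to
effect_mean (0.3 vs 1.0 in `two_class_config`, giving ≈ 3 % relative sd
of the realized class variance); large dispersions would make the
closed-form oracle misleading.

Presets: `pure_noise_config` (exchangeable null for calibration),
`two_class_config` (two orthogonal study classes; σ is solved from the
requested within-class ρ via ρ = v/(v + σ²)), and `paper_like_config` —
33 studies whose composition (19 human including 6 nigral and 2
cortical, 9 mouse, 4 rat, 1 macaque; blood, MPTP, genetic and cell-line
groups; a few λ up to 8 inflated studies) echoes the published PD corpus.
The preset is an illustrative stand-in, not the published data: it
reproduces the qualitative structure (highest concordance in human
nigral studies, distinct blood and MPTP signals, magnitude outliers),
not the published Table 1 values, which depend on the original
GEO datasets and are therefore documented as context only.

Planted pathways for enrichment power studies are drawn from the
*positive-effect* part of a class support, modeling coherently regulated
gene sets; a sign-agnostic draw would scatter members to both ends of
the ranking and dilute the KS statistic by construction.  Synthetic
reference gene lists take the union of chosen class supports plus a
chosen contamination fraction of non-signal genes.

What the generator does **not** emulate: probe-level intensities and
normalization artifacts, correlated noise between genes (co-expression),
batch effects, tissue-specific baseline expression, and annotation noise
in ortholog maps.  Tests passing on synthetic corpora therefore
establish the statistical machinery (calibration, power, oracles), not
robustness to those real-data pathologies.

## Pipeline, seeds, and problem sizes

`run_pipeline` derives named integer substreams (corpus, GSEA, null
resampling, bootstrap, pathway and reference generation) from one root
seed via a seed sequence, so every artifact is byte-reproducible.
Subgroups are metadata queries (`=`, `AND`, `OR`, `NOT`, parentheses);
queries matching fewer than three studies are reported as skipped.  The
report (JSON + TSV tables + Newick tree) contains every configured
subgroup exactly once.

Default problem sizes were chosen so the full synthetic demonstration
(33 studies × 2,500 genes, 200 GSEA permutations per study, null
resampling capped at 100,000 subsets per size, 10 bootstrap scales ×
1000 replicates) runs in well under a minute on one CPU; the test
suite's simulation studies (200 null corpora, 20–40 seeded replicates
per power/recovery check) complete in a few minutes.

## Known limitations

- The worst-p probe-collapse rule and multi-gene probe duplication are
  kept for procedural fidelity even though both are debatable; switch
  the policy explicitly if fidelity is not the goal.
- Signature-level concordance depends on the support convention; union
  (default) and intersection can differ materially when signatures
  barely overlap.
- Gene-label permutation treats genes as exchangeable, ignoring
  inter-gene correlation; on real data the GSEA p-values are
  anti-conservative to an unknowable degree (a limitation shared by all
  preranked GSEA implementations).
- AU values from the probit fit are asymptotic approximations; for
  saturated clusters they reduce to plain BP by construction, and for
  very small corpora (< 4 studies) no support is computed at all.
- Vote counting discards effect sizes entirely; it answers "how often is
  a gene top-ranked", not "how large is its effect".
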