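# Methods

## The connectivity-mapping model

`fishcmap` connects chemical treatment conditions by the similarity of their
transcriptomic profiles. The two objects at the core are:

**Rank-ordered gene lists (ROGLs).** For each treated sample, every probe of
the platform receives a log2 fold-change (LogFC) against its control
reference. Probes are sorted by |LogFC| ascending and assigned ranks
1..N in that order, each rank signed by the direction of change, so a ROGL
is a complete signed permutation of the platform. No statistical filtering
is applied at this stage: weakly responding probes simply occupy low ranks,
where they contribute little to any score. The reference database is a
collection of ROGLs organized into sets by shared experimental parameters
(chemical; chemical + tissue; ...).

**Query signatures.** A signature is the small set of differentially
expressed probes for one condition, each carrying a ±1 direction sign and
its source LogFC. Differential probes are called by an empirical-Bayes
moderated t-test and ranked by Benjamini–Hochberg FDR; a signature keeps
the FDR-ascending head, subject to a minimum of 4 probes (conditions below
that contribute ROGLs only) and a maximum of 100 (within-platform use) or
500 (cross-platform use, where translation losses argue for larger inputs).

**Scoring.** The raw connectivity of a signature *s* against a ROGL with
signed ranks *r* is

    c_raw = Σ_i  s_i · r(probe_i),      s_i ∈ {+1, −1}

normalized by the largest attainable value, `max_score(m, N) =
Σ_{j=N−m+1}^{N} j`, giving c ∈ [−1, 1] comparable across signature and
platform sizes; c = +1 exactly when the signature's probes occupy the top m
absolute ranks with matching signs, −1 when all signs oppose. A ROGL set is
scored by the arithmetic mean of its members' normalized scores, so set
size does not bias the statistic. The same statistic is applied to the null
signatures, which is what "accounting for set-size variation" amounts to
here; no further adjustment is applied to the ranking score.

**Significance.** The null distribution is generated from simulated
signatures of the same size m: probes drawn uniformly without replacement
from the platform's probes, each with an independent uniform ±1 sign — a
sign-symmetric null with mean score 0. The empirical p-value is the plain
proportion of null set scores greater than or equal to the observed one
(10,000 simulations by default). Across a collection of S sets, connections
with p ≤ 1/S are flagged significant; this calibrates the expected number
of false connections per query to one, and the package reproduces that
calibration empirically (random signatures against S = 20 random sets flag
at a rate statistically indistinguishable from 1/S). A probes-only null
(all signs +1, comparison on |score|) is available behind
`signed_null=False`, and `(k+1)/(n+1)` smoothing behind `smoothing=True`
for users who object to literal p = 0.

## The moderated t-test

Per-probe residual variances s² with d degrees of freedom are shrunk toward
a prior: the hierarchical model takes the true probe variances as scaled
inverse-χ² with prior variance s₀² and prior degrees of freedom d₀, giving
the posterior

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),     t = Δmean / (s̃·SE-scale)

with d₀ + d degrees of freedom. (s₀², d₀) are estimated by method of
moments on log s²: the excess variance of `log s² − ψ(d/2) + log(d/2)` over
`ψ′(d/2)` is inverted through the trigamma function for d₀, and the mean
gives s₀². Non-positive excess variance means the probe variances are no
more dispersed than sampling noise, so d₀ = ∞ and every probe uses the
pooled variance. The implementation agrees with the Bioconductor eBayes
fit to machine precision on shared fixtures (an R cross-check test runs
when `Rscript` is available), and `prior_df=0` recovers the ordinary
pooled-variance t exactly. One-color and common-reference designs are
analyzed as two-group comparisons; two-color direct designs as a one-sample
t on dye-swap-corrected pair LogFCs. A Welch t is available as a fallback
for grossly heteroscedastic groups.

## Cross-platform translation

A signature interrogates another platform by substituting its probe IDs
through a (possibly many-to-many) probe-equivalence table while keeping
source signs and LogFCs. Every source probe expands to all its targets;
duplicate targets collapse to the source record with the largest |LogFC|;
a target receiving conflicting signs is dropped rather than given a
fabricated direction. The result is re-ranked by source FDR and truncated
at `max_size`. This conservative policy is a design choice — the upstream
construction of the mapping (sequence alignment, shared gene IDs) is out of
scope and the table is an input.

## Networks and the informative-connection rate

Significant, non-self connections (a connection is "self" when signature
and ROGL set share an experiment of origin) aggregate into an undirected
network over condition labels at a chosen granularity (chemical by default;
chemical+tissue and chemical+dose+tissue for finer views). Per unordered
pair, only the single highest-scored connection in either query direction
survives, so the network is order-independent in its inputs.
`filter_subnetwork` keeps nodes with at least one incident edge above a
score threshold — and then *all* surviving edges among kept nodes, including
weak ones, matching how sub-networks of strongly connected chemicals are
usually displayed. A query is scored "informative" when any of its top-5
ranked significant hits is a self hit (counted as the same chemical) or
involves a chemical sharing an MOA class label; judgment calls about
related-but-distinct classes are encoded as explicit class-similarity pairs
in the MOA table, never hard-coded.

## The synthetic-data generator

`simulate_study` emulates the regime of multi-laboratory fish microarray
studies: log2-scale baseline probe means ~ Normal(8, 2), additive Gaussian
per-sample noise, and per-chemical differential-expression modules whose
probes shift by ±(effect × dose multiplier). Chemicals belong to MOA
classes; same-class chemicals share a core fraction of their module with
identical signs, which is what makes class structure recoverable by
connectivity. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_probes` | 10,000 | platform size N (real arrays: ~15K–44K) |
| `chemicals` | 3 classes × 3 chemicals | ER agonists, AhR agonists, GABA-targeting neurotoxicants |
| `module_size` | 100 | true DE probes per chemical |
| `class_overlap` | 0.6 | module fraction shared within a class |
| `effect_size` | 1.0 | log2 units (a 2-fold change) |
| `noise_sd` | 0.5 | log2 units per sample |
| `n_treated`, `n_control` | 4, 4 | replicate fish per condition |
| `dose_multipliers` | (1.0,) | linear scaling of the effect |

At these conditions the moderated-t/BH pipeline calls on the order of 5–40
of the 100 module probes at FDR ≤ 0.05 — deliberately far from saturation,
mirroring real conditions where many treatments yield few DEGs and some
drop below the 4-probe signature minimum. What the generator does **not**
emulate: probe-level cross-hybridization, dye bias, intensity-dependent
variance, batch effects between laboratories, and correlated noise across
probes. Passing recovery tests therefore demonstrate the pipeline's logic
and calibration, not robustness to those real-data artifacts (a Student-t
noise flag, `noise_df`, provides heavier tails for robustness checks).

## Numerical choices

- **Tie-breaking in ROGLs:** stable ascending sort with lexicographic
  probe-ID tiebreak; zero LogFC gets a positive sign (zeros land in the
  lowest ranks where they matter least). Both choices are arbitrary but
  fixed, making ROGLs bit-reproducible.
- **Control averaging** is done on the log2 scale by default (geometric
  mean of intensities); `control_average="intensity"` averages raw
  intensities instead. The two differ only for heterogeneous control
  groups.
- **Exact vs Monte-Carlo p-values:** enumeration is auto-selected when the
  null space C(N, m)·2^m ≤ 10⁵, making small-instance results exactly
  reproducible; Monte Carlo requires an explicit seed.
- **Null sampling** uses rejection sampling of index rows when m² ≤ N
  (collisions are rare) and a random-key partial sort otherwise; both are
  exactly uniform over m-subsets. A per-(set, m) cache can share null
  draws across a batch of queries where only the ranking matters.
- **Missing data:** probes missing in a profile are excluded and the ROGL
  built over the remaining N′; signature probes absent from a ROGL are
  dropped per-ROGL with that ROGL's m′ used in its `max_score`; queries
  abort if any m′ falls below the minimum signature size.
- **Degenerate inputs** are errors, not silent defaults: empty control
  groups, all-missing profiles, m > N, S = 0, empty collections.

## Problem sizes in the shipped tests

The test suite and `scripts/acceptance.py` keep simulations compact: 20
replicate end-to-end studies at the default conditions for parameter
recovery, 500 (tests) / 200 (script) null-calibration queries against
S = 20 sets of 120-probe ROGLs at 400 simulations each, and exhaustive-
enumeration cross-checks on ROGLs of up to 8 probes. These sizes give the
binomial tolerances quoted in the tests; all rates are reported with their
denominators.

## Known limitations

- The set-level score (mean of member-normalized scores, identical statistic
  in the null) is this package's reading of set-size adjustment; other
  connectivity-mapping implementations use unpublished variants, so absolute
  score values are not comparable across tools — rankings generally are.
- The informative-connection evaluation depends entirely on the MOA table
  provided; chemicals missing from it can never be informative.
- Ordered (rank-weighted) signatures and KS/GSEA-style enrichment scores
  are out of scope; signatures are always unordered ±1 sets.
- Normalization is upstream: matrices are assumed log2-normalized, and no
  background correction or quantile/loess normalization is provided.
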