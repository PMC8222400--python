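# Methods

This note documents the statistical models implemented in `reposcreen`,
the parameter defaults and why they were chosen, what the synthetic
benchmark does and does not emulate, and the numerical conventions that
make results reproducible.

## 1. Gene-set integration

Disease gene lists from multiple named sources are normalised
(whitespace-trimmed, upper-cased), resolved through an optional alias map
(alias → official symbol; chains are followed to a fixed point, cycles
are a configuration error), unioned, and filtered against a
caller-supplied drop list.  Removing "genes of unknown function" is a
curation judgement, not an algorithm, so it is exposed as data (the drop
list) rather than logic.  Unknown aliases pass through with a warning
instead of failing the merge: real source lists always contain a tail of
unmappable identifiers and discarding a whole merge for them would be
worse than carrying them.  Provenance (gene → contributing sources) is
kept on every merged set, which makes Venn-style source breakdowns exact
rather than re-derived.

## 2. Interaction network

Scored edge tables (STRING-dialect: `protein1 protein2 combined_score`,
score in [0, 1]) are filtered at a confidence cutoff, default **0.9,
inclusive** — an edge scoring exactly 0.9 is retained.  Unscored lists
(PINA/HuRI-style) are taken whole.  All sources are unioned into one
undirected simple graph, orientation-invariantly deduplicated, with
per-edge source tags.  The combined score is treated as opaque; we do not
recompute it from evidence channels.  All distances are **unweighted hop
counts** (breadth-first search); disconnected pairs get an `UNREACHABLE`
sentinel (`inf`) rather than an arbitrary large constant.

## 3. Network proximity

### Statistic

For disease set *G*, target set *T*:

d(G,T) = (1/|T'|) Σ_{t∈T'} [ min_{g∈G} d(g,t) + w(t) ],
w(t) = −ln(deg(t)+1) if t ∈ G else 0,

where *T'* ⊆ *T* is the set of *contributing* targets.  Targets absent
from the network, or unreachable from every disease gene, are dropped
from the average (and counted in `n_targets_dropped`): the closest-
distance form is undefined for infinite distances and imputing a large
finite value would make the statistic depend on an arbitrary constant.
The identical dropping rule applies to null draws so observed and null
distances are comparable.

*D* in the weight is the degree of the target itself.  The weight only
applies in the branch where the target is a disease gene, so "degree of
the disease gene" and "degree of the target" coincide there; we use the
target's degree throughout.

Because min_{g∈G} d(g,t) depends only on *t* (one multi-source BFS from
*G*), each node's contribution to d(G,T) is a fixed scalar.  Scoring a
drug or a null draw is then an O(k) average over precomputed values,
which is what makes 10,000-draw nulls per drug cheap.

### Null model and z-score

The reference distribution draws *k* = |T'| distinct nodes uniformly
from the network (default 10,000 draws), scores each draw identically,
and reports z = (d_obs − μ)/σ with σ the sample (ddof = 1) standard
deviation.  Draws whose nodes are all unreachable are redrawn.  A σ
numerically indistinguishable from zero (relative tolerance 1e−12, which
absorbs the O(eps) spread a constant sample acquires from floating-point
averaging) raises a degenerate-null error rather than returning ±inf
z-scores.

Uniform sampling is the default because the method's published form
specifies only "randomly selected in the network"; a log2-degree-binned
matched sampling mode is available (`mode="degree_binned"`) for users
who want to control for target degree, but it is not the default.  The
null samples from the full supplied network, not the disease
subnetwork.

Each drug's random stream is seeded by a BLAKE2 hash of
`(global seed, drug_id)`, so per-drug results are independent of drug
ordering and reproducible in isolation.

### Screen

The screening statistic for the distance threshold (default 1.0,
**strict** `<`) is the raw weighted distance d(G,T), not the z-score;
z-scores are reported alongside.  The two scales answer different
questions (absolute closeness vs closeness beyond size-matched chance)
and the published screen is phrased on the distance scale.  The density
summary (drugs vs reference distances) uses a Gaussian KDE on a shared
grid so both curves integrate to 1.

## 4. Signature enrichment (IGSEA-style screen)

Profiles are single ranked signatures (one statistic per gene), sorted
descending with ties broken by symbol so ranking is total and
deterministic.  The enrichment score is the classic weighted running
sum: at member genes the walk rises by |stat|^p / Σ_members |stat|^p
(weight exponent p = 1 by default; if all member stats are zero the
increments fall back to 1/N_hit), at non-members it falls by
1/(N − N_hit); ES is the signed extremum of the walk and lies in
[−1, 1].  When the set covers the whole list ES = 1.

"Inverted" screening is interpreted as two-sidedness: a disease set
concentrated at *either* extreme of a drug's signature (|ES| large,
negative ES = enrichment at the bottom, i.e. potential reversal) counts
as a candidate.  One-sided modes (`greater`, `less`) are available.

Permutations are **gene-label** permutations — random member sets of the
same overlap size drawn without replacement — because profiles arrive as
single signatures with no sample-level data to permute.  The p-value
uses the add-one estimator p = (1 + #{|ES_null| ≥ |ES_obs|})/(1 + n_perm)
(valid for permutation tests, never exactly zero), with 1,000
permutations by default.  Null ES values are computed vectorised from
member positions via prefix sums (the walk's extrema occur at member
positions), which is algebraically identical to the explicit walk.

BH FDR is applied across all profiles screened in one run — the family
is the screen, not each drug.  Candidate tiers are **strict**:
FDR < 0.25 (candidate) and FDR < 0.1 (top tier); FDR exactly at a cutoff
is outside the tier.  The generic hypergeometric over-representation
test (one-sided upper tail, BH across terms, significant at FDR < 0.05)
takes user-supplied term → gene annotations; no ontology services are
queried.

## 5. Differential expression and intersection

Expression values must be positive (an optional pseudo-count handles
zeros).  The pipeline log2-transforms, then per-gene centers and scales
— with the **sample (n−1) standard deviation** — for visualisation and
clustering; constant genes scale to 0 and are flagged.  The two-group
test runs on **log2 values** (`test_on="scaled"` switches, for
sensitivity analysis): centering-and-scaling removes exactly the
per-gene location the test estimates, so testing scaled values is not
the default.

The default test is Welch's t (unequal variances), two-sided, with a
pooled-variance option.  At cohort sizes where this package is used the
moderated-variance refinements of microarray-era pipelines change little;
the accuracy claims here are calibration (type-I at nominal rate) and
planted-effect recovery, both verified in the acceptance tests.  Genes
identical in both groups are reported as statistic 0, p = 1.  DEGs are
genes with p **strictly** below α = 0.05.

The intersection step annotates each DEG that is a target of a candidate
drug (by default the FDR < 0.1 tier's targets) with the contributing
drugs.  Group summaries use linear-interpolation quartiles and 1.5·IQR
whiskers (whiskers end at the most extreme observation inside the
fences).  Clustering of intersection genes uses average linkage on
correlation distance (1 − Pearson) over standardized expression, cut at
2 clusters by default; the distance/linkage pair is this package's
choice (none is prescribed by the method's published form), constant
rows are excluded, genes are processed in sorted order and labels
renumbered by first occurrence so assignments are input-order invariant.

## 6. Synthetic benchmark

The generator produces every input with known planted structure:

| component | default | rationale |
|---|---|---|
| network | scale-free (preferential attachment, m = 2), 1,000 nodes | heavy-tailed degrees, to which the hub weight −ln(D+1) is sensitive; Erdős–Rényi (edge-count matched, p = 4/(n−1)) available as contrast |
| disease module | 50 genes, BFS-grown | disease genes interact: the module's induced subgraph is connected (≥ size−1 internal edges) |
| proximal drugs | 10 drugs × 5 targets from module ∪ first neighbors | should pass the proximity screen |
| distal drugs | 10 drugs × 5 targets at hop distance ≥ 3 | beyond first/second neighbors, so the separation is unambiguous at small n |
| perturbation effect | shift of 2 (sd units) on disease genes, sign fixed per drug | rank-extreme concentration detectable at 50/1000 genes |
| expression cohort | 20 cases / 20 controls, log-normal values, DE shift 2 sd on the module genes | log2 step is meaningful on log-normal data; effect-2 at n = 20/20 gives near-complete power, nulls stay at nominal |

Generation is a pure function of (parameters, seed); sub-stages use
fixed seed offsets.  The writers emit exactly the formats the pipeline
reads (GMT with the module split into three overlapping pseudo-sources
to exercise provenance; STRING-dialect edge TSV; drug-target TSV;
profile TSV; expression TSV + label file).

**What passing tests do not show.**  The benchmark's network is
scale-free but has none of the ascertainment bias of curated
interactomes (well-studied genes have inflated degree); its profiles
are i.i.d. normal rather than correlated across genes; its expression
matrix has no batch effects, array-normalization artifacts, or
covariates.  Calibration and recovery on this benchmark validate the
statistics' implementation and power at stated effect sizes — not the
biological accuracy of any screen run on real data, which depends on
the completeness of the input databases.

## 7. Pipeline

Stages run in analysis order: gene merge → network → proximity screen →
enrichment (only drugs passing the distance screen, unless
`screen_all_drugs`) → differential expression → intersection against the
FDR < 0.1 tier's targets.  All thresholds and iteration counts live in
one flat config whose defaults are the published operating points
(score ≥ 0.9, distance < 1.0, p < 0.05, FDR 0.25/0.1, 10,000
randomizations, 1,000 permutations).  `validate_config` collects every
violation rather than failing at the first.  With a fixed seed, reruns
are byte-identical on all TSV outputs (the JSON report additionally
carries wall-clock times, which naturally differ).  Any stage failure
aborts with the stage name after writing the partial report.

## 8. Problem sizes in the evaluation

The acceptance evaluation (`scripts/acceptance.py`, mirrored by the
acceptance tests) uses: 1,000 random networks ≤ 30 nodes for the
proximity oracle; exhaustive enumeration of all 66 2-subsets of a
12-node graph against a 10,000-draw null; 500 null replicates for z
calibration (1,000-draw nulls); the default 1,000-gene scenario for
planted-signal recovery; 1,000 random instances for the ES oracle; 500
null profiles and 20 planted screens (1 hit among 9 nulls, 1,000
permutations) for enrichment calibration and power; and 2,000 genes at
n = 20/20 for DE calibration and power.  These sizes give stable
estimates (binomial SE ≈ 0.01 on the calibration rates) while keeping
the full evaluation under a minute.

## 9. Known limitations

* Proximity is only as good as the input interactome and target
  annotations; dropped (unmapped/unreachable) targets are reported but
  silently shrink |T|, so drugs with many dropped targets deserve
  scrutiny.
* The uniform null does not control for target degree; hub-heavy target
  sets get systematically negative z.  The degree-binned mode mitigates
  but does not remove this.
* The enrichment walk's conventions (weight exponent, two-sided
  inversion) are reasonable defaults, not a reconstruction of any
  specific published variant.
* Welch's t on 4–8 samples per group is underpowered and its p-values
  should not be over-read; the moderated alternatives are out of scope.
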