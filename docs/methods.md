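# Methods

`addr` implements a union-then-filter drug-repurposing pipeline for a
target disease on a heterogeneous biomedical knowledge graph: metapath
feature ranking of candidate indications, pooling of several models'
top-k lists, literature-evidence stratification by formula-defined rates,
and survival validation in a left-truncated longitudinal cohort. This
note records the models, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical choices a
maintainer would want to know about.

## Hetnet representation

Nodes are typed opaque strings; edges are typed and stored directed, but
degree counting and all path traversal treat them as traversable in both
directions (the semantics under which the upstream graph models operate).
The metagraph schema is inferred from observed `(source_type, edge_type,
target_type)` triples. Parallel edges are kept as a multiset and each
counts toward degree and toward path instances; a self-loop counts twice
toward degree (once per endpoint), and the same convention is used in the
matrix route so the two traversal implementations agree exactly.

## Degree-weighted path counts

For a metapath λ (an alternating node-type/edge-type schema such as
drug–target–gene–association–disease) and a node pair (s, t),

    DWPC_λ(s, t) = Σ_{p ∈ P_λ(s,t)} Π_{v ∈ p \ {s,t}} deg(v)^(−w)

with damping exponent w = 0.4 by default. Choices that needed fixing:

- **Path vs walk semantics.** `P_λ` contains node-distinct paths by
  default; repeated-node walks inflate counts through degenerate
  backtracking. Walk semantics remain available
  (`path_semantics="walks"`) and are computed by a damped sparse
  matrix-product chain; path semantics use a pruned depth-first traversal
  per source. Both agree with an independent exhaustive enumerator to
  1e−9 in the tests.
- **Damping degree.** The degree of an intermediate node v traversed in
  via edge type `e_in` and out via `e_out` counts v's incident edges
  whose type is `e_in` or `e_out`. This makes the one-path closed form
  (single gene with one drug edge and one disease edge) equal 2^(−0.4).
  A `degree_mode="total"` variant counts all incident edges.
- **Metapath enumeration.** All schema-valid metapaths between the
  endpoint types up to 4 hops, traversing schema triples in both
  directions but never immediately reversing the triple just traversed:
  a bounce like drug–indication–disease–indication–drug adds no
  connectivity beyond the direct relation and would otherwise multiply
  the feature set without bound. Output is deduplicated and ordered by
  (length, abbreviation) so feature columns — and therefore fitted
  coefficients — are reproducible.
- **Label-edge exclusion.** The bare length-1 metapath of the label edge
  type ("indication") is excluded from the feature table: under
  node-distinct semantics it is exactly an indicator of the edge being
  predicted. Longer metapaths that traverse indication edges between
  *other* node pairs are kept; node-distinctness guarantees a pair's own
  direct edge cannot appear inside any longer path for that pair.
- **Prior.** The degree-based indication prior for (drug, disease) is
  `deg_ind(drug) · deg_ind(disease) / n_ind²`, clipped to [0, 1] — a
  closed-form prevalence estimate chosen over permutation-derived priors
  for determinism and speed. It is 0 when the graph has no indication
  edges and 1 in the degenerate single-indication case.

## Indication ranking

Labels follow the closed-world assumption: every (drug, disease) pair
without a recorded indication edge is a negative; the full negative set
is used unweighted. The classifier is elastic-net-penalized logistic
regression on standardized DWPC features,

    logit(y) = β₀ + Σ_λ β_λ DWPC_λ(s, t) + β_prior · prior,

with penalty mix 0.5 and overall strength selected by 5-fold
cross-validated log-loss over a logarithmic grid (seeded) — standard
elastic-net practice where the source method leaves the hyperparameters
open. Coefficients are reported on the standardized scale. Zero-variance
columns are removed before the solver (the saga optimizer otherwise
returns a spurious intercept on constant designs); if nothing varies the
intercept-only fit is the closed-form logit of prevalence. One global
model is fitted across all diseases; the target disease's column is used
at ranking time. Ranking removes masked drugs (for Alzheimer's disease,
the eight approved therapeutics in `DEFAULT_AD_MASK`) before truncation
to the top k = 30, with lexicographic drug-id tie-breaks.

The candidate pool is the set union of the per-model ranked lists with
per-model rank provenance. No score harmonization or rank aggregation is
done across models — pooling is deliberately union-then-filter.

## Evidence rates and stratification

Each abstract about a candidate drug receives one judgment in
{+1, 0, −1}. Per drug, counts (P, U, N) with |T| = P + U + N give rates
R_p = P/|T|, R_u = U/|T|, R_n = N/|T|, kept as exact rationals
(`fractions.Fraction`); the printed two-decimal values are display-only.
Criterion 1 labels a drug NeutralRelation when R_u ≥ 0.99, otherwise
PotentiallyTherapeutic when R_p ≥ R_n, else PotentiallyAdverse; both
branches of the published rule are satisfiable at the tie R_p = R_n, and
the tie resolves to therapeutic (the branch order that reproduces the
published tied row). Criterion 2 flags any drug with at least one
positive judgment. Drugs with |T| = 0 are InsufficientKnowledge under
both rules, and Criterion-1-therapeutic implies Criterion-2-therapeutic
(verified exhaustively over all count triples with |T| ≤ 60). Abstracts
whose backend fails after retries are recorded as unjudged and excluded
from |T| rather than coerced to neutral, which would silently inflate
R_u. Retrieval limits (publication year ≥ 2000, ≤ 200 abstracts per
drug) are enforced at ingestion regardless of backend.

The default judgment backend is a deterministic lexicon mock (editable
token lists under `src/addr/data/lexicons/`): positive iff a
positive-lexicon token appears without any negative token, negative for
the converse, neutral otherwise including both-present ties. An adapter
for chat-completion backends is provided; its prompt instructs judgment
from the supplied text only and demands exactly one of the three labels.
The mock exists so every downstream computation is network-free; it
makes no claim of emulating LLM judgment quality, only the judgment
*interface* and the downstream arithmetic.

## Cohort validation

Per drug, a Cox proportional-hazards model on the age timescale with
risk sets defined by (entry age, exit age] intervals (left truncation,
right censoring), adjusting for baseline age, sex, education, marital
status, and living situation; categorical covariates are one-hot encoded
against fixed reference levels (married; living with partner). Ties use
the Efron approximation (the standard default; event times here are
continuous so ties are essentially absent). Exposure is the baseline
chronic-use flag — the drug documented at two or more consecutive visits
— not a time-varying covariate. The fit returns not-estimable (rendered
"NA") when the drug is absent, exposure is constant, or no events occur
among the exposed; significance is flagged at the strict 0.05 and
exploratory 0.30 thresholds. Trial cross-tabulation counts, among pool
drugs with at least one registered trial, those each criterion labels
potentially therapeutic; a published trial count may exceed its listed
registry ids (printed tables truncate the id list), never undercut them.

## Synthetic generators

All three generators are deterministic given their seed and are
first-class, tested code.

**Knowledge graph.** Typed nodes (default 50 drugs, 20 diseases, 100
genes, 10 pathways — a reduced-scale stand-in for a harmonized
multi-source biomedical graph), independent Bernoulli edges per schema
triple at low densities (0.5–2%), and a configurable number of planted
drug→disease indication edges (default 40), each additionally supported
by 2 drug–gene and gene–disease edges through dedicated genes so the
signal is recoverable from multi-hop topology when the direct edge is
held out. It does not emulate degree heterogeneity (hubs), correlated
edge placement, or the relation-type richness of real graphs, so passing
recovery tests shows the estimator works when the planted mechanism
matches the feature family — not that it ranks well on real graphs.

**Abstract corpus.** For planted per-drug counts (P, U, N), emits P
abstracts containing a positive-lexicon token, N a negative token, and U
neither, with synthetic pmids and years ≥ 2000, under the 200-abstract
cap. The lexicon backend recovers the planted counts exactly (the closed
loop is an arithmetic check, not a text-understanding check); real
abstracts' ambiguity, hedging, and class imbalance are not modeled.

**Cohort.** Entry ages uniform on 60–85; sex/education/marital/living
drawn from frequencies typical of ageing research cohorts; small nonzero
covariate effects so adjustment is exercised. Event ages are exponential
with rate `baseline_hazard · exp(linear predictor)` (default 0.08/year);
because the exponential is memoryless, drawing the residual time after
entry is exactly the event distribution conditional on being event-free
at entry, i.e. correct left-truncation sampling. Censoring combines an
administrative horizon (8 years) with random dropout times drawn
independently of the event process (dropout probability 0.2) — an
earlier draft made dropout a fraction of the event time, which is
informative censoring and biased the recovered hazard ratio; the
independent scheme restored calibration. `censoring_rate ≥ 1` is the
degenerate all-censored contract (no events, downstream fits
not-estimable, warning emitted). Chronic users carry the drug at every
visit; a sporadic fraction carries it at a single visit only and
receives no hazard effect, exercising the consecutive-visit rule. Every
participant gets at least two visits so chronic use is observable. Not
emulated: time-varying exposure, exposure–covariate confounding,
competing risks, or visit-dependent event ascertainment.

## Problem sizes and tolerances in the shipped tests

DWPC oracle equivalence is checked on 50 random hetnets (8–40 nodes) to
1e−9. Planted-indication recovery averages held-out AUROC over 5 seeds
of the default graph (40 planted indications, 25% held out), passing
above 0.8 (observed ≈ 0.92). Cox calibration uses 1000 null replicates
at n = 500 (type-I error required within [0.03, 0.07]; observed 0.054)
and 30 seeds at n = 3000 for recovery of a planted log-HR of −0.5
(mean HR within ±0.05 of 0.6065; observed ≈ 0.59). The evidence closed
loop and the criterion-implication check are exact. These sizes keep the
full suite to a few minutes while leaving the Monte-Carlo bands
comfortably wider than the observed error.

## Known limitations

- The pipeline consumes external graph models (e.g. GNN link predictors)
  only as score tables; nothing here retrains them.
- The degree-based prior is a closed-form surrogate for
  permutation-derived priors and inherits their known optimism for
  high-degree nodes.
- The lexicon backend is a deterministic stand-in for semantic judgment;
  conclusions about LLM reliability cannot be drawn from it.
- The Cox stage assumes proportional hazards and a single absorbing
  event; no diagnostic suite is included.
- Expert-review scores enter only as an optional manually supplied
  column; the package does not model them.
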