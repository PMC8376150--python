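# Methods

This note documents the models, conventions and design choices behind
`assocnet` — what each stage computes, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Data model

The raw input is a long-format table with one row per associative
response: `participant_id, cohort, sex, cue, response, position`.
`cohort` and `sex` are the grouping axes; `position` is the 1-based
rank of the response within its (participant, cue) list and must be
contiguous.  A *cue set* fixes the node vocabulary: an ordered list of
cues, a category per cue, and a subset of *focal concepts* (the core
cues whose neighborhoods the analysis targets).  The reference layout
is 47 cues — three categories of 15 plus the two core concepts.

## Preprocessing

Responses are lowercased and trimmed; plural forms are converted to
singular only when the stripped form (`-es`, then `-s`) is in the
accepted wordlist, which protects mass nouns like "fitness"; responses
outside the wordlist (non-words) and responses equal to any cue word
(echoes) are removed; positions are re-indexed.  Normalization is
idempotent.  Spelling correction is off by default and available only
as an explicit user-supplied replacement map, because automatic
correction is not verifiable.

Participant exclusion applies three rules:

1. *Missing cues* — missed-cue fraction above `missing_cue_threshold`
   (default 0.10).
2. *Low output* — mean responses per answered cue below the group mean
   minus `low_output_sd_multiplier` (default 2.0) group SDs, computed
   within the participant's analysis-group stratum.  Whether counts are
   taken before or after cleaning, and whether unanswered cues count as
   zeros, is genuinely underdetermined; all three conventions are
   exposed (`low_output_basis`), defaulting to post-cleaning counts
   over answered cues, since those reflect usable data.
3. *Non-words* — pre-removal non-word fraction above
   `participant_nonword_threshold` (default 0.5).  Per-response removal
   already handles sporadic typos, so this rule only catches
   participants whose output is mostly noise; no principled cutoff
   exists, so it is a config value.

## Network estimation

The response profile of cue *c* is the vector of **distinct-participant
counts** per response type.  Distinct-participant counting (rather than
token counts or binary occurrence) is robust to response-list length
variation; the alternative encodings can be obtained by preprocessing
the table before `build_profile_matrix`.  Cue–cue similarity is the
Pearson correlation over the response-type dimension; zero-variance
profiles get similarity 0 to everything and are flagged.

The PMFG filter sorts all candidate edges by descending similarity —
ties broken by node-pair order in the matrix, making the filter fully
deterministic — and inserts them greedily, skipping any insertion that
would break planarity (tested with a combinatorial planarity check used
as a black box; no embedding is produced or needed).  Negative
correlations participate in the ordering (they can only enter after all
positive candidates), which guarantees exactly 3(n−2) edges for a
complete candidate set.  The result is binarized: all analysis is on
unweighted, undirected graphs.  Consequences worth keeping in mind:
every estimated network is a *maximal planar triangulation*, so edge
count and mean degree are structural constants, and graph measures move
only through the *arrangement* of edges, not their number.

## Measures and baselines

*CC* is the mean local clustering coefficient with degree-0/1 nodes
contributing 0 (the Watts–Strogatz convention).  *ASPL* is the mean
shortest-path length over all unordered pairs with unit edge lengths;
disconnected inputs either raise or, by policy, use the largest
component.  *Q* is Newman modularity Σᵢ (eᵢᵢ − aᵢ²), computed on the
consensus partition.  Baselines are means over Erdős–Rényi *G(n, m)*
graphs with the same node and edge counts (default 1,000 realizations,
seeded); degree-preserving rewiring is deliberately not the default —
the null matches only size and density — and baselines enter no
statistical test.

## Bootstrap comparison

Group networks yield one value per measure, so sampling distributions
are built with the without-replacement node bootstrap: per realization,
a uniform subset of ⌊n/2⌋ nodes (23 of 47); per group, the PMFG is
**re-filtered on the restricted similarity submatrix** (not the induced
subgraph), so partial networks again have exactly 3(k−2) edges.  By
default the same subset sequence is shared across groups within a
realization, so each realization contrasts the groups on identical
concept subsets.  Q inside the bootstrap uses a deliberately light
consensus (50 Louvain repetitions, 5 iterations) because it runs once
per realization and group; full-network consensus uses the 1,000-rep
default.

Comparison statistics: classical one-way ANOVA (F, df = (k−1, Σnᵢ−k),
η² = SS_between/SS_total) and pairwise t tests.  The pairwise default
is the **independent pooled-variance t** (df = n_a + n_b − 2) with
Cohen's d = mean difference / pooled SD; the paired-on-realizations
variant (df = n − 1, d = mean diff / SD of diffs) is available via
`mode="paired"`.  With shared subsets the realizations are paired by
construction, but the independent test's degrees of freedom match the
convention this methodology reports in practice; neither mode is
claimed to be uniquely correct.  All p-values are two-sided; no
multiple-comparison correction is applied by default (a hook exists in
the caller's hands — the pairwise results carry raw p-values).

Calibration caveat: bootstrap realizations from one similarity matrix
are not independent samples of anything — the test is well calibrated
when groups are bootstrapped *independently* from the same matrix
(rejection rate ≈ 5% at α = 0.05, verified in the test suite), but
with two *different* estimated matrices the t statistic scales with the
realization count and any sampling difference between matrices becomes
"significant" eventually.  Treat the statistics as descriptive of
network differences, as this methodology does, not as participant-level
inference.

## Consensus communities and partition statistics

Louvain (networkx's seeded implementation) is rerun `n_reps` times with
distinct sub-seeds; the co-assignment matrix records the fraction of
runs placing each node pair together; entries below τ (default 0.5) are
dropped and the surviving weighted agreement graph is re-clustered,
iterating until all runs agree (error after `max_iterations`, carrying
the last matrix).  Community ids are canonicalized by smallest-member
order, making consensus deterministic given the seed.

Partitions are compared with the Rand index (fraction of node pairs
treated identically) and the adjusted Rand index, via scikit-learn.
Category dispersion is the **sample SD (n−1 denominator) of a
category's member counts over occupied communities only**; a category
occupying a single community returns SD 0 with a `fully_clustered`
flag.  This convention is the only one consistent with a two-member
category split across two communities scoring exactly 0 — counts
(1, 1) — which is the structural signature of the two core concepts
landing in different communities.  Note the reading direction: *low* SD
means spread out, *high* SD means concentrated.

## Cue selection

The stimulus-construction stage operates on any supplied embedding
table (word2vec text format) plus a corpus frequency *ranking* — rank,
not raw counts, decouples the module from any specific corpus.  Cosine
nearest-neighbor lists are built for concept A, concept B, and the
elementwise vector sum A+B; ties broken by better frequency rank, then
lexicographically.  Exclusive-term selection keeps tokens appearing in
exactly one list, ordered by descending corpus frequency; phrase tokens
(containing underscores) are excluded by default.  Training embeddings
is out of scope.

## The synthetic-data generator

The generator emulates the statistical shape of a group
free-association study, not its semantics: tokens are synthetic
strings, and no lexical statistics of any real language are modeled.

Per participant, group and non-missing cue it draws
`max(1, Poisson(λ_g))` distinct responses (λ defaults 6.67–7.45 per
cohort, matching published group norms; truncation at one response
raises the mean of Poisson(7) by only ~0.006).  Each response comes
from the cue's own category vocabulary with probability `p_within`
(default 0.8), from a designated *partner* category with `p_between`
(default 0.05; partners default to the cyclic successor), and uniformly
from a global vocabulary otherwise.  Category vocabularies share a
Zipf-like popularity ranking; cue *i*'s Zipf exponent is `ρ_g · h_i`,
where `ρ_g` is the group concentration and `h_i` a fixed per-category
"generality ladder" spanning `generality_range` (default 0.8–1.2, focal
cues at the midpoint).

Design rationale, found empirically during development:

- *Ladder, not a uniform exponent.*  Because the PMFG always has
  3(n−2) edges, a uniform concentration knob leaves CC nearly unchanged
  and direction-unstable.  The ladder grades within-category similarity
  by exponent distance, so raising ρ reliably makes networks more
  segregated: **lower CC, higher ASPL, higher Q** (seed ranges
  non-overlapping at ρ ∈ {0.5, 1.0, 1.5}).  That is the older-cohort
  signature, so the study-like configuration gives older cohorts higher
  ρ.  The intuition that more response overlap should *raise*
  clustering does not survive the planar filter's fixed edge budget.
- *Ladder width.*  A wide ladder (0.5–1.5) fragments categories into
  5–6 consensus communities and degrades category recovery; 0.8–1.2
  keeps categories cohesive (Rand ≥ 0.84 against planted labels over
  15 probe seeds) while preserving the ρ leverage.
- *Focal cues at mid-ladder.*  The midpoint maximizes a cue's mean
  correlation with the rest of its block, anchoring the core concepts
  firmly inside their aligned categories; at the ladder extreme a focal
  cue occasionally ended up weakly embedded and mis-assigned.
- *Focal cues respond like an aligned category.*  Each core concept
  draws from the vocabulary of its designated category (defaults: the
  first two categories), mirroring the real task where the core cue
  behaves like its own category's terms.  Without this, the two focal
  cues would correlate only with each other and could never occupy
  *different* communities.
- *Partner symmetry.*  With two categories and mutual partners,
  `p_within = p_between` makes within- and between-category expected
  profiles identical, so the correlation gap vanishes — a sharp
  self-test of the mixture design.  With three categories the partner
  map is cyclic and the planted block structure dominates.

Contaminants are injected per response (non-word, cue echo, plural
variant, at configured rates) and logged with record ids; participants
engineered to violate the exclusion rules (one response per cue, or 20%
missing cues) are listed in the planted truth, so preprocessing can be
tested for exact recovery.  Everything is deterministic given the
config seed.

What passing tests on generated data do **not** show: real
free-association data have heavy-tailed response-type distributions
with massive idiosyncratic tails, semantically graded cross-category
overlap, spelling noise far richer than the injected contaminants, and
participant-level heterogeneity in verbosity and vocabulary.  Recovery
results here certify the pipeline's correctness, not expected effect
sizes on human data.

## Pipeline, seeds, determinism

`run_pipeline` executes simulate/read → preprocess → estimate (per
group plus the pooled "general" network, which always shares the cue
node set) → consensus communities → measures → bootstrap comparison →
neighborhoods, and writes everything as plain text (CSV/TSV/JSON/
GraphML).  Every stage's seed is derived from the single global seed as
`SHA-256(f"{seed}:{stage}") mod 2^31`, so stages are decoupled and a
rerun with the same configuration is byte-identical.  The manifest
echoes configuration, derived seeds and package version; wall-clock
information goes to stderr logs only, keeping outputs reproducible at
the byte level.

## Problem sizes used in the checked examples

The test suite and acceptance script run the full method at the study's
printed geometry (47 cues, half-node subsets of 23) with sizes chosen
for fast, stable verification: 100 participants per group for recovery
checks, 200 bootstrap realizations for the planted-effect comparison,
100–250 Louvain repetitions for consensus (1,000 remains the library
default for standalone analyses), a 16-cue layout for the 200-replicate
null-calibration sweep, and 1,000 Erdős–Rényi realizations where the
G(n, m) baseline itself is under test.

## Known limitations

- PMFG insertion is O(candidate · planarity-check); at 47 nodes a
  network takes well under a second, but very large cue sets would want
  a faster planarity routine.
- The bootstrap's statistical caveats above: realization count inflates
  t statistics between *different* matrices by construction.
- Consensus non-convergence is an error by design (it signals an
  unstable community structure), not silently resolved.
- The depluralization rule is dictionary-guarded English `-s/-es`
  stripping only; no stemming or lemmatization.
- `cc_rand`/`aspl_rand` are qualitative context only; they enter no
  test, and a G(n, m) null is not degree-matched.
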