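# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the conventions chosen where a convention was
required, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinates and the masking classifier

All sequence coordinates are 1-based and inclusive (the UniProt convention;
a degron written ¹⁹FSDLWKLL²⁶ spans residues 19–26 and has length 8).
Two regions **overlap** when they share at least one residue; the overlap
length is the size of the intersection. Disjoint regions are **adjacent**
when the gap — the number of residues strictly between them, i.e.
`later.start − earlier.end − 1` — is between 1 and the adjacency window
(default 10 residues). Anything farther is unrelated. A secondary degron
given only as a Ubsite position is treated as a single-residue region and
classified with the same rules.

Interaction confidence filtering keeps pairs with score ≥ 0.3 (the
IntAct-miscore convention); retention is decided per interaction pair, so
all features of a dropped pair drop together. Four feature kinds carry
masking evidence with equal weight: sufficient binding region,
binding-associated region, necessary binding region, and mutation evidence
(mutations in or near a site that alter the interaction locate a physical
contact just as a mapped region does); the kind is preserved in outputs so
downstream users can stratify. Partners annotated (directly or through any
ontology descendant) with a UPS blacklist term are removed before the
census, because E3s, E2s and proteasome components bind degrons *as part
of* degradation and must not be counted as stabilizing maskers. The
blacklist is a required configuration input; the synthetic ontology ships a
dedicated UPS branch for it.

In the census, a partner with interactions but no feature annotation counts
toward the substrate's partner total but can never be masking. Adjacent
sites count as masking by default (they sterically compete just as
overlapping ones do at this resolution); a flag excludes them, and the
overlap-only counts are always reported alongside.

## Tertiary degron inference

The tertiary degron is the intrinsically disordered region nearest in
sequence to a Ubsite that contains at least 20 consecutive residues with
disorder score ≥ 0.5 (the conventional binary cutoff for per-residue
disorder predictors; both the run length and threshold are configurable).
Runs are maximal; a run containing the Ubsite has distance 0; for two runs
at exactly equal distance the upstream (lower-coordinate) run is chosen —
the choice is arbitrary but must be deterministic, and upstream matches the
N-to-C reading order.

## Abundance model and rank bins

Abundances are parts-per-million: within one dataset each protein's value
is relative to the whole expressed proteome, so totals sum to ~10⁶ (a
validator warns outside ±10%, since real files deviate slightly). Because
ppm values are only proportions, cross-dataset comparisons use rank bins:
proteins are sorted from highest to lowest ppm (ties broken by protein id
so binning is deterministic) and assigned
`bin = floor(100·(rank−1)/N) + 1`. This quantile form keeps bin occupancies
within one of each other for every N and always places the most abundant
protein in bin 1 — including datasets smaller than 100 proteins, where a
ceiling-of-rank-quantile variant would push the top protein out of bin 1.
Missing proteins are reported as missing, never as a synthetic bin.

Role comparisons pool each (protein, dataset) occurrence as one
observation, once per module occurrence when a protein serves several
modules (a switch pools once per dataset instead). Between-group tests are
two-sided Mann–Whitney U: exact null distribution when both groups have
≤ 8 observations and no ties, normal approximation with tie correction
otherwise. Correlations are Spearman with average ranks; a correlation over
fewer than 3 points is reported absent. The substrate–ΣAP correlation uses
only datasets in which the substrate and *every* one of its alternate
partners are measured, so the sum is never a partial sum.

## Wang semantic similarity

The Wang measure is implemented from its recursion, not wrapped from an
existing implementation. For a term *t*, the semantic contribution of *t*
to itself is 1 and to each ancestor *a* is
`S_t(a) = max over edges (c → a) of w_rel · S_t(c)` restricted to *t*'s
ancestor closure, with edge weights 0.8 (is_a) and 0.6 (part_of) — the
measure's published defaults, exposed as configuration and recorded in
output metadata. The computation is a topological-order dynamic program
over the closure; a memo-free depth-first path-product oracle exists in the
test suite and must agree to 10⁻⁹. Term similarity is the standard
normalized sum over common ancestors; gene similarity is best-match
average: the mean of (mean of row maxima, mean of column maxima) of the
pairwise term matrix. Only is_a and part_of edges enter the closure (the
measure defines weights for no other relation); annotations are filtered
to Biological Process terms with IDA or IPI evidence, and terms missing
from the ontology (e.g. obsolete) are dropped with a warning.

## Half-life ratios, randomization and degronons

The half-life ratio of a pair is min/max, always within one half-life
dataset (relative values and minutes are never mixed). Categories:
similar [0.8, 1.0], different [0.5, 0.8), very different (0, 0.5). The
published interval labels overlap at the boundaries, so a convention is
required: a ratio exactly at 0.5 or 0.8 joins the upper category.

Randomized networks preserve the node set and degree multiset: (1) a
double-edge-swap shuffle (10·|E| accepted swaps, rejecting self-loops and
parallel edges) — a seeded Markov-chain equivalent of drawing from the
fixed-degree-sequence ensemble; (2) a node-label permutation without
replacement; (3) removal of any surviving original edge, so the final
overlap with the real network is exactly zero. Diagnostics report the
pruning loss (below 1% on sparse graphs) and the residual overlap (always
0). The ratio envelope compares the real edge histogram with the per-bin
mean ± 1 sd over 10 randomizations.

Shortest paths use breadth-first search expanding neighbors in lexical
order, which deterministically selects the lexicographically smallest next
node wherever ties exist (library all-pairs routines return an arbitrary
representative, which would make outputs run-dependent). Distance profiles
count unordered pairs once; degronon detection iterates ordered paths (a
path from A and its reverse from B are distinct candidates) and then
deduplicates identical ordered member lists, with an additional helper to
collapse to unordered member sets for reporting. A degronon is a path in
which every member has BP SemSim ≥ 0.6 to the first member; paths with a
member lacking a similarity value are excluded from the high-SemSim subset
(missing data, not failure); paths of length ≥ 6 hops are reported with
per-member similarity and half-life ratio versus the first member.

## What the synthetic generator emulates

Each generator operation draws from its own RNG stream derived from the
master seed, so outputs are byte-reproducible and adding one generator
never perturbs another. Defaults are the study conditions used throughout
the tests:

- **Substrates** (length 200–800): one primary degron of 6–14 residues, one
  Ubsite lysine, and a piecewise-constant disorder profile (disordered
  blocks ~0.8, ordered background ~0.2, ±0.1 noise, clipped to [0, 1])
  whose block nearest the Ubsite spans ≥ 20 residues and is recorded as the
  true tertiary degron; an optional decoy block sits strictly farther away.
- **Interactions**: a configurable fraction of partners (default 0.5)
  carries a feature overlapping a degron; the rest bind degron-free
  segments or carry no feature. Confidences come from a two-component
  mixture (10% below the 0.3 cutoff); 10% of partners are UPS-flagged and
  annotated into the ontology's UPS branch. The recoverable ground truth
  excludes low-confidence and UPS-flagged pairs, and the mask stage
  recovers it exactly at the standard thresholds.
- **Ontology/annotations**: one BP root; per-module branches whose 3 leaf
  terms all module members share (IDA); per-gene background leaves under
  rotating branches (so background pairs score low); IEA records that the
  evidence filter must drop.
- **Abundances**: log₁₀-normal per role with medians substrate 1.5, E3 1.0,
  AP 2.0 (AP:E3 fold 10, the observed effect size), noise sd 0.4, a
  dataset-level latent factor (sd 0.3) shared by substrates and E3s to
  induce their cross-dataset correlation, ~1000 background proteins, exact
  renormalization to 10⁶ after noise.
- **Network**: each module is a backbone chain of 8 proteins (the planted
  degronon path) plus one span-2 chord, attached to the background by a
  single edge (a single attachment cannot create alternative in-module
  shortest paths); half-lives share a module mean with CV 0.05, so > 80%
  of planted pairs have ratio ≥ 0.8; 500 background proteins carry
  independent log-normal half-lives (ln-sd 0.6, median pair ratio ≈ 0.56)
  and ~2 edges per node; co-expression centers at 0.8 within modules and 0
  elsewhere.

What it does **not** emulate: real IntAct miscore calibration, real GO term
semantics or annotation depth, ortholog structure, correlated measurement
error between PaxDb datasets, or hub-dominated degree distributions.
Passing recovery tests therefore demonstrates that the machinery extracts
planted signal at the stated thresholds — not that real data contain such
signal at any particular strength.

A calibration subtlety worth recording: with the substrate–E3 latent factor
active, pooled (protein, dataset) observations are clustered, and the
pooled Mann–Whitney test becomes conservative (cross-dataset comparisons
largely cancel in U, shrinking its variance; mean null P ≈ 0.56 in our
measurements). The null-calibration checks therefore zero the latent
coupling (`substrate_e3_latent_sd = 0`), under which null P-values are
uniform. Users pooling clustered real data should expect the same
conservatism.

## Problem sizes

The recovery analyses run on the default conditions (5 modules × 8
proteins + 500 background, 50 abundance datasets, 10 randomizations); the
oracle equivalences run exhaustively to coordinate 60 (≈ 3.3 million
interval pairs) and over 100 random DAGs of ≤ 30 terms; the null
calibration uses 100 seeds. These sizes keep a full verification run in
well under a minute per analysis on one CPU.

## Known limitations

- The degronon definition is path-based; overlapping complexes appear as
  multiple paths sharing members, and no community detection is attempted.
- The published headline numbers tied to live database snapshots (IntAct
  funnel counts, r_S = 0.4 / 0.34 against 170 PaxDb datasets, the Fig.-6
  style group sizes) are snapshot-dependent and are not reproduction
  targets; parsers for the published degron dataset and Collins network are
  provided and verified against the printed counts when users supply those
  files.
- Disorder profiles are consumed, not predicted; database retrieval is out
  of scope (files are read, never fetched).
- The edge-swap randomizer is a Markov chain: 10·|E| accepted swaps mixes
  sparse graphs well, but extremely dense or highly constrained degree
  sequences may need more swaps (configurable).
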