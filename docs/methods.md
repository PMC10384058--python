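# Methods

## Scope and model

`amplidiv` treats integrated amplicon diversity estimation as a fixed
deterministic procedure over four inputs: a gapped, taxonomically
annotated fragment alignment; a sample table (sample id → free-text
origin); a reference set of described species with ranked taxonomy;
and a per-sample relative-abundance matrix. The package does not align
sequences (alignment is upstream) and does not re-annotate taxonomy.
Everything downstream — region choice, cutoff calibration, clustering,
naming, ecology — is a function of those inputs plus a handful of
tunable parameters.

## Pairwise identity

Identity between two ungapped sequences is computed from an end-to-end
global alignment under match +1, mismatch −1, gap −1, as
matches / alignment columns. Two numerical choices close gaps the
definition leaves open:

- **Tie-break.** Several alignments can share the optimal score. The
  most *compact* one (fewest gap columns, equivalently fewest matches
  at equal score) is used. For equal-length sequences this reduces to
  the gap-free alignment whenever it is optimal, so identity equals
  1 − hamming/length there — the behaviour practitioners expect from
  region-trimmed amplicons. The greedier alternative (most matches)
  pads alignments with compensating gaps and systematically deflates
  identity by ~0.5 pp on 282-base fragments.
- **Closed form for the length.** Under this scoring every alignment
  satisfies `columns = 2·matches − score`, so a (score, −matches)
  dynamic programme suffices; no traceback is needed. The inner loop is
  numba-compiled with a pure-Python fallback.

`N` is treated as an ordinary character (it matches only `N`); the
coverage filter upstream already limits how many ambiguous positions a
kept record can carry.

## Region selection and the length filter

Per-column coverage counts every non-gap character, including `N` — the
filter is about sequenced positions, not unambiguous calls. The
selected region is the longest contiguous run of columns with coverage
at least `plateau_fraction` (default 0.8) of the maximum, leftmost run
on ties; a manual window override is available since published analyses
sometimes fix the region by inspection. The keep rule is *strictly more
than* `min_fraction × expected_bases`, where `expected_bases` counts
the designated reference's bases inside the window — with 282 expected
bases and the 0.8 default this keeps 226 and drops 225. An absolute
`min_bases_override` exists because published workflows sometimes quote
an absolute cutoff (e.g. 229) that is not derivable from the fraction;
the package exposes both rather than guessing which was intended.
Coordinates are 0-based half-open throughout.

## Cutoff calibration

Cutoffs are unweighted means over reference species *pairs* (pairs
sharing a genus → species cutoff; sharing only a family → genus cutoff;
different families → family cutoff), rounded half-up to two decimals.
Averaging over pairs rather than over species is a choice — pairs are
what the identity distribution is made of — and is the simplest reading
of "on average". A stratum with zero pairs, or means that are not
strictly ordered species > genus > family, abort calibration loudly;
clamping would silently produce a cutoff set the data contradict.

## Taxonomy-informed clustering

Entries are binned by annotated lineage truncated at the deepest
nonempty rank (at most genus); entries unannotated below that depth
form an `unclassified` child bin of their deepest annotated ancestor,
which is where novel families and genera surface. Within a bin,
clustering is greedy incremental: entries in canonical order
(multiplicity descending, length descending, id ascending) join the
*first* representative at or above the cutoff, else found a new
cluster; representatives are founding sequences and are never updated.
The hierarchy is top-down: family-cutoff clusters (fOTUs) are
re-clustered at the genus cutoff (gOTUs), then at the species cutoff
(sOTUs), which guarantees nesting by construction. Choices worth
flagging:

- Neither the ordering nor first-vs-best assignment is forced by the
  procedure's description in the literature; abundance-first ordering
  and first-match assignment are classic incremental-clustering
  practice and make runs deterministic and order-invariant. A
  `best_hit` flag switches to best-match assignment.
- Labels are zero-padded ordinals (`FOTU0001`, …) issued in canonical
  processing order (bins sorted by key, clusters in founding order), so
  identical inputs yield identical labels regardless of input order.
- `oracle_cluster` replays the same greedy process against a fully
  materialised all-pairs identity matrix for bins of ≤ 40 entries; it
  exists purely as an equivalence check on the lazy implementation.

## Species naming

Each reference maps to its best-identity sOTU representative and the
mapping counts at identity ≥ 0.98 (a `strictly_above` flag gives the
> 0.98 reading). References landing on one sOTU merge into a
slash-joined name, epithets merged under the genus when all share it.
Global identity is used rather than a local-alignment heuristic:
references and representatives are co-trimmed to the same region, so
global identity is the stable like-for-like comparison.

## Ecology

Free-text origins map through an ordered keyword table to the fixed
categories (saline water, freshwater, soil, air, plant, host, plant/
host saline water, bioreactor, other); lab-assembled systems map to
`excluded` and contribute to no statistic. Per sOTU, prevalence counts
*all* positive samples (abundance > 0) while the ≥ 0.1% rule (≥, so the
boundary counts) gates which sOTUs enter the focused analysis — the two
columns published side by side require exactly this reading. Dominant
environment is the mode over positive samples, ties resolved by larger
summed abundance then fixed category order (an invented but documented
rule — the source material is silent); a flag restricts the mode to
≥-threshold samples instead. Cosmopolitan means ≥ 50 positive samples.

## Reporting

Percentages round half-up to two decimals, which reproduces published
table arithmetic exactly (e.g. 4483/15049 → 29.79%). Species-count
histograms bin at {1, 2–10, 11–50, ≥ 51}; a count of exactly 51 goes to
the top bin, resolving the gap the published binning leaves between
"11 to 50" and "more than 51". Top-N tables sort by positive-sample
count and by maximum abundance, ties by sOTU label.

## Synthetic data generator

The generator emulates: a planted family > genus > species hierarchy at
controlled identities (~0.90/0.92/0.96 between/within families/genera
by default), fragments targeting two overlapping windows of a gapped
master alignment (60/40 by default) whose intersection is the 282-base
core, a `short_fragment_rate` of truncated fragments that fail the
coverage filter, environment labels drawn from a built-in synonym table
so the categorizer is exercised nontrivially, and long-tailed Dirichlet
abundance profiles in which every fourth species is scaled to peak
below the 0.1% gate.

Substitutions are planted on **disjoint site pools**: each family,
genus and species branch owns its own core positions, and reads draw
theirs from a shared leftover pool. Pairwise distances are then exact
sums of branch counts — two reads of sister species differ at
2·k_s + (read sites) positions, etc. — so realized identities sit on
the configured targets by construction (to whole-substitution rounding)
instead of on average, and the strict ladder
species > genus > family > across holds on every draw. Identity targets
refer to *fragment* pairs, the quantity the pipeline itself measures;
reference (species-level) sequences land correspondingly higher. Ladders
that round to zero substitutions on some branch, or whose site budget
exceeds the region, raise an infeasibility error up front. An earlier
design iterated on substitution counts to hit targets on average; the
disjoint-pool construction was adopted instead because it makes the
tolerance guarantee analytic.

Default conditions: 3 × 3 × 3 hierarchy, 282-base core with 40-base
flanks and fixed all-gap columns, identity targets
0.99/0.96/0.92/0.90, 18 fragments per species, 60 samples,
`short_fragment_rate` 0.05, Dirichlet α 0.3. The cluster-recovery test
conditions use targets 0.97/0.93/0.905/0.88 — separated from the
0.96/0.92/0.90 cutoffs by ≥ 0.005 at fragment level — under which
recovery of the planted (3, 9, 27) counts is exact. Note that the
*default* targets deliberately place within-genus fragment identity at
the species cutoff (a calibrated cutoff is the mean of exactly that
distribution), so default runs show realistic borderline splitting
rather than perfect recovery.

What the generator does **not** emulate: chimeras, per-base quality or
sequencing-error profiles, indel evolution, length heterogeneity beyond
window choice and truncation, and any correlation between environment
and clade. Passing tests therefore demonstrate the pipeline's
correctness and determinism on substitution-structured data, not
robustness to real amplicon artefacts.

## Determinism

All randomness flows through seeded numpy generators keyed by
(config seed, stage); clustering order, label issue order, tie-breaks
and file output ordering are all fixed, so identical configurations
produce byte-identical outputs.

## Problem sizes

The shipped tests and the acceptance script run the recovery conditions
at ~500 fragments, oracle equivalence at 200 bins × ≤ 40 sequences and
500 identity pairs, and the ecology brute-force comparison at 200 sOTUs
× 500 samples — sizes at which every all-pairs oracle remains exact
while the full suite completes in well under a minute.

## Known limitations

- Greedy incremental clustering is order-dependent by nature; the
  canonical order makes it reproducible, not optimal. Counts can differ
  from linkage-based clustering near cutoff boundaries.
- The published absolute length cutoff (229) and the more-than-80% rule
  (226 at 282 expected bases) disagree; both are exposed, neither is
  silently preferred.
- Dominant-environment tie-breaking and pair-averaged calibration are
  documented choices, not community standards.
- The environment categorizer is a keyword table; labels outside its
  vocabulary fall to `other` with a warning.
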