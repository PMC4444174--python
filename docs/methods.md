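# Methods

This note documents the operational definitions, the statistical
procedures, the synthetic-data model and the numerical choices made in
`movelead`, in the spirit of a methods section a maintainer can audit.

## Observation model

The atomic datum is a time-stamped behavioral event by one individual.
Event kinds fall into four functional classes:

* **pre-departure acts** (`move_away`, `stay_peripheral`,
  `follow_mover`, `join_peripheral`, `pause`) — intention movements
  that signal readiness to leave;
* **locomotor commitment** (`departure`, `joining`, `arrival`) — a
  departure is sustained directed walking over more than the group
  diameter; a joining is the same act in the direction of an already
  moving animal and is treated as that individual's departure time;
* **walking order** (`front`) — an annotation naming the individual
  heading the progression at the moment of record;
* **agonistic** interactions with winner (actor) and loser (target).

Timestamps are seconds from session start (the field protocol is
tape-recorded continuous observation; no absolute clock exists).
Files are plain CSV with a header; the schema is this package's own
convention since ethology has no standard interchange format.

## Movement segmentation

A collective movement runs from the first departure to the last
arrival and must carry at least `participation_fraction` (default
0.5) of the group: a cluster of departure/joining events qualifies iff
distinct movers ≥ ⌈0.5 N⌉.  Parameters, all in seconds:

| parameter | default | role |
| --- | --- | --- |
| `simultaneity_window_s` | 10 | departures within this window of the earliest are simultaneous first movers (boundary inclusive) |
| `predeparture_window_s` | 1200 | half-open window [t₀−1200, t₀) scanned for pre-departure acts |
| `bout_gap_s` | 60 | quiet gap after a group pause that opens a new bout |
| `movement_gap_s` | 600 | quiet gap between mover events that separates movements |

The source protocol does not quantify "at the same time" for
simultaneous departures, nor the tape recorder's effective resolution;
10 s is this package's default and is configurable
(`--simultaneity-window`).  Events at exactly t₀ belong to the
departure, not the pre-departure window.  The front individual is read
from the `front` record nearest the movement's temporal midpoint;
zero records, or several individuals sharing the nearest record time
(animals abreast), leave the front undefined, and such movements are
excluded from front-position tallies only — which is why front
denominators are smaller than departure denominators.  Multi-bout
movements (a pause by at least the participation fraction of movers
followed by renewed departures after `bout_gap_s`) are segmented but
dropped from the leadership analyses, which use single-bout movements
only.

## Leadership proxies and inference

Per individual, three counts: movements in which it (1) displayed at
least one pre-departure act, (2) was the sole first mover (movements
with simultaneous first movers credit nobody and are excluded from the
departure analysis), (3) was the scored front individual.

**Uniformity test.**  Each count vector is tested against the discrete
uniform distribution with G = 2 Σ oᵢ ln(oᵢ/eᵢ) (zero cells contribute
0), divided by Williams' factor q = 1 + (k²−1)/(6n(k−1)).  With n of
11–79 over k = 6–12 cells the χ² reference is poor, so the null
distribution is simulated: B = 2000 multinomial draws of size n from
uniform, each receiving the identical Williams correction
(exchangeability), with the add-one estimator
p = (1 + #{G\* ≥ G}) / (B + 1), which can never return 0.  Degrees of
freedom are reported as k − 1.

**Per-individual chance tests.**  The follow-up is an exact two-sided
binomial test of each count against success probability 1/k (two-sided
because both above- and below-chance participation are informative),
with Holm step-down over the k tests as one family at α = 0.05.  The
choice of the exact binomial is a design decision: "pairwise
comparison against the chance value" admits several readings, and the
exact test is the one whose null is precisely the uniform multinomial
marginal.

**Rank statistics.**  Spearman correlations use mid-ranks for ties;
the two-sided p is the exact permutation probability for n ≤ 9 and
the t approximation above that.  Kruskal-Wallis (tie-corrected, χ²
reference on k−1 df) compares joining durations across first movers
with at least `min_departures = 3` sole initiations; with fewer than
two qualifying movers the omnibus is reported as not applicable.
Joining duration is last departure − first departure, undefined (not
zero) for single-departure episodes.

## Concordance between definitions

For each individual: forward conditionals P(sole first mover | it
displayed pre-departure), P(front | displayed), P(first ∧ front |
displayed), and retrospective conditionals P(displayed | sole first
mover), P(displayed | front), each carried with its integer
numerator/denominator.  Cells with zero denominators are undefined and
are distinguished from true 0% cells.  Column means and SEMs average
over defined cells only: a defined 0% is evidence, an undefined cell
is absence of a denominator.  On the bundled BO summary this
convention reproduces the printed column means (forward departing
20.88%, retrospective 58.11%) exactly.

## Count reconstruction from published tables

Percentage tables printed to two decimals are inverted by denominator
search: for each candidate d, counts = round(p·d/100), and a candidate
survives iff 100·c/d reproduces every input within 0.005 (printed
precision) and, when a column total is known, the counts sum to it.
Exactly one candidate must survive; otherwise the error lists the
residuals or the ambiguous set.  The search exists because such tables
mix denominators within one layout — in the bundled data the front
column of one group is percentaged over the single-first-mover total
(35) even though only 21 movements carried a front score.  One known
irreducible ambiguity is documented rather than resolved: the
pre-departure columns are integer-consistent with the
single-first-mover totals (giving 66 and 79 displays), but the
published per-movement participant means (3.1 and 3.5) are not exactly
recoverable under any printed denominator, and the published AD
pre-departure test statistic duplicates that group's departure triple;
`run_from_summary` reports what the reconstructed counts actually give
and does not force agreement.

## Dominance hierarchy

Agonistic wins accumulate in an N×N matrix; a dyad's direction is the
strict majority of wins, exact ties and silent dyads being unknown.
Bidirectional dyads are reported, not hidden, since unidirectionality
is an assumption to check.  Linearity uses Landau's index with the
standard half-point treatment of undecided dyads
(vᵢ = dᵢ + uᵢ/2), which keeps h ∈ [0, 1] on incomplete matrices, and
the improved index h′ = h + 6u/(N³−N) — the expectation of h over
random orientations of the u unknown dyads, so h′ = h when the matrix
is complete.  Significance is by randomization holding the
unknown-dyad pattern fixed and coin-flipping the decided dyads
(add-one right-tail p).  Two consequences worth knowing: a fully
linear 6-individual hierarchy with no unknowns gives p ≈ 6!/2¹⁵ ≈
0.022 (the chance a random tournament is transitive), and a matrix
with every dyad unknown is degenerate with p = 1.  Because h takes few
distinct values at small N, the randomization p is discrete and
conservative: under random matrices its tail mass satisfies
P(p ≤ α) ≤ α but its distribution is not exactly uniform.

Rank orders minimize the number of dyads whose subordinate outranks
its dominant.  For N ≤ 16 an exact subset dynamic program (O(2ᴺ·N))
finds the provable minimum with deterministic tie-breaks (win total
descending, then id); this covers any realistic family group, and a
deterministic insertion-descent heuristic exists beyond that.  An
all-zero matrix degenerates to id order with a warning.

## Synthetic data model

The generator realizes, per movement: pre-departure participants
(independent Bernoulli per individual with per-individual rates), a
primary first mover drawn either from the participant set (with
probability `coupling`, weights = renormalized propensities) or from
the whole group, optional simultaneous co-departures (2–3 movers
within 8 s), a joining process in which the remaining members depart
over a span D = 11 + Exp(mean − 11) s (the 11 s guard keeps joiners
out of the simultaneity window; the shift preserves the configured
mean exactly), arrivals after 300–600 s of travel, an optional front
record at the temporal midpoint (probability `front_scored_prob`;
unscored movements are either silent or "abreast" with two
simultaneous records), optional two-bout structure, and transitive
agonistic interactions decided by rank.  First-mover propensities come
from a symmetric Dirichlet(κ) — large κ is shared decision-making,
small κ or an explicit spike is despotism — or are fixed explicitly.

Two structural guarantees make ground truth exactly recoverable by
the default segmentation: joiners are spread over the joining span
with bounded gaps (span capped at guard + n·540/1.8 s) so a movement
can never straddle a 600 s quiet gap, and consecutive movements are
separated by at least the pre-departure window plus travel time so no
event of one movement contaminates another's window.  All randomness
descends from a single root seed through per-movement substreams
(`numpy` `SeedSequence.spawn`), so identical configs give identical
logs and truth records.

The calibrated presets (`paper_BO_like`, `shared_AD_like`) take their
defaults from the bundled group summaries: 42/43 movements,
first-mover propensities proportional to the reconstructed departure
counts, per-individual pre-departure rates equal to the printed
display percentages, coupling 0.58/0.59 (the printed retrospective
means), joining means 471/249 s, and exact allocation of the
simultaneous (14/42, 8/43) and front-scored (11/42, 21/43) shares —
realized as exact per-run counts rather than Bernoulli draws so that a
single 42-movement run reproduces the published denominators.  Note
that rates derived from the printed tables imply ≈2.4 (BO) and ≈2.3
(AD) pre-departure participants per movement, whereas the published
per-movement means are 3.1 and 3.5; this is the same table
inconsistency discussed above, and the presets follow the printed
per-individual percentages.

What the generator does **not** emulate: spatial trajectories and
direction changes, ecological context (shelter vs. foraging moves),
herding or breeding-season dynamics, observer error in event coding,
and inter-movement behavioral dependence (movements are exchangeable
given the propensities).  Passing tests therefore demonstrate that the
pipeline recovers the statistical structure it assumes — not that real
horse groups satisfy those assumptions.

## Test scale and calibration checks

The suite verifies, at sizes chosen to keep the whole run around a
minute: type-I error of the Monte-Carlo G at the nominal 5% ± 2% over
500 uniform-null pipeline replicates (42 movements each, B = 2000);
≥95% power to flag a 0.8-propensity initiator over 100 replicates of
500 movements; generator propensity recovery to within 0.02 at 10⁴
movements; Spearman and Kruskal-Wallis against brute-force oracles on
short sequences; linearity against the direct vᵢ formula and the
transitive-tournament probability; and exact byte-level determinism
of reports and logs under fixed seeds.

## Known limitations

* The front position is read from explicit walking-order annotations;
  nothing is inferred from spatial data.
* The per-individual chance tests treat movements as independent
  Bernoulli trials; serial dependence between movements would make
  them anticonservative.
* h′ significance is a randomization against unordered nulls with the
  observed unknown pattern; it is not an I&SI implementation, and the
  rank order is a minimum-violation order, not a Matman-style ranking
  with tie-handling conventions.
* Percentage-table reconstruction requires the printed precision to be
  faithful; tables rounded inconsistently (or percentaged over
  undisclosed denominators) surface as reconstruction errors by
  design.
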