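# Methods

## The model

`thermopattern` treats protein thermostability as a property inherited from
the source organism: a microorganism's optimal growth temperature (GT, °C)
classifies each of its proteins as psychrophilic (GT < 20), mesophilic
(20 ≤ GT ≤ 40) or thermophilic (GT > 40). The defining inequalities are
strict on the outer classes; the boundary values 20 and 40 are assigned to
the mesophilic (closed) interval, so the classifier is a total, monotone
step function of GT. Within one protein family the two populations of
homologues are assumed to differ in local sequence composition, and the
compositional feature used is the *gapped residue pair*: an ordered pair
(A, X, B) of standard amino acids A, B with exactly X intervening residues,
X = 0…10 inclusive. The grid of 20 × 20 × 11 = 4,400 patterns is counted per
sequence, and per-pattern count distributions are compared between groups.

The inferential claim is deliberately weak: a pattern whose count
distribution differs between the groups *and* is on average more frequent in
thermophilics marks local arrangements associated with thermotolerant
members of the family. Completing such an arrangement in a mesophilic target
— one substitution at a time — is then proposed as a stabilizing mutation.
No energetic, structural, or conservation reasoning enters; the procedure is
purely sequence-driven, which is both its reach (no structure needed) and
its main limitation.

## Counting conventions

* **Overlap.** All ordered index pairs (i, i + X + 1) are counted, including
  self-overlapping runs: `AAA` contains the adjacent pair A·A twice. With
  this convention the counts at fixed spacing X over the 400 residue pairs
  sum to exactly L − X − 1 for an all-standard sequence of length L, which
  makes the counter auditable by a closed form (and is enforced by a
  property test).
* **Ambiguity codes.** Inputs may contain B, J, O, U, X, Z (real UniProt
  records do). A window whose *endpoints* are not both standard matches no
  pattern; intervening residues are unconstrained, so `A?E` with an
  ambiguous middle still counts toward A1E. Ambiguous positions are likewise
  never mutation sites or anchors in the suggestion step.
* **Normalization.** Counts are raw per-sequence occurrence numbers. Group
  means of raw counts for a ~150-residue protein sit in the 1–2 range, the
  scale on which the screen's group averages are reported. An optional flag
  divides counts at spacing X by the number of windows L − X − 1 for
  length-heterogeneous families; it is off by default.

## The screen

For each pattern the thermophilic and mesophilic count vectors are compared
with a two-sided Wilcoxon rank-sum (Mann–Whitney U) test:

* both groups ≤ 8: the exact permutation distribution, computed by
  enumerating all C(n + m, n) assignments of the pooled midranks — exact
  under ties as well;
* otherwise: the tie-corrected normal approximation, *without* continuity
  correction. Pattern counts are heavily tied (mostly 0/1/2), and in null
  calibration simulations (uniform background, 30 vs 30 sequences of length
  150) the continuity-corrected variant is conservative (significant
  fraction ≈ 0.048, occasionally drifting below 0.04 per family) while the
  uncorrected variant sits at ≈ 0.050. Columns with zero pooled variance get
  p = 1.

Defaults: α = 0.05 per pattern, no multiple-testing correction across the
4,400 tests — the screen is a generator of candidates whose cost of a false
positive is one wasted suggestion, not an inferential endpoint.
Benjamini–Hochberg is available (`correction="benjamini_hochberg"`) when a
controlled discovery list is wanted. Families qualify for screening when
both the mesophilic and the thermophilic bin hold strictly more than
`min_group_size` = 20 sequences ("more than", not "at least"); smaller
families require an explicit `force`. Psychrophilic members are carried in
the data model but excluded from the mesophilic-vs-thermophilic screen; the
same machinery can screen any two bins by relabelling.

## Mutation suggestion

For every significant, thermophilic-enriched pattern (A, X, B) the target is
scanned for near-miss sites:

* **AXY** — target[i] = A and target[i + X + 1] = Y with Y ≠ B: suggest
  Y→B at position i + X + 1;
* **ZXB** — target[i + X + 1] = B and target[i] = Z with Z ≠ A: suggest
  Z→A at position i.

The same substitution typically arises from many patterns; suggestions are
deduplicated by (position, wild type, mutant) with every supporting
(pattern, anchor, side) retained, because the downstream validation counts
mutations — one experimental outcome per substitution — not pattern hits.
Output order is deterministic: best supporting p-value ascending, then
position, then mutant residue.

Two guarantees hold by construction and are property-tested against a
brute-force oracle that tries every (position, mutant) substitution: the
suggestion set is exactly the set of substitutions that create a new
occurrence of an enriched pattern under the two anchoring rules, and a
suggested mutant never equals the wild type. One subtlety: a substitution
always creates its anchored occurrence, but the *total* count of the
supporting pattern can stay flat when the replaced residue itself
participated in an overlapping occurrence of the same pattern (pattern A0C
on `AAC`: A→C at position 2 creates the occurrence at (1, 2) and destroys
the one at (2, 3)). The tested invariant is therefore "creates the anchored
occurrence and never decreases a supporting pattern's count", not a strict
increase.

## Validation against ΔT records

Suggestions are matched to experimental melting-temperature changes by
(wild type, 1-based position, mutant). Success means ΔT > 0; ΔT = 0 counts
as failure (no improvement). Mutations with several records are resolved by
a *conflict policy* — `conservative` (default: any non-positive record ⇒
failure), `first`, or `mean` — and every mutation with records of opposing
outcome is listed in the report regardless of policy. The success rate is
reported over distinct matched mutations; the per-record rate is emitted
alongside for transparency.

The bundled worked example (`thermopattern/data/rnase_hi_mutations.tsv`,
loadable via `load_example_mutations()`) is a table of 65 pattern hits for
*E. coli* ribonuclease HI (Pfam PF00075) with ProTherm-derived ΔT values:
36 distinct mutations, all matched, 26 with positive ΔT — a 72% success rate
under the conservative policy (the A52K +19.5/−19.5 sign conflict counts as
the tenth failure). Counted per pattern-hit row instead, the rate is 73.8%;
the distinct-mutation convention is the package's bookkeeping unit.

## Synthetic families

`generate_family` draws two groups of sequences i.i.d. from a common
background residue distribution (uniform over the 20 standard residues by
default) and plants enrichment only in the thermophilic group: per sequence
and per planted pattern, an occurrence count is drawn from a Poisson law
with the configured mean (`extra_rate`, expected extra occurrences per
sequence), and each occurrence overwrites an unreserved anchor pair at a
uniformly chosen position. Overwriting preserves length; anchor clashes are
redrawn up to a bounded number of attempts, after which the configuration is
rejected as infeasible. A single integer seed drives one `numpy` generator
through a documented draw order, so families are bit-reproducible.

Default study conditions used throughout the tests: 30 mesophilic and 30
thermophilic sequences of length 150, uniform background, one pattern
planted at `extra_rate` 1.0 — a regime where the screen's power to recover
the planted pattern exceeds 90% across seeded replicates, while a null
configuration (nothing planted) yields a significant fraction within
binomial noise of α.

What the generator does *not* emulate: phylogenetic correlation between
family members, alignment structure, positional composition preferences, or
length variation tied to category. Passing tests on these families show the
statistics behave as designed under their own assumptions — exchangeable
sequences, independent residues — not that the screen's p-values are
calibrated on real Pfam families, where relatedness inflates effective
significance. An optional first-order Markov background exists for
robustness experiments.

`generate_target_with_sites` builds targets for exercising the suggester:
an inert filler residue (one absent from every enriched pattern) forms the
background, pattern residues are placed farther apart than any window span,
and the expected suggestion list is derived by an independent position-major
scan of the finished sequence; placement is retried until the induced
support count equals the requested number of sites exactly.

## Numerical and implementation notes

* Counting is vectorized per spacing (shift-and-compare plus `bincount`
  over 400 residue-pair codes); the full 4,400-pattern screen of a 60 × 150
  family takes well under a second.
* Large-sample p-values for the whole grid are computed in one vectorized
  Mann–Whitney call; small-group screens fall back to the per-pattern exact
  enumeration.
* The exact enumerator compares |U − nm/2| with a 1e−12 slack so midrank
  arithmetic cannot flip boundary assignments.
* Ties in output ordering (equal p-values) break on position, then mutant
  residue; all file emitters are deterministic given identical inputs.
* Problem sizes in the test and acceptance runs (1,000 counting-oracle
  cases, 500 suggestion-oracle instances, 50 recovery replicates, group
  sizes ≤ 6 for the exact-test enumeration) were chosen so each check is
  statistically meaningful yet the whole suite completes in seconds.

## Known limitations

* Growth temperature is an imperfect proxy for protein melting temperature;
  thermophilic organisms also differ in pH and salinity tolerance.
* No correction is made for family phylogeny: closely related thermophilic
  sequences count as independent evidence.
* Suggestions are single substitutions; combined effects and epistasis are
  out of scope, as is any ΔΔG or structure-based scoring.
* The 72% worked-example success rate concerns one well-measured protein;
  it is a demonstration of the bookkeeping, not an accuracy estimate for
  arbitrary families.
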