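# Methods

This note records the semantics the package implements, the choices made
where the design was genuinely open, and what the synthetic cohort does and
does not establish.

## Event model

An event is one occurrence of a clinical activity with typed attributes.
Two lifecycle timestamps are reserved — `start time` and `complete time` —
and at least one must be present; the *canonical* time of an event is its
complete time, falling back to its start time. Traces are sorted stably by
canonical time, so simultaneous events keep their input order, and
re-sorting is the identity. All timestamps are naive local times at minute
or finer granularity; timezone offsets encountered on input are dropped
after normalising to the stated clock time, since guideline thresholds
(door-to-needle minutes) are defined on the local clock.

Tabular input with a single `Timestamp` column populates the complete time
only: the rules that subtract timestamps reference complete (and start)
times explicitly, and a lone recorded timestamp in hospital exports almost
always marks completion. An optional `Start_Timestamp` column fills the
start time. Attribute kinds come from a user-supplied dictionary
(name → kind); unmapped attributes default to `admin` with a warning rather
than an error, because logs routinely carry bookkeeping columns no rule
references. Actors map to an `action`-kind attribute named `executor`.

In XES, an event holding both timestamps is written as two adjacent
elements (lifecycle `start` then `complete`) sharing an `identity:id`;
reading merges exactly that pattern — adjacent, same activity, same or
absent id. Non-adjacent lifecycle pairs stay separate events: correlating
them would require an instance key the format does not guarantee. The
attribute-kind classification is persisted as a nested `clin:kind` string
attribute so typing survives round-trips.

## Template semantics

The supported template set is the standard Declare core (17 kinds in four
families); it is a documented closed set — extending it means adding the
template's formula in the semantics layer and its activation rule in the
checker. Counted templates
follow the convention `existence_n` ≥ n, `absence_n` ≤ n, `exactly_n` = n
occurrences. Finite-trace conventions: `next` is false at the last
position, `weak next` true; `weak until` holds when the release never
triggers; the empty trace satisfies every universal formula. `eval_ltl` is
a deliberately naive position-indexed recursion — its value is being
obviously correct, so it can serve as the brute-force oracle for the
incremental checker (the two are compared exhaustively over a three-letter
alphabet up to length 6 in the test suite).

## Checking algorithm

For one constraint on one trace the checker proceeds event by event:

1. **Activation.** Events of the activating activity are gated by the
   conditions on their own side (`ψ(i,·)` for source-activated templates,
   `ψ(·,j)` for precedence-like target-activated ones). An event failing
   its gate simply does not activate the constraint. Which side activates
   is per template: response-like templates and the existence family
   activate on A-events; precedence-like templates on T-events; negative
   relations on A-events; choice templates are trace-level with one
   synthetic activation.
2. **Counterpart search.** Each activation scans its structural scope in
   the template's direction, nearest candidate first (first subsequent
   target for response, latest preceding source for precedence, the
   immediate neighbour for chain templates, the inter-occurrence window for
   alternate templates). Candidates failing the counterpart-side or
   correlation conditions are *non-qualifying*: the search continues rather
   than failing immediately. One counterpart may fulfil many activations.
3. **Resolution.** A qualifying counterpart fulfils the activation (for
   negative templates it violates it). With no qualifying counterpart, the
   violation section is `data_flow` when non-qualifying candidates existed
   and `control_flow` when none did. For unary constraints all conditions —
   including a self-correlation like `executor ≠ proofreader`, whose two
   sides both bind to the activated event — are checks, not gates: failing
   them is a `data_flow` violation.

A constraint is **satisfied** iff it has no violated activations and its
control-flow section holds (for the existence/choice families the
control-flow section is the occurrence-count predicate itself). It is
**vacuous** iff it has no activations *and* the control-flow section holds;
vacuous implies satisfied. A missing mandatory activity is therefore a
control-flow violation, never vacuity. A condition referencing an attribute
absent from the involved event makes that atom false and annotates the
record with a "missing attribute" note instead of raising — absent
documentation is itself a deviation worth surfacing, not a crash.

Rule-level disjunction lives above the templates: a rule group is satisfied
iff any member constraint is, and the reported detail is the first
satisfied branch, else the branch with fewest violations (first listed on
ties). Incomparable values under an ordering operator (a string against a
number) evaluate false rather than raising. Checking is deterministic;
there is no randomness anywhere in the checker.

At the log level a case is `violated` / `fulfilled` / `vacuous` per rule;
the printable table folds vacuous into the fulfilled column so the two
columns sum to the cohort size, while the JSON report keeps the three
outcomes separate. Optional (non-mandatory) rules are reported but never
flip a case into the headline violated set.

## The packaged stroke model

Six rule groups, seven constraint tuples. The guideline sentence "CT and
blood glucose before thrombolysis" is a conjunction, so it becomes two
sibling groups (1.1, 1.2) under one rule label — folding both constraints
into one group would have turned the *and* into the group-level *or*. The
heparin rule is the one true disjunction: either heparin and thrombolysis
never coexist, or the dose preceded the needle by more than 24·60 minutes.
Timestamp differences are computed as target-event time minus source-event
time, in minutes — the orientation that makes both packaged time rules read
naturally (thrombolysis − admit < 60; thrombolysis start − heparin complete
\> 1440). Thresholds are minutes unless a model file states otherwise. The
blood-pressure rule's printed target activity (`antipyretic`) is kept
verbatim from its source table even though the rule text concerns
thrombolysis; the packaged file documents the rule by its description, and
changing the activity would silently change which events activate the
check. An alias table maps demonstration-log spellings ("Blood sugar
test", "Intravenous thrombolysis") onto the model alphabet.

## Synthetic cohort

The generator emulates thrombolysis episodes: admission, CT (plus an
incidental MRI in 30 % of cases), blood-glucose test and a vital-signs
measurement within 2–9 minutes of arrival; thrombolysis with start and
complete times; dispensing with two nurse attributes; an antipyretic
administration, statins in 70 % of cases, and discharge after 3–10 days.
Case start times are spaced one day apart from a fixed epoch and all draws
go through one seeded generator, so identical configs give byte-identical
XES.

Violations are injected *constructively*, independently per rule and case:
omit the CT or glucose test; draw the door-to-needle time from the violated
band 61–240 min instead of the fulfilled band 10–59 min (never exactly 60);
push systolic ≥ 180 or diastolic ≥ 100 mm Hg; place the heparin dose 30–1380
minutes before the needle instead of > 1440 (compliant cases carry an old
dose with probability 0.25, otherwise none — making the heparin rule the
only rule with vacuous cases); let one nurse both dispense and proofread.
The bands are disjoint from the thresholds by whole minutes, and each rule's
pattern touches only its own activities/attributes, so conformance checking
must recover the injected outcome of every (case, rule) pair **exactly** —
the central end-to-end test and the reason no rejection sampling is needed.

What passing does and does not show: the cohort exercises every packaged
rule, both failure sections and the vacuity path, but its traces are far
more regular than hospital data — no missing documentation, no repeated
activities within an episode, no transfers, no clock skew between source
systems, and violation injection is independent across rules whereas real
deviations correlate. Exact recovery therefore validates the checker's
semantics, not the difficulty of real-world preprocessing. The published
per-rule violation frequencies of the original private cohort are not
reproduced and are not a target.

## Problem sizes

The exhaustive oracle comparison uses all 1,093 traces over a three-letter
alphabet up to length 6 against all 17 templates (18,581 checks); the
recovery experiment uses 1,500 generated cases (9,000 case–rule pairs); the
partition invariant 1,000 randomized pairs; round-trips 30 randomized logs.
These sizes are where the properties stabilise — they are exact, not
statistical, so larger inputs add runtime without adding evidence.

## Known limitations

* No alignment-based conformance: the checker localises deviations but does
  not compute optimal alignments or fitness costs.
* No model discovery and no online/streaming checking.
* Lifecycle merging is adjacency-based; interleaved start/complete pairs of
  the same activity are treated as separate events.
* The bracket grammar supports conjunction only; express negation with the
  complementary operator, disjunction at the rule-group level.
* Attribute-kind assignment is by dictionary, not inference; terminology
  binding is out of scope.
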