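# clindeclare

Multi-perspective declarative conformance checking for clinical event logs.

Hospital information systems record diagnosis and treatment as event logs:
each patient episode (a *case*) is an ordered sequence of activities with
timestamps, actors and clinical measurements. Quality-management teams want
to know where recorded care deviates from guideline recommendations — not
only in the *order* of activities (control flow) but also in timing,
personnel and measured values (data flow). `clindeclare` is a toolkit for
exactly that audit: it represents guideline rules as declarative
constraints over activities *and* their typed attributes, and checks every
case of a log against them, attributing each deviation to the control-flow
or the data-flow perspective.

## The representation

A rule is a constraint tuple

```
c = <template, A, T, ψ>
```

where `template` is a Declare template with LTL-over-finite-traces
semantics (existence, response, precedence, not-coexistence, ...), `A` is a
source activity, `T` a target activity (absent for unary templates), and
`ψ` a set of data conditions. Event attributes are classified into seven
clinically meaningful kinds — 1 time, 2 demography, 3 observation,
4 evaluation, 5 instruction, 6 action, 7 admin (the last five mirroring the
openEHR entry categories) — and every condition is indexed by the kinds it
constrains: `ψ(i,·)` conditions the source, `ψ(·,j)` the target and
`ψ(i,j)` relates the two; arranged on those indices, the conditions of one
constraint form its 7×7 constrained-relationship matrix. Conditions are
written in a compact bracket notation, e.g. a door-to-needle limit as a
timestamp difference in minutes:

```
ψ(1,1) = [complete time, complete time, 60, <]
ψ(3,·) = [systolic pressure, 180, <]&[diastolic pressure, 100, <]
ψ(6,6) = [executor, proofreader, !=]
```

The checker walks each trace once per constraint: events that *activate*
the constraint (each response source, each precedence target, ...) are
resolved against the nearest qualifying counterpart, and every activation
ends up *fulfilled* or *violated* — with a `control_flow` section when the
counterpart is structurally absent and a `data_flow` section when
counterparts exist but the data conditions fail. A case is compliant when
no mandatory rule is violated; constraints without activations are
vacuously satisfied.

The package ships a worked five-rule model for acute ischemic stroke
thrombolysis (CT and blood-glucose testing before IV thrombolysis,
door-to-needle time under 60 min, blood pressure below 180/100 mm Hg, no
thrombolysis within 24 h of a low-molecular-weight-heparin dose, and
double-checked drug dispensing), plus a seeded synthetic-cohort generator
with ground-truthed injected violations, since real stroke cohorts are
privacy-restricted.

## Worked example

Generate a 200-case synthetic rt-PA cohort with violations injected into
the door-to-needle rule (10 %) and the heparin rule (20 %), then audit it
against the built-in stroke model:

```bash
$ clindeclare generate --n-cases 200 --seed 11 --p-rule2 0.1 --p-rule4 0.2 --out-dir demo
$ clindeclare check demo/synthetic.xes --model stroke --out-dir demo/report
No   Description                                                                                      rt-PA Vio  rt-PA Ful
--------------------------------------------------------------------------------------------------------------------------
1.1  Before IV thrombolysis, CT should be tested                                                      0          200
1.2  Before IV thrombolysis, blood glucose should be tested                                           0          200
2    The door-to-needle time (DNT) should be within 60 min                                            17         183
3    BP need to be kept less than 180/100 mm Hg                                                       0          200
4    No IV alteplase after a treatment dose of low-molecular-weight heparin within the previous 24 h  45         155
5    For dispensing drugs, at least two nurses should execute a double check                          0          200
```

Seventeen cases drew a door-to-needle time above 60 minutes and 45 cases a
heparin dose inside the 24 h window; the `Ful` column counts fulfilled plus
vacuously satisfied cases, so each row sums to the cohort size. The exit
code is 1 because mandatory rules are violated (0 = compliant, 2 = usage
error), and `demo/report/report.{json,csv}` hold the per-case outcomes and
the individual deviating events. The same numbers are available in the
library API:

```python
from clindeclare import GeneratorConfig, generate, check_log, stroke_model

log, truth = generate(GeneratorConfig(n_cases=200, p_rule2=0.1, p_rule4=0.2, seed=11))
report = check_log(log, stroke_model())
report.counts("2")   # {'violated': 17, 'fulfilled': 183, 'vacuous': 0}
```

Because injection is constructive, `report` agrees with `truth` on every
(case, rule) pair exactly — this end-to-end identity is the package's
central test.

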