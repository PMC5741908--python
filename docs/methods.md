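# Methods

## The screening model

`labguard` screens laboratory test orders at order-entry time against a
declarative rule set. One appropriateness rule binds an analyte to:

- a **minimum retest interval** (the shortest clinically meaningful time
  between repeats of the same test),
- the **criteria** used to judge the previous result — time only, or
  time plus a quantitative check of the prior value against a
  sex/age-stratified normality range,
- optional **within-order incompatibilities** (analytes that must not be
  requested together, e.g. ANA with ANA Reflex),
- a **scope**: order priority (routine/urgent), ward groups, sample type,
- an **outcome**: hard stop (`BLOCK`, the request can only be cancelled)
  or soft stop (`WARN_WITH_MOTIVATION`, overridable with a coded
  motivation: specialist request, clinical evidence, laboratory data
  confirmation, or free-text other),
- a **reporting comment** shown to the prescriber.

For each request in an order the engine:

1. resolves the requested code to a canonical analyte via the rule set's
   per-system code maps; unresolvable codes exempt the request from
   screening and are recorded on the audit event;
2. selects the applicable rule after scope filtering; if several match,
   the most severe outcome wins (`BLOCK` over `WARN`), ties broken by
   lexicographic `rule_id` — screening output therefore never depends on
   the order of rules in the config file;
3. finds the latest **executed** prior result strictly before the order
   timestamp (pending requests never anchor the clock) and flags the
   request iff `elapsed < min_interval`. The comparison is strict: an
   elapsed time exactly equal to the interval is appropriate, one second
   less always triggers. Elapsed time runs from the prior's specimen
   collection timestamp to the order timestamp, both compared in UTC;
4. for rules with the quantitative criterion, annotates the alert with
   whether the prior value fell inside the patient's matched normality
   range, and when it did, attaches a structured prior-result report
   (analyte, value, units, collection time, range, in-range flag). The
   quantitative criterion never suppresses an alert: the prior's
   validity governs the report, not the warning.

Order-level checks add one `BLOCK` alert per incompatible analyte pair
present and one per analyte requested more than once in the same order.
Duplicate alerts carry the analyte's retest rule id when one exists and
no rule id otherwise (duplication is an intrinsic integrity check, not
the consequence of any single configured rule). Incompatibility and
duplicate checks honour the declaring rule's ward-group scope;
per-request priority and sample-type filters apply only to retest rules,
since an incompatible pair is a property of the order, not of either
request's priority.

Alerts are emitted in a canonical order — (analyte, rule id, reason) —
so the screening result is invariant under any permutation of the rule
list *and* of the request list.

Every `check_order` call appends one audit event (timestamp, requesting
system, order id, request count, alerts, resolutions, unmapped codes),
whether or not alerts fired; the audit trail is append-only JSON lines.
Resolutions are validated: a hard stop can only be cancelled, a soft
stop can be overridden only with a motivation, the `OTHER` motivation
requires free text, and an alert can be resolved at most once. An
override does **not** reset the retest clock for later orders: the
executed prior still anchors elapsed time (the alternative —
interpreting an override as a fresh baseline — has no support in
practice guidance and would let a single override silence a whole chain
of repeats).

### Normality ranges

Ranges are half-open in age (`age_min <= age < age_max`, age as
completed years at the order time) and may be sex-specific or `ANY`.
Lookup prefers the exact-sex range; two matches at equal specificity are
a configuration defect, rejected when the config loads (overlap check
per analyte and sex) and reported as a hard error if one slips through.

### Durations

Rule configs spell intervals as `"24h"`, `"3d"`, `"6mo"`. Internally
everything is hours; 1 d = 24 h and 1 month = 30 d = 720 h, fixed, so
"not before 3 months" is a deterministic 2160-hour boundary rather than
a calendar-dependent one.

## The default rule set

The package ships the publicly documented minimum-retest-interval rules
for seven high-volume analytes — aPTT 24 h, vancomycin 72 h, blood
count 24 h, CRP 72 h, PT 24 h, ferritin 3 months, TSH 6 months — plus
the sodium 24 h soft stop with a quantitative criterion (adult range
135–145 mmol/L) and the ANA / ANA-Reflex hard-stop incompatibility.
Production deployments of such systems carry larger rule sets; these
are the rules with published intervals, and the config format makes
extension trivial.

## Impact evaluation

- `percent_change(pre, post) = 100 x (post - pre) / pre`, reported to
  two decimals with **half-away-from-zero** rounding. This is the
  convention under which the published ward-level reference percentages
  (e.g. -1.85% from -1.845057…) reproduce exactly; banker's rounding
  does not reproduce them.
- `ward_comparison` requires each ward to appear exactly once per
  period, reports per-ward rows and per-group totals (cells summed
  before the percentage is taken), with absolute deltas alongside.
  One published cost total is printed 0.25 euros below the sum of its
  ward cells; the comparison always recomputes totals from the cells.
- `cost_of_orders` prices a retained request stream against a
  per-analyte fee table (euros per test, the regional-charge costing
  perspective: reagent, labour and overhead differences between
  laboratories are deliberately out of scope). The bundled fee table is
  synthetic — regional fee schedules are not published.
- `two_proportion_test` is the pooled-variance z test with a two-sided
  normal p-value. It is exposed as a general operation (e.g. mortality
  rate pre vs post); the package does not assert any specific clinical
  significance claim because the underlying counts are not published.
- `cronbach_alpha` uses the variance decomposition
  `alpha = k/(k-1) (1 - sum_i s_i^2 / s_total^2)` with `n-1`
  denominators and listwise deletion of incomplete respondents; zero
  total variance is signalled as undefined, never returned as a number.
- `cohens_d = (mean_b - mean_a) / s_pooled` with
  `s_pooled = sqrt(((n_a-1)s_a^2 + (n_b-1)s_b^2)/(n_a+n_b-2))`. The two
  survey waves are treated as independent samples by default; where a
  fraction of respondents answered both waves this understates
  precision, and a paired variant is deliberately not guessed at —
  callers with linked responses should pair explicitly before calling.

## Synthetic cohort generator

The generator emulates the evaluated study layout: two ward groups
(intervention: Medicine, Cardiology; control: Post-Acute/Long-term
care, Coronary Intensive Care, University Medicine), two disjoint
3-month observation windows a year apart, and an elderly inpatient
cohort. Defaults: 1233 patients, 51.25% female, age ~ N(74, 9) truncated
to [18, 100], planted violation rate 0.20 among repeat requests (the
published range for repeat-criteria inappropriateness is roughly 6–22%),
soft-stop override rate 0.5, mortality 10.46% and 30-day readmission
10.46% planted as deterministic counts (`round(rate x N)`) so cohort
descriptives recover them exactly.

Per (patient, analyte, period) the order process is a sequence of
base/follow-up **pairs**: the follow-up lands inside the retest interval
with probability `redundancy_rate` (uniform offset in 0.05–0.95 of the
interval) and outside it otherwise (1.05–2.0 of the interval);
consecutive pairs are separated by at least 1.05 intervals plus an
exponential gap, and a pair is only started if the widest possible
follow-up still fits inside the period. Consequently every repeat
request's violation status is exact by construction, base orders never
violate, and the engine-recovered alert fraction over repeat requests
is a clean Binomial(n, r) draw — the parameter-recovery tests check it
against three binomial standard errors. For analytes whose interval is
comparable to the window (ferritin 3 months, TSH 6 months) a compliant
repeat cannot fit, so at most one order per patient per period is
generated; the inter-period gap (9 months) keeps cross-period repeats
compliant. Every order has a matching executed result at the same
timestamp (the pre-intervention world, where everything ordered was
performed); values are normal, truncated at zero.

The single seed expands into independent named substreams (patients /
timing / values / overrides) via `numpy` `SeedSequence.spawn`, so
changing one component's draw count never perturbs the others; equal
seeds give byte-identical CSV output.

`apply_cdss_effect` converts a screened pre-intervention stream into a
post-intervention one: hard-stopped requests are cancelled, each
soft-stopped request is retained with probability `override_rate`.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: disease progression, correlated test
panels, admission/discharge structure of ordering intensity, realistic
value physiology or analytical variation, clustering of ordering
behaviour by prescriber, and seasonal case-mix shifts. The generator
demonstrates that the engine and analytics recover planted parameters;
it cannot validate the clinical appropriateness of any rule.

## Problem sizes and numerical choices

Example runs and the verification script use cohorts of a few hundred
patients (~10,000 requests, ~5,000 of them repeats), which puts three
binomial standard errors around the 0.20 violation rate at about
±0.016 — tight enough to detect an implementation bias while keeping
any run under a few seconds. Timestamps are second-resolution; the
boundary contract (`elapsed == interval` never triggers,
`interval - 1 s` always does) is tested explicitly. CSV round trips
read only empty cells as missing, because the sodium analyte code "NA"
must never be parsed as NaN.

## Known limitations

- The shipped rule set covers only analytes with published intervals.
- The audit log holds one process's screening stream; there is no
  concurrency or ordering guarantee across processes.
- Costing is linear in the fee table; indirect and intangible costs
  (specimen transport, patient time, follow-on treatment) are out of
  scope by design.
- The survey statistics operate on whatever item subsets they are
  given; instrument validity of a modified questionnaire is a study
  question, not a package guarantee.
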