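# Methods

This note documents the models and procedures implemented in `ethnirec`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data evidence does and does not
show about real data.

## Code mapping

Ethnicity codes are opaque strings keyed by coding system (`read`,
`snomed`, `hes_ethnos`); no vocabulary hierarchy logic is applied. A code
list maps each (code, system) pair to one of six high-level categories.
Unknown must be an explicit entry: an absent category field is a format
error, because silently treating gaps as Unknown would hide data
problems. Lookup is strict by default (unlisted code → error); a lenient
mode maps unlisted codes to Unknown with a logged warning, for
exploratory work with incomplete lists. A code appearing twice within one
system is rejected rather than resolved by precedence — there is no
principled tie-break between conflicting list entries.

The bundled lists are synthetic examples (the HES ethnos letters follow
the public NHS standard grouping; the Read/SNOMED entries are
format-illustrative). They exist so the pipeline runs end-to-end;
substantive analyses require the user's own lists in the same format.

## Ingest and population rules

Practice-level deduplication keeps Aurum and drops every GOLD patient
whose practice appears in the bridging file; no patient-level
cross-database deduplication is attempted. Population filters
(acceptable, currently registered, linkage eligible) are conjunctive and
independently applicable. Secondary-care records default to being
restricted to linkage-eligible patients, because linked hospital data
only exists for them. Per-dataset coverage cut-off dates
(APC 2021-03-31, OP/DID 2020-10-31, A&E 2020-03-31) trigger validation
warnings only, never row drops: windowing is the caller's decision.

## The resolution cascade

Candidate categories are the distinct known categories among a patient's
usable records. Numerical/ordering choices that the cascade's verbal
description leaves open were fixed as follows:

* **Recency of a category** is the maximum record date over that
  category's records; records with missing dates sort strictly oldest
  (sentinel = the minimum representable date). A category whose records
  are all undated can therefore never win a recency comparison against a
  dated one.
* **Frequency counts every record row**, including repeated identical
  hospital episodes — multiplicity is treated as evidence. Whether the
  original implementations counted per episode, per spell or per distinct
  (date, code) is not documented; this choice is isolated in one
  aggregation step and easy to swap.
* **Care-tier priority** keeps a category if *any* of its records come
  from the prioritised tier. When all surviving categories have
  prioritised-tier evidence, or none do, the step is non-discriminating
  and passes through. The alternative ("all records from the tier") was
  rejected because one prioritised-tier record is positive evidence.
* **The census step always resolves** because the configured ordering is
  required to be a strict total order over exactly the five known
  categories. If a supplied census distribution contains tied
  percentages, the tie is broken by canonical category order at
  configuration time, keeping the ordering strict.
* **The non-Other rewrite** reruns the full cascade on the Other-free
  record set instead of literally taking "the second most frequent"
  category. The two coincide in the simple case; the rerun generalises
  correctly when the remainder itself ties. A patient whose records are
  unanimously Other is never rewritten.
* **Determinism**: no step ever breaks ties by record order, so same-day
  duplicates and input permutations cannot change any result.

The default census ordering is the England 2021 Census distribution
(White 81.05, Asian 9.61, Black 4.22, Mixed/Multiple 2.96, Other 2.18),
chosen because the representativeness analysis is against England; any
five-category distribution can be supplied instead.

Three implementations exist: a per-patient cascade (`derive_patient`), a
literal record-filtering oracle with no per-category aggregation
(`brute_force_derive`, for testing), and a vectorised pandas
implementation (`derive_cohort`). The test suite checks all three against
each other on randomised record sets, and checks that the cohort path
decomposes into independent per-patient derivations.

## Evaluation

Percentages are rounded half-up to two decimals, κ and SE to four, in
human-readable outputs; machine-readable outputs keep full precision.

Cohen's κ uses the large-sample standard error
`√(p_o(1−p_o)/(n(1−p_e)²))`. The Fleiss–Cohen–Everitt exact variance is a
known alternative and deliberately not the default: the large-sample form
is the most common implementation and reproduces the tiny standard errors
seen at multi-million-patient scale. When both categorisations are
constant (`p_e = 1`), κ is undefined and the code raises rather than
returning a conventional 0 or 1.

Unknown is an ordinary sixth category in the main analysis; the
`drop_unknown_pairs` option removes the Unknown row and column (i.e.
every pair where either categorisation is unknown) before computing
marginals, as a sensitivity analysis separating "different known
category" disagreement from "known vs unknown" disagreement.

Three band schemes ship. The default —
(0, 0.20] none/slight, (0.20, 0.40] fair, (0.40, 0.60] moderate,
(0.60, 0.80] good, (0.80, 0.90] strong, (0.90, 1] almost perfect — is the
only banding consistent with all the printed label/κ pairings this
toolkit is validated against (fair at 0.36, moderate at 0.55, strong at
0.89, almost perfect above 0.90); Landis–Koch and McHugh are selectable
alternatives.

The representativeness comparison requires the Unknown-excluded
(renormalised) distribution, since census references only cover stated
ethnic groups. Note the printed England 2021 reference column sums to
100.02 due to rounding, so a distribution identical to the reference can
still show ±0.02 pp differences.

## Synthetic cohort generator

The generator emulates the statistical structure of linked UK EHR data,
not its content. Parameters, defaults and the reasoning behind them:

| parameter | default | why |
|---|---|---|
| `true_distribution` | England 2021 Census | the natural known-truth reference |
| `aurum_fraction` | 0.7604 | published database split |
| `linkage_eligible_fraction` | 0.8218 | published linkage eligibility |
| `p_record_primary` / `p_record_secondary` | 0.40 / 0.52 | calibrated jointly so (i) ~64–66% of patients have a usable record, the reported completeness level, and (ii) primary-only and APC-only coverage are comparable, matching the reported near-equality of the two single-source agreement statistics |
| `records_per_patient_mean` | 5.0 | shifted Poisson (≥1 given presence); several records per patient are typical over decades of registration, and consensus resolution needs enough evidence per patient for majority voting to defeat record-level noise |
| `misclassification_rate` | 0.05 | uniform over the other four known categories; a confusion-matrix override exists because real recording error is differential, but no calibrated values are published |
| `p_unknown_code` | 0.05 | unknown-coded records exist in all sources |
| `date_window` | 2004-01-01 – 2021-03-31 | spans the QOF-era rise in GP ethnicity recording up to the APC coverage cut-off; dates are uniform by default, with an optional `recency_trend` skew |
| `secondary_given_primary_odds` | 1.0 | primary/secondary presence independent by default; the odds knob allows positive dependence |
| `acceptable_fraction`, `currently_registered_fraction` | 0.95, 0.50 | plausible round values; neither is published for the relevant builds |
| HES dataset weights | APC .50 / OP .30 / A&E .15 / DID .05 | invented; APC-dominant, which drives the source-set agreement ordering |

Secondary-care records are generated only for linkage-eligible patients.
Hospital record counts are drawn once per patient and split across the
four datasets per record.

**What the generator does not emulate.** Completeness conditional on
registration status (so the reported 82.0%-among-registered and
79.3%-both-sources figures are not reproduced — they would require
registration-dependent presence probabilities, which the parameter set
does not model); differential missingness by ethnic group (a documented
feature of real HES data — the confusion-matrix hook exists but no
calibrated values ship); realistic code-usage frequencies; practice-level
clustering of ethnicity; geography and deprivation. Consequently, passing
recovery tests show that the *algorithm* recovers a known truth under
uniform noise and missingness; they do not show that real derived
ethnicity is unbiased, since real missingness and error are differential.

## Problem sizes used in the checks

The automated checks run the cascade-vs-oracle comparison on 10 000
randomised record sets (≤ 6 records each, all categories, sources and a
3-year date window, seeded), and cohort-level properties on 50 000-patient
cohorts — Unknown-count invariance across presets, the source-set
agreement ordering, and distribution recovery averaged over five seeds at
completeness 0.8/0.6 with 5% record misclassification. Recovery is
assessed under the `algorithm4` preset: the non-Other rewrite
intentionally redistributes the Other category (switching it off roughly
triples the Other share, qualitatively matching the published contrast),
so recovery of the true distribution is only a meaningful expectation
without it. These sizes give sampling error well below the property
tolerances (±0.5 pp per category for recovery).

## Known limitations

* The cascade is deterministic by design; probabilistic resolution and
  imputation are out of scope.
* Only the six-category high-level classification is supported, not the
  finer census categories.
* The bundled code lists are illustrative, not research-grade.
* Run manifests include a timestamp; reproducibility guarantees
  (byte-identical reruns given config + seed) therefore apply to all data
  outputs, and to manifests up to the timestamp field.
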