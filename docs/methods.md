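# Methods

## Scope and design

`prostasim` is an event-driven micro-simulation: for each man it draws an
other-cause death age, a latent prostate-cancer course, and the full set of
uniform random numbers that screening and survival will consume. Any strategy
(no screening, classical PSA→TRUSGB, PSA→mpMRI→MRIGB) and any draw of test
parameters is then evaluated against those same numbers. This
common-random-numbers (CRN) discipline has three consequences worth stating
up front:

* the unscreened "twin" of every screened man shares his disease course
  exactly, which is what makes lead time and overdiagnosis well defined;
* a screen-detected man who is not cured dies at precisely his twin's death
  age, so lead time is never credited as survival;
* replicate-to-replicate spread in the probabilistic sensitivity analysis
  reflects parameter uncertainty, not Monte-Carlo noise — the desk-scale
  analogue of eliminating noise with an enormous simulated population.
  A flag (`PsaConfig.common_random_numbers=False`) re-simulates the cohort
  per replicate instead.

## Natural history

Tumor onset follows a piecewise-constant age hazard (default bands rising
from 0.0008/y at 35–45 to 0.0060/y at 65–75, zero before 35). Onset enters
state (T1, Gleason <7, local-regional) by default; the entry distribution is
configurable. The preclinical space is T-stage × Gleason category × spread =
18 states. From each state four events compete with exponential waiting
times: T-advance, grade-advance, metastasis (local-regional → distant only),
and clinical diagnosis. Axes never move downward, and each transition moves
exactly one axis one step, so a course makes at most five transitions before
diagnosis absorbs it.

Dwell times are exponential. Nothing in the published material pins the dwell
distribution; exponential competing risks keep the walk analytically
checkable — the test suite verifies simulated state occupancy against an
independent matrix-exponential solution of the same generator — and the
distribution sits behind a single sampling site should a Weibull variant be
wanted. Event-time ties are measure-zero; if floating-point produces one, the
precedence is clinical diagnosis > metastasis > grade-advance > T-advance
(fixed by column order).

One wording point: the state count (3 × 3 × 2 = 18) fixes the spread axis at
two levels (local-regional, distant); that resolution is adopted throughout.

## Other-cause mortality

A closed single-year life table (`age,qx`, terminal qx = 1) supplies
other-cause death. The packaged table is synthetic Gompertz–Makeham
(μ(x) = A + B·e^{Cx}, A = 5·10⁻⁴/y, C = 0.11/y, B solved by bisection so life
expectancy at birth is 80 y, a Dutch-male-like figure); any real table can be
substituted via CSV. Death ages are continuous: the death year is drawn from
the table's discrete law and the sub-year offset is uniform (the standard
demographic assumption). Women are not modeled.

## Screening

Invitations run from 55 to 64 at 3-year intervals (55, 58, 61, 64), 80%
attendance per invitation (independent across rounds by default; an
all-or-none `persistent_attendance` switch exists for sensitivity analysis),
90% biopsy compliance. PSA positivity is modeled as state-dependent
sensitivity (defaults 0.45/0.72/0.90 by T-stage locally, 0.95 when distant)
rather than as simulated PSA levels. Cancer-free false positives are not
simulated man-by-man; they enter the accounting through the biopsy PPV
identity below. A detected man exits further screening.

Test characteristics (probabilities): mpMRI 0.94 for high-grade (HGC) and
0.74 for low-grade (LGC) cancer; TRUSGB 0.90 for either grade; MRIGB 0.91
(HGC) / 0.44 (LGC); recorded-grade misclassification of detected HGC 0.363
(TRUSGB) / 0.087 (MRIGB). The grade dichotomy defaults to HGC = {Gleason =7,
>7} ("clinically significant") and is configurable.

**Biopsy volumes and the mpMRI bridge.** Total biopsies per arm (including
negatives) are imputed as detections / PPV. The mpMRI scan count in the MRI
arm adds, to the simulated cancer-bearing PSA positives, the cancer-free PSA
positives implied by the classical arm's identity: (total classical biopsies −
simulated cancer biopsies) / compliance. These imputed events carry the
modality's unit cost (and, switchable, the biopsy disutility) at the
attendance-weighted average round discount factor. `mpmri_pos_rate_nocancer`
is the derived mpMRI positivity among those men; it exists for this bridge
and for sensitivity analysis, not as a simulated test.

## Treatment, survival, and cure

Treatment (RP, RT, watchful waiting/surveillance) is drawn from a matrix by
age band (<60, 60–69, ≥70), T-stage, and *recorded* grade class; distant
disease is managed conservatively. Default cells send low-grade diagnoses
predominantly to surveillance and high-grade localized disease predominantly
to curative treatment — which is exactly why misrecording an HGC as LGC is
harmful.

Baseline post-diagnosis survival is a per-cell mixture keyed by (spread,
grade class) with an age-band multiplier: with probability `death_prob`
(defaults 0.12 LR·LGC, 0.45 LR·HGC, 0.85–0.92 distant) the cancer is fatal
and the time from clinical diagnosis to death is Weibull (scales 14, 9, and
~3 years respectively); otherwise the man dies of other causes. Curative
treatment of local-regional disease multiplies the fatality probability by a
relative risk of 0.56 (RP and RT alike).

Screen detection helps only through cure: with probability
`c0 + (cmax − c0)(1 − e^{−kL})` in lead time L (defaults c0 = 0, cmax = 0.80,
k = 0.22/y) a local-regional, curatively treated, screen-detected cancer is
cured. Two deliberate design choices:

* **Cure requires curative treatment of localized disease.** The benefit of
  early detection operates through treatment actually delivered; a cancer
  parked on surveillance because its biopsy under-graded it receives no cure
  chance. This is the mechanism that lets better grade classification (MRIGB)
  buy life-years despite a slightly lower raw HGC detection product, and it is
  what makes the misclassification rates consequential at all.
* **No cure ⇒ the twin's clock.** The uncured screen-detected man's death age
  is the unscreened twin's, unchanged — the standard guard against lead-time
  bias.

Overdiagnosed detections (twin never clinically diagnosed) can never die of
prostate cancer, cured or not; they still incur diagnosis, treatment, and
quality-of-life harms.

## Accounting

Three cost categories add exactly to the total: screening (PSA tests, mpMRI,
biopsies including PPV-imputed negatives), diagnosis & treatment (work-up,
primary treatment, annual follow-up for up to 10 years while alive), and
palliative/terminal care (charged once per prostate-cancer death). Utility
losses follow the product rule — men × (1 − utility) × duration — per
transient state (screening visit, biopsy, diagnosis, treatment, post-
treatment, palliative, terminal), with the MRIGB biopsy loss pinned to half
the TRUSGB loss unless overridden.

Costs and effects are discounted continuously at 3.5%/y at exact event ages,
referenced to the first invitation age (55). Accounting is restricted to the
invited cohort (alive, not yet clinically diagnosed at 55): all other men
have identical outcomes in every arm and cancel from any comparison, and the
restriction guarantees no event precedes the reference. Discounted life-years
count years lived from the reference on; undiscounted life-years keep the
full lifespan (only differences are ever reported). Net outcomes are
(strategy − no screening) scaled per 1000 invited men.

## Probabilistic and one-way sensitivity analysis

Per replicate, the four pathway-specific sensitivities are drawn from normals
truncated to [0,1] (means 0.94/0.74/0.91/0.44, SDs 0.06/0.06/0.05/0.05) via
inverse-CDF truncation (exact, no rejection bias), and the three imaging/
biopsy unit costs from classic Beta-PERT (λ = 4) on (min, mode, max) =
mode ± 15%. Everything else stays fixed. The headline ICER is the ratio of
means (mean Δcost / mean ΔQALY across replicates); the mean of per-replicate
ratios is exposed as a diagnostic only. iNMB = WTP·mean ΔQALY − mean Δcost at
WTP €20,000; the CEAC reports, per WTP, the fraction of replicates with
positive net benefit; CE-plane quadrant fractions use the convention that a
zero Δ counts as non-positive. Confidence intervals are t-based
(mean ± t₀.₉₇₅,ₙ₋₁·sd/√n).

One-way sweeps rerun the deterministic comparison at a parameter's two bounds
with the cohort seed fixed, so a parameter without differential effect leaves
the ICER exactly unchanged.

## Synthetic defaults and calibration

The packaged parameter set is entirely synthetic: the original model family's
calibration data are not public. Defaults were chosen once to be clinically
plausible and to land inside coarse bands rather than to match any published
money value: lifetime clinical incidence without screening 0.09–0.12 (shipped
defaults simulate ≈0.114), mean lead time 5–10 y (≈6), MRI-pathway biopsy
reduction 25–35% (≈30% after PPV calibration), cumulative screen detection
20–120 per 1000 invited (≈23 MRI / 37 classical — the MRI arm deliberately
forgoes low-grade detections). The biopsy PPVs (0.45 classical, 0.40 MRI) are
the frozen output of a reproducible grid search (`calibrate` subcommand) that
places the biopsy reduction at the band center; the MRI PPV may sit below the
classical one because mpMRI enrichment and MRIGB's low LGC sensitivity pull
in opposite directions. Unit costs printed nowhere (work-up €1200, RP €9000,
RT €8500, surveillance €1500, follow-up €350/y, palliative €26,000) and the
utility table are labeled placeholders in the config with ordinary
literature-style magnitudes; no test or reported result depends on their
specific values, only on printed test characteristics and structural
identities.

### What the generator does and does not emulate

It emulates: a realistic male life table; a latent progression process with
stage/grade/spread structure; screening cascades with imperfect, grade-
dependent tests; overdiagnosis and lead time by construction; cost and QALY
accounting with discounting. It does not emulate: PSA level growth and
threshold behavior, between-round attendance correlation (beyond the
all-or-none switch), repeat/confirmatory biopsies or active-surveillance
biopsy schedules, treatment drift over calendar time, biopsy complications,
or indirect costs. Passing tests therefore demonstrate internal correctness
and plausible structure, not predictive validity for any real population.

## Numerical choices

* Named `SeedSequence` substreams (other-cause mortality, disease course,
  screening, survival) from one master seed; every output is reproducible
  from (config digest, seed), and derived seeds stay below 2³¹.
* Onset sampling inverts the piecewise-constant cumulative hazard exactly;
  the walk caps at 6 trajectory entries (provably sufficient).
* Degenerate inputs: zero-rate events never fire (time = ∞); a state with all
  rates zero is latent forever; a zero cure probability consumes no
  randomness (keeps twin streams aligned); an empty cohort tallies to zeros.
* Percent columns are rounded only at presentation; CSV outputs keep full
  precision.

## Problem sizes

The analysis drivers use 500,000 men for the single-run table and 100
replicates × 200,000 men for the probabilistic analysis; the test suite uses
10,000–200,000 men depending on what a check needs to resolve. These sizes
keep per-1000 quantities stable to a few percent; the CRN design means
incremental comparisons are far more precise than either arm alone.

## Known limitations

Beyond the emulation gaps above: cure is binary (no partial stage-shift
benefit); post-treatment and palliative utility losses are charged as fixed
packets at event ages rather than truncated at death; treatment choice does
not depend on mpMRI findings; and the synthetic calibration makes absolute
money/QALY levels illustrative — directional and structural results are the
meaningful outputs.
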