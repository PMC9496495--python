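# Methods

This note records the scoring model, the statistical estimators, the
synthetic-data generator and the numerical/design choices behind
`epochsleep`, at the level of detail a re-implementer would need.

## Epoch data model

An epoch stream is one subject-device sequence of fixed-length records
(default 60 s) carrying a timestamp, binary lying-down and sleep
indicators, and an optional binary wear indicator. Timestamps are
treated as naive wall-clock times: no timezone or daylight-saving logic
is applied, because exported epoch files carry none. A duplicated
timestamp is a hard input error; a skipped span is simply a gap. Gaps
and records with `wearing = 0` are *nonwear*: they score as upright
wake, and a `sleeping = 1 ∧ wearing = 0` record is flagged on read
since it cannot be interpreted.

Analysis days are anchored at noon (slot 0 = 12:00, slot 1439 = 11:59
the next calendar day) so an entire night lies inside one analysis day.
All clock arithmetic — means, SDs, midpoints — happens on this
minutes-since-noon axis, where overnight times are monotone integers;
this avoids the circular-mean pitfalls of averaging times near
midnight. A noon day is labelled weekend when its anchor (noon start)
date is a Saturday or Sunday: the night the day covers begins on the
anchor date. Validity: a day needs ≥ 1361 wear minutes (95% of 1440;
boundary inclusive), a week ≥ 2 valid weekdays and ≥ 1 valid weekend
day. Partial first/last days of a wear period are not special-cased;
the wear rule excludes them naturally. Two-device alignment intersects
timestamps worn on both devices and keeps only days valid on both.

## Nightly scoring

Within the night window (defaults 19:00 → 11:59 next day):

1. Candidate onset = first epoch with lying ∧ sleeping.
2. Scanning forward before midnight, every wake bout whose length
   (measured to the next sleep epoch, even across midnight) reaches
   `wake_reset_minutes` (default 10) moves the onset to that next sleep
   epoch. The rule applies iteratively to every qualifying bout, not
   only the first, and fires only for bouts *starting* before midnight.
   Nights where it fires are flagged `onset_reset` for audit.
3. If the subject is not asleep at 24:00, onset is the first sleep
   epoch after midnight (flag `onset_after_midnight`). This branch also
   resolves the rare night with sleep-while-not-lying epochs only: if
   no lying ∧ sleeping epoch exists and the subject is awake at
   midnight, the first post-midnight sleep epoch still starts the
   window; if there is no such epoch the night is unscored.
4. Offset = one past the last sleep epoch that is followed, before any
   further sleep, by ≥ `upright_terminate_minutes` (default 90)
   *consecutive* not-lying epochs. "Consecutive" is the deliberate,
   stricter reading of upright time; cumulative upright would terminate
   windows on restless nights. The upright lookahead never crosses the
   end of the analysis day — a window still open at 11:59 is truncated
   there and flagged `truncated_at_night_end`.

Bedtime extends onset backward through its contiguous lying run
(bedtime = onset when the onset epoch is not lying, giving SOL = 0);
waketime extends the last sleep epoch's lying run forward. The backward
scan may cross the night-window start (someone in bed from 18:30 keeps
that bedtime).

All intervals are half-open, so the identities
`TST + WASO = offset − onset`, `SOL = onset − bedtime` and
`TIB = waketime − bedtime` are exact integer arithmetic. SF counts
maximal wake runs inside the window with no minimum bout length: a
single wake minute is one fragmentation. The midpoint is
`onset + (offset − onset)/2`, kept to 0.5-min precision. Nonwear
epochs inside the bed window score as wake and flag the night
(`nonwear_in_tib`).

A note on monotonicity: within a *fixed* window, flipping a wake epoch
to sleep always raises TST and lowers WASO. Under full re-scoring the
same flip can split a ≥ 10-min evening wake bout, undo an onset reset,
and enlarge the window — so whole-night WASO may legitimately increase.
The property tests therefore pin the fixed-window form.

Epoch lengths other than 60 s are supported; every minute-valued
threshold must convert to a whole number of epochs, otherwise
configuration fails loudly.

## Weekly summaries

Per subject-device, weekly summaries are the arithmetic mean and sample
SD (n−1 denominator) of each nightly index across valid nights,
computed only when the week rule passes, with clock variables averaged
in minutes-since-noon. Sleep regularity is the sample SD of waketime in
minutes, over the same weekly-valid subset of nights used for the other
summaries (≥ 2 nights required; it is undefined for one).

## Agreement statistics

**TOST equivalence.** For paired differences d (device A − device B of
per-subject weekly means) and margin δ, the paired-t TOST tests
H0: μ ≤ −δ and H0: μ ≥ +δ one-sidedly; p = max of the two, equivalence
declared at p < α (default 0.05). The Wilcoxon TOST applies one-sided
signed-rank tests to d + δ and d − δ. With ≤ 10 non-zero values the
null distribution is enumerated exactly over all 2^n sign assignments
(midranks for ties, zeros dropped), above that the normal approximation
with continuity correction is used. Zero-variance differences take a
degenerate branch: p = 0 if |d| < δ else 1. Default margins: 30 min
for bedtime, onset, offset, waketime, midpoint, TIB and TST; 10 min for
SOL, WASO and regularity; 5 events for SF; 3% for SE. The report
carries both test variants for every variable plus a default choice —
Wilcoxon when a Shapiro–Wilk test rejects normality of the differences
at 0.05 — since no principled per-variable rule exists.

**Repeated-measures Bland–Altman.** With several person-days per
subject the differences are correlated within subject, so the SD
entering the limits of agreement combines the between-subject variance
component and the within-subject mean square from a one-way ANOVA of d
on subject (method of moments; the unbalanced-design divisor
n0 = (N − Σmᵢ²/N)/(k−1); a negative between component is clamped to 0).
LoA = bias ± 1.96·sd_total describe a single future difference.
Proportional bias is the slope of d on the pair mean, estimated by
working-independence estimating equations with a cluster-by-subject
sandwich variance; because ~30 clusters make the plain sandwich biased
low, the slope CI uses the Mancl–DeRouen bias-reduced covariance with a
t critical value on G−1 degrees of freedom — the standard small-sample
treatment, restoring ~95% coverage in simulation. A single subject is
an error (the between component is inestimable); degenerate inputs
(constant d or constant means) return slope 0.

**Intraclass correlations.** From the two-way ANOVA mean squares of the
n-subjects × 2-raters table (complete cases): ICC(2,1) =
(MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n) for absolute agreement, ICC(3,1)
= (MSR−MSE)/(MSR+(k−1)MSE) for consistency. Zero subject variance is
reported as ICC 0 with a degeneracy flag. Note the two coincide exactly
when MSC = MSE; with merely equal rater means (MSC = 0) they differ by
the O(1/n) rater term in the ICC(2,1) denominator. In the two-device
pipeline, ICCs and Bland–Altman run on matched person-days; TOST runs
on weekly summaries.

**Epoch confusion.** Restricted to nighttime minutes (19:00–11:59),
with a required reference-device designation: sensitivity = share of
reference sleep minutes the test device scores as sleep, specificity
the analogue for wake, LR+ = sens/(1−spec), LR− = (1−sens)/spec, always
from unrounded pooled values. Per-subject means carry a t-based 95% CI;
a subject with no reference wake (or sleep) minutes is excluded from
the corresponding mean with a warning.

## Synthetic study generator

The generator emulates a free-living two-device validation cohort:
defaults are 30 subjects × 7 consecutive noon days starting on a Monday
(so a full week contributes 5 weekdays + 2 weekend days), bedtime
22:44 ± 60 min and waketime 06:46 ± 62 min (typical self-reported
values in middle-aged adults), geometric sleep-onset latency with mean
14 min, Poisson(10) nocturnal awakenings of geometric length (mean
5 min, so WASO ≈ 50 min and SF ≈ 10), a geometric lying-awake tail
(mean 5 min) before rising, and a 30-min daytime nonwear block. Draws
are resampled (≤ 100 attempts) until bedtime falls after 19:00,
waketime before 11:59, sleep offset after midnight and the sleep window
spans ≥ 120 min.

The truth table records exactly the indices implied by the generated
epochs, and the generator enforces the constraints that make its own
bookkeeping coincide with the scorer on noiseless data: the first and
last sleep minutes stay asleep, wake bouts starting before midnight are
capped at 9 min (below the onset-reset threshold) and the midnight
minute is kept asleep whenever onset precedes midnight. Scoring a
noiseless stream therefore reproduces the truth table with *zero*
tolerance — the self-consistency oracle the tests pin.

Device error is independent Bernoulli epoch misclassification: a true
sleep epoch is observed as sleep with probability `sleep_detect_prob`
(default 0.94) and a true wake epoch as wake with `wake_detect_prob`
(default 0.88) — values typical of wearable sensitivity/specificity —
plus optional uniform integer jitter on lying-run boundaries and an
optional constant shift of each night's sleep end for injecting
systematic offset/waketime bias. Independence makes the confusion
metrics analytically known (pooled sensitivity/specificity converge to
the set probabilities), which is what the error-recovery tests exploit.

What the generator does *not* emulate: serially correlated
misclassification (real devices err in runs; a Markov overlay was
considered and left out of the default), naps and daytime sleep (the
scorer cannot detect them, and excluding them keeps truth recovery
exact), circadian drift, and sleep architecture. One consequence worth
knowing: i.i.d. false-sleep minutes sprinkled through the upright
morning recur more often than every 90 min, so on noisy simulated
devices the termination rule rarely fires before the night end and
scored offsets/WASO inflate relative to real devices. Passing tests on
simulated data therefore demonstrate pipeline correctness, not
field accuracy of any device.

## Problem sizes and determinism

Everything is seeded through `numpy.random.default_rng`; identical
seeds give byte-identical simulated bundles. The test suite uses
10,000 random nights for scorer-oracle equivalence, a 30 × 7 cohort for
truth recovery and error-rate recovery (≥ 100,000 nighttime epochs),
500 random cases for exact signed-rank enumeration, 200 replicates for
TOST power/size and 500 replicates of 30 × 7 differences for
limits-of-agreement coverage; the acceptance script simulates one
30 × 7 study per run. These sizes give Monte-Carlo error comfortably
below the asserted tolerances while keeping a full run to a few
minutes.

## Known limitations

- Naps and daytime sleep are out of scope by construction (the night
  window is fixed); shift workers' sleep is not scored meaningfully.
- The onset-reset rule resolves an ambiguity in its prose description
  in favour of "the next sleep minute after the extended wake bout";
  affected nights are flagged so users can audit them.
- Nonwear inside the bed window is scored as wake, biasing WASO upward
  on flagged nights; there is no imputation.
- The per-variable choice between t-TOST and Wilcoxon-TOST in published
  reports rarely states a rule; the default here (Shapiro–Wilk at 0.05)
  is a convention, and both p-values are always reported.
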