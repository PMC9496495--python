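# epochsleep

Sleep quantity, timing and quality indices from minute-epoch wearable
data, plus the statistical battery used to validate one wearable device
against another.

Many armband and consumer wearables export minute-by-minute epochs with
a posture (lying-down) indicator and a binary sleep/wake classification,
but no sleep timing or quality summaries. `epochsleep` scores such
streams into the standard nightly indices used in actigraphy research,
aggregates them into per-subject weekly summaries, and compares two
devices worn simultaneously with paired equivalence tests,
repeated-measures Bland–Altman limits of agreement, intraclass
correlations and epoch-level sensitivity/specificity. It is aimed at
sleep and physical-activity researchers validating a device, or
re-analysing archived 24-h epoch datasets.

## The scoring algorithm

Analysis days run noon-to-noon (12:00–11:59) so a night is never split
across days; a day is valid with ≥ 1361 min of wear (95%), and a week
with ≥ 2 valid weekdays and ≥ 1 valid weekend day. Within a night
window (default 19:00–11:59 the next day) the scorer finds, per night:

1. **Sleep onset** — the first epoch classified lying *and* asleep.
   Any wake bout ≥ 10 min before midnight pushes the onset to the next
   sleep epoch (evening dozing does not start the night), and a subject
   awake at midnight gets the first sleep epoch after midnight.
2. **Sleep offset** — one past the last sleep epoch that is followed by
   ≥ 90 consecutive minutes of upright (not lying) time, or the end of
   the night window.
3. **Bedtime / waketime** — the lying runs containing onset and offset,
   extended backwards and forwards.

From the half-open windows `[onset, offset)` and `[bedtime, waketime)`:

| index | definition |
|---|---|
| TIB | waketime − bedtime (min) |
| TST | sleep minutes in `[onset, offset)` |
| SE | 100 · TST / (offset − onset) (%) |
| SOL | onset − bedtime (min) |
| WASO | wake minutes in `[onset, offset)` |
| SF | number of distinct wake bouts in `[onset, offset)` |
| midpoint | onset + (offset − onset)/2 |
| regularity | per-subject SD of waketime across nights (min) |

The agreement battery: two one-sided paired *t* or Wilcoxon signed-rank
tests (exact sign-flip enumeration at small n) against a-priori margins
(30 min for timing variables/TIB/TST, 10 min for SOL/WASO/regularity,
5 events for SF, 3% for SE); Bland–Altman bias and limits of agreement
with between/within-subject variance components from one-way ANOVA;
proportional bias via a working-independence GEE slope with
cluster-robust (bias-reduced) confidence intervals; Shrout–Fleiss
ICC(2,1)/ICC(3,1); and nighttime epoch sensitivity, specificity and
likelihood ratios against a designated reference device.

A built-in simulator generates ground-truth sleep processes for a
cohort and overlays per-device Bernoulli epoch misclassification, so
the whole pipeline is testable with no data download.

## Worked example

```python
import epochsleep as es
from epochsleep.timeutil import slot_to_clock

# a 4-subject, 7-night cohort; score the noiseless streams
streams, truth = es.simulate_truth(es.TruthParams(n_subjects=4, n_days=7, seed=11))
nightly = es.score_streams(streams)
weekly = es.weekly_table(nightly)
```

`nightly` holds one row per scored night (clock fields are minutes
since the anchoring noon; `slot_to_clock` renders them):

```
subject_id anchor_date bedtime sleep_onset sleep_offset waketime  tib  tst   se  sol  waso  sf
       S01  2024-01-01   22:46       23:02        08:10    08:10  564  533 97.3   16    15   4
       S01  2024-01-02   23:12       23:51        07:21    07:37  505  411 91.3   39    39   7
       S01  2024-01-03   23:27       23:44        06:26    06:27  420  359 89.3   17    43  13
```

Subject S01 went to bed at 22:46 on the first night, fell asleep 16 min
later (SOL), slept 533 of the 548 min between onset and offset
(SE 97.3%, WASO 15 min across 4 awakenings) and rose at 08:10. The
weekly table gives per-subject means ± SD and the regularity index:

```
subject_id  n_valid_days  tst_mean  tst_sd  se_mean  regularity
       S01             7     393.9    78.8     92.7        58.0
       S02             7     431.3    58.5     88.6        36.3
```

Comparing two simulated devices end-to-end:

```python
bundle = es.simulate_study(es.TruthParams(seed=1), es.DeviceModel(), es.DeviceModel())
nightly_a = es.score_streams(bundle["device_a"])
nightly_b = es.score_streams(bundle["device_b"])
paired = es.build_paired_epochs(bundle["device_a"], bundle["device_b"])
report = es.compare_devices(nightly_a, nightly_b, paired, reference="a")
report["equivalence"]   # TOST table across weekly variables
report["icc"]           # ICC(2,1) / ICC(3,1) per variable
report["confusion"]     # epoch sensitivity/specificity vs device A
```

The same pipeline is exposed on the command line:

```bash
epochsleep simulate --out study --seed 7
epochsleep score study/deviceA.csv --out scored_a
epochsleep compare study/deviceA.csv study/deviceB.csv --out report --reference a
```

Every run writes `run_config.json` (effective configuration + package
version) next to its outputs.

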