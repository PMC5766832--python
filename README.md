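# whisklearn

Analysis pipeline for head-fixed whisker-detection learning
experiments: signal-detection behavior, multi-area sensory-evoked
potentials, time-resolved ROC stimulus decoding, spike-train
modulation testing, inactivation statistics, and a synthetic cohort
generator that emulates the task's trial structure and neural signal
statistics.

It is written for systems neuroscientists analyzing go/no-go detection
tasks with simultaneous multi-site LFP and single-unit recordings —
either on their own session bundles (HDF5 containers with a trial
table, continuous LFP, and sorted spike trains) or on fully synthetic
cohorts for method validation and power analysis.

## The analyses

**Behavior.** Sessions are scored by hit rate (licks within the 1 s
response window on stimulus trials), false-alarm rate (catch trials),
and sensitivity

```
d' = Z(hit rate) − Z(FA rate)
```

with Z the standard-normal quantile and the loglinear correction
(n+0.5)/(N+1) applied throughout so d' is finite at extreme rates.
Trained-condition sessions are the first three days with day > 4 and
d' > 1.

**Sensory-evoked potentials.** Continuous LFP is artifact-blanked,
band-passed 0.1–100 Hz (zero phase), epoched around trial onsets, and
baseline-corrected over the 50 ms before onset. First peaks (earliest
supra-noise local extremum of each area's polarity), onset latencies,
and fixed-time condition contrasts (first day vs trained, hit vs miss;
paired Wilcoxon per 5 ms window) quantify how evoked responses change
with learning; the peak amplitude is correlated with d' across days
(Pearson r with t-based p).

**ROC decoding.** The Stimulus Probability SP(t) is the ROC area
between stimulus- and catch-trial distributions of mean LFP amplitude
in 10 ms windows slid by 2.5 ms (ties ½, equal to Mann-Whitney
U/(n₁n₂)), with chance bands from 100 label shuffles.

**Spikes.** Units are split into regular- and fast-spiking by
waveform trough-to-peak duration; stimulus modulation is tested by
bootstrapping (1000×) the per-trial difference of post- vs pre-onset
(1 s) firing rates; hit-vs-miss differences use a permutation test.

**Inactivation.** Optogenetic sessions compare light-on vs light-off
hit/FA rates (paired signed-rank); muscimol sessions are scored in a
5 min block 30 min post injection against pooled Ringer's controls
(Mann-Whitney, Holm-corrected).

The nonparametric statistics (inverse-normal CDF, signed-rank,
rank-sum with exact small-sample nulls, Holm, and the joint-ranking
all-pairs group comparison) are implemented in `whisklearn.stats` and
cross-checked against independent oracles in the test suite. See
`docs/methods.md` for every convention, default, and known limitation.

## Worked example

```python
import whisklearn as wl
from whisklearn import experiments

scenario = wl.detection_scenario(n_mice=6, n_days=8,
                                 trials_per_session=200, seed=7)
res = experiments.analyze_learning_cohort(
    scenario, areas=["wS1", "mPFC"], lfp_days="all")

perf = res.perf_table
print(perf.groupby("day").dprime.mean().round(2).to_dict())
for area in ("wS1", "mPFC"):
    r, p, n = res.peak_dprime_correlation(area)
    print(f"{area}: peak-amplitude vs d' r={r:.2f}, p={p:.1e} (n={n})")
```

prints

```
{1: 0.2, 2: 0.51, 3: 0.66, 4: 1.11, 5: 1.32, 6: 1.51, 7: 1.81, 8: 1.96}
wS1: peak-amplitude vs d' r=0.18, p=2.3e-01 (n=48)
mPFC: peak-amplitude vs d' r=0.98, p=4.6e-35 (n=48)
```

— the cohort learns over ~5 days (d' rising from ≈0.2 to ≈2.0), the
primary somatosensory evoked response is unrelated to performance,
and the prefrontal evoked amplitude tracks d' across training days,
the learning-coupled signature the pipeline is built to detect.

The same stages are scriptable from the shell:

```bash
whisklearn simulate --paradigm detection --n-mice 2 --n-days 3 \
    --trials 30 --seed 1 --out runs/demo/sessions
whisklearn behavior --sessions runs/demo/sessions --out runs/demo/behavior
whisklearn report --results-dir runs/demo --out runs/demo/report.md
```

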