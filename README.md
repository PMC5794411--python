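# etamu

Weighted z-score deficit indices for separating **visuoperceptive (VP)** from
**visuomotor-coordination (VMC)** impairment in children's psychometric test
profiles — the Eta-Mu model — with cohort summaries, pre/post-treatment
comparison, and a seeded synthetic-subject simulator for validation.

## The problem and who this is for

Children with (suspected) learning disabilities are assessed with batteries
of standardized tests, each reported as an age-normed z-score (negative =
below norm). Most of these tests recruit *both* the visuoperceptive and the
visuomotor-coordination domain, so a low composite score says that something
is wrong but not *where*. Rehabilitation, however, should target the
defective domain. This package is for clinicians and researchers who have a
profile of z-scores per child and want a quantitative, reproducible split of
the impairment into its VP and VMC share.

## The model

Each test *n* in the battery carries judged recruitment weights
VP\_n + VMC\_n = 100 (percent). Over the *n* administered tests:

```
η  = −Σ (VP_n  · z_n) / n          (VP impairment index)
μ  = −Σ (VMC_n · z_n) / n          (VMC impairment index)

η_exp = mean(VP)  · |avg z|        (baseline: equally impaired subject)
μ_exp = mean(VMC) · |avg z|

Δη = η − η_exp ,  Δμ = μ − μ_exp
```

Both indices are 0 for a normal profile and grow with impairment. A subject
equally impaired in both domains (identical z on every test) lands exactly on
the baselines, so the excesses localise the deficit: **Δη > 0** marks a
prevalent VP defect, **Δμ > 0** a prevalent VMC defect, and both near zero
(within a configurable tolerance, default 2.0) points at the VP/VMC
*integration* level. Because per-test weights sum to 100, Δη = −Δμ whenever
the average z ≤ 0. Incomplete sessions (a refused test is common) are scored
over the administered subset, with the baseline weights re-averaged over that
subset.

The default battery is a 10-test diagnostic set (Corsi MLVS visual /
simultaneous / sequential spatial memory, BHK handwriting quality and
velocity, TCM cancellation velocity and accuracy, ROCF copy and memory, DEM
ratio score) with mean recruitment 76% VP / 24% VMC; any battery whose
per-test weights sum to 100 can be supplied as a JSON config.

## Worked example

The package ships its reference profiles; the classic explanatory profile
scores as:

```python
import etamu

battery = etamu.default_battery()
session = etamu.load_example_session()          # 10 z-scores, avg −1.65
result = etamu.score_session(session, battery)
print(etamu.results_frame([result]).to_string(index=False))
```

```
subject_id session  n_tests  avg_z   eta   mu  eta_exp  mu_exp  delta_eta  delta_mu  mean_vp  mean_vmc classification
   example    demo       10  -1.65 140.5 24.5    125.4    39.6       15.1     -15.1     76.0      24.0   VP_PREVALENT
```

Read: the profile averages 1.65 SD below norms. Were VP and VMC equally
affected, the indices would be η = 125.4 and μ = 39.6; the observed η = 140.5
exceeds its baseline by Δη = 15.1, so the impairment is prevalently
visuoperceptive.

The same from the shell, for a whole cohort:

```bash
etamu cohort path/to/subject_table.csv --out scores.csv
```

On the shipped four-child pre-treatment cohort this prints
`n=4 median avg_z=-1.04 hinges=[-1.46, -0.89]` and writes one scored row per
session, e.g. `subject3,pre,7,-1.16,82.7,33.44,76.32,39.82,6.38,-6.38,...,VP_PREVALENT`
— note the 7-test session automatically reweighted (mean VP 65.71).

Other subcommands: `etamu score` (per-session results), `etamu compare`
(pre/post improvement and paired signed-rank test), `etamu simulate`
(synthetic cohorts with known VP/VMC severities, Gaussian noise and missing
tests), `etamu report` (full JSON + markdown report). All honor
`--battery`, `--tolerance`, `--seed`, `--out`, `--strict`, `--log-level`.

Input is a tidy CSV with header `subject_id,session,test_name,z_score`
(decimal commas are accepted and normalized; a wide per-subject layout is
supported via `etamu.read_wide_table`).

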