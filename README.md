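# cptspect

Simulation and temporal/spectral analysis of continuous-performance-task
(CPT) reaction-time data: an end-to-end pipeline for studying sustained
attention through the time-on-task drift of RT variability and through
infraslow (0.01–0.10 Hz) oscillations of the RT series.

The pipeline has five stages, each usable on its own:

1. **simulate** — generate sessions of an A→K letter CPT (480 trials,
   85 ms stimulus + 900 ms ISI, 100 targets balanced 25-per-120-trial
   block) with group-structured RT processes: baseline mean/SD, linear
   time-on-task trend, a sinusoidal infraslow component, a block-linear
   drift in noise SD (a coefficient-of-variation trend), exponential tail,
   and miss/commission processes.
2. **preprocess** — classify responses into hits / misses / commissions /
   correct rejections under an extended 1135 ms response window (one SOA
   plus 150 ms into the next trial, so late lapses are still credited to
   the eliciting target) and drop sessions below 60% target accuracy.
3. **vigilance** — coefficient of variation (SD/mean) of hit RTs in 8
   blocks of 60 trials, modeled as
   `cov ~ group * block_centered + age + sex` with per-participant random
   intercepts and slopes; Satterthwaite-approximated F-tests, per-group
   simple slopes, Tukey-adjusted pairwise contrasts, marginal/conditional
   R².
4. **spectrum** — per participant, linearly detrend the hit-RT series and
   compute the classical normalized Lomb-Scargle periodogram on a
   1/T … n/(2T) frequency grid (uneven sampling is intrinsic here: RTs
   exist only where targets were answered).
5. **fda** — project each periodogram onto a cubic B-spline basis (44
   equally spaced interior knots by default), evaluate all participants on
   a common grid, and locate group differences with covariate-adjusted
   pointwise F-tests (significant bands = contiguous runs above the
   critical F) plus pairwise pointwise t-tests with uncorrected and
   Bonferroni-corrected critical lines.

## Command-line usage

```sh
# full pipeline from a config file (see examples/demo_config.yaml)
cptspect run --config examples/demo_config.yaml --seed 42 --out run_dir

# or stage by stage
cptspect simulate  --config examples/demo_config.yaml --out sim
cptspect preprocess --trials sim/trials.tsv --out pp
cptspect vigilance  --trials sim/trials.tsv --out vig
cptspect spectrum   --trials sim/trials.tsv --out sp
cptspect fda --periodograms sp/periodograms.tsv \
             --covariates sim/covariates.tsv --out fda
```

All interchange is tab-separated text; `run` additionally writes
`manifest.json` with the config snapshot, seed, per-stage row counts, and
a SHA-256 checksum per artifact (identical config + seed ⇒ byte-identical
outputs). External trial logs in the same schema (`participant_id, group,
age, sex, trial_index, onset_time_s, stimulus, is_target, rt_ms`) can be
fed to any stage or to `run` via `input_trials`.

## Library use

```python
from cptspect import (
    TaskSpec, GroupSpec, generate_cohort,
    classify_cohort, apply_accuracy_filter,
    build_cov_table, fit_vigilance_model,
    lomb_scargle, series_from_session,
    smooth_spectrum, pointwise_group_ftest,
)
```

See the module docstrings in `src/cptspect/` for the formulas and
conventions (sample SD with n−1; Lomb-normalized power with white-noise
expectation ≈ 1; treatment coding against a configurable reference group).
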