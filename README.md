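# sitefidelity

Does personality predict how specialized a seabird's foraging is? Bolder
individuals of central-place foragers such as black-legged kittiwakes may
rely on routine — returning to the same foraging sites and making
similar-length trips — while shyer birds track the environment more
flexibly. `sitefidelity` is a tested Python pipeline for that question:
from raw GPS fixes and novel-object tests to per-bird boldness scores,
decoded foraging sites, a randomization-based site-fidelity index, and
bold-vs-shy comparisons of trip repeatability, exercised end-to-end on
synthetic data with known ground truth.

## What it computes

* **Trips** — fixes farther than 300 m from the colony, in runs longer than
  1 h, linearly interpolated to the stage's fix interval; distance, duration
  and maximum range (with the 75%-return rule for truncated recordings).
* **Behavioural states** — a 3-state hidden Markov model on step lengths
  (gamma) and turning angles (von Mises), fitted by direct maximisation of
  the forward-algorithm likelihood and decoded with Viterbi; consecutive
  foraging fixes aggregate into foraging sites.
* **Boldness** — covariance PCA of the five novel-object behaviour
  proportions; PC1 is the bold–shy axis. Adjusted repeatability
  R = σ²_bird / (σ²_bird + σ²_res) from a random-intercept mixed model with
  parametric-bootstrap CIs; one boldness estimate per bird from a linear
  model; median split into bold and shy.
* **Site fidelity** — each focal site is randomly paired with a same-bird
  site from another trip and one site per other colony member; the index is
  the proportion of neighbours farther than the bird's own paired site
  (1 = nobody forages closer than the bird itself does on repeat visits).
  1,000 randomization iterations, a binomial GLM per iteration, and a looped
  linear model of fidelity on boldness, sex, colony and date.
* **Repeatability comparison** — R of log10 trip metrics per bold/shy group
  with 84% bootstrap CIs; non-overlapping 84% intervals ≈ z test at 0.05.
  Linear mixed models of site latitude/longitude test for spatial
  partitioning by boldness.

See `docs/methods.md` for the model details and conventions.

## Worked example

The analysis is a sequence of numbered drivers over the library, sharing
`analysis/config.yaml` (seed 1; four colonies × 12 birds × 3 incubation
trips):

```
cd analysis
python 01_simulate_dataset.py
python 02_process_tracks.py
python 03_decode_behaviour.py
python 04_score_boldness.py
python 05_estimate_site_fidelity.py
python 06_compare_repeatability.py
python 07_compile_report.py
```

Output from that run:

```
simulated 48 birds at 4 colonies: 8,862 GPS fixes, 78 novel-object tests
segmented 144 trips; 0 excursions dropped (below minimum duration)
  incubation: 144 trips, mean duration 9.3 h, mean max range 37.5 km
incubation: loglik -70827.6, state step means (m/fix)
  {'travelling': 2994, 'resting': 61, 'foraging': 304}
foraging sites: 223; trips kept 144, dropped for no area-restricted search 0
PC1 explains 96.3% of test variance
adjusted repeatability R = 0.583 (95% CI 0.292-0.784, p = 0.00036)
median split: 24 bold, 24 shy
incubation: 48 birds, median fidelity 0.673 (range 0.059-0.991)
  boldness effect 0.263 +/- 0.351 (iteration range 0.040-0.482); F_1,41 = 0.68, p = 0.416
incubation  distance bold: R = 0.535 (84% CI 0.312-0.664)
...
trip bookkeeping reconciles: {'excursions_below_min_duration': 0,
  'trips_segmented': 144, 'dropped_no_ars': 0, 'trips_kept': 144}
```

Reading it: the fitted state step means (2994 / 304 / 61 m per 10-min fix)
recover the generating values (3000 / 300 / 60); boldness repeatability
0.583 (CI 0.29–0.78) brackets the generating 0.678; median fidelity 0.67
reflects the baseline fidelity level 0.6; and at this sample size the weak
planted boldness→fidelity slope is, correctly, not significant (p = 0.42) —
the across-iteration "iteration range" is narrower than the model SE because
it captures randomization noise only. Everything lands under
`results/pipeline/` as CSV/JSON (trips, states, sites, boldness, fidelity
estimates, repeatability table, report.json).

The same stages are available as subcommands of the `sitefid` CLI
(`sitefid all --config analysis/config.yaml --seed 1`).

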