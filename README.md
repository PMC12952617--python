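# circavar

Quantitative machinery for detecting increased inter-individual circadian
behavioral variability in *Drosophila* locomotor and bioluminescence data:

- **dam_io** — read/write TriKinetics DAM2-style monitor files, bin raw
  beam-crossing counts, annotate bins with light regime and
  Zeitgeber/circadian time.
- **entrainment** — Entrainment Index per fly and light transition
  (activity in the 6 h before a transition over the flanking 12 h; a fly
  with day-averaged EI strictly above 0.75 counts as synchronized), with
  an optional startle correction.
- **activity_hmm** — a 2-state negative-binomial hidden Markov model with
  logit-harmonic time-of-day switching probabilities and per-fly random
  intercepts (shared variance, Gauss–Hermite marginal likelihood).
  Emission parameters are fitted on controls only and frozen for other
  genotypes. The endpoint is the model-implied probability of the active
  state over the 24-h cycle (periodically stationary distribution) and
  its between-fly SD at the control-defined morning/evening peaks.
- **phase_circular** — per-fly free-running peak phases (DD days 2–3,
  circular low-pass + argmax), circular summaries (μ, median, R̄,
  circular SD, κ, coherence = 1/circular SD), Watson's goodness-of-fit
  test with parametric-bootstrap p-values, and pairwise
  equal-concentration tests with Bonferroni adjustment.
- **rhythmicity** — autocorrelogram period estimation and rhythmic
  strength (RS = third-peak height over the 2/√N confidence line);
  arrhythmic flies are excluded from phase analysis.
- **luc_wavelet** — 30-min binning, exponential-decay detrending, and
  Morlet (ω₀ = 6) wavelet period ridges in a 16–32 h band for
  bioluminescence traces.
- **stats_estimation** — bootstrap mean-difference estimation statistics.
- **synthetic_data** — seeded generators producing exactly the structure
  the analysis assumes (two-state switching with random intercepts,
  Von Mises phase dispersal, DD period dilation, startle spikes;
  decaying oscillatory luciferase traces; two-group intensity samples).
- **pipeline / cli** — TOML-configured end-to-end LD and DD analyses with
  CSV tables and a JSON run manifest; fully deterministic under seeds.

## CLI

```bash
# full pipeline from a config (simulation scenario or DAM directory)
circavar run --config analysis.toml --out results/ --segment both

# entrainment indexing of one monitor file
circavar ei --dam Monitor1.txt --channels 1-32 --lights-on 8 --lights-off 20

# bioluminescence period estimation (CSV: t_minutes, cps)
circavar wavelet --in sample.csv --bin 30

# bootstrap mean-difference estimation statistics
circavar esdiff --a groupA.csv --b groupB.csv --boot 5000 --seed 11

# materialize a simulation scenario as DAM2 files
circavar simulate --config analysis.toml --out sim/ --seed 5
```

A minimal config:

```toml
[experiment]
control = "ctrl"
lights_on = 8.0
lights_off = 20.0
n_ld_days = 4
n_dd_days = 6
seed = 17

[options]
harmonics = 2
rs_threshold = 1.5

[genotypes.ctrl]
n_flies = 30
mu = [0.5, 12.0]       # NB means (inactive, active) per 30-min bin
phi = [2.0, 5.0]       # NB dispersions; variance = mu + mu^2/phi
beta12 = [-2.5, 1.0, 0.0]  # logit switching coefficients (b0, a1, b1)
beta21 = [-1.5, 0.0, 0.0]
sigma_u = 0.3          # random-intercept SD

[genotypes.mut]
n_flies = 30
mu = [0.5, 12.0]
phi = [2.0, 5.0]
beta12 = [-2.5, 1.0, 0.0]
beta21 = [-1.5, 0.0, 0.0]
sigma_u = 1.5
kappa_phase = 1.0      # Von Mises phase dispersal in DD
```

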