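# suvrkit

Reference-tissue PET quantification toolkit for validating **windowed SUVR**
against **SRTM2-derived DVR**, built around synaptic-density
([¹¹C]UCB-J-like) imaging in Alzheimer disease.

## The scientific problem

Fully quantitative synaptic-density PET reports the **distribution volume
ratio** DVR = V_T(target)/V_T(reference), estimated by fitting the
simplified reference tissue model 2 (SRTM2) to 60 minutes of dynamic data
with a whole-cerebellum reference. Multicenter and longitudinal studies
would rather acquire a short static scan and report the **standardized
uptake value ratio** (SUVR) over a late window. SUVR is only a valid
surrogate if (i) it tracks DVR tightly, (ii) its bias against the identity
line is small, and (iii) group effect sizes (CN vs AD, Cohen *d*) are
preserved. The catch is perfusion: early-scan activity ratios reflect
relative tracer delivery R1 = K1(target)/K1(reference), and perfusion is
itself altered in AD, so early windows confound synaptic density with
blood flow.

`suvrkit` implements the entire validation chain on synthetic cohorts:

* **kinetics** — one-tissue-compartment (1TC) simulation
  C_T(t) = K1·∫C_p(s)·e^(−k2·(t−s))ds with a tri-exponential bolus plasma
  input, exact exponential-sum convolution, frame averaging over the
  27-frame 90-min schedule (6×0.5, 3×1, 2×2, 16×5 min), count-statistics
  noise, and weighted 1TC fitting;
* **srtm** — SRTM and SRTM2 basis-function fitting
  (C_T = R1·C_R + R1·(k2′−k2a)·C_R⊗e^(−k2a·t); DVR = R1·k2′/k2a),
  with reference-efflux (k2′) estimation strategies;
* **suvr** — the nine standard scan windows (30–60 … 70–90 min) and
  duration-weighted SUVR;
* **perfusion** — the K1-perturbation simulation: AD hippocampal K1 rescaled
  0–40 % below the CN mean at constant V_T, tracing %SUVR difference and
  Cohen *d* versus scan time;
* **stats** — pooled-SD Cohen *d*, SUVR-on-DVR regression, identity-line
  bias, and the per-window effect-size table;
* **cohort** — a synthetic two-group cohort generator (CN n=16, AD n=31)
  with per-region density and perfusion reductions;
* **pipeline / cli** — end-to-end orchestration (`suvrkit run-all`).

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (seed 1) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_fit_dvr.py
python analysis/03_compute_suvr.py
python analysis/04_group_stats.py
python analysis/05_perfusion_sim.py
```

`02_fit_dvr.py` reports the quality of kinetic quantification
(`median k2' = 0.0231 /min`, `DVR recovery error … median +0.07%`), and
`04_group_stats.py` prints the two headline comparisons:

```
SUVR-on-DVR pooled regressions (all subjects x regions):
  30-50: slope 0.802, r 0.949, identity deviation -0.045
  30-60: slope 0.819, r 0.959, identity deviation -0.041
  60-90: slope 0.917, r 0.990, identity deviation -0.021
  70-90: slope 0.935, r 0.992, identity deviation -0.017

Effect sizes (mean Cohen d across regions):
  30-60  d = 0.703 ± 0.360  r(d vs d_DVR) = 0.939
  ...
  30-50  d = 0.713 ± 0.371  r(d vs d_DVR) = 0.927
  70-90  d = 0.638 ± 0.292  r(d vs d_DVR) = 0.986
  DVR    d = 0.602 ± 0.260
```

Reading: later windows hug the identity line (deviation −0.017 vs −0.045)
and correlate more strongly with DVR (r 0.992 vs 0.949), while earlier
windows inflate the CN-vs-AD effect size (d 0.713 at 30–50 min vs 0.638 at
70–90 min) because they fold the perfusion deficit into the ratio.
`05_perfusion_sim.py` makes the mechanism explicit:

```
true DVR %difference (constant across scenarios): 5.54%
 K1 diff  R1 diff  %SUVR @12.5  %SUVR @87.5
      0%   -0.40%        0.76%        5.25%
     20%   19.68%       17.25%        6.65%
     40%   39.76%       35.28%       12.00%
```

At 12.5 min the %SUVR group difference sits next to the R1 difference; by
87.5 min it has fallen back toward the true DVR difference — early windows
measure perfusion, late windows measure synaptic density.

The same pipeline is available as a CLI
(`suvrkit run-all --seed 1 --out results/run`), with resumable
subcommands `simulate-cohort`, `fit-dvr`, `compute-suvr`, `perfusion-sim`
and `compare`.

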