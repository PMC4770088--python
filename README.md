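# modflex

Analysis pipeline for how cytosine modifications — 5-methyl- (5-mC),
5-hydroxymethyl- (5-hmC), 5-formyl- (5-fC) and 5-carboxyl-cytosine (5-caC) —
change the mechanics of DNA and nucleosomes.  It is written for structural
biophysicists who work with rigid base-pair descriptions of duplex DNA,
single-molecule cyclization assays and smFRET force spectroscopy, and who
need a tested, reproducible implementation of the standard analyses plus
synthetic-data generators that stand in for MD trajectories and
single-molecule recordings.

## What it computes

* **Rigid base-pair geometry** (`modflex.geometry`): base reference frames by
  least-squares superposition of ring atoms, the six intra-base-pair
  parameters (shear, stretch, stagger, buckle, propeller, opening) and six
  step parameters (shift, slide, rise, tilt, roll, twist) via the mid-frame
  (CEHS/3DNA-style) decomposition, and the exact inverse that rebuilds frame
  chains from parameters.
* **Synthetic ensembles** (`modflex.ensemble`): Gaussian parameter
  fluctuations around B-DNA baselines with modification effects localized at
  CpG steps and decaying over ±3 bp, realized to multi-model PDB coordinates
  and re-extractable end-to-end.
* **Fluctuation statistics** (`modflex.fluctuations`): per-position Gaussian
  summaries with block-averaged standard errors, Δmean/Δsd profiles vs
  distance from the CpG-step centre, windowed summaries and a flexibility
  ranking of the modifications.
* **Cyclization kinetics** (`modflex.looping`): two-state looping
  simulations, exponential fits f_eq·(1 − e^(−t/τ)) of looped fraction vs
  time with bootstrap-calibrated errors on the apparent looping time τ, and
  fold changes between constructs.
* **Loop-closure Monte Carlo** (`modflex.closure`): seeded, vectorized
  closure-propensity estimates for a fluctuating 90-step chain with exact
  binomial CIs — the quantitative link between fluctuation amplitudes and
  looping.
* **smFRET force spectroscopy** (`modflex.smfret`): ratiometric FRET
  efficiencies, Gaussian histogram peak fits, stretching-trace simulation and
  change-point classification into the three nucleosome-unwrapping
  behaviours, trace averaging and class percentages.

Constructs (sequences, CpG scanning, modification placement, cyclization
geometry) live in `modflex.constructs`; a `modflex` CLI exposes the common
operations (`modflex constructs cpg-scan`, `modflex loopkin simulate|fit`,
`modflex loopmc run|compare`, `modflex forcefret simulate|classify|average|hist`,
`modflex fluct profile|rank`).

See `docs/methods.md` for the model conventions, defaults and limitations.

## Worked example

Rank the modifications by their effect on roll fluctuations (synthetic
5,000-frame ensembles of the 70-bp construct, four modified CpG steps), then
compare looping times for a flexible (5-fC-like, τ = 200 s) vs unmodified
(τ = 600 s) construct:

```python
from modflex.constructs import CENTRAL_70BP, ModifiedDuplex
from modflex.ensemble import condition_suite
from modflex.fluctuations import delta_profile, window_average_delta_sd, rank_modifications
from modflex.looping import simulate_looping, fit_looping, fold_change, default_sample_times

duplex = ModifiedDuplex(CENTRAL_70BP)
suite = condition_suite(duplex, ["unmodified", "5mC", "5hmC", "5fC", "5caC"],
                        seed=1, n_frames=5000, parameters=("roll",))
steps = [22, 28, 34, 46]
wa = {}
for cond in ["5mC", "5hmC", "5fC", "5caC"]:
    prof = delta_profile(suite[cond], suite["unmodified"], "roll", steps,
                         block_length_ns=1.0)
    wa[cond] = window_average_delta_sd(prof)
wa["unmodified"] = (0.0, wa["5fC"][1])
print("ranking:", rank_modifications(wa))

times = default_sample_times(3000.0, 25)
fits = {}
for label, tau in (("unmodified", 600.0), ("5fC", 200.0)):
    tc = simulate_looping(500, 0.8 / tau, 0.2 / tau, times, seed=11)
    fits[label] = fit_looping(tc, bootstrap_seed=5)
ratio, se = fold_change(fits["unmodified"], fits["5fC"])
print(f"fold change (unmodified / 5fC): {ratio:.2f} +/- {se:.2f}")
```

Output:

```
ranking: 5-fC>5-caC≳5-hmC>unmodified C>5-mC
fold change (unmodified / 5fC): 3.01 +/- 0.33
```

The window-averaged Δsd values behind the ranking were (degrees of roll,
± propagated SE): 5-fC +0.764 ± 0.022, 5-caC +0.071 ± 0.020, 5-hmC
+0.063 ± 0.020, unmodified 0, 5-mC −0.619 ± 0.019.  5-fC stands clearly
first and 5-mC clearly last; 5-hmC, 5-caC and unmodified are near-tied by
calibration, so their internal order (joined by "≳" when within one
propagated SE) varies between seeds.  The looping fit recovers the
generative threefold flexibility contrast with a calibrated,
bootstrap-derived uncertainty: the 95% CI covers 3.0.

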