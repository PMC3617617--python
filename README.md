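# icpd — intra-crystalline protein decomposition geochronology

`icpd` is a Python toolkit for amino-acid-racemization (AAR) dating of
biominerals whose intra-crystalline protein behaves as a closed system —
massive *Porites* coral skeleton being the motivating material. After death
(or burial within a growing colony), the L-amino acids locked inside the
crystals slowly racemize toward an equilibrium D/L ratio near 1, so the D/L
value of an amino acid such as aspartic acid (Asx) is a chronometer. The
package turns raw per-analysis D/L and concentration tables into dated
samples with quantified uncertainty. It is aimed at geochronologists and
palaeoclimatologists who need rapid, cheap age screening of coral (and
similar biomineral) material against independently dated reference cores.

It provides four stages, usable as a library or through the `icpd` CLI:

1. **Quality screening** (`icpd.screening`) — compromised analyses are
   removed using the covariance structure that closed-system diagenesis
   imposes: FAA-vs-THAA Asx D/L and Asx-vs-Glx D/L follow smooth power
   relations and Asx-vs-Glx THAA concentrations decline together linearly.
   Non-linear relations are tested twice with the axes swapped (a point
   must exceed the standardised-residual cutoff, default 2.5 sd, in *both*
   orientations); the linear concentration test uses orthogonal distance
   regression. A 4-sd screen on analytical-duplicate differences and a
   2-sd screen on total THAA concentration complete the pipeline.
2. **Inter-study corrections** (`icpd.corrections`) — Arrhenius rate
   ratios, scaling of hydrolysis-induced D/L between preparative
   protocols (extent ∝ k(T)·t), time-axis shifts for datasets analysed
   years apart, orthogonal-regression comparison of analytical methods,
   and the seasonal *effective temperature* Teff solving
   k(Teff) = mean over one year of A·exp(−Ea/RT(t)).
3. **Monotone Monte Carlo age model** (`icpd.agemodel`) — the calibration
   curve m(t) is piecewise linear between measurement ages and fitted by
   minimising

       Σᵢ ((m(tᵢ) − dᵢ)/σᵢ)²  +  λ · Σⱼ (log(sⱼ₊₁/sⱼ))²,   sⱼ ≥ 0,

   where sⱼ are segment slopes — an uncertainty-weighted least-squares
   fit constrained to be non-decreasing, with a penalty on relative rate
   changes. A Monte Carlo ensemble (perturb data by σ, refit, jitter
   segment rates lognormally) yields pointwise 68.3/95.4% envelopes and,
   by inverting each ensemble curve, dated ages for samples of unknown
   age. A simpler window estimator dates a sample from the spread of
   independently ascribed ages within a D/L window.
4. **Synthetic data** (`icpd.synth`) — a generator for multi-colony
   datasets with known ground truth (kinetic trajectories, per-colony rate
   multipliers, declining concentrations, %FAA growth, duplicate noise and
   planted outliers), used to validate every stage.

## Worked example

```python
from icpd import SynthConfig, generate_dataset, run_screening, MonotoneAgeModel

ds, truth = generate_dataset(SynthConfig(seed=42))   # 8 colonies, 512 analyses
screened, report = run_screening(ds)
model = MonotoneAgeModel.from_dataset(screened, "SIM01", "Asx", "THAA")
res = model.fit_monte_carlo(n_iter=5000, seed=7)
print(res.summary())
est = res.estimate_age(dl_measured=0.21, dl_sigma=0.005)
print(f"D/L 0.21 -> {est.median_age:.1f} yr, 95% {est.ci95}")
```

prints

```
Monte Carlo monotone age model
========================================
series:        SIM01 Asx THAA
observations:  30   sigma: 0.0039087
iterations:    5000   seed: 7
age grid:      10-460 yr (451 points)
D/L span:      0.07672-0.3605
95% band half-width (D/L):
  at 235 yr: 0.0048286
D/L 0.21 -> median age 119.3 yr, 95% interval 95.0-143.6 yr
```

The screening step kept 483 of 512 analyses (29 excluded, 2 single-value
removals); the per-series analytical sigma (0.0039 D/L) is pooled from the
analytical duplicates; and a THAA Asx D/L of 0.21 measured on a sample of
unknown age dates it to 119 years before collection with a 95% interval of
95–144 years, obtained by inverting all 5000 ensemble curves.

The same workflow from a shell:

```sh
icpd simulate --seed 42 --out sim.csv --cores cores.csv --truth truth.csv
icpd screen   --in sim.csv --cores cores.csv --cutoff 2.5 \
              --out screened.csv --report report.json
icpd agemodel --in screened.csv --cores cores.csv --core SIM01 --aa Asx \
              --fraction THAA --iters 5000 --seed 7 \
              --out envelope.csv --ensemble-out ensemble.csv
icpd date     --method ensemble --ensemble ensemble.csv \
              --dl 0.21 --dl-sigma 0.005 --seed 9
```

Every output file carries a provenance header (version, seed, config
hash); rerunning with the same seed is byte-identical.

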