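# resistmix

Mixture modelling of dynamic chemoresistance from time-resolved drug
dose-response assays.

## The problem

After a transient pulse of a cytotoxic drug (e.g. doxorubicin on MCF-7
breast cancer cells), the drug sensitivity of a surviving cell
population changes over the following weeks. A weekly dose-response
assay measures viability `V` at a panel of doses `d`, but no single
molecular marker identifies which cells are resistant. `resistmix`
infers the composition of the population from the dose-response curves
alone, by fitting grouped viability data to three nested sigmoidal
models and letting model selection decide whether the data demand a
heterogeneous population:

* **single static** — one logistic curve for all weeks
  (no time-dependence; 2 free parameters):
  `V(d) = V_max / (1 + exp(m_ss (d − c_ss)))`
* **single dynamic** — an independent curve per week
  (2 parameters per week): `V(d, t) = V_max / (1 + exp(m(t) (d − c(t))))`
* **two population** — a fixed *sensitive* and a fixed *resistant*
  state whose mixing fraction changes per week
  (4 + 1-per-week parameters):

  `V(d, t) = V_max [ f_s(t) / (1 + exp(m_s (d − c_s))) + (1 − f_s(t)) / (1 + exp(m_r (d − c_r))) ]`

Here `c` is the LD50 (µM), `m` the slope (1/µM, the reciprocal of the
spread of the lethal-dose distribution), `V_max` the baseline viability
at zero dose, and `f_s(t)` the sensitive fraction of the population in
week `t`. Models are compared by AIC; parameter uncertainty comes from
a stratified case bootstrap (500 resampled datasets by default);
fitted fractions combine with weekly cell counts into resistant and
sensitive cell-number trajectories.

Because real assay tables of this design are rarely public, the
package ships a synthetic-assay generator (12-dose doxorubicin panel,
weekly groups or known sensitive/resistant mixtures, dose-dependent
truncated-Gaussian noise) used for validation and identifiability
studies.

## Worked example

Simulate an 8-week course from the two-population model (sensitive
LD50 22.4 µM, resistant LD50 79.7 µM, resistance peaking in weeks 2–3),
then let AIC pick the model:

```python
import resistmix as rm
from resistmix import reference as ref

truth = rm.TwoPopulationParams(ref.SENSITIVE_STATE, ref.RESISTANT_STATE,
                               groups=tuple(range(1, 9)),
                               f_sens=ref.DEFAULT_FSENS_TRAJECTORY, v_max=0.9)
design = rm.make_time_course_design(ref.DEFAULT_FSENS_TRAJECTORY, truth)
data = rm.simulate_assay(design, rm.NoiseModel.constant(0.03, seed=42))

comparison = rm.compare_models(data, v_max=0.9)
print(comparison.table.round(4))
print("winner:", comparison.winner)
fit = comparison.fits["two_population"]
print(f"sensitive LD50 {fit.params.sensitive.ld50:.1f} uM, "
      f"resistant LD50 {fit.params.resistant.ld50:.1f} uM")
```

prints

```
                 k  n_obs     rss     mse        aic  converged
model
single_static    2    384  2.3269  0.0061 -1956.7469       True
single_dynamic  16    384  0.5041  0.0013 -2516.0724       True
two_population  12    384  0.3051  0.0008 -2716.8404       True
winner: two_population
sensitive LD50 21.8 uM, resistant LD50 82.8 uM
```

The mixture model wins decisively (lowest AIC with fewer parameters
than the single dynamic model), and the recovered state LD50s sit
within a few µM of the generative truth — under this noise level the
weekly drug response is explained by two fixed states whose
proportions shift, not by one curve drifting.

The same stages are available from the shell:

```sh
resistmix simulate --kind time-course --seed 42 --sd 0.03 --out assay.csv
resistmix compare --input assay.csv --vmax 0.9 --out comparison.csv
resistmix bootstrap --input assay.csv --model two_population --out ci.csv
resistmix pipeline --config run.yaml     # fit -> compare -> bootstrap -> dynamics
```

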