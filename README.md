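# lymphkin

Whole-organism kinetics of lymphocyte recirculation.

Naive lymphocytes patrol the body by cycling between blood, lymph and
tissues, and the speed of that cycle sets how quickly a local infection
can be detected.  `lymphkin` implements the compartment model behind the
classic quantification of this cycle: adoptively transferred,
radio-labeled thoracic-duct lymphocytes (TDLs) tracked as percentages of
the injected bolus across the blood, lung, liver, spleen, subcutaneous
lymph nodes (SCLNs), mesenteric lymph nodes (MLNs) and Peyer's patches
(PPs) of rats.  It is aimed at quantitative immunologists and modelers
who want to re-derive, perturb or re-fit those recirculation kinetics.

## The model

Blood feeds organ $i$ at entry rate $s_i$ (min⁻¹) and organ $i$ returns
cells at exit rate $m_i$, with two anatomical exceptions: Peyer's-patch
efflux drains into the mesenteric LNs, and SCLN efflux reaches the blood
via the thoracic duct only with probability $f \approx 0.5$ (the rest
uses the right lymphatic duct).  Lymph nodes and PPs are chains of $k$
serial sub-compartments with a common per-stage rate $m_{LN}$, so their
transit times are gamma-distributed with shape $k$ and mean $k/m_{LN}$.
A removal rate $\mu$ drains blood into death/unsampled tissue, a
fraction $\varphi$ of it accumulating in the liver as dead (still
labeled) cells.  During thoracic-duct cannulation the duct flow —
$m_{LN}e^{-\nu t}\,(f\,\mathrm{SCLN}_k + \mathrm{MLN}_k)$ — is harvested
instead of recirculated, with the LN/PP rates decaying at $\nu$ as the
cannula drains node cellularity.

The package provides:

* exact simulation of the linear system (matrix exponential; stiff ODE
  integration when rates are time-varying), with label conserved to 1e-6;
* closed-form steady states and mean residence times ($1/m$ for single
  compartments, $k/m_{LN}$ for chains);
* nonlinear least-squares fitting of migration time courses and a
  generalized-likelihood joint fit of migration + cannulation data with
  dataset-specific error variances, multi-start and log/logit
  parameterization;
* nested F-tests, least-squares AIC, and residual-bootstrap confidence
  intervals;
* virtual experiments: cannulation forecasts, steady-state perturbations
  (inflammation, anti-CD62L, FTY720), stimulated-node entry/exit
  decomposition, entry-blockade simulations and Bernoulli pass counting;
* a synthetic-data generator reproducing the experimental sampling grids
  and error model, plus CSV readers/writers and a CLI (`lymphkin`).

## Worked example

```python
import lymphkin as lk

p = lk.reference_parameters()          # published rat TDL estimates, k = 2

# long-run distribution of label over the seven organs
for organ, pct in lk.steady_state(p.replace(removal_rate=0.0)).items():
    print(f"{organ:<8}{pct:6.1f} %")
```

```
blood      2.6 %
lung       2.2 %
liver      0.9 %
spleen    21.1 %
scln      40.3 %
mln       24.6 %
pp         8.2 %
```

At equilibrium only ~2.6% of the cells are in transit in the blood;
two-thirds sit in lymph nodes.  Residence times explain why — a cell
spends ~26 s in the blood per pass but ~9.8 h crossing a lymph node:

```python
60 * lk.mean_residence_time(p, "blood")   # 25.6  (seconds)
lk.mean_residence_time(p, "scln") / 60    # 9.8   (hours)

curve = lk.predict_cannulation(p, f=0.5, nu=0.0)
curve["cumulative_pct"].iloc[-1]          # 79.8  (% collected in 45 h)
```

The cannulation forecast says that if cannulation did not perturb the
nodes, ~80% of the transferred cells would be collected from the
thoracic duct within 45 h — far more than real cannulation experiments
recover, which is the evidence that cannulation itself slows LN transit
(the $\nu$ mechanism).

Fitting works on any migration dataset in the long CSV format; here a
synthetic one generated from the reference rates:

```python
data = lk.generate_migration_dataset(p, noise=lk.NoiseSpec(seed=7))
res = lk.fit_migration(data, k=2, starts=2, seed=0)
print(res.summary())
```

```
Recirculation model fit
===============================================
observations: 91   free parameters: 12
converged: True
SSR (migration): 14.694
error SD (migration): 0.4018
-----------------------------------------------
parameter       estimate                95% CI
s_lung            1.6948
s_liver          0.35492
s_spleen        0.056398
s_scln          0.026723
s_mln           0.010802
s_pp           0.0055138
m_lung            2.0196
m_liver          0.99607
m_spleen       0.0068381
m_ln           0.0034298
mu             0.0049992
phi              0.48789
```

The estimates recover the generating rates (lung entry 1.83, shared
LN/PP exit 0.0034 min⁻¹, ...) to within the noise;
`res.bootstrap(n_boot=1000, seed=0)` fills the CI column.

The same pipeline is available from the shell:

```sh
lymphkin steady-state --scenario lung_inflammation
lymphkin synth --seed 1 --out data/
lymphkin fit --migration data/migration.csv --out fit/
```

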