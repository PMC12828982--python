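# proteomicelle

Quantitative analysis of detergent- versus ligand-driven stabilization of a
detergent-solubilized G protein-coupled receptor.

Detergent micelles (DM, DDM, LMNG, ...) are the workhorse membrane mimetic
for GPCR biophysics, but they do more than solubilize: a tightly packed
micelle rigidifies the receptor's apo ensemble, raising baseline
thermostability while leaving less conformational freedom for an agonist to
stabilize. This package implements the machinery for dissecting that
trade-off for a thermostabilized neurotensin receptor 1 variant (enNTS1)
solubilized in decyl maltoside (DM), dodecyl maltoside (DDM), or lauryl
maltose neopentyl glycol (LMNG):

* **Thermal melt model** — the six-parameter Boltzmann sigmoid

  $$y(T) = (a_\mathrm{low} + m_\mathrm{low} T) +
  \frac{(a_\mathrm{high} + m_\mathrm{high} T) - (a_\mathrm{low} + m_\mathrm{low} T)}
       {1 + e^{(T_m - T)/s}}$$

  fitted to CD 222 nm melts (secondary-structure $^{2°}T_m$) and
  fluorescent-ligand retention melts (tertiary-structure $^{3°}T_m$), with
  parameter constraints (e.g. a fixed high-temperature asymptote of 0.07, or
  zero baseline slopes) and Jacobian standard errors.

* **Steady-state binding model** — the quadratic single-site equation that
  accounts for ligand depletion in a biolayer interferometry (BLI) assay,

  $$f = \frac{(R_t + L_t + K_d) - \sqrt{(R_t + L_t + K_d)^2 - 4 R_t L_t}}{2 L_t},
  \qquad y = R_\mathrm{max} f + n_s R_t ,$$

  yielding $K_d$ with asymptotic confidence intervals.

* **Relative partitioning calculus** — using the apo $^{3°}T_m$ as a proxy
  for the detergent-driven component ($\Delta G_\mathrm{conf,rel}$) and the
  ligand-induced shift $\Delta^{3°}T_m$ as a proxy for the ligand-driven
  component ($\Delta G_\mathrm{ligand,rel}$), both normalized to a reference
  detergent; plus the cross-level ($^{2°}T_m$ vs $^{3°}T_m$) and
  energy-vs-stability linear correlations.

* **Proteomicelle trajectory metrics** — from-scratch implementations of
  RMSD/RMSF, a Ramachandran-window helicity criterion, gyration-tensor
  micelle eccentricity, head/tail radial distribution functions with their
  2 nm AUC, voxel spatial occupancy, short-range Lennard-Jones + Coulomb
  interaction energies, contact frequencies with persistence thresholds
  (interhelical hydrogen bonds and vdW contacts, ligand contact maps and
  deltas), Shrake-Rupley SASA, and residual hydrophobic mismatch (exposed
  hydrophobic TM surface with <20% detergent-contact persistence).

* **Synthetic data generators** — seeded noisy melts and dose series, plus a
  toy proteomicelle (ideal helical bundle wrapped in a coarse-bead detergent
  shell with tunable packing, mobility, and contact persistence) so the
  whole pipeline runs and is tested without any external data.

The melt and binding models follow the model/results convention of
statsmodels: construct a model from data, `fit()` it, and read estimates,
standard errors, `conf_int()`, `summary()` and `plot()` off the results
object.

## Worked example

```python
import numpy as np
from proteomicelle import (MeltSimSpec, gen_melt, fit_boltzmann6,
                           load_fixtures, relative_partition, linear_corr)

# fit a synthetic CD-style melt (DDM apo conditions), constraining the
# high-temperature asymptote as done for sparse upper baselines
params = dict(a_low=1.0, a_high=0.07, m_low=0.0, m_high=0.0, tm=71.6, s=4.4)
curve = gen_melt(MeltSimSpec(params=params, noise_sd=0.02, seed=3))
res = fit_boltzmann6(curve, constraints={"a_high": 0.07})
print(res.summary())
```

```
Six-parameter Boltzmann melt fit
  n points: 476   RSS: 0.189912   nfev: 7
  constrained: {'a_high': 0.07}
  param          value          SE
  a_low         0.9979      0.0029
  a_high        0.0700      0.0000
  m_low         0.0001      0.0001
  m_high        0.0000      0.0000
  tm           71.5146      0.0723
  s             4.4458      0.0614
```

The fitted melting temperature (71.51 +/- 0.07 C) recovers the generating
value of 71.6 C to within its standard error; `s` is the transition slope
in C. Partitioning the published stability table:

```python
fx = load_fixtures()                       # published Kd / Tm tables
part = relative_partition(fx.stability_table(), "DM").rounded()
print(part.conf_rel)       # {'DDM': 1.6, 'DM': 1.0, 'LMNG': 2.1}
print(part.ligand_rel)     # {'DDM': 0.5, 'DM': 1.0, 'LMNG': 0.1}

corr = linear_corr([fx.tm2[(d, "apo")] for d in ("DM", "DDM", "LMNG")],
                   [fx.tm3[(d, "apo")] for d in ("DM", "DDM", "LMNG")])
print(f"slope={corr.slope:.2f} r2={corr.r_squared:.2f}")   # slope=1.18 r2=0.99
```

The detergent-driven component roughly doubles from DM to LMNG while the
ligand-driven component collapses by an order of magnitude — the
stabilization/flexibility trade-off in two numbers per detergent.

## Command line

```bash
proteomicelle simulate melt --config melt.yaml --out sim_
proteomicelle fit-melt --curves sim_melt.csv --constrain a_high=0.07 --out fits.csv
proteomicelle fit-binding --curves bli.csv --lt 5 --out kd.csv
proteomicelle partition --out part.csv
proteomicelle traj --ensemble sys.pdb --roles roles.csv --tm tm.yaml \
    --do rdf,shape,rmsf,helicity,mismatch --out prefix_
proteomicelle report --out report/
```

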