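# biphasekit

Analysis toolkit for the **biphasic (bell-shaped) activation–inhibition
dose-responses** of γ-secretase-targeting drugs (DAPT, semagacestat,
LY-411,575, avagacestat), for pharmacologists and enzymologists who need
to quantify such curves, reason about the kinetics behind them, or analyze
the accompanying structural-dynamics data.

Many γ-secretase inhibitors *increase* Aβ1-40 production at low
concentration and suppress it at high concentration. `biphasekit` provides
four connected layers:

1. **Empirical model** — the seven-parameter curve

       S(x) = PA + (MA − PA)·A(x) − (MA − MI)·I(x),   x = log10[drug]

   with rising/falling logistics `A, I` (midpoints EC50/IC50, Hill
   coefficients p/q), baseline `PA` at vehicle, activation plateau `MA`,
   and residual plateau `MI`.
2. **Fitting** — bounded multi-start nonlinear regression, delta-method
   standard errors, wild-bootstrap intervals, and nested model selection
   (flat / activation-only / inhibition-only / biphasic) by small-sample
   AICc on replicate means.
3. **Mechanism** — a rapid-equilibrium two-site enzyme-modifier scheme
   (activation site divides Km by α; uncompetitive dead-end site on the
   ES complex) whose closed-form rate law

       v/(kcat·E0) = s(1 + aα) / (1 + a + s(1 + aα)(1 + i)),   s = S/Km

   reproduces Michaelis–Menten at zero drug, the textbook uncompetitive
   form at α = 1, and yields bell-shaped dose-responses **only at
   sub-saturating substrate** — the regime of cellular assays.
4. **Trajectory mobility** — Kabsch superposition, RMSD series,
   per-residue RMSF with quartile mobility classes, essential-dynamics
   PCA, ΔRMSF comparisons and salt-bridge occupancy for multi-model
   PDB/XYZ ensembles.

A synthetic-data module generates ELISA-like dose-response panels (dose
grid, replicates, proportional noise, 6–125 pM linear-window censor
flags) and pseudo-Cα trajectories with known per-residue amplitudes, so
the entire pipeline is testable without external data. See
`docs/methods.md` for the model details, defaults and limitations.

## Worked example

Simulate the four-drug panel and fit every curve:

```python
from biphasekit import four_drug_panel, fit_biphasic, summary_table, FitConfig

panel = four_drug_panel(seed=1)
results = [fit_biphasic(item.dataset, FitConfig(n_starts=8))
           for item in panel.values()]
print(summary_table(results).to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

```
        drug   EC50_M  p_hill_activation   IC50_M  q_hill_inhibition  PA_baseline  MA_max_activity  MI_residual selected_model  aicc_margin  r_squared
   LY-411575 1.03e-09               1.46 3.16e-08                2.4         29.8               89         4.06       biphasic         92.6      0.995
 avagacestat 1.78e-09              0.931 5.32e-08               1.56         30.5             65.8         3.95       biphasic         47.5      0.993
semagacestat 1.71e-08               1.34 4.38e-07               1.63         30.5             80.4          3.7       biphasic         39.4      0.988
        DAPT 7.72e-08              0.907 3.78e-06               1.87         29.8             54.1         4.17       biphasic         20.5      0.989
```

Reading the table: every drug is recognized as biphasic (`aicc_margin` is
the AICc gap to the runner-up model). LY-411,575 activates at ~1 nM and
inhibits at ~30 nM with the steepest transitions and the highest maximal
activation (MA ≈ 3× baseline); DAPT needs ~75 nM / ~4 µM with the
shallowest transitions; all four share the ~30 pM Aβ1-40 baseline of the
common cell batch, and the inhibition phase is steeper than the activation
phase (q > p) throughout — the signature of multiple drug molecules
binding.

The same pipeline runs from the shell:

```bash
biphasekit --seed 1 --outdir out simulate
biphasekit --seed 1 --outdir out fit out/*.csv        # writes fit_summary.csv
biphasekit --outdir out mechanism                      # prints "biphasic"
biphasekit --outdir out traj ensemble.pdb --compare other.pdb
```

Why the curve is biphasic at all:

```python
from biphasekit import MechanismParams, dose_response_curve, classify_response
import numpy as np

m = MechanismParams(kcat=1.0, Km=1e-6, K_act=1e-8, alpha=10.0, K_inh=1e-6)
grid = np.concatenate([[0.0], np.geomspace(1e-10, 1e-4, 24)])
print(classify_response(dose_response_curve(m, 0.1 * m.Km, grid)).value)  # biphasic
print(classify_response(dose_response_curve(m, 100 * m.Km, grid)).value)  # monotone_decreasing
```

The same enzyme with the same drug affinities is activated only while the
substrate is sub-saturating; at saturating substrate the uncompetitive
inhibition alone remains.

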