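# Methods

## The biphasic dose-response model

Drugs that target γ-secretase commonly raise Aβ1-40 production above the
vehicle baseline at low concentration and suppress it at high
concentration. `biphasekit` describes this with the sum of a rising and a
falling logistic transition in log10 molar concentration:

    S(x) = PA + (MA − PA)·A(x) − (MA − MI)·I(x),      x = log10(conc)
    A(x) = 1 / (1 + 10^((log10_EC50 − x)·p))
    I(x) = 1 / (1 + 10^((log10_IC50 − x)·q))

with `S(0) = PA` exactly (the vehicle is a special case, not a pseudo-log
floor), `S → MI` as conc → ∞, and a plateau near `MA` when the transitions
are well separated. `p` and `q` are Hill coefficients; values above one
indicate multi-molecule binding per transition.

Parameter semantics and two documented alternatives:

* `MI` is read as the **residual-activity plateau** in response units. The
  alternative reading — `MI` as the magnitude of maximal inhibition below
  `MA` — is available via the `mi_as_magnitude=True` flag on the
  evaluation functions.
* The type-level constraint `MA ≥ PA` holds for any physically meaningful
  activation (`MA = PA` encodes "no activation") but is **not** enforced at
  construction, so that unconstrained regression output remains
  representable; `has_activation` tests it explicitly. `MI ≤ MA`,
  `PA, MI ≥ 0` and `p, q > 0` are always enforced.

Midpoints are stored as log10 of molar concentration because the dose axis
is logarithmic and the regression is much better conditioned in log space.

## Fitting and model selection

`fit_biphasic` minimizes unweighted least squares on the linear response
scale (optional inverse-variance weighting per concentration) with
`scipy.optimize.least_squares` (TRF, box bounds). Bounds: `PA, MA, MI ≥ 0`
with `MA ≥ MI` enforced structurally (the free vector carries `MI` and
`MA − MI ≥ 0`), Hill coefficients in (0, 10], midpoints within the observed
log-concentration range ± 2 log units. Vehicle rows participate in the fit
(they anchor `PA`); rows flagged outside the assay's linear window are
included by default and excluded or down-weighted only by explicit config.

Multi-start seeding is deterministic: midpoint pairs on an m×m
(center × separation) grid over the observed log range with
m = ⌈√n_starts⌉, every pair satisfying `log10_EC50 < log10_IC50`; with one
start this reduces to midpoints at the range tertiles. `PA/MA/MI` are
seeded from the lowest-dose mean, the maximum, and the highest-dose mean.

The nested family {flat (1), activation_only (4), inhibition_only (4),
biphasic (7)} is compared by small-sample AICc with the error variance
counted as a fitted parameter (the standard least-squares convention), and
ties within 2 AICc units resolved toward fewer parameters. Two design
choices matter here:

* **AICc is evaluated on per-concentration replicate means.** The wells of
  this assay are technical replicates of one cell batch, so the
  independent unit for model comparison is the concentration group.
  Treating every well as independent makes the comparison non-regular: the
  7-parameter model can park a Hill coefficient at its upper bound and fit
  a step between two noisy groups, winning by AICc in roughly one in eight
  true-monotone simulations. At the group level (n = 13) the small-sample
  correction prices the extra parameters correctly. Point estimates are
  unaffected (for balanced designs the well-level and mean-level optima
  coincide).
* **Detection power.** At 5 % proportional noise (3 replicates) the
  measured per-class assignment accuracy is: flat 98–100 %,
  inhibition-only ≥ 99 %, biphasic ≥ 99 % when the activation amplitude is
  at least 8× the replicate noise SD with transitions ≈ 2.5 log units
  apart. That amplitude is the documented effect size for the selection
  studies; smaller activation bumps are increasingly absorbed into the
  monotone families, by design of the parsimony tie-break.

Standard errors come from the delta method on the TRF Jacobian.
`bootstrap_ci` produces percentile intervals from refits of perturbed
data; the default is a dof-inflated **wild bootstrap** (each residual
scaled by an independent standard normal), which preserves the
heteroscedasticity of proportional assay noise. Classic within-
concentration case resampling is available (`method="case"`) but
understates the sampling variance badly at 3 replicates per concentration;
homoscedastic residual resampling is the automatic fallback (with a
warning) when any concentration has a single replicate.

**Known limitation:** at the default design (12 concentrations × 3
replicates, 5 % CV) the midpoint estimators are heavy-tailed, and *no*
percentile-type interval we evaluated (case, residual, wild, parametric,
BCa) reaches nominal 95 % coverage for `log10_EC50`; the wild default
measures ≈ 75–85 %. Treat the intervals as indicative of precision, not as
calibrated 95 % statements.

## The two-site enzyme-modifier mechanism

The kinetic scheme is the minimal rapid-equilibrium embodiment of
"activation by facilitated substrate binding, inhibition by uncompetitive
dead-end binding next to the substrate":

* the drug occupies an activation site on both E and ES with the same
  dissociation constant `K_act` (concerted stoichiometry `n_act`); its only
  kinetic effect is `Km → Km/alpha`;
* the drug occupies an inhibition site only on substrate-bound states
  (`K_inh`, `n_inh`), giving catalytically dead complexes.

Summing species fractions with `a = (D/K_act)^n_act`, `i = (D/K_inh)^n_inh`
and `s = S/Km`:

    v/(kcat·E0) = s·(1 + a·α) / (1 + a + s·(1 + a·α)·(1 + i))

    Vmax_app = kcat/(1 + i),     Km_app = Km·(1 + a) / ((1 + a·α)(1 + i))

Checks that follow analytically and are enforced by tests: `D = 0` gives
Michaelis–Menten exactly; `α = 1`, `n = 1` gives the textbook
uncompetitive form `S/(Km + S(1 + D/K_inh))` with `Vmax_app/Km_app`
independent of `D`; the closed form agrees with a brute-force enumeration
of all bound states to ≤ 1e-10 relative.

**Sub-saturating substrate is required for the bell shape.** At small
`s` the rate scales like `s(1 + aα)/(1 + a)`, which rises toward `α`-fold
activation as `a` grows before the dead-end term `1 + i` takes over; at
`s ≫ 1` the `a`-dependent factors cancel and only inhibition remains. The
peak-over-baseline ratio is non-increasing in `S/Km` and tends to 1 —
which is why cell assays (substrate far below Km) show biphasic curves
while saturated in-vitro assays show only inhibition.

**Bridge to the empirical model.** Fitting the empirical model to
mechanism-generated curves at `S = 0.1·Km` maps the fitted midpoints onto
the site constants, but only approximately: half-activation occurs near
`a ≈ α^(−1/2)`, i.e. EC50 → `K_act·α^(−1/(2·n_act))` at strong activation,
and the apparent IC50 exceeds `K_inh` when the two phases overlap at weak
activation. The documented bridge grid is therefore the moderate regime —
α ∈ {5, 10}, K_inh ∈ {1, 10 µM}, n ∈ {1, 2}, with K_act = 10 nM and
Km = 1 µM — where both recovered midpoints stay within 0.5 log units of
the site constants and R² > 0.99. At α = 3 the IC50 drift reaches
+0.64 log, at α = 30 the EC50 drift reaches −0.56 log; both follow from
the rate law, not from fitting error.

## Synthetic assay data

`AssayDesign` defaults define the emulated study conditions: 12 log-spaced
concentrations from 0.1 nM to 100 µM plus a DMSO vehicle (0 M), 3
replicates, 5 % proportional noise (plus optional additive SD), and a
6–125 pM ELISA linear window. Rows whose measured response falls outside
the window are **flagged** (`below`/`above`), never dropped — exclusion is
an explicit fitting choice. The replicate count and noise level are
package defaults chosen as typical for triplicate sandwich-ELISA work;
they are documented, not inferred from any source.

The four-drug panel encodes the qualitative orderings reported for these
compounds in SH-SY5Y cells, with values chosen once (units pM Aβ1-40;
log10 molar midpoints):

| drug         | PA | MA | MI | log10 EC50 | log10 IC50 | p   | q   |
|--------------|----|----|----|------------|------------|-----|-----|
| LY-411575    | 30 | 90 | 4  | −9.0       | −7.5       | 1.6 | 2.4 |
| avagacestat  | 30 | 66 | 4  | −8.8       | −7.3       | 1.0 | 1.5 |
| semagacestat | 30 | 75 | 4  | −7.8       | −6.3       | 1.3 | 2.0 |
| DAPT         | 30 | 60 | 4  | −7.0       | −5.5       | 1.0 | 1.6 |

LY-411,575 has the lowest midpoints, highest Hills and highest maximal
activation; DAPT the highest midpoints with the lowest; semagacestat sits
between; avagacestat matches LY's midpoints with lower Hills; every drug
shares the same baseline (one cell batch split four ways) and has a
steeper inhibition than activation phase (q > p). The 4 pM residual
plateau deliberately sits below the ELISA floor so saturating-inhibition
rows exercise the censor flags. Semagacestat and DAPT have overlapping
transitions (1.5 log separation), so under 5 % noise a single panel
realization can occasionally blur their EC50 ordering — the round-trip
ordering test therefore checks a majority over several panel draws.

The trajectory generator places one pseudo-Cα per residue on a helical
backbone and adds per-frame isotropic Gaussian displacements with
per-residue σ (Å), optionally wrapped in a random global rotation +
translation per frame. The expected RMSF is σ·√3. It emulates only the
amplitude structure of a real ensemble — no covariance between residues,
no solvent, no timescales — so trajectory tests validate the analytics,
not molecular realism.

## Trajectory analytics

Superposition uses the Kabsch algorithm (SVD with a determinant
correction; degenerate point sets raise), with a once-iterated mean
reference: frames are aligned to frame 0, the mean is formed, and all
frames are re-aligned to that mean — standard essential-dynamics practice.
The default selection is Cα atoms; no mass weighting.

RMSF is `sqrt(mean_frames |r_i − ⟨r_i⟩|²)` on the aligned selection;
mobility classes are RMSF quartiles with boundary ties going to the lower
bin. PCA diagonalizes the 3N positional covariance of the aligned
selection via SVD; eigenvalues sum to the total positional variance by
construction. ΔRMSF aligns two profiles by residue and reports contiguous
runs of decrease beyond a threshold (default 0.1 Å), largest total
decrease first. Salt bridges use the common 4.0 Å N–O criterion between
Asp/Glu carboxylate oxygens (plus C-terminal OXT) and Lys NZ / Arg
NH1/NH2/NE, any-atom-pair per frame; occupancy is the fraction of frames.

A finite-size effect worth knowing: unweighted rigid-body fitting leaks
the noisiest atoms' motion into the quietest ones (the fitted transform
chases the large-amplitude atoms). With heterogeneous σ the leakage
inflates small-σ RMSF by O(6·mean σ²/(3N·σ_i²)); at N = 20 residues and a
7.5-fold σ range it reaches tens of percent, at N = 100 with σ in
[0.5, 1.5] Å it stays below the 5 % tolerance used in the recovery tests.
That is why the amplitude-recovery fixtures use 100 residues.

PDB output quantizes coordinates to 0.001 Å (the format's precision);
write→read→write is byte-stable, while in-memory analyses stay float64.
XYZ input assigns one pseudo-residue per atom (the format carries no
topology).

## Numerical choices

* TRF termination at 1e-12 (xtol/ftol/gtol), max 500 function
  evaluations; noise-free round-trips recover parameters to ≤ 1e-4
  relative (measured ~1e-15).
* AICc RSS floor of `n·(1e-10·scale)²` keeps noise-free fits comparable
  (flat data then selects flat by parsimony instead of −∞ ties).
* Classification tolerance defaults to 1 response unit on %-normalized
  curves; a biphasic verdict requires the maximum to beat both endpoints
  by more than the tolerance.
* Quartile ties in mobility classes go to the lower bin, making uniform
  profiles all "low".
* All stochastic steps take explicit integer seeds; the CLI derives stage
  seeds from the master seed by hashing, and output files carry a
  provenance header (stage, config hash, seed — no timestamps) so reruns
  are byte-identical.

## Problem sizes

The test suite and the acceptance script use: 1000 random draws for the
closed-form and rate-law oracles; 200 simulated assays (12 × 3, 5 % CV)
for recovery medians; 100 simulations per generator for selection
accuracy; a 12-point mechanism grid for the saturation property and an
8-point grid for the bridge; 5000-frame/100-residue ensembles for RMSF
recovery; and 24 datasets × 120 resamples for the bootstrap-coverage
check. These sizes keep the full suite to a few minutes on one CPU while
leaving the Monte-Carlo error well below every asserted tolerance.

## Limitations

* The empirical model and the kinetic scheme share no parameters; the
  bridge is an approximate mapping, valid in the documented regime only.
* The mechanism is rapid-equilibrium with concerted stoichiometries; no
  steady-state treatment, no sequential site constants, no
  substrate-competition or processive-cleavage kinetics.
* Bootstrap intervals are indicative, not calibrated (see above).
* The assay generator has no plate, edge, or batch-drift effects; the
  trajectory generator has no inter-residue covariance. Passing tests
  demonstrate correctness of the analytics under known ground truth, not
  performance on real data.
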