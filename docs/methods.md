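# Methods

`amorphmob` quantifies molecular mobility in amorphous lactose/water
mixtures above the glass transition. It couples a deliberately minimal
coarse-grained trajectory generator to an analysis chain: a
species-decomposed spread statistic, mobility coefficients via a
simplified Einstein relation, Arrhenius activation energies, probe-based
free volume, and WLF Strength-parameter kinetics.

## The simulant cells

A cell is a cubic periodic box of M lactose and N water molecules, one
tracking point per molecule (the oxygen nearest the molecule's geometric
center — the only per-molecule information the analysis consumes). The
composition encodes a mimic water activity a_w; for 100-molecule cells at
0.5 g/cm³ the studied grid is

| a_w  | lactose:water | box side (Å) | Tg (K) |
|------|---------------|--------------|--------|
| 0.11 | 68:32         | 42.9         | 338    |
| 0.22 | 57:43         | 40.7         | 313    |
| 0.33 | 52:48         | 39.6         | 303    |
| 0.44 | 38:62         | 36.0         | 286    |

Tg values are experimental calorimetric onsets. Other cell sizes scale the
box side by (n_total/100)^(1/3) at fixed density; the lactose count is
round(fraction x n_total) with water taking the remainder, so the studied
ratios are exact at n_total = 100. Activities between grid points
interpolate the lactose fraction, box side and Tg linearly and are flagged
`interpolated`; outside the grid the nearest studied value is used.

## The trajectory generator

Each molecule performs overdamped Brownian motion: per recorded interval
`dt_record` (default 1 ps, 100 ps total → 101 frames) it takes a Gaussian
step of per-coordinate variance 2·D_sp·dt, wrapped into the box (NVT
semantics: the box never changes). The species mobility is
temperature-activated and water-plasticized:

    D_sp(T, a_w) = D0_sp · exp(−Ea_sp / (R·T)) · (1 + c·a_w),

with R = 8.314 J/(mol·K). Defaults: D0_water = 3.0 Å²/ps,
D0_lactose = 1.2 Å²/ps, Ea_water = 11 kJ/mol, Ea_lactose = 13 kJ/mol,
plasticization gain c = 1. These were chosen once for physical
plausibility: activation energies sit in the 7–13 kJ/mol range observed
for these matrices, and the resulting D(T) near Tg (≈0.05 Å²/ps for
water, ≈0.01 Å²/ps for lactose) is one to two orders of magnitude below
bulk-water self-diffusion (0.23 Å²/ps), i.e. a viscous glass-former.

Two features emulate the two-phase mobility pathway of these systems:

* **Initial compact placement.** Molecules start in a Gaussian blob about
  the box center (per-axis sd `init_spread`, default box/8), standing in
  for an incompletely pre-equilibrated configuration. Free diffusion then
  *expands* the spread statistic — the rapid near-linear rise over the
  first ~20 ps, followed by a plateau as the spread saturates.
* **Equilibrium clustering.** After `t_cluster` (default 20 ps) each
  molecule additionally drifts toward the instantaneous all-molecule
  centroid at rate `kappa_cluster` (default 0.05 /ps; set 0 to disable).
  This Ornstein–Uhlenbeck-style contraction is the simplest mechanism
  producing the observed late-time decline of the spread statistic; no
  hydrogen-bond network is modeled, and none is claimed.

What the generator does **not** emulate: force-field energetics,
molecular shape and excluded volume, hydrogen bonding, crystallization,
and any coupling between molecules other than the shared centroid drift.
Tests passing on these trajectories therefore validate the *analysis
chain* (estimator correctness, invariances, parameter recovery under the
assumed statistical model), not force-field realism.

## The spread-RMSD statistic

For N water points w_i(t), M lactose points l_j(t) and the mixture
centroid μ(t) = (Σw_i + Σl_j)/(N+M), deviations are δ_i = w_i − μ for
water and δ_j = (l_j − μ)/r for lactose, where r is the lactose/water
molecular size ratio (1.18/0.13 ≈ 9.08, configurable); the statistic is

    RMSD(t) = sqrt[ (Σ|δ_i|² + Σ|δ_j|²) / (N+M) ].

Interpretation matters: this is a *spread about the instantaneous
centroid*, not a displacement from t = 0. It is translation invariant,
can decrease (clustering), and for a single species with r = 1 reduces to
the radius-of-gyration-style RMS spread. The double-sum notation for the
mean position is read as the centroid of all N+M points — the only
reading under which water and lactose deviations share an origin and the
statistic is dimensionally coherent. A conventional from-origin MSD
(`msd_from_origin`, with periodic unwrapping) is provided separately; it,
not the spread series, is the quantity the Einstein relation applies to
exactly, and it is what the parameter-recovery tests use.

Periodic unwrapping (minimum-image continuity between consecutive frames)
is OFF by default for the spread statistic and ON by default for the
from-origin MSD; it is valid while no molecule moves more than half a box
side between recorded frames, comfortably true at the default cadence.

## Mobility coefficients and activation energies

The linear portion of a series (default window 0–20 ps, the rapid-rise
regime) is fitted by ordinary least squares, y = kx + b, and the mobility
coefficient is D = |k|/6. Two conventions are fixed deliberately:

* **Absolute value.** A contracting series (negative k) still reports a
  positive mobility; the reference tables this mirrors pair negative
  slopes with positive D at exactly |k|/6 (4 d.p.) in the a_w = 0.11
  rows. The sign stays available on the fit object.
* **Units.** Fitting the spread series (Å) gives D in Å/ps — a mobility
  *coefficient*, a length per time, kept in those units. Fitting an MSD
  series (Å²) gives a true diffusion coefficient in Å²/ps
  (× 1e−4 → cm²/s, helper provided). The conversion helper is only
  meaningful for the MSD route.

Activation energies come from least squares of ln D on 1/T
(natural log, R = 8.314), Ea = −slope·R in kJ/mol, D0 = exp(intercept).
On noiseless Arrhenius data the estimator is exact to machine precision.
One documented non-reproducibility: applying this estimator to the
printed mobility quadruple (0.0405, 0.0489, 0.0537, 0.0562 Å/ps at
338–368 K) gives 11.2108 kJ/mol, whereas the source table prints
10.9878 kJ/mol; the fitting variant behind the printed value is unstated,
so the least-squares value is the one this package asserts and reports.
Similarly, for a_w ≥ 0.22 the printed D values are not |k|/6 of the
printed slopes; only the a_w = 0.11 rows are used as exact anchors.

## Free volume

Free volume is estimated on a voxel grid: the box is tiled with
n = round(box/spacing) voxels per axis (the effective spacing box/n makes
the tiling exact), and a voxel is occupied when its center lies within
(species radius + probe radius) of any molecule center under periodic
minimum image. This inflated-sphere criterion approximates the
solvent-excluded (Connolly) surface without its reentrant patches —
adequate at the one-sphere-per-molecule level, and within 2% of analytic
sphere and two-sphere-union volumes at 0.25 Å spacing. Free volume is
non-increasing in probe radius, and grid refinement is bounded by the
surface-layer estimate 4πr²·spacing.

Defaults: probe 1.0 Å, spacing 0.5 Å, effective radii water 1.4 Å and
lactose 4.6 Å. The radii are a calibration, not measured vdW radii: with
the default probe they place the free-volume fraction of a uniformly
filled 100-molecule cell at ≈51%, inside the ≈40–56% band these matrices
exhibit. Because the reference free-volume tables print neither radii nor
probe, no exact agreement with them is claimed or tested; the qualitative
behavior (clustering concentrates occupancy and frees volume late in a
run) is tested instead.

## WLF kinetics and the Strength parameter

Above Tg the relaxation time follows

    log10(τ/τ_g) = −C1·(T−Tg) / (C2 + (T−Tg)),

defined for T−Tg > −C2. The Strength parameter is the temperature rise at
which flow drops by d_s decades (d_s = 4 for carbohydrate systems):

    S = d_s·C2 / (C1 − d_s),   requiring C1 > d_s.

This closed form is the unique solution of the WLF equation for a
d_s-decade drop; the implementation is cross-checked against numerical
root finding to 1e−9 K across a C1 × C2 sweep. C1 and C2 are material
constants supplied by the user (they are not printed in the reference
work and are never hard-coded). τ(T−Tg = S) = τ_g·10^(−d_s) holds
exactly by construction.

Cell-scale relaxation times are translated to laboratory timescales by an
*explicit* conversion factor: the literature arithmetic behind such
translations (a reported 2.0e−11 s becoming 1.8e6 s "considering
Avogadro's constant") is not recoverable as written, so two readings are
exposed — a raw user-supplied factor, and a per-gram convention
(Avogadro/molar mass)/n_cell (≈1.76e17 for lactose and a 10,000-molecule
cell). Both are labeled interpretations.

## Pipeline, replicates, reproducibility

`run_pipeline` sweeps a_w × (T−Tg) × seeds (defaults: T−Tg ∈ {0, 10, 20,
30} K, 3 seeds — replicate runs are the in-silico triplicate). Per run it
writes the trajectory and spread series; aggregated outputs are a
mobility table (slope, R², D with replicate mean/sd/95% CI), an
activation-energy table computed both from the spread-slope route and
from per-species from-origin MSD, and a free-volume table at selected
times. The 95% CI uses the t distribution (n−1 dof); for n = 1 the sd is
reported as 0 and the CI as NaN. Significance testing beyond descriptive
CIs is intentionally absent.

Each (seed, a_w, T) combination gets an independent, reproducible random
stream (`SeedSequence([seed, i_aw, i_T])`); a JSON manifest captures the
config, its hash and the package version, and re-running from the
manifest reproduces every CSV byte for byte. Every CSV carries the config
hash in a leading comment line so outputs of different configurations
cannot be mixed silently.

## Problem sizes and numerical choices

Statistical tests run at desk scale, chosen so sampling error sits well
inside the asserted bands: single-condition diffusion recovery uses
500–1000 molecules; the 10%-band per-species MSD check uses 1000
molecules × 100 ps × 5 seeds; the 15%-band end-to-end activation-energy
recovery uses 2000 molecules × 4 temperatures × 3 seeds (relative
standard error of ln D ≈ 2% per point); the two-phase clustering fixture
uses 1000 molecules with `init_spread` = 2 Å so both slope signs are many
standard errors from zero. Degenerate inputs are defined rather than
fatal where a value exists (single-molecule frames have zero spread; an
empty box has 100% free volume via a dedicated constructor), and are
errors where none does (empty frames in the statistic, D ≤ 0 in the
Arrhenius fit, fit windows with fewer than two points).

## Known limitations

* One isotropic sphere per molecule: no shape, no excluded volume, no
  hydrogen bonding; clustering is phenomenological centroid drift.
* The spread statistic and |k|/6 give a mobility coefficient in Å/ps
  whose absolute magnitude depends on the initial spread; quantitative
  cross-study comparisons should use the MSD route.
* Free-volume absolute values depend on the calibrated radii and probe;
  only trends and bounds are meaningful.
* WLF constants must come from experiment; the package only propagates
  them.
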