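# Methods

## The model

`oriseg` simulates the positioning and segregation of the *E. coli*
replication origin (*ori*) by self-organised MukBEF, an SMC-like complex
that forms dynamically positioned clusters on the nucleoid.  The model has
three tiers:

1. **MukBEF reaction–diffusion (module `model_core`).**  MukBEF cycles
   between a well-mixed cytosolic state w, a mobile DNA-associated state u
   and a slowly diffusing clustered state v on a 1-D lattice of
   compartments of width h = 0.1 µm spanning the long cell axis.  Per
   molecule, u converts to v at a basal rate α and cooperatively through
   the tri-molecular channel u + 2v → 3v (propensity β̂·u·v·(v−1), with β̂
   the mass-action constant β rescaled by the compartment volume); v
   reverts to u at γ; both DNA-associated states unbind into the cytosol at
   δ and w rebinds as u at ε, split across compartments by loading weights
   g (uniform, or elevated by the `loading_ratio` in compartments that
   contain an *ori*, with Σg = 1 so the total loading rate is unchanged).
   Because D_u ≫ D_v, the u–v subsystem is Turing unstable
   (`linear_stability_check` evaluates the dispersion relation of the u–v
   linearisation over the discrete reflecting-boundary modes) and v
   condenses into one cluster in short (2.5 µm) cells or two quarter-
   positioned clusters in long (5 µm) cells.  The well-mixed w state
   supplies a spatially uniform source of u whose capture flux into a
   cluster is proportional to the nucleoid length on each side; this flux
   imbalance centres the pattern (flux balance).  Simulation is an exact
   spatial Gillespie (RDME) realisation; event selection uses a two-level
   linear search (blocks of 8 compartments → compartment → channel) and an
   inline 64-bit xoshiro256+ generator so that the very low relative rates
   of the *ori* channels are sampled accurately.  All propensities are
   recomputed from the integer counts whenever they change, and the cached
   partial sums are refreshed periodically, so floating-point drift cannot
   accumulate.

2. **Ori coupling (module `ori_coupling`).**  The *ori* is a point particle
   on a finer lattice of n_sub = 21 sub-compartments per compartment.  Its
   hop rates follow the Wang–Peskin–Elston discretisation
   F = (D_ori/h_s²)·a/(1−e^{−a}), B = (D_ori/h_s²)·a/(e^{a}−1), which
   satisfies detailed balance and the exact drift identity
   (F−B)·h_s = D_ori·a/h_s.  The bias towards higher clustered-MukBEF
   density is a = μ·Δv/h, where Δv is the difference of the linearly
   interpolated v profile across one sub-step and h the reaction-
   compartment width: the potential experienced by the *ori* is μ times
   the linear density v/h of the clustered species, so a is dimensionless
   (μ in µm) and the physical drift D_ori·μ·Δv_comp/h² is invariant under
   sub-compartment refinement — the property that motivates the
   sub-lattice in the first place.  This convention simultaneously
   reproduces the ~40% inflation of the apparent diffusion constant when
   sub-compartments are disabled, its stability above ~5 sub-compartments,
   the steeper focus-referenced velocity profile, tight ori–cluster
   colocalisation and the loading-ratio trends.  Entropic
   repulsion between newly duplicated sisters is a Gaussian-potential
   separation speed v_s = k·d·e^{−d²/2σ²}; each sister carries v_s/2,
   translated into an additional bias a_rep = v_s·h_s/(2·D_ori) through
   the same drift identity.  Duplication is triggered at a cell length
   drawn from a normal distribution (mean 3 µm, CV 0.16) truncated to
   [2.5, 5] µm by rejection; note the asymmetric truncation places the
   mean of the truncated law at ≈ 3.13 µm and the median duplication time
   at ≈ 32 min under the exponential length–time map.  The sister appears
   in the same sub-compartment and moves independently afterwards.

3. **Lattice polymer with dynamic looping (module `polymer_looping`).**
   To show how directed *ori* motion can arise mechanistically, the
   chromosome is modelled as a self-avoiding ring polymer in the
   bond-fluctuation representation (monomer = 2³ lattice cube, squared
   bond lengths {4, 5, 6, 9, 10}) confined by hard walls in a 4:1 cuboid
   (default 22 × 22 × 88 sites, 464 monomers, ≈ 9% volume fraction).  One
   marked monomer (*ori*) forms transient loops with distal monomers
   (candidates within bond range, excluding ±2 ring neighbours, one
   uniformly chosen attempt per MCS) with probability given by a Gaussian
   profile of the *ori*'s relative long-axis position (sd 0.1 of the long
   axis; centred for one chromosome, at the quarter positions for two);
   each loop lives exactly `loop_lifetime` MCS.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| α | 0.5 s⁻¹ | basal u→v conversion |
| β | 1.5×10⁻⁴ nM⁻²s⁻¹ | cooperative conversion (β̂ ≈ 0.165 s⁻¹ per molecule pair in a 0.1 µm compartment) |
| γ | 3.6 s⁻¹ | v→u reversion |
| δ | ln2/50 s⁻¹ | unbinding to the cytosol (≈ 1 min cluster turnover) |
| ε | 3δ | cytosol rebinding; with unbinding from both bound states this fixes a 3:1 bound:cytosolic partition |
| D_u, D_v | 0.3, 0.012 µm²s⁻¹ | differential diffusion driving the instability |
| C | 520 nM | total concentration (391 molecules at the 1.25 fL birth volume; 1000 nM in the multifork scenario) |
| D_ori | 5.4×10⁻⁵ (fixed-length) / 5.1×10⁻⁵ (growth) µm²s⁻¹ | ori mobility |
| μ | 0.026 / 0.052 µm | drift strength up the v gradient |
| n_sub | 21 | sub-compartments per compartment (odd) |
| loading_ratio | 1 (off), 6 or 10 in loading scenarios | preferential loading at ori |
| k, σ | 1 s⁻¹ (5 without loading), 0.2 µm | sister repulsion strength and range |
| L_birth→L_div, T | 2.5→5 µm, 120 min | exponential growth; one empty compartment inserted at a uniform slot per 0.1 µm of growth, molecules topped up through the cytosol to track C·V(t) to the nearest integer |

## Reaction topology

The cytosolic exchange applies to **both** DNA-associated states (u→w and
v→w at δ).  This is a deliberate design choice: with unbinding from u only,
the nucleoid-bound pool communicates with the cytosol almost exclusively
through the well-mixed u state, the homogeneous cytosolic fraction drops to
a few molecules, and the flux-balance signal vanishes — deterministically
the v peak pins at a cell pole, and stochastically a mid-cell cluster is
unstable.  With δ acting on both bound states the cluster exchanges
directly with the uniform cytosolic source, off-centre clusters relax to
mid-cell within ~10 minutes, and 5 µm cells form quarter-positioned peaks.
A configuration switch (`TuringParams.v_to_w=False`) retains the
alternative topology.

## Trajectory statistics

Tracks are read out every 60 s.  The step-wise velocity
v = (x(t+δt)−x(t))/δt is binned (0.1 µm bins, bins with < 20 steps
suppressed) by position relative to mid-cell or to the detected MukBEF
focus (3-compartment moving-average smoothing; two-peak profiles split at
the smoothed minimum between maxima at least 1 µm apart, requiring the
second maximum to carry at least 10% of the first).  Diffusion in a
harmonic potential gives E[v|x₀] = x₀(e^{−δt·d_a}−1)/δt and
Var[v] = D_a·τ(1−e^{−2δt/τ})/δt², so a weighted linear fit over the
central region (|x| ≤ 0.3 µm, inverse-variance weights) yields the drift
rate d_a = 1/τ from the slope (full expression, not the small-δt limit)
and D_a from the pooled central variance; fits with non-negative slope are
flagged invalid.  The restoring force is F = kT(d_a/D_a)x with
kT = 4.19×10⁻²¹ J (30 °C).  Partitioning accuracy is the fraction of runs
with the two oris in opposite cell halves (exact mid-cell ties excluded
with a warning); crossings are sign changes of x₁−x₂ with zeros attributed
to the following step; the segregation velocity subtracts the instantaneous
dilation |d|·ln2/T from the step-wise rate of change of the separation.
Colocalisation is tested against an independence null obtained by
resampling pairs from the two marginal position distributions, and by the
median-absolute-deviation correlation
r = (MAD(u+v)²−MAD(u−v)²)/(MAD(u+v)²+MAD(u−v)²) on MAD-standardised
variables.

## Synthetic data

`synthetic_data` draws locus tracks from the exact OU transition density
(initial point from the stationary law), so analysis-stage tests have
known ground truth at any readout interval.  Boundary handling is by
reflection, applied only when a step exits [0, L]; a warning is raised when
the stationary spread makes walls relevant.  The generator emulates the
statistical structure the analysis assumes (a single harmonic home
position, Gaussian steps, optional Gaussian localisation error); it does
not emulate cell-length variation, home-position drift after duplication,
or non-Gaussian displacement tails of real tracking data — passing
recovery tests therefore validates the estimators, not the microscopy
pipeline.

## Problem sizes and numerical choices

Simulations in the test-suite and in `scripts/acceptance.py` run at desk
scale: 20–44 replicates instead of the hundreds used at production scale,
300-minute fixed-length runs, and polymer systems reduced to 48–96
monomers in a 10 × 10 × 40 box (volume fraction ≈ 10% preserved) with
readouts every 100–250 MCS.  Confidence allowances in the statistical
assertions are set accordingly.  Tolerances: homogeneous-root residuals
< 10⁻¹⁰ (Brent); jump-rate evaluation switches to a series below
|a| = 10⁻⁹ and to asymptotic forms beyond |a| = 700; ties in
partitioning/crossing statistics are handled as stated above; growth
insertion slots include both poles.

## Known limitations

* In fixed 5 µm cells the partitioned and unpartitioned two-ori
  configurations mix on a multi-hour timescale, so the equal-likelihood
  (~50%) statistic requires ~9 h of simulated time from a quarter-
  positioned start; shorter runs under-sample the unpartitioned state.
* The duplication-length rule (truncated normal, mean 3 µm) implies a
  median duplication time of ~32 min, earlier than the ~40 min mean of the
  experimentally derived timing it stands in for; the earlier duplication
  leaves co-trapped sisters longer under a single MukBEF cluster and
  depresses the end-of-cycle partitioning accuracy of the
  preferential-loading (no-repulsion) growing-cell scenario below the
  published value.
* The two-chromosome polymer runs start from side-by-side rings (the
  bond-fluctuation representation excludes overlap by construction), so
  the entropic repulsion between interpenetrating chains is largely
  absent at desk scale; looping then pins oris near the central dip of the
  quarter-position profile before locking them at the quarters, and the
  early-time acceleration of segregation by looping is not reproduced,
  while quarter positioning and locked separation are.
* One spatial dimension only: the compartment-based stochastic method is
  unreliable for tri-molecular reactions in higher dimensions at small
  compartment sizes, and the long axis is the dimension along which
  positioning occurs.
* No cell division, daughter partitioning, replication forks or sister
  cohesion; "duplication" corresponds to initial sister separation.
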