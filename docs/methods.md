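# Methods

`focusdyn` quantifies how fast a virus spreads from cell to cell in a
monolayer of stationary cells, and shows why — and how — the classical
mass-action description of that process must be corrected for space.
This note documents the models, the simulator that generates the study
data, the fitting machinery, and the numerical and design choices made
where the design was genuinely open.

## 1. Population-level models

The model family couples target cells `T(t)`, infected cells `I(t)` and
extracellular virus `V(t)`:

    dT/dt = -beta_f V T - g(I) beta_c I T
    dI/dt = +beta_f V T + g(I) beta_c I T
    dV/dt = rho I - c V

with `beta_f` the cell-free (CF) and `beta_c` the cell-to-cell (CC)
transmission rate.  Cell death and proliferation are out of scope
(`delta_T = delta_I = 0`), so `T + I` is conserved — a property the test
suite asserts.  `g(I) = 1` recovers the classical variants (CF, CC,
CCF); the adjusted variants (aCC, aCCF) use `g(I) = fc(I)` described
next.  Delay variants (CC-dI, aCC-dI) replace `I(t)` in the infection
term with `I(t - tau)`, modelling the time a newly infected cell needs
to become infectious; their history is constant, `I(s) = I0` for
`s <= t0`.

### The perimeter-fraction correction fc(I)

When spread is purely cell-to-cell among stationary cells, newly
infected cells appear only at the rim of a focus.  Under idealized
radial growth on a lattice with `k` neighbors per cell, a focus that
has completed `n` rings has

    size       I(n, k) = (k/2) n^2 + (k/2) n + 1
    contributor fraction fc(n, k) = 2 k n / (k n^2 + k n + 2),

and eliminating `n` gives the continuous branch
`fc(I) = (sqrt(k^2 + 8kI - 8k) - k) / (2I)` for `I >= k`.  For
`I <= k` every infected cell still touches an uninfected cell, so
`fc = 1`; a cubic `f2(I) = a (I-k)^3 + b (I-k)^2 + 1` joins the two
branches over `k < I < k + z` with matching value and first derivative
at `I = k + z` (a 2x2 linear system solved in closed form; `f2(k) = 1`
and `f2'(k) = 0` hold by construction).  The window width `z` (cells)
is a fittable parameter.  Cultures seeded with `psi` foci whose growth
is irregular by a factor `theta >= 1` evaluate the correction at the
effective per-focus size `I / (psi theta)`; `theta` is fitted,
`psi` is fixed by the design (1 for a single focus, the expected
inoculum size otherwise — the realized mean is available as an option).
We read the multi-focus divisor as the product `psi * theta`, which
makes `theta` interpretable as "effective sub-foci per seeded focus"
in both single- and multi-focus fits.

## 2. The lattice simulator

The monolayer is a hexagon-shaped patch of a hexagonal lattice
(`3 s^2 - 3 s + 1` cells for `s` cells per edge; 24,031 cells at the
bench scale `s = 90`, 4,681 at the reduced scale `s = 40` used
throughout the tests).  Per cell, infection status, intracellular viral
RNA `R`, local extracellular virus `V`, and the full infection lineage
(route, infector, time) are tracked.

Per time step `dt = 1 min`:

1. **Intracellular replication/export** — explicit Euler on
   `dR/dt = alpha R (1 - R/Rcap) - (gamma + rho) R`,
   `dV/dt = finf rho R - c V` for infected cells (validated
   `alpha dt << 1`; the R-equation is logistic with net rate
   `alpha - gamma - rho` and effective capacity
   `Rcap (alpha-gamma-rho)/alpha`, which the tests check against the
   closed-form solution).
2. **Diffusion** — synchronous conservative neighbor exchange
   `V <- V + (m/k) * sum_nbr (V_nbr - V)`, applied as a sparse
   one-step operator.  A literal reading of the source scheme carries
   the opposite sign, which anti-diffuses and destabilizes uniform
   fields; we use the standard exchange form, which conserves the
   lattice total exactly (no-flux boundary, divisor fixed at `k`).
3. **Infection** — evaluated on the pre-step state.  CF: each
   uninfected cell fires with `min(1, sf V_local dt)`.  CC: each
   infected neighbor independently fires with
   `min(1, sc finf R_donor dt)`.  Candidate events are randomly
   permuted and the first event per cell wins; a successful CC donor
   loses **half** its RNA per transmission and the recipient starts at
   `R = 1`.  The halving implements the transfer of viral material in
   a way that makes repeated transmission by one donor rate-limited;
   with a negligible (one-copy) cost the founder cell re-infects its
   whole neighborhood far faster than the growth rates the
   population-level estimates imply (Section 5).
4. **Inoculation** (scenarios with an inoculum) — during the first
   17 h, new infections are seeded at a density proportional to
   `exp(-lam t)` normalized to an expected total of `I0hat` cells;
   the per-step Poisson mass is the exact integral of the density over
   the step, so the normalization carries no discretization bias.  At
   17 h the medium is changed (all extracellular virus removed) and,
   in the CC-only multifocus design, CF transmission is blocked from
   then on.

Scenario presets: `single_focus_cc` (one central cell, CC only),
`multifocus_cc` (inoculation, CF blocked at 17 h), `mixed_slow/fast_
diffusion` (both routes; `m = 0.004` slow, `m = 0.66` fast — a 165x
faster flux), `cf_only_slow/fast`.  A helper maps `m` to a physical
diffusion coefficient `D = m dx^2 / (4 dt)`; it is informational only.

### Intracellular fixture and calibration

The per-cell replication parameters are a package fixture (defaults:
`alpha = 2e-3`, `gamma = 2e-4`, `rho = 6e-4` per min, `Rcap = 170`,
`finf = 0.5`, `c = 1.67e-3` per min), giving a stationary load of
~102 RNA reached over roughly 2.5 days — a rise-over-days-to-plateau
time course.  The transmission scalings were calibrated once, before
any model comparison, to population-level anchors implied by published
bench-scale estimates of these dynamics: CC-only scenarios
(`sc = 1e-4` per RNA per min) reproduce slow first-day growth from a
single cell (mean I(24 h) ≈ 2) with a focus of order 10^2–10^3 cells at
day 10; the mixed/CF scenarios (`sc = 5e-5`, `sf = 1e-4`) make both
transmission routes contribute appreciably under fast diffusion
(final CF-infected share ≈ 0.4).  Transmission probabilities differing
between study designs mirrors bench practice, where they are varied
between experiments to probe different route contributions.

### What the generator does and does not emulate

It reproduces: local ring-like focus growth and the declining
contributor fraction, inoculation-timing heterogeneity, focus merging,
route-resolved lineages, diffusion-limited versus well-mixed cell-free
spread, and replicate-level stochasticity.  It does not model cell
death or division, 3D tissue, immune effectors, virion transport
beyond nearest-neighbor exchange, or multiple strains.  Passing tests
therefore speak to the spatial-correction methodology, not to any
specific virus's kinetics.

One structural property matters for interpreting results: founder and
frontier cells obey identical kinetics, so the ratio of front speed to
early exponential growth is pinned by lattice geometry.  Real in-vitro
foci can grow more irregularly (fitted `theta` well above 1), which
this generator does not reproduce — fitted `theta` here stays near its
lower bound, and as a consequence the infectiousness delay `tau` is
only weakly identified on single-focus data generated by this
simulator: the maximum-likelihood delay is small but positive (~1 h),
while the likelihood varies by only ~0.02 along the `tau` profile, so
a pronounced, well-constrained delay does not emerge.

## 3. Inference

Replicate series are summarized per time point by mean and SD
(`ddof = 1`).  The Gaussian log-likelihood uses the per-time combined
variance `sigma^2(t) = sigma_t^2 / n + sigma_me^2` in both the residual
and the `ln sigma^2(t)` normalization term (the per-point form is the
only proper likelihood when `sigma_t` varies); the measurement error
`sigma_me` is estimated.  Channels carrying the viral load — and the
infected-cell channel whenever the load is co-fitted — switch to
relative residuals `(xbar - f)/f` with the empirical SD rescaled by the
mean.  CC-only fits drop the `V` equation entirely (viral turnover is
not identifiable there and does not feed back on the cells).

Optimization is Nelder-Mead in transformed space (log for positive
rates, linear for `tau`), with Latin-hypercube restarts (default 50 for
the library `fit`; the scenario pipelines use 4–8 restarts at the
reduced scale) plus, for delay variants, a warm start from the
non-delayed counterpart's optimum (the models are nested at
`tau = 0`).  Model ranking uses `AICc = 2k - 2L + 2k(k+1)/(n-k-1)`,
with differences quoted against the best model.

95% confidence intervals come from profile likelihood: the parameter is
scanned toward each bound, all other parameters re-optimized with warm
starts, and the interval edge is the crossing of the
`chi2_1(0.95)/2 = 1.9207` drop, located by quadratic interpolation
through the last three profile points (exact for locally parabolic
log-likelihoods; the Gaussian-mean closed form is a test oracle).  A
side that reaches its bound without crossing is reported open-ended;
a parameter flat to both bounds is flagged non-identifiable.  The
alternative CI construction based on clouds of random-restart fits is
not implemented.  Joint fits across datasets share named parameters
(`beta_f`, `rho`, `c` between the mixed and CF-only designs) and sum
the per-dataset log-likelihoods, with separate `sigma_me` per dataset.

## 4. Numerical choices

* Non-delayed trajectories: LSODA, `rtol = atol = 1e-8`.
* Delay trajectories: reduced to the scalar `I` equation using
  `T = T0 + I0 - I` (valid since all delay variants in scope have
  `beta_f = 0` and no death), method of steps with fixed-step RK4,
  `h = tau / ceil(tau / 1 h)` so the delayed argument falls on stored
  grid nodes; refining the step 5x changes endpoints by < 1e-4
  relative, far below the data noise.  Delays under 0.05 h (3 min) are
  dynamically indistinguishable from zero and routed to the
  non-delayed integrator.
* Per-step infection probabilities are capped at 1 (`min(1, rate dt)`);
  at `dt = 1 min` rates are far from the cap in all presets.
* CC-only fits drop saturated time points from the reduced chi-square
  (zero replicate SD carries no information on that scale) and the
  degrees of freedom.
* `z` has a numerical floor of 0.5 cells in fitting (the connection
  solve degenerates as `z -> 0`); `theta` is bounded to [1, 20],
  `tau` to [0, 24] h.

## 5. Open design points, resolved

* **Donor bookkeeping.** The transfer amount in CC transmission is not
  fully specified by the population-level description; we let the donor
  lose half its RNA per event.  A one-copy cost makes the founder's
  first-day output (~5–8 infections) inconsistent with the slow early
  growth that bench-scale transmission-rate estimates imply (~1–3);
  the halving restores it while leaving front propagation
  transmission-limited.
* **psi for multifocus fits** defaults to the expected inoculum size;
  the realized mean count is exposed as `psi_mode="realized"`.
* **Slow-diffusion mixed fits** use infected cells only (the load is
  effectively unobservable in that design); the fast-diffusion design
  is fitted jointly with a CF-only dataset on cells and virus.
* **Viral turnover in CF fits** (`rho`, `c`) is fitted rather than
  pinned: the analyst would not know the effective production timescale
  of ramping cells a priori.

## 6. Known limitations

* Fitted `theta` stays near 1 under this generator (Section 2), so the
  single-focus delay `tau` is only weakly identified here: its MLE is
  positive (~1 h) but its profile is nearly flat and the CI includes 0.
  The multifocus result `tau ~ 0` does reproduce.  Scenario runs at the
  reduced scale report `beta_c` ratios (adjusted/mass-action) of
  ~1.5–1.65.
* The reduced chi-square contrast between slow- and fast-diffusion
  CF-only designs is washed out at 12 replicates (slow-scenario
  replicate variance is large); the fast design's fit quality
  (`chi^2_red` ≈ 0.9) is reproduced.
* Profile CIs use a finite grid per side (default 12 points); extremely
  asymmetric profiles may localize an edge only to grid resolution.
* The reduced scale (side-40 lattice, 12–20 replicates, 10 days at
  24 h sampling; single runs take seconds, full scenario pipelines
  minutes) is the default; `paper_scale=True` restores the side-90,
  100-replicate design.
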