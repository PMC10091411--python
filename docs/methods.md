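# Methods

## Reaction network and model assumptions

The core model is the mass-action network for AcMP-11-mediated
*S*-nitrosothiol formation:

1. `Fe3_H2O + RS(H/-) ⇌ Fe3_RS` — thiol binding to the ferric aqua complex.
   This step is a **dead end**: the thiol-bound ferric complex does not react
   with NO. `k_on_RS` is an apparent constant against the total thiol pool,
   implemented as parallel elementary reactions of RSH and RS⁻ with the same
   constant so the pooled rate is `k_on_RS·[RS]_T` while every reaction stays
   elementary (molecularity ≤ 2). Release returns RSH; in unclamped
   simulations a fast exchange pair (10⁶ s⁻¹ scale, ratio 10^(pH−pKa))
   re-partitions the pool.
2. `Fe3_H2O + NO ⇌ Fe2_NOplus` — reductive nitrosylation of the aqua
   complex, with the independently measured `k_on_NO = 3.7 × 10⁶ M⁻¹s⁻¹`,
   `k_off_NO = 3.4 s⁻¹` as defaults.
3. `Fe2_NOplus + RSminus ⇌ I1` — thiolate attack forming the N-coordinated
   RSNO adduct; only the anion reacts (`k_on(RSH) = k_off(RSH) = 0`;
   the measured pH dependence of the apparent constants is consistent with a
   zero intercept in the 1/[H⁺] regression).
4. `I1 → Fe2_NO + RSNO` — lumped product step under NO excess, first order
   with default `k₂ = 0.05 s⁻¹`. The magnitude is a package choice: the
   transformation is known only to be much slower than I₁ formation, so the
   default keeps it ≥ 10× slower than every binding relaxation in the
   default scenarios. It is switched off (`include_product_step=False`,
   or `k₂ = 0`) for true-equilibrium analyses. Whether the step is really
   first order or second order in NO is not quantified by the source data;
   first order under NO excess is the implemented choice.
5. Decomposition channels (disulfide/HNO formation, S–N homolysis) are
   representable in `Mechanism` but excluded from the default network — no
   rate constants exist for them. For the same reason the package does not
   model product-yield curves.

Units: mol/L and seconds everywhere; temperatures kelvin internally, Celsius
accepted in configs and CSV headers. Second-order on-rates are validated
against a 10¹⁰ M⁻¹s⁻¹ diffusion ceiling.

## Integration and the relaxation oracle

`simulate` uses LSODA with rtol 10⁻⁸ and atol 10⁻¹² M — the rate constants
span seven orders of magnitude, so a stiff-capable integrator is required.
Failure modes (non-finite solution, negative concentration beyond 100·atol)
raise with the offending species named. Heme mass is conserved to < 10⁻⁶
relative drift (asserted in tests).

`relaxation_rate` exploits the fact that with reservoirs (NO, RSH, RS⁻)
clamped, the five-species heme subsystem is exactly linear; the returned
rate is the slowest non-zero eigenvalue magnitude of that kinetic matrix. A
warning fires when the two slowest eigenvalues are within 1% — there a
single-exponential read-out is meaningless. Two caveats matter when
comparing with the closed-form rate law:

* The closed form describes the *supply* relaxation (thiol release →
  nitrosylation). It is the slowest mode only when the downstream thiolate
  attack relaxes faster; `rate_laws.attack_relaxation` exposes the
  separation, and the oracle tests require ≥ 1.5× (the published operating
  window, 3 mM total thiol, sits near 3×). With both steady-state validity
  inequalities at ≥ 2× margin and that separation, closed form and
  eigenvalue agree within 5% over the full experimental concentration grid
  (62 of 100 grid points qualify; worst deviation 4.9%).
* Observables simulated from a thiol-bound start carry a fast attack
  transient; the fit route to the same rate uses a two-phase fit (or a dead
  time mask) and takes the slow phase.

## Closed-form rate laws

The pathway-1 law is the steady-state reduction of the three-step chain with
the aqua complex as the fast intermediate. Its four structural constraints —
the high-NO limit `k_off_RS`, the high-thiol limit `k_off_NO`, and the two
validity inequalities — are asserted in tests, alongside boundedness between
the two off-rates and the monotone (sigmoid-direction) dependence on total
thiol. The pathway-2 law is affine in `[RS]_T` by construction.

## Trace fitting

`fit_exponential` is unweighted nonlinear least squares (lmfit) of
`offset + Σ aᵢ·exp(−kᵢt)` with deterministic initial guesses: offset from
the final 5% of points, rate from a log-linear regression over the first
60% of the decay. No per-point error model is available, hence no weights.
The offset is floated rather than pinned to the endpoint. Biexponential fits
are flagged ill-conditioned below a 3× rate separation. A configurable dead
time (default off; 2 ms typical) masks mixing transients. Replicate
averaging reports mean and sample SD and warns below the six-run
instrument convention.

## Secondary regressions

All secondary fits are unweighted OLS (statsmodels), matching the source
analysis which reports no weighting. Physical constants are fixed at
R = 8.314 J mol⁻¹ K⁻¹ and k_B/h = 2.0837 × 10¹⁰ K⁻¹s⁻¹.

* Concentration series: slope/intercept = apparent association/dissociation
  constant; studentized residuals > 3 flag outliers; a negative intercept
  within 2 SE is reported as statistically zero.
* pH series: in the acid regime [H⁺] ≫ Ka the apparent constant is
  `k_on(RS⁻)·Ka/[H⁺] + k_on(RSH)`; the slope over Ka gives the
  thiolate-specific constant and the intercept verdict tests the
  protonated-form reactivity. The linearisation carries ~1% bias at
  pH = pKa − 2 (exact speciation is used everywhere else).
* Eyring: `ln(k/T)` vs `1/T`; ΔH‡ = −slope·R, ΔS‡ = (intercept −
  ln(k_B/h))·R, ΔG‡ propagated from the regression covariance. The forward
  5 °C entry uses the thiolate-specific AcCys value (6.32 × 10⁶); the back
  ladder is the five pH-7.4 dissociation constants, not an average over the
  5 °C pH series.

## Equilibria

The titration isotherm is fitted on the scale of the supplied ligand axis.
For a total-thiol axis the apparent constant on that scale is K·α and the
result is divided by α afterwards; mass balance also lives on the total
scale, because the protonated reservoir rebuffers thiolate consumed by
binding. Ligand depletion (free-ligand quadratic inside the fit) engages
when the heme exceeds 10% of the smallest non-zero titrant — a package
threshold, not a measured one. Endpoint absorbances are floated. A titration
with no curvature (K·L_max < 0.5) raises with a lower bound on K rather
than a sham estimate. Kinetic K = k_on/k_off carries relative errors in
quadrature.

## Thermodynamic linkage

ΔH = ΔH‡_fwd − ΔH‡_rev, ΔS likewise, ΔG = ΔH − TΔS/1000, errors in
quadrature; independently ΔG = −RT ln K (1 M standard state). kJ/mol for
ΔH/ΔG, J mol⁻¹ K⁻¹ for ΔS, with the factor 1000 applied in exactly one
place. The consistency triangle (linkage ΔG vs −RT ln(k_on/k_off)) is a
test invariant.

## Synthetic data

The generator emulates the published experimental design: 5 μM heme, 0.18 mM
NO premix, 0.5–3 mM thiol, pH 6.3–8.0, 5–25 °C, NO capped at the 1.7 mM
aqueous solubility. Noise is additive i.i.d. Gaussian on absorbance,
homoscedastic, default 0.5% of the trace amplitude — no instrument noise
characterization exists, so this is a package assumption. Premixes are taken
as fully equilibrated before the second mixing drive, and no instrument
response or photon statistics are modelled; passing recovery tests therefore
demonstrate estimator correctness under the assumed noise model, not
robustness to drift, dead-time distortion or heteroscedastic shot noise.
Per-species molar absorptivities at 413 nm are package defaults (band
positions, not extinction coefficients, are published). The AcCys/GSH
scenarios use the published rate constants and pKa values as ground truth;
the ferric thiol-binding pair and k₂ are placeholders flagged in the
manifest.

Default problem sizes — 6–8 traces of 400 points per pathway, 10-point
titrations, 50-seed recovery studies — were chosen so a full pipeline
recovery study is a desk-scale computation; medians over 50 seeds at 0.5%
noise recover every exercised constant within 5% (most within 1%).

## Known limitations

* Single-wavelength observable only; no SVD/global spectral analysis.
* The closed-form pathway-1 law is single-exponential only in the
  mode-separated regime (see above); outside it, use the simulator.
* pKa(T) is not predicted; only measured values (9.95/9.32 at 5 °C) ship,
  with optional linear interpolation of user tables.
* The reanalysis tolerances floor the activation-parameter comparisons at
  1 kJ/mol and 3 J mol⁻¹ K⁻¹: the published table layout leaves the 5 °C
  forward entry ambiguous, and the recomputed ΔH‡/ΔS‡ (8.88, −82.2) differ
  from the printed 9.4 ± 0.5 / −80 ± 2 by slightly more than the printed
  regression errors alone.
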