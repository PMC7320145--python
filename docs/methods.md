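# Methods

This note documents the models, numerical choices, and design decisions
behind `chankin`, and what the synthetic-data tests do and do not show
about real assay data.

Units throughout: concentrations in μM (oligomer concentrations counted
per NADH-binding site — four per GAPDH or LDH tetramer), time in minutes
for kinetics and seconds for sedimentation, rates in μM·min⁻¹, specific
activities in U/mg (1 U = 1 μmol·min⁻¹).

## Binding equilibrium

Free ligand for a single-site receptor comes from the mass-balance
quadratic; the code evaluates the positive root in the cancellation-safe
conjugate form `2·Kd·N / (b + sqrt(b² + 4·Kd·N))` whenever
`b = G − N + Kd > 0` (the tight-binding regime where the naive form loses
up to half its digits), and verifies every result by back-substituting
into the mass-action law, falling back to Brent bisection on
`[0, ligand_total]` if the relative residual exceeds 1e−8.  Property
tests compare against an independent bisection oracle over a
1e−3–1e3 μM grid in all three parameters at 1e−9 relative tolerance.

One effective Kd per donor is assumed.  GAPDH's strong negative
cooperativity (site affinities spreading ~1000-fold across a tetramer) is
deliberately **not** in the default model; an optional two-class-site
mass balance (`free_ligand_two_class`) is provided for sensitivity
checks but nothing downstream uses it.

The titration isotherm is `S = S0 + ΔS · θ`, with θ the bound-**site**
fraction from the exact quadratic — required because the fluorimeter
cuvette holds ~1 μM sites, comparable to the tight donor's 0.8 μM Kd, so
ligand depletion shifts the apparent midpoint by ~half the site
concentration.  The fit is unweighted least squares (lmfit, tolerances
1e−13 so noiseless round-trips recover Kd to 1e−6); ΔS's sign is free,
accommodating quenching (negative) and FRET/anisotropy (positive)
readouts without being told.  A flat signal or one whose rank correlation
with ligand is below 0.5 is rejected as a fit failure rather than
returning a meaningless Kd.  Cross-mode aggregation is the unweighted
mean ± sample SD, matching how multi-mode determinations are usually
summarized.

## Rate extraction

Absorbance at 340 nm converts by Beer–Lambert with ε = 6220 M⁻¹cm⁻¹.
Two regimes:

- **linear** (starting NADH ≥ 30 μM): OLS slope over the initial window
  consuming ≤ 10% of the starting NADH (the window length is a package
  choice — configurable — since only the regime, not the window, is
  standard); rates are offset-invariant by construction.
- **exponential** (below 30 μM, substrate under Km from the outset):
  `c(t) = A·exp(−kt) + c∞`, v₀ = A·k, initialized by log-linear
  regression; the offset absorbs incomplete conversion, so v₀ is
  invariant to it.  The 30–40 μM gap is assigned to the linear method.

Scattering drift (slow donor precipitation at high loading) is removed by
subtracting a blank interpolated onto the sample's time grid; the blank
must cover the sample's time range.

On model-generated noiseless curves both methods recover the model's
initial steady rate within 3%; the residual bias is the genuine rate
decline across the measurement window, not an extraction artifact.

## Channeling analysis

`V_cal = Vmax·f/(Km+f)` with `f` the exact free NADH; the channeling
ratio is the plain quotient `v_measured / V_cal` (the natural reading of
"ratio between measured and calculated activity").  Uncertainty on V_cal
is first-order delta-method propagation of Vmax, Km and optionally Kd.
Negative channeled components (`v_measured < V_cal`) are retained, never
clipped, so the no-channeling null is unbiased — over 200 seeded
replicates at 2% multiplicative noise the mean ratio of channeling-off
datasets lies in [0.98, 1.02].

The channeled profile `v_ch = v_measured − V_cal` is fit to a
Michaelis–Menten law in the **donor–NADH complex** concentration
(`N − f`); a flag switches the axis to total NADH for comparison with
conventional plots — under tight binding the two are nearly identical.
A caveat the tests document explicitly: with the assay's 10–40 μM NADH
range and apparent Km values of 50–130 μM, the profile reaches only ~1/3
of saturation, so the (Vmax, Km) split is ill-conditioned under noise
even though the fitted curve through the sampled range is stable to ~15%.
Apparent Km always exceeds the free-NADH Km on model-generated data, the
qualitative signature of path competition.

The antibody competition check compares the high-antibody plateau
(accepted when the last two points agree within 10%) to V_cal; agreement
within 15% (configurable) confirms that blocking the protein–protein
interface collapses the activity onto the free-diffusion prediction.

## Transient-complex mass-action model

Species: free acceptor sites L, free donor sites G, free NADH N, the
binary complexes GN and LN, the ternary complex LGN, and product.
Reactions:

    G + N  ⇌ GN        kon_gn / koff_gn
    L + N  ⇌ LN        kon_ln / koff_ln        (diffusive capture)
    L + GN ⇌ LGN       kon_cx / koff_cx        (transient complex)
    LGN    → LN + G    k_transfer              (hand-over)
    LN     → L + NAD⁺  kcat                    (pyruvate saturating, folded in)

The acceptor–NADH pool is carried as two label pools (channeled- vs
diffusion-loaded) with identical kinetics, making the product flux
partition exact without perturbing the dynamics; NADH that dissociates
back to solution loses its label.  Subunit structure is not modeled: L
and G are independent site pools.  Pyruvate (630 μM, saturating
throughout) is folded into kcat.

Calibration (`RateConstants.from_calibration`): kcat = Vmax·M_site
(35 kDa per acceptor subunit ⇒ 4900 min⁻¹ for 140 U/mg); kon_ln from the
Briggs–Haldane identity Km = (koff_ln + kcat)/kon_ln with koff_ln = kcat
by default; koff_gn = Kd·kon_gn.  Three defaults deserve justification:

- **kon_gn = 6000 μM⁻¹min⁻¹ (1e8 M⁻¹s⁻¹)** — fast, electrostatically
  steered binding of a charged dinucleotide into a positively charged
  site; the implied NADH off-rates (80 s⁻¹ tight, 820 s⁻¹ weak) are in
  the range where hand-over can compete with turnover.  With the generic
  1.7e6 M⁻¹s⁻¹ protein default the off-rates would be so slow that the
  ternary complex acts as a net inhibitor.
- **k_transfer = koff_gn** — hand-over inside the ternary complex *is*
  the donor's NADH-release event, captured by the adjacent acceptor site
  instead of escaping; tying the two rates is what lets the model express
  the off-rate-overlap mechanism at all.
- **koff_cx = 3e5 min⁻¹ (0.2 ms complex lifetime), kon_cx = 300
  μM⁻¹min⁻¹** — a genuinely transient encounter complex (Kd ≈ 1 mM,
  invisible to sedimentation, consistent with the one-component AUC
  fits), in the regime where hand-over probability per encounter,
  k_transfer/(k_transfer + koff_cx), stays roughly linear in the donor
  off-rate.

With these conditions the model reproduces, qualitatively: ratios rising
along donor titrations and as NADH falls; measured/calculated ratios of
~1.1–1.5 for the tight donor (0.8 μM) at 100–240 μM sites and ~1.3–2.0
for the weak donor (8.2 μM) at its 240–480 μM design; apparent channeled
Km of ~40–130 μM ≫ the 4.4 μM free-NADH Km; and channeled-path effective
turnover always below the diffusive kcat (the extra hand-over step always
costs — they converge only as k_transfer → ∞).

One structural fact worth recording: at a *fixed* assay condition the
channeled **fraction** of product necessarily falls as the donor off-rate
rises with Kd uncompensated — per free acceptor site the diffusive flux
grows linearly with free NADH (∝ Kd) while hand-over probability
saturates.  The off-rate-overlap effect proper appears when Kd is held
fixed (kon compensating): then the channeled fraction rises monotonically
with koff_gn, and `offrate_sweep` defaults to that mode.  The
weak-donor > tight-donor contrast seen in measured *ratios* arises from
the combination of off-rate-driven hand-over and the weak donor's
higher-site-concentration design, which is how the package's tests assert
it.

Integration: BDF with analytic Jacobian, rtol 1e−8, atol 1e−12 μM;
trajectories are checked for L/G/N pool conservation (1e−6 relative) and
nonnegativity (−1e−10 floor).  Steady rates pre-equilibrate the binding
steps with turnover off (as the assay incubates donor and NADH before
adding acceptor), then switch turnover on and fit the product slope over
the second half of a window consuming 1% of the NADH — past the
~10⁻⁴ min occupancy transient but before substrate depletion bends the
trace.

## Sedimentation velocity

The Lamm equation in a sector cell is solved Claverie-style: linear
finite elements on a uniform radial grid (default 500 points over the
5.9–7.2 cm column of a standard 12-mm double-sector cell), consistent
mass and stiffness matrices with the sector weight `r`, zero-flux
boundaries (mass conservation is then exact in the weak form; observed
drift < 1e−5), Crank–Nicolson in time with a banded solve per step, and
an automatic step of `min(10 s, Δr/2u)` at the maximum sedimentation
velocity `u = sω²r_b`.  A cell-Péclet diagnostic (`uΔr/D > 2`) rejects
grids too coarse for the centrally weighted elements rather than
producing oscillatory profiles.  The rotor speed must be given in rpm
(default 23,000, which delivers ≈40,000 g at mid-cell; a relative
centrifugal force alone does not determine a speed — `rpm_from_rcf`
makes the conversion explicit).  Diffusion follows from the Svedberg
relation D = sRT/(M(1 − v̄ρ)).

Validation: agreement with the Faxén boundary-free approximation within
1% of loading at mid-cell after 4 h; 2× grid refinement changes profiles
by < 0.5% of the local signal (the thin accumulation layer at the base
reaches tens of times the loading, so a loading-relative criterion is
applied only over the optically observable column).

Single-species fitting runs nonlinear least squares over (s, Mr,
loading) with the solver as forward model on a coarser 200-point grid
for speed; on noiseless data the inversion recovers parameters within
1%, at 1% Gaussian noise within 3%.  The self-association detectability
analysis simulates a mixture with a fraction of the signal as a compact
dimer (2× mass, s scaled by 2^(2/3)), exploiting the equation's
linearity, and compares the model separation against the single-species
residual floor; the mass-action identity
Kd = (A−c)(B−c)/c with c = fraction·min(A,B) converts a just-detectable
fraction into an interaction bound (10% association of a 6 μM + 6 μM
mixture ⇒ Kd = 48.6 μM).

## Synthetic data

Generators emulate: four-mode fluorescence titrations (12 points,
log-spaced kd/16–12.5·kd around the true value, 1 μM sites);
enzyme-buffering grids driven by the mass-action model (donor sites
100–240 μM tight / 240–480 μM weak at 40 μM NADH, or NADH 10–40 μM at
fixed donor, acceptor at 10 nM); progress curves (total reduced NADH →
absorbance, optional linear scattering drift with its matching blank);
antibody competition series (single-site occupancy removes the channeled
path, scales the free path by 1 − α·occupancy with small α); and
sedimentation scans at 30 μm radial increments every 240 s over 7 h.

Noise is multiplicative Gaussian at 2% of signal by default (routine
assay precision of a few percent); scan noise is additive at
noise_sd·loading, the natural model for absorbance optics.  All
randomness derives from a single integer seed through independent named
streams, so outputs are byte-identical under a fixed seed and every
generator's noiseless output is exactly inverted by its analysis stage.

What passing these tests does **not** show about real data: the
generators share their forward models with the analysis, so round-trip
tests verify internal consistency, numerical correctness, and noise
robustness — not the adequacy of the single-Kd binding model, the
lumped hand-over mechanism, or the absence of instrument artifacts
(lamp flicker, radial calibration error, inner-filter effects), none of
which are emulated.

## Problem sizes

Defaults are sized so a full test run (ODE trajectories for every design,
200 null-control replicates, three Lamm-solver fits) completes in well
under a minute on one core: 8-point assay grids, 41-point steady-rate
windows, 500-point radial grids with ~10 s time steps, 11 scans per
sedimentation run.  All are parameters, not constants.
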