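# chankin

Analysis toolkit for **enzyme-buffering substrate-channeling assays**, built
around NADH transfer from glyceraldehyde-3-phosphate dehydrogenase (GAPDH,
the donor) to lactate dehydrogenase (LDH, the acceptor).

## The problem

In cytosol-mimicking conditions almost every NADH molecule is bound to
GAPDH, the most abundant dehydrogenase. If LDH can only use *free* NADH,
its steady-state activity is fully predicted by two measured quantities:
the GAPDH–NADH dissociation constant and LDH's Michaelis–Menten constants.
Free NADH follows from the exact single-site mass balance (ligand depletion
included, since donor sites far exceed both NADH and K_D):

    [NADH]_free = ( -(G - N + K_D) + sqrt((G - N + K_D)^2 + 4 K_D N) ) / 2

with `G` the donor site concentration, `N` total NADH (both μM, sites
counted per subunit).  The predicted free-diffusion activity is

    V_cal = V_max [NADH]_free / (K_M + [NADH]_free)

and the **channeling ratio** `R = v_measured / V_cal` is the statistic of
interest: `R ≈ 1` means diffusive delivery only; `R > 1` means LDH also
draws NADH directly from the GAPDH–NADH complex — substrate channeling
through a transient LDH-(GAPDH–NADH) complex.

The package implements every stage of that analysis plus its two supports:

- `binding_equilibrium` — exact tight-binding free-ligand arithmetic and
  K_D estimation from fluorescence titrations (four detection modes,
  depletion-corrected isotherm);
- `rate_extraction` — initial steady-state rates from 340 nm progress
  curves (linear and exponential regimes, scattering-blank subtraction);
- `channeling` — V_cal, channeling ratios, channeled-profile subtraction,
  apparent Michaelis constants for the complex substrate, and the antibody
  competition diffusion-limit check;
- `transient_complex` — a mass-action ODE model of the parallel channeled
  and diffusive paths (hand-over inside a short-lived ternary complex),
  with flux partitioning and off-rate sweeps;
- `sedimentation` — a Claverie-type finite-element Lamm-equation solver,
  single-species (s, Mr) fitting, and the self-association detectability
  bound for sedimentation-velocity runs;
- `synthetic` — seeded generators for every input family, driven by the
  mass-action model, so the whole pipeline is testable without instrument
  data;
- `pipeline` / `cli` — YAML-configured end-to-end runs and the `chankin`
  command line.

## Worked example

Generate a synthetic NADH titration (donor sites fixed at 200 μM, NADH
10→40 μM, 2% assay noise, channeling on) and analyze it:

```python
from chankin import synthetic as syn
from chankin.channeling import channeled_profile

spec = syn.GeneratorSpec(seed=11)          # tight-binding donor, Kd 0.8 uM
dataset = syn.gen_buffering_dataset(spec, "titrate_nadh_fixed_gapdh")
result = channeled_profile(dataset)
```

which prints, per assay point:

```
 NADH_uM  free_uM  v_meas   v_cal  ratio
    10.0    0.042    1.95    1.32   1.48
    14.0    0.060    2.84    1.88   1.51
    18.0    0.079    3.61    2.46   1.47
    22.0    0.098    4.54    3.06   1.48
    26.0    0.119    5.31    3.68   1.44
    30.0    0.140    6.15    4.33   1.42
    35.0    0.169    7.07    5.17   1.37
    40.0    0.199    8.15    6.05   1.35
apparent channeled-path constants: Vmax = 6.0 U/mg, Km = 73 uM (free-NADH Km: 4.4 uM)
```

Reading the columns: at 200 μM donor sites only 0.04–0.2 μM NADH is free,
so the free-diffusion prediction `v_cal` is small; the measured rates sit
35–50% above it (`ratio` > 1, growing as NADH drops), and subtracting the
free-diffusion profile leaves a channeled component whose apparent K_M for
the donor–NADH complex (~70 μM) is far above the 4.4 μM free-NADH K_M —
the signature of competition between the channeled and diffusive paths.
With the complex path disabled (`channeling=False`) the same pipeline
returns ratios of 1.00 within noise.

The same stages are scriptable from the shell, e.g.

```sh
chankin generate buffering --seed 1 --out buffering.csv --design titrate_nadh_fixed_gapdh
chankin analyze buffering.csv --config assay.yaml --out results/
chankin fit-kd titration_*.csv --out kd_table.csv
chankin auc simulate --config cell.yaml --out scans.csv
```

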