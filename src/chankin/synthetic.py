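"""Seeded generators for every input family the analysis consumes.

Each generator emulates one assay type at the conditions the analysis is
designed for — fluorescence titrations across four detection modes,
enzyme-buffering rate grids driven by the mass-action channeling model,
absorbance progress curves, antibody competition series, and sedimentation
scans — with multiplicative Gaussian noise (default 2% of signal, matching
routine assay precision of a few percent).  All randomness flows from the
single seed in the spec; a fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import transient_complex as tc
from .binding_equilibrium import (
    FluorescenceTitration,
    TITRATION_MODES,
    bound_site_fraction,
)
from .channeling import AssayPoint, BufferingDataset, MichaelisParams
from .errors import InvalidInputError
from .rate_extraction import NADH_EPSILON_340, ProgressCurve
from .sedimentation import RadialScan, SedimentationParams, simulate_lamm

__all__ = [
    "GeneratorSpec",
    "AntibodySeries",
    "ProgressCurveSet",
    "gen_titration",
    "gen_buffering_dataset",
    "gen_progress_curves",
    "gen_antibody_series",
    "gen_scans",
    "steady_rates_for_design",
]

#: Per-mode (baseline, amplitude) of the titration signal; quenching modes
#: lose signal on binding, FRET and anisotropy gain it.
_MODE_SIGNAL = {
    "protein_quench": (100.0, -40.0),
    "ligand_quench": (80.0, -30.0),
    "fret": (10.0, 50.0),
    "anisotropy": (0.05, 0.15),
}


def _default_mm() -> MichaelisParams:
    # acceptor constants for free NADH at saturating (630 μM) pyruvate
    return MichaelisParams(vmax=140.0, km=4.4, vmax_err=20.0, km_err=0.4)


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth and design grids for all generators.

    Defaults describe the tight-binding donor experiment: Kd 0.8 μM,
    donor sites titrated 100-240 μM at 40 μM NADH, or NADH titrated
    10-40 μM at 200 μM donor sites, acceptor at 10 nM.
    """

    seed: int = 0
    noise_sd: float = 0.02  # relative, multiplicative
    true_kd: float = 0.8  # μM, donor-NADH
    true_mm: MichaelisParams = field(default_factory=_default_mm)
    true_rates: tc.RateConstants | None = None  # derived from kd/mm when None
    ldh_nM: float = 10.0
    titration_site_conc: float = 1.0  # μM sites in the fluorimeter cuvette
    titration_n_points: int = 12
    gapdh_sites_grid: tuple[float, ...] = (100.0, 120.0, 140.0, 160.0, 180.0, 200.0, 220.0, 240.0)
    nadh_grid: tuple[float, ...] = (10.0, 14.0, 18.0, 22.0, 26.0, 30.0, 35.0, 40.0)
    fixed_nadh: float = 40.0
    fixed_gapdh_sites: float = 200.0
    antibody_grid_nM: tuple[float, ...] = (0.0, 15.0, 30.0, 60.0, 125.0, 250.0, 500.0, 750.0, 1000.0)
    scan_times_s: tuple[float, ...] = tuple(float(t) for t in range(1200, 25201, 2400))

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be nonnegative")
        if self.true_kd <= 0:
            raise InvalidInputError("true_kd must be positive")

    @classmethod
    def weak_donor(cls, seed: int = 0, **overrides) -> "GeneratorSpec":
        """The weak-binding donor experiment: Kd 8.2 μM, sites 240-480 μM.

        Mirrors the yeast-donor design, where the ten-fold weaker NADH
        affinity forces higher site concentrations to keep NADH bound.
        """
        defaults = dict(
            true_kd=8.2,
            gapdh_sites_grid=(240.0, 280.0, 320.0, 360.0, 400.0, 440.0, 480.0),
            fixed_gapdh_sites=480.0,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    @property
    def rates(self) -> tc.RateConstants:
        if self.true_rates is not None:
            return self.true_rates
        return tc.RateConstants.from_calibration(self.true_kd, self.true_mm)

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for one output stream of this spec."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _noisy(rng: np.random.Generator, values: np.ndarray, noise_sd: float) -> np.ndarray:
    if noise_sd == 0:
        return values.copy()
    return values * (1.0 + noise_sd * rng.standard_normal(values.shape))


def gen_titration(spec: GeneratorSpec, mode: str) -> FluorescenceTitration:
    """One fluorescence titration: signal tracks exact bound-site fraction."""
    if mode not in TITRATION_MODES:
        raise InvalidInputError(f"unknown titration mode {mode!r}")
    rng = spec.rng(stream=1 + TITRATION_MODES.index(mode))
    ligand = np.geomspace(spec.true_kd / 16.0, spec.true_kd * 12.5, spec.titration_n_points)
    s0, ds = _MODE_SIGNAL[mode]
    frac = bound_site_fraction(spec.titration_site_conc, ligand, spec.true_kd)
    signal = _noisy(rng, s0 + ds * frac, spec.noise_sd)
    return FluorescenceTitration(
        mode=mode, site_conc=spec.titration_site_conc,
        ligand_concs=ligand, signals=signal,
    )


def steady_rates_for_design(
    spec: GeneratorSpec, design: str, *, channeling: bool = True
) -> tuple[list[AssayPoint], np.ndarray]:
    """Noiseless assay points and model rates for one titration design.

    Exposed separately so replicate studies can reuse the (expensive)
    noiseless rates and redraw only the noise.
    """
    constants = spec.rates if channeling else spec.rates.without_channeling()
    ldh_sites = spec.ldh_nM * 1e-3  # nM acceptor ≈ μM sites × 1e-3
    if design == "titrate_gapdh_fixed_nadh":
        grid = [(g, spec.fixed_nadh) for g in spec.gapdh_sites_grid]
    elif design == "titrate_nadh_fixed_gapdh":
        grid = [(spec.fixed_gapdh_sites, n) for n in spec.nadh_grid]
    else:
        raise InvalidInputError(f"unknown design {design!r}")
    points, rates = [], []
    for gapdh, nadh in grid:
        v = tc.steady_rate(constants, ldh_sites, gapdh, nadh)
        rates.append(v)
        points.append(
            AssayPoint(
                nadh_total=nadh, gapdh_sites=gapdh, ldh_conc=spec.ldh_nM,
                v_measured=v, kd_gapdh=spec.true_kd,
            )
        )
    return points, np.asarray(rates)


def gen_buffering_dataset(
    spec: GeneratorSpec,
    design: str,
    *,
    channeling: bool = True,
    base: tuple[list[AssayPoint], np.ndarray] | None = None,
) -> BufferingDataset:
    """A noisy enzyme-buffering dataset driven by the mass-action model."""
    if base is None:
        base = steady_rates_for_design(spec, design, channeling=channeling)
    points, rates = base
    rng = spec.rng(stream=2000 + (0 if design == "titrate_gapdh_fixed_nadh" else 1))
    noisy = _noisy(rng, rates, spec.noise_sd)
    noisy_points = tuple(
        replace(p, v_measured=float(v)) for p, v in zip(points, noisy)
    )
    return BufferingDataset(design=design, points=noisy_points, acceptor_mm=spec.true_mm)


@dataclass(frozen=True)
class ProgressCurveSet:
    """A generated progress curve, its blank, and the model's true t=0 rate."""

    curve: ProgressCurve
    blank: ProgressCurve | None
    true_v0_uM_min: float  # μM/min NADH oxidation at t = 0


def gen_progress_curves(
    spec: GeneratorSpec,
    *,
    nadh_total: float | None = None,
    gapdh_sites: float | None = None,
    duration_min: float = 0.5,
    n_points: int = 151,
    drift_abs_per_min: float = 0.0,
    path_length: float = 1.0,
) -> ProgressCurveSet:
    """Absorbance progress curve from a model trajectory.

    Total reduced NADH (free plus protein-bound) carries the 340 nm signal;
    an optional linear scattering drift emulates slow donor precipitation
    at high loading, with the matching blank returned for subtraction.
    """
    nadh = spec.fixed_nadh if nadh_total is None else nadh_total
    gapdh = spec.fixed_gapdh_sites if gapdh_sites is None else gapdh_sites
    constants = spec.rates
    ldh_sites = spec.ldh_nM * 1e-3
    eq = tc.equilibrate(constants, tc.initial_state(ldh_sites, gapdh, nadh))
    net = tc.build_scheme(constants)
    times = np.linspace(0.0, duration_min, n_points)
    traj = tc.simulate(net, eq, duration_min, t_eval=times)
    reduced = nadh - traj.series("product")
    # the extractable truth: the post-transient initial steady rate, volumetric
    v0 = tc.steady_rate(constants, ldh_sites, gapdh, nadh) * ldh_sites * tc.LDH_SITE_KDA
    absorbance = reduced * 1e-6 * NADH_EPSILON_340 * path_length
    drift = drift_abs_per_min * times
    rng = spec.rng(stream=3000)
    noisy_abs = _noisy(rng, absorbance, spec.noise_sd) + drift
    curve = ProgressCurve(times=times, absorbance=noisy_abs, path_length=path_length)
    blank = None
    if drift_abs_per_min != 0.0:
        blank = ProgressCurve(times=times, absorbance=drift, path_length=path_length)
    return ProgressCurveSet(curve=curve, blank=blank, true_v0_uM_min=v0)


@dataclass(frozen=True)
class AntibodySeries:
    """Antibody competition series plus the condition it was measured at."""

    antibody_nM: np.ndarray
    v_measured: np.ndarray  # U/mg
    point: AssayPoint  # zero-antibody condition
    mm: MichaelisParams


def gen_antibody_series(
    spec: GeneratorSpec,
    *,
    antibody_kd_nM: float = 20.0,
    alpha_free_path: float = 0.1,
) -> AntibodySeries:
    """Competition series: antibody occupancy removes the channeled path.

    Bulky antibodies block the donor-acceptor interface: the channeled flux
    scales with (1 - occupancy) while the free-NADH path is only slightly
    hindered, by (1 - alpha·occupancy) with small alpha.  Occupancy follows
    a single-site hyperbola in antibody concentration (antibody in excess
    over the 10-20 nM acceptor).
    """
    constants = spec.rates
    ldh_sites = spec.ldh_nM * 1e-3
    gapdh, nadh = spec.fixed_gapdh_sites, spec.fixed_nadh
    v_total = tc.steady_rate(constants, ldh_sites, gapdh, nadh)
    traj = tc._run_to_conversion(constants, ldh_sites, gapdh, nadh, 0.02)
    frac_chan = tc.flux_partition(traj).channeled_fraction
    v_chan, v_free = v_total * frac_chan, v_total * (1.0 - frac_chan)
    ab = np.asarray(spec.antibody_grid_nM, float)
    occupancy = ab / (ab + antibody_kd_nM)
    v = v_chan * (1.0 - occupancy) + v_free * (1.0 - alpha_free_path * occupancy)
    rng = spec.rng(stream=4000)
    v = _noisy(rng, v, spec.noise_sd)
    point = AssayPoint(
        nadh_total=nadh, gapdh_sites=gapdh, ldh_conc=spec.ldh_nM,
        v_measured=float(v[0]), kd_gapdh=spec.true_kd,
    )
    return AntibodySeries(antibody_nM=ab, v_measured=v, point=point, mm=spec.true_mm)


def gen_scans(
    spec: GeneratorSpec,
    params: SedimentationParams,
    *,
    radial_increment_cm: float = 0.003,
) -> list[RadialScan]:
    """Sedimentation scans: Lamm solver output plus noise at 30 μm steps."""
    n_radial = int(round((params.bottom - params.meniscus) / radial_increment_cm)) + 1
    clean = simulate_lamm(params, spec.scan_times_s, n_radial=n_radial)
    rng = spec.rng(stream=5000)
    out = []
    for sc in clean:
        noise = spec.noise_sd * params.loading * rng.standard_normal(sc.signal.shape)
        out.append(RadialScan(time=sc.time, radii=sc.radii, signal=sc.signal + noise))
    return out
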