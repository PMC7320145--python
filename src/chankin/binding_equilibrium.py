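"""Single-site tight-binding equilibrium and Kd estimation from titrations.

All concentrations are in μM and, for the oligomeric dehydrogenases handled
here, are expressed *per NADH-binding site* (a GAPDH or LDH tetramer carries
four sites).  The central primitive is the exact mass-balance solution for
free ligand when a receptor at site concentration ``G`` binds a ligand at
total concentration ``N`` with dissociation constant ``Kd``::

    complex**2 - (G + N + Kd) * complex + G * N = 0

solved for the free-ligand root

    free = ( -(G - N + Kd) + sqrt((G - N + Kd)**2 + 4 * Kd * N) ) / 2

Ligand depletion is never neglected: in enzyme-buffering assays the site
concentration (100-480 μM) exceeds both the ligand (10-40 μM) and Kd
(0.8-8.2 μM), the "tight-binding" regime where the hyperbolic isotherm is
badly wrong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import lmfit
from scipy.optimize import brentq
from scipy.stats import spearmanr

from .errors import FitFailureError, InvalidInputError, UndefinedFractionError

__all__ = [
    "LigandBindingSystem",
    "FluorescenceTitration",
    "KdEstimate",
    "TITRATION_MODES",
    "free_ligand",
    "free_ligand_quadratic",
    "free_ligand_two_class",
    "bound_fraction",
    "bound_site_fraction",
    "fit_binding_isotherm",
    "aggregate_kd",
    "sites_from_tetramer",
    "tetramer_from_sites",
]

#: Detection modes used to read out NADH binding fluorimetrically.
TITRATION_MODES = ("protein_quench", "ligand_quench", "fret", "anisotropy")

SITES_PER_TETRAMER = 4


def sites_from_tetramer(tetramer_uM: float, n_sites: int = SITES_PER_TETRAMER) -> float:
    """Convert a tetramer concentration to NADH-binding-site concentration."""
    return tetramer_uM * n_sites


def tetramer_from_sites(sites_uM: float, n_sites: int = SITES_PER_TETRAMER) -> float:
    """Convert a site concentration back to tetramer concentration."""
    return sites_uM / n_sites


@dataclass(frozen=True)
class LigandBindingSystem:
    """One single-site binding equilibrium.

    Parameters
    ----------
    site_total : float
        Receptor concentration in μM of NADH-binding sites.
    ligand_total : float
        Total ligand (NADH) concentration, μM.
    kd : float
        Dissociation constant, μM (> 0).
    """

    site_total: float
    ligand_total: float
    kd: float

    def __post_init__(self) -> None:
        if self.site_total < 0 or self.ligand_total < 0:
            raise InvalidInputError(
                f"concentrations must be nonnegative, got site_total="
                f"{self.site_total}, ligand_total={self.ligand_total}"
            )
        if not self.kd > 0:
            raise InvalidInputError(f"kd must be positive, got {self.kd}")


def free_ligand_quadratic(
    site_total, ligand_total, kd, *, check_tol: float = 1e-8
):
    """Vectorised exact free-ligand concentration (μM).

    Uses the cancellation-safe conjugate form when ``site_total - ligand_total
    + kd > 0`` (the regime where naive subtraction loses precision) and falls
    back to bisection on any element whose back-substituted mass-action
    residual exceeds ``check_tol`` relative.
    """
    g = np.asarray(site_total, dtype=float)
    n = np.asarray(ligand_total, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(g < 0) or np.any(n < 0):
        raise InvalidInputError("negative concentration in free_ligand")
    if np.any(kd <= 0):
        raise InvalidInputError("kd must be positive")

    b = g - n + kd
    disc = b * b + 4.0 * kd * n
    sqrt_disc = np.sqrt(disc)
    # root = (-b + sqrt(disc)) / 2; multiply by conjugate when b > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        conj = 2.0 * kd * n / (b + sqrt_disc)
    direct = 0.5 * (sqrt_disc - b)
    free = np.where(b > 0, conj, direct)
    free = np.where(n == 0, 0.0, free)

    # Residual of site_free * ligand_free - kd * complex, on the scale kd * n.
    complex_ = n - free
    resid = free * (g - complex_) - kd * complex_
    scale = np.maximum(kd * n, np.finfo(float).tiny)
    bad = np.abs(resid) / scale > check_tol

    if np.any(bad):
        flat_free = np.atleast_1d(free).ravel()
        flat_g = np.broadcast_to(g, flat_free.shape).ravel()
        flat_n = np.broadcast_to(n, flat_free.shape).ravel()
        flat_kd = np.broadcast_to(kd, flat_free.shape).ravel()
        for i in np.nonzero(np.atleast_1d(bad).ravel())[0]:
            gi, ni, ki = flat_g[i], flat_n[i], flat_kd[i]

            def f(x, gi=gi, ni=ni, ki=ki):
                return x * (gi - ni + x) - ki * (ni - x)

            flat_free[i] = 0.0 if ni == 0 else brentq(f, 0.0, ni, xtol=1e-15, rtol=1e-14)
        free = flat_free.reshape(np.shape(free)) if np.ndim(free) else flat_free[0]
    return free if np.ndim(free) else float(free)


def free_ligand(system: LigandBindingSystem) -> float:
    """Free ligand concentration (μM) for one binding system."""
    return float(
        free_ligand_quadratic(system.site_total, system.ligand_total, system.kd)
    )


def bound_fraction(system: LigandBindingSystem) -> float:
    """Fraction of total ligand bound, in [0, 1]."""
    if system.ligand_total == 0:
        raise UndefinedFractionError("bound fraction undefined at zero total ligand")
    free = free_ligand(system)
    frac = (system.ligand_total - free) / system.ligand_total
    return float(min(max(frac, 0.0), 1.0))


def bound_site_fraction(site_total, ligand_total, kd):
    """Fraction of receptor *sites* occupied (vectorised over ligand_total)."""
    g = np.asarray(site_total, dtype=float)
    if np.any(g <= 0):
        raise InvalidInputError("site_total must be positive for site occupancy")
    free = free_ligand_quadratic(site_total, ligand_total, kd)
    return (np.asarray(ligand_total, dtype=float) - free) / g


def free_ligand_two_class(
    site_totals: Sequence[float],
    kds: Sequence[float],
    ligand_total: float,
) -> float:
    """Free ligand with two independent site classes (optional extension).

    Models a receptor whose sites split into pools with distinct affinities
    (e.g. strong negative cooperativity across an oligomer).  The default
    analysis elsewhere in the package uses one effective Kd; this helper is
    provided for sensitivity checks and is not used by the main pipeline.
    """
    if len(site_totals) != 2 or len(kds) != 2:
        raise InvalidInputError("exactly two site classes expected")
    g1, g2 = (float(x) for x in site_totals)
    k1, k2 = (float(x) for x in kds)
    if min(g1, g2) < 0 or ligand_total < 0 or min(k1, k2) <= 0:
        raise InvalidInputError("invalid two-class parameters")
    if ligand_total == 0:
        return 0.0

    def mass_balance(free):
        bound = g1 * free / (k1 + free) + g2 * free / (k2 + free)
        return free + bound - ligand_total

    return float(brentq(mass_balance, 0.0, ligand_total, xtol=1e-15, rtol=1e-14))


@dataclass(frozen=True)
class FluorescenceTitration:
    """A ligand-into-receptor fluorescence titration at fixed site concentration."""

    mode: str
    site_conc: float
    ligand_concs: np.ndarray
    signals: np.ndarray
    excitation_nm: float | None = None
    emission_nm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand_concs", np.asarray(self.ligand_concs, float))
        object.__setattr__(self, "signals", np.asarray(self.signals, float))
        if self.mode not in TITRATION_MODES:
            raise InvalidInputError(f"unknown titration mode {self.mode!r}")
        if len(self.ligand_concs) != len(self.signals) or len(self.signals) < 5:
            raise InvalidInputError("need >= 5 matched (ligand, signal) points")
        if np.any(np.diff(self.ligand_concs) <= 0) or self.ligand_concs[0] < 0:
            raise InvalidInputError("ligand_concs must be nonnegative, strictly increasing")
        if self.site_conc <= 0:
            raise InvalidInputError("site_conc must be positive")


@dataclass(frozen=True)
class KdEstimate:
    """Result of one isotherm fit."""

    kd: float
    stderr: float
    mode: str
    fit_residual: float

    def __post_init__(self) -> None:
        if not self.kd > 0 or self.stderr < 0:
            raise InvalidInputError("kd must be > 0 and stderr >= 0")


def fit_binding_isotherm(titration: FluorescenceTitration) -> KdEstimate:
    """Fit ``signal = S0 + dS * bound_site_fraction`` for Kd.

    The bound-site fraction comes from the exact depletion-corrected
    quadratic, so the fit remains valid when ``site_conc`` is comparable to
    or larger than Kd.  The sign of ``dS`` is free: quenching modes fit with
    negative amplitude, FRET/anisotropy with positive, without being told.

    Raises
    ------
    FitFailureError
        If the signal carries no ligand-dependent variation or the optimiser
        cannot separate amplitude from affinity.
    """
    y = titration.signals
    x = titration.ligand_concs
    span = float(np.ptp(y))
    noise_scale = max(abs(float(np.mean(y))), 1.0)
    if span == 0.0 or span < 1e-12 * noise_scale:
        raise FitFailureError(
            f"{titration.mode}: signal is flat (range {span:g}); no binding information"
        )
    rho = spearmanr(x, y).statistic
    if not math.isfinite(rho) or abs(rho) < 0.5:
        raise FitFailureError(
            f"{titration.mode}: signal does not vary monotonically with ligand "
            f"(rank correlation {rho:.2f}); not a binding isotherm"
        )

    model = lmfit.Model(
        lambda ligand, s0, ds, kd: s0
        + ds * bound_site_fraction(titration.site_conc, ligand, kd),
        independent_vars=["ligand"],
    )
    params = model.make_params(
        s0=float(y[0]),
        ds=float(y[-1] - y[0]),
        kd=dict(value=float(np.median(x)), min=1e-9, max=1e9),
    )
    try:
        result = model.fit(
            y, params, ligand=x,
            fit_kws={"xtol": 1e-13, "ftol": 1e-13, "gtol": 1e-13},
        )
    except Exception as exc:  # lmfit wraps scipy failures variously
        raise FitFailureError(f"{titration.mode}: isotherm fit failed: {exc}") from exc

    if not result.success or not math.isfinite(result.params["kd"].value):
        raise FitFailureError(f"{titration.mode}: isotherm fit did not converge")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum(result.residual**2))
    if ss_tot > 0 and ssr > 0.9 * ss_tot:
        raise FitFailureError(
            f"{titration.mode}: model explains <10% of signal variance "
            f"(SSR {ssr:.3g} vs total {ss_tot:.3g}); signal not monotone in binding"
        )
    kd = float(result.params["kd"].value)
    stderr = float(result.params["kd"].stderr or 0.0)
    return KdEstimate(kd=kd, stderr=stderr, mode=titration.mode, fit_residual=ssr)


def aggregate_kd(estimates: Sequence[KdEstimate]) -> tuple[float, float]:
    """Unweighted mean and sample SD of Kd across detection modes."""
    if len(estimates) < 2:
        raise InvalidInputError("need at least two Kd estimates to aggregate")
    values = np.array([e.kd for e in estimates], dtype=float)
    return float(values.mean()), float(values.std(ddof=1))
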