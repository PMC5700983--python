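"""Quantitative binding analysis.

The core model is the ligand-depletion (quadratic) single-site isotherm:
with labelled protein at a concentration comparable to Kd, the fraction of
protein bound at total ligand concentration [l] is the root of the mass-
action quadratic rather than the simple hyperbola:

    f(l) = Unbound + (Bound - Unbound)
           * ((l + P + Kd) - sqrt((l + P + Kd)^2 - 4 l P)) / (2 P)

Thermophoresis (MST) dilution series are fitted per replicate; the reported
Kd is the mean over replicates and its error the sample standard deviation
("esd"). A "no binding detected" (NBD) call is made when the fitted
amplitude is indistinguishable from noise or the fitted Kd exceeds the
highest tested concentration. Single-site ITC titrations are fitted with
the standard displaced-volume correction. Redox-coupled free energies use
Delta-G = -n F Delta-E.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingCurve",
    "Eq1Params",
    "BindingFit",
    "ItcTitration",
    "ItcFit",
    "RedoxCouple",
    "BindingError",
    "FARADAY_KJ_PER_V",
    "eq1_model",
    "fit_mst",
    "itc_forward",
    "fit_itc",
    "selectivity_ratio",
    "redox_delta_g",
]

#: Faraday constant in kJ mol^-1 V^-1.
FARADAY_KJ_PER_V = 96.485

#: Final labelled-protein concentration in the standard MST protocol
#: (100 nM labelled protein mixed 1:1 with the ligand series).
DEFAULT_MST_PROTEIN_CONC = 50e-9


class BindingError(ValueError):
    """Raised for invalid binding data or failed fits."""


@dataclass
class BindingCurve:
    """One MST dilution series: matched ligand concentrations (M, strictly
    monotone) and signals, at a known final protein concentration."""

    ligand_conc: np.ndarray
    signal: np.ndarray
    replicate_id: int = 0
    protein_conc: float = DEFAULT_MST_PROTEIN_CONC

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ligand_conc.shape != self.signal.shape or self.ligand_conc.ndim != 1:
            raise BindingError("ligand_conc and signal must be matched 1-D arrays")
        if self.ligand_conc.size < 8:
            raise BindingError("need >= 8 titration points")
        if np.any(self.ligand_conc <= 0):
            raise BindingError("ligand concentrations must be strictly positive")
        d = np.diff(self.ligand_conc)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise BindingError("ligand concentrations must be strictly monotone")
        if self.protein_conc <= 0:
            raise BindingError("protein_conc must be positive")


@dataclass
class Eq1Params:
    """Parameters of the quadratic single-site isotherm."""

    Kd: float
    Bound: float
    Unbound: float

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise BindingError("Kd must be positive")


@dataclass
class BindingFit:
    """Replicate-wise MST fit: per-replicate Kd values, their mean and
    sample standard deviation, pooled amplitude, and the NBD flag."""

    per_replicate_Kd: list[float]
    Kd_mean: float
    Kd_esd: float
    amplitude: float
    nbd: bool
    max_tested_conc: float
    n_failed: int = 0

    def report_kd(self) -> str:
        """Kd as printed in an affinity table (NBD as a lower bound)."""
        if self.nbd:
            return f"> {self.max_tested_conc * 1e6:g} uM"
        return f"{self.Kd_mean * 1e6:.3g} +/- {self.Kd_esd * 1e6:.2g} uM"


@dataclass
class ItcTitration:
    """An ITC experiment: syringe ligand titrated into the sample cell."""

    cell_protein_conc: float
    syringe_ligand_conc: float
    cell_volume: float  # microlitres
    injection_volumes: np.ndarray  # microlitres
    heats: np.ndarray  # microjoules per injection
    skip_first: bool = True

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.injection_volumes.shape != self.heats.shape:
            raise BindingError("injection_volumes and heats must be matched")
        if np.any(self.injection_volumes <= 0) or self.cell_volume <= 0:
            raise BindingError("volumes must be positive")
        if self.cell_protein_conc <= 0 or self.syringe_ligand_conc <= 0:
            raise BindingError("concentrations must be positive")


@dataclass
class ItcFit:
    """Single-site ITC fit with standard errors from the fit covariance."""

    Kd: float
    Kd_se: float
    dH: float  # kJ/mol
    dH_se: float
    n_sites: float
    n_sites_se: float
    residual_sd: float


@dataclass(frozen=True)
class RedoxCouple:
    """A two-half-reaction couple: electrons flow from the donor couple
    (more negative standard potential) to the acceptor."""

    E_donor: float  # volts
    E_acceptor: float  # volts
    n_electrons: int = 2

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise BindingError("n_electrons must be >= 1")


def eq1_model(
    ligand_conc: float | np.ndarray,
    params: Eq1Params,
    protein_conc: float,
) -> float | np.ndarray:
    """Quadratic single-site depletion isotherm.

    Exact fraction-bound solution of the mass-action equilibrium for total
    ligand ``l`` and total protein ``P``; reduces to the hyperbola
    l/(l+Kd) as P -> 0. The returned signal lies between Unbound and Bound.
    """
    l = np.asarray(ligand_conc, dtype=float)
    if np.any(l < 0):
        raise BindingError("ligand concentration must be >= 0")
    if protein_conc <= 0:
        raise BindingError("protein concentration must be positive")
    P = protein_conc
    s = l + P + params.Kd
    disc = s * s - 4.0 * l * P
    if np.any(disc < -1e-12 * np.max(s * s)):
        raise BindingError("negative discriminant in depletion quadratic")
    frac = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * P)
    out = params.Unbound + (params.Bound - params.Unbound) * frac
    return float(out) if np.isscalar(ligand_conc) else out


def _fit_one_curve(curve: BindingCurve) -> tuple[Eq1Params, float]:
    """Least-squares fit of one replicate; returns params and residual sd.

    Kd is fitted in log-space (positivity by construction) with a
    deterministic multistart at {0.1x, 1x, 10x} the geometric mean of the
    concentration series; the best SSE wins.
    """
    l, y, P = curve.ligand_conc, curve.signal, curve.protein_conc
    geo = float(np.exp(np.mean(np.log(l))))
    lo, hi = float(y.min()), float(y.max())
    amp0 = hi - lo if hi > lo else 1.0
    best = None
    for factor in (0.1, 1.0, 10.0):
        x0 = np.array([math.log(factor * geo), lo + amp0, lo])
        try:
            res = least_squares(
                lambda x: eq1_model(l, Eq1Params(math.exp(x[0]), x[1], x[2]), P) - y,
                x0,
                method="lm",
                max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise BindingError(f"replicate {curve.replicate_id}: fit did not converge")
    kd = math.exp(best.x[0])
    params = Eq1Params(Kd=kd, Bound=best.x[1], Unbound=best.x[2])
    dof = max(l.size - 3, 1)
    resid_sd = float(np.sqrt(2.0 * best.cost / dof))
    return params, resid_sd


def fit_mst(curves: Sequence[BindingCurve]) -> BindingFit:
    """Fit each MST replicate independently and pool the Kd estimates.

    Kd_mean is the arithmetic mean over replicates and Kd_esd the sample
    standard deviation (n-1 denominator). The NBD ("no binding detected")
    flag is raised when the pooled fitted amplitude is below 3x the
    residual noise sd, or when the fitted Kd exceeds the highest tested
    ligand concentration; the Kd is then reported as a lower bound at the
    top tested concentration.
    """
    if not curves:
        raise BindingError("no curves supplied")
    kds: list[float] = []
    amps: list[float] = []
    noises: list[float] = []
    n_failed = 0
    max_conc = max(float(c.ligand_conc.max()) for c in curves)
    for curve in curves:
        try:
            params, resid_sd = _fit_one_curve(curve)
        except BindingError:
            n_failed += 1
            continue
        kds.append(params.Kd)
        amps.append(abs(params.Bound - params.Unbound))
        noises.append(resid_sd)
    if not kds:
        raise BindingError("all replicate fits failed")
    kd_mean = float(np.mean(kds))
    kd_esd = float(np.std(kds, ddof=1)) if len(kds) > 1 else 0.0
    amplitude = float(np.mean(amps))
    noise = float(np.mean(noises))
    nbd = amplitude < 3.0 * noise or kd_mean > max_conc
    return BindingFit(
        per_replicate_Kd=kds,
        Kd_mean=kd_mean,
        Kd_esd=kd_esd,
        amplitude=amplitude,
        nbd=nbd,
        max_tested_conc=max_conc,
        n_failed=n_failed,
    )


def _bound_concentration(p_tot: float, l_tot: float, kd: float, n_sites: float) -> float:
    """Concentration of occupied sites from the depletion quadratic."""
    sites = n_sites * p_tot
    s = sites + l_tot + kd
    disc = s * s - 4.0 * sites * l_tot
    return (s - math.sqrt(max(disc, 0.0))) / 2.0


def itc_forward(
    kd: float,
    dH: float,
    n_sites: float,
    titration: ItcTitration,
) -> np.ndarray:
    """Predicted heats (microjoules) per injection for a single-site model.

    Total concentrations in the cell are updated per injection with the
    standard displaced-volume (perfusion) correction: each injection of
    volume dV dilutes existing contents by (1 - dV/V0) and delivers
    ligand at the syringe concentration. The heat of injection i is
    dH * V0 * (bound_i - bound_{i-1} * (1 - dV/V0)), i.e. the enthalpy of
    newly formed complex net of complex expelled with the displaced volume.
    Heat-of-dilution subtraction is the caller's responsibility.
    """
    if kd <= 0:
        raise BindingError("Kd must be positive")
    V0 = titration.cell_volume * 1e-6  # litres
    p_tot = titration.cell_protein_conc
    l_tot = 0.0
    bound_prev = _bound_concentration(p_tot, l_tot, kd, n_sites)
    heats = np.empty(titration.injection_volumes.size)
    for i, dv_ul in enumerate(titration.injection_volumes):
        dv = dv_ul * 1e-6
        f = 1.0 - dv / V0
        p_tot *= f
        l_tot = l_tot * f + titration.syringe_ligand_conc * (dv / V0)
        bound = _bound_concentration(p_tot, l_tot, kd, n_sites)
        # dH kJ/mol -> J/mol is *1e3; J -> uJ is *1e6
        heats[i] = dH * 1e9 * V0 * (bound - bound_prev * f)
        bound_prev = bound
    return heats


def fit_itc(titration: ItcTitration) -> ItcFit:
    """Least-squares single-site fit of an ITC titration.

    Fits (log Kd, dH, n_sites); the first injection is excluded when
    ``skip_first`` is set. Standard errors come from the Jacobian-based
    covariance scaled by the residual variance.
    """
    mask = np.ones(titration.heats.size, dtype=bool)
    if titration.skip_first:
        mask[0] = False
    n_used = int(mask.sum())
    if n_used < 10:
        raise BindingError(f"need >= 10 usable injections, have {n_used}")
    y = titration.heats[mask]
    if np.allclose(y, 0.0):
        raise BindingError("all heats are zero; single-site fit is degenerate")

    def residuals(x: np.ndarray) -> np.ndarray:
        kd, dh, n = math.exp(x[0]), x[1], x[2]
        return itc_forward(kd, dh, n, titration)[mask] - y

    total_ratio = abs(float(np.sum(y))) * 1e-9 / (
        titration.cell_volume * 1e-6 * titration.cell_protein_conc
    )
    dh0 = -total_ratio if np.sum(y) < 0 else total_ratio
    kd0 = titration.cell_protein_conc / 10.0
    best = None
    for kd_factor in (0.1, 1.0, 10.0):
        x0 = np.array([math.log(kd0 * kd_factor), dh0 if dh0 != 0 else -10.0, 1.0])
        try:
            res = least_squares(residuals, x0, method="lm", max_nfev=10000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise BindingError("ITC fit did not converge from any start")

    dof = max(n_used - 3, 1)
    resid_var = 2.0 * best.cost / dof
    J = best.jac
    try:
        cov = resid_var * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        raise BindingError("ITC fit covariance is singular; parameters unresolved")
    kd = math.exp(best.x[0])
    return ItcFit(
        Kd=kd,
        Kd_se=kd * se[0],  # delta method on log Kd
        dH=best.x[1],
        dH_se=se[1],
        n_sites=best.x[2],
        n_sites_se=se[2],
        residual_sd=float(np.sqrt(resid_var)),
    )


def selectivity_ratio(fit_a: BindingFit, fit_b: BindingFit) -> tuple[float, float]:
    """Fold selectivity Kd_a / Kd_b with first-order propagated error.

    Quantifies statements like "N-fold weaker binding for ligand A than B".
    NBD fits have no defined Kd; the ratio is then only a bound and this
    function refuses to compute it.
    """
    if fit_a.nbd or fit_b.nbd:
        raise BindingError(
            "ratio undefined for NBD fits; report as a bound "
            "(> max_tested_conc / Kd) instead"
        )
    ratio = fit_a.Kd_mean / fit_b.Kd_mean
    rel = math.sqrt(
        (fit_a.Kd_esd / fit_a.Kd_mean) ** 2 + (fit_b.Kd_esd / fit_b.Kd_mean) ** 2
    )
    return ratio, ratio * rel


def redox_delta_g(couple: RedoxCouple) -> float:
    """Standard transformed free energy (kJ/mol) of a coupled redox reaction.

    Delta-G = -n F (E_acceptor - E_donor); negative means exergonic.
    E.g. phosphite oxidation to phosphate (E°' = -0.650 V) coupled to
    NAD+ reduction (E°' = -0.320 V) with n = 2 gives -63.7 kJ/mol.
    """
    dE = couple.E_acceptor - couple.E_donor
    return -couple.n_electrons * FARADAY_KJ_PER_V * dE
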