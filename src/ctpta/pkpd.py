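"""Deterministic PK engine: steady-state plasma and ELF concentration profiles.

Plasma follows a two-compartment disposition model with zero-order (constant
rate) infusion and first-order elimination.  At periodic steady state under
q-τ-hourly dosing the profile over one interval is available in closed form as
a superposition of within-interval infusion / post-infusion biexponential
segments; the geometric accumulation factor 1/(1 − e^{−λτ}) sums the tails of
all previous doses.

Epithelial lining fluid (ELF) is attached as a hypothetical link compartment
with first-order influx from plasma (k_in) and first-order loss (k_out):

    dC_ELF/dt = k_in · C_plasma(t) − k_out · C_ELF(t)

Because the plasma forcing is a piecewise sum of constants and exponentials,
the periodic ELF solution is also closed form: per-segment particular
solutions plus a homogeneous e^{−k_out·t} term whose coefficients are fixed by
continuity at end of infusion and periodicity C(0) = C(τ).

All concentrations are in μg/mL, times in hours, amounts in mg, volumes in L
(mg/L ≡ μg/mL), clearances in L/h, rate constants in 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._errors import InputError, ParameterError

__all__ = [
    "DosingRegimen",
    "PKParameters",
    "ConcentrationProfile",
    "ExposureMetrics",
    "default_time_grid",
    "plasma_profile_ss",
    "elf_profile_ss",
    "free_profile",
    "exposure_metrics",
]

#: grid spacing (h) giving trapezoidal AUC error well below 0.1 %
DEFAULT_DT = 0.005


@dataclass(frozen=True)
class DosingRegimen:
    """A repeated zero-order intravenous infusion schedule."""

    dose: float  # mg per administration
    infusion_duration: float  # h
    interval: float  # h, the dosing interval τ
    drug_label: str = ""

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ParameterError(f"dose must be positive, got {self.dose}")
        if self.interval <= 0:
            raise ParameterError(f"interval must be positive, got {self.interval}")
        if not 0 < self.infusion_duration <= self.interval:
            raise ParameterError(
                "infusion_duration must lie in (0, interval], got "
                f"{self.infusion_duration} with interval {self.interval}"
            )

    @property
    def rate(self) -> float:
        """Infusion rate R0 in mg/h."""
        return self.dose / self.infusion_duration


@dataclass(frozen=True)
class PKParameters:
    """Structural PK parameters for one drug in one subject.

    ``CL``/``V1`` are central clearance and volume, ``Q``/``V2`` the
    distributional clearance and peripheral volume; ``Q = 0`` collapses the
    model to one compartment.  ``k_in``/``k_out`` drive the ELF link
    compartment.  ``fu_plasma``/``fu_elf`` are unbound fractions: ceftolozane
    is ~21 % protein bound in plasma (fu 0.79), tazobactam ~30 % (fu 0.70);
    binding in ELF is taken as nil (fu 1.0) for both drugs.
    """

    cl: float
    v1: float
    q: float
    v2: float
    k_in: float
    k_out: float
    fu_plasma: float = 1.0
    fu_elf: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "v2", "k_in", "k_out"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.q < 0:
            raise ParameterError(f"q must be non-negative, got {self.q}")
        for name in ("fu_plasma", "fu_elf"):
            fu = getattr(self, name)
            if not 0 < fu <= 1:
                raise ParameterError(f"{name} must lie in (0, 1], got {fu}")

    def with_updates(self, **kwargs) -> "PKParameters":
        return replace(self, **kwargs)


@dataclass
class ConcentrationProfile:
    """Total and free concentration versus time over one steady-state interval."""

    times: np.ndarray
    regimen: DosingRegimen
    plasma_total: np.ndarray | None = None
    plasma_free: np.ndarray | None = None
    elf_total: np.ndarray | None = None
    elf_free: np.ndarray | None = None

    def to_frame(self):
        """Tabular export: time_h plus whichever concentration columns exist."""
        import pandas as pd

        data = {"time_h": self.times}
        for col in ("plasma_total", "plasma_free", "elf_total", "elf_free"):
            arr = getattr(self, col)
            if arr is not None:
                data[col] = arr
        return pd.DataFrame(data)

    def concentration(self, matrix: str = "plasma", free: bool = True) -> np.ndarray:
        """Return the requested concentration array, raising if absent."""
        key = f"{'plasma' if matrix == 'plasma' else 'elf'}_{'free' if free else 'total'}"
        if matrix not in ("plasma", "ELF", "elf"):
            raise InputError(f"unknown matrix {matrix!r}; expected 'plasma' or 'ELF'")
        arr = getattr(self, key if matrix == "plasma" else key.replace("plasma", "elf"))
        if arr is None:
            raise InputError(f"profile does not carry {key}")
        return arr


@dataclass(frozen=True)
class ExposureMetrics:
    """AUC over one dosing interval and peak concentration for one matrix."""

    auc_0_tau: float
    cmax: float
    matrix_label: str


def default_time_grid(regimen: DosingRegimen, dt: float = DEFAULT_DT) -> np.ndarray:
    """Uniform grid over [0, τ] with an exact node at end of infusion.

    Cmax occurs at end of infusion for this model class, so the grid must
    contain that instant exactly.
    """
    n = int(round(regimen.interval / dt))
    grid = np.linspace(0.0, regimen.interval, n + 1)
    if not np.any(np.isclose(grid, regimen.infusion_duration, atol=1e-12)):
        grid = np.sort(np.append(grid, regimen.infusion_duration))
    return grid


def _disposition_terms(params: PKParameters) -> tuple[np.ndarray, np.ndarray]:
    """Exponents λ_i and coefficients c_i of the unit-impulse response c(t)=Σ c_i e^{−λ_i t}.

    Two-compartment micro-constants: k10 = CL/V1, k12 = Q/V1, k21 = Q/V2.
    The macro-exponents α, β are the roots of λ² − (k10+k12+k21)λ + k10·k21,
    with coefficients A = (k21−α)/(V1(β−α)), B = (k21−β)/(V1(α−β)).
    With Q = 0 the model degenerates to one compartment (λ = k10, c = 1/V1).
    """
    if params.q == 0:
        return np.array([params.cl / params.v1]), np.array([1.0 / params.v1])
    k10 = params.cl / params.v1
    k12 = params.q / params.v1
    k21 = params.q / params.v2
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    a = (k21 - alpha) / (params.v1 * (beta - alpha))
    b = (k21 - beta) / (params.v1 * (alpha - beta))
    return np.array([alpha, beta]), np.array([a, b])


def _validate_times(times: np.ndarray, regimen: DosingRegimen) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InputError("time grid is empty")
    if np.any(np.diff(times) <= 0):
        raise InputError("time grid must be strictly increasing")
    if times[0] < -1e-12 or times[-1] > regimen.interval + 1e-9:
        raise InputError(
            f"time grid must lie within [0, τ={regimen.interval}], got "
            f"[{times[0]}, {times[-1]}]"
        )
    return times


def _plasma_ss_terms(
    params: PKParameters, regimen: DosingRegimen
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-exponential representation of the steady-state plasma profile.

    Returns (lambdas, const_infusion, coef_infusion, coef_washout) such that

        C(t) = Σ_i const_i + coef_inf_i · e^{−λ_i t}        for 0 ≤ t ≤ Tinf
        C(t) = Σ_i coef_wash_i · e^{−λ_i t}                 for Tinf ≤ t ≤ τ
    """
    lam, coef = _disposition_terms(params)
    r0 = regimen.rate
    tinf, tau = regimen.infusion_duration, regimen.interval
    base = r0 * coef / lam  # per-term plateau R0·c_i/λ_i
    accum = 1.0 / -np.expm1(-lam * tau)  # 1/(1 − e^{−λτ})
    rise = -np.expm1(-lam * tinf)  # 1 − e^{−λ·Tinf}
    # within-infusion: current dose (1 − e^{−λt}) plus tails of all prior doses
    coef_inf = base * (-1.0 + rise * np.exp(lam * tinf) * np.exp(-lam * tau) * accum)
    # post-infusion: all doses including the current one
    coef_wash = base * rise * np.exp(lam * tinf) * accum
    return lam, base, coef_inf, coef_wash


def _eval_piecewise(
    times: np.ndarray,
    tinf: float,
    lam: np.ndarray,
    const_inf: np.ndarray,
    coef_inf: np.ndarray,
    coef_wash: np.ndarray,
) -> np.ndarray:
    e = np.exp(-np.outer(times, lam))  # (nt, nterms)
    during = e @ coef_inf + const_inf.sum()
    after = e @ coef_wash
    return np.where(times <= tinf + 1e-12, during, after)


def plasma_profile_ss(
    params: PKParameters,
    regimen: DosingRegimen,
    times: Sequence[float] | np.ndarray | None = None,
) -> ConcentrationProfile:
    """Steady-state total and free plasma concentration over one dosing interval."""
    if times is None:
        times = default_time_grid(regimen)
    times = _validate_times(np.asarray(times, dtype=float), regimen)
    lam, base, coef_inf, coef_wash = _plasma_ss_terms(params, regimen)
    conc = _eval_piecewise(times, regimen.infusion_duration, lam, base, coef_inf, coef_wash)
    conc = np.maximum(conc, 0.0)  # guard round-off at trough
    return ConcentrationProfile(
        times=times,
        regimen=regimen,
        plasma_total=conc,
        plasma_free=params.fu_plasma * conc,
    )


def _link_particular(
    lam: np.ndarray, coef: np.ndarray, k_in: float, k_out: float
) -> tuple[np.ndarray, np.ndarray]:
    """Particular-solution coefficients for forcing terms coef_i·e^{−λ_i t}.

    Returns (phi, resonant) where the particular solution is
    Σ phi_i e^{−λ_i t} plus, where resonant_i is nonzero (λ_i ≈ k_out),
    resonant_i · t · e^{−λ_i t}.
    """
    phi = np.zeros_like(coef)
    res = np.zeros_like(coef)
    near = np.abs(k_out - lam) < 1e-9 * max(k_out, 1.0)
    phi[~near] = k_in * coef[~near] / (k_out - lam[~near])
    res[near] = k_in * coef[near]
    return phi, res


def elf_profile_ss(
    params: PKParameters,
    regimen: DosingRegimen,
    times: Sequence[float] | np.ndarray | None = None,
    driven_by: str = "total",
) -> ConcentrationProfile:
    """Steady-state ELF (and plasma) concentrations over one dosing interval.

    ``driven_by`` selects whether the link influx k_in acts on total (default)
    or free plasma concentration; with free driving, the ELF input is simply
    scaled by fu_plasma.
    """
    if driven_by not in ("total", "free"):
        raise InputError(f"driven_by must be 'total' or 'free', got {driven_by!r}")
    if times is None:
        times = default_time_grid(regimen)
    times = _validate_times(np.asarray(times, dtype=float), regimen)
    tinf, tau = regimen.infusion_duration, regimen.interval
    k_in, k_out = params.k_in, params.k_out
    drive = params.fu_plasma if driven_by == "free" else 1.0

    lam, base, coef_inf, coef_wash = _plasma_ss_terms(params, regimen)
    base = drive * base
    coef_inf = drive * coef_inf
    coef_wash = drive * coef_wash

    # particular solutions per segment
    const_part = k_in * base.sum() / k_out  # response to the infusion plateau
    phi_inf, res_inf = _link_particular(lam, coef_inf, k_in, k_out)
    phi_wash, res_wash = _link_particular(lam, coef_wash, k_in, k_out)

    def pa(t: float) -> float:  # particular, infusion segment
        e = np.exp(-lam * t)
        return const_part + float(phi_inf @ e + (res_inf * t) @ e)

    def pb(t: float) -> float:  # particular, washout segment
        e = np.exp(-lam * t)
        return float(phi_wash @ e + (res_wash * t) @ e)

    # homogeneous coefficients from continuity at Tinf and periodicity C(0)=C(τ)
    g_a = (pb(tau) - pa(0.0) + (pa(tinf) - pb(tinf)) * np.exp(-k_out * (tau - tinf))) / -np.expm1(
        -k_out * tau
    )
    g_b = g_a + (pa(tinf) - pb(tinf)) * np.exp(k_out * tinf)

    e_out = np.exp(-k_out * times)
    e_lam = np.exp(-np.outer(times, lam))
    during = g_a * e_out + const_part + e_lam @ phi_inf + (e_lam * times[:, None]) @ res_inf
    after = g_b * e_out + e_lam @ phi_wash + (e_lam * times[:, None]) @ res_wash
    elf = np.where(times <= tinf + 1e-12, during, after)
    elf = np.maximum(elf, 0.0)

    plasma = _eval_piecewise(times, tinf, lam, base / drive, coef_inf / drive, coef_wash / drive)
    plasma = np.maximum(plasma, 0.0)
    return ConcentrationProfile(
        times=times,
        regimen=regimen,
        plasma_total=plasma,
        plasma_free=params.fu_plasma * plasma,
        elf_total=elf,
        elf_free=params.fu_elf * elf,
    )


def free_profile(profile: ConcentrationProfile, params: PKParameters) -> ConcentrationProfile:
    """Fill the free-concentration fields from the totals via the unbound fractions."""
    out = ConcentrationProfile(times=profile.times, regimen=profile.regimen)
    if profile.plasma_total is not None:
        out.plasma_total = profile.plasma_total
        out.plasma_free = params.fu_plasma * profile.plasma_total
    if profile.elf_total is not None:
        out.elf_total = profile.elf_total
        out.elf_free = params.fu_elf * profile.elf_total
    if out.plasma_total is None and out.elf_total is None:
        raise InputError("profile carries no total concentrations")
    return out


def exposure_metrics(
    profile: ConcentrationProfile, matrix: str = "plasma", free: bool = False
) -> ExposureMetrics:
    """Trapezoidal AUC over [0, τ] and observed Cmax for one matrix."""
    times = profile.times
    if times.size < 3:
        raise InputError("grid too sparse for exposure metrics")
    conc = profile.concentration(matrix=matrix, free=free)
    label = ("ELF" if matrix.lower() == "elf" else "plasma") + (" free" if free else "")
    return ExposureMetrics(
        auc_0_tau=float(np.trapezoid(conc, times)),
        cmax=float(conc.max()),
        matrix_label=label,
    )
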