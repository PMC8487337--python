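"""Stratified virtual-patient generation and covariate-based individualization.

Virtual subjects carry paired body weight and creatinine clearance (CrCl).
Weight is log-normal; CrCl given weight follows a log-scale linear regression,
so the weight–CrCl correlation of real cohorts is preserved.  Within a renal
stratum, CrCl is drawn from the conditional distribution truncated to the
stratum bounds.

Individual PK parameters follow the usual power-law covariate models with
log-normal inter-individual variability (IIV):

    CL_i  = CL_ref · (CrCl_i / CrCl_ref)^θ_CrCl · e^{η_CL}
    V_i   = V_ref · (WT_i / WT_ref)^θ_WT · m_pneu · e^{η_V}

with pneumonia acting multiplicatively on volume and on the ELF influx and
elimination rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._errors import ConfigurationError, InputError, ParameterError
from .pkpd import PKParameters

__all__ = [
    "RenalStratum",
    "DemographicModel",
    "CovariateModel",
    "IIVModel",
    "VirtualSubject",
    "canonical_strata",
    "table_strata",
    "sample_stratum",
    "individualize",
    "individualize_cohort",
    "cohort_frame",
]


@dataclass(frozen=True)
class RenalStratum:
    """A CrCl interval; closed on the left, open on the right, unless flagged.

    The normal-function stratum [80, 130] is closed at both ends; the
    terminal ARC stratum is capped inclusively at 312 mL/min.
    """

    label: str
    crcl_low: float
    crcl_high: float
    low_inclusive: bool = True
    high_inclusive: bool = False

    def __post_init__(self) -> None:
        if not self.crcl_low < self.crcl_high:
            raise ConfigurationError(
                f"stratum {self.label!r}: need crcl_low < crcl_high, got "
                f"[{self.crcl_low}, {self.crcl_high}]"
            )

    def contains(self, crcl: float) -> bool:
        lo_ok = crcl >= self.crcl_low if self.low_inclusive else crcl > self.crcl_low
        hi_ok = crcl <= self.crcl_high if self.high_inclusive else crcl < self.crcl_high
        return lo_ok and hi_ok


def canonical_strata() -> list[RenalStratum]:
    """The four PTA strata: normal 80–130 and three ARC severities up to 312."""
    return [
        RenalStratum("80-130", 80.0, 130.0, high_inclusive=True),
        RenalStratum("130-180", 130.0, 180.0, low_inclusive=False),
        RenalStratum("180-210", 180.0, 210.0),
        RenalStratum("210-312", 210.0, 312.0, high_inclusive=True),
    ]


def table_strata() -> list[RenalStratum]:
    """The exposure-summary binning (≥80–<150, ≥150–<180, ≥180–<210, ≥210)."""
    return [
        RenalStratum("80-150", 80.0, 150.0),
        RenalStratum("150-180", 150.0, 180.0),
        RenalStratum("180-210", 180.0, 210.0),
        RenalStratum("210-312", 210.0, 312.0, high_inclusive=True),
    ]


@dataclass(frozen=True)
class DemographicModel:
    """Joint weight/CrCl model: log-normal weight, conditional log-scale CrCl.

    ln CrCl = crcl_log_intercept + crcl_log_slope · (ln WT − log_weight_mean) + ε,
    ε ~ N(0, crcl_residual_sd²).  Defaults emulate the trial's demographics:
    median weight 80 kg, median CrCl around 105 mL/min with a positive
    weight–CrCl association.
    """

    log_weight_mean: float = float(np.log(80.0))
    log_weight_sd: float = 0.165
    crcl_log_intercept: float = float(np.log(105.0))
    crcl_log_slope: float = 0.6
    crcl_residual_sd: float = 0.35

    def __post_init__(self) -> None:
        if self.log_weight_sd < 0 or self.crcl_residual_sd < 0:
            raise ParameterError("standard deviations must be non-negative")


@dataclass(frozen=True)
class CovariateModel:
    """Power-law covariate effects with pneumonia status multipliers."""

    cl_ref: float
    cl_crcl_exponent: float
    crcl_ref: float
    v_ref: float
    v_weight_exponent: float
    wt_ref: float
    pneumonia_v_multiplier: float = 1.0
    pneumonia_kin_multiplier: float = 1.0
    pneumonia_kout_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl_ref", "crcl_ref", "v_ref", "wt_ref"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in (
            "pneumonia_v_multiplier",
            "pneumonia_kin_multiplier",
            "pneumonia_kout_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("cl_crcl_exponent", "v_weight_exponent"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")


@dataclass(frozen=True)
class IIVModel:
    """Log-scale standard deviations of the between-subject random effects."""

    omega_cl: float = 0.0
    omega_v1: float = 0.0
    omega_q: float = 0.0
    omega_v2: float = 0.0
    omega_kin: float = 0.0
    omega_kout: float = 0.0

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if getattr(self, f) < 0:
                raise ParameterError(f"{f} must be non-negative")


@dataclass
class VirtualSubject:
    subject_id: int
    weight: float
    crcl: float
    stratum: str
    params_by_drug: dict[str, PKParameters] = field(default_factory=dict)


def sample_stratum(
    stratum: RenalStratum,
    n: int,
    demo: DemographicModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> list[VirtualSubject]:
    """Draw ``n`` subjects with paired weight and CrCl truncated to the stratum.

    Weight is drawn from its marginal; CrCl from the weight-conditional
    log-normal truncated to the stratum bounds.  With zero residual sd, CrCl
    is deterministic in weight and weights are rejection-sampled until the
    implied CrCl falls in the stratum.
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    demo = demo or DemographicModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    log_lo, log_hi = np.log(stratum.crcl_low), np.log(stratum.crcl_high)

    if demo.crcl_residual_sd == 0:
        weights, crcls = [], []
        attempts = 0
        while len(weights) < n:
            attempts += 1
            if attempts > 1000 * n + 1000:
                raise ConfigurationError(
                    f"stratum {stratum.label!r} infeasible under the demographic model "
                    "(deterministic CrCl never falls inside the bounds)"
                )
            w = float(np.exp(rng.normal(demo.log_weight_mean, demo.log_weight_sd)))
            log_c = demo.crcl_log_intercept + demo.crcl_log_slope * (np.log(w) - demo.log_weight_mean)
            if log_lo <= log_c <= log_hi and stratum.contains(float(np.exp(log_c))):
                weights.append(w)
                crcls.append(float(np.exp(log_c)))
        weights = np.array(weights)
        crcls = np.array(crcls)
    else:
        weights = np.exp(rng.normal(demo.log_weight_mean, demo.log_weight_sd, size=n))
        mu = demo.crcl_log_intercept + demo.crcl_log_slope * (np.log(weights) - demo.log_weight_mean)
        a = (log_lo - mu) / demo.crcl_residual_sd
        b = (log_hi - mu) / demo.crcl_residual_sd
        crcls = np.exp(truncnorm.rvs(a, b, loc=mu, scale=demo.crcl_residual_sd, random_state=rng))
        # truncation is on the closed interval; nudge off excluded endpoints
        eps = 1e-9
        if not stratum.low_inclusive:
            crcls = np.maximum(crcls, stratum.crcl_low * (1 + eps))
        if not stratum.high_inclusive:
            crcls = np.minimum(crcls, stratum.crcl_high * (1 - eps))
    return [
        VirtualSubject(subject_id=i, weight=float(weights[i]), crcl=float(crcls[i]), stratum=stratum.label)
        for i in range(n)
    ]


def individualize(
    subject: VirtualSubject,
    cov: CovariateModel,
    iiv: IIVModel,
    base: PKParameters,
    pneumonia: bool = True,
    rng: np.random.Generator | None = None,
) -> PKParameters:
    """Individual PK parameters from covariates plus one IIV draw per subject."""
    if subject.weight <= 0 or subject.crcl < 0:
        raise InputError(f"subject {subject.subject_id}: non-positive covariates")
    rng = rng or np.random.default_rng()
    eta = {
        name: (rng.normal(0.0, sd) if sd > 0 else 0.0)
        for name, sd in (
            ("cl", iiv.omega_cl),
            ("v1", iiv.omega_v1),
            ("q", iiv.omega_q),
            ("v2", iiv.omega_v2),
            ("kin", iiv.omega_kin),
            ("kout", iiv.omega_kout),
        )
    }
    m_v = cov.pneumonia_v_multiplier if pneumonia else 1.0
    m_kin = cov.pneumonia_kin_multiplier if pneumonia else 1.0
    m_kout = cov.pneumonia_kout_multiplier if pneumonia else 1.0
    wt_scale = (subject.weight / cov.wt_ref) ** cov.v_weight_exponent
    return PKParameters(
        cl=cov.cl_ref * (subject.crcl / cov.crcl_ref) ** cov.cl_crcl_exponent * np.exp(eta["cl"]),
        v1=cov.v_ref * wt_scale * m_v * np.exp(eta["v1"]),
        q=base.q * np.exp(eta["q"]),
        v2=base.v2 * wt_scale * m_v * np.exp(eta["v2"]),
        k_in=base.k_in * m_kin * np.exp(eta["kin"]),
        k_out=base.k_out * m_kout * np.exp(eta["kout"]),
        fu_plasma=base.fu_plasma,
        fu_elf=base.fu_elf,
    )


def individualize_cohort(
    subjects: list[VirtualSubject],
    drug_label: str,
    cov: CovariateModel,
    iiv: IIVModel,
    base: PKParameters,
    pneumonia: bool = True,
    seed: int | np.random.Generator | None = None,
) -> list[VirtualSubject]:
    """Attach individualized parameters for one drug to every subject, in place."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for s in subjects:
        s.params_by_drug[drug_label] = individualize(s, cov, iiv, base, pneumonia, rng)
    return subjects


def cohort_frame(subjects: list[VirtualSubject]) -> pd.DataFrame:
    """Tabular view of a cohort: demographics plus one column per PK parameter per drug."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "weight_kg": s.weight,
            "crcl_ml_min": s.crcl,
            "stratum": s.stratum,
        }
        for drug, p in s.params_by_drug.items():
            for f in ("cl", "v1", "q", "v2", "k_in", "k_out", "fu_plasma", "fu_elf"):
                row[f"{drug}_{f}"] = getattr(p, f)
        rows.append(row)
    return pd.DataFrame(rows)
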