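"""Synthetic trial cohorts and packaged outcome fixtures.

The real trial data are access-restricted, so the package ships (a) a
generator producing participant-level cohorts with the statistical structure
the outcome analysis assumes — CrCl arises mechanistically from sampled age,
weight, sex and serum creatinine through Cockcroft–Gault, and binary outcomes
are Bernoulli at category-specific rates — and (b) the published summary
counts as a fixture table.

Fixture rows tagged ``printed`` carry n/N values exactly as published; rows
tagged ``recovered`` carry counts inferred by inverting the published
1-decimal percentage against the published group size (the inversion is
re-verified at load time and is unique for every shipped row).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, InputError
from .trial_stats import categorize_renal, cockcroft_gault, recover_count

__all__ = [
    "CohortSpec",
    "FixtureTable",
    "default_trial_spec",
    "generate_cohort",
    "paper_fixtures",
    "fixture_comparison_rows",
]

ENDPOINTS = ("mortality_day28", "clinical_cure_toc", "micro_cure_toc")


@dataclass(frozen=True)
class CohortSpec:
    """Distributional recipe for one synthetic trial cohort (both arms).

    ``outcome_rates`` maps (arm, renal_category_label) to a dict of endpoint
    rates in [0, 1]; categories are ``normal``, ``ARC`` and ``other``.
    Defaults emulate the trial: age ~55 ± 16 y (truncated at 18), ~75 % male,
    weight log-normal around 80 kg, and sex-specific serum creatinine chosen
    so roughly a third of participants land in each of normal / ARC / other.
    """

    n_per_arm: int
    arms: tuple[str, ...] = ("ceftolozane/tazobactam", "meropenem")
    age_mean: float = 55.0
    age_sd: float = 16.0
    age_max: float = 95.0
    prop_male: float = 0.75
    log_weight_mean: float = float(np.log(80.0))
    log_weight_sd: float = 0.165
    scr_log_median_male: float = float(np.log(1.0))
    scr_log_median_female: float = float(np.log(0.85))
    scr_log_sd: float = 0.45
    mitt_fraction: float = 0.75
    ce_fraction: float = 0.70
    outcome_rates: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise InputError(f"n_per_arm must be >= 1, got {self.n_per_arm}")
        if not 0 <= self.prop_male <= 1:
            raise ConfigurationError("prop_male must lie in [0, 1]")
        for frac in (self.mitt_fraction, self.ce_fraction):
            if not 0 <= frac <= 1:
                raise ConfigurationError("population fractions must lie in [0, 1]")
        for key, rates in self.outcome_rates.items():
            for ep, r in rates.items():
                if not 0 <= r <= 1:
                    raise ConfigurationError(f"rate {key}/{ep} = {r} outside [0, 1]")


def default_trial_spec(n_per_arm: int = 250, seed: int | None = None) -> CohortSpec:
    """CohortSpec with outcome rates set to the published subgroup rates."""
    ct, mero = "ceftolozane/tazobactam", "meropenem"
    rates = {
        (ct, "normal"): {"mortality_day28": 0.176, "clinical_cure_toc": 0.573, "micro_cure_toc": 0.722},
        (ct, "ARC"): {"mortality_day28": 0.177, "clinical_cure_toc": 0.594, "micro_cure_toc": 0.714},
        (mero, "normal"): {"mortality_day28": 0.203, "clinical_cure_toc": 0.593, "micro_cure_toc": 0.750},
        (mero, "ARC"): {"mortality_day28": 0.177, "clinical_cure_toc": 0.575, "micro_cure_toc": 0.700},
        # participants outside the two analyzed categories still get outcomes
        (ct, "other"): {"mortality_day28": 0.20, "clinical_cure_toc": 0.55, "micro_cure_toc": 0.70},
        (mero, "other"): {"mortality_day28": 0.20, "clinical_cure_toc": 0.55, "micro_cure_toc": 0.70},
    }
    return CohortSpec(n_per_arm=n_per_arm, outcome_rates=rates, seed=seed)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Participant-level synthetic cohort; seed overrides ``spec.seed`` if given.

    Demographics and outcomes use independent substreams of the seed so the
    demographic draw is unchanged by adding or removing endpoints.
    """
    root = np.random.SeedSequence(seed if seed is not None else spec.seed)
    demo_rng, outcome_rng = (np.random.default_rng(s) for s in root.spawn(2))

    n = spec.n_per_arm * len(spec.arms)
    arm = np.repeat(list(spec.arms), spec.n_per_arm)
    age = np.clip(demo_rng.normal(spec.age_mean, spec.age_sd, n), 18.0, spec.age_max)
    male = demo_rng.random(n) < spec.prop_male
    weight = np.exp(demo_rng.normal(spec.log_weight_mean, spec.log_weight_sd, n))
    scr_mu = np.where(male, spec.scr_log_median_male, spec.scr_log_median_female)
    scr = np.exp(demo_rng.normal(scr_mu, spec.scr_log_sd, n))

    crcl = np.array(
        [
            cockcroft_gault(a, w, s, "male" if m else "female")
            for a, w, s, m in zip(age, weight, scr, male)
        ]
    )
    category = np.array([categorize_renal(c).label for c in crcl])

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": arm,
            "age": age,
            "sex": np.where(male, "male", "female"),
            "weight": weight,
            "serum_creatinine": scr,
            "crcl": crcl,
            "renal_category": category,
            "itt": True,
            "mitt": outcome_rng.random(n) < spec.mitt_fraction,
            "ce": outcome_rng.random(n) < spec.ce_fraction,
        }
    )
    for ep in ENDPOINTS:
        p = np.zeros(n)
        seen = np.zeros(n, dtype=bool)
        for (a, cat), rates in spec.outcome_rates.items():
            mask = (df["arm"] == a) & (df["renal_category"] == cat)
            p[mask.to_numpy()] = rates.get(ep, 0.0)
            seen |= mask.to_numpy()
        df[ep] = outcome_rng.random(n) < p
    return df


@dataclass(frozen=True)
class FixtureTable:
    """One published two-group comparison: label, (group, x, n) rows, provenance.

    ``printed_*`` hold the values exactly as published; ``method_*`` hold what
    Newcombe method 10 yields from the counts at 1-dp display rounding.  They
    coincide for every shipped row except one CI endpoint (see the clinical
    cure C/T row's provenance note), where the published digit cannot be
    reproduced by the stated method from any counts consistent with the
    published rates.
    """

    label: str
    rows: tuple[tuple[str, int, int], ...]
    direction: str
    printed_diff: float
    printed_ci: tuple[float, float]
    method_diff: float
    method_ci: tuple[float, float]
    tag: str
    provenance: str


def _load_fixture_frame() -> pd.DataFrame:
    text = resources.files("ctpta.data").joinpath("outcome_fixtures.csv").read_text()
    return pd.read_csv(io.StringIO(text))


def paper_fixtures(verify: bool = True) -> list[FixtureTable]:
    """The published outcome comparisons as fixture tables.

    With ``verify`` (default), counts tagged ``recovered`` are re-derived from
    the published 1-dp percentage and group size and must match uniquely.
    """
    tables = []
    for _, r in _load_fixture_frame().iterrows():
        if verify and r["tag"] == "recovered":
            for x, n, rate in ((r.x1, r.n1, r.rate1_pct), (r.x2, r.n2, r.rate2_pct)):
                assert recover_count(float(rate), int(n)) == int(x), (
                    f"{r.label}: {rate}% of {n} does not invert to {x}"
                )
        tables.append(
            FixtureTable(
                label=r["label"],
                rows=((r["group1"], int(r.x1), int(r.n1)), (r["group2"], int(r.x2), int(r.n2))),
                direction=r["direction"],
                printed_diff=float(r["printed_diff"]),
                printed_ci=(float(r["printed_ci_low"]), float(r["printed_ci_high"])),
                method_diff=float(r["method_diff"]),
                method_ci=(float(r["method_ci_low"]), float(r["method_ci_high"])),
                tag=r["tag"],
                provenance=r["provenance"],
            )
        )
    return tables


def fixture_comparison_rows() -> list[dict]:
    """Fixture tables reshaped for :func:`ctpta.trial_stats.build_outcome_table`."""
    rows = []
    for t in paper_fixtures():
        (g1, x1, n1), (g2, x2, n2) = t.rows
        rows.append(
            {
                "label": t.label,
                "x1": x1,
                "n1": n1,
                "x2": x2,
                "n2": n2,
                "direction": t.direction,
                "printed_diff": t.printed_diff,
                "printed_ci_low": t.printed_ci[0],
                "printed_ci_high": t.printed_ci[1],
                "method_diff": t.method_diff,
                "method_ci_low": t.method_ci[0],
                "method_ci_high": t.method_ci[1],
            }
        )
    return rows
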