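"""Loading and validation of drug parameter-set files.

A parameter set is a YAML file with blocks ``regimen`` (dose and schedule),
``pk`` (typical-subject structural parameters at the reference covariates,
without pneumonia), ``covariates`` (power-law covariate model and pneumonia
multipliers), ``iiv`` (log-scale between-subject SDs) and ``target`` (the
drug's PK/PD target).  The package ships calibrated sets for ceftolozane and
tazobactam under :mod:`ctpta.data`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from ._errors import ConfigurationError
from .pkpd import DosingRegimen, PKParameters
from .population import CovariateModel, IIVModel
from .pta import PDTarget

__all__ = ["DrugModelSpec", "load_drug_spec", "packaged_drug_names"]

_PACKAGED = ("ceftolozane", "tazobactam")


@dataclass(frozen=True)
class DrugModelSpec:
    """Everything the simulator needs to know about one drug."""

    name: str
    regimen: DosingRegimen
    base: PKParameters
    covariates: CovariateModel
    iiv: IIVModel
    target: PDTarget

    def target_in(self, matrix: str) -> PDTarget:
        """The drug's PK/PD target evaluated in the given matrix."""
        return PDTarget(
            drug_label=self.name,
            threshold_type=self.target.threshold_type,
            required_fraction=self.target.required_fraction,
            threshold_value=self.target.threshold_value,
            matrix=matrix,
            use_free=True,
        )


def packaged_drug_names() -> tuple[str, ...]:
    return _PACKAGED


def _read_yaml(source: str | Path) -> dict:
    if isinstance(source, str) and source in _PACKAGED:
        text = resources.files("ctpta.data").joinpath(f"{source}.yaml").read_text()
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"parameter file not found: {source}")
        text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"parameter file {source} is not a mapping")
    return data


def load_drug_spec(source: str | Path) -> DrugModelSpec:
    """Load a drug parameter set from a packaged name or a YAML path."""
    data = _read_yaml(source)
    try:
        reg = data["regimen"]
        pk = data["pk"]
        cov = data["covariates"]
        iiv = data.get("iiv", {})
        tgt = data["target"]
        name = str(data["drug"])
        return DrugModelSpec(
            name=name,
            regimen=DosingRegimen(
                dose=float(reg["dose_mg"]),
                infusion_duration=float(reg["infusion_h"]),
                interval=float(reg["interval_h"]),
                drug_label=name,
            ),
            base=PKParameters(**{k: float(v) for k, v in pk.items()}),
            covariates=CovariateModel(**{k: float(v) for k, v in cov.items()}),
            iiv=IIVModel(**{k: float(v) for k, v in iiv.items()}),
            target=PDTarget(
                drug_label=name,
                threshold_type=str(tgt["threshold_type"]),
                required_fraction=float(tgt["required_fraction"]),
                threshold_value=float(tgt["threshold_value"]),
            ),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"parameter file {source}: {exc}") from exc
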