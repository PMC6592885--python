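"""Parameter-space delta-change perturbation.

Monthly GCM x RCP change factors are applied to *generator parameters*
rather than to a generated record: temperature means are shifted
additively, and the precipitation amount distribution is scaled
multiplicatively (gamma scale, or every entry of the empirical quantile
table), which scales the mean wet-day amount by the monthly ratio while
leaving occurrence untouched.  An optional wet-frequency multiplier hook
is provided but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .generators import PWGParams, SEWGParams
from .synthetic import ScenarioSpec

__all__ = ["PerturbedParams", "apply_delta", "apply_delta_pwg", "apply_delta_sewg"]


@dataclass
class PerturbedParams:
    """A perturbed parameter set with scenario provenance."""

    params: object  # PWGParams or SEWGParams
    gcm_label: str
    rcp_label: str
    source_wg: str

    @property
    def scenario_label(self) -> str:
        return f"{self.gcm_label}x{self.rcp_label}"


def _check_order(mean_tmax, mean_tmin, where: str) -> None:
    if (mean_tmax < mean_tmin).any():
        m, s = np.argwhere(mean_tmax < mean_tmin)[0]
        raise ValueError(
            f"perturbation makes mean_tmax < mean_tmin at month {m + 1}, "
            f"state {'wet' if s else 'dry'} ({where})")


def apply_delta_pwg(params: PWGParams, scenario: ScenarioSpec,
                    source_wg: str = "pwg",
                    wet_frequency_factor: np.ndarray | None = None) -> PerturbedParams:
    """Perturb parametric-generator parameters with monthly change factors.

    ``mean_tmax/mean_tmin`` shift by the monthly deltas in both states;
    ``gamma_scale`` is multiplied by the monthly precipitation ratio
    (shape preserved, so the mean wet-day amount scales by the ratio).
    Occurrence probabilities are unchanged unless an explicit
    ``wet_frequency_factor`` (12 monthly multipliers, clipped to [0, 1]
    after application) is supplied.
    """
    mean_tmax = params.mean_tmax + scenario.dT_max[:, None]
    mean_tmin = params.mean_tmin + scenario.dT_min[:, None]
    _check_order(mean_tmax, mean_tmin, scenario.label)
    new = replace(params, mean_tmax=mean_tmax, mean_tmin=mean_tmin,
                  gamma_scale=params.gamma_scale * scenario.rP)
    if wet_frequency_factor is not None:
        f = np.asarray(wet_frequency_factor, dtype=float)
        new = replace(new, p01=np.clip(params.p01 * f, 0.0, 1.0),
                      p11=np.clip(params.p11 * f, 0.0, 1.0))
    return PerturbedParams(params=new, gcm_label=scenario.gcm_label,
                           rcp_label=scenario.rcp_label, source_wg=source_wg)


def apply_delta_sewg(params: SEWGParams, scenario: ScenarioSpec,
                     source_wg: str = "sewg") -> PerturbedParams:
    """Perturb semi-empirical-generator parameters: temperature means shift
    additively; every entry of each monthly amount quantile table is
    multiplied by the monthly ratio; spell histograms are unchanged."""
    mean_tmax = params.mean_tmax + scenario.dT_max[:, None]
    mean_tmin = params.mean_tmin + scenario.dT_min[:, None]
    _check_order(mean_tmax, mean_tmin, scenario.label)
    new = replace(
        params,
        mean_tmax=mean_tmax, mean_tmin=mean_tmin,
        amount_quantiles=[np.asarray(q) * scenario.rP[m]
                          for m, q in enumerate(params.amount_quantiles)],
    )
    return PerturbedParams(params=new, gcm_label=scenario.gcm_label,
                           rcp_label=scenario.rcp_label, source_wg=source_wg)


def apply_delta(params, scenario: ScenarioSpec, source_wg: str) -> PerturbedParams:
    """Dispatch on parameter family."""
    if isinstance(params, PWGParams):
        return apply_delta_pwg(params, scenario, source_wg)
    if isinstance(params, SEWGParams):
        return apply_delta_sewg(params, scenario, source_wg)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")
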