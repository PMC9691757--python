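"""Synthetic per-period patient-flag demand and capacity utilization.

The financial model assumes that every review period a fixed share of the
population (50% or 75%) is flagged for a telemedicine contact and that the
clinic's flexible capacity is fully booked. This module stress-tests that
assumption: it simulates stochastic per-patient, per-period flags —
either as independent Bernoulli draws or from synthetic continuous-
glucose-monitor (CGM) summary metrics with the triage rule *flag when
time-in-range < 65% or sensor wear < 50%* — serves demand against a fixed
per-period capacity, and reports utilization, unmet demand and realized
remote-monitoring revenue.

Flags are independent across patients and periods; within-patient
persistence and hypoglycemia-specific flags are absorbed into the overall
flag probability, which is all the financial model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .clinic_model import InvalidParameterError

__all__ = ["DemandStream", "UtilizationSummary", "TIR_THRESHOLD",
           "WEAR_THRESHOLD", "DEFAULT_TIR_BETA", "DEFAULT_WEAR_BETA",
           "simulate_flags_bernoulli", "simulate_flags_cgm",
           "utilization_summary"]

#: triage thresholds: flag when TIR < 65% or CGM wear < 50% of the period
TIR_THRESHOLD = 0.65
WEAR_THRESHOLD = 0.50

# Beta(a, b) defaults for the per-period TIR and wear fractions, chosen so
# the marginal flag probability is ~0.50 (the steady-state 50%-coverage
# assumption): P(TIR<0.65) = 0.482, P(wear<0.50) = 0.035, combined 0.500.
DEFAULT_TIR_BETA = (3.2, 1.8)
DEFAULT_WEAR_BETA = (6.0, 1.5)


@dataclass(frozen=True)
class DemandStream:
    """A simulated patient x period binary flag matrix.

    ``tir`` and ``wear`` carry the underlying CGM summary draws for the
    cgm-metric model and are ``None`` for the Bernoulli model. The same
    seed and parameters always reproduce the same stream.
    """

    flags: np.ndarray
    n_patients: int
    periods: int
    model: str
    model_params: dict
    seed: int
    tir: Optional[np.ndarray] = None
    wear: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.flags.shape != (self.n_patients, self.periods):
            raise InvalidParameterError("flag matrix shape mismatch")

    @property
    def demand_per_period(self) -> np.ndarray:
        """Flagged patients in each period (length ``periods``)."""
        return self.flags.sum(axis=0)

    @property
    def total_flags(self) -> int:
        return int(self.flags.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format (patient, period, flag[, tir, wear]) table."""
        patients, periods = np.indices(self.flags.shape)
        data = {"patient": patients.ravel(), "period": periods.ravel(),
                "flag": self.flags.ravel().astype(int)}
        if self.tir is not None:
            data["tir"] = self.tir.ravel()
            data["wear"] = self.wear.ravel()
        return pd.DataFrame(data)


@dataclass(frozen=True)
class UtilizationSummary:
    """Capacity-utilization statistics for one demand stream.

    Demand is served greedily up to ``capacity_per_period`` each period;
    ``realized_contacts + unmet_contacts`` always equals the total
    flagged demand.
    """

    capacity_per_period: float
    mean_demand_per_period: float
    mean_utilization: float
    saturated_period_fraction: float
    realized_contacts: int
    unmet_contacts: int
    realized_rpm_revenue: float


def simulate_flags_bernoulli(n_patients: int, periods: int, flag_prob: float,
                             seed: int) -> DemandStream:
    """Independent per-patient, per-period flags with fixed probability."""
    if not 0 <= flag_prob <= 1:
        raise InvalidParameterError("flag_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flags = rng.random((n_patients, periods)) < flag_prob
    return DemandStream(flags=flags, n_patients=n_patients, periods=periods,
                        model="bernoulli",
                        model_params={"flag_prob": flag_prob}, seed=seed)


def simulate_flags_cgm(n_patients: int, periods: int,
                       tir_beta: tuple[float, float] = DEFAULT_TIR_BETA,
                       wear_beta: tuple[float, float] = DEFAULT_WEAR_BETA,
                       *, seed: int) -> DemandStream:
    """Flags driven by synthetic per-period CGM summary metrics.

    For each patient-period a time-in-range fraction and a sensor-wear
    fraction are drawn from Beta distributions; the patient is flagged
    when TIR < 0.65 or wear < 0.50 (the triage rule). Degenerate
    point-mass draws may be requested by passing a Beta shape pair whose
    first entry is ``None``: ``(None, value)`` fixes the metric at
    ``value`` exactly.
    """
    rng = np.random.default_rng(seed)
    shape = (n_patients, periods)

    def _draw(beta_params, name):
        a, b = beta_params
        if a is None:  # point mass, for deterministic checks
            if not 0 <= b <= 1:
                raise InvalidParameterError(f"{name} point mass not in [0,1]")
            return np.full(shape, float(b))
        if a <= 0 or b <= 0:
            raise InvalidParameterError(f"{name} Beta shapes must be > 0")
        return rng.beta(a, b, size=shape)

    tir = _draw(tir_beta, "tir")
    wear = _draw(wear_beta, "wear")
    flags = (tir < TIR_THRESHOLD) | (wear < WEAR_THRESHOLD)
    return DemandStream(flags=flags, n_patients=n_patients, periods=periods,
                        model="cgm-metric",
                        model_params={"tir_beta": tuple(tir_beta),
                                      "wear_beta": tuple(wear_beta)},
                        seed=seed, tir=tir, wear=wear)


def utilization_summary(stream: DemandStream, capacity_per_period: float,
                        rpm_rate: float) -> UtilizationSummary:
    """Serve the stream against a fixed per-period contact capacity."""
    if capacity_per_period < 0:
        raise InvalidParameterError("capacity_per_period must be >= 0")
    demand = stream.demand_per_period
    served = np.minimum(demand, capacity_per_period)
    realized = int(served.sum())
    total = int(demand.sum())
    if capacity_per_period > 0:
        utilization = float(served.mean() / capacity_per_period)
    else:
        utilization = 0.0
    return UtilizationSummary(
        capacity_per_period=capacity_per_period,
        mean_demand_per_period=float(demand.mean()),
        mean_utilization=utilization,
        saturated_period_fraction=float((demand >= capacity_per_period
                                         ).mean()),
        realized_contacts=realized,
        unmet_contacts=total - realized,
        realized_rpm_revenue=realized * rpm_rate,
    )
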