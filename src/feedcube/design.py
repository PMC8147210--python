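"""Feed-sample moisture design emulation.

Emulates a drying/rewetting study on five feed groups (a total mixed ration
and four by-product materials).  Per group: one sample is kept in its
original condition, one sample is withdrawn from a 40 °C drying oven at each
fixed interval over the drying duration, and a further series is built by
adding incremental 5 mL water doses to a fresh 200 g aliquot.  With the
default 9 h 30 min drying at 30 min withdrawals (19 dried samples) and
20 rewetting increments this yields 40 samples per group, 200 in total.

Moisture bookkeeping is on a wet basis: ``M_wb = W_m / (W_m + W_d)`` where
``W_m`` is water mass and ``W_d`` dry-matter mass.  Dry matter of a sample of
initial mass ``W_o`` is ``DM = W_o * (1 - M_wb)``.  Drying removes only
water; rewetting adds only water (1 mL ≡ 1 g), so dry matter is conserved
along both treatment arms.

Drying kinetics are modelled as exponential water loss,
``W_m(k) = W_m0 * (1 - r)^k`` per withdrawal step, a monotone and positive
closed form; the default rate spans roughly the moisture ranges observed for
such materials (e.g. ~13-78 % wet basis for a TMR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError

__all__ = [
    "GROUPS",
    "TREATMENTS",
    "SampleRecord",
    "DesignConfig",
    "moisture_wet_basis",
    "dry_matter",
    "emulate_design",
    "records_to_frame",
]

GROUPS = (
    "S1 TMR",
    "S2 mixed by-products",
    "S3 palm kernel expeller",
    "S4 almond pie",
    "S5 corn bran",
)
TREATMENTS = ("original", "dried", "rewetted")


def moisture_wet_basis(W_m: float, W_d: float) -> float:
    """Wet-basis moisture fraction, water mass over total mass.

    Parameters
    ----------
    W_m : water mass in g (>= 0)
    W_d : dry-matter mass in g (> 0)
    """
    W_m, W_d = float(W_m), float(W_d)
    if W_d <= 0:
        raise DomainError(f"dry mass must be positive, got {W_d}")
    if W_m < 0:
        raise DomainError(f"water mass must be non-negative, got {W_m}")
    return W_m / (W_m + W_d)


def dry_matter(W_o: float, M_wb: float) -> float:
    """Dry-matter mass in g of a sample of initial mass ``W_o`` at moisture ``M_wb``."""
    W_o, M_wb = float(W_o), float(M_wb)
    if W_o <= 0:
        raise DomainError(f"initial mass must be positive, got {W_o}")
    if not (0.0 <= M_wb < 1.0):
        raise DomainError(f"wet-basis moisture must be in [0, 1), got {M_wb}")
    return W_o * (1.0 - M_wb)


@dataclass(frozen=True)
class SampleRecord:
    """One feed sample: masses, treatment arm and derived moisture."""

    group_id: str
    treatment: str
    step_index: int
    W_o: float  # initial (pre-treatment) mass, g
    W_m: float  # water mass, g
    W_d: float  # dry-matter mass, g
    M_wb: float  # wet-basis moisture fraction
    DM: float  # dry matter, g

    def __post_init__(self) -> None:
        if self.group_id not in GROUPS:
            raise DesignError(f"unknown group {self.group_id!r}")
        if self.treatment not in TREATMENTS:
            raise DesignError(f"unknown treatment {self.treatment!r}")
        if abs(self.M_wb - moisture_wet_basis(self.W_m, self.W_d)) > 1e-12:
            raise DesignError("M_wb inconsistent with W_m/(W_m+W_d)")

    @property
    def moisture_percent(self) -> float:
        return 100.0 * self.M_wb


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the drying/rewetting design.

    Defaults reproduce the five-group, 40-samples-per-group layout:
    9 h 30 min of drying sampled every 30 min (19 dried samples), 20
    incremental 5 mL rewets of a 200 g aliquot, plus the original sample.
    Initial per-group moistures sit inside the wet-basis ranges typical of
    each material.
    """

    n_groups: int = 5
    initial_moisture: tuple[float, ...] = (0.45, 0.30, 0.35, 0.32, 0.28)
    initial_mass: tuple[float, ...] = (200.0, 200.0, 200.0, 200.0, 200.0)
    drying_duration: float = 570.0  # minutes (9 h 30 min)
    withdrawal_interval: float = 30.0  # minutes
    drying_rate: float = 0.085  # per-step fractional water loss
    rewet_increment: float = 5.0  # mL == g of water per step
    rewet_count: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_groups > len(GROUPS):
            raise DesignError(f"n_groups must be in 1..{len(GROUPS)}")
        if len(self.initial_moisture) < self.n_groups or len(self.initial_mass) < self.n_groups:
            raise DesignError("need one initial moisture and mass per group")
        if self.withdrawal_interval <= 0:
            raise DesignError("withdrawal_interval must be positive")
        n_steps = self.drying_duration / self.withdrawal_interval
        if self.drying_duration < 0 or abs(n_steps - round(n_steps)) > 1e-9:
            raise DesignError("drying_duration must be a whole number of withdrawal intervals")
        if self.rewet_increment <= 0:
            raise DesignError("rewet_increment must be positive")
        if not (0.0 <= self.drying_rate < 1.0):
            raise DesignError("drying_rate must be in [0, 1)")
        if self.rewet_count < 0:
            raise DesignError("rewet_count must be non-negative")

    @property
    def n_withdrawals(self) -> int:
        return int(round(self.drying_duration / self.withdrawal_interval))


def emulate_design(config: DesignConfig) -> list[SampleRecord]:
    """Generate the full list of sample records for a design.

    Per group: 1 original + ``n_withdrawals`` dried + ``rewet_count``
    rewetted records.  Dry matter is conserved within each arm; rewetted
    moisture is ``(W_m0 + k*dose) / (W_o + k*dose)`` exactly.
    """
    records: list[SampleRecord] = []
    for g in range(config.n_groups):
        group = GROUPS[g]
        W_o = float(config.initial_mass[g])
        M0 = float(config.initial_moisture[g])
        if not (0.0 <= M0 < 1.0):
            raise DesignError(f"group {group}: initial moisture {M0} outside [0, 1)")
        W_m0 = W_o * M0
        W_d = W_o - W_m0  # == dry_matter(W_o, M0)

        def rec(treatment: str, k: int, W_m: float) -> SampleRecord:
            if W_m < 0:
                raise DesignError(f"group {group}, {treatment} step {k}: negative water mass")
            M = moisture_wet_basis(W_m, W_d)
            if M >= 1.0:
                raise DesignError(f"group {group}, {treatment} step {k}: moisture >= 1")
            return SampleRecord(group, treatment, k, W_o, W_m, W_d, M, W_d)

        records.append(rec("original", 0, W_m0))
        for k in range(1, config.n_withdrawals + 1):
            records.append(rec("dried", k, W_m0 * (1.0 - config.drying_rate) ** k))
        for k in range(1, config.rewet_count + 1):
            records.append(rec("rewetted", k, W_m0 + k * config.rewet_increment))
    return records


def records_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    """Reference table: one row per sample, moisture in percent."""
    return pd.DataFrame(
        {
            "group_id": [r.group_id for r in records],
            "treatment": [r.treatment for r in records],
            "step_index": [r.step_index for r in records],
            "W_o": [r.W_o for r in records],
            "W_m": [r.W_m for r in records],
            "W_d": [r.W_d for r in records],
            "M_wb_percent": [100.0 * r.M_wb for r in records],
            "DM_g": [r.DM for r in records],
        }
    )
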