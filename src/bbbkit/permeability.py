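"""Two-compartment sampling-assay permeability and barrier categorization.

A fluorescent tracer (e.g. lucifer yellow at 150 μg/ml) is loaded into the
top compartment of a membrane device; after an incubation the bottom
compartment is sampled and the tracer concentration read on a plate
reader. Under sink conditions the system permeability is

    P_S = (C_t · V) / (C_i · t · A)

where ``C_t`` is the sampled bottom concentration, ``V`` the effective
bottom/sample volume, ``C_i`` the loading concentration, ``t`` the
incubation time and ``A`` the membrane area. The membrane and the cell
monolayer act as resistances in series, so the endothelial coefficient is
recovered from a cell-free membrane measurement ``P_M``:

    1/P_e = 1/P_S − 1/P_M

Barriers are categorized by the endothelial lucifer-yellow coefficient:
Tight (P_e ≤ 0.6 × 10⁻³ cm/min), Leaky (0.6 × 10⁻³ < P_e ≤ 1.5 × 10⁻³)
and Disrupted (P_e > 1.5 × 10⁻³), boundaries inclusive as stated.

All permeabilities are stored in cm/min; rendering in 10⁻³ cm/min belongs
to the reporting layer only.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BarrierCategory",
    "PermeabilityRecord",
    "PermeabilityResult",
    "system_permeability",
    "endothelial_permeability",
    "classify_barrier",
    "analyze_record",
    "contingency",
]

#: category thresholds for the endothelial lucifer-yellow coefficient, cm/min
TIGHT_MAX = 0.6e-3
LEAKY_MAX = 1.5e-3

#: relative closeness of P_S to P_M treated as numerically unbounded
NEAR_SINGULAR_FRACTION = 0.01


class BarrierCategory(str, enum.Enum):
    TIGHT = "Tight"
    LEAKY = "Leaky"
    DISRUPTED = "Disrupted"


@dataclass
class PermeabilityRecord:
    """One device's sampling-assay measurement.

    Fields: ``Ct`` sampled bottom-compartment concentration (μg/ml), ``V``
    effective volume read on the plate (ml), ``Ci`` initial top
    concentration (μg/ml), ``t`` incubation time (min), ``A`` membrane area
    (cm², measured per device), ``Pm`` cell-free membrane system
    permeability (cm/min) or None when unavailable (micropore membranes),
    ``membrane_type`` "NPN" (nanopores only) or "DS" (added micropores).
    """

    Ct: float
    V: float
    Ci: float
    t: float
    A: float
    Pm: float | None = None
    membrane_type: str = "NPN"

    def __post_init__(self) -> None:
        for name in ("V", "Ci", "t", "A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Ct < 0:
            raise ValueError("Ct must be non-negative")
        if self.Ct >= self.Ci:
            raise ValueError("Ct must be below the loading concentration Ci")
        if self.Pm is not None and self.Pm <= 0:
            raise ValueError("Pm must be positive when given")
        if self.membrane_type not in ("NPN", "DS"):
            raise ValueError("membrane_type must be 'NPN' or 'DS'")
        if self.Ct / self.Ci > 0.1:
            warnings.warn(
                "Ct/Ci > 0.1: sink-condition assumption of the linear "
                "permeability estimate is questionable", stacklevel=2)


@dataclass
class PermeabilityResult:
    """Derived permeability of one device.

    ``basis`` records whether ``category`` applies: the Tight/Leaky/
    Disrupted categories are defined for the endothelial coefficient only.
    ``unbounded`` marks a near-singular membrane correction (P_S within 1%
    of P_M), where P_e is reported as ``inf`` rather than a huge number.
    """

    Ps: float
    Pe: float | None
    category: BarrierCategory | None
    basis: str  # "endothelial" | "system"
    unbounded: bool = False


def system_permeability(rec: PermeabilityRecord) -> float:
    """System permeability P_S = C_t·V / (C_i·t·A), cm/min."""
    return rec.Ct * rec.V / (rec.Ci * rec.t * rec.A)


def endothelial_permeability(Ps: float, Pm: float) -> float:
    """Endothelial coefficient from the series-resistance correction.

    P_e = (1/P_S − 1/P_M)⁻¹. Requires 0 < P_S < P_M; a system permeability
    at or above the cell-free membrane value means the cell layer adds no
    resistance and is rejected. P_S within 1% of P_M yields ``inf`` with a
    warning (numerically unbounded) instead of a huge finite number.
    """
    if Ps <= 0:
        raise ValueError("Ps must be positive")
    if Pm <= 0:
        raise ValueError("Pm must be positive")
    if Ps >= Pm:
        raise ValueError(
            "Ps >= Pm is non-physical: the cell layer adds no resistance")
    if Ps >= (1.0 - NEAR_SINGULAR_FRACTION) * Pm:
        warnings.warn(
            "Ps within 1% of Pm: endothelial permeability is numerically "
            "unbounded; reporting inf", stacklevel=2)
        return float("inf")
    return 1.0 / (1.0 / Ps - 1.0 / Pm)


def classify_barrier(Pe: float, basis: str = "endothelial") -> BarrierCategory:
    """Categorize a barrier by its endothelial lucifer-yellow coefficient.

    Tight: P_e ≤ 0.6 × 10⁻³ cm/min (boundary inclusive); Leaky: up to and
    including 1.5 × 10⁻³; Disrupted above. System-basis coefficients are
    rejected — the thresholds are calibrated for the cell layer alone.
    """
    if basis != "endothelial":
        raise ValueError("barrier categories are defined for the "
                         "endothelial coefficient only")
    if Pe <= 0:
        raise ValueError("Pe must be positive")
    if Pe <= TIGHT_MAX:
        return BarrierCategory.TIGHT
    if Pe <= LEAKY_MAX:
        return BarrierCategory.LEAKY
    return BarrierCategory.DISRUPTED


def analyze_record(rec: PermeabilityRecord) -> PermeabilityResult:
    """Full pipeline for one device: P_S, then P_e and category if a
    cell-free membrane permeability is available.

    Without ``Pm`` (e.g. DS membranes, where a cell-free control cannot be
    sampled) the result carries system basis and no category.
    """
    ps = system_permeability(rec)
    if rec.Pm is None:
        return PermeabilityResult(Ps=ps, Pe=None, category=None, basis="system")
    pe = endothelial_permeability(ps, rec.Pm)
    if pe == float("inf"):
        return PermeabilityResult(Ps=ps, Pe=float("inf"), category=None,
                                  basis="endothelial", unbounded=True)
    return PermeabilityResult(Ps=ps, Pe=pe, category=classify_barrier(pe),
                              basis="endothelial")


def contingency(
    groups: Mapping[str, Iterable[BarrierCategory | str]],
) -> pd.DataFrame:
    """Treatment-group × barrier-category count table.

    Rows are groups in input order, columns Tight/Leaky/Disrupted; row sums
    equal group sizes. Unknown category labels raise.
    """
    if not groups:
        raise ValueError("need at least one group")
    order = [c.value for c in BarrierCategory]
    rows = {}
    for name, cats in groups.items():
        counts = dict.fromkeys(order, 0)
        for c in cats:
            label = c.value if isinstance(c, BarrierCategory) else str(c)
            if label not in counts:
                raise ValueError(f"unknown barrier category: {label!r}")
            counts[label] += 1
        rows[name] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=order)
    df.index.name = "group"
    return df
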