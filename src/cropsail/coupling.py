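"""Crop-state to radiative-transfer-parameter coupling.

Each :class:`~cropsail.trajectory.CropState` is converted into the 14 input
parameters of the canopy forward model through fixed empirical
transformations: the mesophyll structure parameter from specific leaf area,
equivalent water thickness from growth stage and dead-leaf fraction (two
branches), dry matter from leaf dry weight per leaf area, chlorophyll from
leaf nitrogen, carotenoids as a fixed fraction of chlorophyll, and the
hot-spot parameter inversely proportional to LAI. Anthocyanins, brown
pigment, soil brightness, average leaf angle and viewing zenith are held
fixed. Solar angles come from the observation geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

from .errors import CouplingDomainError, DegenerateStateError
from .geometry import ObservationGeometry
from .trajectory import CropState

__all__ = [
    "RTMParams",
    "DerivedLeafQuantities",
    "derive_leaf_quantities",
    "couple",
    "couple_trajectory",
    "HSPOT_A",
    "CAR_TO_CAB",
    "CAB_PER_LNC",
    "FIXED_FIELDS",
]

#: empirical numerator of the hot-spot relation hspot = a / LAI
HSPOT_A = 0.5
#: carotenoid-to-chlorophyll ratio
CAR_TO_CAB = 0.216
#: chlorophyll (ug cm-2) per unit leaf nitrogen content (g m-2)
CAB_PER_LNC = 26.0
#: parameters held constant throughout the framework
FIXED_FIELDS = {"Cant": 0.0, "Cbrown": 0.0, "psoil": 1.0, "ALA": 50.0, "VZA": 0.0}

#: structure-parameter range outside which a coupled record is flagged
NS_PLAUSIBLE = (1.0, 3.5)


@dataclass(frozen=True)
class RTMParams:
    """The 14 forward-model inputs.

    Units: Cw, Cm in g cm-2; Cab, Car, Cant in ug cm-2; LAI in m2 m-2;
    ALA, SZA, VZA, RAA in degrees; hspot in m m-1; Ns, Cbrown, psoil
    unitless.
    """

    Ns: float
    Cw: float
    Cm: float
    Cab: float
    Car: float
    LAI: float
    hspot: float
    SZA: float
    RAA: float
    Cant: float = 0.0
    Cbrown: float = 0.0
    psoil: float = 1.0
    ALA: float = 50.0
    VZA: float = 0.0
    #: True when Ns fell outside the plausible leaf-structure range (record kept)
    ns_flagged: bool = False

    @staticmethod
    def field_names() -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(RTMParams) if f.name != "ns_flagged")


@dataclass(frozen=True)
class DerivedLeafQuantities:
    """Leaf-level quantities derived from a crop state.

    SLA: specific leaf area, cm2 mg-1; LNC: leaf nitrogen per leaf area,
    g m-2; f_dead: dead-leaf fraction in [0, 1].
    """

    SLA: float
    LNC: float
    f_dead: float


def derive_leaf_quantities(state: CropState) -> DerivedLeafQuantities:
    """SLA = 10*LAI_total/LDW, f_dead = LAI_dead/LAI_total, LNC = CNC/LAI_total."""
    if state.LAI_total <= 0 or state.LDW <= 0:
        raise DegenerateStateError(
            f"cannot derive leaf quantities for LAI_total={state.LAI_total}, LDW={state.LDW}"
        )
    return DerivedLeafQuantities(
        SLA=10.0 * state.LAI_total / state.LDW,
        LNC=state.CNC / state.LAI_total,
        f_dead=state.LAI_dead / state.LAI_total,
    )


def _cw(zs: float, f_dead: float) -> float:
    """Equivalent water thickness, g cm-2 (two-branch form, branch on f_dead == 0)."""
    if f_dead == 0.0:
        cw = -0.000196 * zs + 0.0298
    else:
        cw = 0.0223 * math.exp(-1.90 * f_dead)
    # the green branch stays positive for any Zadok score on the 0-100 scale
    assert cw > 0.0, f"computed Cw={cw} <= 0 (Zs={zs}, f_dead={f_dead})"
    return cw


def couple(
    state: CropState,
    geometry: ObservationGeometry,
    hspot_a: float = HSPOT_A,
) -> RTMParams:
    """Convert one crop state plus observation geometry into forward-model inputs.

    Raises :class:`DegenerateStateError` for bare states (LAI_total = 0) and
    :class:`CouplingDomainError` when SLA <= 0.1 cm2 mg-1, where the
    structure-parameter relation has a pole. Records whose computed Ns falls
    outside the plausible range are flagged (``ns_flagged``) but retained.
    """
    q = derive_leaf_quantities(state)
    if q.SLA <= 0.1:
        raise CouplingDomainError(
            f"SLA={q.SLA:.4f} cm2 mg-1 <= 0.1: structure parameter undefined"
        )
    ns = (0.9 * q.SLA + 0.025) / (q.SLA - 0.1)
    cab = CAB_PER_LNC * q.LNC
    return RTMParams(
        Ns=ns,
        Cw=_cw(state.Zs, q.f_dead),
        Cm=1e-4 * state.LDW / state.LAI_total,
        Cab=cab,
        Car=CAR_TO_CAB * cab,
        LAI=state.LAI_total,
        hspot=hspot_a / state.LAI_total,
        SZA=geometry.SZA,
        RAA=geometry.RAA,
        ns_flagged=not (NS_PLAUSIBLE[0] <= ns <= NS_PLAUSIBLE[1]),
        **FIXED_FIELDS,
    )


def couple_trajectory(
    states, geometry: ObservationGeometry, hspot_a: float = HSPOT_A
) -> list[RTMParams]:
    """Couple every non-bare state of a trajectory; bare states are skipped."""
    out = []
    for s in states:
        if s.LAI_total <= 0:
            continue
        out.append(couple(s, geometry, hspot_a=hspot_a))
    return out
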