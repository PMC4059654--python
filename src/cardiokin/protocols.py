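"""The characteristic kinetic assays and their simulators.

Six experiments constrain the model family:

``RESP_ADP`` / ``RESP_ATP``
    Oxygraphy: steady-state respiration after stepwise additions of ADP or
    ATP.  Each titration point is treated as an independent steady state
    with the solution clamped at the titrant concentration (the other
    nucleotide at zero) — the quasi-steady approximation for a large
    chamber.  Respiration is the ATP-synthase flux divided by the
    ATP-per-O₂ stoichiometry, plus the basal (leak) rate.
``RESP_PEP_PK``
    PK-competition oxygraphy: respiration is first stimulated by 2 mM ATP
    with PEP in solution (endogenous PK active), then exogenous PK is
    added.  Both stages are closed-chamber steady states conserving the
    total adenine nucleotide.
``ATPASE_ATP``
    Spectrophotometric total ATPase activity versus ATP with respiration
    inhibited and the PK+LDH reporter system present: NADH consumption
    tracks the summed (exogenous + endogenous) PK flux, which at steady
    state equals the total ATPase flux.
``PKEND_ADP``
    Spectrophotometric endogenous PK activity versus ADP, respiration
    inhibited, no exogenous PK.

Rates are nmol O₂·min⁻¹·mg⁻¹ for respiration and nmol ATP·min⁻¹·mg⁻¹ for
the spectrophotometric activities.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .steady_state import CompartmentState, SolverError, solve_steady_state
from .topology import ATPASE2, ModelTopology

RESP_ADP = "RESP_ADP"
RESP_ATP = "RESP_ATP"
RESP_PEP_PK = "RESP_PEP_PK"
ATPASE_ATP = "ATPASE_ATP"
PKEND_ADP = "PKEND_ADP"
RESP_BASAL = "RESP_BASAL"  # single basal-respiration reading

TITRATION_ASSAYS = (RESP_ADP, RESP_ATP, ATPASE_ATP, PKEND_ADP)
ASSAY_IDS = TITRATION_ASSAYS + (RESP_PEP_PK, RESP_BASAL)

O2_UNITS = "nmol O2/min/mg"
ATP_UNITS = "nmol ATP/min/mg"

#: default stepwise-addition schedules (mM); configurable per protocol
ADP_SCHEDULE = (0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0)
ATP_SCHEDULE = (0.05, 0.1, 0.25, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class AssayProtocol:
    """Machine description of one characteristic experiment."""

    assay_id: str
    titration_schedule: tuple[float, ...] = ()
    pep_present: bool = False
    pkexo_present: bool = False
    mito_active: bool = True
    basal_rate: float = 0.0          # nmol O2/min/mg, respiration offset
    chamber_density: float = 0.125   # mg protein/ml (closed-chamber assays)
    total_nucleotide: float = 2.0    # mM, closed-chamber ATP load

    def __post_init__(self):
        if self.assay_id not in ASSAY_IDS:
            raise ValueError(
                f"unknown assay id {self.assay_id!r}; valid: {ASSAY_IDS}")
        if self.assay_id in (ATPASE_ATP, PKEND_ADP) and self.mito_active:
            raise ValueError(
                f"{self.assay_id}: respiration must be inhibited "
                "(spectrophotometric assay)")
        if any(x < 0 for x in self.titration_schedule):
            raise ValueError("negative titrant concentration")
        if list(self.titration_schedule) != sorted(set(self.titration_schedule)):
            raise ValueError("titration schedule must be strictly increasing")


def default_protocols(basal_rate: float = 0.0) -> dict[str, AssayProtocol]:
    """The six assays with default schedules and conditions."""
    return {
        RESP_ADP: AssayProtocol(RESP_ADP, ADP_SCHEDULE, basal_rate=basal_rate),
        RESP_ATP: AssayProtocol(RESP_ATP, ATP_SCHEDULE, basal_rate=basal_rate),
        ATPASE_ATP: AssayProtocol(ATPASE_ATP, ATP_SCHEDULE, pep_present=True,
                                  pkexo_present=True, mito_active=False),
        PKEND_ADP: AssayProtocol(PKEND_ADP, ADP_SCHEDULE, pep_present=True,
                                 mito_active=False),
        RESP_PEP_PK: AssayProtocol(RESP_PEP_PK, (0.0, 1.0), pep_present=True,
                                   pkexo_present=True, basal_rate=basal_rate),
        RESP_BASAL: AssayProtocol(RESP_BASAL, (0.0,), basal_rate=basal_rate),
    }


def save_protocols(path: str | Path,
                   protocols: dict[str, AssayProtocol]) -> None:
    """Write a protocol-preset JSON file (assay_id -> field mapping)."""
    with open(path, "w") as fh:
        json.dump({aid: dataclasses.asdict(p) for aid, p in protocols.items()},
                  fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_protocols(path: str | Path) -> dict[str, AssayProtocol]:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for aid, fields in payload.items():
        fields = dict(fields)
        fields["titration_schedule"] = tuple(
            fields.get("titration_schedule", ()))
        out[aid] = AssayProtocol(**fields)
    return out


@dataclass
class AssayCurve:
    """Simulated (or measured) titration curve of one assay."""

    assay_id: str
    points: list[tuple[float, float]]
    y_units: str = ATP_UNITS
    states: list[CompartmentState] = field(default_factory=list, repr=False)

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"assay_id": self.assay_id, "x_mM": self.x,
                             "y": self.y, "y_units": self.y_units})


def _solve_point(topo, params, protocol, x, init):
    """One titration steady state; clamp layout depends on the assay."""
    if protocol.assay_id in (RESP_ADP, PKEND_ADP):
        boundary = {"ADP": x, "ATP": 0.0}
    elif protocol.assay_id == RESP_ATP:
        boundary = {"ATP": x, "ADP": 0.0}
    elif protocol.assay_id == ATPASE_ATP:
        # solution ADP is free: the exogenous PK reaction consumes the ADP
        # released by the cells
        boundary = {"ATP": x}
    else:
        raise ValueError(f"{protocol.assay_id} is not a titration assay")
    return solve_steady_state(
        topo, params, boundary, pep_present=protocol.pep_present,
        pkexo_present=protocol.pkexo_present, mito_active=protocol.mito_active,
        init=init)


def _curve_value(protocol, params, state: CompartmentState) -> float:
    if protocol.assay_id in (RESP_ADP, RESP_ATP, RESP_PEP_PK):
        return protocol.basal_rate + state.synthase_flux / params.atp_per_o2
    if protocol.assay_id == ATPASE_ATP:
        return state.total_pk_flux()           # = total ATPase flux (closure)
    if protocol.assay_id == PKEND_ADP:
        return state.total_pk_flux(endogenous_only=True)
    if protocol.assay_id == RESP_BASAL:
        return protocol.basal_rate
    raise ValueError(protocol.assay_id)


def simulate_titration(topo: ModelTopology, params: ParameterSet,
                       protocol: AssayProtocol) -> AssayCurve:
    """Predict a titration curve, one independent steady state per point."""
    if protocol.assay_id not in TITRATION_ASSAYS:
        raise ValueError(
            f"simulate_titration expects one of {TITRATION_ASSAYS}, got "
            f"{protocol.assay_id}")
    units = O2_UNITS if protocol.assay_id.startswith("RESP") else ATP_UNITS
    curve = AssayCurve(protocol.assay_id, [], y_units=units)
    init = None
    for x in protocol.titration_schedule:
        try:
            state = _solve_point(topo, params, protocol, x, init)
        except SolverError as err:
            raise SolverError(
                f"{protocol.assay_id} at {x} mM: {err}", err.residual) from err
        init = np.array([state.concentrations[c] for c in topo.compartments])
        curve.points.append((x, _curve_value(protocol, params, state)))
        curve.states.append(state)
    return curve


def simulate_pk_competition(topo: ModelTopology, params: ParameterSet,
                            protocol: AssayProtocol) -> tuple[float, float]:
    """The two PK-competition respiration rates (PEP, then PEP + exo PK).

    Returns ``(vo2_pep, vo2_pep_pk)``; adding the competing exogenous PK
    cannot raise respiration, so the second rate never exceeds the first.
    """
    boundary = {"total": protocol.total_nucleotide}
    pep = solve_steady_state(topo, params, boundary, pep_present=True,
                             pkexo_present=False,
                             mito_active=protocol.mito_active)
    pep_pk = solve_steady_state(topo, params, boundary, pep_present=True,
                                pkexo_present=True,
                                mito_active=protocol.mito_active)
    resp = replace(protocol, assay_id=RESP_PEP_PK) \
        if protocol.assay_id != RESP_PEP_PK else protocol
    return (_curve_value(resp, params, pep), _curve_value(resp, params, pep_pk))


def c4_fraction(topo: ModelTopology, params: ParameterSet,
                atp: float) -> float:
    """Fraction of total ATPase flux carried by the C4 compartment.

    Evaluated under the spectrophotometric ATPase condition: respiration
    inhibited, PEP and exogenous PK present, solution clamped at the given
    ATP concentration.  Models without C4 return 0.  The result is a pure
    flux ratio, independent of the respiration stoichiometry.
    """
    if atp < 0:
        raise ValueError(f"ATP concentration must be >= 0, got {atp}")
    if not topo.has_c4:
        return 0.0
    state = solve_steady_state(topo, params, {"ATP": atp}, pep_present=True,
                               pkexo_present=True, mito_active=False)
    total = state.total_atpase_flux()
    if total <= 0:
        return 0.0
    return state.fluxes[ATPASE2] / total
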