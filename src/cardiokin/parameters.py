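"""Kinetic parameter sets and packaged presets.

A :class:`ParameterSet` carries the free kinetic constants of one model
variant (maximal rates in nmol·min⁻¹·mg protein⁻¹, Michaelis constants in
mM, exchange coefficients in nmol·min⁻¹·mg⁻¹·mM⁻¹) together with the fixed
auxiliary constants shared by the whole family:

``Km_syn_adp`` / ``Ki_syn_atp``
    apparent ADP affinity and competitive ATP product inhibition of the
    lumped ATP-synthase reaction (mM).  These are calibration constants of
    the reconstruction, not fitted quantities; see docs/methods.md.
``atp_per_o2``
    stoichiometric conversion between ATP synthesis flux and oxygen
    consumption (nmol ATP per nmol O₂).
``V_pkexo`` / ``Km_pkexo_adp``
    effective capacity (nmol·min⁻¹·mg⁻¹) and ADP affinity (mM) of the
    exogenously added pyruvate kinase, expressed per mg of cell protein.

Presets named ``table3_<model_id>`` package the published point estimates
for the ouabain-inhibited (NKA-inhibited) condition.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .topology import FREE_PARAMS, MODEL_IDS, ModelTopology

#: default fixed auxiliary constants (see docs/methods.md for the calibration)
AUX_DEFAULTS = {
    "Km_syn_adp": 0.02,     # mM
    "Ki_syn_atp": 0.059,    # mM; None disables product inhibition
    "atp_per_o2": 4.13,     # nmol ATP per nmol O2
    "V_pkexo": 465.0,       # nmol/min/mg protein
    "Km_pkexo_adp": 0.3,    # mM
}

AUX_NAMES = tuple(AUX_DEFAULTS)

#: fitting bounds, shared by every model variant
KM_BOUNDS = (0.05, 10.0)        # mM
RATE_BOUNDS = (0.0, 1.0e7)      # nmol/min/mg
EXCHANGE_BOUNDS = (0.0, 1.0e6)  # nmol/min/mg/mM


@dataclass
class ParameterSet:
    """Named kinetic constants for one model variant.

    Free parameters that are absent from a topology are left ``None`` and
    are never reported for it.
    """

    V_syn: float | None = None
    C_sol_cyt: float | None = None
    C_cyt_ims: float | None = None
    C_c4: float | None = None
    V_atpase1: float | None = None
    Km_atp1: float | None = None
    Km_adp1: float | None = None
    V_atpase2: float | None = None
    Km_atp2: float | None = None
    Km_adp2: float | None = None
    V_pkend1: float | None = None
    V_pkend2: float | None = None
    Km_pk_adp: float | None = None
    # fixed auxiliary constants
    Km_syn_adp: float = AUX_DEFAULTS["Km_syn_adp"]
    Ki_syn_atp: float | None = AUX_DEFAULTS["Ki_syn_atp"]
    atp_per_o2: float = AUX_DEFAULTS["atp_per_o2"]
    V_pkexo: float = AUX_DEFAULTS["V_pkexo"]
    Km_pkexo_adp: float = AUX_DEFAULTS["Km_pkexo_adp"]

    def __getitem__(self, name: str) -> float | None:
        return getattr(self, name)

    def replace(self, **updates) -> "ParameterSet":
        return dataclasses.replace(self, **updates)

    def validate(self, topo: ModelTopology) -> None:
        """Check that every free parameter of *topo* is present and sane."""
        for name in topo.free_parameters:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"model {topo.model_id}: parameter {name} missing")
            if value < 0:
                raise ValueError(f"parameter {name} = {value} must be >= 0")

    def free_vector(self, topo: ModelTopology) -> list[float]:
        self.validate(topo)
        return [getattr(self, name) for name in topo.free_parameters]

    @classmethod
    def from_free_vector(cls, topo: ModelTopology, values, **aux) -> "ParameterSet":
        names = topo.free_parameters
        if len(values) != len(names):
            raise ValueError(
                f"model {topo.model_id} expects {len(names)} parameters, got "
                f"{len(values)}")
        return cls(**dict(zip(names, map(float, values))), **aux)

    def to_dict(self, topo: ModelTopology | None = None) -> dict:
        """JSON-ready mapping; restricted to *topo*'s parameters if given."""
        if topo is None:
            out = {f.name: getattr(self, f.name)
                   for f in dataclasses.fields(self)
                   if getattr(self, f.name) is not None}
        else:
            out = {name: getattr(self, name) for name in topo.free_parameters}
            out.update({name: getattr(self, name) for name in AUX_NAMES})
            out["model_id"] = topo.model_id
        return out


def load_parameters(source: str | Path | dict) -> tuple[str | None, ParameterSet]:
    """Read a parameter JSON file (or mapping); returns (model_id, params)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            payload = json.load(fh)
    else:
        payload = dict(source)
    model_id = payload.pop("model_id", None)
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    return model_id, ParameterSet(**payload)


def save_parameters(path: str | Path, params: ParameterSet,
                    topo: ModelTopology | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(topo), fh, indent=1, sort_keys=True)
        fh.write("\n")


def preset(model_id: str) -> ParameterSet:
    """Packaged point estimates for the NKA-inhibited condition."""
    mid = str(model_id)
    if mid not in MODEL_IDS:
        raise KeyError(f"unknown model id {model_id!r}; valid ids: {MODEL_IDS}")
    ref = resources.files("cardiokin.presets").joinpath(f"table3_{mid}.json")
    _, params = load_parameters(json.loads(ref.read_text()))
    return params


def bounds_for(topo: ModelTopology) -> list[tuple[float, float]]:
    """Fitting bounds, ordered like ``topo.free_parameters``."""
    out = []
    for name in topo.free_parameters:
        if name.startswith("Km"):
            out.append(KM_BOUNDS)
        elif name.startswith("C_"):
            out.append(EXCHANGE_BOUNDS)
        else:
            out.append(RATE_BOUNDS)
    return out


__all__ = [
    "ParameterSet", "AUX_DEFAULTS", "AUX_NAMES", "KM_BOUNDS", "RATE_BOUNDS",
    "EXCHANGE_BOUNDS", "load_parameters", "save_parameters", "preset",
    "bounds_for", "FREE_PARAMS",
]
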