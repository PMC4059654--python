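"""Steady-state solver for the compartmental reaction–exchange network.

Each model variant defines a set of well-mixed compartments carrying free
ATP and ADP, 1:1 interconversion reactions (ATP synthase, ATPases, pyruvate
kinases) and linear inter-compartment exchange (flux = coefficient times
concentration difference).  A steady state is a concentration assignment at
which every compartment's net production of each nucleotide vanishes.

Boundary conditions come in two flavours:

clamped solution
    One or both solution-side concentrations are held fixed — the
    quasi-steady treatment of a titration step in a large chamber.  An
    unclamped solution species keeps its own balance equation (fed by the
    exogenous PK reaction and cell exchange).
closed chamber
    No clamps; the total adenine nucleotide concentration referenced to the
    solution volume is conserved (the PK-competition respiration protocol).

The solver is a damped Newton iteration with analytic Jacobian,
step-halving on residual increase, and nonnegativity clipping of the
iterates.  Convergence requires the max-norm mass-balance residual to fall
below ``tol`` relative to the largest flux in the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import _mm
from .parameters import ParameterSet
from .topology import (ATP_SYNTHASE, ATPASE1, ATPASE2, PKEND1, PKEND2, PKEXO,
                       SOLUTION, ModelTopology, TopologyError)

ATP, ADP = 0, 1
_SPECIES = ("ATP", "ADP")


class SolverError(RuntimeError):
    """Steady-state iteration failed; carries the last residual max-norm."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class CompartmentState:
    """Concentrations and fluxes of one solved (or probed) network state.

    ``concentrations`` maps compartment -> (ATP, ADP) in mM.  ``fluxes``
    maps reaction name -> signed ATP production rate?  No: reaction fluxes
    are reported as nonnegative turnover rates (nmol·min⁻¹·mg⁻¹) in the
    direction each enzyme runs.  ``exchange_fluxes`` maps a compartment
    pair to the net (ATP, ADP) flux from the first to the second member.
    """

    concentrations: dict[str, tuple[float, float]]
    fluxes: dict[str, float] = field(default_factory=dict)
    exchange_fluxes: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict)
    residual: float = np.nan
    converged: bool = False

    def atp(self, compartment: str) -> float:
        return self.concentrations[compartment][ATP]

    def adp(self, compartment: str) -> float:
        return self.concentrations[compartment][ADP]

    def total_atpase_flux(self) -> float:
        return (self.fluxes.get(ATPASE1, 0.0) + self.fluxes.get(ATPASE2, 0.0))

    def total_pk_flux(self, endogenous_only: bool = False) -> float:
        total = self.fluxes.get(PKEND1, 0.0) + self.fluxes.get(PKEND2, 0.0)
        if not endogenous_only:
            total += self.fluxes.get(PKEXO, 0.0)
        return total

    @property
    def synthase_flux(self) -> float:
        return self.fluxes.get(ATP_SYNTHASE, 0.0)


# reaction spec: (name, substrate species, inhibitor species | None,
#                 V name, (Km name, Ki name | None), gate, sign for ATP)
def _reaction_specs(topo: ModelTopology):
    key = (topo.model_id, tuple(sorted(topo.reactions.items())),
           topo.shared_affinities)
    cached = _SPEC_CACHE.get(key)
    if cached is not None:
        return cached
    specs = []
    for name, comp in topo.reactions.items():
        if name == ATP_SYNTHASE:
            specs.append((name, comp, ADP, ATP, "V_syn",
                          ("Km_syn_adp", "Ki_syn_atp"), "mito", +1))
        elif name in (ATPASE1, ATPASE2):
            km, ki = topo.affinity_names(name)
            vname = "V_atpase1" if name == ATPASE1 else "V_atpase2"
            specs.append((name, comp, ATP, ADP, vname, (km, ki), None, -1))
        elif name in (PKEND1, PKEND2):
            (km,) = topo.affinity_names(name)
            vname = "V_pkend1" if name == PKEND1 else "V_pkend2"
            specs.append((name, comp, ADP, None, vname, (km, None), "pep", +1))
        elif name == PKEXO:
            specs.append((name, comp, ADP, None, "V_pkexo",
                          ("Km_pkexo_adp", None), "pkexo", +1))
        else:  # pragma: no cover - topology() never produces this
            raise TopologyError(f"unknown reaction {name}")
    _SPEC_CACHE[key] = specs
    return specs


_SPEC_CACHE: dict[tuple, list] = {}


def reaction_fluxes(topo: ModelTopology, params: ParameterSet,
                    state: CompartmentState, *, pep_present: bool = False,
                    pkexo_present: bool = False,
                    mito_active: bool = True) -> CompartmentState:
    """Fill ``state.fluxes`` and ``state.exchange_fluxes`` from concentrations.

    Every reaction converts one nucleotide into the other with 1:1
    stoichiometry; pyruvate kinase reactions run only when PEP is present
    (PEP is a saturating on/off switch, not a state variable).
    """
    for comp in topo.compartments:
        if comp not in state.concentrations:
            raise TopologyError(
                f"state lacks concentrations for compartment {comp}")
    c = np.array([state.concentrations[comp] for comp in topo.compartments],
                 dtype=float)
    if (c < 0).any():
        raise ValueError("negative concentration in state")
    idx = {comp: i for i, comp in enumerate(topo.compartments)}
    gates = {"pep": 1.0 if pep_present else 0.0,
             "pkexo": 1.0 if (pkexo_present and pep_present) else 0.0,
             "mito": 1.0 if mito_active else 0.0, None: 1.0}
    state.fluxes = {}
    for name, comp, sub, inh, vn, (kmn, kin), gate, _sign in _reaction_specs(topo):
        i = idx[comp]
        V = params[vn]
        if V is None:
            raise ValueError(f"model {topo.model_id}: parameter {vn} missing")
        ki = params[kin] if kin is not None else None
        inh_c = c[i, inh] if inh is not None else 0.0
        rate, _, _ = _mm(V * gates[gate], c[i, sub], params[kmn], inh_c, ki)
        state.fluxes[name] = rate
    state.exchange_fluxes = {}
    for (a, b), cname in topo.exchanges.items():
        coeff = params[cname]
        if coeff is None:
            raise ValueError(f"model {topo.model_id}: parameter {cname} missing")
        ia, ib = idx[a], idx[b]
        state.exchange_fluxes[(a, b)] = (
            coeff * (c[ia, ATP] - c[ib, ATP]),
            coeff * (c[ia, ADP] - c[ib, ADP]),
        )
    return state


def solve_steady_state(topo: ModelTopology, params: ParameterSet,
                       boundary: dict, *, pep_present: bool = False,
                       pkexo_present: bool = False, mito_active: bool = True,
                       init: np.ndarray | None = None, tol: float = 1e-9,
                       max_iter: int = 200) -> CompartmentState:
    """Solve the steady state under a boundary condition.

    Parameters
    ----------
    boundary
        Mapping with keys among ``"ATP"``, ``"ADP"`` (clamped solution
        concentrations, mM) and ``"total"`` (closed-chamber total adenine
        nucleotide, mM).  ``"total"`` excludes the clamps.
    init
        Optional warm-start concentration array, shape ``(n_compartments, 2)``.
    tol
        Relative mass-balance tolerance (max-norm over compartments and
        species, relative to the largest flux in the network).
    """
    params.validate(topo)
    if "total" in boundary and ("ATP" in boundary or "ADP" in boundary):
        raise ValueError("closed-chamber 'total' excludes solution clamps")
    clamps = {}
    for key in ("ATP", "ADP"):
        if key in boundary:
            value = float(boundary[key])
            if value < 0:
                raise ValueError(f"clamped {key} must be >= 0, got {value}")
            clamps[_SPECIES.index(key)] = value
    total = float(boundary["total"]) if "total" in boundary else None
    if total is not None and total < 0:
        raise ValueError(f"total nucleotide must be >= 0, got {total}")
    if total is None and not clamps:
        raise ValueError("boundary must clamp the solution or set 'total'")

    comps = topo.compartments
    n = len(comps)
    idx = {comp: i for i, comp in enumerate(comps)}
    isol = idx[SOLUTION]
    specs = _reaction_specs(topo)
    gates = {"pep": 1.0 if pep_present else 0.0,
             "pkexo": 1.0 if (pkexo_present and pep_present) else 0.0,
             "mito": 1.0 if mito_active else 0.0, None: 1.0}
    exch = [(idx[a], idx[b], params[cname])
            for (a, b), cname in topo.exchanges.items()]

    # unknown (compartment, species) slots, flattened as 2*i + species
    unknown = [2 * i + s for i in range(n) for s in (ATP, ADP)
               if not (i == isol and s in clamps)]
    # equations: balances for every unknown slot, except that in the closed
    # chamber the solution-ATP balance (linearly dependent through total
    # nucleotide conservation) is swapped for the conservation constraint.
    eq_rows = list(unknown)
    conservation_row = None
    if total is not None:
        eq_rows.remove(2 * isol + ATP)
        conservation_row = len(eq_rows)

    def full_conc(x):
        c = np.empty((n, 2))
        c.flat[unknown] = x
        for s, v in clamps.items():
            c[isol, s] = v
        return c

    def residual_jacobian(x):
        c = full_conc(x)
        B = np.zeros((n, 2))            # net production per slot
        J = np.zeros((2 * n, 2 * n))    # d balance / d concentration
        max_flux = 0.0
        throughput = 0.0                # roundoff scale of the cancellations
        for _nm, comp, sub, inh, vn, (kmn, kin), gate, sign in specs:
            i = idx[comp]
            V = params[vn] * gates[gate]
            ki = params[kin] if kin is not None else None
            inh_c = c[i, inh] if inh is not None else 0.0
            rate, d_dS, d_dI = _mm(V, max(c[i, sub], 0.0), params[kmn],
                                   max(inh_c, 0.0), ki)
            max_flux = max(max_flux, abs(rate))
            # reaction converts substrate into the other species, 1:1
            B[i, sub] -= rate
            B[i, 1 - sub] += rate
            J[2 * i + sub, 2 * i + sub] -= d_dS
            J[2 * i + (1 - sub), 2 * i + sub] += d_dS
            if inh is not None:
                J[2 * i + sub, 2 * i + inh] -= d_dI
                J[2 * i + (1 - sub), 2 * i + inh] += d_dI
            assert sign in (-1, +1)
        for ia, ib, coeff in exch:
            for s in (ATP, ADP):
                flux = coeff * (c[ia, s] - c[ib, s])
                max_flux = max(max_flux, abs(flux))
                throughput = max(throughput, coeff * max(abs(c[ia, s]),
                                                         abs(c[ib, s])))
                B[ia, s] -= flux
                B[ib, s] += flux
                J[2 * ia + s, 2 * ia + s] -= coeff
                J[2 * ia + s, 2 * ib + s] += coeff
                J[2 * ib + s, 2 * ia + s] += coeff
                J[2 * ib + s, 2 * ib + s] -= coeff
        R = B.reshape(-1)[eq_rows].copy()
        Jr = J[np.ix_(eq_rows, range(2 * n))][:, unknown]
        if conservation_row is not None:
            cons = c[isol, ATP] + c[isol, ADP] - total
            grad = np.zeros(2 * n)
            grad[2 * isol + ATP] = 1.0
            grad[2 * isol + ADP] = 1.0
            R = np.concatenate([R, [cons]])
            Jr = np.vstack([Jr, grad[unknown]])
        return R, Jr, max_flux, throughput

    # initial guess: clamped solution values everywhere (titrations) or the
    # loaded nucleotide split evenly (closed chamber)
    if init is not None:
        x = np.asarray(init, dtype=float).reshape(n, 2).reshape(-1)[unknown]
    else:
        guess = np.zeros((n, 2))
        if total is not None:
            guess[:, ATP] = 0.75 * total
            guess[:, ADP] = 0.25 * total
        else:
            for s in (ATP, ADP):
                guess[:, s] = clamps.get(s, 0.0)
        x = guess.reshape(-1)[unknown]
    x = np.clip(x, 0.0, None)

    eps = np.finfo(float).eps
    scale = 1.0
    last_norm = np.inf
    for _it in range(max_iter):
        R, Jr, max_flux, throughput = residual_jacobian(x)
        scale = max(1.0, max_flux)
        norm = np.abs(R).max()
        # second term: roundoff floor of the exchange-flux cancellations
        # (relevant only for near-infinite exchange coefficients)
        if norm <= max(tol * scale, 16 * eps * throughput):
            break
        try:
            step = np.linalg.solve(Jr, -R)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Jr, -R, rcond=None)[0]
        alpha = 1.0
        while alpha > 1e-8:
            x_new = np.clip(x + alpha * step, 0.0, None)
            R_new = residual_jacobian(x_new)[0]
            if np.abs(R_new).max() < norm:
                break
            alpha *= 0.5
        else:
            # flat direction: accept a tiny damped step and keep iterating
            x_new = np.clip(x + 1e-8 * step, 0.0, None)
        x = x_new
        last_norm = norm
    else:
        raise SolverError(
            f"steady state did not converge in {max_iter} iterations "
            f"(last residual max-norm {last_norm:.3e})", residual=last_norm)

    c = full_conc(x)
    state = CompartmentState(
        concentrations={comp: (float(c[i, ATP]), float(c[i, ADP]))
                        for comp, i in idx.items()},
        residual=float(np.abs(R).max() / scale), converged=True)
    reaction_fluxes(topo, params, state, pep_present=pep_present,
                    pkexo_present=pkexo_present, mito_active=mito_active)
    return state
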