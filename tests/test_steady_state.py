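"""Solver correctness: oracles, conservation, nesting, monotonicity."""

import numpy as np
import pytest

import cardiokin as ck
from cardiokin.steady_state import ATP, ADP, CompartmentState
from cardiokin.topology import (ATP_SYNTHASE, ATPASE1, ATPASE2, PKEND1,
                                PKEND2, SOLUTION)

from _oracles import clamped_oracle
from conftest import random_params


def balance_residuals(topo, params, state, **flags):
    """Recompute per-compartment, per-species mass balances from the state."""
    ck.reaction_fluxes(topo, params, state, **flags)
    net = {comp: [0.0, 0.0] for comp in topo.compartments}
    consumes_atp = {ATPASE1, ATPASE2}
    for name, rate in state.fluxes.items():
        comp = topo.reactions[name]
        if name in consumes_atp:
            net[comp][ATP] -= rate
            net[comp][ADP] += rate
        else:  # synthase and the PKs convert ADP -> ATP
            net[comp][ATP] += rate
            net[comp][ADP] -= rate
    for (a, b), (fa, fd) in state.exchange_fluxes.items():
        net[a][ATP] -= fa
        net[b][ATP] += fa
        net[a][ADP] -= fd
        net[b][ADP] += fd
    return net


def test_no_sources_equilibrates_to_clamp():
    topo = ck.topology("2s")
    params = ck.preset("2s").replace(V_syn=0.0, V_atpase1=0.0, V_pkend1=0.0)
    st = ck.solve_steady_state(topo, params, {"ATP": 2.0, "ADP": 0.0})
    for comp in topo.compartments:
        assert st.atp(comp) == pytest.approx(2.0, abs=1e-9)
        assert st.adp(comp) == pytest.approx(0.0, abs=1e-9)
    assert all(abs(f) < 1e-9 for f in st.fluxes.values())


def test_infinite_exchange_reduces_to_single_compartment():
    """With unrestricted exchange the ATPase sees the clamped solution."""
    params = ck.preset("1").replace(C_sol_cyt=1e9, C_cyt_ims=1e9)
    st = ck.solve_steady_state(ck.topology("1"), params,
                               {"ATP": 2.0, "ADP": 0.1})
    expected = ck.mm_rate(params.V_atpase1, 2.0, params.Km_atp1, 0.1,
                          params.Km_adp1)
    assert st.fluxes[ATPASE1] == pytest.approx(expected, rel=1e-6)


def test_model1_finite_exchange_fixed_point():
    """Flux through the solution-cytosol barrier equals the local MM rate."""
    params = ck.preset("1")
    st = ck.solve_steady_state(ck.topology("1"), params,
                               {"ATP": 2.0, "ADP": 0.0}, mito_active=False)
    J = st.fluxes[ATPASE1]
    assert J == pytest.approx(
        params.C_sol_cyt * (2.0 - st.atp("cytosol")), rel=1e-6)
    assert J == pytest.approx(
        ck.mm_rate(params.V_atpase1, st.atp("cytosol"), params.Km_atp1,
                   st.adp("cytosol"), params.Km_adp1), rel=1e-6)
    oracle = clamped_oracle(params, 2.0, 0.0, mito_active=False)
    assert J == pytest.approx(oracle["atpase1"], rel=1e-6)


@pytest.mark.parametrize("model_id,with_pk", [("1", False), ("2s", True)])
def test_solver_agrees_with_bisection_oracle(model_id, with_pk):
    """Grid+bisection on the reduced fixed point, 100 random draws each."""
    topo = ck.topology(model_id)
    rng = np.random.default_rng(42 if with_pk else 7)
    for trial in range(100):
        params = random_params(rng, model_id)
        atp_s = float(rng.uniform(0.0, 2.0))
        adp_s = float(rng.uniform(0.0, 2.0))
        if atp_s + adp_s < 0.05:
            atp_s += 0.5
        pep = bool(rng.integers(2)) if with_pk else False
        mito = bool(rng.integers(2))
        st = ck.solve_steady_state(topo, params,
                                   {"ATP": atp_s, "ADP": adp_s},
                                   pep_present=pep, mito_active=mito)
        oracle = clamped_oracle(params, atp_s, adp_s, pep=pep,
                                mito_active=mito, with_pk=with_pk)
        scale = max(1.0, oracle["atpase1"])
        assert st.fluxes[ATPASE1] == pytest.approx(
            oracle["atpase1"], rel=1e-6, abs=1e-6 * scale), trial
        assert st.adp("cytosol") == pytest.approx(
            oracle["adp_cyt"], rel=1e-6, abs=1e-9)
        if with_pk:
            assert st.fluxes[PKEND1] == pytest.approx(
                oracle["pkend1"], rel=1e-6, abs=1e-6 * scale)


@pytest.mark.parametrize("model_id", ck.MODEL_IDS)
def test_nucleotide_conservation_random_draws(model_id):
    """Every compartment balances, and the ATPase/ATP-source budget closes."""
    topo = ck.topology(model_id)
    rng = np.random.default_rng(100 + ck.MODEL_IDS.index(model_id))
    for _ in range(20):
        params = random_params(rng, model_id)
        st = ck.solve_steady_state(topo, params, {"ATP": 1.5, "ADP": 0.2},
                                   pep_present=True)
        scale = max(1.0, max(abs(v) for v in st.fluxes.values()))
        net = balance_residuals(topo, params, st, pep_present=True)
        for comp, (datp, dadp) in net.items():
            if comp == SOLUTION:
                continue      # clamped reservoir
            assert abs(datp) < 1e-6 * scale
            assert abs(dadp) < 1e-6 * scale
        # ATP consumed by ATPases = ATP made in-cell + net uptake from solution
        atp_sources = st.synthase_flux + st.total_pk_flux(endogenous_only=True)
        sol_export = sum(f[ATP] for (a, b), f in st.exchange_fluxes.items()
                         if a == SOLUTION) - \
            sum(f[ATP] for (a, b), f in st.exchange_fluxes.items()
                if b == SOLUTION)
        assert st.total_atpase_flux() == pytest.approx(
            atp_sources + sol_export, rel=1e-6, abs=1e-6 * scale)


def test_monotone_in_clamped_atp():
    topo, params = ck.topology("2s"), ck.preset("2s")
    fluxes = [ck.solve_steady_state(topo, params, {"ATP": x, "ADP": 0.1},
                                    pep_present=True).total_atpase_flux()
              for x in (0.0, 0.05, 0.2, 0.5, 1.0, 2.0, 5.0)]
    assert np.all(np.diff(fluxes) >= -1e-9)


@pytest.mark.parametrize("rich_id", ["2s", "2", "3s", "4s"])
def test_nesting_reduces_to_model_1(rich_id):
    """Zeroing the extra reactions reproduces model 1's fluxes exactly."""
    p1 = ck.preset("1")
    extras = {"V_pkend1": 0.0, "Km_pk_adp": 0.6}
    if rich_id in ("2",):
        extras.update(V_atpase2=0.0, Km_atp2=1.0, Km_adp2=1.0)
    if rich_id in ("3s", "4s"):
        extras.update(V_atpase2=0.0, V_pkend2=0.0, C_c4=5.0)
    rich_params = p1.replace(**extras)
    st1 = ck.solve_steady_state(ck.topology("1"), p1,
                                {"ATP": 2.0, "ADP": 0.0}, tol=1e-12)
    st_rich = ck.solve_steady_state(ck.topology(rich_id), rich_params,
                                    {"ATP": 2.0, "ADP": 0.0}, tol=1e-12)
    for name in (ATP_SYNTHASE, ATPASE1):
        assert st_rich.fluxes[name] == pytest.approx(st1.fluxes[name],
                                                     abs=1e-7)
    for name in (ATPASE2, PKEND1, PKEND2):
        assert st_rich.fluxes.get(name, 0.0) == pytest.approx(0.0, abs=1e-12)


def test_reaction_fluxes_examples(preset_2s):
    """Half-saturation check: PKEND1 at its Km runs at V/2."""
    topo = ck.topology("2s")
    state = CompartmentState(concentrations={
        c: (2.0, 0.614) for c in topo.compartments})
    ck.reaction_fluxes(topo, preset_2s, state, pep_present=True)
    assert state.fluxes[PKEND1] == pytest.approx(230.0)
    # without PEP the PK reactions are switched off
    ck.reaction_fluxes(topo, preset_2s, state, pep_present=False)
    assert state.fluxes[PKEND1] == 0.0
    # model 1 has no endogenous PK reaction at all
    state1 = CompartmentState(concentrations={
        c: (2.0, 0.614) for c in ck.topology("1").compartments})
    ck.reaction_fluxes(ck.topology("1"), ck.preset("1"), state1,
                       pep_present=True)
    assert PKEND1 not in state1.fluxes


def test_all_rates_zero_gives_zero_fluxes(preset_2s):
    topo = ck.topology("2s")
    params = preset_2s.replace(V_syn=0.0, V_atpase1=0.0, V_pkend1=0.0,
                               V_pkexo=0.0)
    state = CompartmentState(concentrations={
        c: (1.0, 1.0) for c in topo.compartments})
    ck.reaction_fluxes(topo, params, state, pep_present=True,
                       pkexo_present=True)
    assert all(v == 0.0 for v in state.fluxes.values())


def test_solver_error_reports_residual():
    with pytest.raises(ck.SolverError) as err:
        ck.solve_steady_state(ck.topology("1"), ck.preset("1"),
                              {"ATP": 2.0, "ADP": 0.0}, max_iter=1)
    assert err.value.residual is not None


def test_boundary_validation():
    topo, p = ck.topology("1"), ck.preset("1")
    with pytest.raises(ValueError):
        ck.solve_steady_state(topo, p, {})
    with pytest.raises(ValueError):
        ck.solve_steady_state(topo, p, {"ATP": -1.0})
    with pytest.raises(ValueError):
        ck.solve_steady_state(topo, p, {"total": 2.0, "ATP": 1.0})
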