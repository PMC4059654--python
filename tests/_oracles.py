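"""Independent brute-force oracles for the steady-state network.

For models 1 and 2s with the solution clamped, summing the ATP and ADP
balances of each internal compartment shows that the total nucleotide is
uniform (exchange conserves the sum and every reaction is a 1:1
interconversion), so the network reduces to a single unknown — the
cytosolic ADP concentration — with a nested one-dimensional root for the
IMS.  These reductions are solved here by plain grid scan + bisection,
fully independent of the package's Newton solver.
"""

from __future__ import annotations


def _mm(V, S, Km, I=0.0, Ki=None):
    km_eff = Km if Ki is None else Km * (1.0 + I / Ki)
    denom = S + km_eff
    return 0.0 if denom <= 0 else V * S / denom


def _ims_flux(params, adp_cyt, atp_cyt, mito_active):
    """Synthase flux consistent with the IMS balances, by bisection.

    Given cytosolic concentrations, the IMS ADP balance reads
    C_cyt_ims*(ADP_cyt - ADP_ims) = synthase(ADP_ims, ATP_ims) with
    ATP_ims = ATP_cyt + ADP_cyt - ADP_ims (nucleotide-sum uniformity).
    """
    if not mito_active or params.V_syn == 0:
        return 0.0, adp_cyt
    C = params.C_cyt_ims

    def h(x):
        atp_ims = atp_cyt + adp_cyt - x
        return C * (adp_cyt - x) - _mm(params.V_syn, x, params.Km_syn_adp,
                                       atp_ims, params.Ki_syn_atp)

    lo, hi = 0.0, adp_cyt
    if h(hi) >= 0.0:       # synthase cannot keep up even at ADP_ims = ADP_cyt
        return C * 0.0, adp_cyt
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h(mid) >= 0.0:
            lo = mid
        else:
            hi = mid
    x = 0.5 * (lo + hi)
    return C * (adp_cyt - x), x


def clamped_oracle(params, atp_sol, adp_sol, *, pep=False, mito_active=True,
                   with_pk=False):
    """Reduced fixed point for model 1 (``with_pk=False``) or 2s (True).

    Returns a dict with the cytosolic concentrations and the reaction
    fluxes at the steady state under a fully clamped solution.
    """
    T = atp_sol + adp_sol

    def atpase(adp_c):
        atp_c = T - adp_c
        return _mm(params.V_atpase1, atp_c, params.Km_atp1, adp_c,
                   params.Km_adp1)

    def pk(adp_c):
        if not (with_pk and pep):
            return 0.0
        return _mm(params.V_pkend1, adp_c, params.Km_pk_adp)

    def resid(adp_c):
        S, _ = _ims_flux(params, adp_c, T - adp_c, mito_active)
        return (atpase(adp_c) - pk(adp_c)
                - params.C_sol_cyt * (adp_c - adp_sol) - S)

    # grid scan for the sign change, then bisection
    npts = 400
    grid = [T * i / npts for i in range(npts + 1)]
    lo = hi = None
    prev = resid(grid[0])
    if prev <= 0.0:
        lo = hi = grid[0]
    else:
        for g in grid[1:]:
            cur = resid(g)
            if cur <= 0.0:
                lo, hi = g - T / npts, g
                break
            prev = cur
    if lo is None:
        raise AssertionError("oracle: no sign change on [0, T]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    adp_c = 0.5 * (lo + hi)
    atp_c = T - adp_c
    S, adp_ims = _ims_flux(params, adp_c, atp_c, mito_active)
    return {
        "adp_cyt": adp_c, "atp_cyt": atp_c,
        "adp_ims": adp_ims, "atp_ims": atp_c + adp_c - adp_ims,
        "atpase1": atpase(adp_c), "pkend1": pk(adp_c), "synthase": S,
    }
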