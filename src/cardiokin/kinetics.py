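"""Phenomenological Michaelis–Menten rate law with competitive inhibition."""

from __future__ import annotations


def mm_rate(V: float, S: float, Km: float,
            I: float = 0.0, Ki: float | None = None) -> float:
    """Rate of a one-substrate reaction, optionally product-inhibited.

    Returns ``V*S / (S + Km*(1 + I/Ki))``; with ``Ki`` ``None`` (inhibition
    disabled) the plain ``V*S/(S + Km)``.  Continuous and nondecreasing in
    the substrate concentration ``S``.

    Parameters
    ----------
    V : maximal rate (any rate unit; the result shares it).
    S : substrate concentration, mM.
    Km : apparent Michaelis constant, mM.
    I : competitive inhibitor concentration, mM.
    Ki : inhibition constant, mM; ``None`` disables the inhibition term.
    """
    if V < 0 or S < 0 or Km < 0:
        raise ValueError(f"negative V/S/Km in rate law: V={V}, S={S}, Km={Km}")
    if Ki is not None and Ki <= 0:
        raise ValueError(f"Ki must be positive (or None to disable): {Ki}")
    if I < 0:
        raise ValueError(f"negative inhibitor concentration: {I}")
    rate, _, _ = _mm(V, S, Km, I, Ki)
    return rate


def _mm(V, S, Km, I, Ki):
    """Unchecked rate plus partial derivatives (d/dS, d/dI)."""
    km_eff = Km if Ki is None else Km * (1.0 + I / Ki)
    denom = S + km_eff
    if denom <= 0.0:  # S = Km = 0
        return 0.0, 0.0, 0.0
    rate = V * S / denom
    d_dS = V * km_eff / (denom * denom)
    d_dI = 0.0 if Ki is None else -V * S * (Km / Ki) / (denom * denom)
    return rate, d_dS, d_dI
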