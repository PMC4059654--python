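"""Synthetic kinetic datasets with the dispersion structure of the assays.

Real recordings pool 5–7 biological replicates per condition and show
roughly 20–25% coefficient-of-variation scatter.  The generator simulates
the noise-free model curves, draws multiplicative Gaussian noise
(truncated at ±3σ) per replicate, and stores the replicate mean and
sample standard deviation for every condition — the same (mean, sd)
summary the fitting objective consumes.  A fixed seed reproduces the
dataset bit for bit.

The default pooled layout mirrors the characteristic experiment set:
7 ADP-respiration + 6 ATP-respiration + 6 total-ATPase + 7 endogenous-PK
curve points, the 2 PK-competition respiration rates, and 1 basal reading
— 29 points in all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import KineticDataset
from .parameters import ParameterSet, preset
from .protocols import (RESP_BASAL, RESP_PEP_PK, TITRATION_ASSAYS,
                        AssayProtocol, default_protocols,
                        simulate_pk_competition, simulate_titration)
from .topology import ModelTopology


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative replicate noise applied to noise-free model curves."""

    cv: float = 0.22          # coefficient of variation per replicate
    floor: float = 0.1        # absolute sd floor, assay units
    replicates: int = 7       # experiments per condition
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _truncated_normal(rng: np.random.Generator, size: int,
                      cut: float = 3.0) -> np.ndarray:
    """Standard normal draws rejected outside ±cut (keeps moments finite)."""
    out = rng.standard_normal(size)
    bad = np.abs(out) > cut
    while bad.any():
        out[bad] = rng.standard_normal(bad.sum())
        bad = np.abs(out) > cut
    return out


def generate_dataset(topo: ModelTopology, true_params: ParameterSet,
                     protocols: dict[str, AssayProtocol] | None = None,
                     noise: NoiseModel = NoiseModel()) -> KineticDataset:
    """Noisy pooled dataset drawn around the model's noise-free curves."""
    protocols = dict(protocols or default_protocols())
    rng = np.random.default_rng(noise.seed)
    rows = []

    def emit(assay, x, y_true):
        if noise.cv == 0 or noise.replicates < 2:
            mean, sd = float(y_true), noise.floor
        else:
            eps = _truncated_normal(rng, noise.replicates)
            reps = y_true * (1.0 + noise.cv * eps)
            mean = float(reps.mean())
            sd = max(float(reps.std(ddof=1)), noise.floor)
        rows.append((assay, float(x), mean, sd))

    for assay in TITRATION_ASSAYS:
        curve = simulate_titration(topo, true_params, protocols[assay])
        for x, y in curve.points:
            emit(assay, x, y)
    vo2 = simulate_pk_competition(topo, true_params, protocols[RESP_PEP_PK])
    emit(RESP_PEP_PK, 0.0, vo2[0])
    emit(RESP_PEP_PK, 1.0, vo2[1])
    emit(RESP_BASAL, 0.0, protocols[RESP_BASAL].basal_rate)
    return KineticDataset.from_points(rows)


def ground_truth_preset(model_id: str) -> ParameterSet:
    """Packaged point-estimate parameter sets (NKA-inhibited condition)."""
    return preset(model_id)
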