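"""Weighted least-squares estimation of the kinetic parameters.

The objective pools every assay into one dimensionless residual sum of
squares, ``rss = Σ ((y_model − y)/w)²`` with per-point weights ``w`` (the
experimental sd where available, the assay's max |y| otherwise).  Free
parameters are optimized in log10 space under bounds — Michaelis constants
in [0.05, 10] mM, rates and exchange coefficients over several decades —
by bounded trust-region least squares restarted from a seeded
latin-hypercube of initial points plus one data-driven guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .dataset import KineticDataset
from .parameters import ParameterSet, bounds_for
from .protocols import (ATPASE_ATP, PKEND_ADP, RESP_ADP, RESP_ATP, RESP_BASAL,
                        RESP_PEP_PK, AssayCurve, AssayProtocol,
                        _curve_value, _solve_point, default_protocols,
                        simulate_pk_competition)
from .steady_state import SolverError
from .topology import ModelTopology, topology

_PENALTY = 1e4  # residual assigned to points whose steady state failed


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Outcome of one bounded multi-start fit."""

    model_id: str
    params: ParameterSet
    rss: float
    k: int
    n: int
    converged: bool
    at_bounds: list[str] = field(default_factory=list)
    per_assay_rss: dict[str, float] = field(default_factory=dict)
    n_starts: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        topo = topology(self.model_id)
        return {
            "model_id": self.model_id,
            "params": self.params.to_dict(topo),
            "rss": self.rss, "k": self.k, "n": self.n,
            "converged": self.converged, "at_bounds": self.at_bounds,
            "per_assay_rss": self.per_assay_rss,
            "n_starts": self.n_starts, "seed": self.seed,
        }


class DatasetPredictor:
    """Vectorized model prediction for every row of a pooled dataset.

    Steady states are warm-started from the previous parameter iterate,
    which cuts the Newton iteration count sharply during optimization.
    """

    def __init__(self, topo: ModelTopology, dataset: KineticDataset,
                 protocols: dict[str, AssayProtocol] | None = None):
        self.topo = topo
        self.dataset = dataset
        self.protocols = (default_protocols() if protocols is None
                          else dict(protocols))
        for assay in dataset.assays:
            if assay not in self.protocols:
                raise FitError(f"no protocol configured for assay {assay!r}")
        self._warm: dict[tuple, np.ndarray] = {}
        self._y_obs = dataset.df["y"].to_numpy(dtype=float)
        self._w = dataset.weights()
        # (assay, x, row positions) in dataset order, titrations x-sorted
        self._plan = []
        df = dataset.df
        for assay in dataset.assays:
            rows = df.index[df["assay_id"] == assay]
            xs = df.loc[rows, "x_mM"]
            order = np.argsort(xs.to_numpy(), kind="stable")
            self._plan.append((assay, [(float(xs.iloc[i]), int(rows[i]))
                                       for i in order]))

    def __call__(self, params: ParameterSet) -> np.ndarray:
        y = np.full(self.dataset.n, np.nan)
        for assay, points in self._plan:
            proto = self.protocols[assay]
            if assay == RESP_BASAL:
                for _x, row in points:
                    y[row] = proto.basal_rate
            elif assay == RESP_PEP_PK:
                try:
                    vo2 = simulate_pk_competition(self.topo, params, proto)
                except SolverError:
                    continue
                for x, row in points:
                    y[row] = vo2[0] if x < 0.5 else vo2[1]
            else:
                init = None
                for x, row in points:
                    key = (assay, x)
                    try:
                        state = _solve_point(self.topo, params, proto, x,
                                             self._warm.get(key, init))
                    except SolverError:
                        try:  # retry cold
                            state = _solve_point(self.topo, params, proto,
                                                 x, None)
                        except SolverError:
                            continue
                    conc = np.array([state.concentrations[c]
                                     for c in self.topo.compartments])
                    self._warm[key] = conc
                    init = conc
                    y[row] = _curve_value(proto, params, state)
        return y


def pooled_cost(topo: ModelTopology, params: ParameterSet,
                dataset: KineticDataset,
                protocols: dict[str, AssayProtocol] | None = None) -> float:
    """Weighted residual sum of squares of *params* against *dataset*."""
    predictor = DatasetPredictor(topo, dataset, protocols)
    r = _residuals(predictor, params)
    return float(r @ r)


def _residuals(predictor: DatasetPredictor, params: ParameterSet) -> np.ndarray:
    y_model = predictor(params)
    r = (y_model - predictor._y_obs) / predictor._w
    return np.where(np.isfinite(r), r, _PENALTY)


def _heuristic_start(topo: ModelTopology, dataset: KineticDataset,
                     params0: ParameterSet) -> ParameterSet:
    """Data-driven initial guess: plateau heights set the maximal rates."""
    df = dataset.df
    def peak(assay, default):
        sub = df[df["assay_id"] == assay]["y"]
        return float(sub.max()) if len(sub) else default
    guess = {
        "V_syn": params0.atp_per_o2 * peak(RESP_ADP, 90.0) * 1.1,
        "C_sol_cyt": 3000.0, "C_cyt_ims": 600.0,
        "V_atpase1": max(peak(ATPASE_ATP, 100.0), 1.0),
        "Km_atp1": 0.1, "Km_adp1": 0.1,
        "V_pkend1": max(1.3 * peak(PKEND_ADP, 300.0), 1.0),
        "Km_pk_adp": 0.6,
        "C_c4": 10.0, "V_atpase2": max(peak(ATPASE_ATP, 100.0), 1.0),
        "Km_atp2": 0.1, "Km_adp2": 0.1,
        "V_pkend2": 50.0,
    }
    return ParameterSet(**{k: guess[k] for k in topo.free_parameters})


def fit_model(model: str | ModelTopology, dataset: KineticDataset,
              protocols: dict[str, AssayProtocol] | None = None, *,
              seed: int = 0, n_starts: int = 20,
              init: ParameterSet | None = None,
              fixed: dict[str, float] | None = None,
              aux: dict | None = None) -> FitResult:
    """Multi-start bounded weighted least squares for one model variant.

    Parameters
    ----------
    seed
        Seeds the latin-hypercube of starting points; mandatory for
        reproducibility (identical seed, identical fit).
    n_starts
        Total number of local optimizations (one data-driven start plus
        ``n_starts - 1`` latin-hypercube draws).
    fixed
        Parameter values to freeze during the fit (used by the
        re-optimizing profile mode); frozen parameters do not count
        toward ``k``.
    """
    topo = model if isinstance(model, ModelTopology) else topology(model)
    fixed = dict(fixed or {})
    free_names = [p for p in topo.free_parameters if p not in fixed]
    k = len(free_names)
    if dataset.n < k + 2:
        raise FitError(
            f"dataset has {dataset.n} points; need at least {k + 2} "
            f"for model {topo.model_id}")
    predictor = DatasetPredictor(topo, dataset, protocols)
    aux = dict(aux or {})

    all_bounds = dict(zip(topo.free_parameters, bounds_for(topo)))
    lo = np.array([max(all_bounds[p][0], 1e-3 if not p.startswith("Km")
                       else all_bounds[p][0]) for p in free_names])
    hi = np.array([all_bounds[p][1] for p in free_names])
    zlo, zhi = np.log10(lo), np.log10(hi)

    def make_params(z) -> ParameterSet:
        values = dict(zip(free_names, 10.0 ** np.asarray(z)))
        values.update(fixed)
        return ParameterSet(**values, **aux)

    def fun(z):
        return _residuals(predictor, make_params(z))

    starts = []
    base = init or _heuristic_start(topo, dataset,
                                    ParameterSet(**aux) if aux else
                                    ParameterSet())
    z_base = np.clip(np.log10(np.clip(
        [getattr(base, p) or lo[i] for i, p in enumerate(free_names)],
        lo, hi)), zlo, zhi)
    starts.append(z_base)
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=k, seed=int(seed))
        draws = sampler.random(n_starts - 1)
        starts.extend(zlo + draws * (zhi - zlo))

    best = None
    diagnostics = []
    for z0 in starts:
        try:
            sol = least_squares(fun, z0, bounds=(zlo, zhi), method="trf",
                                ftol=1e-12, xtol=1e-12, gtol=1e-12,
                                max_nfev=2000)
        except Exception as err:  # pragma: no cover - optimizer failure
            diagnostics.append(str(err))
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(f"all {len(starts)} starts failed: {diagnostics}")

    z_hat = best.x
    params_hat = make_params(z_hat)
    r = fun(z_hat)
    rss = float(r @ r)
    at_bounds = [p for p, z, a, b in zip(free_names, z_hat, zlo, zhi)
                 if z - a < 1e-6 or b - z < 1e-6]
    per_assay = {}
    for assay in dataset.assays:
        mask = (dataset.df["assay_id"] == assay).to_numpy()
        per_assay[assay] = float(r[mask] @ r[mask])
    return FitResult(model_id=topo.model_id, params=params_hat, rss=rss,
                     k=k, n=dataset.n, converged=bool(best.success),
                     at_bounds=at_bounds, per_assay_rss=per_assay,
                     n_starts=len(starts), seed=seed)


@dataclass
class MMFit:
    """Apparent Michaelis–Menten summary of a single titration curve."""

    Vmax: float
    Km: float
    basal: float = 0.0
    acr: float = math.nan       # (basal + Vmax)/basal, when basal > 0
    warning: str | None = None  # degenerate or non-saturating data


def fit_michaelis_menten(curve: AssayCurve | tuple, *,
                         with_basal: bool = False) -> MMFit:
    """Least-squares apparent (Vmax, Km) fit, optional basal offset.

    Accepts an :class:`AssayCurve` or an ``(x, y)`` pair of arrays.  At
    least three distinct titrant concentrations are required.  Data with a
    vanishing amplitude leave Km undefined; curves that do not approach
    saturation within the sampled range are flagged.
    """
    if isinstance(curve, AssayCurve):
        x, y = curve.x, curve.y
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct titrant concentrations")
    amp = float(y.max() - (y.min() if with_basal else 0.0))
    if amp <= 0 or not np.any(y > 0):
        return MMFit(Vmax=0.0, Km=math.nan, warning="zero amplitude")

    half = (y.min() if with_basal else 0.0) + amp / 2.0
    km0 = float(np.interp(half, y, x)) if np.all(np.diff(y) >= 0) else \
        float(np.median(x))
    km0 = min(max(km0, x[x > 0].min() / 10), x.max() * 10)

    def resid(theta):
        if with_basal:
            vmax, km, basal = theta
        else:
            (vmax, km), basal = theta, 0.0
        return basal + vmax * x / (x + km) - y

    theta0 = [amp, km0] + ([float(y.min())] if with_basal else [])
    lower = [0.0, 1e-6] + ([0.0] if with_basal else [])
    upper = [np.inf, np.inf] + ([np.inf] if with_basal else [])
    sol = least_squares(resid, theta0, bounds=(lower, upper), ftol=1e-14,
                        xtol=1e-14)
    vmax, km = float(sol.x[0]), float(sol.x[1])
    basal = float(sol.x[2]) if with_basal else 0.0
    warning = None
    if km > x.max():
        warning = "non-saturating data: Km beyond sampled range"
    acr = (basal + vmax) / basal if basal > 0 else math.nan
    return MMFit(Vmax=vmax, Km=km, basal=basal, acr=acr, warning=warning)
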