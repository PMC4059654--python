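"""Model/Results front door.

``CompartmentalKinetics`` binds one model variant to a pooled kinetic
dataset; ``fit`` returns a ``CompartmentalKineticsResults`` carrying the
estimates, information criteria, per-assay diagnostics, profile confidence
intervals and a ``summary()`` table.  Simulation of the characteristic
assays hangs off both objects.

>>> from cardiokin import synthetic, topology
>>> data = synthetic.generate_dataset(topology("2s"),
...                                   synthetic.ground_truth_preset("2s"))
>>> res = CompartmentalKinetics(data, model_id="2s").fit(seed=1, n_starts=4)
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataset import KineticDataset, read_dataset
from .fitting import DatasetPredictor, FitResult, fit_model, pooled_cost
from .parameters import ParameterSet
from .protocols import (AssayProtocol, c4_fraction, default_protocols,
                        simulate_pk_competition, simulate_titration)
from .selection import (ComparisonTable, ProfileCI, aic, aicc, bic,
                        comparison_table, nested_f_test, profile_ci)
from .topology import ModelTopology, topology


class CompartmentalKinetics:
    """One model variant bound to a pooled kinetic dataset."""

    def __init__(self, dataset: KineticDataset, model_id: str = "2s",
                 protocols: dict[str, AssayProtocol] | None = None):
        self.dataset = dataset
        self.topology: ModelTopology = topology(model_id)
        self.protocols = (default_protocols() if protocols is None
                          else dict(protocols))
        self._predictor = DatasetPredictor(self.topology, dataset,
                                           self.protocols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model_id: str = "2s",
                       **kwargs) -> "CompartmentalKinetics":
        return cls(KineticDataset(df), model_id=model_id, **kwargs)

    @classmethod
    def from_csv(cls, path, model_id: str = "2s",
                 **kwargs) -> "CompartmentalKinetics":
        return cls(read_dataset(path), model_id=model_id, **kwargs)

    @property
    def model_id(self) -> str:
        return self.topology.model_id

    def predict(self, params: ParameterSet):
        """Model value for every dataset row, in dataset order."""
        return self._predictor(params)

    def cost(self, params: ParameterSet) -> float:
        """Weighted residual sum of squares at *params*."""
        return pooled_cost(self.topology, params, self.dataset,
                           self.protocols)

    def fit(self, seed: int = 0, n_starts: int = 20,
            init: ParameterSet | None = None,
            **kwargs) -> "CompartmentalKineticsResults":
        result = fit_model(self.topology, self.dataset, self.protocols,
                           seed=seed, n_starts=n_starts, init=init, **kwargs)
        return CompartmentalKineticsResults(self, result)


@dataclass
class CompartmentalKineticsResults:
    """Fit outcome plus model-comparison and simulation conveniences."""

    model: CompartmentalKinetics
    result: FitResult

    @property
    def params(self) -> ParameterSet:
        return self.result.params

    @property
    def rss(self) -> float:
        return self.result.rss

    @property
    def k(self) -> int:
        return self.result.k

    @property
    def n(self) -> int:
        return self.result.n

    @property
    def aic(self) -> float:
        return aic(self.rss, self.k, self.n)

    @property
    def aicc(self) -> float:
        return aicc(self.rss, self.k, self.n)

    @property
    def bic(self) -> float:
        return bic(self.rss, self.k, self.n)

    def profile_ci(self, param_name: str, alpha: float = 0.05,
                   reoptimize: bool = False) -> ProfileCI:
        return profile_ci(self.result, param_name, self.model.dataset,
                          self.model.protocols, alpha=alpha,
                          reoptimize=reoptimize)

    def f_test_against(self, simpler: "CompartmentalKineticsResults"):
        """Extra-sum-of-squares F-test of this fit against a nested one."""
        return nested_f_test(simpler.rss, simpler.k, self.rss, self.k, self.n)

    def simulate(self, assay_id: str):
        proto = self.model.protocols[assay_id]
        if assay_id == "RESP_PEP_PK":
            return simulate_pk_competition(self.model.topology, self.params,
                                           proto)
        return simulate_titration(self.model.topology, self.params, proto)

    def c4_fraction(self, atp: float = 2.0) -> float:
        return c4_fraction(self.model.topology, self.params, atp)

    def summary(self, cis: dict[str, ProfileCI] | None = None) -> str:
        lines = [
            f"Compartmental kinetics fit — model {self.result.model_id}",
            f"  n = {self.n} points, k = {self.k} free parameters",
            f"  weighted RSS = {self.rss:.4g}   converged = "
            f"{self.result.converged}",
            f"  AIC = {self.aic:.2f}   AICc = {self.aicc:.2f}   "
            f"BIC = {self.bic:.2f}",
            "",
            f"  {'parameter':<12}{'estimate':>12}{'95% CI':>24}",
        ]
        for name in self.model.topology.free_parameters:
            value = getattr(self.params, name)
            tag = "  (at bound)" if name in self.result.at_bounds else ""
            ci = ""
            if cis and name in cis:
                c = cis[name]
                ci = f"[{c.lower:.3g}, {c.upper:.3g}]"
            lines.append(f"  {name:<12}{value:>12.4g}{ci:>24}{tag}")
        if self.result.per_assay_rss:
            lines.append("")
            lines.append("  per-assay RSS: " + ", ".join(
                f"{a}={v:.3g}" for a, v in self.result.per_assay_rss.items()))
        return "\n".join(lines)


def compare(results) -> ComparisonTable:
    """Criteria table plus nested F-tests for several fitted variants."""
    fits = {}
    for r in results:
        fits[r.result.model_id if isinstance(
            r, CompartmentalKineticsResults) else r.model_id] = (
            r.result if isinstance(r, CompartmentalKineticsResults) else r)
    return comparison_table(fits)
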