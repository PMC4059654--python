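"""Model comparison statistics for least-squares fits.

For a fit with weighted residual sum of squares ``rss`` on ``n`` points
and ``k`` free parameters the least-squares information criteria are

    AIC  = n·ln(rss/n) + 2k
    AICc = AIC + 2k(k+1)/(n−k−1)
    BIC  = n·ln(rss/n) + k·ln(n)

(the smaller, the better).  Nested fits are compared with the
extra-sum-of-squares F-test,

    F = ((rss_simple − rss_complex)/(k_complex − k_simple))
        / (rss_complex/(n − k_complex)),

whose upper-tail p-value is the probability that the simpler model was
sufficient and the richer model's improvement arose by chance.  When the
richer fit is no better (rss_complex ≥ rss_simple) the test degenerates
and p is reported as 1.

One-parameter confidence intervals use the same F-test with df1 = 1: a
parameter is displaced from its optimum — the remaining parameters held at
their fitted values — until the p-value of the extra-sum-of-squares test
against the optimal fit reaches the significance level.  A re-optimizing
(profile-likelihood proper) mode is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import KineticDataset
from .fitting import DatasetPredictor, FitResult, _residuals, fit_model
from .parameters import bounds_for
from .protocols import AssayProtocol
from .topology import NESTED_PAIRS, topology


def aic(rss: float, k: int, n: int) -> float:
    """Least-squares Akaike information criterion."""
    if rss <= 0 or n <= 0:
        raise ValueError("rss and n must be positive")
    return n * math.log(rss / n) + 2 * k


def aicc(rss: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return aic(rss, k, n) + 2 * k * (k + 1) / (n - k - 1)


def bic(rss: float, k: int, n: int) -> float:
    """Least-squares Bayesian information criterion."""
    if rss <= 0 or n <= 0:
        raise ValueError("rss and n must be positive")
    return n * math.log(rss / n) + k * math.log(n)


def nested_f_test(rss_simple: float, k_simple: int, rss_complex: float,
                  k_complex: int, n: int) -> tuple[float, float]:
    """Extra-sum-of-squares F-test of two nested least-squares fits.

    Returns ``(F, p)``.  Degenerate improvements (the richer model fits no
    better) clamp F to 0 and report p = 1.
    """
    df1 = k_complex - k_simple
    df2 = n - k_complex
    if df1 <= 0 or df2 <= 0:
        raise ValueError(f"invalid degrees of freedom: df1={df1}, df2={df2}")
    if rss_complex <= 0:
        raise ValueError("rss_complex must be positive")
    if rss_complex >= rss_simple:
        return 0.0, 1.0
    F = ((rss_simple - rss_complex) / df1) / (rss_complex / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), p


@dataclass
class ComparisonTable:
    """Criteria per model and F-test p-values per nested pair."""

    models: list[str]
    criteria: pd.DataFrame          # index model, cols AIC/AICc/BIC/rss/k/n
    f_tests: pd.DataFrame           # cols simple, complex, F, df1, df2, p

    def to_frame(self) -> pd.DataFrame:
        return self.criteria

    def p_value(self, simple: str, complex_: str) -> float:
        sel = self.f_tests[(self.f_tests["simple"] == simple)
                           & (self.f_tests["complex"] == complex_)]
        if len(sel) == 0:
            raise KeyError(f"models {simple} and {complex_} not compared")
        return float(sel["p"].iloc[0])

    def to_text(self) -> str:
        """Aligned text: criteria columns then the p-value matrix."""
        crit = self.criteria.round(2)
        pmat = self.f_tests.pivot(index="simple", columns="complex",
                                  values="p")
        pmat = pmat.reindex(index=self.models,
                            columns=self.models).dropna(how="all")
        lines = ["Model comparison", crit.to_string(),
                 "", "F-test p-values (row = simpler model)"]
        lines.append(pmat.to_string(
            float_format=lambda v: "" if np.isnan(v) else
            ("<0.0001" if v < 1e-4 else f"{v:.3f}")))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.criteria.to_csv(path)


def comparison_table(fits: dict[str, FitResult] | list[FitResult],
                     n: int | None = None) -> ComparisonTable:
    """Assemble criteria and nested F-tests from a collection of fits."""
    if not isinstance(fits, dict):
        fits = {f.model_id: f for f in fits}
    if not fits:
        raise ValueError("no fits to compare")
    sizes = {f.n for f in fits.values()}
    n = n if n is not None else sizes.pop()
    rows, tests = [], []
    order = [m for m in ("1", "2s", "2", "3s", "3", "4s", "4") if m in fits]
    for mid in order:
        f = fits[mid]
        rows.append({"model": mid, "AIC": aic(f.rss, f.k, n),
                     "AICc": aicc(f.rss, f.k, n), "BIC": bic(f.rss, f.k, n),
                     "rss": f.rss, "k": f.k, "n": n})
    for simple, complex_ in NESTED_PAIRS:
        if simple in fits and complex_ in fits:
            fs, fc = fits[simple], fits[complex_]
            F, p = nested_f_test(fs.rss, fs.k, fc.rss, fc.k, n)
            tests.append({"simple": simple, "complex": complex_, "F": F,
                          "df1": fc.k - fs.k, "df2": n - fc.k, "p": p})
    return ComparisonTable(models=order,
                           criteria=pd.DataFrame(rows).set_index("model"),
                           f_tests=pd.DataFrame(
                               tests, columns=["simple", "complex", "F",
                                               "df1", "df2", "p"]))


@dataclass
class ProfileCI:
    """One-parameter confidence interval from the F-test stopping rule."""

    parameter: str
    estimate: float
    lower: float
    upper: float
    alpha: float = 0.05
    hit_bound: tuple[bool, bool] = (False, False)


def profile_ci(fit: FitResult, param_name: str,
               dataset: KineticDataset | None = None,
               protocols: dict[str, AssayProtocol] | None = None, *,
               alpha: float = 0.05, reoptimize: bool = False,
               seed: int = 0, cost=None) -> ProfileCI:
    """Confidence interval for one fitted parameter.

    The parameter is scanned away from its optimum while the other
    parameters stay at their fitted values (set ``reoptimize=True`` to
    re-fit them at every probe instead); the interval end is the first
    value where the extra-sum-of-squares F-test against the optimal fit
    reaches ``alpha``.  Ends are located by geometric bracketing plus
    bisection to three significant digits and clamp at the fitting bounds.
    """
    if not fit.converged:
        raise ValueError("profile CI requires a converged fit")
    topo = topology(fit.model_id)
    if param_name not in topo.free_parameters:
        raise KeyError(
            f"{param_name} is not a free parameter of model {fit.model_id}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    theta_hat = getattr(fit.params, param_name)
    rss0, n, k = fit.rss, fit.n, fit.k
    df2 = n - k
    f_crit = float(stats.f.isf(alpha, 1, df2)) if alpha < 1 else 0.0
    bounds = dict(zip(topo.free_parameters, bounds_for(topo)))[param_name]
    if cost is None and dataset is None:
        raise ValueError("provide a dataset or an explicit cost function")
    predictor = (DatasetPredictor(topo, dataset, protocols)
                 if cost is None else None)

    def rss_at(theta: float) -> float:
        if cost is not None:
            return float(cost(theta))
        if reoptimize:
            sub = fit_model(topo, dataset, protocols, seed=seed, n_starts=1,
                            init=fit.params.replace(**{param_name: theta}),
                            fixed={param_name: theta})
            return sub.rss
        r = _residuals(predictor, fit.params.replace(**{param_name: theta}))
        return float(r @ r)

    def excess(theta: float) -> float:
        return (rss_at(theta) - rss0) / (rss0 / df2) - f_crit

    def search(direction: int) -> tuple[float, bool]:
        if f_crit <= 0:
            return theta_hat, False
        bound = bounds[1] if direction > 0 else bounds[0]
        # geometric bracketing away from the optimum
        span = max(abs(theta_hat), 1e-3) * 0.05
        inner, outer = theta_hat, None
        for _ in range(60):
            probe = theta_hat + direction * span
            if (direction > 0 and probe >= bound) or \
               (direction < 0 and probe <= bound):
                probe = bound
            if excess(probe) >= 0:
                outer = probe
                break
            inner = probe
            if probe == bound:
                return bound, True     # flat to the bound: clamped
            span *= 2.0
        if outer is None:
            return bound, True
        # bisection to ~3 significant digits
        for _ in range(80):
            mid = 0.5 * (inner + outer)
            if excess(mid) >= 0:
                outer = mid
            else:
                inner = mid
            scale = max(abs(outer), abs(inner), 1e-12)
            if abs(outer - inner) <= 5e-4 * scale:
                break
        return 0.5 * (inner + outer), False

    upper, hit_hi = search(+1)
    lower, hit_lo = search(-1)
    return ProfileCI(parameter=param_name, estimate=theta_hat,
                     lower=min(lower, theta_hat), upper=max(upper, theta_hat),
                     alpha=alpha, hit_bound=(hit_lo, hit_hi))
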