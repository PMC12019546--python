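"""Farm economics: EBIT, correlated-price Monte Carlo, the hybrid carbon
tax/credit mechanism, and marginal abatement cost curves.

Operating profit is earnings before interest and tax: product income
plus diversification income, less variable costs (including purchased
feed), overheads, intervention cost deltas and straight-line
depreciation of intervention capital.

Price risk enters through a Gaussian copula: correlated standard
normals are mapped through each commodity's marginal inverse CDF
(normal, lognormal or beta-PERT families). A 10,000-iteration seeded
Monte Carlo gives the profit distribution.

The hybrid carbon policy taxes a net-positive 20-year mean emission at
$80 per Mg CO2e and credits a net-negative mean at $28 per Mg CO2e —
the price differential rewards reaching net-zero more than it rewards
going beyond it. A marginal abatement cost curve orders interventions
by dollars of (pre-carbon-price) profit foregone per Mg CO2e mitigated;
negative costs are win-wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .inventory import NetPosition

__all__ = [
    "Marginal",
    "PriceModel",
    "CarbonPolicy",
    "ProfitDistribution",
    "CarbonAccount",
    "MaccPoint",
    "sample_prices",
    "operating_profit",
    "monte_carlo_profit",
    "carbon_account",
    "macc",
    "default_price_model",
]


@dataclass(frozen=True)
class Marginal:
    """One commodity price distribution.

    families: ``normal`` (loc, scale), ``lognormal`` (mean and sd of the
    underlying log), ``pert`` (min, mode, max — classic beta-PERT with
    shape 4).
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal", "pert"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "pert":
            lo, mode, hi = self.params
            if not lo <= mode <= hi or lo == hi:
                raise ValueError("PERT requires min <= mode <= max, min<max")
        elif self.params[1] < 0:
            raise ValueError("scale parameter must be >= 0")

    def ppf(self, q: np.ndarray) -> np.ndarray:
        if self.family == "normal":
            loc, scale = self.params
            if scale == 0:
                return np.full_like(q, loc, dtype=float)
            return stats.norm.ppf(q, loc=loc, scale=scale)
        if self.family == "lognormal":
            mu, sigma = self.params
            if sigma == 0:
                return np.full_like(q, np.exp(mu), dtype=float)
            return stats.lognorm.ppf(q, s=sigma, scale=np.exp(mu))
        lo, mode, hi = self.params
        alpha = 1.0 + 4.0 * (mode - lo) / (hi - lo)
        beta = 1.0 + 4.0 * (hi - mode) / (hi - lo)
        return lo + (hi - lo) * stats.beta.ppf(q, alpha, beta)

    @property
    def allows_negative(self) -> bool:
        return self.family == "normal"


@dataclass(frozen=True)
class PriceModel:
    marginals: dict[str, Marginal]
    correlated: tuple[str, ...] = ()  # commodities sharing the copula
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (len(self.correlated), len(self.correlated)):
                raise ValueError("correlation shape mismatch")
            if not np.allclose(corr, corr.T) or not np.allclose(
                np.diag(corr), 1.0
            ):
                raise ValueError(
                    "correlation matrix must be symmetric with unit diagonal"
                )


@dataclass(frozen=True)
class CarbonPolicy:
    tax_rate: float = 80.0  # $ per Mg CO2e of residual net emissions
    credit_price: float = 28.0  # $ per Mg CO2e of net-negative emissions

    def __post_init__(self) -> None:
        if self.tax_rate < 0 or self.credit_price < 0:
            raise ValueError("carbon prices must be >= 0")
        if self.tax_rate < self.credit_price:
            raise ValueError(
                "tax_rate must be >= credit_price (net-zero is weighted "
                "above further mitigation)"
            )


@dataclass(frozen=True)
class ProfitDistribution:
    iterations: np.ndarray
    seed: int
    negative_price_draws: int = 0

    @property
    def n(self) -> int:
        return len(self.iterations)

    @property
    def mean(self) -> float:
        return float(self.iterations.mean())

    @property
    def sd(self) -> float:
        return float(self.iterations.std(ddof=1)) if self.n > 1 else 0.0

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.iterations, q))

    def summary(self) -> dict[str, float]:
        return {
            "mean": self.mean, "sd": self.sd,
            "p5": self.percentile(5), "p50": self.percentile(50),
            "p95": self.percentile(95), "n": self.n,
        }


@dataclass(frozen=True)
class CarbonAccount:
    mean_net: float  # Mg CO2e/yr
    tax: float  # $/yr
    credit_income: float  # $/yr
    post_account_profit: float  # $/yr


@dataclass(frozen=True)
class MaccPoint:
    intervention: str
    abatement: float  # Mg CO2e/yr, baseline net minus intervention net
    cost_per_mg: float  # $ per Mg CO2e; negative = profit-increasing


def sample_prices(model: PriceModel, n: int, seed: int
                  ) -> pd.DataFrame:
    """Draw n joint price vectors via a Gaussian copula.

    Commodities listed in ``model.correlated`` share correlated normal
    scores (Cholesky factorisation of the correlation matrix); the rest
    are independent. Every score maps through its marginal's inverse
    CDF.
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    if model.correlated:
        corr = np.asarray(
            model.correlation
            if model.correlation is not None
            else np.eye(len(model.correlated)),
            dtype=float,
        )
        try:
            chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"correlation matrix is not positive semi-definite: "
                f"{corr.tolist()}"
            ) from exc
        z = rng.standard_normal((n, len(model.correlated))) @ chol.T
        u = stats.norm.cdf(z)
        for j, name in enumerate(model.correlated):
            cols[name] = model.marginals[name].ppf(u[:, j])
    for name, marg in model.marginals.items():
        if name in cols:
            continue
        cols[name] = marg.ppf(rng.uniform(size=n))
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class CostStructure:
    """Fixed and variable cost lines for the EBIT computation."""

    overheads: float = 0.0  # $/yr
    variable_per_head: float = 0.0  # $/head/yr
    total_head: float = 0.0
    capex: float = 0.0  # depreciated straight-line
    capex_life_years: float = 10.0
    annual_cost_delta: float = 0.0
    annual_income_delta: float = 0.0


def operating_profit(
    meat_mg: float,
    wool_mg: float,
    supplement_mg: float,
    prices: pd.Series | dict,
    costs: CostStructure,
) -> float:
    """Annual operating profit (EBIT), $/yr, for one price draw.

    Prices are $/Mg for meat (liveweight), wool (greasy) and feed
    (purchased supplement dry matter).
    """
    income = (
        meat_mg * prices["meat"]
        + wool_mg * prices["wool"]
        + costs.annual_income_delta
    )
    depreciation = (
        costs.capex / costs.capex_life_years
        if costs.capex_life_years > 0 else 0.0
    )
    outgo = (
        supplement_mg * prices["feed"]
        + costs.overheads
        + costs.variable_per_head * costs.total_head
        + costs.annual_cost_delta
        + depreciation
    )
    return income - outgo


def monte_carlo_profit(
    meat_mg: float,
    wool_mg: float,
    supplement_mg: float,
    model: PriceModel,
    costs: CostStructure,
    n: int = 10_000,
    seed: int = 0,
) -> ProfitDistribution:
    """Seeded n-iteration Monte Carlo profit distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    draws = sample_prices(model, n, seed)
    negative = int((draws < 0).any(axis=1).sum())
    # vectorised form of operating_profit (linear in the price draw)
    depreciation = (
        costs.capex / costs.capex_life_years
        if costs.capex_life_years > 0 else 0.0
    )
    profits = (
        meat_mg * draws["meat"].to_numpy()
        + wool_mg * draws["wool"].to_numpy()
        + costs.annual_income_delta
        - supplement_mg * draws["feed"].to_numpy()
        - costs.overheads
        - costs.variable_per_head * costs.total_head
        - costs.annual_cost_delta
        - depreciation
    )
    return ProfitDistribution(iterations=profits, seed=seed,
                              negative_price_draws=negative)


def carbon_account(
    net: NetPosition | float,
    policy: CarbonPolicy,
    pre_tax_profit: float,
) -> CarbonAccount:
    """Apply the hybrid tax/credit mechanism to a mean net position.

    tax = tax_rate * max(0, mean_net); credit = credit_price *
    max(0, -mean_net); exactly one of the two is nonzero (both zero at
    net-zero), and the account is continuous in mean_net at 0.
    """
    mean_net = net.mean_net if isinstance(net, NetPosition) else float(net)
    if not np.isfinite(mean_net):
        raise ValueError("mean net emissions must be finite")
    tax = policy.tax_rate * max(0.0, mean_net)
    credit = policy.credit_price * max(0.0, -mean_net)
    return CarbonAccount(
        mean_net=mean_net,
        tax=tax,
        credit_income=credit,
        post_account_profit=pre_tax_profit - tax + credit,
    )


def macc(
    baseline_net: float,
    baseline_profit: float,
    interventions: list[tuple[str, float, float]],
    zero_tolerance: float = 1e-9,
) -> tuple[list[MaccPoint], list[str], list[str]]:
    """Marginal abatement cost curve from (name, net, profit) triples.

    Profits are pre-carbon-price. Returns (curve sorted ascending by
    cost, zero-abatement names, emission-increasing names). Abatement
    is baseline net minus intervention net; cost per Mg is the profit
    foregone divided by abatement (negative = win-win).
    """
    points, zero, increasing = [], [], []
    for name, net, profit in interventions:
        abatement = baseline_net - net
        if abs(abatement) <= zero_tolerance:
            zero.append(name)
        elif abatement < 0:
            increasing.append(name)
        else:
            points.append(MaccPoint(
                intervention=name,
                abatement=abatement,
                cost_per_mg=(baseline_profit - profit) / abatement,
            ))
    points.sort(key=lambda p: p.cost_per_mg)
    return points, zero, increasing


def default_price_model() -> PriceModel:
    """Shipped commodity price model (config stand-in values, $/unit).

    Meat $/Mg liveweight, wool $/Mg greasy, feed $/Mg DM, carbon credit
    $/Mg CO2e. Livestock-product prices share a 0.6 correlation.
    """
    return PriceModel(
        marginals={
            "meat": Marginal("pert", (2200.0, 3000.0, 4200.0)),
            "wool": Marginal("lognormal", (np.log(13000.0), 0.25)),
            "feed": Marginal("pert", (250.0, 350.0, 550.0)),
            "carbon": Marginal("normal", (28.0, 4.0)),
        },
        correlated=("meat", "wool"),
        correlation=np.array([[1.0, 0.6], [0.6, 1.0]]),
    )
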