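"""Normalised multidimensional impact scores and sensitivity sweeps.

Each compared scenario gets three components, each normalised by the
maximum over the compared set: livestock production, pre-carbon-price
operating profit, and net GHG emissions inverse-coded as one minus the
normalised net (lower emissions are better). The total is their
unweighted sum on a 0-3 scale; 3 means best-in-set production and
profit with zero mean net emissions.

Normalisation is set-relative (a figure panel's worth of scenarios),
so scores are only comparable within one set. Net-negative scenarios
would push the inverse-coded component above 1; it is clamped to [0, 1]
to preserve the printed 0-3 range. Negative profits are floored at 0
before normalising and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ImpactScore",
    "normalize_scores",
    "ternary_coordinates",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class ImpactScore:
    scenario: str
    norm_production: float
    norm_profit: float
    norm_ghg: float  # inverse-coded: 1 is zero (or negative) net emission
    adoptability: int = 3
    profit_floored: bool = False

    @property
    def total(self) -> float:
        return self.norm_production + self.norm_profit + self.norm_ghg


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def normalize_scores(
    results: list[tuple[str, float, float, float]],
    adoptability: dict[str, int] | None = None,
) -> list[ImpactScore]:
    """Normalise (label, production, profit, mean_net) tuples in-set.

    Each component divides by the set maximum (clamped to [0, 1]); the
    emissions component is inverse-coded. A metric column that is zero
    (or, for profit, non-positive) for every scenario scores 0 for all.
    """
    if not results:
        raise ValueError("cannot normalise an empty scenario set")
    labels = [r[0] for r in results]
    prod = np.array([r[1] for r in results], dtype=float)
    profit = np.maximum(0.0, np.array([r[2] for r in results], dtype=float))
    floored = [r[2] < 0 for r in results]
    net = np.array([r[3] for r in results], dtype=float)

    max_prod = prod.max()
    max_profit = profit.max()
    max_net = net.max()

    scores = []
    for i, label in enumerate(labels):
        np_ = _clamp01(prod[i] / max_prod) if max_prod > 0 else 0.0
        npr = _clamp01(profit[i] / max_profit) if max_profit > 0 else 0.0
        if max_net > 0:
            # plain-float division: an extreme ratio just clamps
            ng = _clamp01(1.0 - float(net[i]) / float(max_net))
        else:
            # nothing in the set emits on net: full marks on emissions
            ng = 1.0
        scores.append(ImpactScore(
            scenario=label,
            norm_production=np_,
            norm_profit=npr,
            norm_ghg=ng,
            adoptability=(adoptability or {}).get(label, 3),
            profit_floored=bool(floored[i]),
        ))
    return scores


def ternary_coordinates(score: ImpactScore) -> tuple[float, float, float]:
    """Project a score onto the 2-simplex (components over their sum)."""
    s = score.total
    if s <= 0:
        raise ValueError(
            "ternary point undefined: all score components are zero"
        )
    return (score.norm_production / s, score.norm_profit / s,
            score.norm_ghg / s)


def sensitivity_sweep(
    run,
    inhibition_grid: list[float],
    tree_perturbations: list[float],
    allow_out_of_envelope: bool = False,
) -> pd.DataFrame:
    """Re-run a scenario over an inhibition x tree-perturbation grid.

    ``run(inhibition, tree_perturbation)`` must return a mapping with
    ``mean_net`` (Mg CO2e/yr) and ``post_account_profit`` ($/yr) — the
    full pipeline re-run at one grid point. Grids must sit inside the
    supported envelopes (inhibition 0.10-0.99, tree perturbation ±20%)
    unless explicitly overridden.
    """
    for f in inhibition_grid:
        if not (0.10 <= f <= 0.99) and not allow_out_of_envelope:
            raise ValueError(
                f"inhibition {f} outside [0.10, 0.99]; pass "
                "allow_out_of_envelope to override"
            )
    for t in tree_perturbations:
        if not (-0.2 <= t <= 0.2) and not allow_out_of_envelope:
            raise ValueError(
                f"tree perturbation {t} outside [-0.2, 0.2]; pass "
                "allow_out_of_envelope to override"
            )
    rows = []
    for f in inhibition_grid:
        for t in tree_perturbations:
            res = run(f, t)
            rows.append((f, t, res["mean_net"],
                         res["post_account_profit"]))
    return pd.DataFrame(
        rows, columns=["inhibition", "tree_perturbation", "mean_net",
                       "post_account_profit"],
    )
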