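"""RothC 26.3 soil organic carbon turnover, monthly, per depth layer.

Five pools: decomposable plant material (DPM), resistant plant material
(RPM), microbial biomass (BIO), humified organic matter (HUM) and inert
organic matter (IOM). Each active pool decomposes monthly by

    delta = P * (1 - exp(-k * a * b * c / 12))

with k the annual rate constant and a, b, c the temperature, moisture
and soil-cover rate modifiers. Decomposed carbon splits between respired
CO2 and (BIO + HUM) in the ratio x : 1 with

    x = 1.67 * (1.85 + 1.60 * exp(-0.0786 * clay%))

and the retained share partitions 46% to BIO, 54% to HUM. Incoming
plant carbon splits DPM/RPM by the DPM:RPM ratio; dung carbon enters
with the more-humified farmyard-manure split (49/49/2 DPM/RPM/HUM).

Two layers are modelled (0-30 cm and 30-100 cm) with their own rate
constants — the deep layer decomposing more slowly — and root residue
is routed by the root-fraction-by-layer profile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "SoilLayerParams",
    "SoilCarbonState",
    "init_pools",
    "rate_modifiers",
    "rothc_step",
    "steady_state",
    "run_soil_carbon",
    "TOPSOIL_K",
    "DEEP_K",
]

# annual decomposition rate constants (DPM, RPM, BIO, HUM), yr^-1
TOPSOIL_K = (10.0, 0.17, 0.66, 0.02)
DEEP_K = (0.33, 0.01, 0.02, 0.00)

_POOLS = ("DPM", "RPM", "BIO", "HUM")
_TMIN = -18.27  # °C, domain edge of the temperature modifier


class NonConvergentPool(ValueError):
    """A pool with zero effective rate but nonzero inflow has no fixed point."""


@dataclass(frozen=True)
class SoilLayerParams:
    layer: str  # "0-30cm" | "30-100cm"
    clay_pct: float
    depth_cm: float
    k: tuple[float, float, float, float] = TOPSOIL_K
    dpm_rpm_ratio: float = 1.44  # fresh plant C partition, DPM:RPM
    initial_soc: float = 60.0  # Mg C/ha
    iom: float = 3.0  # Mg C/ha
    init_dpm_fraction: float = 0.01
    init_bio_fraction: float = 0.022  # 2% + 0.2% microbial sub-pools merged
    rpm_share_of_remainder: float = 1.0 / 3.0  # rest split RPM:HUM
    dung_split: tuple[float, float, float] = (0.49, 0.49, 0.02)  # DPM,RPM,HUM

    def __post_init__(self) -> None:
        if any(ki < 0 for ki in self.k):
            raise ValueError("rate constants must be >= 0")
        if self.initial_soc < self.iom or self.iom < 0:
            raise ValueError("require initial_soc >= iom >= 0")
        if self.init_dpm_fraction + self.init_bio_fraction > 1:
            raise ValueError("initial pool fractions sum above 1")
        if abs(sum(self.dung_split) - 1.0) > 1e-9:
            raise ValueError("dung_split must sum to 1")


@dataclass(frozen=True)
class SoilCarbonState:
    """Pools in Mg C/ha plus moisture-deficit memory and respired C."""

    dpm: float
    rpm: float
    bio: float
    hum: float
    iom: float
    tsmd: float = 0.0  # accumulated topsoil moisture deficit, mm (<= 0)
    cum_co2: float = 0.0  # cumulative respired C, Mg C/ha

    def __post_init__(self) -> None:
        if min(self.dpm, self.rpm, self.bio, self.hum, self.iom) < -1e-12:
            raise ValueError("pools must be non-negative")

    @property
    def pools(self) -> np.ndarray:
        return np.array([self.dpm, self.rpm, self.bio, self.hum])

    @property
    def total_soc(self) -> float:
        return self.dpm + self.rpm + self.bio + self.hum + self.iom


def init_pools(params: SoilLayerParams) -> SoilCarbonState:
    """Partition the initial SOC stock across pools.

    DPM and BIO take their configured fractions of total SOC (defaults
    1% and 2.2%), IOM is fixed, and RPM/HUM split the remainder by the
    configured share. The pools sum exactly to initial_soc.
    """
    soc = params.initial_soc
    dpm = params.init_dpm_fraction * soc
    bio = params.init_bio_fraction * soc
    active = soc - params.iom
    if dpm + bio > active:
        # degenerate stocks (IOM close to total SOC): shrink the fast
        # pools proportionally so the partition stays feasible
        scale = active / (dpm + bio) if dpm + bio > 0 else 0.0
        dpm *= scale
        bio *= scale
    remainder = active - dpm - bio
    rpm = params.rpm_share_of_remainder * remainder
    hum = remainder - rpm
    return SoilCarbonState(dpm=dpm, rpm=rpm, bio=bio, hum=hum,
                           iom=params.iom)


def max_tsmd(clay_pct: float, depth_cm: float) -> float:
    """Maximum topsoil moisture deficit (negative mm), depth-scaled.

    The reference value is defined for a 23 cm topsoil and scales
    linearly with layer depth.
    """
    m = -(20.0 + 1.3 * clay_pct - 0.01 * clay_pct**2)
    return m * depth_cm / 23.0


def rate_modifiers(
    tmean: float,
    rain: float,
    pan_evap: float,
    clay_pct: float,
    state: SoilCarbonState,
    soil_covered: bool = True,
    depth_cm: float = 23.0,
) -> tuple[tuple[float, float, float], float]:
    """Monthly rate modifiers (a, b, c) and the updated TSMD.

    a — temperature: 47.91 / (1 + exp(106.06 / (tmean + 18.27)))
    b — moisture: 1.0 while the accumulated deficit is shallower than
        0.444 of the maximum, declining linearly to 0.2 at the maximum
    c — soil cover: 0.6 if vegetated, 1.0 if bare

    The deficit accumulates as rain - 0.75 * pan evaporation (open-pan
    correction), clamped between the clay/depth-dependent maximum
    deficit and zero.
    """
    if tmean <= _TMIN:
        raise ValueError(
            f"tmean must exceed {_TMIN} °C (temperature modifier domain)"
        )
    a = 47.91 / (1.0 + np.exp(106.06 / (tmean - _TMIN)))

    m_max = max_tsmd(clay_pct, depth_cm)
    tsmd = state.tsmd + (rain - 0.75 * pan_evap)
    tsmd = min(0.0, max(m_max, tsmd))

    threshold = 0.444 * m_max  # deficits shallower than this: no limitation
    if tsmd >= threshold:
        b = 1.0
    else:
        b = 0.2 + 0.8 * (m_max - tsmd) / (m_max - threshold)

    c = 0.6 if soil_covered else 1.0
    return (float(a), float(b), float(c)), float(tsmd)


def _co2_split_x(clay_pct: float) -> float:
    return 1.67 * (1.85 + 1.60 * np.exp(-0.0786 * clay_pct))


def _update_matrices(
    params: SoilLayerParams, modifiers: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Linear monthly update P' = A @ P + inputs_effective.

    Returns (A, retained) where retained[i] is the fraction of pool i's
    monthly loss that re-enters the (BIO, HUM) pools.
    """
    a, b, c = modifiers
    k = np.asarray(params.k)
    e = np.exp(-k * a * b * c / 12.0)
    x = _co2_split_x(params.clay_pct)
    retain = 1.0 / (x + 1.0)
    A = np.diag(e)
    loss = 1.0 - e
    A[2, :] += 0.46 * retain * loss
    A[3, :] += 0.54 * retain * loss
    return A, loss


def _input_vector(plant_c: float, dung_c: float,
                  params: SoilLayerParams) -> np.ndarray:
    r = params.dpm_rpm_ratio
    dpm_frac = r / (1.0 + r)
    u = np.zeros(4)
    u[0] = plant_c * dpm_frac + dung_c * params.dung_split[0]
    u[1] = plant_c * (1.0 - dpm_frac) + dung_c * params.dung_split[1]
    u[3] = dung_c * params.dung_split[2]
    return u


def rothc_step(
    state: SoilCarbonState,
    plant_c: float,
    dung_c: float,
    params: SoilLayerParams,
    modifiers: tuple[float, float, float],
    tsmd: float | None = None,
) -> SoilCarbonState:
    """Advance the pools one month. Carbon is conserved exactly:
    change in total pools = inputs - respired CO2.
    """
    if plant_c < 0 or dung_c < 0:
        raise ValueError("carbon inputs must be non-negative")
    A, loss = _update_matrices(params, modifiers)
    p = state.pools
    u = _input_vector(plant_c, dung_c, params)
    new = A @ p + u
    x = _co2_split_x(params.clay_pct)
    co2 = float(loss @ p) * (x / (x + 1.0))
    if (new < -1e-9).any():
        raise AssertionError("internal invariant violated: negative pool")
    new = np.maximum(new, 0.0)
    return SoilCarbonState(
        dpm=new[0], rpm=new[1], bio=new[2], hum=new[3], iom=state.iom,
        tsmd=state.tsmd if tsmd is None else tsmd,
        cum_co2=state.cum_co2 + co2,
    )


def steady_state(
    plant_c: float,
    dung_c: float,
    params: SoilLayerParams,
    modifiers: tuple[float, float, float],
) -> np.ndarray:
    """Fixed point of the monthly linear update under constant forcing.

    Solves (I - A) p = u for the four active pools. A pool whose
    effective rate is zero while receiving inflow has no fixed point;
    that is reported as :class:`NonConvergentPool` rather than a number.
    """
    A, _ = _update_matrices(params, modifiers)
    u = _input_vector(plant_c, dung_c, params)
    a, b, c = modifiers
    k = np.asarray(params.k)
    eff = k * a * b * c
    M = np.eye(4) - A
    u = u.copy()
    # a pool with zero turnover diverges if anything flows into it;
    # with no inflow at all, any level is a fixed point — pin it to 0
    for i in range(4):
        if eff[i] == 0.0:
            internal_inflow = any(A[i, j] > 0 for j in range(4) if j != i)
            if u[i] > 0 or internal_inflow:
                raise NonConvergentPool(
                    f"pool {_POOLS[i]} has zero effective rate with "
                    "nonzero inflow; no steady state exists"
                )
            M[i, :] = 0.0
            M[i, i] = 1.0
            u[i] = 0.0
    return np.linalg.solve(M, u)


def run_soil_carbon(
    climate_records: pd.DataFrame,
    plant_c_by_layer: np.ndarray,
    dung_c: np.ndarray,
    params_by_layer: list[SoilLayerParams],
    soil_covered: bool = True,
) -> pd.DataFrame:
    """Run both layers over an aligned monthly climate / input series.

    plant_c_by_layer: (n_layers, n_months) Mg C/ha of plant residue
    (litter + root) entering each layer; dung_c: (n_months,) entering
    the top layer only. Returns a tidy frame with one row per year per
    layer carrying end-of-year SOC and the annual change (positive =
    accrual).
    """
    n = len(climate_records)
    plant_c_by_layer = np.asarray(plant_c_by_layer, dtype=float)
    dung_c = np.asarray(dung_c, dtype=float)
    if plant_c_by_layer.shape != (len(params_by_layer), n) or len(dung_c) != n:
        raise ValueError(
            "climate, plant-C and dung-C series lengths do not align"
        )
    rows = []
    recs = climate_records.reset_index(drop=True)
    for li, params in enumerate(params_by_layer):
        state = init_pools(params)
        prev_soc = state.total_soc
        for i in range(n):
            mods, tsmd = rate_modifiers(
                recs.loc[i, "tmean"], recs.loc[i, "rain"],
                recs.loc[i, "pan_evap"], params.clay_pct, state,
                soil_covered, params.depth_cm,
            )
            dung = dung_c[i] if li == 0 else 0.0
            state = rothc_step(
                state, plant_c_by_layer[li, i], dung, params, mods, tsmd
            )
            if recs.loc[i, "month"] == 12 or i == n - 1:
                rows.append((int(recs.loc[i, "year"]), params.layer,
                             state.total_soc, state.total_soc - prev_soc))
                prev_soc = state.total_soc
    return pd.DataFrame(
        rows, columns=["year", "layer", "soc_mg_ha", "delta_soc_mg_ha"]
    )
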