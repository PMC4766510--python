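"""The two mixed-model designs of the price analysis.

Design A (:func:`fit_price_model`): inflation-adjusted annual price
regressed on taxonomic group (ungulate vs carnivore), a pair of diversity
contributions, and their group interactions, with a random intercept per
calendar year shared across species.

Design B (:func:`fit_trend_model`): per-species standardized price
regressed on a polynomial in time (years since the panel start), a pair
of contributions, and contribution x time interactions, with a random
intercept per species and AR(1) residual correlation within species.
Polynomial order is chosen by forward likelihood-ratio testing
(:func:`select_poly_order`); the influence of each contribution on the
trend is judged by dropping its time interactions (df = order) in
:func:`contribution_tests`.

Contributions always enter as the deviation-from-equal-contribution form,
and are paired either as (ED, FD) -- overall contributions -- or as
(PC, FC) -- unique contributions -- never mixed, because each pair's
members are strongly correlated with their counterparts in the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import LMMFit, LRTResult, fit_lmm, lrt

PAIRS = {"overall": ("ED", "FD"), "unique": ("PC", "FC")}
GROUPS = ("carnivore", "ungulate")  # carnivore is the reference level


def _pair_columns(pair: str) -> tuple[str, str]:
    try:
        return PAIRS[pair]
    except KeyError:
        raise ValueError(f"pair must be one of {sorted(PAIRS)}, got {pair!r}") from None


def _require(data: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"analysis table is missing columns: {missing}")


def build_price_design(data: pd.DataFrame, pair: str) -> pd.DataFrame:
    cphy, cfun = _pair_columns(pair)
    _require(data, ["group", cphy, cfun])
    levels = sorted(data["group"].unique())
    if set(levels) - set(GROUPS):
        raise ValueError(f"unknown group labels: {sorted(set(levels) - set(GROUPS))}")
    if len(levels) < 2:
        raise ValueError("price model needs both taxonomic groups present")
    g = (data["group"] == "ungulate").astype(float)
    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            "group[ungulate]": g,
            cphy: data[cphy].astype(float),
            cfun: data[cfun].astype(float),
            f"group[ungulate]:{cphy}": g * data[cphy].astype(float),
            f"group[ungulate]:{cfun}": g * data[cfun].astype(float),
        }
    )
    return X


def fit_price_model(data: pd.DataFrame, pair: str = "overall", reml: bool = True) -> LMMFit:
    """Design A: adjusted price ~ group * contributions + (1 | year)."""
    _require(data, ["price", "year"])
    if data["year"].nunique() < 2:
        raise ValueError("price model needs at least 2 years")
    X = build_price_design(data, pair)
    return fit_lmm(
        data["price"].to_numpy(float), X, groups=data["year"].to_numpy(),
        ar1=False, reml=reml,
    )


def build_trend_design(
    data: pd.DataFrame, pair: str, poly_order: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    if poly_order not in (1, 2, 3):
        raise ValueError("poly_order must be 1, 2 or 3")
    cphy, cfun = _pair_columns(pair)
    _require(data, ["species", "year", "scaled_price", cphy, cfun])
    t = data["year"].astype(float) - float(data["year"].min())
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(data))}
    for j in range(1, poly_order + 1):
        cols[f"time^{j}" if j > 1 else "time"] = (t**j).to_numpy()
    cols[cphy] = data[cphy].to_numpy(float)
    cols[cfun] = data[cfun].to_numpy(float)
    for c in (cphy, cfun):
        for j in range(1, poly_order + 1):
            tn = f"time^{j}" if j > 1 else "time"
            cols[f"{c}:{tn}"] = cols[c] * cols[tn]
    return pd.DataFrame(cols), t.to_numpy()


def fit_trend_model(
    data: pd.DataFrame, pair: str = "overall", poly_order: int = 2, reml: bool = True
) -> LMMFit:
    """Design B: scaled price ~ poly(time) * contributions + (1 | species),
    AR(1) residuals within species."""
    X, t = build_trend_design(data, pair, poly_order)
    return fit_lmm(
        data["scaled_price"].to_numpy(float), X,
        groups=data["species"].to_numpy(), times=t, ar1=True, reml=reml,
    )


@dataclass
class PolySelection:
    order: int
    fits: dict[int, LMMFit]
    table: pd.DataFrame  # comparison, statistic, df, pvalue


def select_poly_order(
    data: pd.DataFrame,
    pair: str = "overall",
    orders: tuple[int, ...] = (1, 2, 3),
    alpha: float = 0.05,
) -> PolySelection:
    """Forward LRT selection of the polynomial order of the time trend.

    Each order is tested against the previous one (ML fits); selection
    stops at the first non-significant increase.
    """
    orders = tuple(sorted(orders))
    fits = {k: fit_trend_model(data, pair, poly_order=k, reml=False) for k in orders}
    rows = []
    chosen = orders[0]
    for prev, cur in zip(orders, orders[1:]):
        res = lrt(fits[cur], fits[prev])
        rows.append((f"order {cur} vs {prev}", res.statistic, res.df, res.pvalue))
        if res.pvalue < alpha and chosen == prev:
            chosen = cur
    table = pd.DataFrame(rows, columns=["comparison", "statistic", "df", "pvalue"])
    return PolySelection(chosen, fits, table)


def contribution_tests(
    data: pd.DataFrame, pair: str = "overall", poly_order: int = 2
) -> dict[str, LRTResult]:
    """LRT of each contribution's influence on the price trend.

    For each covariate in the pair, the full trend model is compared with
    the model lacking that covariate's interactions with every polynomial
    time term (main effects are retained), giving df = ``poly_order``.
    """
    full = fit_trend_model(data, pair, poly_order, reml=False)
    X_full, t = build_trend_design(data, pair, poly_order)
    y = data["scaled_price"].to_numpy(float)
    groups = data["species"].to_numpy()
    out: dict[str, LRTResult] = {}
    for c in _pair_columns(pair):
        keep = [name for name in X_full.columns if not name.startswith(f"{c}:")]
        reduced = fit_lmm(y, X_full[keep], groups=groups, times=t, ar1=True, reml=False)
        out[c] = lrt(full, reduced)
    return out
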