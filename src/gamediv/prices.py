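"""Auction-price panels: sex averaging, CPI adjustment, standardization.

A price panel is a tidy table of (species, year, price) records, with
optional ``price_male`` / ``price_female`` columns before sex averaging.
Inflation adjustment expresses all prices at a reference year's level by
the ratio of December CPI index values; per-species standardization turns
each species' series into deviations from its mean in units of its sample
standard deviation, which is what the temporal-trend models analyse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import normalize_name


@dataclass
class CPISeries:
    """December consumer-price-index values per calendar year."""

    index: pd.Series  # year -> index value

    def __post_init__(self):
        s = pd.Series(self.index).astype(float)
        s.index = s.index.astype(int)
        s = s.sort_index()
        if (s <= 0).any():
            raise ValueError("CPI index values must be positive")
        years = s.index.to_numpy()
        if len(years) > 1 and not (np.diff(years) == 1).all():
            raise ValueError("CPI years must be contiguous")
        self.index = s

    @property
    def years(self) -> list[int]:
        return list(self.index.index)

    def ratio(self, ref_year: int, year: int) -> float:
        """CPI(ref_year) / CPI(year): the factor taking a nominal price
        observed in ``year`` to the price level of ``ref_year``."""
        for y in (ref_year, year):
            if y not in self.index.index:
                raise ValueError(f"CPI year missing: {y}")
        return float(self.index[ref_year] / self.index[year])

    def annual_inflation(self) -> pd.Series:
        """Year-on-year December-to-December inflation rates."""
        return self.index.pct_change().dropna()

    @classmethod
    def from_inflation(
        cls, rates: dict[int, float], base_year: int, base_value: float = 100.0
    ) -> "CPISeries":
        """Build an index by chaining annual rates forward from a base year."""
        values = {base_year: base_value}
        for year in sorted(rates):
            values[year] = values[year - 1] * (1.0 + rates[year])
        return cls(pd.Series(values))

    @classmethod
    def from_csv(cls, path) -> "CPISeries":
        frame = pd.read_csv(path)
        year_col, cpi_col = frame.columns[0], frame.columns[1]
        return cls(pd.Series(frame[cpi_col].values, index=frame[year_col].values))

    def to_csv(self, path) -> None:
        frame = pd.DataFrame({"year": self.index.index, "cpi_december": self.index.values})
        frame.to_csv(path, index=False)


def read_price_csv(path) -> pd.DataFrame:
    panel = pd.read_csv(path)
    panel["species"] = [normalize_name(s) for s in panel["species"]]
    panel["year"] = panel["year"].astype(int)
    return panel


def validate_panel(panel: pd.DataFrame) -> None:
    if panel.duplicated(["species", "year"]).any():
        dups = panel[panel.duplicated(["species", "year"])]
        raise ValueError(
            "duplicate species-year records: "
            + ", ".join(f"({r.species}, {r.year})" for r in dups.itertuples())
        )
    if "price" in panel.columns and (panel["price"].dropna() <= 0).any():
        raise ValueError("non-positive prices in panel")


def average_sexes(panel: pd.DataFrame) -> pd.DataFrame:
    """Collapse sex-specific prices into one combined price per record.

    An explicitly reported combined price takes precedence; otherwise the
    unweighted arithmetic mean of whichever sex prices are present.  A
    record with no price at all is an error.
    """
    panel = panel.copy()
    for col in ("price", "price_male", "price_female"):
        if col not in panel.columns:
            panel[col] = np.nan
    sex_mean = panel[["price_male", "price_female"]].mean(axis=1, skipna=True)
    combined = panel["price"].where(panel["price"].notna(), sex_mean)
    missing = combined.isna()
    if missing.any():
        bad = panel.loc[missing, ["species", "year"]]
        raise ValueError(
            "records with no price: "
            + ", ".join(f"({r.species}, {r.year})" for r in bad.itertuples())
        )
    out = panel[["species", "year"]].copy()
    if "group" in panel.columns:
        out["group"] = panel["group"]
    out["price"] = combined.astype(float)
    return out


def inflation_adjust(
    panel: pd.DataFrame, cpi: CPISeries, ref_year: int
) -> pd.DataFrame:
    """Express every price at the reference year's level.

    adjusted(s, y) = price(s, y) * CPI_Dec(ref_year) / CPI_Dec(y), which
    equals chaining the annual December-to-December inflation rates over
    the intervening years.  Adjusting to a record's own year is the
    identity.  A record year missing from the CPI series is an error
    naming the year.
    """
    missing = sorted(set(panel["year"]) - set(cpi.years))
    if ref_year not in cpi.index.index:
        missing.append(ref_year)
    if missing:
        raise ValueError(
            "CPI year missing: " + ", ".join(str(y) for y in sorted(set(missing)))
        )
    out = panel.copy()
    factors = out["year"].map(lambda y: cpi.ratio(ref_year, int(y)))
    out["price"] = out["price"].astype(float) * factors
    out.attrs["adjusted"] = True
    out.attrs["reference_year"] = int(ref_year)
    return out


def standardize_by_species(
    panel: pd.DataFrame, min_years: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species z-scores of the (inflation-adjusted) price series.

    scaled(s, y) = (p(s, y) - mean_y p(s, .)) / SD_y p(s, .), with the
    sample (n-1) standard deviation.  Species observed in fewer than
    ``min_years`` years, or with zero price variance, are dropped; the
    second return value reports every dropped species with its reason.
    """
    records = []
    drops = []
    for species, sub in panel.groupby("species", sort=True):
        n = len(sub)
        if n < min_years:
            drops.append((species, f"only {n} year(s) of prices (minimum {min_years})"))
            continue
        sd = sub["price"].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            drops.append((species, "zero price variance"))
            continue
        scaled = (sub["price"] - sub["price"].mean()) / sd
        for (_, row), z in zip(sub.iterrows(), scaled):
            records.append((species, int(row["year"]), float(z)))
    drop_report = pd.DataFrame(drops, columns=["species", "reason"])
    if not records:
        raise ValueError("all species dropped during standardization")
    scaled_panel = pd.DataFrame(records, columns=["species", "year", "scaled_price"])
    return scaled_panel.sort_values(["species", "year"]).reset_index(drop=True), drop_report
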