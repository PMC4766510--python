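#!/usr/bin/env python
"""Clean the price panel: average sexes, adjust to 2012 price levels via
December CPI ratios, and standardize each species' series to zero mean
and unit sample SD.  Species with fewer than 3 priced years, or no price
variation, are dropped and reported.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent))

from gamediv.prices import (
    CPISeries,
    average_sexes,
    inflation_adjust,
    read_price_csv,
    standardize_by_species,
    validate_panel,
)

BASE = Path(__file__).resolve().parent.parent / "results" / "analysis"
DATA = BASE / "data"


def main() -> None:
    cpi = CPISeries.from_csv(DATA / "cpi.csv")
    ref_year = max(cpi.years)
    raw = read_price_csv(DATA / "prices.csv")
    n_sexed = raw["price"].isna().sum()
    panel = average_sexes(raw)
    validate_panel(panel)
    adjusted = inflation_adjust(panel, cpi, ref_year)
    scaled, drops = standardize_by_species(adjusted, min_years=3)

    adjusted.to_csv(BASE / "panel_adjusted.csv", index=False)
    scaled.to_csv(BASE / "panel_scaled.csv", index=False)
    drops.to_csv(BASE / "drop_report.tsv", sep="\t", index=False)

    print(f"{len(panel)} records; {n_sexed} reported as separate sex prices and averaged")
    print(f"adjusted to {ref_year} levels (December CPI ratios)")
    print(
        f"standardized {scaled['species'].nunique()} species; "
        f"dropped {len(drops)}:"
    )
    for row in drops.itertuples(index=False):
        print(f"  {row.species}: {row.reason}")


if __name__ == "__main__":
    main()
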