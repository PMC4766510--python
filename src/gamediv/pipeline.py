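"""End-to-end orchestration: metrics -> price prep -> merged table -> models.

The pipeline reads one Newick tree and one trait table per assemblage, a
price CSV and a CPI CSV, and writes contribution tables, dendrograms,
adjusted and standardized price panels, model fits, LRT tables and a run
manifest (input checksums, config echo, package version).  Species are
matched across files by normalized name with an inner join; unmatched
species are reported loudly rather than silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import LINKAGE_METHODS, select_linkage
from .contributions import ContributionTable, phylo_contributions, write_contribution_tsv
from .cluster import functional_contributions
from .gower import gower_distance
from .models import contribution_tests, fit_price_model, select_poly_order
from .prices import (
    CPISeries,
    average_sexes,
    inflation_adjust,
    read_price_csv,
    standardize_by_species,
    validate_panel,
)
from .traits import read_trait_csv, standardize_traits
from .trees import read_newick_file

log = logging.getLogger("gamediv")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    trees: dict[str, str]          # group -> newick path
    traits: dict[str, str]         # group -> trait CSV path
    trait_schemas: dict[str, str]  # group -> schema JSON path
    prices: str
    cpi: str
    outdir: str
    reference_year: int | None = None  # default: last CPI year
    min_years: int = 3
    pairs: tuple[str, ...] = ("overall", "unique")
    linkage_candidates: tuple[str, ...] = LINKAGE_METHODS
    poly_orders: tuple[int, ...] = (1, 2, 3)
    trend_group: str = "ungulate"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)  # YAML is a JSON superset
        raw["pairs"] = tuple(raw.get("pairs", ("overall", "unique")))
        raw["linkage_candidates"] = tuple(
            raw.get("linkage_candidates", LINKAGE_METHODS)
        )
        raw["poly_orders"] = tuple(raw.get("poly_orders", (1, 2, 3)))
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        out = {"prices": self.prices, "cpi": self.cpi}
        for group, path in self.trees.items():
            out[f"tree_{group}"] = path
        for group, path in self.traits.items():
            out[f"traits_{group}"] = path
        for group, path in self.trait_schemas.items():
            out[f"schema_{group}"] = path
        return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def merge_analysis_table(
    contributions: dict[str, dict[str, ContributionTable]],
    prices: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join prices with per-species contribution deviations.

    ``contributions`` maps group -> metric -> table.  Unmatched species on
    either side are logged with counts; an empty intersection is an error.
    """
    frames = []
    for group, tables in sorted(contributions.items()):
        frame = None
        for metric, table in sorted(tables.items()):
            col = table.deviation.rename(metric)
            frame = col.to_frame() if frame is None else frame.join(col)
        frame = frame.reset_index(names="species")
        frame.insert(1, "group", group)
        frames.append(frame)
    contrib = pd.concat(frames, ignore_index=True)

    merged = prices.merge(contrib, on="species", how="inner", suffixes=("", "_c"))
    if "group_c" in merged.columns:
        mismatch = merged["group"] != merged["group_c"]
        if mismatch.any():
            raise PipelineError(
                "merge", "group-mismatch",
                f"{int(mismatch.sum())} records assigned to conflicting groups",
            )
        merged = merged.drop(columns="group_c")
    elif "group" not in merged.columns:
        merged = prices.merge(contrib, on="species", how="inner")

    only_prices = sorted(set(prices["species"]) - set(contrib["species"]))
    only_contrib = sorted(set(contrib["species"]) - set(prices["species"]))
    if only_prices:
        log.warning(
            "merge: %d priced species without contributions: %s",
            len(only_prices), ", ".join(only_prices),
        )
    if only_contrib:
        log.info(
            "merge: %d species on trees without prices: %s",
            len(only_contrib), ", ".join(only_contrib),
        )
    if merged.empty:
        raise PipelineError("merge", "empty-intersection",
                            "no species shared between prices and contributions")
    return merged.sort_values(["group", "species", "year"]).reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and persist all outputs; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "stages": {}}

    # ---- diversity contributions per assemblage -------------------
    contributions: dict[str, dict[str, ContributionTable]] = {}
    for group in sorted(config.trees):
        stage = f"contributions[{group}]"
        try:
            tree = read_newick_file(config.trees[group])
            tables = dict(phylo_contributions(tree))
            traits = read_trait_csv(config.traits[group], config.trait_schemas[group])
            d = gower_distance(standardize_traits(traits))
            selection = select_linkage(d, config.linkage_candidates)
            fd, fc = functional_contributions(selection.dendrogram)
            tables["FD"], tables["FC"] = fd, fc
        except Exception as exc:
            raise PipelineError(stage, "stage-failure", str(exc)) from exc
        contributions[group] = tables
        d.to_csv(outdir / f"distance_{group}.csv")
        (outdir / f"dendrogram_{group}.nwk").write_text(
            selection.dendrogram.to_newick() + "\n"
        )
        write_contribution_tsv(list(tables.values()), outdir / f"contributions_{group}.tsv")
        report["stages"][stage] = {
            "n_species_tree": tree.n_tips,
            "n_species_traits": len(traits.species),
            "linkage": selection.method,
            "cophenetic_correlations": selection.scores,
        }
        log.info("%s: %d species, linkage=%s", stage, tree.n_tips, selection.method)

    # ---- price preparation ----------------------------------------
    try:
        cpi = CPISeries.from_csv(config.cpi)
        ref_year = config.reference_year or max(cpi.years)
        raw_panel = read_price_csv(config.prices)
        panel = average_sexes(raw_panel)
        validate_panel(panel)
        adjusted = inflation_adjust(panel, cpi, ref_year)
        scaled, drop_report = standardize_by_species(adjusted, config.min_years)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("price_prep", "stage-failure", str(exc)) from exc
    adjusted_out = adjusted.copy()
    adjusted_out["reference_year"] = ref_year
    adjusted_out.to_csv(outdir / "panel_adjusted.csv", index=False)
    scaled.to_csv(outdir / "panel_scaled.csv", index=False)
    drop_report.to_csv(outdir / "drop_report.tsv", sep="\t", index=False)
    report["stages"]["price_prep"] = {
        "reference_year": ref_year,
        "n_records": len(adjusted),
        "n_species_scaled": int(scaled["species"].nunique()),
        "dropped": drop_report.to_dict("records"),
    }

    # ---- merged analysis table ------------------------------------
    merged = merge_analysis_table(contributions, adjusted)
    merged.to_csv(outdir / "merged_table.csv", index=False)

    # ---- models ----------------------------------------------------
    fits: dict = {}
    lrt_rows = []
    summary_lines = []
    for pair in config.pairs:
        try:
            fit_a = fit_price_model(merged, pair=pair)
        except Exception as exc:
            raise PipelineError(f"price_model[{pair}]", "stage-failure", str(exc)) from exc
        fits[f"price_model_{pair}"] = fit_a.to_dict()
        summary_lines += [f"== Price model ({pair} contributions) ==", fit_a.summary(), ""]

        trend_data = scaled.merge(
            merged[["species", "group", "ED", "PC", "FD", "FC"]].drop_duplicates(),
            on="species", how="inner",
        )
        trend_data = trend_data[trend_data["group"] == config.trend_group]
        try:
            selection = select_poly_order(trend_data, pair, config.poly_orders)
            fit_b = selection.fits[selection.order].refit(reml=True)
            tests = contribution_tests(trend_data, pair, poly_order=selection.order)
        except Exception as exc:
            raise PipelineError(f"trend_model[{pair}]", "stage-failure", str(exc)) from exc
        fits[f"trend_model_{pair}"] = fit_b.to_dict()
        fits[f"trend_model_{pair}"]["poly_order"] = selection.order
        for row in selection.table.itertuples(index=False):
            lrt_rows.append((pair, row.comparison, row.statistic, row.df, row.pvalue))
        for metric, res in tests.items():
            lrt_rows.append(
                (pair, f"{metric} x time interactions", res.statistic, res.df, res.pvalue)
            )
        summary_lines += [
            f"== Trend model ({pair} contributions, order {selection.order}) ==",
            fit_b.summary(),
            "",
        ]

    lrt_table = pd.DataFrame(
        lrt_rows, columns=["pair", "comparison", "statistic", "df", "pvalue"]
    )
    lrt_table.to_csv(outdir / "lrt_table.tsv", sep="\t", index=False)
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))
    (outdir / "model_summary.txt").write_text("\n".join(summary_lines))
    report["stages"]["models"] = {"pairs": list(config.pairs), "n_lrt": len(lrt_rows)}

    # ---- manifest --------------------------------------------------
    cfg = asdict(config)
    for key in ("pairs", "linkage_candidates", "poly_orders"):
        cfg[key] = list(cfg[key])
    manifest = {
        "version": __version__,
        "config": cfg,
        "input_checksums": {k: _sha256(v) for k, v in sorted(config.input_paths().items())},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["manifest"] = manifest
    return report
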