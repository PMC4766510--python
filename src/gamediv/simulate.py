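"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator produces, for one species assemblage: a pure-birth (Yule)
phylogeny rescaled to a fixed depth; numeric traits evolved by Brownian
motion along that tree plus uniform categorical traits; a December CPI
series with annual inflation drawn uniformly from a range; and a
longitudinal price panel with per-species log-normal baselines, a shared
quadratic trend in time, optional amplification of the trend by each
species' diversity-contribution deviations, and AR(1) errors.

Two price-panel forms exist:

* :func:`simulate_prices` generates price *levels* (the pipeline's input;
  run through CPI nominalization, sex splitting, adjustment and
  per-species standardization).
* :func:`simulate_trend_panel` generates the standardized response
  directly from the trend model itself (species random intercepts, the
  quadratic trend, AR(1) errors), which is the correctly specified feed
  for parameter-recovery and type-I-error studies.

Default sizes mirror the study: an ungulate assemblage of 41 species (37
priced) and a carnivore assemblage of 13 (6 priced, short series), over
the 22 years 1991-2012.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contributions import ContributionTable, phylo_contributions
from .cluster import functional_contributions, linkage_cluster, select_linkage
from .gower import gower_distance
from .prices import CPISeries
from .traits import CATEGORICAL, NUMERIC, TraitTable, standardize_traits
from .trees import Phylogeny, read_newick

PRICE_FLOOR = 0.05  # keeps simulated price levels positive; a simulation artifact


@dataclass
class SimConfig:
    """Generative settings for one assemblage's synthetic data."""

    n_species: int = 41          # tips on the tree
    n_priced: int = 37           # species with price records
    tree_depth: float = 25.0     # root-to-tip depth, arbitrary units (~Myr)
    n_numeric_traits: int = 4
    n_categorical_traits: int = 2
    missing_trait_rate: float = 0.0
    start_year: int = 1991
    n_years: int = 22
    baseline_log_mean: float = 9.2   # exp(9.2) ~ 10 000 currency units
    baseline_sd: float = 1.0         # SD of per-species log baselines
    beta_time: float = 0.15          # shared trend, linear term
    beta_time2: float = -0.01        # shared trend, quadratic term
    gamma_phylo: float = 0.0         # trend amplification per unit ED deviation
    gamma_func: float = 0.0          # trend amplification per unit FD deviation
    ar1_phi: float = 0.4
    sigma_resid: float | None = None  # AR(1) innovation SD; None = calibrated
    amplitude: float = 0.2           # relative-price scale of trend + noise
    inflation_range: tuple[float, float] = (0.03, 0.09)
    sex_split_rate: float = 0.3      # fraction of records reported per sex
    sex_gap: float = 0.2             # male/female relative price gap
    n_record_years: int | None = None  # subsample of years per species (carnivores)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_priced > self.n_species:
            raise ValueError("cannot price more species than exist")
        if self.n_numeric_traits + self.n_categorical_traits < 1:
            raise ValueError("need at least one trait")
        if not -1 < self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in (-1, 1)")
        if self.sigma_resid is not None and self.sigma_resid <= 0:
            raise ValueError("sigma_resid must be positive")


def trend_curve(t: np.ndarray, beta_time: float, beta_time2: float) -> np.ndarray:
    return beta_time * t + beta_time2 * t**2


def calibrated_sigma(config: SimConfig) -> float:
    """Innovation SD making the within-species series variance ~= 1.

    The trend-model response is standardized per species, so the
    generator targets a unit within-species variance: stationary AR(1)
    noise variance = 1 - Var_t(trend), floored at 0.05.
    """
    if config.sigma_resid is not None:
        return config.sigma_resid
    t = np.arange(config.n_years, dtype=float)
    var_f = float(np.var(trend_curve(t, config.beta_time, config.beta_time2)))
    stat_var = max(0.05, 1.0 - var_f)
    return float(np.sqrt(stat_var * (1.0 - config.ar1_phi**2)))


# ----------------------------------------------------------------- tree


def simulate_tree(
    n_species: int, depth: float, seed_or_rng, label_prefix: str = "sp"
) -> Phylogeny:
    """Pure-birth topology with exponential waiting times, rescaled so the
    root-to-tip depth equals ``depth`` (the tree is exactly ultrametric)."""
    rng = np.random.default_rng(seed_or_rng)
    if n_species < 2:
        raise ValueError("need at least 2 species")
    # the root splits at time 0; each lineage then splits at rate 1
    birth = {0: 0.0, 1: 0.0, 2: 0.0}
    children: dict[int, list[int]] = {0: [1, 2], 1: [], 2: []}
    tips = [1, 2]
    now = 0.0
    next_id = 3
    while len(tips) < n_species:
        now += rng.exponential(1.0 / len(tips))
        k = int(rng.integers(len(tips)))
        parent = tips.pop(k)
        for _ in range(2):
            birth[next_id] = now
            children[parent].append(next_id)
            children[next_id] = []
            tips.append(next_id)
            next_id += 1
    now += rng.exponential(1.0 / n_species)  # extend terminal branches
    scale = depth / now if now > 0 else 1.0

    labels = {tip: f"{label_prefix}{j + 1:03d}" for j, tip in enumerate(sorted(tips))}

    def newick(node: int) -> str:
        if not children[node]:
            body = labels[node]
        else:
            body = "(" + ",".join(newick(c) for c in children[node]) + ")"
        if node == 0:
            return body
        end = now if not children[node] else birth[children[node][0]]
        return f"{body}:{(end - birth[node]) * scale:.12g}"

    return read_newick(newick(0) + ";")


# ---------------------------------------------------------------- traits


def simulate_traits(
    tree: Phylogeny,
    n_numeric: int,
    n_categorical: int,
    seed_or_rng,
    missing_rate: float = 0.0,
) -> TraitTable:
    """Brownian-motion numeric traits, uniform 3-level categorical traits."""
    rng = np.random.default_rng(seed_or_rng)
    species = tree.tip_labels
    data: dict[str, list] = {}
    schema: dict[str, str] = {}
    order = list(tree.preorder())
    for k in range(n_numeric):
        x = np.zeros(tree.n_nodes)
        for i in order:
            if i == 0:
                continue
            x[i] = x[tree.parents[i]] + rng.normal(0.0, np.sqrt(tree.lengths[i]))
        col = f"num{k + 1}"
        vals = {tree.tip_label[i]: x[i] for i in tree.tip_label}
        data[col] = [vals[s] for s in species]
        schema[col] = NUMERIC
    levels = np.array(["a", "b", "c"])
    for k in range(n_categorical):
        col = f"cat{k + 1}"
        data[col] = list(rng.choice(levels, size=len(species)))
        schema[col] = CATEGORICAL
    frame = pd.DataFrame(data, index=species)
    if missing_rate > 0:
        mask = rng.random(frame.shape) < missing_rate
        # keep every species partly observed and every numeric trait usable
        for i in range(mask.shape[0]):
            if mask[i].all():
                mask[i, int(rng.integers(mask.shape[1]))] = False
        for j, col in enumerate(frame.columns):
            while schema[col] == NUMERIC and (~mask[:, j]).sum() < 2:
                mask[int(rng.integers(mask.shape[0])), j] = False
        frame = frame.mask(mask)
    return TraitTable(frame, schema)


# ------------------------------------------------------------------ CPI


def simulate_cpi(
    start_year: int, n_years: int, inflation_range: tuple[float, float], seed_or_rng
) -> CPISeries:
    """December CPI index with annual inflation uniform in the given range."""
    rng = np.random.default_rng(seed_or_rng)
    if n_years < 1:
        raise ValueError("empty year span")
    lo, hi = inflation_range
    rates = rng.uniform(lo, hi, size=n_years - 1)
    values = {start_year: 100.0}
    for k, r in enumerate(rates, start=1):
        values[start_year + k] = values[start_year + k - 1] * (1.0 + r)
    return CPISeries(pd.Series(values))


# ---------------------------------------------------------------- prices


def simulate_prices(
    ed_dev: pd.Series,
    fd_dev: pd.Series,
    config: SimConfig,
    seed_or_rng,
) -> pd.DataFrame:
    """Real-terms price levels for the priced species of one assemblage.

    p(s, t) = exp(a_s) * max(eps, 1 + A * [f(t) (1 + g_p dev_ED + g_f dev_FD)
    + e_st]), with a_s ~ N(mu0, baseline_sd), f the shared quadratic trend,
    e an AR(1) process and A the relative amplitude.  Standardization is
    invariant to exp(a_s) and to A, so the fitted trend model sees the
    calibrated f + e structure.
    """
    rng = np.random.default_rng(seed_or_rng)
    species = list(ed_dev.index)
    priced = sorted(rng.choice(species, size=config.n_priced, replace=False))
    t = np.arange(config.n_years, dtype=float)
    years = config.start_year + t.astype(int)
    f = trend_curve(t, config.beta_time, config.beta_time2)
    sigma = calibrated_sigma(config)
    stat_sd = sigma / np.sqrt(1.0 - config.ar1_phi**2)
    records = []
    for s in priced:
        a = rng.normal(config.baseline_log_mean, config.baseline_sd)
        amp = 1.0 + config.gamma_phylo * ed_dev[s] + config.gamma_func * fd_dev[s]
        e = np.empty(config.n_years)
        e[0] = rng.normal(0.0, stat_sd)
        for k in range(1, config.n_years):
            e[k] = config.ar1_phi * e[k - 1] + rng.normal(0.0, sigma)
        rel = 1.0 + config.amplitude * (f * amp + e)
        price = np.exp(a) * np.maximum(PRICE_FLOOR, rel)
        keep = np.arange(config.n_years)
        if config.n_record_years is not None and config.n_record_years < config.n_years:
            keep = np.sort(rng.choice(keep, size=config.n_record_years, replace=False))
        for k in keep:
            records.append((s, int(years[k]), float(price[k])))
    return pd.DataFrame(records, columns=["species", "year", "price"])


def to_nominal(panel: pd.DataFrame, cpi: CPISeries, ref_year: int) -> pd.DataFrame:
    """Convert a real-terms panel to nominal prices (inverse of adjustment)."""
    out = panel.copy()
    out["price"] = [
        p / cpi.ratio(ref_year, int(y)) for p, y in zip(out["price"], out["year"])
    ]
    return out


def split_sexes(panel: pd.DataFrame, rate: float, gap: float, seed_or_rng) -> pd.DataFrame:
    """Report a fraction of records as separate male/female prices whose
    mean equals the combined price (exercises sex averaging losslessly)."""
    rng = np.random.default_rng(seed_or_rng)
    out = panel.copy()
    out["price_male"] = np.nan
    out["price_female"] = np.nan
    split = rng.random(len(out)) < rate
    out.loc[split, "price_male"] = out.loc[split, "price"] * (1.0 + gap)
    out.loc[split, "price_female"] = out.loc[split, "price"] * (1.0 - gap)
    out.loc[split, "price"] = np.nan
    return out


# ------------------------------------------------- model-space trend panel


def simulate_trend_panel(
    ed_dev: pd.Series,
    fd_dev: pd.Series,
    config: SimConfig,
    seed_or_rng,
    sigma_species: float = 0.15,
) -> pd.DataFrame:
    """Standardized-price panel drawn from the trend model itself.

    y(s, t) = b_s + f(t) (1 + g_p dev_ED + g_f dev_FD) + e_st with
    b_s ~ N(0, sigma_species^2) and AR(1) errors; the correctly specified
    generative twin of :func:`gamediv.models.fit_trend_model`.
    """
    rng = np.random.default_rng(seed_or_rng)
    species = list(ed_dev.index)
    t = np.arange(config.n_years, dtype=float)
    years = config.start_year + t.astype(int)
    f = trend_curve(t, config.beta_time, config.beta_time2)
    sigma = calibrated_sigma(config)
    stat_sd = sigma / np.sqrt(1.0 - config.ar1_phi**2)
    records = []
    for s in species:
        b = rng.normal(0.0, sigma_species)
        amp = 1.0 + config.gamma_phylo * ed_dev[s] + config.gamma_func * fd_dev[s]
        e = np.empty(config.n_years)
        e[0] = rng.normal(0.0, stat_sd)
        for k in range(1, config.n_years):
            e[k] = config.ar1_phi * e[k - 1] + rng.normal(0.0, sigma)
        y = b + f * amp + e
        for k in range(config.n_years):
            records.append((s, int(years[k]), float(y[k])))
    return pd.DataFrame(records, columns=["species", "year", "scaled_price"])


# ------------------------------------------------------------ assemblages


@dataclass
class AssemblageData:
    """Everything generated for one assemblage."""

    group: str
    config: SimConfig
    tree: Phylogeny
    traits: TraitTable
    contributions: dict[str, ContributionTable]  # ED, PC, FD, FC
    prices_real: pd.DataFrame
    prices_nominal: pd.DataFrame  # with optional per-sex columns

    def contribution_frame(self) -> pd.DataFrame:
        """Wide per-species deviations: species, group, ED, PC, FD, FC."""
        out = pd.DataFrame({"species": self.tree.tip_labels})
        out["group"] = self.group
        for metric, table in self.contributions.items():
            out[metric] = table.deviation.reindex(out["species"]).to_numpy()
        return out


def simulate_assemblage(
    group: str, config: SimConfig, cpi: CPISeries, seed_or_rng
) -> AssemblageData:
    rng = np.random.default_rng(seed_or_rng)
    tree = simulate_tree(config.n_species, config.tree_depth, rng,
                         label_prefix=group[:3] + "_")
    traits = simulate_traits(
        tree,
        config.n_numeric_traits,
        config.n_categorical_traits,
        rng,
        config.missing_trait_rate,
    )
    contribs = dict(phylo_contributions(tree))
    dend = linkage_cluster(gower_distance(standardize_traits(traits)), "upgma")
    fd, fc = functional_contributions(dend)
    contribs["FD"], contribs["FC"] = fd, fc
    real = simulate_prices(
        contribs["ED"].deviation, contribs["FD"].deviation, config, rng
    )
    ref_year = config.start_year + config.n_years - 1
    nominal = split_sexes(
        to_nominal(real, cpi, ref_year), config.sex_split_rate, config.sex_gap, rng
    )
    return AssemblageData(group, config, tree, traits, contribs, real, nominal)


@dataclass
class StudyData:
    seed: int
    cpi: CPISeries
    assemblages: dict[str, AssemblageData]
    reference_year: int


def default_study_configs(seed: int = 0) -> dict[str, SimConfig]:
    """Study-scale defaults: 41/37 ungulates with full series, 13/6
    carnivores recorded in only a handful of years."""
    return {
        "ungulate": SimConfig(seed=seed),
        "carnivore": SimConfig(
            n_species=13, n_priced=6, n_record_years=8, seed=seed + 1
        ),
    }


def simulate_study(seed: int, configs: dict[str, SimConfig] | None = None) -> StudyData:
    """Generate both assemblages plus the shared CPI series."""
    configs = configs or default_study_configs(seed)
    rng = np.random.default_rng(seed)
    any_cfg = next(iter(configs.values()))
    cpi = simulate_cpi(any_cfg.start_year, any_cfg.n_years, any_cfg.inflation_range, rng)
    assemblages = {
        group: simulate_assemblage(group, cfg, cpi, rng.integers(2**31))
        for group, cfg in sorted(configs.items())
    }
    ref_year = any_cfg.start_year + any_cfg.n_years - 1
    return StudyData(seed, cpi, assemblages, ref_year)


def write_study(study: StudyData, outdir) -> dict:
    """Write the synthetic bundle as plain-text files plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": study.seed, "reference_year": study.reference_year,
                      "groups": {}, "files": {}}
    study.cpi.to_csv(outdir / "cpi.csv")
    manifest["files"]["cpi"] = "cpi.csv"
    price_frames = []
    for group, asm in study.assemblages.items():
        (outdir / f"tree_{group}.nwk").write_text(asm.tree.to_newick() + "\n")
        asm.traits.to_csv(outdir / f"traits_{group}.csv")
        (outdir / f"schema_{group}.json").write_text(
            json.dumps(asm.traits.schema, indent=2, sort_keys=True)
        )
        frame = asm.prices_nominal.copy()
        frame.insert(2, "group", group)
        price_frames.append(frame)
        cfg = asdict(asm.config)
        cfg["inflation_range"] = list(cfg["inflation_range"])
        manifest["groups"][group] = cfg
        manifest["files"][f"tree_{group}"] = f"tree_{group}.nwk"
        manifest["files"][f"traits_{group}"] = f"traits_{group}.csv"
        manifest["files"][f"schema_{group}"] = f"schema_{group}.json"
    prices = pd.concat(price_frames, ignore_index=True)
    prices = prices.sort_values(["group", "species", "year"]).reset_index(drop=True)
    prices.to_csv(outdir / "prices.csv", index=False)
    manifest["files"]["prices"] = "prices.csv"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
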