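# gamediv

Do wildlife markets price species in line with their biological
importance? `gamediv` implements, end to end, an analysis linking
longitudinal game-auction prices of southern African ungulates and large
carnivores to each species' contribution to the phylogenetic and
functional diversity of its assemblage. It is aimed at ecologists and
conservation scientists who want the full chain — diversity metrics,
price cleaning, and mixed-model inference — as tested, reusable,
seed-reproducible code.

## What it computes

**Species contributions.** On a rooted phylogeny with branch lengths,
the evolutionary distinctiveness of species *i* is the fair-proportion
score

    ED_i = Σ_{e ∈ path(root→i)} L_e / n_e ,

(branch length `L_e` divided by the `n_e` tip species sharing the
branch), and the phylogenetic contribution `PC_i` is the terminal branch
length. Fair proportion partitions the tree: `Σ_i ED_i = T`, the total
branch length. Both are scaled by `T` and expressed as deviations from
the equal share `1/S`. The functional analogues FD and FC apply the same
algorithms to a trait dendrogram built by standardization → Gower
distance (mixed numeric/categorical traits, missing values handled by
pairwise deletion) → agglomerative clustering with the linkage chosen by
cophenetic correlation (UPGMA and friends).

**Price preparation.** Sex-specific prices are averaged; prices are
expressed at a reference year's level through December CPI ratios,
`p × CPI(ref)/CPI(y)`; for trend analysis each species' series is
standardized to zero mean and unit sample SD.

**Inference.** Two linear mixed-model designs, with a purpose-built
(RE)ML fitter supporting a single random intercept and AR(1) residual
correlation within groups:

- *price level*: adjusted price ~ group × contributions, random
  intercept per year;
- *price trend* (ungulates): standardized price ~ poly(time) ×
  contributions, random intercept per species, AR(1) errors; polynomial
  order chosen by likelihood-ratio testing, and each contribution's
  influence on the trend judged by a df-2 LRT on its time interactions.

A seeded synthetic-data module generates Yule trees, Brownian-motion
traits, CPI series and price panels with the exact statistical structure
the models assume, so the whole pipeline runs and is testable without
any external data. See `docs/methods.md` for models, assumptions and
limitations.

## Worked example

```python
from gamediv import (read_newick, evolutionary_distinctiveness,
                     scale_contributions)

tree = read_newick("((A:1,B:1):1,C:2);")
ed = evolutionary_distinctiveness(tree)
print(ed.to_dict())
table = scale_contributions(ed, tree, "ED")
print(table.scaled.to_dict(), round(table.deviation.sum(), 12))
```

prints

```
{'A': 1.5, 'B': 1.5, 'C': 2.0}
{'A': 0.3, 'B': 0.3, 'C': 0.4} 0.0
```

A shares its 1-long stem with B (1/2 each) plus its own terminal branch,
so `ED_A = 1 + 1/2 = 1.5`; C's ED is its terminal branch alone. The
scores sum to the total branch length 5, scale to proportions of it,
and the deviations from the equal share 1/3 sum to zero.

The full synthetic study runs as four numbered drivers:

```sh
python analysis/01_simulate.py        # trees, traits, CPI, prices
python analysis/02_contributions.py   # ED/PC and FD/FC per assemblage
python analysis/03_prepare_prices.py  # sex averaging, CPI adjustment, scaling
python analysis/04_fit_models.py      # both model designs + LRTs
```

whose final step prints, for the default seed:

```
[trend model, overall] selected polynomial order 2
  order 2 vs 1: chi2 = 69.02, df = 3, p = 0.000
  order 3 vs 2: chi2 = 3.13, df = 3, p = 0.372
  time: beta = 0.114 (SE 0.022); time^2: beta = -0.0086 (SE 0.0010); AR(1) phi = 0.29
  ED x time LRT: chi2(2) = 0.63, p = 0.728
  FD x time LRT: chi2(2) = 0.11, p = 0.944
```

— a hump-shaped price trend (rise, then decline), best described by a
quadratic, whose shape is not significantly modulated by either
diversity contribution, exactly the structure the generator encodes at
its null settings. The same pipeline is scriptable from one config file
via the `gamediv run-all` CLI (also `simulate`, `phylo-contrib`,
`func-contrib`, `prices`, `fit`).

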