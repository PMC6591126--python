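# rhizonet

MIC-based co-occurrence network analysis for root-microbiome OTU tables:
keystone-taxon identification, network comparison across management
systems, and driver attribution.

## The scientific problem

Field surveys of root-associated fungal communities ask whether farming
intensity reshapes not just community *composition* but community
*structure*: the web of statistical associations among taxa. The standard
workflow is to rarefy an OTU count table, score every OTU pair with the
maximal information coefficient (MIC) — a grid-based, normalized
mutual-information statistic in [0, 1] that detects positive, negative,
and nonlinear rank dependence alike — call edges by permutation
significance with Benjamini–Hochberg FDR control, and study the resulting
undirected networks per management group. **Keystone taxa** are then
defined operationally as nodes combining high degree *k*, high closeness
centrality *C*, and low betweenness centrality *B* (taxa embedded in
densely interconnected neighborhoods rather than fragile bridges), and
their abundance is attributed to soil covariates with a random-forest
permutation-importance analysis.

For an OTU pair (x, y) with n samples, MIC is

    MIC(x, y) = max over grids (k_x x k_y), k_x * k_y <= n^0.6, of
                I*(x, y; k_x, k_y) / log2 min(k_x, k_y)

where one axis is rank-equipartitioned and the other is partitioned by a
dynamic program maximizing mutual information over candidate cut points.
The dynamic program is exact: it provably equals exhaustive enumeration of
every cut-point partition (property-tested against a brute-force oracle).

This package implements the whole pipeline as a library (`rhizonet.*`)
with a thin `rhizonet` CLI, plus a synthetic-study generator that plants
hub modules, occupancy-coupled partner taxa, and background guilds with
known ground truth, so that keystone recovery, FDR control, and driver
attribution can be tested end to end.

## Worked example

Simulate a 3-system study (20 farms per system, 1000 reads per farm,
100 OTUs with 10/2/0 planted hub taxa) and run the full analysis:

```bash
rhizonet run --seed 3 --out demo_out
```

prints the keystone counts per network

```json
{
  "pooled": 0,
  "conventional": 0,
  "no_till": 0,
  "organic": 11
}
```

and writes reports under `demo_out/`. The manifest for this run records
92 OTUs analyzed after filtering, per-network edge counts

```json
"edge_counts": {"pooled": 513, "conventional": 60, "no_till": 57, "organic": 139}
```

a PERMANOVA of farming system on Bray–Curtis distances (pseudo-F = 22.67,
P = 0.001, explained variation = 44.3%), and a negative
connectivity–intensity regression (slope = −1.20, R² = 0.543,
P = 1.9e-11): farms with a higher agricultural-intensity index have
sparser induced subnetworks. The organic network's keystones are
dominated by the planted mycorrhizal hub orders, e.g.

```
OTU_0007  degree 13  closeness 0.477  betweenness 0.065  Diversisporales
OTU_0008  degree 13  closeness 0.477  betweenness 0.020  Glomerales
```

and the random-forest driver report selects the planted soil covariates
(total P, Olsen P, bulk density, AMF colonization at p = 0.01 here; pH is
borderline in this single run) while the unplanted PLFA covariate scores
near zero importance.

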