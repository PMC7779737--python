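# clusterbench

Benchmarking toolkit for **spatial cluster detection in rare-disease
incidence data**, built around the setting of childhood cancers on the
German district system (402 NUTS-3 districts, ~11 million children under
15).  For a disease as rare as nephroblastoma (annual incidence
λ = 7/1,000,000 children) most districts see zero or one case per decade,
and the question of whether a surveillance method can find a true high-risk
area at all — and at what cost in false alarms — is best answered by
simulation.

The package simulates that experiment end to end and is aimed at
epidemiologists and biostatisticians planning cluster surveillance for rare
entities:

1. **Geography** — load a real district system (adjacency matrix,
   populations u_i, centroids) or generate a synthetic 402-cell lattice
   whose populations follow a truncated log-normal matching the German
   range (3,594–492,448 children per district).
2. **True clusters** — grow a connected set of 1–50 adjacent districts from
   a uniformly random start, filling "donut" holes, and assign it a relative
   risk RR.
3. **Cases** — draw 10-year district counts c_i ~ Poisson(RR_i · e_i) with
   e_i = λ · u_i · T.
4. **Detection** by three standard methods, each exposed as a model class
   whose `fit()` returns a results object:
   - `BesagNewell` — local test: for each district, the number m_i of
     nearest neighbors needed to accumulate k cases, with Poisson tail
     probability `P = 1 − Σ_{s<k} e^{−μ} μ^s/s!`, μ = U_{m_i}(i)·C/N.
   - `ScanStatistic` — Kulldorff circular scan: max log-likelihood ratio
     `D ln(D/E) + (C−D) ln((C−D)/(C−E))` over population-capped circles,
     Monte Carlo p-value, optional secondary clusters.
   - `BYMModel` — Besag–York–Mollié disease mapping:
     `c_i ~ Poisson(e_i·RR_i)`, `log RR_i = μ + s_i + ν_i` with an intrinsic
     CAR prior on s and an exchangeable ν, district flagged high-risk when
     the 95% credible interval for RR_i lies above 1.
5. **Scoring** — sensitivity, specificity, PPV/NPV, exact and minimum
   power, correct classification, diagnostic likelihood ratios and false
   positive/negative rates, with SDs, 95% CIs and the Monte Carlo error of
   the cumulative-RR estimand, one tidy row per
   (method × cluster size × RR) cell.

## Worked example

```python
import numpy as np
from clusterbench import (
    german_like_spec, make_lattice_map, grow_cluster,
    ScenarioConfig, simulate_cases, BesagNewell, ScanStatistic, BYMModel,
)

dmap = make_lattice_map(german_like_spec(seed=0))   # 402 districts
rng = np.random.default_rng(1)
cluster = grow_cluster(dmap, size=5, rng=rng, rr=10.0)
cases = simulate_cases(dmap, cluster, ScenarioConfig(), rng)

print(BesagNewell(dmap, cases, k=5).fit().summary())
print(ScanStatistic(dmap, cases, n_mc=999, seed=2).fit().summary())
print(BYMModel(dmap, cases).fit().summary())
```

Output (abridged):

```
Besag-Newell local cluster test
  districts: 402   total cases: 989
  k = 5   alpha = 0.05
  R (significant districts) = 11
  labeled high-risk districts = 13
Kulldorff spatial scan statistic (Poisson, conditional)
  districts: 402   total cases: 989
  population cap: 10% of N   n_mc = 999
  max LLR = 34.0539   p = 0.0010
  most likely cluster (5 districts): ['D190', 'D170', 'D189', 'D191', 'D210']
  secondary clusters: 1   labeled districts: 7
Besag-York-Mollie disease mapping model
  districts: 402   total cases: 989
  backend: laplace-gaussian (empirical Bayes over precisions)
  intercept mu = +0.0726 (sd 0.0406)
  high-risk districts at 95% credibility: 5
```

Here the true cluster is {D170, D190, D191, D210, D230} at RR 10, and the
simulation produced 989 cases overall (~919 expected): the Besag–Newell
test found 11 significant circles covering 13 districts, the scan's most
likely cluster (p = 0.001) covers four of the true five plus one neighbor,
and the BYM credible intervals flag 5 districts.

The full factorial experiment (sizes × RR levels × iterations × methods)
runs from a YAML config:

```bash
clusterbench map make-lattice --rows 21 --cols 20 --n-districts 402 --out bundle/
clusterbench run --config config.yaml        # writes metrics.csv per cell, resumable
clusterbench report --metrics out/metrics.csv --out fig.png
```

Real geographies are imported from CSV (square 0/1 adjacency matrix or edge
list, `district_id,population`, `district_id,x,y` or GeoJSON centroids) via
`clusterbench map import`.

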