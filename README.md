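# gutweb

Season-wide food-web analysis from molecular gut-content data.

Invertebrate generalist predators (ground beetles, rove beetles, spiders) in
cereal fields can be screened with taxon-specific PCR assays, giving, for
every captured individual, a binary vector of prey detections. `gutweb`
turns such individual-level diet data into a replicated time series of
bipartite predator × prey interaction webs and quantifies how strongly the
predator community partitions its diet — and how that changes over a
growing season.

The pipeline, one sampling unit (plot × treatment × field × session × year)
at a time:

1. **Web building** — self-detections (an individual testing positive for
   its own taxon's assay) are zeroed, then detections are averaged across
   all individuals of each species in the unit, giving a matrix of
   detection proportions `a_ij`.
2. **Network-level specialization** — the two-dimensional Shannon entropy
   `H2 = −Σ p_ij ln p_ij` of the web is standardized by the extremes
   attainable under its marginal totals:

   `H2′ = (H2max − H2) / (H2max − H2min)`

   so `H2′ = 0` means every predator's diet tracks overall prey
   availability (absolute generalization) and `H2′ = 1` means complete
   diet partitioning (absolute specialization).
3. **Randomization null and SES** — the individual diet data points are
   randomly recombined many times (by default permuting each prey's
   detection column across all individuals of the year, preserving
   detection totals and sampling effort), the web is rebuilt and `H2′`
   recomputed each time, and the observed value is expressed as a Cohen's-d
   standardized effect size `(observed − null mean) / null SD`; positive
   values mean more specialized than expected at random.
4. **Diversity and reporting** — Shannon–Weaver diversity
   `H = −Σ p_i ln p_i` of the predator and prey communities per unit (with
   plant-dwelling aphid abundances taken from tiller counts rather than
   pitfall traps), joined with the SES into a tidy per-unit time series
   plus per-session summaries, ready for mixed-model fitting or plotting.

A Dirichlet-multinomial synthetic-data generator emulates the underlying
field design (replicate fields split into fertilized/unfertilized halves,
biweekly sessions over two years) with a per-session concentration dial, so
the whole pipeline is exercisable and testable without any field data.

## Worked example

```python
from gutweb import *
from gutweb.design import DesignSpec
from gutweb.synthetic import SyntheticParams
from gutweb.nullmodels import NullConfig

design = DesignSpec(years=["2020"], fields_per_year=1,
                    treatments=["fertilized", "unfertilized"],
                    plots_per_treatment=2, sessions_per_year={"2020": 7})
params = SyntheticParams(design=design, seed=1)     # U-shaped seasonal kappa
records = remove_self_detections(simulate_detections(params),
                                 design.self_detection_map)
webs = build_webs(records, design)                  # 28 webs from 639 records
res = h2_prime(webs[0])
print(f"{webs[0].unit}: H2'={res.H2prime:.3f}")

ses = run_ses(records, design, NullConfig(n_randomizations=999, seed=2))
print(ses_table(ses).groupby("session").ses_d.mean().round(2))
```

Output:

```
2020/F1/fertilized/P1/s1: H2'=1.000
session
1    4.79
2    3.45
3    1.51
4    0.50
5    2.38
6    4.11
7    3.27
```

The first-session web is fully specialized (`H2′ = 1`: with concentrated
early-season preferences each species' diet is disjoint). The per-session
mean SES is positive everywhere — webs are always more specialized than the
recombination null — and dips sharply at session 4, recovering the
generator's mid-season generalization valley: predators overlap their diets
most when prey are most plentiful.

The same stages are available from a shell:

```bash
gutweb validate --config examples/config.yaml
gutweb simulate --config examples/config.yaml --out-dir sim --seed 1
gutweb build-webs --detections sim/detections.csv --out webs.csv
gutweb specialize --detections sim/detections.csv --out h2.csv
gutweb ses --detections sim/detections.csv --n-null 999 --seed 2 --out ses.csv
gutweb report --ses ses.csv --pitfall sim/pitfall.csv --tillers sim/tillers.csv \
              --out-dir report --plots
```

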