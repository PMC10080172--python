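# hli — healthy lifespan inequality from abridged life-table data

Average-based indicators — life expectancy (LE) and health-adjusted life
expectancy (HALE) — say how long people live, and live healthily, *on
average*.  They are silent about how unequal those durations are across
individuals.  `hli` measures that missing dimension: from the abridged
quantities a Global Burden of Disease (GBD) results-tool extract
publishes (age-specific death probabilities `nqx`, remaining life
expectancies `ex`, and remaining HALE, each with uncertainty intervals),
it reconstructs the mortality curve `ℓx` and the morbidity curve `ℓ*x`
(survival in good health), derives the age-at-death distribution
`ndx = ℓx − ℓx+n` and the age-at-morbidity-onset distribution
`nd*x = ℓ*x − ℓ*x+n`, and computes

* **LI** (lifespan inequality) — the standard deviation of age at death,
* **HLI** (healthy lifespan inequality) — the standard deviation of age
  at morbidity onset,

with CV and Gini alternatives, the age-65-conditioned variants LE65,
HALE65, LI65, HLI65, the HLI/LI ratio, morbidity
compression/expansion trend classification, pooled expectancy–inequality
OLS fits, and 80% Monte Carlo uncertainty intervals propagated from the
published input intervals.

The methodological core is two exact inversions of standard demographic
operators:

1. **nax recovery** — the person-years identity `Tx = ex·ℓx` lets the
   within-interval timing of deaths be recovered from published
   `(nqx, ex)` pairs: `nax = (nLx − n·ℓx+n)/ndx`;
2. **Sullivan inversion** — healthy person-years `T*x = HALE(x)·ℓx`,
   with onsets timed at the mortality `nax`, determine `ℓ*x` by a
   backward recursion from the open age group.

Both are tested against their forward oracles to 1e−10.  A
synthetic-data generator (Gompertz–Makeham illness–death model with
closed-form curves and known continuous truth) makes the whole chain
verifiable offline, including a million-individual microsimulation
cross-check and a coverage study of the uncertainty intervals.  See
`docs/methods.md` for the model, assumptions and numerical conventions.

Intended users: demographers and population-health researchers working
with GBD-style abridged estimates who want distributional indicators of
health, not just averages.

## Worked example

```python
import hli

# A synthetic population with known ground truth (stands in for one
# location-sex-year of a GBD extract).
pop = hli.make_synthetic_population(hli.SyntheticModel())

row = hli.compute_indicators(
    pop.qx, pop.ex, pop.hale,
    key=("Synthetica", "both", 2019),
    uncertainty=hli.UncertaintySpec(n_draws=1000, seed=42),
)
for name in ("le", "hale0", "li", "hli", "li65", "hli65", "hli_li_ratio"):
    print(f"{name:13s} {row[name]:7.3f}")
```

prints

```
le             76.299
hale0          61.115
li             17.104
hli            19.582
li65            8.809
hli65           6.229
hli_li_ratio    1.145
```

Reading: this population lives 76.3 years on average, 61.1 of them in
good health.  Ages at death have a spread of 17.1 years, but ages at
which health is lost spread over 19.6 years — health deterioration is
*more* unequal than death (ratio 1.14).  Above age 65 the ordering
reverses (8.8 vs 6.2 years), as later onsets are squeezed against the
survival horizon.  The generator's continuous-time truth for this
population is LI 17.097 and HLI 19.584 — the pipeline recovers both to
well under 1%.  `row.intervals["hli"]` carries the 80% uncertainty
interval ([18.17, 19.60] with these seeds and the default interval
widths).

The same pipeline runs from the shell on CSV extracts:

```sh
hli simulate --out demo/                 # GBD-shaped synthetic extract
hli compute --input demo/gbd_extract.csv --draws 1000 --seed 42 \
    --out indicators.csv
hli trend --in indicators.csv            # compression vs expansion
hli fit --in indicators.csv --x le --y li
```

`hli compute` accepts real results-tool exports; differing column
headers are handled by a YAML column map passed via `--config`.

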