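# coretransim

Ecologists routinely split the species recorded at a survey site into **core**
members — those maintaining a self-sustaining population there — and
**transients**, which turn up only through dispersal from elsewhere. Because
demographic rates are rarely measured, the split is usually made from
*temporal occupancy*: the fraction of survey years in which the species was
detected. That shortcut can fail in two ways. A genuinely core species can be
missed in enough years (low abundance, low detectability) to look transient;
a genuinely transient species can arrive so reliably from adjacent source
habitat (mass effects in a heterogeneous landscape) that it looks core.

`coretransim` quantifies both error rates by simulation. It is a tool for
community ecologists who use occupancy-based core/transient classification
and want to know when to trust it.

## The model in brief

- A 32 x 32 lattice of two habitat types (A with proportion *h_A*), each cell
  a community capped at *K* = 100 individuals.
- 40 habitat specialists (20 per habitat) with lognormal regional abundances
  (the GSAD) driving immigration at rate *m* = 0.001 per empty slot.
- Per time step: death (*d* = 0.5) → birth (*f* = 2 propagules per matched
  adult) → dispersal (half-normal kernel, 99% of moves ≤ 4 cells, mean
  1.24 cells; mismatched adults also disperse) → establishment into empty
  slots. 200 steps per run.
- Observation: each individual at the central focal cell is detected with
  probability *p* each of the last 15 steps. Species detected in ≤ 5 years
  are classified transient, in > 10 years core, otherwise excluded.
- True status is habitat match at the focal cell. Crossing true with inferred
  status gives the core misclassification rate A/(A+C) and the transient
  misclassification rate D/(B+D), analysed against *p* and against
  *landscape similarity* (the share of the 7 x 7 neighbourhood matching the
  focal habitat) by OLS, plus a logit GLM of classification outcome on log
  relative abundance.

See `docs/methods.md` for assumptions, design choices and limitations.

## Worked example

```python
import numpy as np
from coretransim import (SimulationConfig, run_simulation,
                         occupancy_from_record, tabulate)

for seed in (5, 1):
    record = run_simulation(SimulationConfig(h_a=0.9, seed=seed))
    print(f"seed={seed}: focal habitat {record.focal_habitat}, "
          f"similarity {record.similarity:.2f}")
    rng = np.random.default_rng(2)
    for p in (0.1, 0.5, 1.0):
        t = tabulate(occupancy_from_record(record, p, rng))
        print(f"  p={p:.1f}  A={t.a:2d} B={t.b:2d} C={t.c:2d} D={t.d:2d}  "
              f"core_err={t.core_error:.2f} transient_err={t.transient_error:.2f}")
```

prints

```
seed=5: focal habitat A, similarity 0.90
  p=0.1  A= 9 B= 0 C= 1 D= 0  core_err=0.90 transient_err=nan
  p=0.5  A= 4 B= 1 C=11 D= 0  core_err=0.27 transient_err=0.00
  p=1.0  A= 3 B= 1 C=15 D= 0  core_err=0.17 transient_err=0.00
seed=1: focal habitat B, similarity 0.12
  p=0.1  A= 1 B= 9 C= 0 D= 2  core_err=1.00 transient_err=0.18
  p=0.5  A= 2 B= 7 C= 0 D= 9  core_err=1.00 transient_err=0.56
  p=1.0  A= 4 B= 3 C= 0 D=10  core_err=1.00 transient_err=0.77
```

The first run drew a homogeneous neighbourhood (similarity 0.90): core
misclassification is severe only at the lowest detection level and no
transient is ever mistaken for core (the `nan` marks a run where no true
transient was observed at all, reported as missing rather than zero). The
second drew a focal cell of the rare habitat (similarity 0.12, the worst
case): the steady rain of immigrants from the surrounding mismatched habitat
crowds the cell, so the few true core species that appear never hold it long
enough to look core, and raising detection only makes the transients easier
to see — transient misclassification climbs from 0.18 to 0.77.

The same pipeline scales up from the shell:

```bash
coretransim sweep --hA 0.5,0.6,0.7,0.8,0.9 --p 0.1:1.0:0.1 --reps 10 \
    --q99 4 --seed 1 --out results/sweep/
coretransim analyze --in results/sweep/ --out results/report/
```

which writes the per-(run, p) table (`sweep.csv`), the OLS battery
(`fits.csv`: slope and R² of each error rate and species count against
detection and similarity) and the abundance GLM (`glm.json`). Use
`--reps 50` for the full-scale design.

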