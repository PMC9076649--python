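# candycodes

Tools for **CandyCodes** — edible physical unclonable functions for
pharmaceutical anti-counterfeiting. A pill is coated with a few dozen
multicolored candy spheres (nonpareils); the random arrangement that
results is easy to manufacture but effectively impossible to duplicate,
so it can serve as a per-pill unique identifier. This package implements
the full computational side of the scheme:

- **Encoding** a particle pattern into a canonical set of strings: the
  Delaunay triangulation of the particle centers defines each particle's
  neighbors; each neighborhood becomes a string (center color letter +
  neighbor letters read clockwise from the lexicographically smallest
  starting point); short, hull-adjacent and low-color-diversity strings
  are discarded.
- **Matching** a suspect pattern against a database of known-good codes
  with an inverted index. The match statistic is the multiset
  intersection count Σ_s min(c_a(s), c_b(s)): photographs of the *same*
  pill share tens of strings, different pills almost never share more
  than two.
- **Simulating** CandyCode libraries (random sequential adsorption of
  non-overlapping disks on a pill face, colors drawn from a configurable
  alphabet) and **measuring uniqueness at scale**: the largest number of
  strings shared between any two codes grows only logarithmically with
  library size *N*,

      max-shared(N) ≈ a + b·log10(N),

  and the fitted slope *b* determines how large a library can get before
  two different pills risk being confused.
- **Rendering and detecting**: synthetic pill images and a
  connected-components particle detector close the photograph →
  coordinates loop without physical candy.

Three built-in color alphabets: **A** (8 colors, white 5× more frequent,
as on commercial chocolate nonpareils), **B** (8 equal colors), **C** (15
equal colors).

## Worked example

```python
import numpy as np
from candycodes import (
    SimConfig, PerturbConfig, CodeDatabase,
    simulate_library, perturb_candycode, encode_candycode, query,
)

# Manufacturer: simulate 120 pills and store their string sets
sets = simulate_library(120, SimConfig(seed=7))
db = CodeDatabase(sets)
print(sets[0].total())              # 52   strings retained for pill 1

# Consumer: re-photograph pill 1 (position jitter) and verify it
from candycodes.simulator import library_member
pill = library_member(SimConfig(seed=7), 0)
reshot = perturb_candycode(pill, PerturbConfig(), np.random.default_rng(1))
report = query(db, encode_candycode(reshot))
print(report.verdict, report.best_id, report.best_shared, report.runner_up_shared)
# authentic sim_000001 26 2
```

The genuine pill shares 26 strings with its own database entry but at
most 2 with any other pill — the gap that makes verification trivial.
A counterfeit pill (any code not in the database) scores ≤ 2 everywhere
and is rejected. The same flow is available from the shell:

```
candycode demo --n-codes 120 --seed 1 --out-dir demo/
candycode simulate --n-codes 120 --seed 17 --out-dir codes/
candycode encode --in codes/sim_000001.csv --out suspect.txt
candycode verify --db codes/strings.txt --suspect suspect.txt
candycode sweep --alphabet A --sizes 10,100,1000,10000 --reps 20 --seed 7 --out sweep.csv
candycode fit --in sweep.csv --extrapolate 1e17
candycode render --in codes/sim_000001.csv --out pill.png
candycode detect --in pill.png --out recovered.csv
```

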