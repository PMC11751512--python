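# pistonalign

Label-free quantification of cell alignment to suspended microstructures.

When a microfluidic cell-culture channel carries a suspended "micro-piston" —
a PDMS structure hanging ~100 um above the monolayer with a circular,
triangular or square footprint — some cancer cell lines (notably SKOV-3
ovarian cancer cells) visibly orient to the *projected outline* of the
structure despite never touching it.  `pistonalign` is the analysis toolkit
for quantifying that behavior from nothing but cell outlines: no stains, no
nuclear markers, no tracking.  It is aimed at groups doing mechanobiology /
contact-guidance experiments in microfluidic devices who outline cells in
ImageJ (or simulate them) and need reproducible orientation statistics.

## What it computes

For each cell outline that crosses the projected periphery of a reference
shape:

1. **Cell angle** `α` — the orientation of the major axis of the
   moment-matched ellipse of the outline polygon (closed-form Green's-theorem
   moments, `α = ½·atan2(2μ₁₁, μ₂₀−μ₀₂)`), measured from the image x-axis on
   the axial scale [0°, 180°).
2. **Shape-relative angle** — for a circle, `90° − (β − α)` folded to
   [0°, 180°), where `β = atan2(y_cell, x_cell)` is the position angle of the
   cell centroid seen from the piston centroid (90° = radial, 0° =
   along the periphery); for triangles and squares, the axial difference
   between `α` and the direction of the nearest polygon edge.
3. **Angle class** — radial `[70°, 110°]`, peripheral `<20° or >160°`, or one
   of two oblique classes (`50–70°/110–130°` and `20–50°/130–160°`).
4. **Group statistics** — per-group four-bin frequency tables; Pearson χ²
   (no continuity correction) comparing piston vs control distributions; and a
   two-sample *t-test between percents* per bin (pooled two-proportion
   statistic referred to Student's t with n₁+n₂−2 df).

Control groups use the same geometry overlaid at a seeded random piston-free
position of the monolayer.  A synthetic monolayer generator (von Mises /
uniform orientation mixture in a periphery zone, lognormal cell geometry,
packing constraint, day-dependent growth) exercises every stage without
microscopy data and backs power/calibration experiments.  See
`docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from pistonalign import (ReferenceShape, SyntheticConfig, generate_monolayer,
                         score_region, frequency_table, chi_square_test,
                         t_test_between_percents)

shape = ReferenceShape("circle", centroid=(200.0, 200.0), size=300.0)
config = SyntheticConfig(shape=shape, align_fraction=0.7, kappa=3.0, seed=42)

groups = {}
for region in ("piston", "control"):
    outlines, truth = generate_monolayer(config, day=2, region=region)
    result = score_region(shape, outlines)
    groups[region] = frequency_table(result.records, region, day=2)
    print(region, "cells:", len(outlines), "scored:", groups[region].n,
          "excluded:", dict(result.excluded))

for region, ft in groups.items():
    print(f"{region:8s} counts={ft.counts} percents=" +
          "(" + ", ".join(f"{p:.1f}" for p in ft.percents) + ")")

chi = chi_square_test(groups["piston"], groups["control"])
print(f"chi-square: statistic={chi.statistic:.2f} df={chi.df} p={chi.p_two_sided:.2e}")
t = t_test_between_percents(groups["piston"].percents[0], groups["piston"].n,
                            groups["control"].percents[0], groups["control"].n)
print(f"radial-bin t-test: t={t.statistic:.2f} df={t.df} p={t.p_two_sided:.2e}")
```

Output:

```
piston cells: 450 scored: 71 excluded: {'not_crossing': 379}
control cells: 450 scored: 55 excluded: {'not_crossing': 395}
piston   counts=(40, 6, 16, 9) percents=(56.3, 8.5, 22.5, 12.7)
control  counts=(18, 3, 14, 20) percents=(32.7, 5.5, 25.5, 36.4)
chi-square: statistic=11.81 df=3 p=8.07e-03
radial-bin t-test: t=2.64 df=124 p=9.43e-03
```

Both monolayers grew to 450 cells by Day 2; 71 piston-field and 55
control-field cells crossed the projected periphery and were scored.  In the
piston field 56% of crossing cells elongate radially (across the periphery)
versus 33% in the uniform control, the χ² test rejects equality of the bin
distributions (p ≈ 0.008), and the radial bin alone differs significantly
between the groups.

The same analysis runs from the shell on ImageJ `RoiSet.zip` files or plain
polygon CSVs:

```sh
pistonalign measure --roi RoiSet.zip --out measurements.csv
pistonalign score   --roi RoiSet.zip --shape shape.yaml --out records.csv
pistonalign stats   --records records.csv --out stats.csv
pistonalign simulate --config sim.yaml --outdir sim_out --seed 7
pistonalign reproduce-tables
```

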