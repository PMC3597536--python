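# ebsim — rules-based 3D simulation of embryoid-body differentiation patterns

Pluripotent embryonic stem cells cultured as 3D aggregates (embryoid bodies,
EBs) spontaneously lose pluripotency, and the loss — tracked through the
transcription factor Oct4 — unfolds in characteristic spatial patterns.
`ebsim` is an agent-based toolkit for studying how simple probabilistic
rules of cell–cell influence generate those patterns.  It is aimed at
computational/systems biologists who want a transparent, fully scriptable
model of pattern emergence in multicellular spheroids.

The package provides, end to end:

1. **Structure** — cells as incompressible rigid spheres (diameters drawn
   from a Coulter-style distribution, mean 6.6 µm) seeded in a box and
   pulled by a point attractor into a packed spheroid; validated by
   projected radius, circularity, and contact-graph connection statistics.
2. **Rules** — binary, irreversible Oct4+ → Oct4− transitions evaluated
   synchronously on the contact graph.  With β Oct4− and γ Oct4+ neighbours,
   ε = 12 the maximum neighbour count (FCC/HCP kissing number), and basal
   rate α = 0.01 per step:
   - *random*: P = α
   - *positive feedback*: P = 1 − (1 − α)(1 − β/ε)
   - *competing feedback*: P = 1 − (1 − α)(1 − w·β²/(β² + γ²))
   (the two mechanisms combine through a probabilistic or-gate).
3. **Pattern analytics** — six-class classification (Oct4+, inside-out,
   outside-in, connected, random, Oct4−; 90%/10% composition thresholds)
   and the undifferentiated/differentiated cluster numbers (UCN/DCN,
   clusters = connected same-state groups of ≥ 2 cells) tracked on a
   normalised time axis τ.
4. **Growth** — a dynamic variant with mass-spring mechanics and
   unsynchronised symmetric division (18 h doubling for Oct4+ cells, 51 h
   for Oct4−), with stop criteria at 144 h, 99% differentiated, or 40,000
   cells.

## Worked example

```python
from ebsim import (RuleKind, RuleParams, build_aggregate,
                   run_static_simulation, structure_report)

agg = build_aggregate(1000, seed=7)          # packed 1000-cell spheroid
rep = structure_report(agg)
print(rep.aggregate_radius, rep.circularity, rep.mean_connection_count)
# 38.1  0.973  6.59

for kind in RuleKind:
    traj = run_static_simulation(agg, RuleParams(kind=kind), seed=3)
    print(kind.name, traj.n_steps, traj.ucn.max(), traj.dcn.max())
# RANDOM              500  36  39
# POSITIVE_FEEDBACK    53  20  19
# COMPETING_FEEDBACK   21   6  21
```

The structure line says the packed spheroid is ~38 µm in radius, nearly
circular in projection (0.97), with ~6.6 contacts per cell.  The rule lines
show each rule's cluster signature: the random rule (1%/step) runs into the
500-step cutoff and fragments both populations (peak UCN 36 / DCN 39);
positive feedback drives extinction of Oct4+ through many isolated pockets
(peak UCN 20); competing feedback — where Oct4+ neighbours oppose the
transition — keeps the undifferentiated population in a few coherent blocks
(peak UCN 6) and is the regime whose patterns best resemble real EBs.

The `examples/` directory has one short narrative script per capability
(structure building, static rules, pattern classification, dynamic growth),
and the `ebsim` command line exposes the same stages
(`build-aggregate`, `fixtures`, `sim-static`, `sim-dynamic`, `classify`,
`analyze`, `run`).

## Documentation

`docs/methods.md` describes the model, its assumptions, the parameter
defaults and the numerical choices in detail.
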