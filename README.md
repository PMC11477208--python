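# myolever

Crossbridge-centric analysis of myosin lever-arm orientation dynamics in
molecular-dynamics trajectories.

## The problem

In the pre-powerstroke (M.ADP.Pi) state, β-cardiac myosin heads carry a
"primed" lever arm whose orientation relative to the motor domain sets how
heads present themselves to the thin filament. Small-molecule myotropes such
as omecamtiv mecarbil (OM), which bind a pocket at the converter/N-terminal
domain junction, shift both the mean lever-arm orientation and its
conformational heterogeneity. Quantifying those shifts from MD ensembles
needs more than a per-structure RMSD: it needs a filament-anchored coordinate
system, a rigid-core alignment that is not confused by the swinging lever
arm, replicate-aware statistics, and contact/conformer bookkeeping.

`myolever` packages that analysis stack for structural biophysicists:

* **Crossbridge frame** — an orthonormal triad built from a weakly-bound
  actomyosin reference: origin at the actin-pentamer centroid, axis **e₂**
  along the thin filament (dominant principal axis), **e₁** toward the
  myosin anchor (interfilament direction), **e₃ = e₁ × e₂**. The lever-arm
  ("tail") direction **v** — the unit vector joining backbone (N, Cα, C)
  centroids of residues 769–771 and 784–787 — is summarized by
  elevation = 90° − ∠(v, e₁), azimuth = atan2(v·e₃, v·e₂), and
  tilt = ∠(v, e₃).
* **LOVO rigid-core alignment** — iterative low-order-value optimization:
  align on the current least-mobile Cα subset, re-average, re-rank, keep the
  lowest fraction φ (default 0.35) until membership is a fixed point.
* **Replicate statistics** — per-replicate time averages as observations,
  pooled-variance two-tailed Student's *t* (df = n₁+n₂−2) for RMSD tables,
  per-residue ΔRMSF maps, and differential residue–residue contacts
  (5 Å heavy-atom criterion, p ≤ 0.05 and ≥ 10 % occupancy difference).
* **Ligand conformer clustering** — poses aligned on the rigid central
  moiety, average-linkage agglomeration, and the Kelley–Gardner–Sutcliffe
  penalty (normalized spread + cluster count) to pick the cut level.
* **Synthetic hinged-domain generator** — a rigid pseudo-motor plus a hinged
  converter/tail/ELC body whose per-frame (elevation, azimuth) are drawn from
  condition-specific Gaussians and realized exactly, with planted contacts,
  pose mixtures, and an elevation-gated salt bridge, so every stage has a
  recoverable ground truth.

## Worked example

Simulate the default apo-like (broad, mean elevation 23°) and holo-like
(narrow, mean 33°) conditions, superpose on the helix-loop-helix surrogate,
and measure tail angles in the crossbridge frame:

```python
import pandas as pd
from myolever.synthetic import apo_spec, holo_spec, make_hinged_system, simulate_trajectories
from myolever.geometry import superpose_to_reference, angle_timeseries, angle_summary
from myolever.model_io import select

rows = []
for ctor, seed in ((apo_spec, 0), (holo_spec, 1)):
    spec = ctor(n_frames=400, n_replicates=3, seed=seed)
    system = make_hinged_system(spec)
    trajs, _ = simulate_trajectories(spec, system)
    ref = system.reference_complex
    ref_sel = select(ref, system.hlh_expression)
    for t in trajs:
        placed = superpose_to_reference(t, system.hlh_selection(), ref, ref_sel)
        rows.append(angle_timeseries(placed, system.frame))
print(angle_summary(pd.concat(rows, ignore_index=True)).round(2))
```

prints

```
          elevation       azimuth         tilt
               mean   std    mean   std   mean   std
condition
apo           23.43  5.95   33.85  7.72  59.50  6.97
holo          32.84  2.52   45.11  3.95  53.55  3.14
```

i.e. the generated priming shift (+~10° elevation, +~11° azimuth) and the
variance reduction of the ligand-bound condition are recovered by the full
measurement path within sampling error. Tilt is a derived diagnostic of the
same direction vector (cos tilt = cos el · sin az).

The whole stage sequence (LOVO fit, RMSD table, RMSF difference map, angle
densities, contacts, differentials, ligand occupancy and clustering, morphs)
runs with one call or one command:

```bash
myolever report --out results/run1 --seed 7 --frames 400
```

which writes CSV tables, morph multi-model PDBs, and a `manifest.json` that
pins config, seed, and versions. `myolever simulate / align / angles / rmsf /
contacts / ligand / cluster / morph` expose the individual stages.

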