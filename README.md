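# dpdmix

Dissipative particle dynamics (DPD) simulation and analysis of **two-species
single-tail lipid mixtures in water**: membrane, perforated-membrane and
vesicle self-assembly, the three-stage formation dynamics, and
Irving–Kirkwood interfacial-tension profiles.

## Who this is for

Soft-matter and membrane-biophysics researchers who want a compact,
reproducible coarse-grained pipeline for binary amphiphile mixtures: build a
seeded initial state, run the DPD dynamics, and measure the structural and
mechanical observables of the assembled aggregate — all in reduced DPD units
(m = rc = kBT = 1) on a single core.

## The model in brief

Each lipid is a linear chain, one hydrophilic head block (H) plus one
hydrophobic tail block (T); water is a single bead (W).  Beads within the
cutoff rc feel a soft repulsion a_ij(1 − r/rc)r̂ plus the momentum-conserving
DPD thermostat (dissipative −γw²(r̂·v)r̂ and random σwζΔt^(−1/2)r̂ forces,
σ² = 2γkBT).  Bonds are harmonic, F = ks(1 − r/rs)r̂, and every three
consecutive beads carry a bending potential kθ(θ − θ0)².  Like beads and
head–water contacts repel weakly (a = 25); all other unlike contacts repel
strongly (a = 100), i.e. a Flory–Huggins χ = 0.286·(a_ij − a_ii) ≈ 21.45 —
strong segregation, which drives bilayer assembly.  Observables include
per-species density profiles, the P2 = (3cos²θ − 1)/2 orientational order
parameter, per-chain gyration tensors and the shape factor
δ = 1 − 3(L1²L2² + L2²L3² + L1²L3²)/(L1² + L2² + L3²)², leaflet mixing
counts, pore metrics, and the interfacial tension
σ_z = p_zz − (p_xx + p_yy)/2 from a slab-resolved Irving–Kirkwood pressure
tensor.  See `docs/methods.md` for the full account.

## Worked example

Run the reduced membrane production (15 × 15 × 30 rc³, 225 + 225 chains with
3 head and 9 tail beads each, 20,250 beads total, layered unmixed start) and
analyse it:

```python
import dataclasses
from dpdmix import pipeline
from dpdmix.pipeline import desk_config, simulate

cfg = dataclasses.replace(desk_config(nt1=9, nt2=9, seed=1),
                          n_steps=36_000, frame_stride=500)
traj = simulate(cfg)                       # ~7 min on one core
seg = traj.segmentation()
report = pipeline.analyze(traj, which={"classify", "profiles",
                                       "order", "gyration"})
print(report["classification"]["label"])   # membrane
print(round(report["thickness"], 1))       # 10.9
print(round(report["order_parameter"]["max"], 2))   # 0.72
print(round(report["gyration"]["type-I"]["delta"], 2))  # 0.86
print([round(m, 2) for m in seg.stage_means])  # [6.81, 6.53, 6.51]
```

Reading the numbers: the layered start relaxes into a mixed bilayer
**membrane** whose head-density profile is ~11 rc thick between half-maximum
crossings; head chains stand nearly normal to the membrane (peak P2 ≈ 0.72
against 1.0 for perfect alignment); chains are rod-like (δ ≈ 0.86 on the
0 = sphere … 1 = rod scale); and the per-bead total energy decays through
the initial → adjustment → stable stages of the dynamics, settling near
6.5 kBT.  With short asymmetric tails (nt1=5, nt2=6, run to 60,000 steps)
the same pipeline yields a thinner bilayer whose chains are slightly more
rod-like (δ ≈ 0.90); strongly asymmetric tails (e.g. 3 and 7) give
vesicles.

The same workflow is scriptable from the shell:

```sh
dpdmix simulate --preset desk --nt1 9 --nt2 9 --steps 36000 --out run/
dpdmix analyze  --preset desk --nt1 9 --nt2 9 --steps 36000 --out run/
dpdmix sweep --nt1-range 3,6,9 --nt2-range 3,6,9 --steps 20000 --out sweep/
```

`full_scale_config()` gives the full-scale production box (30³ rc³, 81,000
beads, 300,000 steps) for full-length runs.

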