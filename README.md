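# dvhkit

Dose–volume histogram (DVH) analysis for radiotherapy treatment plans.

Evaluating a 3D conformal or intensity-modulated (IMRT) plan means reducing
a 3D dose distribution over contoured anatomy to quantities a physicist or
physician can act on: how much of the target receives the prescription
dose (PD), how hot the hot spots are, how much of each organ at risk (OAR)
exceeds its tolerance, and what the modelled biological consequences are.
`dvhkit` implements that reduction chain as a tested library plus CLI:

* **Rasterization** — planar closed contours per CT slice are converted to
  (optionally fractional) voxel masks on the dose lattice by even-odd
  point-in-polygon sampling, with stratified sub-voxel supersampling for
  partial-volume accuracy.
* **Histograms** — differential DVHs (volume per dose bin), cumulative
  DVHs `V(≥D)` on a 501-point dose axis by default, per-slice spatial DVHs
  (zDVH, satisfying `DVH(Dᵢ) = Σₙ zDVH(Dᵢ, zₙ)` exactly), and dose-surface
  histograms (DSH) over 6-connectivity boundary voxels.
* **Statistics** — Vx / Dx / PD-relative coverage queries, min / max /
  mean / median, answered from the curves; Dx inversion goes through a
  smoothed curve model (cosine midpoint interpolation with weight 0.5 plus
  windowed least-squares polynomials over the six nearest samples).
* **Plan indices** — the ten-index set
  {TCI, COSI, RCI, PITV, HI, MHI, CN, TVR, DGI, NCI} with auxiliaries
  TR = PIV/PTV_PD and CI = 1/TR, and the quality factor
  `QF = 2.718·exp(−Σ Wᵢ Xᵢ)`. Every index is 1 for an ideal plan.
* **Outcome models** — Poisson tumour control probability
  `TCP = (1/2)^Σ vᵢ exp[2γ₅₀(1−Dᵢ/TCD₅₀)ln2]` and Lyman probit NTCP
  `Φ[(EUD−TD₅₀)/(m·TD₅₀)]` with the generalized mean dose
  `EUD = (Σ vᵢ Dᵢ^{1/n})ⁿ`.
* **Phantoms** — a seeded generator of plan bundles (sphere/box targets,
  shell OARs, plateau / linear-falloff / two-level dose models) whose DVHs
  have closed forms, so every stage can be validated against an exact
  oracle.

Plan bundles are plain-text directories (header, slice-major dose grid,
per-structure contour files); the format is documented in
`dvhkit/plan_io.py`. Reports are CSV files mirroring the conventional
four-section spreadsheet layout (target statistics and coverage,
normalized and absolute organ coverage, per-structure Vx/min/max/mean/median).

## Worked example

Generate a phantom (20 mm-radius spherical target, concentric shell OAR,
3900 cGy plateau with 10 mm linear falloff, 1 mm grid) and score it:

```sh
dvhkit synth --preset sphere --seed 42 --out bundle
dvhkit indices --bundle bundle --ptv PTV --oars OAR:2000 --out indices.json
dvhkit radiobio --bundle bundle --structure PTV --model tcp
```

`indices.json` contains (abridged):

```json
"indices": {"TCI": 1.0, "RCI": 1.0, "PITV": 1.0, "HI": 1.0, "MHI": 1.0,
            "CN": 1.0, "TVR": 1.0, "DGI": 1.0, "NCI": 1.0,
            "COSI": 0.612},
"QF": 1.039
```

The plateau covers the target exactly, so all conformity/homogeneity
indices are unity; COSI drops to 0.61 because 39% of the shell OAR sits
above its 2000 cGy tolerance in the falloff region, and QF moves
accordingly. The TCP call prints `"probability": 0.4805` — a uniform
3900 cGy target dose sits just below this model's TCD₅₀ of 4180 cGy.

From Python, the same phantom validates the DVH engine against its
closed-form curve:

```python
import numpy as np, dvhkit as dk
from dvhkit.phantom import PhantomSpec, make_phantom_plan, analytic_cdvh

spec = PhantomSpec(seed=42)
bundle = make_phantom_plan(spec)
grid = bundle.grids["PTV1"]
mask = dk.rasterize_structure(bundle.structure("OAR"), grid, supersample=2)
cdvh = dk.cumulate(dk.compute_ddvh(grid, mask))
exact = analytic_cdvh(spec, "OAR")
probes = np.linspace(0, spec.d0, 501)
print(dk.nrmsd(cdvh, exact, probes))   # 0.259  (% of total volume)
print(dk.dta(cdvh, exact, 0.5, spec.pd))  # 0.302  (% of PD at half volume)
```

Both figures sit inside the package's acceptance envelope (NRMSD < 1%,
distance-to-agreement at 50% volume < 0.5% of PD).

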