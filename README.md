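# recruitkit

Quantification toolkit for three measurement problems that recur in studies
of autophagy-initiation machinery (and of peripheral membrane proteins
generally):

1. **GUV membrane-recruitment assays** — two-channel confocal time-lapses of
   giant unilamellar vesicles (GUVs), where the question is how much
   fluorescent protein is recruited to each vesicle membrane over time.
2. **Differential HDX-MS** — hydrogen–deuterium exchange mass spectrometry
   of a protein or complex measured with and without a binding partner,
   where the question is which peptides become protected or deprotected.
3. **Filament contour statistics** — traced paths of elongated particles
   (e.g. coiled-coil scaffolds in negative-stain EM), where the question is
   the distribution of contour lengths and end-to-end distances, compared
   with the span expected for an uninterrupted coiled coil.

Every analysis stage has a matching synthetic-data generator with exact
ground truth, so the entire pipeline is testable end to end without any
external data.

## Methods at a glance

**GUV quantification.** Each frame's membrane channel is reduced to a local
contrast image `C(p) = max_{disk(p,w)} I − min_{disk(p,w)} I`; the vesicle
rings are the connected components of `C ≥ T_Otsu(C)`, where `T_Otsu`
maximizes the between-class variance `ω₀ω₁(μ₀−μ₁)²` over a 256-bin
histogram. The per-vesicle readout at frame *t* is

    v(t) = mean_{ring}(P_t) − ½ (mean_{lumen}(P_t) + mean_{exterior}(P_t))

with `P_t` the protein channel; vesicles are linked across frames by
nearest-centroid assignment and reported as mean ± sample SD across GUVs.

**Differential HDX.** Per peptide, percent deuteration at exchange time *t* is

    %D(t) = 100 · (m_t − m_unexchanged) / (m_maxlabel − m_unexchanged)

which cancels uniform back-exchange. The condition-versus-reference
difference `Δ%D = %D_cond − %D_ref` (SD propagated in quadrature over N = 3
replicates) is classified at a fixed effect-size threshold: protected if
`Δ%D ≤ −10`, deprotected if `Δ%D ≥ +10` points, and same-class peptide spans
are merged into contiguous residue regions.

**Contour statistics.** For a traced path with points `x_i` and pixel size
`s`, contour length is `s·Σ|x_{i+1}−x_i|` and end-to-end distance
`s·|x_N−x_1|`. The span of an uninterrupted dimeric coiled coil of *n*
residues is `n · 1.485 Å` (canonical axial rise per residue), so a
710-residue coiled-coil domain (residues 790–1500 of the FIP200 scaffold)
predicts ≈105 nm.

## Worked example

```python
import numpy as np
from recruitkit.synthetic_data import GuvSimSpec, RecruitmentKinetics, simulate_guv_timelapse
from recruitkit.guv_quant import build_trajectories
from recruitkit.cc_trace import domain_residue_count, predicted_cc_span

spec = GuvSimSpec(
    image_shape=(160, 400),
    vesicles=[(40.0 + 80.0 * r, 40.0 + 75.0 * c, 20.0) for r in range(2) for c in range(5)],
    kinetics=RecruitmentKinetics(model="exponential_rise", rate_per_min=0.1),
    noise_sigma=5.0,
    seed=2024,
)
res = simulate_guv_timelapse(spec)
trajectories, agg = build_trajectories(res.stack)
print(f"tracked vesicles: {len(trajectories)}")
for t, m, s in zip(agg.times_min, agg.mean, agg.sd):
    print(f"{t:7.1f} {m:7.2f} {s:6.2f}")
n = domain_residue_count(790, 1500)
print(f"predicted span of a {n}-residue coiled coil: {predicted_cc_span(n):.1f} nm")
```

prints

```
tracked vesicles: 10
    0.0    0.55   0.16
    5.0   20.50   0.27
   10.0   32.87   0.27
   15.0   40.36   0.33
   20.0   44.81   0.24
   25.0   47.55   0.38
   30.0   49.19   0.29
   35.0   50.25   0.32
predicted span of a 710-residue coiled coil: 105.4 nm
```

Ten simulated GUVs carrying an exponential-rise recruitment signal
(k = 0.1/min) are segmented, tracked, and quantified; the aggregate mean
rises with the expected saturating kinetics (background-subtracted ring
intensity, arbitrary units) with a small vesicle-to-vesicle SD, and the
closed-form coiled-coil prediction reproduces the ≈105 nm figure.

A command-line interface mirrors the library:

```bash
recruitkit simulate guv --config sim.json --out sim/ --seed 5
recruitkit quantify-guv --tiff sim/stack.tif --metadata sim/stack_meta.json --out quant/
recruitkit hdx-diff --uptake uptake.csv --condition bound --reference apo --timepoint 60 --out hdx/
recruitkit trace-stats --paths tracks.csv --pixel-size-nm 0.88 --out trace/
```

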