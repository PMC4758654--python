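# angiofield

A hybrid continuum–discrete simulator of coupled tumor growth and
angiogenesis in two dimensions, for computational-oncology researchers who
want a compact, fully reproducible model of the angiogenic switch: the
transition of a solid tumor from diffusion-limited (avascular) dormancy to
capillary-fed (vascular) growth, and the counter-intuitive slowdown of that
growth when Dll4/Notch lateral inhibition is blocked.

## Model

Four coupled fields live on a quarter of a rectangular tissue domain
(2625 µm × 2025 µm full size; symmetry across the left and top edges), plus
discrete agents:

* **Tumor phase field** φ ∈ [0, 1] — Allen–Cahn gradient flow of the free
  energy ½λ<sub>φ</sub>²|∇φ|² + g(φ) + m(σ)h(φ), with the symmetric double
  well g(φ) = φ²(1−φ)², the interpolant h(φ) = φ²(3−2φ), and the nutrient
  tilt m(σ) = −(2/3.01π)·arctan(15(σ−σ<sup>h−v</sup>)):

  ∂φ/∂t = M<sub>φ</sub>(λ<sub>φ</sub>²Δφ − μ<sub>φ</sub>(φ, σ)),  μ<sub>φ</sub> = g′(φ) + m(σ)h′(φ).

  Below the hypoxic–viable threshold σ<sup>h−v</sup> the host state is
  energetically preferred and the tumor regresses; above it the tumor grows.

* **Nutrient** σ ∈ [0, 1] — reaction–diffusion with capillary production
  scaled by the network functionality S and two-tier uptake
  (V<sub>u</sub><sup>T</sup> ≫ V<sub>u</sub><sup>H</sup>):

  ∂σ/∂t = ∇·(D<sub>σ</sub>∇σ) + V<sub>p</sub><sup>c</sup>(1−σ)cH(c)S − V<sub>u</sub><sup>T</sup>σφ − V<sub>u</sub><sup>H</sup>σH(1−φ).

* **Capillaries** c ∈ [−1, 1] — Cahn–Hilliard dynamics with a
  TAF-dependent endothelial proliferation term B<sub>p</sub>(f)cH(c), where
  B<sub>p</sub>(f) = B<sub>p</sub>·min(f, f<sub>p</sub>).

* **Tumor angiogenic factor** f ∈ [0, 1] — secreted by hypoxic tumor cells
  (a Gaussian bump G(σ) centered mid-hypoxia), diffusing fast, consumed by
  capillaries.

* **Tip endothelial cells** — circular mesh-free agents of radius R that
  activate where c ≥ c<sub>act</sub>, f ≥ f<sub>act</sub> and no other tip
  cell lies within the Dll4 exclusion distance δ₄ (lateral inhibition);
  migrate up ∇f with speed χ·J(φ), probe for nearby capillaries with
  filopodia, redirect and anastomose with them, and are stamped into c with
  radial template functions.  Network functionality is the segment-length
  statistic S = l<sub>max</sub>/Σl<sub>i</sub> — a single vessel gives
  S = 1, denser networks deliver nutrient less efficiently.

The PDEs are integrated with DCT-based semi-implicit (linearly stabilized
IMEX) schemes on a zero-flux finite-difference grid with adaptive step-size
control; see `docs/methods.md` for the numerics and parameter table.

## Worked example

Run the reference Dll4 experiment pair on a coarse grid (about 15 s each)
and compare the endpoints:

```bash
angiofield run configs/vascular.yaml      --grid 128 99 --seed 0 --outdir out_v
angiofield run configs/dll4_blockade.yaml --grid 128 99 --seed 0 --outdir out_d
angiofield compare out_v out_d
```

which prints (numbers from the exact commands above):

```
 run  t_days  g_re  capillary_area        S  n_anastomoses
out_v     5.1  -1.0   143348.211115 0.166577             91
out_d     5.1  -1.0   156129.705256 0.142559            202
```

Reducing the Dll4 exclusion distance from 80 to 55 (down-regulated Notch
signaling) produces a denser capillary network (larger capillary area, more
anastomoses) that is *less* functional (lower S) and does not accelerate
tumor growth.  `g_re = (A_t − A_0)/A_0` is the relative tumor-area change;
with the reference parameter table the tumor interface moves fast enough
that the lesion regresses completely within the 5.1-day horizon in both
arms (see the parameter discussion in `docs/methods.md`), so the Dll4
comparison is carried by the network statistics.

Each run directory contains `timeseries.csv` (one row per output time:
areas, g_re, S, region decomposition, tip-cell counts), VTK/npz field
snapshots viewable in ParaView, `tec_events.csv` (activations, redirects,
anastomoses with positions and times) and a `manifest.json` holding the
full configuration and seed for exact reproduction.

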