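# ciliaquant

Quantification toolkit for **multiciliated ependymal cells** — the cells lining
the brain ventricles whose beating cilia drive cerebrospinal-fluid flow. Each
cell carries tens of centrioles (basal bodies) clustered in a *centriolar
patch* at the apical surface, embedded in apical and subapical F-actin
networks. Quantifying how drugs, mutations or gene knock-downs change this
system requires a stack of image- and signal-analysis steps, all of which this
package implements as a tested, reusable pipeline:

* **3D centriole detection and counting** — Gaussian + Laplacian-of-Gaussian
  filtering of centrin-labelled stacks, 3D local-maxima extraction in physical
  units, assignment of spots to cell-border polygons.
* **Patch geometry** — density-based patch boundary, convex-hull patch area
  (µm²), nearest-neighbour inter-centriolar distances (xy).
* **Basal-body orientation** — each centriole is paired with its Cep164
  (distal-appendage) punctum by minimum-total-distance assignment (Hungarian
  algorithm); the centrin→Cep164 unit vectors give per-cell circular
  statistics: mean beat direction, resultant length *R*, deviations, 20°
  rose-plot histograms, and Watson *U*² / Kolmogorov–Smirnov two-sample tests.
* **Actin intensity ratios** — mean phalloidin intensity in the patch over the
  rest of the cell surface, on 6-slice sum projections at the apical (Cep164)
  and subapical (Akap450) planes; neighbour-cell and contralateral fold-change
  normalisations; ROUT-style outlier removal; Mann–Whitney / Kruskal–Wallis +
  Dunn / χ²-trend comparisons.
* **Cilia beat kinetics** — kymographs from line ROIs of 250-fps recordings;
  beat frequency by peak counting with a periodogram cross-check; peak-to-peak
  beat amplitude.
* **Force model** — a beating cilium idealised as a slender cylinder (radius
  *r*, length *L*) in low-Reynolds-number fluid of viscosity *μ*:

  ```
  C        = 4πμ / log10(L/r)          normal drag coefficient
  F_flow   = C · f · A · L             force at the base countering fluid drag
  F_torque = F_flow · L / L_c          amplified force on the centriole (length L_c)
  ```

  With the measured geometry of ependymal cilia (r = 99 nm, L = 11.1 µm,
  L_c = 510 nm, μ = 10⁻³ N·s·m⁻²) this gives C ≈ 6×10⁻³ N·s·m⁻² and an
  amplification factor L/L_c ≈ 21.8.

Because raw microscopy data of this kind are rarely deposited, the package
ships a first-class **synthetic-data generator** (`ciliaquant.synthetic`) that
renders multichannel 3D stacks (centrin, Cep164, actin, membrane channels,
Gaussian PSF, Poisson + Gaussian camera noise) and beating traces with exact
ground truth, so every stage is testable end to end.

## Worked example

Run the full image pipeline on a synthetic field of 4 cells with 30
centrioles each (noiseless, seed 3):

```python
import ciliaquant as cq

cfg = cq.RunConfig(scene=cq.SceneSpec(), seed=3)
table = cq.run_image_pipeline(cfg)
print(table.round(3))
```

```
 cell_id  centriole_count  patch_area_um2  mean_nn_um  resultant_length  apical_ratio  subapical_ratio
       0               30           7.740       0.511             0.940           2.0              1.5
       1               30           7.750       0.484             0.862           2.0              1.5
       2               30           7.765       0.480             0.926           2.0              1.5
       3               30           8.325       0.506             0.945           2.0              1.5
```

All 120 centrioles are recovered (30 per cell), patch hull areas are ~8 µm²,
mean nearest-neighbour spacing ~0.5 µm, the per-cell resultant length R ≈ 0.9
reflects the generator's 0.35-rad angular dispersion of basal-body
orientations, and the apical/subapical actin ratios recover the generator's
targets (2.0 and 1.5) exactly on the noiseless render.

The force model from the command line, for a cilium beating at 25 Hz with
8 µm amplitude:

```bash
$ ciliaquant forces -f 25 -a 8um
{
  "C_Nsm2": 0.006130870619073651,
  "F_flow_pN": 13.610532774343502,
  "F_torque_pN": 296.2292427357115,
  "amplification_L_over_Lc": 21.76470588235294
}
```

i.e. a drag coefficient of 6.1×10⁻³ N·s·m⁻², ~14 pN of flow-countering force
at the ciliary base, amplified ~22-fold to ~300 pN on the centriole by the
beating-induced torque.

Other subcommands: `simulate`, `detect`, `geometry`, `orient`, `quantify`,
`kinetics`, `pipeline` (see `ciliaquant --help`).

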