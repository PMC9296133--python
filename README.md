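# nedyn

Quantification of nuclear envelope (NE) formation and growth in early
*C. elegans* embryos. The first embryonic division is a stereotyped assay for
how nuclear pore complexes (NPCs) and membrane supply together build a
transport-competent, growing nucleus; `nedyn` implements the measurement side
of that assay as a tested, reusable pipeline for:

* **Nuclear-import kinetics** — per-frame background-corrected
  nucleocytoplasmic ratio `(N − bg)/(C − bg)`, optionally scaled by nuclear
  area (µm²), from two-channel time-lapse stacks, referenced to an anchor
  event (anaphase onset, furrow ingression, pseudocleavage regression);
  onset detection and normalized-difference curves.
* **FRAP recovery** — prebleach normalization and nonlinear least-squares
  fitting of `f(t) = A·(1 − e^(−τt))`, giving the mobile fraction `A`,
  rate `τ`, half-time `T½ = ln 2/τ`, and immobile fraction `1 − A`.
* **Nuclear morphometry** — equivalent diameter from thresholded central
  sections with sphere surface area `4πr²` and volume `(4/3)πr³`; contour
  volume integration (shoelace area × 0.1625 µm slice spacing, summed);
  theoretical volume from the widest slice; a within-10% sphericity check;
  OLS nuclear-expansion rate.
* **Nuclear-rim line scans** — 3-px-wide profiles with a perpendicular
  redraw averaged in, end-point background correction, max-normalization,
  and NE:cytoplasm / NE:nucleoplasm ratios.
* **Nascent-NPC hole morphometry** — gap detection in membrane polylines
  traced from EM tomogram slices, classification by three criteria
  (width < 100 nm, tapered edges, continuous ≥100 nm flanks), and hole
  densities per µm² (per region, mean of regions, and pooled).
* **Tabular assays** — embryonic lethality / brood size from count tables
  and qPCR relative expression by `2^(−ΔΔCt)`.

A synthetic-data module generates every input type with closed-form ground
truth (growing importing nuclei, exponential FRAP curves, traced spheres,
membrane fields with known gaps), so each estimator is validated by
round-trip against a known answer.

## Worked example

```sh
nedyn demo --seed 7 -o demo_out
```

generates a synthetic embryo time lapse, FRAP curves for a slow-turnover
("control", true A = 0.20) and a fast-turnover ("depleted", true A = 0.47)
condition, an ideally spherical traced pronucleus, and a membrane field with
three gaps (50 nm tapered, 95 nm blunt, 120 nm tapered), then runs every
analysis and writes CSVs plus `summary.json`:

```json
{
  "frap_control_mean_mobile": 0.2011759807046099,
  "frap_depleted_mean_mobile": 0.4754669573997921,
  "hole_density_per_um2": 10.0,
  "import_onset_s": 120.0,
  "sphericity_deviation_pct": 0.022263464438307047
}
```

Reading this: the mean fitted mobile fractions (0.201, 0.475) recover the
generating truths (0.20, 0.47) — the >2-fold contrast between conditions is
preserved; import onset is detected at 120 s, one frame after the generated
import start of 100 s; the contour-integrated volume of the ideal sphere
agrees with the widest-slice theoretical volume to 0.022%, far inside the
10% sphericity bound; and exactly one of the three membrane gaps (the
50 nm tapered one) is accepted as a nascent-NPC hole, giving 1 hole in the
0.1 µm² field = 10 µm⁻². The run is deterministic: the same seed reproduces
every output byte for byte.

Each stage is also a standalone subcommand (`nedyn import-trace`,
`nedyn frap fit`, `nedyn diameter`, `nedyn volume`, `nedyn linescan`,
`nedyn holes`, `nedyn lethality`, `nedyn ddct`, `nedyn synth ...`) and a
plain library call; see `docs/methods.md` for the models and parameters.

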