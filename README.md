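# mosaicband

Zone-based quantification of clonal interfaces in mosaic epithelial
tissue images, with a hexagonal contact-topology model of how interface
signalling scales with clone size.

## The problem

Epithelia eliminate cells whose fate program differs from their
neighbours' ("interface surveillance"). In mosaic *Drosophila* wing
imaginal discs, stress signalling (JNK, read out by a TRE-RFP reporter)
and apoptosis (cleaved Dcp1 puncta) concentrate in roughly one cell row on
*both* sides of the clone/wild-type contact, and their strength falls as
clones grow. Quantifying this requires a reproducible way to turn
multi-channel fluorescence images into per-zone measurements:

- segment the disc (DAPI), the GFP-marked clones, and the apoptotic
  puncta with calibrated filter-and-threshold chains;
- build a disjoint zone system in physical units — a 4 µm wild-type
  interface band around every clone, a second 4 µm band ("row 2"), a
  4 µm clone-side interface band and the clone interior (defined for
  clones ≥ 180 µm²), plus background;
- measure mean reporter intensity and percent apoptotic **area** per
  zone, per clone, and bin clones by area
  (small [10, 140), medium [140, 650), large [650, ∞) µm²);
- test the comparisons the design calls for: paired *t*, one/two-way
  ANOVA, Spearman ρ, and the semi-log fit
  `signal = a + b · log₁₀(area)`.

`mosaicband` implements that measurement chain as a library with a thin
CLI, and — because no public micrographs accompany the procedure — ships a
synthetic mosaic-tissue generator that renders all four channels with
known ground truth, so every stage is testable end to end.

## The topology model

On a hexagonal lattice a lone aberrant cell touches 6 wild-type cells
with all 6 of its surfaces, while each wild-type neighbour commits only
1 surface. For a compact clone of *n* cells the mean number of
heterotypic contacts per clone-side interface cell falls from 6 toward
≈ 2.1, while the wild-type-side mean stays below 2. If per-cell
signalling is `base + g · contacts`, interface signalling is strongly
biased toward small clones — exactly the clone-size scaling the image
pipeline measures.

## Worked example

```python
from mosaicband import RunConfig, SyntheticSpec, run_pipeline

spec = SyntheticSpec(seed=1, reporter_model="band",
                     reporter_enrichment=2.0, reporter_lambda_um=4.0)
res = run_pipeline(RunConfig(simulate=spec, seed=1, output_dir="out"))
t = res.zone_stats
means = t[(t.clone == 0) & (t.metric == "mean")].set_index("zone").value
print(means.round(2))
print("interface / row-2:", round(means["CLONE_INTERFACE"] / means["WT_ROW2"], 3))
```

prints

```
zone
WT_BACKGROUND      18.96
WT_ROW2            20.87
WT_INTERFACE       40.19
CLONE_INTERFACE    39.90
CLONE_INTERIOR     25.61
CLONE_SMALL        39.87
interface / row-2: 1.912
```

The generator doubled the reporter (E = 2) within 4 µm of every
clone/wild-type interface over a base of 20 AU; the pipeline — from raw
channels through segmentation, band construction and zone statistics —
recovers the bilateral pattern (both interface bands ≈ 40 AU, row 2 and
background at base) and the enrichment ratio 1.91, within 5 % of truth.
The clone-interior mean (25.6) sits above base because segmentation
places the interior boundary a pixel or two inside the true one.

The numbered drivers under `analysis/` run the full study on synthetic
data: `01` generates the reference field, `02` segments and zones it
(per-clone IoU ≈ 0.93), `03` recovers reporter enrichment, `04` recovers
per-zone apoptosis rates (10 / 2 / 0.5 % → 9.7 / 3.3 / 0.47 %), `05`
measures the size-binned reporter decline (one-way ANOVA F ≈ 78,
p ≈ 2·10⁻¹⁸; Spearman ρ ≈ −0.87), `06` tabulates the contact-topology
curves, and `07` calibrates the tests under the null. Each writes its
tables under `results/`.

A CLI mirrors the stages: `mosaicband simulate | segment | zones |
quantify | stats | topology | run`.

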