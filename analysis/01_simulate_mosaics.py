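#!/usr/bin/env python
"""Generate the reference synthetic mosaic disc and its ground truth.

Produces one 512x512 field (1 µm/px) with ~10 clones spanning the three
size bins, the four channels (DAPI / GFP / TRE / cDcp1) as OME-TIFF, and
the generator's truth tables.  Everything downstream (02-05) can be traced
back to this field or regenerates its own with different parameters.
"""

from pathlib import Path

from mosaicband.image import write_image, write_labels
from mosaicband.synthetic import SyntheticSpec, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "01_simulate"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SyntheticSpec(seed=seed)
    image, truth = simulate(spec)
    write_image(OUT / "mosaic.ome.tif", image)
    write_labels(OUT / "true_genotype.tif", truth.genotype)
    write_labels(OUT / "true_cells.tif", truth.cells)
    truth.spots.to_csv(OUT / "true_spots.csv", index=False)
    areas = truth.genotype.areas_um2()
    print(f"simulated disc: {truth.cells.n_labels} cells, "
          f"{truth.genotype.n_labels} clones "
          f"({min(areas.values()):.0f}-{max(areas.values()):.0f} µm²), "
          f"{len(truth.spots)} apoptotic spots -> {OUT}")


if __name__ == "__main__":
    main()
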