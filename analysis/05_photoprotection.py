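#!/usr/bin/env python
"""Photoprotection by confined activation in sequential-layer 3D imaging.

Two experiments on a shell-structured volume (layers 600 nm apart):

* Protection scheme: activate a center and a below layer, image the center
  repeatedly with STED, then activate the layer above.  With 2PA the above
  layer was never activated, so every imaging dose passed it by and its full
  fluorescence is recovered; with 1PA it was uncaged from the start and
  bleaches scan by scan.

* Volume acquisition: image all layers top to bottom.  2PA (activate each
  layer just before imaging it) gives a flat depth-intensity curve; 1PA
  (activate everything up front) decays with depth.

Writes results/protection.json and results/depth_intensity_{1pa,2pa}.csv.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pa2p import optics, protocols, synthetic_data

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
LAYER_SPACING_NM = 600.0
BLEACH_PER_SCAN = 0.1
N_STED_SCANS = 10


def main() -> None:
    OUT.mkdir(exist_ok=True)
    volume = synthetic_data.generate_volume_sample(
        24, 24, 7, structure="shells", seed=SEED, z_step=LAYER_SPACING_NM
    )
    sted = optics.BeamModel(process_order=2, rayleigh_range=350.0)
    step = protocols.ImagingStep(
        bleach_fraction=BLEACH_PER_SCAN,
        crosstalk_profile=protocols.default_crosstalk_profile(sted, LAYER_SPACING_NM),
    )

    report = {}
    for mode in ("2pa", "1pa"):
        res = protocols.run_protection_experiment(
            volume, mode, N_STED_SCANS, step, seed=SEED
        )
        report[mode] = {
            "above_recovered_fraction": res.above_recovered_fraction,
            "below_trajectory": res.below_trajectory.tolist(),
        }
        print(f"{mode}: above-layer recovered fraction after {N_STED_SCANS} "
              f"STED scans = {res.above_recovered_fraction:.4f}; below layer "
              f"faded to {res.below_trajectory[-1]:.4f}", file=sys.stderr)

        acq = protocols.run_volume_acquisition(
            volume, mode, step, seed=SEED, noiseless=True
        )
        pd.DataFrame({
            "depth_nm": np.arange(volume.n_layers) * LAYER_SPACING_NM,
            "intensity": acq.depth_intensity,
        }).to_csv(OUT / f"depth_intensity_{mode}.csv", index=False)
        # compare only layers that contain labelled structure
        occupied = np.flatnonzero(volume.density.sum(axis=(1, 2)) > 0)
        lo, hi = occupied[0], occupied[-1]
        print(f"{mode}: depth-intensity deepest/shallowest (occupied layers "
              f"{lo}-{hi}) = "
              f"{acq.depth_intensity[hi]/acq.depth_intensity[lo]:.3f}",
              file=sys.stderr)

    (OUT / "protection.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {OUT/'protection.json'}", file=sys.stderr)


if __name__ == "__main__":
    main()
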