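#!/usr/bin/env python
"""Simulate the activation/readout characterisation experiment.

Renders a microtubule-like filament phantom and runs the Frame 0 /
activation / readout sequence at seven activation powers (1–8 mW), with the
three-state rates scaling as k_act ~ P^2 and k_bl ~ P^1.54.  Writes the
per-frame mean signals for every power to results/mean_signals.csv and the
lowest- and highest-power stacks as TIFF.

The mean-signal curves show the characteristic behaviour: a rise while
activation dominates, a maximum, then decay once bleaching of already
activated molecules takes over — earlier and faster at higher power.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pa2p import io, kinetics, synthetic_data

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
POWERS_MW = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0)
C_ACT = 0.5 / 16.0  # k_act = 0.5/frame at the 4 mW working power
C_BL = 0.1 / 4.0**1.54  # bleaching 5-fold slower at 4 mW, exponent 1.54


def main() -> None:
    OUT.mkdir(exist_ok=True)
    phantom = synthetic_data.generate_filament_phantom(
        96, 96, 12, labels_per_length=0.5, pixel_size=40.0, seed=SEED
    )
    print(f"phantom: {phantom.density.shape}, "
          f"{phantom.total_filament_length/1000:.1f} µm of filament", file=sys.stderr)

    rows = []
    for i, p in enumerate(POWERS_MW):
        rates = kinetics.RateParams(C_ACT * p**2, C_BL * p**1.54)
        proto = synthetic_data.AcquisitionProtocol(
            activation_power=p, n_cycles=39, seed=SEED * 1000 + i
        )
        series = synthetic_data.simulate_activation_series(
            phantom, rates, proto, photons_per_fluorophore=25.0
        )
        for t, m in enumerate(series.mean_signal, start=1):
            rows.append({"power_mw": p, "frame": t, "mean_signal": m})
        if p in (POWERS_MW[0], POWERS_MW[-1]):
            io.save_stack(series.frames, OUT / f"series_{p:g}mW.tif", axes="TYX")
        peak_frame = int(np.argmax(series.mean_signal)) + 1
        print(f"P = {p:g} mW: k_act = {rates.k_act:.3f}/frame, "
              f"signal peaks at frame {peak_frame}", file=sys.stderr)

    pd.DataFrame(rows).to_csv(OUT / "mean_signals.csv", index=False)
    print(f"wrote {OUT/'mean_signals.csv'}", file=sys.stderr)


if __name__ == "__main__":
    main()
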