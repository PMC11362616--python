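#!/usr/bin/env python
"""Filament profiles, contrast comparison and the fading-dye scheme gain.

Three measurements on simulated images:

* FWHM of a filament line profile at the sampling and photon budget of a
  STED image (Gaussian fit over constant background) — lands near the
  ~75 nm width of antibody-decorated microtubules.

* Signal-to-background along the same profile with and without the diffuse
  background contributed by out-of-focus activation: the confined (2PA-like)
  image scores the higher SBR.

* Detected-signal ratio of pixel-based vs frame-based activation for a dye
  whose active form fades, as a function of fade rate.

Writes results/profile_measurement.json and results/scheme_comparison.csv.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pa2p import analysis, protocols

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
PIXEL_NM = 15.0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    # filament cross-section: sigma 32 nm (FWHM 75 nm), peak 200 counts
    ny, nx = 48, 64
    x_nm = np.arange(nx) * PIXEL_NM
    filament = 200.0 * np.exp(-((x_nm - 480.0) ** 2) / (2 * 32.0**2))
    clean = np.tile(filament, (ny, 1)) + 3.0
    img_2pa = rng.poisson(clean).astype(float)
    img_1pa = rng.poisson(clean + 25.0).astype(float)  # out-of-focus background

    profile = analysis.extract_line_profile(
        img_2pa, ((ny // 2, 0), (ny // 2, nx - 1)), width=9, pixel_size=PIXEL_NM
    )
    m = analysis.estimate_fwhm(profile)
    print(f"filament FWHM = {m.fwhm:.1f} nm (peak {m.peak:.0f}, "
          f"background {m.background:.1f})", file=sys.stderr)

    rep = analysis.contrast_report(
        img_2pa, img_1pa, ((ny // 2, 0), (ny // 2, nx - 1)),
        width=9, pixel_size=PIXEL_NM,
    )
    print(f"SBR confined/unconfined = {rep['sbr_a']:.1f}/{rep['sbr_b']:.1f} "
          f"(ratio {rep['ratio']:.2f})", file=sys.stderr)

    (OUT / "profile_measurement.json").write_text(json.dumps({
        "fwhm_nm": m.fwhm, "peak": m.peak, "background": m.background,
        "sbr_2pa": rep["sbr_a"], "sbr_1pa": rep["sbr_b"],
        "sbr_ratio": rep["ratio"],
    }, indent=2) + "\n")

    # pixel-based vs frame-based activation for a fading dye
    frame_time = 8.0
    rows = []
    for k in (0.0, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0):
        dye = protocols.FadingDye(fade_rate=k / frame_time, frame_time=frame_time)
        cmp = protocols.compare_activation_schemes(dye, (64, 64))
        rows.append({"fade_rate_per_frame": k, "ratio": cmp.ratio})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "scheme_comparison.csv", index=False)
    print("pixel/frame signal ratio vs fade rate:", file=sys.stderr)
    print(df.to_string(index=False), file=sys.stderr)


if __name__ == "__main__":
    main()
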