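"""End-to-end pipeline: simulate → fit → scaling → section → protect → measure.

Each stage writes its outputs (CSV/JSON/TIFF) under the configured output
directory and the run ends with a manifest recording the seed and a SHA-256
hash per output file, so identical config + seed implies identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, io, kinetics, optics, protocols, synthetic_data
from .config import RunConfig

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("pa2p")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages as configured; returns the manifest dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "hashes": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s ...", name)
            try:
                fn()
            except Exception as err:
                raise PipelineError(name, err) from err
            manifest["stages"][name] = round(time.perf_counter() - t0, 4)
            log.info("stage %s done in %.2fs", name, manifest["stages"][name])

        return deco

    results: dict = {}

    @stage("simulate")
    def _simulate():
        phantom = synthetic_data.generate_filament_phantom(
            config.phantom_width, config.phantom_height, config.n_filaments,
            labels_per_length=config.labels_per_length,
            pixel_size=config.pixel_size, seed=config.seed,
        )
        results["phantom"] = phantom
        series_by_power = {}
        for i, p in enumerate(config.powers_mw):
            scale = (p / config.activation_power) ** 2
            rates = kinetics.RateParams(config.k_act * scale, config.k_bl * scale)
            proto = synthetic_data.AcquisitionProtocol(
                activation_power=p,
                activation_dwell=config.activation_dwell,
                readout_dwell=config.readout_dwell,
                n_cycles=config.n_cycles,
                excitation_power=config.excitation_power,
                read_noise_background=config.read_noise_background,
                seed=config.seed * 1000 + i,
            )
            series_by_power[p] = synthetic_data.simulate_activation_series(
                phantom, rates, proto,
                photons_per_fluorophore=config.photons_per_fluorophore,
            )
        results["series_by_power"] = series_by_power
        ref = series_by_power[config.powers_mw[0]]
        io.save_stack(ref.frames, out / "series_lowest_power.tif", axes="TYX")

    @stage("fit")
    def _fit():
        rows = []
        for p, series in results["series_by_power"].items():
            fit = kinetics.fit_frame_series(series)
            rows.append(
                {
                    "power_mw": p,
                    "k_act": fit.rates.k_act,
                    "k_bl": fit.rates.k_bl,
                    "stderr_k_act": fit.stderr_k_act,
                    "stderr_k_bl": fit.stderr_k_bl,
                    "amplitude": fit.amplitude,
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "fitted_rates.csv", index=False)
        results["fitted_rates"] = df

    @stage("scaling")
    def _scaling():
        df = results["fitted_rates"]
        fit = kinetics.fit_power_law(
            df["power_mw"], df["k_act"], df["stderr_k_act"]
        )
        _write_json(
            out / "power_scaling.json",
            {
                "exponent_n": fit.exponent_n,
                "prefactor_c": fit.prefactor_c,
                "stderr_n": fit.stderr_n,
            },
        )
        results["power_scaling"] = fit

    @stage("section")
    def _section():
        beam = optics.BeamModel(
            rayleigh_range=config.rayleigh_range,
            chromatic_offset=config.chromatic_offset,
            process_order=2,
        )
        counts = {}
        for mode, order in (("2pa", 2), ("1pa", 1)):
            b = optics.BeamModel(
                rayleigh_range=config.rayleigh_range,
                chromatic_offset=config.chromatic_offset,
                process_order=order,
            )
            res = optics.two_layer_experiment(
                config.volume_thickness_um, tuple(config.layer_depths_um), b
            )
            counts[mode] = res.n_resolvable_layers
            pd.DataFrame(
                {"z_nm": res.profile.z, "dose": res.profile.activation_dose}
            ).to_csv(out / f"axial_dose_{mode}.csv", index=False)
        z = np.linspace(-4 * config.rayleigh_range, 4 * config.rayleigh_range, 801)
        fwhm = optics.sectioning_fwhm(optics.plane_integrated_dose(beam, z))
        _write_json(
            out / "sectioning.json",
            {"fwhm_nm": fwhm, "resolvable_layers": counts},
        )
        results["sectioning"] = {"fwhm_nm": fwhm, "resolvable_layers": counts}

    @stage("protect")
    def _protect():
        volume = synthetic_data.generate_volume_sample(
            24, 24, 5, structure="shells", seed=config.seed,
            z_step=config.layer_spacing_nm,
        )
        sted = optics.BeamModel(rayleigh_range=config.rayleigh_range, process_order=2)
        step = protocols.ImagingStep(
            bleach_fraction=config.bleach_fraction,
            crosstalk_profile=protocols.default_crosstalk_profile(
                sted, config.layer_spacing_nm
            ),
        )
        report = {}
        for mode in ("2pa", "1pa"):
            res = protocols.run_protection_experiment(
                volume, mode, config.n_sted_scans, step, seed=config.seed
            )
            report[mode] = {
                "above_recovered_fraction": res.above_recovered_fraction,
                "below_trajectory": res.below_trajectory.tolist(),
            }
            acq = protocols.run_volume_acquisition(
                volume, mode, step, seed=config.seed
            )
            pd.DataFrame(
                {
                    "depth_nm": np.arange(volume.n_layers) * config.layer_spacing_nm,
                    "intensity": acq.depth_intensity,
                }
            ).to_csv(out / f"depth_intensity_{mode}.csv", index=False)
        _write_json(out / "protection.json", report)
        results["protection"] = report

    @stage("measure")
    def _measure():
        series = results["series_by_power"][config.powers_mw[-1]]
        frame = series.frames[int(np.argmax(series.mean_signal)) + 1]
        res = analysis.mean_above_noise(
            frame.astype(float), series.frames[0].astype(float), config.k_sigma
        )
        _write_json(
            out / "measurement.json",
            {
                "mean_above_noise": res.mean if res.has_signal else None,
                "n_pixels": res.n_pixels,
                "has_signal": res.has_signal,
            },
        )

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["hashes"][path.name] = _hash_file(path)
    _write_json(out / "manifest.json", manifest)
    return manifest
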