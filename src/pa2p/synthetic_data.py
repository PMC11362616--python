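"""Ground-truth phantoms and simulated activation/readout acquisitions.

Every downstream stage of the pipeline consumes data produced here: 2D
filament phantoms emulating immunostained microtubules, 3D volumes (filament
tangles or nuclear-envelope-like shells) for the sectioning and protection
experiments, and the scanned acquisition sequence

    Frame 0 (readout, reference) -> [activation scan -> readout frame] x n

in which each activation scan advances the per-pixel three-state kinetics by
one frame unit and each readout frame draws Poisson photon counts.  Readout
scans never change state populations.  All randomness flows from a single
integer seed through named substreams, so identical parameters reproduce
bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .kinetics import RateParams, fluorescent_population

__all__ = [
    "Phantom",
    "AcquisitionProtocol",
    "FrameSeries",
    "VolumeSample",
    "generate_filament_phantom",
    "simulate_activation_series",
    "generate_volume_sample",
]


def _stable_stage_id(stage: str) -> int:
    # str hash() is salted per process; a CRC gives a reproducible stage id
    import zlib

    return zlib.crc32(stage.encode()) % (2**31)


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage.

    The child seed derives from (seed, stage id), so adding stages never
    perturbs the streams of existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, _stable_stage_id(stage)]))


@dataclass
class Phantom:
    """Ground-truth fluorophore density map.

    Attributes
    ----------
    density : ndarray
        2D (y, x) or 3D (z, y, x) non-negative fluorophore count per
        pixel/voxel.
    pixel_size : float
        Lateral sampling, nm per pixel.
    z_step : float or None
        Axial sampling, nm per plane (3D only).
    total_filament_length : float or None
        Arc length (nm) of all rendered filaments, tracked during generation
        for bookkeeping and validation.
    """

    density: np.ndarray
    pixel_size: float
    z_step: float | None = None
    total_filament_length: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.density, dtype=float)
        if d.ndim not in (2, 3):
            raise ValueError("density must be 2D or 3D")
        if any(s < 1 for s in d.shape):
            raise ValueError("density must have extent >= 1 in each axis")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("density must be finite and non-negative")
        self.density = d


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Parameters of one activation/readout sequence.

    Defaults follow the characterisation experiments: 515 nm activation at
    a few mW with 100 µs pixel dwell at 20 MHz repetition rate, 640 nm
    readout at 8 mW with 30 µs dwell, and 39 activation/readout cycles.
    """

    activation_power: float = 4.0  # mW
    activation_dwell: float = 100.0  # µs
    readout_dwell: float = 30.0  # µs
    n_cycles: int = 39
    excitation_power: float = 8.0  # mW
    read_noise_background: float = 0.5  # expected counts/pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation_power < 0 or self.excitation_power < 0:
            raise ValueError("powers must be >= 0")
        if self.activation_dwell <= 0 or self.readout_dwell <= 0:
            raise ValueError("dwell times must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.read_noise_background < 0:
            raise ValueError("background must be >= 0")


@dataclass
class FrameSeries:
    """Readout frames and per-frame mean signals from one sequence.

    ``frames[0]`` is the pre-activation reference (Frame 0); frame ``t`` is
    the readout after the t-th activation scan.  ``mean_signal[t-1]`` is the
    background-subtracted mean count over above-noise pixels of frame ``t``.
    """

    frames: np.ndarray  # (n_cycles+1, ny, nx) counts
    mean_signal: np.ndarray  # (n_cycles,) counts/pixel
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if np.any(f < 0):
            raise ValueError("counts must be non-negative")
        if len(f) != self.protocol.n_cycles + 1:
            raise ValueError("expected n_cycles + 1 frames")
        if len(self.mean_signal) != self.protocol.n_cycles:
            raise ValueError("expected one mean per readout frame")


@dataclass
class VolumeSample:
    """3D ground-truth density with per-voxel three-state fractions.

    ``state_fractions`` has shape (3, nz, ny, nx) holding (N_i, N_f, N_b);
    they sum to 1 per voxel and start with all mass in N_i.
    """

    density: np.ndarray
    state_fractions: np.ndarray
    z_step: float = 600.0  # nm
    pixel_size: float = 50.0  # nm

    def __post_init__(self) -> None:
        if self.density.ndim != 3:
            raise ValueError("density must be 3D (z, y, x)")
        if self.state_fractions.shape != (3, *self.density.shape):
            raise ValueError("state_fractions must be (3, nz, ny, nx)")
        s = self.state_fractions.sum(axis=0)
        if not np.allclose(s, 1.0, atol=1e-12):
            raise ValueError("per-voxel state fractions must sum to 1")

    @property
    def n_layers(self) -> int:
        return self.density.shape[0]


def _render_curve(
    density: np.ndarray,
    start: np.ndarray,
    direction: float,
    length: float,
    curvature_sigma: float,
    labels_per_step: float,
    step: float,
    pixel_size: float,
    rng: np.random.Generator,
) -> float:
    """Walk a smooth random curve, depositing label mass; returns arc length."""
    ny, nx = density.shape
    pos = start.copy()
    theta = direction
    n_steps = int(round(length / step))
    walked = 0.0
    for _ in range(n_steps):
        theta += rng.normal(0.0, curvature_sigma)
        pos[0] += step / pixel_size * np.sin(theta)
        pos[1] += step / pixel_size * np.cos(theta)
        # reflect at borders so the full arc length stays inside the image
        for ax, n in ((0, ny), (1, nx)):
            if pos[ax] < 0:
                pos[ax] = -pos[ax]
                theta = -theta if ax == 0 else np.pi - theta
            elif pos[ax] > n - 1:
                pos[ax] = 2 * (n - 1) - pos[ax]
                theta = -theta if ax == 0 else np.pi - theta
        iy = min(max(int(round(pos[0])), 0), ny - 1)
        ix = min(max(int(round(pos[1])), 0), nx - 1)
        density[iy, ix] += labels_per_step
        walked += step
    return walked


def generate_filament_phantom(
    width: int,
    height: int,
    n_filaments: int,
    labels_per_length: float = 1.0,
    pixel_size: float = 40.0,
    seed: int = 0,
    mean_length: float | None = None,
    curvature_sigma: float = 0.03,
) -> Phantom:
    """Render smooth random curves as line densities (microtubule-like).

    Parameters
    ----------
    width, height : int
        Image size in pixels.
    n_filaments : int
        Number of filaments; 0 yields an all-zero phantom.
    labels_per_length : float
        Fluorophores deposited per nm of filament arc length.
    pixel_size : float
        nm per pixel.
    seed : int
        Fixes the filament geometry; identical seeds give bit-identical
        phantoms.
    mean_length : float, optional
        Mean filament length in nm (default: twice the image width).
    curvature_sigma : float
        Std of the per-step heading change (radians); smaller is straighter.

    Returns
    -------
    Phantom
        With ``total_filament_length`` set to the summed rendered arc length,
        so ``density.sum() == labels_per_length * total_filament_length``.
    """
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be > 0")
    if n_filaments < 0:
        raise ValueError("n_filaments must be >= 0")
    rng = _rng(seed, "phantom")
    density = np.zeros((height, width), dtype=float)
    if mean_length is None:
        mean_length = 2.0 * width * pixel_size
    step = pixel_size / 4.0  # sub-pixel stepping along the curve
    total = 0.0
    for _ in range(n_filaments):
        start = np.array(
            [rng.uniform(0, height - 1), rng.uniform(0, width - 1)], dtype=float
        )
        direction = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.5, 1.5) * mean_length
        total += _render_curve(
            density, start, direction, length, curvature_sigma,
            labels_per_length * step, step, pixel_size, rng,
        )
    return Phantom(
        density=density,
        pixel_size=pixel_size,
        total_filament_length=total,
    )


def simulate_activation_series(
    phantom: Phantom,
    rates: RateParams,
    protocol: AcquisitionProtocol,
    photons_per_fluorophore: float = 1.0,
    noiseless: bool = False,
) -> FrameSeries:
    """Run the Frame 0 / activation / readout sequence on a phantom.

    Each activation scan advances every pixel's state populations by one
    frame unit of the three-state kinetics (readout scans leave states
    untouched).  Readout frame ``t`` has per-pixel expectation

        mu_t = photons_per_fluorophore * density * N_f(t) + background

    and draws Poisson counts from it; Frame 0 contains background only.  In
    ``noiseless`` mode frames hold the expectations themselves and the mean
    signal is taken over the ground-truth support, so it equals
    ``A * N_f(t)`` exactly with ``A = photons_per_fluorophore * mean density
    over support``.
    """
    if phantom.density.ndim != 2:
        raise ValueError("simulate_activation_series expects a 2D phantom")
    rng = _rng(protocol.seed, "acquisition")
    bg = protocol.read_noise_background
    dens = phantom.density
    support = dens > 0

    frames = []
    means = []
    mu0 = np.full(dens.shape, bg)
    frames.append(mu0 if noiseless else rng.poisson(mu0).astype(np.uint16))
    for t in range(1, protocol.n_cycles + 1):
        nf = fluorescent_population(float(t), rates)
        mu = photons_per_fluorophore * dens * nf + bg
        if noiseless:
            frames.append(mu)
            means.append(
                float(mu[support].mean() - bg) if support.any() else 0.0
            )
        else:
            img = rng.poisson(mu).astype(np.uint16)
            frames.append(img)
            means.append(_mean_above_noise_raw(img, frames[0], bg))
    return FrameSeries(
        frames=np.stack(frames), mean_signal=np.asarray(means), protocol=protocol
    )


def _mean_above_noise_raw(frame: np.ndarray, reference: np.ndarray, bg: float) -> float:
    """Background-subtracted mean of pixels above the reference noise level."""
    ref = reference.astype(float)
    thresh = ref.mean() + 3.0 * ref.std()
    mask = frame > thresh
    if not mask.any():
        return 0.0
    return float(frame[mask].mean() - bg)


def generate_volume_sample(
    nx: int,
    ny: int,
    nz: int,
    structure: Literal["filaments", "shells"] = "shells",
    seed: int = 0,
    radius: float | None = None,
    n_objects: int = 3,
    z_step: float = 600.0,
    pixel_size: float = 50.0,
) -> VolumeSample:
    """Generate a 3D phantom spanning multiple z planes.

    ``shells`` places 1-voxel-thick spherical shells (nuclear-envelope-like);
    ``filaments`` scatters smooth 3D random curves.  All state mass starts in
    the caged state N_i.
    """
    if nz < 2:
        raise ValueError("nz must be >= 2")
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")
    rng = _rng(seed, f"volume-{structure}")
    density = np.zeros((nz, ny, nx), dtype=float)
    if structure == "shells":
        r = radius if radius is not None else min(nx, ny, nz) / 3.0
        zz, yy, xx = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        for _ in range(n_objects):
            cz = rng.uniform(r, nz - 1 - r) if nz - 1 > 2 * r else (nz - 1) / 2
            cy = rng.uniform(r, ny - 1 - r) if ny - 1 > 2 * r else (ny - 1) / 2
            cx = rng.uniform(r, nx - 1 - r) if nx - 1 > 2 * r else (nx - 1) / 2
            dist = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
            density[np.abs(dist - r) <= 0.5] += 1.0
    elif structure == "filaments":
        step = 0.25
        for _ in range(n_objects * 4):
            pos = rng.uniform([0, 0, 0], [nz - 1, ny - 1, nx - 1])
            vel = rng.normal(size=3)
            vel /= np.linalg.norm(vel)
            for _ in range(int(4 * max(nx, ny, nz) / step)):
                vel += rng.normal(0, 0.05, size=3)
                vel /= np.linalg.norm(vel)
                pos = pos + step * vel
                if np.any(pos < 0) or np.any(pos > [nz - 1, ny - 1, nx - 1]):
                    break
                iz, iy, ix = (int(round(p)) for p in pos)
                density[iz, iy, ix] += step
    else:
        raise ValueError(f"unknown structure {structure!r}")
    fractions = np.zeros((3, nz, ny, nx))
    fractions[0] = 1.0  # all caged initially
    return VolumeSample(
        density=density, state_fractions=fractions, z_step=z_step, pixel_size=pixel_size
    )
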