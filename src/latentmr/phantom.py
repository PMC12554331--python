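"""Synthetic phantoms, coil maps and noisy undersampled acquisitions.

Everything the reconstruction experiments consume is generated here with
known ground truth: voxelized tissue-parameter maps built from geometric
primitives, smooth complex coil-sensitivity profiles, and seeded noisy
k-t data.  The default fixture is a 64x64 grid with 8 coils and a 32-echo
FSE train, which keeps desk-scale experiments to seconds-to-minutes while
preserving the structure of the full-size acquisitions.

Tissue presets use conventional 3 T relaxation values.  For FSE experiments
the presets pin T1 to the dictionary's fixed T1 so that the signal model and
the dictionary describe the same physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import (
    AcquisitionData,
    b0_phase_operator,
    fft2c,
    forward_timeseries,
)
from .sequences import EPTIParams, MPRAGEParams, epg_cpmg, simulate_epti, simulate_mprage

__all__ = [
    "Region",
    "PhantomSpec",
    "GroundTruth",
    "TISSUES",
    "make_phantom",
    "make_coil_maps",
    "simulate_acquisition",
    "partial_volume_suite",
    "default_fse_phantom_spec",
]

#: conventional 3 T tissue parameters (ms); proton densities relative
TISSUES = {
    "csf": dict(T1=3000.0, T2=400.0, T2star=200.0, pd=1.0),
    "gm": dict(T1=1300.0, T2=110.0, T2star=66.0, pd=0.8),
    "wm": dict(T1=800.0, T2=80.0, T2star=53.0, pd=0.7),
}


@dataclass(frozen=True)
class Region:
    """One tissue region: an ellipse or axis-aligned rectangle.

    Geometry is in fractional image coordinates ([0, 1] per axis):
    ``center`` and ``size`` (semi-axes for ellipses, half-widths for
    rectangles).
    """

    shape: str               # "ellipse" | "rect"
    center: tuple
    size: tuple
    T1: float = 1000.0
    T2: float = 100.0
    T2star: float = 50.0
    pd: complex = 1.0        # complex proton density / M0
    B0: float = 0.0          # off-resonance, Hz

    def support(self, nx: int, ny: int) -> np.ndarray:
        x = (np.arange(nx) + 0.5) / nx
        y = (np.arange(ny) + 0.5) / ny
        X, Y = np.meshgrid(x, y, indexing="ij")
        cx, cy = self.center
        sx, sy = self.size
        if self.shape == "ellipse":
            return ((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2 <= 1.0
        if self.shape == "rect":
            return (np.abs(X - cx) <= sx) & (np.abs(Y - cy) <= sy)
        raise ValueError(f"unknown region shape {self.shape!r}")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple = (64, 64)
    regions: tuple = ()
    sequence: str = "fse"      # which simulator produces the time courses
    echo_count: int = 32
    echo_spacing: float = 5.56
    refocus_angle: float = 160.0   # FSE only
    flip_angle: float = 8.0        # MPRAGE only
    TI: float = 1100.0
    TR: float = 2500.0
    first_TE: float = 1.0          # EPTI only
    mixed_border: int = 0          # partial-volume border width in voxels


@dataclass
class GroundTruth:
    """Parameter maps, clean image series and tissue fractions."""

    T1_map: np.ndarray
    T2_map: np.ndarray            # T2 for FSE, T2* for EPTI, unused for MPRAGE
    M0_map: np.ndarray            # complex proton density
    B0_map: np.ndarray
    series: np.ndarray            # clean [nx, ny, T] complex image series
    echo_times: np.ndarray
    label_map: np.ndarray         # region index per voxel (-1 background)
    fractions: np.ndarray         # [nx, ny, n_regions], sums to 1 on support
    spec: PhantomSpec = None

    @property
    def support(self) -> np.ndarray:
        return self.label_map >= 0


def _region_signal(spec: PhantomSpec, region: Region) -> np.ndarray:
    """Unit-amplitude (normalized shape x nothing) time course for a region."""
    if spec.sequence == "fse":
        return epg_cpmg(spec.echo_count, spec.echo_spacing, spec.refocus_angle,
                        region.T1, region.T2)[:, 0]
    if spec.sequence == "mprage":
        return simulate_mprage(MPRAGEParams(
            echo_count=spec.echo_count, echo_spacing=spec.echo_spacing,
            flip_angle=spec.flip_angle, TI=spec.TI, TR=spec.TR,
            T1=region.T1)).values
    if spec.sequence == "epti":
        return simulate_epti(EPTIParams(
            echo_count=spec.echo_count, echo_spacing=spec.echo_spacing,
            first_TE=spec.first_TE, T2star=region.T2star)).values
    raise ValueError(f"unknown sequence {spec.sequence!r}")


def _echo_times(spec: PhantomSpec) -> np.ndarray:
    if spec.sequence == "epti":
        return spec.first_TE + spec.echo_spacing * np.arange(spec.echo_count)
    return spec.echo_spacing * np.arange(1, spec.echo_count + 1)


def make_phantom(spec: PhantomSpec, seed: int = 0) -> GroundTruth:
    """Voxelize the regions and simulate the clean image time-series.

    Overlapping regions are resolved by draw order (later regions win).
    With ``mixed_border > 0`` voxels within that many voxels of a region
    boundary mix the two adjacent signals by area fraction, giving exact
    linear partial-volume mixtures.  The result is deterministic for a given
    spec and seed.
    """
    nx, ny = spec.grid_shape
    n_reg = len(spec.regions)
    label = np.full((nx, ny), -1)
    for i, reg in enumerate(spec.regions):
        label[reg.support(nx, ny)] = i

    fractions = np.zeros((nx, ny, max(n_reg, 1)))
    for i in range(n_reg):
        fractions[:, :, i] = label == i

    if spec.mixed_border > 0 and n_reg >= 2:
        # supersample each border voxel 4x4 to get area fractions
        fine = 4
        for i, reg in enumerate(spec.regions):
            sup_f = reg.support(nx * fine, ny * fine).astype(float)
            area = sup_f.reshape(nx, fine, ny, fine).mean(axis=(1, 3))
            border = (area > 0) & (area < 1)
            for (xi, yi) in np.argwhere(border):
                if label[xi, yi] < 0 and area[xi, yi] < 0.5:
                    continue
                f = np.zeros(n_reg)
                f[i] = area[xi, yi]
                under = label[xi, yi] if label[xi, yi] != i else -1
                if under >= 0:
                    f[under] = 1 - area[xi, yi]
                fractions[xi, yi, :] = f
                label[xi, yi] = i if area[xi, yi] >= 0.5 else under

    sig = np.stack([_region_signal(spec, r) for r in spec.regions], axis=0) \
        if n_reg else np.zeros((1, spec.echo_count))
    pd = np.array([complex(r.pd) for r in spec.regions]) if n_reg else np.zeros(1)

    series = np.tensordot(fractions * pd[None, None, :n_reg] if n_reg else fractions,
                          sig, axes=([2], [0]))

    def param_map(attr):
        m = np.zeros((nx, ny))
        for i, r in enumerate(spec.regions):
            m[label == i] = getattr(r, attr)
        return m

    B0 = param_map("B0")
    if spec.sequence == "epti" and np.any(B0 != 0):
        series = series * b0_phase_operator(B0, _echo_times(spec))

    M0 = np.zeros((nx, ny), dtype=complex)
    for i, r in enumerate(spec.regions):
        M0[label == i] = complex(r.pd)

    return GroundTruth(
        T1_map=param_map("T1"), T2_map=param_map(
            "T2star" if spec.sequence == "epti" else "T2"),
        M0_map=M0, B0_map=B0, series=series,
        echo_times=_echo_times(spec), label_map=label,
        fractions=fractions, spec=spec,
    )


def make_coil_maps(n_coils: int, shape: tuple, seed: int = 0,
                   support: np.ndarray | None = None) -> np.ndarray:
    """Smooth complex coil-sensitivity profiles, sum-of-squares normalized.

    Gaussian magnitude lobes centered at equiangular positions around the
    FOV with small seeded jitter and a linear phase per coil; the
    sum-of-squares equals 1 everywhere (hence in particular on the object).
    """
    nx, ny = shape
    if n_coils == 1:
        return np.ones((nx, ny, 1), dtype=complex)
    rng = np.random.default_rng(seed)
    x = np.linspace(-0.5, 0.5, nx)[:, None]
    y = np.linspace(-0.5, 0.5, ny)[None, :]
    maps = np.zeros((nx, ny, n_coils), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.normal(0, 0.05)
        cx, cy = 0.55 * np.cos(ang), 0.55 * np.sin(ang)
        width = 0.45 + rng.normal(0, 0.03)
        mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2))
        px, py = rng.normal(0, 1.5, size=2)
        phase = np.exp(1j * 2 * np.pi * (px * x + py * y) + 1j * rng.uniform(0, 2 * np.pi))
        maps[:, :, c] = mag * phase
    sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=2, keepdims=True))
    return maps / np.maximum(sos, 1e-12)


def simulate_acquisition(
    truth: GroundTruth,
    coil_maps: np.ndarray,
    mask: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> AcquisitionData:
    """Forward-simulate masked multi-coil k-t data with seeded complex noise.

    ``noise_sigma`` is relative to the DC magnitude of the noiseless data
    (the largest central k-space amplitude over coils at the first echo).
    """
    phase = None
    if truth.spec is not None and truth.spec.sequence == "epti" and np.any(truth.B0_map):
        phase = None  # B0 phase is already baked into truth.series
    y = forward_timeseries(truth.series, coil_maps, mask, phase)
    nx, ny = truth.series.shape[:2]
    dc = np.abs(fft2c(coil_maps * truth.series[:, :, None, 0])[nx // 2, ny // 2]).max()
    sigma_abs = noise_sigma * dc
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, sigma_abs / np.sqrt(2), size=y.shape + (2,))
        y = y + (noise[..., 0] + 1j * noise[..., 1]) * mask[None, :, None, :]
    return AcquisitionData(
        y=y, mask=mask, coil_maps=coil_maps,
        echo_times=truth.echo_times, noise_sigma=sigma_abs,
        meta={"seed": seed, "relative_sigma": noise_sigma},
    )


def default_fse_phantom_spec(grid=(64, 64), echo_count=32, mixed_border=0) -> PhantomSpec:
    """Three-tissue FSE fixture: T2 spread across the dictionary range.

    T1 is pinned to the FSE dictionary's fixed 1000 ms so dictionary and
    phantom share one signal model.
    """
    regions = (
        Region("ellipse", (0.5, 0.5), (0.42, 0.42), T1=1000, T2=80, pd=0.8),
        Region("ellipse", (0.38, 0.42), (0.16, 0.13), T1=1000, T2=150,
               pd=1.0 * np.exp(0.3j)),
        Region("ellipse", (0.65, 0.6), (0.12, 0.16), T1=1000, T2=300,
               pd=0.9 * np.exp(-0.5j)),
        Region("rect", (0.55, 0.32), (0.06, 0.08), T1=1000, T2=50, pd=0.6),
    )
    return PhantomSpec(grid_shape=grid, regions=regions, sequence="fse",
                       echo_count=echo_count, mixed_border=mixed_border)


def partial_volume_suite(signals, fractions, phase_offsets=(0.0, np.pi),
                         subspaces=None, autoencoder=None, beta_grid=None):
    """Representation error of two-tissue mixtures under each signal model.

    ``signals`` is a pair of length-T single-tissue signal evolutions.  For
    every mixing fraction ``f`` and phase offset ``phi`` the mixture is
    ``f * s1 + (1 - f) * exp(i phi) * s2``.  Each representer is scored by
    NRMSE (%): subspaces by least-squares fit, the auto-encoder by the best
    scale-matched decode over a 1-D latent search seeded from the encoded
    dictionary grid (``beta_grid``) and refined locally.

    Returns a dict mapping representer name -> array [n_phase, n_fraction].
    """
    s1, s2 = (np.asarray(s, dtype=complex) for s in signals)
    fractions = np.asarray(fractions, dtype=float)
    out = {}
    mixtures = np.array([
        [f * s1 + (1 - f) * np.exp(1j * p) * s2 for f in fractions]
        for p in phase_offsets
    ])  # [n_phase, n_frac, T]

    def nrmse(est, ref):
        return np.linalg.norm(est - ref) / np.linalg.norm(ref) * 100.0

    for name, sub in (subspaces or {}).items():
        errs = np.zeros(mixtures.shape[:2])
        for i in range(mixtures.shape[0]):
            for j in range(mixtures.shape[1]):
                mix = mixtures[i, j]
                coef, *_ = np.linalg.lstsq(sub.basis, mix, rcond=None)
                errs[i, j] = nrmse(sub.basis @ coef, mix)
        out[name] = errs

    if autoencoder is not None:
        if beta_grid is None:
            raise ValueError("beta_grid (encoded dictionary codes) required")
        beta_grid = np.asarray(beta_grid, dtype=float).reshape(-1)
        errs = np.zeros(mixtures.shape[:2])
        for i in range(mixtures.shape[0]):
            for j in range(mixtures.shape[1]):
                mix = mixtures[i, j]

                def err_at(bval):
                    q = autoencoder.decode(np.array([bval]))
                    c = np.vdot(q, mix) / max(np.vdot(q, q).real, 1e-30)
                    return nrmse(c * q, mix)

                coarse = [err_at(b) for b in beta_grid]
                k = int(np.argmin(coarse))
                lo = beta_grid[max(k - 1, 0)]
                hi = beta_grid[min(k + 1, beta_grid.size - 1)]
                # golden-section refinement on [lo, hi]
                gr = (np.sqrt(5) - 1) / 2
                a, b = lo, hi
                for _ in range(40):
                    c1, c2 = b - gr * (b - a), a + gr * (b - a)
                    if err_at(c1) < err_at(c2):
                        b = c2
                    else:
                        a = c1
                errs[i, j] = err_at((a + b) / 2)
        out["autoencoder"] = errs
    return out
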