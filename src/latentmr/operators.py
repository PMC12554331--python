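"""Acquisition forward operators for shuffling / EPTI reconstructions.

The measurement chain for one echo image is

    image -> (x) temporal phase H -> (x) coil sensitivities S -> centered
    unitary 2-D FFT -> sampling mask

applied echo-wise.  Composed with a temporal model it yields the two forward
operators used in reconstruction: the linear-subspace operator (coefficients
``alpha``, temporal basis ``Phi``) and the latent operator (real latent maps
``beta`` with a decoder plus a complex per-voxel scale ``M0``).

Array conventions: images are ``[nx, ny, ...]`` with ``ny`` the phase-encode
axis; k-t data is ``[nx, ny, coil, echo]``; masks are boolean ``[ny, echo]``
(the readout direction is always fully sampled); coil maps are
``[nx, ny, coil]``; the phase operator is unit-magnitude ``[nx, ny, echo]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionData",
    "fft2c",
    "ifft2c",
    "forward_linear",
    "adjoint_linear",
    "forward_latent",
    "latent_gradients",
    "forward_timeseries",
    "adjoint_timeseries",
    "make_shuffling_mask",
    "make_epti_mask",
    "acceleration_factor",
    "estimate_b0_lowres",
    "b0_phase_operator",
]


@dataclass
class AcquisitionData:
    """Multi-coil k-t samples with the operators that generated them."""

    y: np.ndarray                      # [nx, ny, coil, echo] complex
    mask: np.ndarray                   # [ny, echo] bool
    coil_maps: np.ndarray              # [nx, ny, coil] complex
    phase: np.ndarray | None = None    # [nx, ny, echo], |H| = 1
    echo_times: np.ndarray | None = None
    noise_sigma: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=complex)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.coil_maps = np.asarray(self.coil_maps, dtype=complex)
        nx, ny, nc, T = self.y.shape
        if self.mask.shape != (ny, T):
            raise ValueError(f"mask shape {self.mask.shape} != {(ny, T)}")
        if self.coil_maps.shape != (nx, ny, nc):
            raise ValueError("coil map shape mismatch")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=complex)
            if self.phase.shape != (nx, ny, T):
                raise ValueError("phase operator shape mismatch")
            if not np.allclose(np.abs(self.phase), 1.0, atol=1e-6):
                raise ValueError("phase operator must be unit magnitude")
        # y is stored dense; unsampled entries must be zero
        if np.any(self.y.transpose(0, 2, 1, 3)[:, :, ~self.mask] != 0):
            raise ValueError("y must be zero where the mask is false")

    @property
    def shape(self):
        return self.y.shape

    @property
    def n_echoes(self):
        return self.y.shape[-1]


def fft2c(img: np.ndarray) -> np.ndarray:
    """Centered, unitary 2-D FFT over the two leading axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=(0, 1)), axes=(0, 1), norm="ortho"),
        axes=(0, 1),
    )


def ifft2c(ksp: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=(0, 1)), axes=(0, 1), norm="ortho"),
        axes=(0, 1),
    )


def forward_timeseries(x, coil_maps, mask, phase=None) -> np.ndarray:
    """Apply H, S, F and the mask to an image time-series [nx, ny, T]."""
    x = np.asarray(x)
    if phase is not None:
        x = x * phase
    imgs = coil_maps[:, :, :, None] * x[:, :, None, :]  # [nx, ny, c, T]
    y = fft2c(imgs)
    return y * mask[None, :, None, :]


def adjoint_timeseries(y, coil_maps, mask, phase=None) -> np.ndarray:
    """Adjoint of :func:`forward_timeseries`: k-t data -> image series."""
    imgs = ifft2c(y * mask[None, :, None, :])
    x = np.sum(np.conj(coil_maps)[:, :, :, None] * imgs, axis=2)
    if phase is not None:
        x = x * np.conj(phase)
    return x


def forward_linear(alpha, basis, coil_maps, mask, phase=None) -> np.ndarray:
    """Subspace forward operator: coefficients [nx, ny, B] -> masked k-t data."""
    alpha = np.asarray(alpha)
    if alpha.shape[-1] != basis.shape[1]:
        raise ValueError(
            f"coefficient count {alpha.shape[-1]} != basis rank {basis.shape[1]}")
    x = alpha @ basis.T.astype(alpha.dtype)  # [nx, ny, T]
    return forward_timeseries(x, coil_maps, mask, phase)


def adjoint_linear(y, basis, coil_maps, mask, phase=None) -> np.ndarray:
    x = adjoint_timeseries(y, coil_maps, mask, phase)
    return x @ np.conj(basis)


def forward_latent(beta, m0, decoder, coil_maps, mask, phase=None) -> np.ndarray:
    """Latent forward operator: beta [nx, ny, L], M0 [nx, ny] -> masked k-t."""
    beta = np.asarray(beta, dtype=float)
    nx, ny, L = beta.shape
    if L != decoder.spec.latent_dim:
        raise ValueError("latent dimension mismatch")
    q = decoder.decode(beta.reshape(-1, L)).reshape(nx, ny, -1)
    x = m0[:, :, None] * q
    return forward_timeseries(x, coil_maps, mask, phase)


def latent_gradients(beta, m0, decoder, coil_maps, mask, y, phase=None):
    """Residual, objective and gradients of the latent data-consistency term.

    Returns ``(obj, grad_beta, grad_m0)`` for
    ``V = || A(M0 . decode(beta)) - y ||_2^2`` where the gradient with respect
    to the complex ``M0`` is the Wirtinger gradient expressed as
    d/d(Re M0) + i d/d(Im M0).
    """
    beta = np.asarray(beta, dtype=float)
    nx, ny, L = beta.shape
    q = decoder.decode(beta.reshape(-1, L)).reshape(nx, ny, -1)
    x = m0[:, :, None] * q
    r = forward_timeseries(x, coil_maps, mask, phase) - y
    obj = float(np.vdot(r, r).real)
    z = adjoint_timeseries(r, coil_maps, mask, phase)  # [nx, ny, T]
    grad_m0 = 2.0 * np.sum(q * z, axis=-1)
    upstream = 2.0 * (m0[:, :, None] * np.conj(z)).real
    grad_beta = decoder.decode_vjp(
        beta.reshape(-1, L), upstream.reshape(-1, q.shape[-1])
    ).reshape(nx, ny, L)
    return obj, grad_beta, grad_m0


# ---------------------------------------------------------------------------
# undersampling masks
# ---------------------------------------------------------------------------

def make_shuffling_mask(shots: int, T: int, n_ky: int, seed: int = 0) -> np.ndarray:
    """Shuffling mask: ``shots`` distinct random ky lines at each echo.

    Lines are drawn without replacement per echo from a seeded generator, so
    the total number of sampled (ky, echo) pairs is ``shots * T`` and the
    acceleration factor with respect to the full k-t grid is
    ``n_ky * T / (shots * T)``.
    """
    if shots < 1:
        raise ValueError("shots must be >= 1")
    if shots > n_ky:
        raise ValueError(f"shots={shots} exceeds n_ky={n_ky}")
    rng = np.random.default_rng(seed)
    mask = np.zeros((n_ky, T), dtype=bool)
    for t in range(T):
        mask[rng.choice(n_ky, size=shots, replace=False), t] = True
    return mask


def make_epti_mask(shots: int, T: int, n_ky: int, seed: int = 0) -> np.ndarray:
    """EPTI mask: interleaved ky ladders, one line per shot per echo.

    Shot ``s`` starts at ky offset ``s * n_ky // shots`` and advances by a
    fixed stride each echo, so each shot traces a ladder through k-space and
    every (shot, echo) pair samples a distinct ky line.  ``seed`` is accepted
    for interface symmetry; the ladder is deterministic.
    """
    if shots < 1:
        raise ValueError("shots must be >= 1")
    if shots * T > n_ky * T:
        raise ValueError("more shot-lines than k-space positions")
    stride = max(1, int(round(n_ky / T)))
    while np.gcd(stride, n_ky) != 1 and stride < n_ky:
        stride += 1
    mask = np.zeros((n_ky, T), dtype=bool)
    for s in range(shots):
        offset = (s * n_ky) // shots
        ky = (offset + stride * np.arange(T)) % n_ky
        if np.unique(ky).size != T:
            raise ValueError("incompatible ladder geometry: repeated ky lines")
        mask[ky, np.arange(T)] = True
    counts = mask.sum(axis=0)
    if np.any(counts > shots):
        raise ValueError("incompatible ladder geometry: shot collisions")
    return mask


def acceleration_factor(mask: np.ndarray) -> float:
    """Full k-t grid size over number of sampled (ky, echo) pairs."""
    return mask.size / int(mask.sum())


# ---------------------------------------------------------------------------
# B0 handling (EPTI)
# ---------------------------------------------------------------------------

def b0_phase_operator(b0_map: np.ndarray, echo_times: np.ndarray) -> np.ndarray:
    """Unit-magnitude phase evolution exp(2i pi B0 TE) (B0 Hz, TE ms)."""
    return np.exp(2j * np.pi * b0_map[:, :, None] * echo_times[None, None, :] * 1e-3)


def estimate_b0_lowres(
    acq: AcquisitionData, n_center_lines: int = 49, n_echoes: int = 6
) -> np.ndarray:
    """Low-resolution B0 map (Hz) from the central ky lines of early echoes.

    Keeps only the central ``n_center_lines`` ky lines of the first
    ``n_echoes`` echoes (zero-filled elsewhere), reconstructs coil-combined
    low-resolution echo images, and fits the per-voxel phase slope across the
    echo times by magnitude-weighted least squares on the inter-echo phase
    increments.  The inter-echo phase must stay below pi for an unambiguous
    fit (Nyquist condition on B0 * echo spacing).
    """
    if n_echoes < 2:
        raise ValueError("need at least 2 echoes for a phase slope")
    if acq.echo_times is None:
        raise ValueError("acquisition carries no echo times")
    nx, ny, nc, T = acq.y.shape
    if n_echoes > T:
        raise ValueError("n_echoes exceeds echo count")
    if n_center_lines > ny:
        raise ValueError("n_center_lines exceeds phase-encode size")
    c0 = ny // 2 - n_center_lines // 2
    ksp = np.zeros((nx, ny, nc, n_echoes), dtype=complex)
    ksp[:, c0:c0 + n_center_lines] = acq.y[:, c0:c0 + n_center_lines, :, :n_echoes]
    imgs = ifft2c(ksp)
    combined = np.sum(np.conj(acq.coil_maps)[:, :, :, None] * imgs, axis=2)
    te = np.asarray(acq.echo_times[:n_echoes], dtype=float)
    # magnitude-weighted phase increments between consecutive echoes
    prod = combined[:, :, :-1].conj() * combined[:, :, 1:]
    dt = np.diff(te) * 1e-3  # s
    w = np.abs(prod)
    slopes = np.angle(prod) / dt[None, None, :]
    b0 = np.sum(w * slopes, axis=-1) / np.maximum(np.sum(w, axis=-1), 1e-30)
    return b0 / (2 * np.pi)
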