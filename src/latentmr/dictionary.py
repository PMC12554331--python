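"""Signal dictionaries, SVD subspaces, compression scoring and matching.

A :class:`SignalDictionary` collects simulated signal evolutions (one column
per tissue-parameter point) for one sequence family.  The first ``B`` left
singular vectors of the atom matrix form a :class:`LinearSubspace`; either a
subspace or a trained auto-encoder can be scored by per-atom normalized RMS
error on a held-out dictionary, and latent codes can be matched back to
tissue parameters by nearest-neighbor search in latent space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .sequences import (
    EPTIParams,
    FSEParams,
    MPRAGEParams,
    epg_cpmg,
    simulate_epti,
    simulate_mprage,
)

__all__ = [
    "SignalDictionary",
    "LinearSubspace",
    "build_dictionary",
    "build_subspace",
    "compression_nrmse",
    "match_latent",
    "fse_dictionary",
    "mprage_dictionary",
    "epti_dictionary",
    "training_grid",
    "testing_grid",
]

#: default uniform grids over the stated tissue-parameter ranges (ms)
GRID_RANGES = {"fse": (50.0, 400.0, 1.0), "mprage": (500.0, 3000.0, 10.0),
               "epti": (10.0, 300.0, 1.0)}


def training_grid(sequence_tag: str) -> np.ndarray:
    lo, hi, step = GRID_RANGES[sequence_tag]
    return np.arange(lo, hi + step / 2, step)


def testing_grid(sequence_tag: str) -> np.ndarray:
    """Training grid offset by half a step (no shared points)."""
    lo, hi, step = GRID_RANGES[sequence_tag]
    return np.arange(lo + step / 2, hi, step)


@dataclass
class SignalDictionary:
    """T x N matrix of signal evolutions with its parameter grid."""

    atoms: np.ndarray
    grid: np.ndarray
    normalized: bool
    sequence_tag: str

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.atoms.shape[1] != self.grid.shape[0]:
            raise ValueError("column count must equal grid length")

    @property
    def T(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]


@dataclass
class LinearSubspace:
    """Orthonormal temporal basis Phi (T x B) from a dictionary SVD."""

    basis: np.ndarray
    singular_values: np.ndarray = field(default=None)

    def __post_init__(self):
        self.basis = np.asarray(self.basis)
        gram = self.basis.conj().T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=1e-10):
            raise ValueError("subspace columns are not orthonormal")

    @property
    def B(self) -> int:
        return self.basis.shape[1]

    def project(self, signals: np.ndarray) -> np.ndarray:
        """Orthogonal projection of length-T signals (columns) onto span(Phi)."""
        return self.basis @ (self.basis.conj().T @ signals)


def build_dictionary(
    grid: Sequence[float],
    simulator: Callable[[float], np.ndarray] | str,
    normalized: bool = True,
    sequence_tag: str | None = None,
    **seq_kwargs,
) -> SignalDictionary:
    """Simulate one signal evolution per grid point and stack as columns.

    ``simulator`` is either a callable mapping one grid value to a length-T
    signal, or one of the tags ``{"fse", "mprage", "epti"}`` (the grid then
    spans T2, T1 or T2* respectively and ``seq_kwargs`` override the sequence
    defaults).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty parameter grid")
    tag = simulator if isinstance(simulator, str) else sequence_tag
    if simulator == "fse":
        ref = FSEParams(**{"T2": float(grid[0]), **seq_kwargs})
        for v in grid:  # validates every point
            FSEParams(**{**seq_kwargs, "T2": float(v)})
        atoms = epg_cpmg(ref.echo_count, ref.echo_spacing, ref.refocus_angle,
                         ref.T1, grid)
    elif simulator == "mprage":
        cols = []
        for v in grid:
            cols.append(simulate_mprage(
                MPRAGEParams(**{**seq_kwargs, "T1": float(v)})).values)
        atoms = np.stack(cols, axis=1)
    elif simulator == "epti":
        cols = []
        for v in grid:
            cols.append(simulate_epti(
                EPTIParams(**{**seq_kwargs, "T2star": float(v)})).values)
        atoms = np.stack(cols, axis=1)
    else:
        cols = []
        for v in grid:
            try:
                cols.append(np.asarray(simulator(float(v))))
            except Exception as exc:
                raise ValueError(f"grid point {v} outside valid domain: {exc}")
        atoms = np.stack(cols, axis=1)
    if normalized:
        atoms = atoms / np.linalg.norm(atoms, axis=0, keepdims=True)
    return SignalDictionary(atoms, grid, normalized, tag or "custom")


def fse_dictionary(grid=None, **kw) -> SignalDictionary:
    grid = training_grid("fse") if grid is None else grid
    return build_dictionary(grid, "fse", **kw)


def mprage_dictionary(grid=None, **kw) -> SignalDictionary:
    grid = training_grid("mprage") if grid is None else grid
    return build_dictionary(grid, "mprage", **kw)


def epti_dictionary(grid=None, **kw) -> SignalDictionary:
    grid = training_grid("epti") if grid is None else grid
    return build_dictionary(grid, "epti", **kw)


def build_subspace(D: SignalDictionary, B: int) -> LinearSubspace:
    """First ``B`` left singular vectors of the atom matrix."""
    T, N = D.atoms.shape
    if not 1 <= B <= min(T, N):
        raise ValueError(f"B={B} out of range [1, {min(T, N)}]")
    U, s, _ = np.linalg.svd(D.atoms, full_matrices=False)
    return LinearSubspace(U[:, :B], s[:B])


def compression_nrmse(D_test: SignalDictionary, representer) -> tuple[np.ndarray, float]:
    """Per-atom and average round-trip NRMSE (%) of a signal representer.

    For a :class:`LinearSubspace` the reconstruction is the orthogonal
    projection; for a trained auto-encoder it is decode(encode(atom)) with a
    per-atom least-squares real scale factor (the complex scaling M0 carries
    magnitude in the reconstruction problem, so only shape is scored).
    """
    atoms = D_test.atoms
    if isinstance(representer, LinearSubspace):
        if representer.basis.shape[0] != atoms.shape[0]:
            raise ValueError("temporal length mismatch")
        rec = representer.project(atoms)
    else:  # auto-encoder with encode/decode on (n, T) batches
        rec = representer.decode(representer.encode(atoms.T)).T
        scale = np.sum(rec * atoms, axis=0) / np.maximum(
            np.sum(rec * rec, axis=0), 1e-30)
        rec = rec * scale
    per_atom = (np.linalg.norm(atoms - rec, axis=0)
                / np.linalg.norm(atoms, axis=0) * 100.0)
    return per_atom, float(per_atom.mean())


def match_latent(beta_map: np.ndarray, D: SignalDictionary, encoder) -> np.ndarray:
    """Nearest-neighbor tissue-parameter lookup in latent space.

    ``beta_map`` has latent dimension on the last axis.  Each voxel is
    assigned the grid parameter whose encoded latent code is closest in
    Euclidean distance; ties break toward the smaller parameter value.
    """
    if D.n_atoms == 0:
        raise ValueError("empty dictionary")
    codes = encoder.encode(D.atoms.T)  # (N, L)
    beta = np.asarray(beta_map)
    flat = beta.reshape(-1, beta.shape[-1])
    # argmin over squared distance; np.argmin returns the first (smallest
    # grid value) among ties because the grid is sorted ascending
    d2 = (np.sum(flat**2, axis=1)[:, None] - 2 * flat @ codes.T
          + np.sum(codes**2, axis=1)[None, :])
    idx = np.argmin(d2, axis=1)
    order = np.argsort(D.grid, kind="stable")
    if not np.all(order == np.arange(D.n_atoms)):  # unsorted grid: re-tie-break
        d2s = d2[:, order]
        idx = order[np.argmin(d2s, axis=1)]
    return D.grid[idx].reshape(beta.shape[:-1])
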