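"""Error metrics and aggregate reports.

NRMSE here is always the Euclidean norm of the complex difference divided by
the Euclidean norm of the reference, as a percentage.  Magnitude-image NRMSE
is available behind a flag for comparison with magnitude-based conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["nrmse", "NRMSEReport"]


def nrmse(est: np.ndarray, ref: np.ndarray, scope: str = "per_echo",
          magnitude: bool = False) -> np.ndarray | float:
    """Normalized RMS error (%) between image series.

    ``scope="per_echo"`` returns one value per trailing (echo) index;
    ``scope="global"`` flattens space and time into a single ratio.
    """
    est = np.asarray(est)
    ref = np.asarray(ref)
    if est.shape != ref.shape:
        raise ValueError(f"shape mismatch {est.shape} vs {ref.shape}")
    if magnitude:
        est, ref = np.abs(est), np.abs(ref)
    if scope == "global":
        den = np.linalg.norm(ref.ravel())
        if den == 0:
            raise ValueError("zero reference norm")
        return float(np.linalg.norm((est - ref).ravel()) / den * 100.0)
    if scope != "per_echo":
        raise ValueError(f"unknown scope {scope!r}")
    axes = tuple(range(ref.ndim - 1))
    den = np.linalg.norm(ref, axis=axes)
    if np.any(den == 0):
        raise ValueError("zero reference norm at some echo")
    return np.linalg.norm(est - ref, axis=axes) / den * 100.0


@dataclass
class NRMSEReport:
    """Per-echo NRMSE summary for one reconstruction."""

    per_echo: np.ndarray
    error_maps: np.ndarray | None = None
    config_digest: str = ""
    seeds: dict = field(default_factory=dict)

    def __post_init__(self):
        self.per_echo = np.asarray(self.per_echo, dtype=float)
        if np.any(self.per_echo < 0):
            raise ValueError("NRMSE values must be non-negative")

    @property
    def average(self) -> float:
        return float(self.per_echo.mean())
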