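"""HDF5 / YAML persistence for dictionaries, subspaces and acquisitions."""

from __future__ import annotations

import h5py
import yaml

from .dictionary import LinearSubspace, SignalDictionary
from .operators import AcquisitionData
from .phantom import PhantomSpec, Region
from .sequences import EPTIParams, FSEParams, MPRAGEParams

__all__ = [
    "save_dictionary", "load_dictionary",
    "save_subspace", "load_subspace",
    "save_acquisition", "load_acquisition",
    "load_sequence_params", "load_phantom_spec",
]


def save_dictionary(path, D: SignalDictionary) -> None:
    with h5py.File(path, "w") as f:
        f["atoms"] = D.atoms
        f["grid"] = D.grid
        f.attrs["normalized"] = D.normalized
        f.attrs["sequence_tag"] = D.sequence_tag


def load_dictionary(path) -> SignalDictionary:
    with h5py.File(path, "r") as f:
        return SignalDictionary(f["atoms"][()], f["grid"][()],
                                bool(f.attrs["normalized"]),
                                str(f.attrs["sequence_tag"]))


def save_subspace(path, sub: LinearSubspace) -> None:
    with h5py.File(path, "w") as f:
        f["basis"] = sub.basis
        if sub.singular_values is not None:
            f["singular_values"] = sub.singular_values


def load_subspace(path) -> LinearSubspace:
    with h5py.File(path, "r") as f:
        sv = f["singular_values"][()] if "singular_values" in f else None
        return LinearSubspace(f["basis"][()], sv)


def save_acquisition(path, acq: AcquisitionData) -> None:
    with h5py.File(path, "w") as f:
        f["y"] = acq.y
        f["mask"] = acq.mask
        f["coil_maps"] = acq.coil_maps
        if acq.phase is not None:
            f["phase"] = acq.phase
        if acq.echo_times is not None:
            f["echo_times"] = acq.echo_times
        f.attrs["noise_sigma"] = acq.noise_sigma
        for k, v in acq.meta.items():
            if isinstance(v, (int, float, str, bool)):
                f.attrs[f"meta_{k}"] = v


def load_acquisition(path) -> AcquisitionData:
    with h5py.File(path, "r") as f:
        return AcquisitionData(
            y=f["y"][()], mask=f["mask"][()], coil_maps=f["coil_maps"][()],
            phase=f["phase"][()] if "phase" in f else None,
            echo_times=f["echo_times"][()] if "echo_times" in f else None,
            noise_sigma=float(f.attrs.get("noise_sigma", 0.0)),
            meta={k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")},
        )


_PARAM_TYPES = {"fse": FSEParams, "mprage": MPRAGEParams, "epti": EPTIParams}


def load_sequence_params(path, block: str | None = None):
    """Read sequence parameters from a YAML config.

    The file maps a sequence tag (``fse``/``mprage``/``epti``) to its
    parameter fields; ``block`` selects one tag (required when the file
    holds several).
    """
    with open(path) as f:
        doc = yaml.safe_load(f)
    if block is None:
        if len(doc) != 1:
            raise ValueError(f"config holds {sorted(doc)}; pick one via block=")
        block = next(iter(doc))
    if block not in _PARAM_TYPES:
        raise ValueError(f"unknown sequence tag {block!r}")
    return _PARAM_TYPES[block](**doc[block])


def load_phantom_spec(path) -> PhantomSpec:
    """Read a phantom spec (grid, sequence, regions) from YAML."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    regions = tuple(
        Region(**{**r, "pd": complex(r.get("pd", 1.0))})
        for r in doc.pop("regions", [])
    )
    doc["grid_shape"] = tuple(doc.get("grid_shape", (64, 64)))
    return PhantomSpec(regions=regions, **doc)
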