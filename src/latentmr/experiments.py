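"""Desk-scale experiment drivers.

Each driver reproduces one of the study's experiment families end to end
from synthetic inputs: dictionary compression tables, undersampled shuffling
reconstructions, noise-stability sweeps, the latent-to-EPG bridge, and the
partial-volume representation tables.  Everything is seeded; drivers return
plain dicts of arrays/scalars and can write artifact directories (CSV +
HDF5) via :func:`run_experiment`.
"""

from __future__ import annotations

import csv
import json
import time
from pathlib import Path

import numpy as np

from .autoencoder import AutoEncoderSpec, TrainedAutoEncoder, TrainingConfig, train_autoencoder
from .dictionary import (
    build_dictionary,
    build_subspace,
    compression_nrmse,
    match_latent,
    testing_grid,
    training_grid,
)
from .metrics import nrmse
from .operators import acceleration_factor, make_shuffling_mask
from .phantom import default_fse_phantom_spec, make_coil_maps, make_phantom, partial_volume_suite, simulate_acquisition
from .recon import ReconConfig, recon_epg, recon_latent, recon_linear

__all__ = [
    "compression_experiment",
    "shuffling_recon_experiment",
    "epti_recon_experiment",
    "mprage_recon_experiment",
    "stability_experiment",
    "epg_bridge_experiment",
    "partial_volume_experiment",
    "run_experiment",
    "EXPERIMENTS",
]

#: full-recipe training configuration (full-batch Adam)
DEFAULT_TRAINING = TrainingConfig(epochs=100_000, learning_rate=1e-4, seed=0)


def train_for(tag: str, latent_dim: int = 1, cfg: TrainingConfig = DEFAULT_TRAINING,
              echo_count: int | None = None) -> TrainedAutoEncoder:
    """Train the standard L-latent auto-encoder for one sequence family."""
    kw = {} if echo_count is None else {"echo_count": echo_count}
    D = build_dictionary(training_grid(tag), tag, **kw)
    return train_autoencoder(D, AutoEncoderSpec(D.T, latent_dim), cfg)


def compression_experiment(sequence_tag: str, L_list=(1, 2, 3, 4),
                           B_list=(1, 2, 3, 4),
                           training_cfg: TrainingConfig = DEFAULT_TRAINING,
                           echo_count: int | None = None) -> dict:
    """Training/testing compression NRMSE grid for subspaces and auto-encoders.

    Subspaces are built from the raw (unnormalized) training dictionary;
    auto-encoders train on the normalized one.  Returns a dict with rows
    ``linear_train/linear_test/ae_train/ae_test`` indexed by B and L.
    """
    kw = {} if echo_count is None else {"echo_count": echo_count}
    D_raw = build_dictionary(training_grid(sequence_tag), sequence_tag,
                             normalized=False, **kw)
    D_tr = build_dictionary(training_grid(sequence_tag), sequence_tag, **kw)
    D_te = build_dictionary(testing_grid(sequence_tag), sequence_tag, **kw)

    out = {"B": list(B_list), "L": list(L_list),
           "linear_train": [], "linear_test": [], "ae_train": [], "ae_test": []}
    for B in B_list:
        sub = build_subspace(D_raw, B)
        out["linear_train"].append(compression_nrmse(D_tr, sub)[1])
        out["linear_test"].append(compression_nrmse(D_te, sub)[1])
    for L in L_list:
        ae = train_autoencoder(D_tr, AutoEncoderSpec(D_tr.T, L), training_cfg)
        out["ae_train"].append(compression_nrmse(D_tr, ae)[1])
        out["ae_test"].append(compression_nrmse(D_te, ae)[1])
    return out


def _fixture_acquisition(echo_count=32, grid=(64, 64), shots=8, noise=1e-3,
                         seed=0, mixed_border=0):
    gt = make_phantom(default_fse_phantom_spec(grid, echo_count,
                                               mixed_border=mixed_border), seed)
    coils = make_coil_maps(8, grid, seed)
    mask = make_shuffling_mask(shots, echo_count, grid[1], seed)
    acq = simulate_acquisition(gt, coils, mask, noise, seed)
    return gt, acq


def shuffling_recon_experiment(
    echo_count=32, grid=(64, 64), shots=8, noise=1e-3, seed=0,
    B_list=(2, 3), latent_iters=1000, linear_iters=250, lam=0.0,
    regularizer="none", model: TrainedAutoEncoder | None = None,
    training_cfg: TrainingConfig = DEFAULT_TRAINING,
) -> dict:
    """Undersampled shuffling reconstruction: latent vs linear subspaces.

    Returns per-echo and average NRMSE for the latent model (L+2 = 3 DOF)
    and each linear rank in ``B_list`` (2B DOF).
    """
    D = build_dictionary(training_grid("fse"), "fse", echo_count=echo_count)
    D_raw = build_dictionary(training_grid("fse"), "fse", echo_count=echo_count,
                             normalized=False)
    if model is None:
        model = train_autoencoder(D, AutoEncoderSpec(echo_count, 1), training_cfg)
    gt, acq = _fixture_acquisition(echo_count, grid, shots, noise, seed)

    results = {"acceleration": acceleration_factor(acq.mask),
               "dof": {"latent": model.spec.latent_dim + 2}}
    res_lat = recon_latent(
        acq, model,
        ReconConfig(problem="latent", iterations=latent_iters, lam=lam,
                    regularizer=regularizer, seed=seed),
        dictionary=D, truth_series=gt.series)
    results["latent"] = {"per_echo": res_lat.per_echo_nrmse,
                         "average": float(res_lat.per_echo_nrmse.mean())}
    for B in B_list:
        sub = build_subspace(D_raw, B)
        res_lin = recon_linear(
            acq, sub,
            ReconConfig(problem="linear", iterations=linear_iters, lam=lam,
                        regularizer=regularizer, seed=seed),
            truth_series=gt.series)
        results["dof"][f"linear_B{B}"] = 2 * B
        results[f"linear_B{B}"] = {"per_echo": res_lin.per_echo_nrmse,
                                   "average": float(res_lin.per_echo_nrmse.mean())}
    results["_solutions"] = {"latent": res_lat}
    return results


def stability_experiment(
    n_instances=25, echo_count=24, grid=(48, 48), shots=6, noise=2e-3,
    seed=0, B_list=(3,), latent_iters=400, linear_iters=150,
    model: TrainedAutoEncoder | None = None,
    training_cfg: TrainingConfig = DEFAULT_TRAINING,
) -> dict:
    """Mean/SD of per-echo NRMSE over seeded noise instances (unregularized).

    A reduced-replicate analogue of g-factor-style stability analysis: the
    same undersampled acquisition is corrupted by ``n_instances`` independent
    noise draws and reconstructed by each unregularized method.
    """
    if n_instances < 2:
        raise ValueError("need at least 2 noise instances")
    D = build_dictionary(training_grid("fse"), "fse", echo_count=echo_count)
    D_raw = build_dictionary(training_grid("fse"), "fse", echo_count=echo_count,
                             normalized=False)
    if model is None:
        model = train_autoencoder(D, AutoEncoderSpec(echo_count, 1), training_cfg)
    gt = make_phantom(default_fse_phantom_spec(grid, echo_count), seed)
    coils = make_coil_maps(8, grid, seed)
    mask = make_shuffling_mask(shots, echo_count, grid[1], seed)
    subs = {B: build_subspace(D_raw, B) for B in B_list}

    curves = {"latent": []} | {f"linear_B{B}": [] for B in B_list}
    err_maps = {k: 0.0 for k in curves}
    for i in range(n_instances):
        acq = simulate_acquisition(gt, coils, mask, noise, seed * 10_000 + i)
        res = recon_latent(acq, model,
                           ReconConfig(problem="latent", iterations=latent_iters,
                                       seed=seed),
                           dictionary=D, truth_series=gt.series)
        curves["latent"].append(res.per_echo_nrmse)
        err_maps["latent"] += np.abs(res.series - gt.series).mean(axis=-1)
        for B, sub in subs.items():
            rl = recon_linear(acq, sub,
                              ReconConfig(problem="linear",
                                          iterations=linear_iters, seed=seed),
                              truth_series=gt.series)
            curves[f"linear_B{B}"].append(rl.per_echo_nrmse)
            err_maps[f"linear_B{B}"] += np.abs(rl.series - gt.series).mean(axis=-1)

    out = {"n_instances": n_instances, "noise": noise}
    for k, v in curves.items():
        arr = np.asarray(v)
        out[k] = {"mean_per_echo": arr.mean(axis=0), "sd_per_echo": arr.std(axis=0),
                  "mean_abs_error_map": err_maps[k] / n_instances}
    return out


def epg_bridge_experiment(
    echo_count=32, grid=(64, 64), shots=8, noise=1e-3, seed=0,
    latent_iters=1000, epg_iters=150, probe_every=50,
    model: TrainedAutoEncoder | None = None,
    training_cfg: TrainingConfig = DEFAULT_TRAINING,
) -> dict:
    """Latent solve, latent-space dictionary matching, EPG-model refinement.

    Runs the latent reconstruction with gradient probing, matches the final
    latent maps to a T2 map, refines with the EPG-in-the-forward-model
    solver initialized there, and reports the space-time NRMSE between the
    two image series plus the probe-norm decay.
    """
    D = build_dictionary(training_grid("fse"), "fse", echo_count=echo_count)
    if model is None:
        model = train_autoencoder(D, AutoEncoderSpec(echo_count, 1), training_cfg)
    gt, acq = _fixture_acquisition(echo_count, grid, shots, noise, seed)
    epg_params = {"echo_spacing": gt.spec.echo_spacing,
                  "refocus_angle": gt.spec.refocus_angle, "T1": 1000.0}
    # start from the plain adjoint encode (no convex warm start): the probe
    # trace should show optimization-driven decay of the EPG gradient norms
    res_lat = recon_latent(
        acq, model,
        ReconConfig(problem="latent", iterations=latent_iters,
                    probe_every=probe_every, seed=seed,
                    initialization="adjoint"),
        dictionary=D, truth_series=gt.series, epg_params=epg_params)
    t2_map = match_latent(res_lat.solution["beta"], D, model)
    res_epg = recon_epg(acq, t2_map, res_lat.solution["m0"],
                        ReconConfig(problem="epg", iterations=epg_iters),
                        truth_series=gt.series, **epg_params)
    bridge = nrmse(res_epg.series, res_lat.series, scope="global")
    probes = np.array([(it, g1, g2) for it, g1, g2 in
                       res_lat.meta.get("probe_trace", [])])
    probe_frac = {}
    if probes.size:
        probe_frac = {"t2_final_over_max": float(probes[-1, 1] / probes[:, 1].max()),
                      "m0_final_over_max": float(probes[-1, 2] / probes[:, 2].max())}
    return {"bridge_nrmse": bridge, "probe_trace": probes, **probe_frac,
            "latent_avg_nrmse": float(res_lat.per_echo_nrmse.mean()),
            "epg_avg_nrmse": float(res_epg.per_echo_nrmse.mean()),
            "latent_result": res_lat, "epg_result": res_epg, "t2_map": t2_map,
            "truth": gt}


def epti_recon_experiment(
    echo_count=40, grid=(64, 64), shots=2, noise=1e-3, seed=0,
    B_list=(2, 3), latent_iters=800, linear_iters=250,
    use_estimated_b0=False, model: TrainedAutoEncoder | None = None,
    training_cfg: TrainingConfig = DEFAULT_TRAINING,
) -> dict:
    """Undersampled GE-EPTI reconstruction with the B0 phase operator.

    Builds a T2*/B0 phantom, an interleaved-ladder EPTI mask, and compares
    the latent model against linear subspaces, both with the per-voxel phase
    evolution H in the forward model.  ``use_estimated_b0`` switches H from
    the true B0 map to the low-resolution calibration estimate.
    """
    from .operators import b0_phase_operator, estimate_b0_lowres, make_epti_mask
    from .phantom import PhantomSpec, Region

    D = build_dictionary(training_grid("epti"), "epti", echo_count=echo_count)
    D_raw = build_dictionary(training_grid("epti"), "epti",
                             echo_count=echo_count, normalized=False)
    if model is None:
        model = train_autoencoder(D, AutoEncoderSpec(echo_count, 1), training_cfg)
    spec = PhantomSpec(
        grid_shape=grid, sequence="epti", echo_count=echo_count,
        echo_spacing=0.93,
        regions=(
            Region("ellipse", (0.5, 0.5), (0.42, 0.42), T2star=60.0, B0=10.0,
                   pd=0.9),
            Region("ellipse", (0.4, 0.45), (0.15, 0.13), T2star=30.0, B0=35.0,
                   pd=1.0),
            Region("ellipse", (0.63, 0.6), (0.12, 0.14), T2star=150.0, B0=-20.0,
                   pd=0.8),
        ))
    gt = make_phantom(spec, seed)
    coils = make_coil_maps(8, grid, seed)
    mask = make_epti_mask(shots, echo_count, grid[1], seed)
    acq = simulate_acquisition(gt, coils, mask, noise, seed)
    # B0 phase lives in the forward model, not the dictionary: attach H and
    # compare against the phase-free clean series
    if use_estimated_b0:
        full = simulate_acquisition(gt, coils,
                                    np.ones((grid[1], echo_count), bool),
                                    noise, seed)
        b0 = estimate_b0_lowres(full, n_center_lines=min(49, grid[1]),
                                n_echoes=6)
    else:
        b0 = gt.B0_map
    H = b0_phase_operator(b0, gt.echo_times)
    truth_unphased = gt.series * np.conj(
        b0_phase_operator(gt.B0_map, gt.echo_times))
    from .operators import AcquisitionData
    acq = AcquisitionData(y=acq.y, mask=acq.mask, coil_maps=acq.coil_maps,
                          phase=H, echo_times=acq.echo_times,
                          noise_sigma=acq.noise_sigma, meta=acq.meta)
    results = {"acceleration": acceleration_factor(mask),
               "dof": {"latent": model.spec.latent_dim + 2}}
    res_lat = recon_latent(acq, model,
                           ReconConfig(problem="latent",
                                       iterations=latent_iters, seed=seed),
                           dictionary=D, truth_series=truth_unphased)
    results["latent"] = {"per_echo": res_lat.per_echo_nrmse,
                         "average": float(res_lat.per_echo_nrmse.mean())}
    for B in B_list:
        sub = build_subspace(D_raw, B)
        res_lin = recon_linear(acq, sub,
                               ReconConfig(problem="linear",
                                           iterations=linear_iters, seed=seed),
                               truth_series=truth_unphased)
        results["dof"][f"linear_B{B}"] = 2 * B
        results[f"linear_B{B}"] = {"per_echo": res_lin.per_echo_nrmse,
                                   "average": float(res_lin.per_echo_nrmse.mean())}
    return results


def mprage_recon_experiment(
    echo_count=64, grid=(64, 64), shots=4, noise=1e-3, seed=0,
    B_list=(2,), latent_iters=800, linear_iters=250,
    model: TrainedAutoEncoder | None = None,
    training_cfg: TrainingConfig = DEFAULT_TRAINING,
) -> dict:
    """Undersampled MPRAGE-shuffling reconstruction, latent vs linear.

    The default shortens the echo train to 64 for desk-scale runs; pass
    ``echo_count=256`` for the full-length train.
    """
    from .phantom import PhantomSpec, Region

    D = build_dictionary(training_grid("mprage"), "mprage",
                         echo_count=echo_count)
    D_raw = build_dictionary(training_grid("mprage"), "mprage",
                             echo_count=echo_count, normalized=False)
    if model is None:
        model = train_autoencoder(D, AutoEncoderSpec(echo_count, 1), training_cfg)
    spec = PhantomSpec(
        grid_shape=grid, sequence="mprage", echo_count=echo_count,
        echo_spacing=7.8,
        regions=(
            Region("ellipse", (0.5, 0.5), (0.42, 0.42), T1=800.0, pd=0.9),
            Region("ellipse", (0.4, 0.45), (0.15, 0.13), T1=1400.0, pd=1.0),
            Region("ellipse", (0.63, 0.6), (0.12, 0.14), T1=2800.0,
                   pd=0.8 * np.exp(0.4j)),
        ))
    gt = make_phantom(spec, seed)
    coils = make_coil_maps(8, grid, seed)
    mask = make_shuffling_mask(shots, echo_count, grid[1], seed)
    acq = simulate_acquisition(gt, coils, mask, noise, seed)
    results = {"acceleration": acceleration_factor(mask),
               "dof": {"latent": model.spec.latent_dim + 2}}
    res_lat = recon_latent(acq, model,
                           ReconConfig(problem="latent",
                                       iterations=latent_iters, seed=seed),
                           dictionary=D, truth_series=gt.series)
    results["latent"] = {"per_echo": res_lat.per_echo_nrmse,
                         "average": float(res_lat.per_echo_nrmse.mean())}
    for B in B_list:
        sub = build_subspace(D_raw, B)
        res_lin = recon_linear(acq, sub,
                               ReconConfig(problem="linear",
                                           iterations=linear_iters, seed=seed),
                               truth_series=gt.series)
        results["dof"][f"linear_B{B}"] = 2 * B
        results[f"linear_B{B}"] = {"per_echo": res_lin.per_echo_nrmse,
                                   "average": float(res_lin.per_echo_nrmse.mean())}
    return results


def partial_volume_experiment(
    sequence_tag="fse", tissues=("wm", "csf"), fractions=np.linspace(0, 1, 11),
    echo_count: int | None = None, model: TrainedAutoEncoder | None = None,
    training_cfg: TrainingConfig = DEFAULT_TRAINING,
) -> dict:
    """Two-tissue in-/out-of-phase mixture representation table."""
    from .phantom import TISSUES
    from .sequences import epg_cpmg, simulate_mprage
    from .sequences import MPRAGEParams

    kw = {} if echo_count is None else {"echo_count": echo_count}
    D = build_dictionary(training_grid(sequence_tag), sequence_tag, **kw)
    D_raw = build_dictionary(training_grid(sequence_tag), sequence_tag,
                             normalized=False, **kw)
    if model is None:
        model = train_autoencoder(D, AutoEncoderSpec(D.T, 1), training_cfg)
    T = D.T
    sigs = []
    for name in tissues:
        p = TISSUES[name]
        if sequence_tag == "fse":
            s = epg_cpmg(T, 5.56, 160.0, 1000.0,
                         np.clip(p["T2"], *GRID_BOUNDS["fse"]))[:, 0]
        elif sequence_tag == "mprage":
            s = simulate_mprage(MPRAGEParams(
                echo_count=T, T1=np.clip(p["T1"], *GRID_BOUNDS["mprage"]))).values
        else:
            raise ValueError("partial-volume suite covers fse and mprage")
        sigs.append(s / np.linalg.norm(s))
    subs = {f"linear_B{B}": build_subspace(D_raw, B) for B in (2, 3, 4)}
    codes = model.encode(D.atoms.T)
    table = partial_volume_suite(sigs, fractions, subspaces=subs,
                                 autoencoder=model, beta_grid=codes)
    return {"fractions": np.asarray(fractions), "phase_offsets": (0.0, np.pi),
            "tissues": tissues, "table": table}


GRID_BOUNDS = {"fse": (50.0, 400.0), "mprage": (500.0, 3000.0)}


# ---------------------------------------------------------------------------
# artifact-writing driver
# ---------------------------------------------------------------------------

def _write_csv(path: Path, header, rows):
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(header)
        w.writerows(rows)


def _np_to_py(obj):
    if isinstance(obj, dict):
        return {k: _np_to_py(v) for k, v in obj.items() if not k.startswith("_")
                and not hasattr(v, "series")}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_np_to_py(v) for v in obj]
    return obj


EXPERIMENTS = {
    "compression-fse": lambda seed, **kw: compression_experiment("fse", **kw),
    "compression-mprage": lambda seed, **kw: compression_experiment("mprage", **kw),
    "compression-epti": lambda seed, **kw: compression_experiment("epti", **kw),
    "recon-shuffling": lambda seed, **kw: shuffling_recon_experiment(seed=seed, **kw),
    "recon-epti": lambda seed, **kw: epti_recon_experiment(seed=seed, **kw),
    "recon-mprage": lambda seed, **kw: mprage_recon_experiment(seed=seed, **kw),
    "stability": lambda seed, **kw: stability_experiment(seed=seed, **kw),
    "epg-bridge": lambda seed, **kw: epg_bridge_experiment(seed=seed, **kw),
    "partial-volume": lambda seed, **kw: partial_volume_experiment(**kw),
}


def run_experiment(name: str, out_dir, seed: int = 0, **kwargs) -> dict:
    """Run a named experiment and write its artifact directory.

    The directory receives a ``result.json`` (scalars and small arrays), any
    tabular outputs as CSV, and a ``config.json`` with the seed and options
    so the run can be reproduced.
    """
    if name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {name!r}; valid names: {sorted(EXPERIMENTS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    result = EXPERIMENTS[name](seed, **kwargs)
    elapsed = time.time() - t0
    with open(out / "config.json", "w") as f:
        json.dump({"experiment": name, "seed": seed, "elapsed_s": elapsed,
                   "options": _np_to_py(kwargs)}, f, indent=2, default=str)
    with open(out / "result.json", "w") as f:
        json.dump(_np_to_py(result), f, indent=2, default=str)
    if name.startswith("compression"):
        _write_csv(out / "table.csv",
                   ["rank_or_latent", "linear_train", "linear_test",
                    "ae_train", "ae_test"],
                   [(b, lt, le, at, ae_) for b, lt, le, at, ae_ in
                    zip(result["B"], result["linear_train"], result["linear_test"],
                        result["ae_train"], result["ae_test"])])
    return result
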