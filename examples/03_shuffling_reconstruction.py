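"""Reconstruct an undersampled shuffling acquisition: latent vs linear.

Simulates a 64x64 three-tissue phantom, an 8-coil acquisition with a random
shuffling mask (a few ky lines per echo), and reconstructs the echo-image
series with (a) the latent signal model (decoder in the forward model,
3 DOF/voxel) and (b) subspace constraints with 4 and 6 DOF/voxel.  Prints
average NRMSE against the known ground truth.  Iteration counts are reduced
so the example finishes in a couple of minutes.
"""

from latentmr import TrainingConfig
from latentmr.experiments import shuffling_recon_experiment
from latentmr.operators import acceleration_factor

out = shuffling_recon_experiment(
    echo_count=32, grid=(64, 64), shots=8, noise=2e-3, seed=0,
    B_list=(2, 3), latent_iters=400, linear_iters=150,
    training_cfg=TrainingConfig(epochs=30_000, seed=1))

print(f"acceleration R = {out['acceleration']:.0f}")
for name in ("latent", "linear_B2", "linear_B3"):
    print(f"  {name:10s} ({out['dof'][name]} DOF/voxel): "
          f"average NRMSE {out[name]['average']:.2f}%")
print("the latent model attains the lowest error with the fewest unknowns: "
      "4 DOF biases (cannot represent the decay family), 6 DOF amplifies "
      "noise at the weak late echoes")
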