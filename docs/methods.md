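# Methods

This note records the models implemented in `latentmr`, the conventions and
parameter choices behind them, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Signal models

**Fast spin echo (CPMG) via EPG.** The extended-phase-graph simulator
tracks dephasing configuration states (F+, F−, Z) through the pulse train:
ideal 90° excitation with the transverse magnetization along the refocusing
axis, refocusing pulses of the stated angle, relaxation and one unit of
gradient dephasing per half echo spacing, signal read from the F0 state at
each echo midpoint. States are truncated at T+2 dephasing orders, which is
exact for a T-echo train. With this phase convention echo amplitudes are
real; for non-180° pulses with T1 regrowth the fully decayed tail (below
~1% of peak) shows a genuine ±1e-3 even/odd alternation around zero, which
the independent isochromat oracle reproduces to machine precision — "echo
signals are positive and decay monotonically" holds per echo parity above
that floor, and the tests assert exactly that.

A forward-mode derivative of the recursion with respect to T2 propagates
(state, ∂state/∂T2) jointly; only the relaxation factors depend on T2, so
the extra cost is about one additional simulation.

**Verification oracles.** The isochromat oracle simulates 2000 spins
uniformly dephased across one 2π gradient cycle per echo spacing with
explicit 3-D rotation/relaxation steps; 2000 spins is converged (agreement
with EPG is at machine precision for uniform dephasing). The MPRAGE oracle
integrates the longitudinal Bloch equation in 0.01–0.05 ms steps. Oracles
share no code with the production simulators.

**MPRAGE.** Transverse signal `Mz_n · sin α` along an inversion-prepared
gradient-echo train; longitudinal recursion
`Mz_{n+1} = 1 + (Mz_n cos α − 1) e^{−esp/T1}` with instantaneous pulses,
iterated over TR cycles until the pre-inversion Mz changes by <1e−8
(steady state; the tests check 1e−6). TI is nominally
inversion-to-first-pulse; when TI + train length exceeds TR (as it does for
the default 1100 ms TI / 2500 ms TR / 256×7.8 ms train), TI is
reinterpreted as inversion-to-center-of-train and the returned object
records the convention used. Inversion efficiency defaults to 1.0 and is
exposed.

**GE-EPTI.** Analytic per-echo decay `exp(−TE/T2*)` with off-resonance
phase `exp(2πi·ΔB0·TE)`; the first echo time is not standardized, so it
defaults to 1 ms and is configurable. In reconstruction, B0 enters through
the unit-magnitude phase operator H rather than the dictionary, so EPTI
dictionaries are real T2* decays.

## Dictionaries, subspaces, auto-encoders

Default parameter grids are uniform: FSE T2 50–400 ms at 1 ms (T1 fixed at
1000 ms, 160° refocusing, 5.56 ms spacing), MPRAGE T1 500–3000 ms at 10 ms
(8° flip, 7.8 ms spacing, 256 echoes), EPTI T2* 10–300 ms at 1 ms (40
echoes, 0.93 ms spacing). Testing grids are offset by half a step so train
and test share no point; subspace NRMSE is insensitive to the exact
spacing (sub-0.1-point changes between 1 and 5 ms steps).

**SVD convention.** Temporal subspaces are computed from the *unnormalized*
atom matrix. Per-atom projection NRMSE is scale-invariant, but the SVD
weighting is not: raw atoms weight long-T2 (high-energy) evolutions more,
and this convention reproduces the reference compression tables; it is also
the natural choice when voxel amplitudes follow the same physics as the
atoms. Auto-encoders, by contrast, train on ℓ2-normalized atoms: shape is
the decoder's job and magnitude belongs to the complex scale M0, and the
compression score for auto-encoders therefore allows a per-atom
least-squares real scale before computing NRMSE.

**Auto-encoder.** Two fully connected layers per half: encoder
T → T/2 (tanh) → L (linear), decoder mirrored with a linear output layer so
decoded signals are not range-clipped; a three-layer variant with
geometrically interpolated widths is available. Training is full-batch Adam
at learning rate 1e−4 for 100k epochs (the full recipe; reduced-epoch
profiles are used in examples and some fixtures), minimizing mean squared
reconstruction error over atoms, float32 arithmetic with float64 loss
accumulation, uniform fan-in initialization from a seeded generator.
Training is deterministic given the seed. Across seeds the tanh FSE models
land within 0.05 NRMSE points of each other; the larger MPRAGE network
shows a real spread (roughly 0.11–0.36% testing NRMSE over seeds) in which
the final *training* loss rank-correlates with the held-out error, so
`train_autoencoder_restarts` offers deterministic best-of-N selection on
the training loss alone — no held-out information enters the choice — and
the headline-number script uses it. Divergence (non-finite loss) raises an
error naming the epoch and learning rate.

The networks are implemented directly in NumPy with hand-written
backpropagation: they are a few thousand parameters, an epoch is a handful
of small GEMMs, and explicit gradients let the decoder expose exact
vector-Jacobian products to the reconstruction solvers.

## Forward operators

2-D imaging (readout × phase encode); 3-D experiments are emulated by a
fully sampled readout and [ky, echo] masks. FFTs are centered and unitary,
so the adjoint equals the inverse on full sampling; the adjoint identity of
the full chain (mask ∘ FFT ∘ coil ∘ phase ∘ temporal model) holds to 1e−8
and is tested. Coil maps are smooth complex Gaussian lobes at equiangular
positions, sum-of-squares normalized. H is identity for FSE/MPRAGE and the
B0 phase operator for EPTI. Noise is i.i.d. complex Gaussian per sampled
k-space point with σ specified relative to the DC magnitude of the
noiseless data, seeded.

Masks: the shuffling mask samples `shots` distinct random ky lines per echo
(acceleration `n_ky·T/(shots·T)`; 4 shots at 256×80 gives R=64); the EPTI
mask interleaves deterministic ky ladders, one line per shot per echo, with
a stride coprime to n_ky (2 shots at 216×40 gives 80 lines, R=108). B0
calibration keeps the central 49 ky lines of the first 6 echoes, and fits
per-voxel phase slopes by magnitude-weighted least squares on inter-echo
phase increments (valid while inter-echo phase stays below π).

## Reconstruction solvers

**Linear (FISTA).** Step size 1/(2·Lipschitz) from 20 power iterations;
optional wavelet (Daubechies-4, 3 levels, periodization, detail-band soft
threshold on complex magnitude) or locally-low-rank (8×8 non-overlapping
blocks, singular-value soft threshold) prox. FISTA is non-monotone, so the
divergence guard triggers only on sustained growth above the starting
objective.

**Latent (Adam).** Joint Adam over real β and (Re M0, Im M0) with learning
rate 3e−2 for β and 3e−2 × max|M0_init| for the scale; 1000 iterations
default. The rate was set by convergence analysis on the 64×64 fixture: at
1e−2 the 1000-iteration solve is visibly short of its own minimum
(objective 3.69 vs 3.18 reached by the EPG refinement, bridge NRMSE 3.6%),
while 3e−2 converges (objective 3.179, bridge 0.65%) and matches the
3000-iteration behavior of smaller rates. Initialization: a short
(100-iteration) unregularized FISTA solve of the convex rank-3 subspace
problem provides a warm series; β comes from encoding its phase-referenced,
ℓ2-normalized time course, clipped to the encoded-grid range (keeps tanh
layers out of saturation), and M0 from the least-squares complex scale of
the decoded β against the warm series. Encoding the raw zero-filled adjoint
instead is cheaper but leaves the nonconvex solve in a bad basin at
stronger undersampling (objective stalls an order of magnitude above the
reachable minimum at 4-shot sampling on the 64×64 fixture), which is why
the convex warm start is the default. No gauge fixing
is needed: a global data phase is absorbed by M0 (tested). Optional
wavelet prox applies separately to β and M0 after each step.

**EPG-in-the-forward-model (L-BFGS-B).** Per-voxel T2 (scaled to O(1),
bounded to [1, 5000] ms — out-of-range initial values are clipped with a
warning) and complex M0, with exact forward-mode EPG derivatives. The
signal model is the ℓ2-normalized EPG shape scaled by M0, consistent with
the normalized-dictionary convention, so latent solutions initialize it
directly via latent-space dictionary matching. A consequence worth knowing:
at voxels whose residual is parallel to the shape (e.g. background), the
T2 gradient vanishes identically because normalized-shape derivatives are
orthogonal to the shape.

**Gradient probe.** Every `probe_every` latent iterations the current β is
dictionary-matched to T2, and the L2 norms of the EPG objective's T2 and M0
gradients are recorded at (T2, M0). The bridge experiment deliberately
starts this solve from the plain adjoint encode (`initialization="adjoint"`)
rather than the convex warm start, so the probe trace shows the
optimization itself driving the EPG gradients down instead of starting at
the floor. Decay of these norms to a small
fraction of their maximum, together with a sub-percent space-time NRMSE
between the latent and EPG-refined series, is the operational evidence that
the decoder is a faithful proxy for differentiating through the simulation.

## Synthetic data: what it does and does not emulate

The default fixture is a 64×64 grid, 8 coils, 32-echo FSE train, three to
four elliptical/rectangular tissue regions with T2 spread across the
dictionary range, T1 pinned to the dictionary's 1000 ms, complex proton
densities, optional 1-voxel partial-volume borders mixed by exact area
fraction, and a default acquisition of 8 shots with relative noise 1e−3 to
2e−3. Full-scale configurations (256×256, T=80/256) are supported by the
same code but not exercised in the tests. Problem sizes in the tests and
the acceptance script (64×64, T=32, 8 shots) were chosen as the package's
desk-scale operating point; they preserve the structure of the full-size
experiments (undersampling per echo, coil encoding, signal families) at
minutes of CPU.

Passing tests on this fixture demonstrate the algorithmic claims — the
compression hierarchy, the reconstruction ordering, the EPG-bridge
consistency — under a known forward model. They do not demonstrate
robustness to effects the generator omits: slice profiles, B1+
inhomogeneity, stimulated-echo weighting from variable flip trains, motion,
flow, non-Cartesian trajectories, gradient imperfections, real coil
geometries, or model mismatch between tissue and dictionary (the phantom's
T1 matches the dictionary's fixed T1 by construction).

## Known limitations

- The latent objective is nonconvex; Adam from the linear warm start is
  reliable at the fixture's operating points (4- and 8-shot sampling), but
  poorer initializations can land in bad basins and heavier undersampling
  can need more iterations (the objective trace is returned precisely so
  this is visible).
- Latent models represent out-of-phase (subtractive) FSE partial-volume
  mixtures poorly — an intrinsic limitation of the single-tissue latent
  manifold; the in-phase additive case and both MPRAGE cases are
  well-represented, and the partial-volume suite quantifies this.
- The MPRAGE timing convention is inferred (see above) since
  inversion-to-first-pulse is infeasible with the default TI/TR/train; both
  conventions are implemented and the choice is recorded per simulation.
- NRMSE is computed on complex images (magnitude available as an option);
  choosing magnitude NRMSE would hide phase errors that the complex metric
  exposes.
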