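# Methods

## Signal models

The bi-exponential IVIM model
`S(b) = S0((1−f)e^{−bD} + f e^{−bD*})` and the tri-exponential model
`S(b) = S0((1−f1−f2)e^{−bD} + f1 e^{−bD1*} + f2 e^{−bD2*})` are evaluated
with decay constants in mm²/s and b in s/mm², so every exponent b·D is
dimensionless. The tri-exponential fit runs in the primed parameterisation
`S(b) = f0'e^{−bD} + f1'e^{−bD1*} + f2'e^{−bD2*}` (with
S0 = f0'+f1'+f2', f1 = f1'/S0, f2 = f2'/S0), which removes the coupling
between S0 and the fractions and makes the amplitude parameters linear in
the model. The two parameterisations agree to better than 1e-12 relative
under that conversion, and the conversion round-trips at machine precision;
both facts are property-tested.

Parameter containers validate their physical invariants (fractions in
[0, 1], f1+f2 ≤ 1, non-negative decay constants, positive S0) at
construction. The forward models assume valid input; this lets bounded
optimisers evaluate at arbitrary interior iterates and validate only the
values they return. No ordering D < D1* < D2* is imposed by the types —
ordering arises from the constraint intervals, which overlap on
[60e-3, 80e-3] mm²/s for D1*/D2*; fits count ordering violations in their
diagnostics instead of forbidding them.

## Simulator

The simulator emulates a free-breathing liver acquisition with 18 b-values
(0, 1, 2, 5, 10, 20, 30, 40, 50, 75, 100, 150, 200, 300, 400, 500, 600,
700 s/mm²). Truth parameters are drawn independently and uniformly from
liver-representative ranges:

| parameter | range | units |
|---|---|---|
| D | 0.5e-3 – 3e-3 | mm²/s |
| f1 | 0.05 – 0.3 | — |
| D1* | 10e-3 – 50e-3 | mm²/s |
| f2 | 0.05 – 0.3 | — |
| D2* | 0.2 – 4 | mm²/s |

S0 is fixed at 1 (curves are generated pre-normalised; fitters still
estimate it). Noise is zero-mean additive Gaussian on the normalised
signal with per-curve standard deviation 1/SNR, SNR defined against
S(b=0)=1. Training-style batches draw the per-curve SNR from an
exponential distribution truncated to [10, 100] by rejection; the
untruncated mean defaults to 20, a choice that concentrates most draws at
the noisy end of the admitted interval (the distribution family and bounds
are fixed, the rate is a config knob). A fixed SNR or "noiseless" can be
requested instead. Noise is drawn once per curve, not redrawn per epoch.
All outputs are bit-reproducible from the config seed; the noise stream is
decoupled from the parameter stream so the same truth can be re-noised.

What the simulator does *not* emulate: Rician/magnitude noise (a Rician
option would be a straightforward extension but Gaussian is the default and
only tested path), respiratory motion, eddy currents, partial-volume and
fat contamination, spatial correlation between voxels. Passing simulation
benchmarks therefore demonstrates estimator behaviour under the assumed
noise model, not robustness to real-liver artefacts.

## Constrained least squares

Voxel-wise fits use trust-region-reflective bounded least squares
(`scipy.optimize.least_squares`) with analytic Jacobians, cost tolerance
1e-10 and at most 1000 evaluations per voxel. Constraint intervals:

* bi: 3e-4 < D < 5e-3 mm²/s, 0 < f < 0.7, 5e-3 < D* < 3e-1 mm²/s,
  0.5 < S0 < 2.5;
* tri (primed): 0 < D < 8e-3 mm²/s, 8e-3 < D1* < 80e-3 mm²/s,
  60e-3 < D2* < 5 mm²/s, 0 < f0' < 2.5, 0 < f1' < 1, 0 < f2' < 1.

Fraction bounds are treated as dimensionless. Initialisation is
deterministic: the geometric midpoint of each interval, with a lower bound
of zero floored at high/1000 before taking the geometric mean (a geometric
midpoint is undefined at 0); one fixed restart from the arithmetic midpoint
if the solver fails. Non-converged or degenerate voxels (all-zero or
non-finite signal) are flagged and filled with arithmetic bound midpoints so
parameter maps are always complete; nothing raises per voxel. On noiseless
curves with truth interior to the bounds, recovery is accurate to ~1e-8
relative, comfortably inside the 1e-3 budget the tests enforce.

ROI-wise fits average masked voxel signals per b-value and fit once with
the same constraints, reporting the adjusted
R² = 1 − (1−R²)(n−1)/(n−p−1) used to compare the bi (p=4) and tri (p=6)
models.

## Self-supervised neural fitters

The networks follow the published physics-informed design: fully-connected
sub-networks take the voxel's normalised signal (one input per b-value) and
emit parameters; the training loss is the RMS error between the input decay
and the decay reconstructed from the predictions. No ground truth is read
anywhere in training — this is audited by a dedicated test.

* **bi**: one sub-network per parameter (S0, D, D*, f), 2 hidden layers,
  fixed learning rate 3e-5, early stop after `patience` epochs without
  validation improvement.
* **tri**: semi-parallel grouping, one sub-network per amplitude/decay
  pair — (f0', D), (f1', D1*), (f2', D2*) — 4 hidden layers, initial
  learning rate 1e-4, plateau scheduler that divides the rate by 5 after 10
  consecutive epochs without validation improvement and stops when a
  freshly reduced rate brings no improvement within its first 10 epochs.
  "Epoch" is one pass over the training split; scheduler patience counts
  epochs.

Hidden width equals the number of b-values; each hidden block is
Linear → batch norm → ELU → dropout(0.1); batch size 128; Adam. Each raw
output passes through `low + (high−low)·σ(z)` with (low, high) taken from
the same FitBounds the LSQ uses, so predictions respect the constraints by
construction and are never clipped. Data are split 90/10 into training and
validation; the validation loss drives the scheduler and early stopping,
and the best-validation weights (including batch-norm running statistics)
are restored at the end. The engine is implemented directly in numpy with
manual reverse-mode gradients — including through the scaled logistic and
the exponential reconstruction — and is exactly reproducible from a single
seed on a fixed thread configuration.

Because the tri-exponential loss surface has a poorly performing local
minimum that captures a minority of runs, training can be repeated from
fresh initialisations (seeds seed+0 … seed+n−1) with the lowest-validation-
loss run kept; all restart losses are logged.

## Evaluation

RMSE against simulation truth is computed per parameter on native scales
(a normalised variant exists for cross-parameter aggregation). Parameter-map
SNR is mean/SD within an ROI using the sample (n−1) SD convention
(recorded in output metadata); zero-variance ROIs are flagged undefined
(NaN). Paired method comparisons use Wilcoxon signed-rank and paired t
statistics, and clinical-grade correlation uses Spearman's tie-corrected
coefficient — all delegated to scipy.stats.

## Problem sizes and observed behaviour

Benchmarks in the test suite and acceptance script run at desk scale as the
package's defaults: 100,000 training curves (max 150 epochs; convergence
typically occurs near 70–90), 10,000-curve test sets at SNR 15 and 50,
30 ROI replicates at SNR 30, 1,000 noiseless recovery curves. At SNR 15 the
trained tri network achieves lower RMSE than the voxel-wise LSQ for all
five parameters. At SNR 50 the ordering holds only for D2* and f2 at this
training-set size: the self-supervised network's shrinkage toward the
training distribution dominates once the LSQ is itself precise, so the
high-SNR ordering should be expected to need substantially larger training
sets (the full-scale protocol uses 5,000,000 curves and 10 restarts).

## Known limitations

* Gaussian noise only in the tested paths; no noise-floor or T2 effects.
* Direction-averaged (trace) signals are assumed; per-direction repeats of
  a b-value are geometric-mean averaged at I/O time (switchable to
  arithmetic), since joint directional fitting is out of scope.
* No spatial regularisation or convolutional variant; voxels are fitted
  independently.
* Bayesian and segmented/stepwise IVIM fitting are out of scope.
* The in-vivo clinical workflow (liver segmentation, histology correlation)
  is supported only insofar as `correlate_with_grades` accepts user-supplied
  per-subject tables.
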