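# ivim3fit

Bi- and tri-exponential intravoxel incoherent motion (IVIM) fitting for
diffusion-weighted MRI, with two back-ends sharing one set of physical
constraints: voxel-wise constrained nonlinear least squares, and
self-supervised physics-informed neural networks in the style of IVIM-NET
and its tri-exponential extension.

## The problem

IVIM imaging separates molecular diffusion from perfusion-driven
pseudo-diffusion in tissue. Signals acquired at a range of diffusion
weightings *b* (s/mm²) are classically fitted with the bi-exponential model

    S(b) = S0 · ((1 − f) · e^(−b·D) + f · e^(−b·D*))

with tissue diffusion coefficient *D*, pseudo-diffusion coefficient *D\**
and perfusion fraction *f*. In the liver, the fast decay at very low
b-values is better described by a tri-exponential model with two perfusion
compartments — slow (microvascular) and fast (large-vessel):

    S(b) = S0 · ((1 − f1 − f2) · e^(−b·D) + f1 · e^(−b·D1*) + f2 · e^(−b·D2*))

For fitting, the tri-exponential model is re-expressed in a "primed" form
`S(b) = f0'·e^(−b·D) + f1'·e^(−b·D1*) + f2'·e^(−b·D2*)` with
`S0 = f0' + f1' + f2'`, `f1 = f1'/S0`, `f2 = f2'/S0`; the summed perfusion
fraction f1+2 = f1 + f2 is directly comparable to the bi-exponential *f*.

Voxel-wise least-squares fits of the tri-exponential model produce noisy
parameter maps, especially for the pseudo-diffusion terms. The neural
fitters here are trained *without ground truth*: a small fully-connected
network per parameter (or per amplitude/decay-constant pair) maps a voxel's
normalised decay to parameters, and the loss is the root-mean-square error
between the measured decay and the decay reconstructed from the predicted
parameters. Outputs pass through a scaled logistic onto the same constraint
intervals the least-squares fit uses, so every prediction is in bounds by
construction.

The package also ships the simulation machinery to benchmark both back-ends:
tri-exponential curves at an 18-b-value scheme (0–700 s/mm²) with
liver-representative parameter ranges and Gaussian noise at a configurable
SNR, plus evaluation utilities (per-parameter RMSE against ground truth,
parameter-map SNR within a homogeneous ROI, adjusted-R² model comparison,
Spearman correlation against ordinal clinical grades).

## Worked example

```python
from ivim3fit import SimConfig, simulate_batch, fit_tri_lsq, fit_roi, rmse

cfg = SimConfig(n_curves=2000, snr_spec=20, seed=42)   # 18 b-values, SNR 20
batch = simulate_batch(cfg)

report = fit_tri_lsq(batch.signals, cfg.bvalues)
errors = rmse(report.maps(), batch.truth.as_dict(),
              ["D", "D1star", "D2star", "f1", "f2"])
for name, err in errors.items():
    print(f"RMSE {name:8s} {err:.4g}")
print(f"converged: {report.converged.sum()}/{len(report.converged)}")

roi = fit_roi(batch.signals, None, cfg.bvalues, "tri")
roi_bi = fit_roi(batch.signals, None, cfg.bvalues, "bi")
print(f"ROI adjusted R2: tri {roi.adjusted_r2:.4f}  bi {roi_bi.adjusted_r2:.4f}")
```

Output:

```
RMSE D        0.0004584
RMSE D1star   0.02303
RMSE D2star   1.924
RMSE f1       0.1042
RMSE f2       0.06048
converged: 1996/2000
ROI adjusted R2: tri 0.9997  bi 0.9805
```

The RMSE values are in native units (mm²/s for decay constants,
dimensionless for fractions): at SNR 20 the voxel-wise least-squares fit
recovers *D* well but the pseudo-diffusion parameters are noisy — the
motivation for the neural fitter. The ROI-averaged fit shows the higher
adjusted R² of the tri-exponential model on tri-exponential data after
penalising its two extra degrees of freedom.

Training a network and predicting maps:

```python
from ivim3fit import NetworkSpec, TrainConfig, train_with_restarts, predict_maps

tf = train_with_restarts(NetworkSpec("tri"), batch.signals, cfg.bvalues,
                         TrainConfig(seed=0, n_restarts=3))
nn_report = predict_maps(tf, batch.signals, cfg.bvalues)
```

## Command line

```bash
ivim3fit simulate --n 10000 --snr exp:10:100 --seed 1 --out curves.csv
ivim3fit simulate --n 512 --snr 20 --shape 8,8,8 --out vol.nii.gz
ivim3fit fit --method lsq --model tri --dwi vol.nii.gz --bval vol.bval --out maps/
ivim3fit fit --method nn  --model tri --dwi vol.nii.gz --bval vol.bval --seed 1 --out nn_maps/
ivim3fit train-sim --n 100000 --restarts 10 --seed 1 --out weights.npz
ivim3fit evaluate --pred maps/ --truth ./ --out rmse.csv
```

Each fit writes one NIfTI per parameter (S0, D, D1star, D2star, f1, f2,
f1plus2 for the tri model) plus a JSON sidecar with the bounds, convergence
counts and a configuration hash.

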