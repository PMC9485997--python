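"""Self-supervised physics-informed neural IVIM fitters.

Two voxel-wise estimators in the style of IVIM-NET and its tri-exponential
extension: small fully-connected networks take a voxel's normalised signal
decay (one input per b-value) and output IVIM parameters, trained end-to-end
by minimising the root-mean-square error between the measured decay and the
decay reconstructed from the predicted parameters.  Ground-truth parameters
are never consulted — the physics of the signal equation is the only
supervision — so the same network can be trained directly on in-vivo data
and then reused for parameter-map inference.

Architecture
------------
* bi-exponential: one sub-network per parameter (S0, D, D*, f), two hidden
  layers, trained at a fixed learning rate of 3e-5.
* tri-exponential: a semi-parallel grouping with one sub-network per
  (amplitude, decay-constant) pair — (f0', D), (f1', D1*), (f2', D2*) — four
  hidden layers, initial learning rate 1e-4, and a plateau scheduler that
  divides the rate by 5 after `patience` epochs without validation
  improvement; training halts when a freshly reduced rate brings no
  improvement within its first `patience` epochs.

Hidden width equals the number of b-values; layers are Linear -> batch norm
-> ELU -> dropout(0.1).  Each raw output is mapped through a scaled logistic
onto its constraint interval, so every prediction lies inside the shared
:class:`~ivim3fit.lsq.FitBounds` by construction — no clipping is ever
applied.  Because the tri-exponential loss landscape has a poorly performing
local minimum that captures a minority of runs, training is repeated with
fresh initialisations and the restart with the lowest validation loss kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._mlp import Adam, BatchNorm, Dropout, ELU, Linear, Sequential
from .lsq import FitBounds, FitReport
from .models import BiParams, BValueScheme, TriParamsPrime, ValidationError

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainedFitter",
    "TrainingDiverged",
    "build_network",
    "physics_loss",
    "train",
    "train_with_restarts",
    "predict_maps",
    "save_fitter",
    "load_fitter",
]

_BI_GROUPS = (("S0",), ("D",), ("Dstar",), ("f",))
_TRI_PAIR_GROUPS = (("f0p", "D"), ("f1p", "D1star"), ("f2p", "D2star"))
_TRI_PARALLEL_GROUPS = (("f0p",), ("f1p",), ("f2p",), ("D",), ("D1star",), ("D2star",))


class TrainingDiverged(RuntimeError):
    """Raised when a training run produces a non-finite loss."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description for a physics-informed fitter."""

    model: str  # "bi" or "tri"
    n_hidden_layers: Optional[int] = None  # default: 2 (bi) / 4 (tri)
    width: Optional[int] = None  # default: number of b-values
    dropout: float = 0.1
    batch_norm: bool = True
    grouping: Optional[str] = None  # parallel_per_parameter | semi_parallel_pairs
    output_bounds: Optional[FitBounds] = None

    def __post_init__(self):
        if self.model not in ("bi", "tri"):
            raise ValidationError("model must be 'bi' or 'tri'")
        if self.n_hidden_layers is None:
            object.__setattr__(self, "n_hidden_layers", 2 if self.model == "bi" else 4)
        if self.n_hidden_layers < 1:
            raise ValidationError("need at least one hidden layer")
        if self.grouping is None:
            object.__setattr__(
                self,
                "grouping",
                "parallel_per_parameter" if self.model == "bi" else "semi_parallel_pairs",
            )
        if self.grouping not in ("parallel_per_parameter", "semi_parallel_pairs"):
            raise ValidationError(f"unknown grouping {self.grouping!r}")
        if self.model == "bi" and self.grouping == "semi_parallel_pairs":
            raise ValidationError("pair grouping is only defined for the tri model")
        if self.output_bounds is None:
            object.__setattr__(
                self,
                "output_bounds",
                FitBounds.bi_defaults() if self.model == "bi" else FitBounds.tri_defaults(),
            )
        if self.output_bounds.model != self.model:
            raise ValidationError("output_bounds model does not match spec model")

    @property
    def groups(self) -> tuple[tuple[str, ...], ...]:
        if self.model == "bi":
            return _BI_GROUPS
        if self.grouping == "semi_parallel_pairs":
            return _TRI_PAIR_GROUPS
        return _TRI_PARALLEL_GROUPS


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation schedule; unspecified fields resolve per model."""

    initial_lr: Optional[float] = None  # 3e-5 (bi) / 1e-4 (tri)
    lr_decay_factor: float = 5.0
    patience: int = 10
    train_fraction: float = 0.9
    batch_size: int = 128
    optimiser: str = "adam"
    seed: int = 0
    n_restarts: int = 10
    max_epochs: int = 300
    use_scheduler: Optional[bool] = None  # default: off (bi) / on (tri)

    def __post_init__(self):
        if not 0 < self.train_fraction <= 1:
            raise ValidationError("train_fraction must be in (0, 1]")
        if self.patience < 1 or self.n_restarts < 1 or self.max_epochs < 1:
            raise ValidationError("patience, n_restarts and max_epochs must be >= 1")
        if self.lr_decay_factor <= 1:
            raise ValidationError("lr_decay_factor must exceed 1")
        if self.optimiser != "adam":
            raise ValidationError("only the adam optimiser is implemented")

    def resolve(self, model: str) -> "TrainConfig":
        kw = {}
        if self.initial_lr is None:
            kw["initial_lr"] = 3e-5 if model == "bi" else 1e-4
        if self.use_scheduler is None:
            kw["use_scheduler"] = model == "tri"
        return replace(self, **kw) if kw else self


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class IVIMNetwork:
    """Bank of parallel sub-networks with bound-respecting outputs."""

    def __init__(self, spec: NetworkSpec, n_b: int, seed: int = 0):
        if n_b < 5:
            raise ValidationError("need at least 5 b-values")
        self.spec = spec
        self.n_b = n_b
        width = spec.width or n_b
        rng = np.random.default_rng(seed)
        self.subnets = []
        for group in spec.groups:
            layers = []
            n_in = n_b
            for _ in range(spec.n_hidden_layers):
                layers.append(Linear(n_in, width, rng))
                if spec.batch_norm:
                    layers.append(BatchNorm(width))
                layers.append(ELU())
                if spec.dropout > 0:
                    layers.append(Dropout(spec.dropout))
                n_in = width
            layers.append(Linear(n_in, len(group), rng))
            self.subnets.append(Sequential(layers))
        self.params = [p for net in self.subnets for p in net.params]
        self.grads = [g for net in self.subnets for g in net.grads]
        bounds = spec.output_bounds.bounds
        self._lo = [np.array([bounds[n][0] for n in g]) for g in spec.groups]
        self._hi = [np.array([bounds[n][1] for n in g]) for g in spec.groups]
        self._sig = None  # cached logistic activations for backward

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(n for g in self.spec.groups for n in g)

    def get_state(self) -> list[np.ndarray]:
        """Weights plus batch-norm running statistics, in a fixed order."""
        state = [p.copy() for p in self.params]
        for net in self.subnets:
            for layer in net.layers:
                if isinstance(layer, BatchNorm):
                    state.append(layer.running_mean.copy())
                    state.append(layer.running_var.copy())
        return state

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        n_par = len(self.params)
        for p, s in zip(self.params, state[:n_par]):
            p[...] = s
        it = iter(state[n_par:])
        for net in self.subnets:
            for layer in net.layers:
                if isinstance(layer, BatchNorm):
                    layer.running_mean[...] = next(it)
                    layer.running_var[...] = next(it)

    def forward(self, x: np.ndarray, train: bool, rng=None) -> dict[str, np.ndarray]:
        out = {}
        self._sig = []
        for net, group, lo, hi in zip(self.subnets, self.spec.groups, self._lo, self._hi):
            z = net.forward(x, train, rng)
            s = _sigmoid(z)
            self._sig.append(s)
            p = lo + (hi - lo) * s
            for j, name in enumerate(group):
                out[name] = p[:, j]
        return out

    def backward(self, dparams: dict[str, np.ndarray]) -> None:
        for net, group, lo, hi, s in zip(
            self.subnets, self.spec.groups, self._lo, self._hi, self._sig
        ):
            dz = np.column_stack([dparams[name] for name in group])
            dz = dz * (hi - lo) * s * (1.0 - s)
            net.backward(dz)


def _bvals(b) -> np.ndarray:
    if isinstance(b, BValueScheme):
        return b.values
    return np.asarray(b, dtype=float).ravel()


def _reconstruct(params: dict, b: np.ndarray, model: str):
    """Predicted decays plus the exponential factors needed for gradients."""
    if model == "bi":
        e0 = np.exp(-np.multiply.outer(params["D"], b))
        e1 = np.exp(-np.multiply.outer(params["Dstar"], b))
        f = params["f"][:, None]
        pred = params["S0"][:, None] * ((1.0 - f) * e0 + f * e1)
        return pred, (e0, e1)
    e0 = np.exp(-np.multiply.outer(params["D"], b))
    e1 = np.exp(-np.multiply.outer(params["D1star"], b))
    e2 = np.exp(-np.multiply.outer(params["D2star"], b))
    pred = (
        params["f0p"][:, None] * e0
        + params["f1p"][:, None] * e1
        + params["f2p"][:, None] * e2
    )
    return pred, (e0, e1, e2)


def _param_grads(params: dict, G: np.ndarray, b: np.ndarray, model: str, cache) -> dict:
    """dLoss/dparam given dLoss/dpredicted-signal G."""
    if model == "bi":
        e0, e1 = cache
        S0 = params["S0"][:, None]
        f = params["f"][:, None]
        return {
            "S0": np.sum(G * ((1.0 - f) * e0 + f * e1), axis=1),
            "D": np.sum(G * (-S0 * (1.0 - f)) * b * e0, axis=1),
            "Dstar": np.sum(G * (-S0 * f) * b * e1, axis=1),
            "f": np.sum(G * S0 * (e1 - e0), axis=1),
        }
    e0, e1, e2 = cache
    return {
        "f0p": np.sum(G * e0, axis=1),
        "f1p": np.sum(G * e1, axis=1),
        "f2p": np.sum(G * e2, axis=1),
        "D": np.sum(G * (-params["f0p"][:, None]) * b * e0, axis=1),
        "D1star": np.sum(G * (-params["f1p"][:, None]) * b * e1, axis=1),
        "D2star": np.sum(G * (-params["f2p"][:, None]) * b * e2, axis=1),
    }


def physics_loss(predicted_params, signals, b, model: str) -> float:
    """Root-mean-square reconstruction error of a batch of predictions.

    The bi model reconstructs S0((1-f)e^{-bD}+f e^{-bD*}); the tri model the
    primed form f0'e^{-bD}+f1'e^{-bD1*}+f2'e^{-bD2*}.
    """
    if isinstance(predicted_params, BiParams):
        predicted_params = predicted_params.as_dict()
    elif isinstance(predicted_params, TriParamsPrime):
        predicted_params = {
            "f0p": predicted_params.f0p, "f1p": predicted_params.f1p,
            "f2p": predicted_params.f2p, "D": predicted_params.D,
            "D1star": predicted_params.D1star, "D2star": predicted_params.D2star,
        }
    params = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in predicted_params.items()}
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    bv = _bvals(b)
    if signals.shape[1] != bv.size:
        raise ValidationError("signal columns do not match b-value count")
    n = next(iter(params.values())).shape[0]
    if signals.shape[0] != n:
        raise ValidationError("parameter rows do not match signal rows")
    pred, _ = _reconstruct(params, bv, model)
    return float(np.sqrt(np.mean((pred - signals) ** 2)))


def build_network(spec: NetworkSpec, n_b: int, seed: int = 0) -> IVIMNetwork:
    """Construct an untrained fitter whose outputs respect spec.output_bounds."""
    return IVIMNetwork(spec, n_b, seed=seed)


@dataclass
class TrainedFitter:
    """A trained network plus everything needed to audit and reuse it."""

    network: IVIMNetwork
    spec: NetworkSpec
    config: TrainConfig
    bvalues: np.ndarray
    training_log: list[dict] = field(default_factory=list)
    final_val_loss: float = np.inf
    restart_losses: Optional[list[float]] = None


def _rmse_loss_grad(pred: np.ndarray, target: np.ndarray):
    r = pred - target
    loss = float(np.sqrt(np.mean(r**2)))
    if loss == 0:
        return 0.0, np.zeros_like(r)
    return loss, r / (r.size * loss)


def train(fitter: IVIMNetwork, signals, b, cfg: TrainConfig) -> TrainedFitter:
    """Optimise the physics-informed loss; self-supervised throughout.

    Splits the voxels into a training and a held-out validation fraction,
    logs per-epoch losses and learning-rate events, keeps the best-validation
    weights, and applies the plateau schedule described in the module
    docstring.  Only the signals are read — no ground truth enters.
    """
    cfg = cfg.resolve(fitter.spec.model)
    bv = _bvals(b)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != bv.size:
        raise ValidationError("signal columns do not match b-value count")
    model = fitter.spec.model
    rng = np.random.default_rng(cfg.seed)

    n = signals.shape[0]
    perm = rng.permutation(n)
    n_train = max(1, int(round(cfg.train_fraction * n)))
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    x_train = signals[train_idx]
    x_val = signals[val_idx] if val_idx.size else x_train

    opt = Adam(fitter.params, fitter.grads, lr=cfg.initial_lr)
    log: list[dict] = []
    best_val = np.inf
    best_state = fitter.get_state()
    epochs_since_improve = 0
    stage_is_fresh = False  # True right after an lr reduction, until improvement

    def val_loss() -> float:
        p = fitter.forward(x_val, train=False)
        pred, _ = _reconstruct(p, bv, model)
        return float(np.sqrt(np.mean((pred - x_val) ** 2)))

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n_train)
        batch_losses = []
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if idx.size < 2 and n_train > 1:
                continue  # batch statistics need >= 2 voxels
            xb = x_train[idx]
            p = fitter.forward(xb, train=True, rng=rng)
            pred, cache = _reconstruct(p, bv, model)
            loss, G = _rmse_loss_grad(pred, xb)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite training loss at epoch {epoch}")
            fitter.backward(_param_grads(p, G, bv, model, cache))
            opt.step()
            batch_losses.append(loss)

        vloss = val_loss()
        if not np.isfinite(vloss):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        improved = vloss < best_val
        lr_reduced = False
        if improved:
            best_val = vloss
            best_state = fitter.get_state()
            epochs_since_improve = 0
            stage_is_fresh = False
        else:
            epochs_since_improve += 1

        stop = False
        if epochs_since_improve >= cfg.patience:
            if not cfg.use_scheduler:
                stop = True
            elif stage_is_fresh:
                # a freshly reduced lr brought no improvement: early stop
                stop = True
            else:
                opt.lr /= cfg.lr_decay_factor
                lr_reduced = True
                epochs_since_improve = 0
                stage_is_fresh = True

        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(batch_losses)) if batch_losses else np.nan,
                "val_loss": vloss,
                "lr": opt.lr,
                "improved": improved,
                "lr_reduced": lr_reduced,
                "best_val": best_val,
            }
        )
        if stop:
            break

    fitter.set_state(best_state)
    return TrainedFitter(
        network=fitter, spec=fitter.spec, config=cfg, bvalues=bv.copy(),
        training_log=log, final_val_loss=best_val,
    )


def train_with_restarts(spec: NetworkSpec, signals, b, cfg: TrainConfig) -> TrainedFitter:
    """Repeat training from fresh initialisations; keep the lowest-loss run.

    Restart ``i`` uses seed ``cfg.seed + i`` for both weight initialisation
    and data shuffling.  All restart losses are retained on the returned
    fitter for diagnostics.
    """
    bv = _bvals(b)
    best: Optional[TrainedFitter] = None
    losses: list[float] = []
    failures = 0
    for i in range(cfg.n_restarts):
        seed_i = cfg.seed + i
        net = build_network(spec, len(bv), seed=seed_i)
        try:
            tf = train(net, signals, b, replace(cfg, seed=seed_i))
        except TrainingDiverged:
            failures += 1
            losses.append(np.inf)
            continue
        losses.append(tf.final_val_loss)
        if best is None or tf.final_val_loss < best.final_val_loss:
            best = tf
    if best is None:
        raise TrainingDiverged(f"all {cfg.n_restarts} restarts diverged")
    best.restart_losses = losses
    return best


def predict_maps(tf: TrainedFitter, signals, b, chunk_size: int = 65536) -> FitReport:
    """One deterministic forward pass per voxel; outputs inside bounds.

    The tri model's primed outputs are converted to normalised fractions and
    the summed perfusion fraction f1+2 appears in the report's maps.  The
    b-value scheme must equal the training scheme.
    """
    bv = _bvals(b)
    if bv.size != tf.bvalues.size or not np.allclose(bv, tf.bvalues):
        raise ValidationError("b-value scheme differs from the training scheme")
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != bv.size:
        raise ValidationError("signal columns do not match b-value count")
    model = tf.spec.model

    chunks = []
    names = tf.network.param_names
    rms = np.empty(signals.shape[0])
    for start in range(0, signals.shape[0], chunk_size):
        xb = signals[start : start + chunk_size]
        p = tf.network.forward(xb, train=False)
        pred, _ = _reconstruct(p, bv, model)
        rms[start : start + xb.shape[0]] = np.sqrt(np.mean((pred - xb) ** 2, axis=1))
        chunks.append(p)
    params = {name: np.concatenate([c[name] for c in chunks]) for name in names}

    if model == "bi":
        fitted = BiParams(S0=params["S0"], D=params["D"], Dstar=params["Dstar"], f=params["f"])
        n_params = 4
        violations = 0
    else:
        prime = TriParamsPrime(
            f0p=params["f0p"], f1p=params["f1p"], f2p=params["f2p"],
            D=params["D"], D1star=params["D1star"], D2star=params["D2star"],
        )
        fitted = prime.to_triparams()
        n_params = 6
        violations = int(np.sum(params["D1star"] > params["D2star"]))
    return FitReport(
        params=fitted,
        residual_rms=rms,
        converged=np.ones(signals.shape[0], dtype=bool),
        n_params=n_params,
        bounds=tf.spec.output_bounds,
        model=model,
        ordering_violations=violations,
    )


def save_fitter(tf: TrainedFitter, path) -> None:
    """Serialise weights, running statistics and configuration to one .npz."""
    import dataclasses
    import json

    meta = {
        "spec": {
            **dataclasses.asdict(tf.spec),
            "output_bounds": {
                "model": tf.spec.output_bounds.model,
                "bounds": tf.spec.output_bounds.bounds,
            },
        },
        "config": dataclasses.asdict(tf.config),
        "final_val_loss": tf.final_val_loss,
        "restart_losses": tf.restart_losses,
        "training_log": tf.training_log,
    }
    state = tf.network.get_state()
    np.savez(
        path,
        bvalues=tf.bvalues,
        meta=np.array(json.dumps(meta)),
        n_state=np.array(len(state)),
        **{f"state_{i}": s for i, s in enumerate(state)},
    )


def load_fitter(path) -> TrainedFitter:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        bvalues = z["bvalues"]
        state = [z[f"state_{i}"] for i in range(int(z["n_state"]))]
    spec_d = dict(meta["spec"])
    ob = spec_d.pop("output_bounds")
    spec = NetworkSpec(
        **spec_d,
        output_bounds=FitBounds(ob["model"], {k: tuple(v) for k, v in ob["bounds"].items()}),
    )
    # NetworkSpec re-resolves defaults; asdict already made them concrete
    cfg = TrainConfig(**meta["config"])
    net = build_network(spec, len(bvalues))
    net.set_state(state)
    return TrainedFitter(
        network=net, spec=spec, config=cfg, bvalues=bvalues,
        training_log=meta["training_log"], final_val_loss=meta["final_val_loss"],
        restart_losses=meta["restart_losses"],
    )
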