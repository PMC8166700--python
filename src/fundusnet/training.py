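"""Optimization loop, repetition harness and random hyperparameter search.

Training uses Adam (beta1=0.9, beta2=0.999) with a staircase learning-rate
schedule (10% decay every 10,000 iterations) on randomly sampled, augmented
patches.  The validation loss is recorded at a fixed interval; training
stops when it fails to improve for ``patience`` consecutive checks or at
the iteration budget, and the best-validation parameter state is kept as
the checkpoint.  The initial learning rate follows the model size: the more
weights, the smaller the rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_pipeline import DatasetSpec, SplitPlan, augment, sample_batch
from .model_family import ArchitectureSpec, NetworkModel, build_network
from .nn import Adam
from .supervision import LossConfig, focal_grad, focal_term, l2_penalty, lr_at

__all__ = [
    "TrainConfig",
    "TrainRun",
    "default_lr",
    "train",
    "repeat_runs",
    "random_search",
    "restore_model",
]


def default_lr(kernel_count: int) -> float:
    """Initial learning rate by model size."""
    if kernel_count <= 2e5:
        return 1e-3
    if kernel_count <= 5e6:
        return 5e-4
    return 1e-4


@dataclass
class TrainConfig:
    lr0: float | None = None          # None -> default_lr by model size
    beta1: float = 0.9
    beta2: float = 0.999
    max_iterations: int = 2000
    validation_interval: int = 500
    patience: int = 10
    loss: LossConfig = field(default_factory=LossConfig)
    augment: bool = True
    n_val_batches: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.lr0 is not None and self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainRun:
    """One trained model: config, loss curves and best checkpoint."""

    spec: ArchitectureSpec
    config: TrainConfig
    plan: SplitPlan | None
    train_curve: list          # (iteration, loss)
    val_curve: list            # (iteration, loss)
    checkpoint: dict
    best_val_loss: float
    converged_iteration: int
    lr0: float = 0.0


class DivergenceError(RuntimeError):
    def __init__(self, iteration):
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration


def _batch_loss_and_grad(model: NetworkModel, x, y, w, cfg: LossConfig):
    """Forward + segmentation/side loss and the gradient w.r.t. the softmax
    output; returns (loss_seg_side, probs, gprobs, gsides)."""
    out = model.net.forward(x, train=True)
    sides = None
    if isinstance(out, tuple):
        probs, sides = out
    else:
        probs = out
    N = y.size
    p_true = np.where(y, probs[:, 1], probs[:, 0])
    loss = float(np.sum(focal_term(p_true, y, cfg) * w)) / N
    gscalar = focal_grad(p_true, y, cfg) * w / N
    gprobs = np.zeros_like(probs)
    gprobs[:, 1] = np.where(y, gscalar, 0.0)
    gprobs[:, 0] = np.where(y, 0.0, gscalar)
    gsides = None
    if sides is not None:
        # each side branch adds mean((s - onehot)^2); d/ds = 2 (s - t) / s.size
        onehot = np.stack([(~y).astype(np.float32), y.astype(np.float32)], axis=1)
        loss += sum(float(np.mean((s - onehot) ** 2)) for s in sides)
        gsides = [2.0 * (s - onehot) / s.size for s in sides]
    return loss, probs, gprobs, gsides


def _eval_loss(model: NetworkModel, batches, cfg: LossConfig):
    total = 0.0
    for x, y, w in batches:
        out = model.net.forward(x, train=False)
        probs = out[0] if isinstance(out, tuple) else out
        p_true = np.where(y, probs[:, 1], probs[:, 0])
        total += float(np.sum(focal_term(p_true, y, cfg) * w)) / y.size
        if isinstance(out, tuple):
            onehot = np.stack([(~y).astype(np.float32), y.astype(np.float32)],
                              axis=1)
            total += sum(float(np.mean((s - onehot) ** 2)) for s in out[1])
    kernels = [p.value for p in model.net.kernel_parameters()]
    reg = cfg.lambda_reg * l2_penalty(kernels, cfg.l2_mode)
    return total / len(batches) + reg


def train(spec: ArchitectureSpec, prepared: dict, plan: SplitPlan,
          db: DatasetSpec, cfg: TrainConfig) -> TrainRun:
    """Train one model on the plan's training images.

    ``prepared`` maps image ids to ``(values, label, weights)`` triples at
    network resolution (see ``data_pipeline.prepare_samples``).  The run is
    deterministic given the config seed.
    """
    model = build_network(spec, seed=cfg.seed)
    lr0 = cfg.lr0 if cfg.lr0 is not None else default_lr(
        model.kernel_weight_count)
    params = model.net.parameters()
    kernel_params = model.net.kernel_parameters()
    n_kernel = sum(p.value.size for p in kernel_params)
    loss_cfg = cfg.loss
    lam = loss_cfg.lambda_reg
    lam_scale = lam if loss_cfg.l2_mode == "sum" else lam / max(n_kernel, 1)

    opt = Adam(params, lr_fn=lambda it: lr_at(it, lr0),
               beta1=cfg.beta1, beta2=cfg.beta2)

    batch_rng = np.random.default_rng([cfg.seed, 1])
    aug_rng = np.random.default_rng([cfg.seed, 2])
    val_rng = np.random.default_rng([cfg.seed, 3])

    def stack(ids):
        imgs = [prepared[i][0] for i in ids]
        labs = [prepared[i][1] for i in ids]
        wgts = [prepared[i][2] for i in ids]
        return imgs, labs, wgts

    tr_imgs, tr_labs, tr_wgts = stack(plan.train)
    val_batches = []
    if plan.validation:
        v_imgs, v_labs, v_wgts = stack(plan.validation)
        for _ in range(cfg.n_val_batches):
            val_batches.append(sample_batch(v_imgs, v_labs, v_wgts, db, val_rng))

    train_curve, val_curve = [], []
    best_val = np.inf
    best_state = model.net.state_dict()
    best_iter = 0
    checks_since_best = 0
    stop_iter = cfg.max_iterations

    for it in range(cfg.max_iterations):
        x, y, w = sample_batch(tr_imgs, tr_labs, tr_wgts, db, batch_rng)
        if cfg.augment:
            for k in range(x.shape[0]):
                x[k, 0], y[k], w[k] = augment(x[k, 0], y[k], w[k], aug_rng)
        loss, probs, gprobs, gsides = _batch_loss_and_grad(
            model, x, y, w, loss_cfg)
        kernels = [p.value for p in kernel_params]
        full_loss = loss + lam * l2_penalty(kernels, loss_cfg.l2_mode)
        if not np.isfinite(full_loss):
            raise DivergenceError(it)
        model.net.zero_grad()
        model.net.backward(gprobs, gsides)
        if lam > 0:
            for p in kernel_params:
                p.grad += lam_scale * p.value
        opt.step()
        train_curve.append((it, full_loss))

        if val_batches and (it + 1) % cfg.validation_interval == 0:
            vloss = _eval_loss(model, val_batches, loss_cfg)
            val_curve.append((it + 1, vloss))
            if vloss < best_val - 1e-9:
                best_val = vloss
                best_state = model.net.state_dict()
                best_iter = it + 1
                checks_since_best = 0
            else:
                checks_since_best += 1
                if checks_since_best >= cfg.patience:
                    stop_iter = it + 1
                    break

    if not val_curve:  # no validation check ran: keep the final state
        best_state = model.net.state_dict()
        best_iter = stop_iter
        best_val = train_curve[-1][1] if train_curve else np.inf

    return TrainRun(spec=spec, config=cfg, plan=plan, train_curve=train_curve,
                    val_curve=val_curve, checkpoint=best_state,
                    best_val_loss=float(best_val),
                    converged_iteration=best_iter, lr0=lr0)


def restore_model(run: TrainRun) -> NetworkModel:
    """Rebuild the network and load the run's best-validation checkpoint."""
    model = build_network(run.spec, seed=run.config.seed)
    model.net.load_state_dict(run.checkpoint)
    return model


def save_run(run: TrainRun, outdir, threshold: float | None = None):
    """Persist a run: checkpoint arrays (npz), metadata (JSON), curves (CSV)."""
    import dataclasses
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": a for i, a in enumerate(run.checkpoint["params"])}
    for i, (rm, rv) in enumerate(run.checkpoint["bn"]):
        arrays[f"bn_mean_{i}"] = rm
        arrays[f"bn_var_{i}"] = rv
    np.savez(outdir / "checkpoint.npz", **arrays)
    pd.DataFrame(run.train_curve, columns=["iteration", "loss"]).to_csv(
        outdir / "train_curve.csv", index=False)
    pd.DataFrame(run.val_curve, columns=["iteration", "loss"]).to_csv(
        outdir / "val_curve.csv", index=False)
    meta = {"spec": dataclasses.asdict(run.spec),
            "seed": run.config.seed, "lr0": run.lr0,
            "best_val_loss": run.best_val_loss,
            "converged_iteration": run.converged_iteration,
            "n_bn": len(run.checkpoint["bn"])}
    if threshold is not None:
        meta["threshold"] = float(threshold)
    (outdir / "run.json").write_text(json.dumps(meta, indent=2))
    return outdir


def load_run(outdir):
    """Rebuild the model from a saved run; returns (model, metadata dict)."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    meta = json.loads((outdir / "run.json").read_text())
    spec = ArchitectureSpec(**meta["spec"])
    model = build_network(spec, seed=meta["seed"])
    data = np.load(outdir / "checkpoint.npz")
    n_params = len(model.net.parameters())
    state = {"params": [data[f"param_{i}"] for i in range(n_params)],
             "bn": [(data[f"bn_mean_{i}"], data[f"bn_var_{i}"])
                    for i in range(meta["n_bn"])]}
    model.net.load_state_dict(state)
    return model, meta


def repeat_runs(spec: ArchitectureSpec, prepared: dict, plan: SplitPlan,
                db: DatasetSpec, cfg: TrainConfig, n: int = 5) -> list[TrainRun]:
    """n independent roll-outs with distinct seeds derived from the master
    seed, as in the five-repetition protocol."""
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = derive_seeds(cfg.seed, n)
    return [train(spec, prepared, plan, db, replace(cfg, seed=int(s)))
            for s in seeds]


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(master_seed).integers(2 ** 31, size=n)


def random_search(space: dict, objective, n_trials: int = 29, seed: int = 0):
    """Seeded independent uniform random search over named ranges.

    ``space`` maps a parameter name to either a ``(low, high)`` numeric
    range (floats drawn uniformly; integer bounds draw integers uniformly,
    inclusive) or a list of choices.  ``objective(config) -> float`` returns
    the validation score (higher is better), e.g. a validation AUC from a
    training run.  Returns ``(trials, best_config)`` with the trial table as
    a DataFrame.
    """
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    rows = []
    best_cfg, best_score = None, -np.inf
    for t in range(n_trials):
        cfg = {}
        for name, rng_spec in space.items():
            if isinstance(rng_spec, (list, tuple)) and len(rng_spec) == 2 and \
                    all(isinstance(v, (int, float)) for v in rng_spec):
                lo, hi = rng_spec
                if isinstance(lo, int) and isinstance(hi, int):
                    cfg[name] = int(rng.integers(lo, hi + 1))
                else:
                    cfg[name] = float(rng.uniform(lo, hi))
            else:
                cfg[name] = rng_spec[int(rng.integers(len(rng_spec)))]
        score = float(objective(cfg))
        rows.append({"trial": t, **cfg, "score": score})
        if score > best_score:
            best_score, best_cfg = score, dict(cfg)
    return pd.DataFrame(rows), best_cfg
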