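"""Adversarial training loop with lossless checkpointing.

One *generator step* is the WGAN-GP unit of work: ``n_critic`` critic
updates on fresh real/synthetic batches, then a single generator update
against the frozen critic plus the perceptual and severity terms.  The
lesion descriptors ``D(x)`` that condition the generator are extracted
once per real image before the loop and cached.

Reproducibility contract: every random draw comes from one PCG64 stream
seeded by the configuration, and checkpoints store model parameters,
both optimizer states, the history table and the exact bit-generator
state — resuming from step k replays the identical remainder of an
unbroken run.  If any loss turns non-finite the loop aborts, reporting
the last finite step (and leaving the last good checkpoint on disk when
checkpointing is enabled).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from ._serialize import load_container, save_container
from ._util import to_nchw
from .gan import (CriticModel, GeneratorModel, LossWeights, condition_stack,
                  critic_objective)
from .grader import DEFAULT_FEATURE_LAYER, GraderModel
from .lesions import extract
from .resample import ResampleSpec
from .synthetic import FundusSample, read_dataset

HISTORY_COLUMNS = ("step", "LW", "penalty", "Lpercept", "Lseverity", "LG", "grad_norm")


@dataclass(frozen=True)
class TrainConfig:
    """Study conditions for one adversarial run."""

    steps: int
    side: int = 64
    batch_size: int = 16
    n_critic: int = 5
    z_dim: int = 128
    base_width: int = 4  # CPU-scale default; raise for real experiments
    lr: float = 1e-4
    beta1: float = 0.0
    beta2: float = 0.9
    weights: LossWeights = field(default_factory=LossWeights)
    resample: ResampleSpec = field(default_factory=lambda: ResampleSpec("bilinear"))
    feature_layer: str = DEFAULT_FEATURE_LAYER
    seed: int = 0
    checkpoint_every: int = 0  # generator steps between checkpoints; 0 disables
    log_every: int = 0  # print cadence; 0 silences
    dtype: str = "float32"  # training arithmetic; float64 available for checking

    def __post_init__(self):
        if self.steps < 0 or self.n_critic < 1 or self.batch_size < 1:
            raise ValueError("steps must be >= 0; n_critic and batch_size >= 1")
        if self.side % 16 != 0:
            raise ValueError("side must be divisible by 16")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    def to_meta(self) -> dict:
        return {
            "steps": self.steps, "side": self.side, "batch_size": self.batch_size,
            "n_critic": self.n_critic, "z_dim": self.z_dim, "base_width": self.base_width,
            "lr": self.lr, "beta1": self.beta1, "beta2": self.beta2,
            "wp": self.weights.wp, "ws": self.weights.ws, "lambda_gp": self.weights.lambda_gp,
            "resample": self.resample.label, "feature_layer": self.feature_layer,
            "seed": self.seed, "checkpoint_every": self.checkpoint_every,
            "log_every": self.log_every, "dtype": self.dtype,
        }

    @classmethod
    def from_meta(cls, m: dict) -> "TrainConfig":
        return cls(steps=m["steps"], side=m["side"], batch_size=m["batch_size"],
                   n_critic=m["n_critic"], z_dim=m["z_dim"], base_width=m["base_width"],
                   lr=m["lr"], beta1=m["beta1"], beta2=m["beta2"],
                   weights=LossWeights(m["wp"], m["ws"], m["lambda_gp"]),
                   resample=ResampleSpec.parse(m["resample"]),
                   feature_layer=m["feature_layer"], seed=m["seed"],
                   checkpoint_every=m["checkpoint_every"], log_every=m["log_every"],
                   dtype=m.get("dtype", "float32"))


@dataclass
class TrainResult:
    generator: GeneratorModel
    critic: CriticModel
    history: np.ndarray  # (steps, len(HISTORY_COLUMNS))
    completed_steps: int
    aborted: bool
    checkpoint_path: str | None


def prepare_conditions(samples, grader: GraderModel,
                       feature_layer: str = DEFAULT_FEATURE_LAYER) -> dict[str, np.ndarray]:
    """Cache per-real-image quantities the loop would otherwise recompute.

    Lesion descriptors D(x), severity scores DR(x) and perceptual
    features F(x) are all pure functions of the frozen grader and the
    real image, so they are computed once per image up front; training
    then only indexes these arrays.
    """
    samples = _as_samples(samples)
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.vessel_mask for s in samples]).astype(np.float64)
    descriptors = np.stack([extract(grader, s.image).stack() for s in samples])
    grades = np.concatenate([grader.predict(images[i:i + 25])
                             for i in range(0, len(samples), 25)])
    feats = np.concatenate([grader.features(images[i:i + 25], feature_layer)
                            for i in range(0, len(samples), 25)])
    return {"images": images, "masks": masks, "descriptors": descriptors,
            "conditions": condition_stack(masks, descriptors),
            "grades": grades, "features": feats}


def _as_samples(data) -> list[FundusSample]:
    if isinstance(data, str) or hasattr(data, "__fspath__"):
        return read_dataset(data)
    return list(data)


def _cast_grader(grader: GraderModel, dtype: np.dtype) -> GraderModel:
    """Clone the frozen grader with parameters cast to the training dtype.

    The grader stays frozen during adversarial training, but its forward
    pass sits inside the generator's graph; a float64 copy would silently
    promote the whole graph, defeating the float32 fast path.
    """
    clone = GraderModel(side=grader.side, stem_channels=grader.stem_channels,
                        widths=grader.widths, init_seed=grader.init_seed,
                        leak=grader.leak)
    for k, v in grader.params.items():
        clone.params[k] = nn.Tensor(v.data.astype(dtype))
    clone.feat_mean = grader.feat_mean.astype(dtype)
    clone.feat_std = grader.feat_std.astype(dtype)
    return clone


def _rng_state_meta(rng: np.random.Generator) -> dict:
    st = rng.bit_generator.state
    return {"state": str(st["state"]["state"]), "inc": str(st["state"]["inc"]),
            "has_uint32": st["has_uint32"], "uinteger": st["uinteger"]}


def _restore_rng(meta: dict) -> np.random.Generator:
    bg = np.random.PCG64()
    bg.state = {"bit_generator": "PCG64",
                "state": {"state": int(meta["state"]), "inc": int(meta["inc"])},
                "has_uint32": meta["has_uint32"], "uinteger": meta["uinteger"]}
    return np.random.Generator(bg)


class _Trainer:
    def __init__(self, config: TrainConfig):
        self.config = config
        self.np_dtype = np.dtype(config.dtype)
        self.generator = GeneratorModel(side=config.side, base_width=config.base_width,
                                        z_dim=config.z_dim, resample=config.resample,
                                        init_seed=config.seed)
        self.critic = CriticModel(side=config.side, base_width=config.base_width,
                                  init_seed=config.seed + 1)
        for model in (self.generator, self.critic):
            for p in model.params.values():
                p.data = p.data.astype(self.np_dtype)
        self.opt_g = nn.Adam(self.generator.params, lr=config.lr,
                             betas=(config.beta1, config.beta2))
        self.opt_c = nn.Adam(self.critic.params, lr=config.lr,
                             betas=(config.beta1, config.beta2))
        self.rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([config.seed % 2**31, 0x7A17])))
        self.step = 0
        self.rows: list[list[float]] = []

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        meta = {"kind": "gan", "config": self.config.to_meta(), "step": self.step,
                "rng": _rng_state_meta(self.rng)}
        arrays: dict[str, np.ndarray] = {}
        for k, v in self.generator.params.items():
            arrays[f"gen.{k}"] = v.data
        for k, v in self.critic.params.items():
            arrays[f"critic.{k}"] = v.data
        for k, v in self.opt_g.state_arrays().items():
            arrays[f"optg.{k}"] = v
        for k, v in self.opt_c.state_arrays().items():
            arrays[f"optc.{k}"] = v
        arrays["history"] = np.asarray(self.rows, dtype=np.float64).reshape(
            len(self.rows), len(HISTORY_COLUMNS))
        save_container(path, meta, arrays)

    @classmethod
    def load(cls, path) -> "_Trainer":
        meta, arrays = load_container(path)
        if meta.get("kind") != "gan":
            raise IOError(f"{path!r} is not a GAN training checkpoint")
        tr = cls(TrainConfig.from_meta(meta["config"]))
        for k in tr.generator.params:
            tr.generator.params[k].data = arrays[f"gen.{k}"]
        for k in tr.critic.params:
            tr.critic.params[k].data = arrays[f"critic.{k}"]
        tr.opt_g.load_state_arrays({k[5:]: v for k, v in arrays.items() if k.startswith("optg.")})
        tr.opt_c.load_state_arrays({k[5:]: v for k, v in arrays.items() if k.startswith("optc.")})
        tr.rng = _restore_rng(meta["rng"])
        tr.step = int(meta["step"])
        tr.rows = [list(r) for r in arrays["history"]]
        return tr

    # -- one generator step ----------------------------------------------------
    def _batch(self, cache):
        idx = self.rng.integers(0, cache["images_nchw"].shape[0], size=self.config.batch_size)
        x = nn.Tensor(cache["images_nchw"][idx])
        y = nn.Tensor(cache["masks_nchw"][idx])
        cond = nn.Tensor(cache["conditions"][idx])
        z = nn.Tensor(self.rng.normal(
            size=(self.config.batch_size, self.config.z_dim)).astype(self.np_dtype))
        return idx, x, y, cond, z

    def run_step(self, cache, grader: GraderModel) -> list[float]:
        cfg = self.config
        c_parts = []
        for _ in range(cfg.n_critic):
            _, x, y, cond, z = self._batch(cache)
            xhat = self.generator.forward(cond, z)
            xhat = nn.Tensor(xhat.data)  # critic update does not touch generator params
            u = self.rng.uniform(0.0, 1.0, size=cfg.batch_size)
            loss, parts = critic_objective(self.critic, x, xhat, y, cfg.weights, u)
            grads = nn.grad(loss, list(self.critic.params.values()))
            self.opt_c.step({k: g.data for k, g in zip(self.critic.params, grads)})
            c_parts.append(parts)

        # generator update; DR(x) and F(x) come from the per-image cache
        idx, x, y, cond, z = self._batch(cache)
        xhat = self.generator.forward(cond, z)
        adv = nn.neg(nn.tmean(self.critic.score(xhat, y)))
        percept = nn.tmean(nn.power(
            grader.features_tensor(xhat, cfg.feature_layer) - nn.Tensor(cache["features"][idx]),
            2.0))
        severity = nn.tmean(nn.absolute(
            nn.Tensor(cache["grades"][idx]) - grader.forward(xhat)))
        g_loss = adv + cfg.weights.wp * percept + cfg.weights.ws * severity
        g_parts = {"perceptual": percept.item(), "severity": severity.item(),
                   "total": g_loss.item()}
        grads = nn.grad(g_loss, list(self.generator.params.values()))
        self.opt_g.step({k: g.data for k, g in zip(self.generator.params, grads)})

        self.step += 1
        row = [
            float(self.step),
            float(np.mean([p["wasserstein"] for p in c_parts])),
            float(np.mean([p["penalty"] for p in c_parts])),
            g_parts["perceptual"],
            g_parts["severity"],
            g_parts["total"],
            float(np.mean([p["grad_norm"] for p in c_parts])),
        ]
        self.rows.append(row)
        return row


def train(data, grader: GraderModel, config: TrainConfig,
          checkpoint_dir: str | None = None,
          resume_from: str | None = None,
          conditions_cache: dict[str, np.ndarray] | None = None) -> TrainResult:
    """Run (or resume) adversarial training.

    ``data`` is a list of :class:`FundusSample` or a manifest path;
    ``grader`` provides the lesion descriptors, the severity score and
    the perceptual features.  With ``checkpoint_dir`` set, a checkpoint
    is written every ``config.checkpoint_every`` generator steps and at
    the end.  ``resume_from`` restores a previous checkpoint and trains
    on to ``config.steps`` total; the configuration stored in the
    checkpoint must match (only bookkeeping fields may differ).
    ``conditions_cache`` may pass a precomputed
    :func:`prepare_conditions` result (for the same ``data``, ``grader``
    and feature layer) to avoid recomputing it across runs.
    """
    if resume_from is not None:
        trainer = _Trainer.load(resume_from)
        stored = replace(trainer.config, steps=config.steps,
                         checkpoint_every=config.checkpoint_every,
                         log_every=config.log_every)
        if stored != config:
            raise ValueError("resume configuration differs from the checkpoint's study conditions")
        trainer.config = config
    else:
        trainer = _Trainer(config)

    cache = (conditions_cache if conditions_cache is not None
             else prepare_conditions(data, grader, config.feature_layer))
    if cache["images"].shape[1] != config.side:
        raise ValueError(
            f"dataset side {cache['images'].shape[1]} != configured side {config.side};"
            " resize the dataset first")
    dt = trainer.np_dtype
    cache = {
        "images_nchw": to_nchw(cache["images"]).astype(dt),
        "masks_nchw": cache["masks"][:, None].astype(dt),
        "conditions": cache["conditions"].astype(dt),
        "grades": cache["grades"].astype(dt),
        "features": cache["features"].astype(dt),
    }
    loss_grader = _cast_grader(grader, dt)

    last_ckpt = None

    def checkpoint(tag: str) -> str:
        path = os.path.join(checkpoint_dir, f"gan_{tag}.ckpt")
        trainer.save(path)
        return path

    aborted = False
    while trainer.step < config.steps:
        row = trainer.run_step(cache, loss_grader)
        if not np.all(np.isfinite(row)):
            aborted = True
            trainer.rows.pop()
            trainer.step -= 1
            break
        if config.log_every and trainer.step % config.log_every == 0:
            print("  ".join(f"{c}={v:.4g}" for c, v in zip(HISTORY_COLUMNS, row)), flush=True)
        if (checkpoint_dir and config.checkpoint_every
                and trainer.step % config.checkpoint_every == 0):
            last_ckpt = checkpoint(f"step{trainer.step:06d}")

    if checkpoint_dir:
        last_ckpt = checkpoint("final" if not aborted else f"abort{trainer.step:06d}")

    history = np.asarray(trainer.rows, dtype=np.float64).reshape(
        len(trainer.rows), len(HISTORY_COLUMNS))
    return TrainResult(generator=trainer.generator, critic=trainer.critic,
                       history=history, completed_steps=trainer.step,
                       aborted=aborted, checkpoint_path=last_ckpt)


def history_to_csv(history: np.ndarray, path) -> None:
    """Write the per-step history table as CSV with the standard columns."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    header = ",".join(HISTORY_COLUMNS)
    np.savetxt(path, history, delimiter=",", header=header, comments="")


def load_generator(path) -> tuple[GeneratorModel, TrainConfig]:
    """Recover the generator (and its study conditions) from a checkpoint."""
    trainer = _Trainer.load(path)
    return trainer.generator, trainer.config
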