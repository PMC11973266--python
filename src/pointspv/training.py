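"""Joint optimization of the encoder and blind unit.

The training objective combines two terms:

* perceptual loss ``L_P``: squared L2 difference between the sighted
  unit's features of the background-free patch and the blind unit's
  features of the rendered phosphene frame, normalized by the feature
  element count W*H*C (a feature-matching loss);
* cross-entropy ``L_CE`` of the blind classifier's prediction against the
  ground-truth object class.

They are blended as ``L = gamma * L_P + (1 - gamma) * L_CE`` with
``gamma = 0.75`` by default.  Gradient routing follows the model's
training contract:

* encoder and blind feature-extractor parameters receive gradients of the
  blended loss ``L``;
* blind classifier parameters receive gradients of ``L_CE`` alone
  (unweighted);
* sighted parameters receive no gradients at all.

The high-level interface is a model object: ``PointSPV(train, val).fit()``
returns a :class:`PointSPVResults` carrying per-epoch loss records, the
trained units, the best-validation checkpoint and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import recognition as rec
from . import simulator as sim
from .encoder import (ActivationMap, Encoder, EncoderConfig, encode,
                      encode_for_training, init_encoder)
from .nn import autograd as ag
from .nn.optim import Adam
from .recognition import BlindUnit, FeatureMap, SightedUnit
from .sampling import PatchPair
from .simulator import SimulatorConfig


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters of a training run (all exposed; seeds included)."""

    gamma: float = 0.75
    split_index: int | None = None      # None -> the backbone's default
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 5
    pretrain_epochs: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0,1]")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch_size")


@dataclass
class LossRecord:
    """One epoch's (or step's) loss bookkeeping; satisfies the blending
    identity L = gamma*L_P + (1-gamma)*L_CE."""

    epoch: int
    L_P: float
    L_CE: float
    L: float
    val_accuracy: float | None = None


# ---------------------------------------------------------------------------
# loss primitives
# ---------------------------------------------------------------------------

def perceptual_loss(feat_sighted, feat_blind) -> float:
    """Feature-matching loss: sum((s-b)^2) / (W*H*C).

    Accepts FeatureMap objects or plain arrays of identical shape; zero iff
    the inputs are equal.
    """
    a = np.asarray(getattr(feat_sighted, "values", feat_sighted), dtype=np.float64)
    b = np.asarray(getattr(feat_blind, "values", feat_blind), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"feature shapes differ: {a.shape} vs {b.shape}")
    d = a - b
    return float((d * d).sum() / d.size)


def combined_loss(L_P: float, L_CE: float, gamma: float = 0.75) -> float:
    """Weighted blend gamma*L_P + (1-gamma)*L_CE."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0,1]")
    if not (math.isfinite(L_P) and math.isfinite(L_CE)):
        raise ValueError("losses must be finite")
    return gamma * L_P + (1.0 - gamma) * L_CE


def collate(pairs: list[PatchPair]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack patch pairs into (patches, patches_no_bg, labels) arrays."""
    if len(pairs) == 0:
        raise ValueError("empty batch")
    patches = np.stack([p.patch.pixels for p in pairs])
    nobg = np.stack([p.patch_no_bg.pixels for p in pairs])
    labels = np.array([p.label for p in pairs], dtype=np.int64)
    return patches, nobg, labels


# ---------------------------------------------------------------------------
# one optimization step with gradient routing
# ---------------------------------------------------------------------------

def train_step(encoder: Encoder, blind: BlindUnit, sighted: SightedUnit,
               batch, config: LossConfig = LossConfig(),
               sim_config: SimulatorConfig | None = None,
               optimizer: Adam | None = None,
               sighted_feats: np.ndarray | None = None) -> LossRecord:
    """Run one routed optimizer step on a batch.

    ``batch`` is a list of PatchPair or a (patches, patches_no_bg, labels)
    tuple.  ``sighted_feats`` may carry precomputed frozen reference
    features (the sighted unit is fixed, so they are cacheable).  When
    ``optimizer`` is None the gradients are computed and left on the
    parameters without updating them.
    """
    if isinstance(batch, (list, tuple)) and len(batch) == 3 and isinstance(batch[0], np.ndarray):
        patches, nobg, labels = batch
    else:
        patches, nobg, labels = collate(list(batch))
    if patches.shape[0] == 0:
        raise ValueError("empty batch")
    if sim_config is None:
        sim_config = SimulatorConfig(frame_size=blind.frame_size,
                                     grid_size=encoder.config.grid_size)

    gamma = config.gamma
    hard, _soft = encode_for_training(encoder, patches)
    frames = sim.simulate_tensor(hard, sim_config)
    if sighted_feats is None:
        sfeats = rec.sighted_features_tensor(sighted, nobg)
    else:
        sfeats = ag.Tensor(sighted_feats)
    bfeats, logits = rec.blind_forward_tensor(blind, frames)
    L_P = ag.feature_mse(sfeats, bfeats)
    L_CE = ag.cross_entropy_logits(logits, labels)

    enc_params = list(encoder.parameters())
    ext_params = list(blind.extractor.parameters())
    cls_params = list(blind.classifier.parameters())
    for p in enc_params + ext_params + cls_params:
        p.zero_grad()

    if gamma == 1.0:
        # blended loss degenerates to L_P for encoder/extractor, but the
        # classifier still learns from the (unweighted) cross-entropy
        L_P.backward()
        stash = [None if p.grad is None else p.grad.copy() for p in enc_params + ext_params]
        L_CE.backward()
        for p, g in zip(enc_params + ext_params, stash):
            p.grad = g
    else:
        total = ag.add(ag.mul(L_P, gamma), ag.mul(L_CE, 1.0 - gamma))
        total.backward()
        # classifier gradients must be pure dL_CE, not (1-gamma)*dL_CE
        scale = 1.0 / (1.0 - gamma)
        for p in cls_params:
            if p.grad is not None:
                p.grad *= scale

    if optimizer is not None:
        optimizer.step()

    lp = float(L_P.data)
    lce = float(L_CE.data)
    return LossRecord(epoch=0, L_P=lp, L_CE=lce, L=combined_loss(lp, lce, gamma))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(encoder: Encoder, blind: BlindUnit, pairs: list[PatchPair],
             sim_config: SimulatorConfig | None = None,
             batch_size: int = 32) -> float:
    """Fraction of patches whose phosphene rendering is classified
    correctly: argmax(classify(simulate(encode(patch)))) == label."""
    if len(pairs) == 0:
        raise ValueError("cannot evaluate on an empty set")
    if sim_config is None:
        sim_config = SimulatorConfig(frame_size=blind.frame_size,
                                     grid_size=encoder.config.grid_size)
    patches, _, labels = collate(pairs)
    enc_training = encoder.training
    blind_training = blind.extractor.training
    encoder.eval()
    blind.eval()
    n_correct = 0
    try:
        with ag.no_grad():
            for i in range(0, len(pairs), batch_size):
                chunk = patches[i:i + batch_size]
                hard, _ = encode_for_training(encoder, chunk)
                frames = sim.simulate_tensor(hard, sim_config)
                _, logits = rec.blind_forward_tensor(blind, frames)
                n_correct += int((logits.data.argmax(axis=1) == labels[i:i + batch_size]).sum())
    finally:
        encoder.train(enc_training)
        blind.train(blind_training)
    return n_correct / len(pairs)


def _silhouette_frames(nobg: np.ndarray, sim_config: SimulatorConfig) -> np.ndarray:
    """Phosphene renderings of the object silhouettes in background-free
    patches: the mask (nonzero pixels) is max-pooled onto the electrode
    grid and rendered by the simulator.  Used only for backbone
    pretraining, as a stand-in for broad exposure to dot-pattern stimuli."""
    g = sim_config.grid_size
    n, p = nobg.shape[0], nobg.shape[1]
    masks = nobg.any(axis=3).astype(np.float64)
    frames = np.empty((n, sim_config.frame_size, sim_config.frame_size))
    edges = (np.arange(p) * g) // p
    for i in range(n):
        grid = np.zeros((g, g))
        np.maximum.at(grid, (edges[:, None].repeat(p, 1), edges[None, :].repeat(p, 0)),
                      masks[i])
        frames[i] = sim.simulate(grid, sim_config).pixels
    return frames


def pretrain_backbone(backbone: rec.Backbone, pairs: list[PatchPair],
                      frame_size: int, epochs: int = 2, lr: float = 1e-3,
                      batch_size: int = 16, rng_seed: int = 0,
                      sim_config: SimulatorConfig | None = None) -> None:
    """Train the full backbone on clean patches and silhouette dot frames.

    Stands in for large-scale pretraining of the recognition backbone: the
    sighted unit's frozen features and the blind unit's starting point
    both come from this classifier.  Half of each batch shows the clean
    background-free patch, half its silhouette rendered as a phosphene
    frame, so the feature space covers both input domains before joint
    training (which then mostly has to teach the encoder).
    """
    _, nobg, labels = collate(pairs)
    rng = np.random.default_rng(rng_seed)
    opt = Adam(backbone.parameters(), lr=lr)
    xs_clean = rec.prepare_patch_batch(nobg, frame_size).data
    if sim_config is not None:
        dots = _silhouette_frames(nobg, sim_config)
        xs_dots = rec.prepare_blind_frames_np(dots, frame_size)
    else:
        xs_dots = xs_clean
    backbone.train()
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for i in range(0, len(pairs), batch_size):
            idx = order[i:i + batch_size]
            if len(idx) < 2:
                continue  # batchnorm needs > 1 sample
            use_dots = rng.random(len(idx)) < 0.5
            xb = np.where(use_dots[:, None, None, None], xs_dots[idx], xs_clean[idx])
            loss = ag.cross_entropy_logits(backbone(ag.Tensor(xb)), labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    backbone.eval()


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class PointSPV:
    """End-to-end phosphene-encoding model bound to a patch dataset.

    Parameters
    ----------
    train_pairs, val_pairs : lists of PatchPair (patch + background-free
        twin + label), e.g. from ``sampling.build_patch_dataset``.
    n_classes : number of object categories.
    encoder_config, sim_config : geometry of the encoder and simulator;
        defaults are the full-scale 32x32 grid / 256x256 frame.
    backbone : registered backbone name (default the 8-stage surrogate).
    config : LossConfig with the optimization hyperparameters.
    """

    def __init__(self, train_pairs: list[PatchPair], val_pairs: list[PatchPair],
                 n_classes: int = 2,
                 encoder_config: EncoderConfig | None = None,
                 sim_config: SimulatorConfig | None = None,
                 backbone: str = "surrogate",
                 config: LossConfig = LossConfig()):
        if len(train_pairs) == 0 or len(val_pairs) == 0:
            raise ValueError("train and validation sets must be nonempty")
        self.train_pairs = train_pairs
        self.val_pairs = val_pairs
        self.n_classes = n_classes
        self.encoder_config = encoder_config or EncoderConfig()
        self.sim_config = sim_config or SimulatorConfig(
            grid_size=self.encoder_config.grid_size,
            frame_size=self.encoder_config.grid_size * 8)
        if self.sim_config.grid_size != self.encoder_config.grid_size:
            raise ValueError("simulator and encoder grid sizes must agree")
        self.backbone_name = backbone
        self.config = config

    @classmethod
    def from_scenes(cls, scenes, points_per_object: int = 5,
                    split_fraction: float = 0.8, patch_size: int | None = None,
                    rng_seed: int = 0, **kwargs) -> "PointSPV":
        """Build the model straight from segmented scenes."""
        from .sampling import build_patch_dataset
        enc_cfg = kwargs.get("encoder_config") or EncoderConfig()
        train, val = build_patch_dataset(
            scenes, points_per_object=points_per_object,
            split_fraction=split_fraction,
            rng=np.random.default_rng(rng_seed),
            patch_size=patch_size or enc_cfg.patch_size)
        n_classes = len({p.label for p in train} | {p.label for p in val})
        return cls(train, val, n_classes=max(n_classes, 2), **kwargs)

    def fit(self, verbose: bool = False) -> "PointSPVResults":
        cfg = self.config
        encoder = init_encoder(self.encoder_config, rng_seed=cfg.rng_seed)
        backbone = rec.make_backbone(self.backbone_name, n_classes=self.n_classes,
                                     rng_seed=cfg.rng_seed + 1)
        frame_size = self.sim_config.frame_size
        if cfg.pretrain_epochs > 0:
            pretrain_backbone(backbone, self.train_pairs, frame_size,
                              epochs=cfg.pretrain_epochs,
                              lr=max(cfg.learning_rate, 1e-3),
                              batch_size=cfg.batch_size, rng_seed=cfg.rng_seed + 2,
                              sim_config=self.sim_config)
        blind, sighted = rec.make_units(backbone, cfg.split_index, frame_size)
        sighted_before = {k: v.copy() for k, v in sighted.extractor.state_dict().items()}

        patches, nobg, labels = collate(self.train_pairs)
        # the sighted unit is frozen, so its reference features are computed once
        sfeats = []
        for i in range(0, len(labels), 32):
            sfeats.append(rec.sighted_features_tensor(sighted, nobg[i:i + 32]).data)
        sfeats = np.concatenate(sfeats, axis=0)

        params = list(encoder.parameters()) + list(blind.parameters())
        optimizer = Adam(params, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.rng_seed + 3)

        records: list[LossRecord] = []
        best = (-1.0, None)
        encoder.train()
        blind.train()
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(len(labels))
            lps, lces, ns = [], [], []
            for i in range(0, len(labels), cfg.batch_size):
                idx = order[i:i + cfg.batch_size]
                if len(idx) < 2:
                    continue
                step = train_step(encoder, blind, sighted,
                                  (patches[idx], nobg[idx], labels[idx]),
                                  cfg, self.sim_config, optimizer,
                                  sighted_feats=sfeats[idx])
                if not (math.isfinite(step.L_P) and math.isfinite(step.L_CE)):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: "
                        f"L_P={step.L_P}, L_CE={step.L_CE}")
                lps.append(step.L_P)
                lces.append(step.L_CE)
                ns.append(len(idx))
            w = np.array(ns, dtype=np.float64)
            lp = float(np.average(lps, weights=w))
            lce = float(np.average(lces, weights=w))
            acc = evaluate(encoder, blind, self.val_pairs, self.sim_config)
            records.append(LossRecord(epoch=epoch, L_P=lp, L_CE=lce,
                                      L=combined_loss(lp, lce, cfg.gamma),
                                      val_accuracy=acc))
            if acc > best[0]:
                best = (acc, {"encoder": encoder.state_dict(),
                              "extractor": blind.extractor.state_dict(),
                              "classifier": blind.classifier.state_dict()})
            if verbose:  # pragma: no cover
                print(f"epoch {epoch}: L_P={lp:.4f} L_CE={lce:.4f} val_acc={acc:.3f}")
        encoder.eval()
        blind.eval()

        sighted_after = sighted.extractor.state_dict()
        assert all(np.array_equal(sighted_before[k], sighted_after[k])
                   for k in sighted_before), "sighted unit drifted during training"
        return PointSPVResults(model=self, encoder=encoder, blind=blind,
                               sighted=sighted, records=records,
                               best_state=best[1], best_val_accuracy=max(best[0], 0.0))


class PointSPVResults:
    """Fitted pipeline: trained units, per-epoch records, best checkpoint."""

    def __init__(self, model: PointSPV, encoder: Encoder, blind: BlindUnit,
                 sighted: SightedUnit, records: list[LossRecord],
                 best_state: dict | None, best_val_accuracy: float):
        self.model = model
        self.encoder = encoder
        self.blind = blind
        self.sighted = sighted
        self.records = records
        self.best_state = best_state
        self.best_val_accuracy = best_val_accuracy

    @property
    def val_accuracy(self) -> float | None:
        return self.records[-1].val_accuracy if self.records else None

    def restore_best(self) -> None:
        """Load the best-validation checkpoint into the live units."""
        if self.best_state is None:
            return
        self.encoder.load_state_dict(self.best_state["encoder"])
        self.blind.extractor.load_state_dict(self.best_state["extractor"])
        self.blind.classifier.load_state_dict(self.best_state["classifier"])

    def evaluate(self, pairs: list[PatchPair] | None = None) -> float:
        return evaluate(self.encoder, self.blind,
                        pairs if pairs is not None else self.model.val_pairs,
                        self.model.sim_config)

    def predict(self, patch) -> np.ndarray:
        """Class probabilities for one viewing patch via the full pipeline."""
        amap = encode(self.encoder, patch)
        frame = sim.simulate(amap, self.model.sim_config)
        return rec.classify(self.blind, frame)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Point-SPV training results",
            "=" * 62,
            f"gamma {cfg.gamma:<6} lr {cfg.learning_rate:<8} batch {cfg.batch_size:<4} "
            f"epochs {cfg.epochs:<3} seed {cfg.rng_seed}",
            f"grid {self.encoder.config.grid_size}x{self.encoder.config.grid_size}  "
            f"frame {self.model.sim_config.frame_size}  "
            f"classes {self.model.n_classes}  "
            f"train/val {len(self.model.train_pairs)}/{len(self.model.val_pairs)}",
            "-" * 62,
            f"{'epoch':>5} {'L_P':>10} {'L_CE':>10} {'L':>10} {'val_acc':>8}",
        ]
        for r in self.records:
            lines.append(f"{r.epoch:>5} {r.L_P:>10.4f} {r.L_CE:>10.4f} "
                         f"{r.L:>10.4f} {r.val_accuracy:>8.3f}")
        lines.append("-" * 62)
        lines.append(f"best validation accuracy: {self.best_val_accuracy:.3f}")
        return "\n".join(lines)


def train(train_pairs: list[PatchPair], val_pairs: list[PatchPair],
          config: LossConfig = LossConfig(), **kwargs
          ) -> tuple[tuple[Encoder, BlindUnit, SightedUnit], list[LossRecord]]:
    """Functional wrapper: fit a PointSPV model, return units and records."""
    res = PointSPV(train_pairs, val_pairs, config=config, **kwargs).fit()
    return (res.encoder, res.blind, res.sighted), res.records


def desk_scale_configs(rng_seed: int = 0) -> tuple[EncoderConfig, SimulatorConfig, LossConfig]:
    """The scaled-down study configuration used for CPU-scale experiments:
    64 px patches, an 8x8 electrode grid rendered into 64x64 frames, and a
    short Adam schedule with brief backbone pretraining."""
    return (EncoderConfig(patch_size=64, internal_size=64, grid_size=8),
            SimulatorConfig(frame_size=64, grid_size=8),
            LossConfig(gamma=0.75, learning_rate=1e-3, batch_size=4,
                       epochs=5, pretrain_epochs=25, rng_seed=rng_seed))
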