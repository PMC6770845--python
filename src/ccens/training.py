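"""Two-stage freeze/transfer training.

Stage 1 (*feature* stage) fits a branch as an autoencoder against its
feature label — the density branch against dot density maps, the mask
branch against foreground masks — with Adam/MSE. Stage 2 (*regression*
stage) freezes the branch weights and fits only the VGG tail against the
integer cell counts on the combined training set. The ensembled model
reuses both previously trained branches (weight transfer), freezes them,
and trains its two-channel tail the same way.

Documented full-scale defaults are 192 epochs / batch 16 for the feature
stage and 1000 epochs for the regression stage; every setting scales
down for desk-size experiments via :class:`TrainingConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import h5py
import numpy as np

from . import _nn
from .models import (ArchitectureConfig, NetworkHandle, build_model,
                     forward_features)
from .simdata import SyntheticDataset

__all__ = ["TrainingConfig", "DatasetSplit", "StageResult",
           "BranchWeightsMissingError", "make_split", "train_feature_stage",
           "freeze", "train_regression_stage", "train_full", "save_model",
           "load_model", "desk_benchmark", "DEFAULT_FEATURE_CONFIG",
           "DEFAULT_REGRESSION_CONFIG"]

logger = logging.getLogger("ccens")


class BranchWeightsMissingError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    epochs: int
    batch_size: int = 16
    optimizer: str = "adam"
    loss: str = "mse"
    learning_rate: float = 1e-3
    seed: int = 0
    freeze: tuple = ()

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "mse":
            raise ValueError("only the mse loss is supported")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


#: documented full-scale settings for the two stages
DEFAULT_FEATURE_CONFIG = TrainingConfig(epochs=192, batch_size=16)
DEFAULT_REGRESSION_CONFIG = TrainingConfig(epochs=1000, batch_size=16)


@dataclasses.dataclass
class DatasetSplit:
    """S1 (dot-corpus train), S2 (mask-corpus train), T (common test)."""

    S1: SyntheticDataset
    S2: SyntheticDataset
    T: SyntheticDataset

    def combined_images(self):
        return np.concatenate([self.S1.images(), self.S2.images()])

    def combined_counts(self):
        return np.concatenate([self.S1.counts(), self.S2.counts()])


@dataclasses.dataclass
class StageResult:
    model: NetworkHandle
    loss_history: list
    stage: str            # "feature" or "regression"
    config: TrainingConfig


def make_split(dot_corpus: SyntheticDataset, mask_corpus: SyntheticDataset,
               n_test_each: int, seed: int = 0) -> DatasetSplit:
    """Randomly hold out ``n_test_each`` samples from each corpus into a
    common test set; everything else forms the per-branch training sets.
    The regression stage trains on the union S1 + S2."""
    if n_test_each < 1:
        raise ValueError("n_test_each must be >= 1")
    for corpus in (dot_corpus, mask_corpus):
        if len(corpus) <= n_test_each:
            raise ValueError("corpus too small for the requested test size")
    rng = np.random.default_rng(seed)

    def split_one(corpus):
        idx = rng.permutation(len(corpus))
        test_idx = set(idx[:n_test_each].tolist())
        train = [s for i, s in enumerate(corpus.samples) if i not in test_idx]
        test = [corpus.samples[i] for i in sorted(test_idx)]
        return train, test

    tr1, te1 = split_one(dot_corpus)
    tr2, te2 = split_one(mask_corpus)
    s1 = SyntheticDataset(tr1, dot_corpus.config, name="S1")
    s2 = SyntheticDataset(tr2, mask_corpus.config, name="S2")
    t = SyntheticDataset(te1 + te2, dot_corpus.config, name="T")
    return DatasetSplit(S1=s1, S2=s2, T=t)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _trainable_params(handle: NetworkHandle):
    triples = []
    for name, module in handle.components.items():
        if handle.trainable.get(name, True):
            triples.extend(_nn.named_params(module, prefix=name + "/"))
    return triples


def _epoch_batches(n, batch_size, rng):
    perm = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield perm[i:i + batch_size]


def _check_finite(loss, stage):
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite loss in {stage} stage: {loss!r}; reduce the "
            "learning rate or inspect the inputs")


def train_feature_stage(branch: NetworkHandle, inputs, targets,
                        config: TrainingConfig) -> StageResult:
    """Fit one branch as an autoencoder against its feature label."""
    names = branch.branch_names()
    if len(names) != 1:
        raise ValueError("feature stage expects a handle with exactly one branch")
    module = branch.components[names[0]]
    x = np.asarray(inputs, dtype=_nn.DTYPE)[..., None]
    y = np.asarray(targets, dtype=_nn.DTYPE)[..., None]
    if x.shape != y.shape:
        raise ValueError("inputs and targets must be aligned and shape-matched")
    rng = np.random.default_rng(config.seed)
    _nn.set_dropout_rng(module, rng)
    opt = _nn.Adam(lr=config.learning_rate)
    triples = _nn.named_params(module, prefix=names[0] + "/")
    history = []
    for _ in range(config.epochs):
        losses, sizes = [], []
        for idx in _epoch_batches(len(x), config.batch_size, rng):
            pred = module.forward(x[idx], training=True)
            loss, dy = _nn.mse_loss(pred, y[idx])
            _check_finite(loss, "feature")
            module.backward(dy)
            opt.step(triples)
            losses.append(loss)
            sizes.append(len(idx))
        history.append(float(np.average(losses, weights=sizes)))
    return StageResult(model=branch, loss_history=history, stage="feature",
                       config=config)


def freeze(model: NetworkHandle, components) -> NetworkHandle:
    """Mark components untrainable; their weights (and batch-norm
    statistics) stay bit-identical through any later training step."""
    for name in components:
        if name not in model.components:
            raise ValueError(f"unknown component {name!r}; "
                             f"have {sorted(model.components)}")
        model.trainable[name] = False
    return model


def train_regression_stage(model: NetworkHandle, images, counts,
                           config: TrainingConfig) -> StageResult:
    """Fit the tail (and any unfrozen branch) against integer counts.

    When every branch is frozen — the canonical procedure — the decoded
    branch maps are computed once in eval mode and the tail is trained on
    the cached features; this is exactly equivalent to backpropagating
    through a frozen branch and much cheaper.
    """
    if "tail" not in model.components:
        raise ValueError(f"{model.kind} has no regression tail to train")
    counts = np.asarray(counts, dtype=_nn.DTYPE)
    if counts.ndim != 1 or not np.isfinite(counts).all() or (counts < 0).any():
        raise ValueError("counts must be a finite non-negative vector")
    for name in config.freeze:
        freeze(model, [name])
    unfrozen = [n for n in model.branch_names() if model.trainable.get(n, True)]
    if unfrozen:
        logger.warning("regression stage with unfrozen branch(es) %s; the "
                       "canonical procedure freezes branch weights", unfrozen)
    x = np.asarray(images, dtype=_nn.DTYPE)[..., None]
    rng = np.random.default_rng(config.seed)
    tail = model.components["tail"]
    _nn.set_dropout_rng(tail, rng)
    opt = _nn.Adam(lr=config.learning_rate)
    history = []

    if not unfrozen:
        feats = _cached_features(model, x)
        triples = _nn.named_params(tail, prefix="tail/")
        for _ in range(config.epochs):
            losses, sizes = [], []
            for idx in _epoch_batches(len(x), config.batch_size, rng):
                pred = tail.forward(feats[idx], training=True)[:, 0]
                loss, dy = _nn.mse_loss(pred, counts[idx])
                _check_finite(loss, "regression")
                tail.backward(dy[:, None])
                opt.step(triples)
                losses.append(loss)
                sizes.append(len(idx))
            history.append(float(np.average(losses, weights=sizes)))
        _nn.reestimate_bn_stats(tail, feats, config.batch_size)
    else:
        triples = _trainable_params(model)
        for _ in range(config.epochs):
            losses, sizes = [], []
            for idx in _epoch_batches(len(x), config.batch_size, rng):
                feats = forward_features(model, x[idx], training=True)
                pred = tail.forward(feats, training=True)[:, 0]
                loss, dy = _nn.mse_loss(pred, counts[idx])
                _check_finite(loss, "regression")
                dfeat = tail.backward(dy[:, None])
                _backprop_branches(model, dfeat)
                opt.step(triples)
                losses.append(loss)
                sizes.append(len(idx))
            history.append(float(np.average(losses, weights=sizes)))
        _nn.reestimate_bn_stats(tail, _cached_features(model, x),
                                config.batch_size)
    return StageResult(model=model, loss_history=history, stage="regression",
                       config=config)


def _cached_features(model: NetworkHandle, x4, batch_size=16):
    outs = []
    for i in range(0, len(x4), batch_size):
        outs.append(forward_features(model, x4[i:i + batch_size],
                                     training=False))
    return np.concatenate(outs)


def _backprop_branches(model: NetworkHandle, dfeat):
    offset = 0
    for name in ("density_branch", "mask_branch"):
        if name not in model.components:
            continue
        d = dfeat[..., offset:offset + 1]
        offset += 1
        if model.trainable.get(name, True):
            model.components[name].backward(d)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def train_full(kind: str, split: DatasetSplit,
               stage1_cfg: TrainingConfig | None,
               stage2_cfg: TrainingConfig | None,
               arch: ArchitectureConfig | None = None,
               branches: dict | None = None) -> NetworkHandle:
    """Run the per-kind staging end to end.

    DRDCNN: feature stage on S1 (density maps), freeze, regression on
    S1+S2. FRDCNN: feature stage on S2 (masks), freeze, regression on
    S1+S2. ERDCNN: requires previously trained branch weights via
    ``branches`` (name -> weight dict or NetworkHandle); freezes both and
    trains the two-channel tail on S1+S2. DDCNN: feature stage on S1
    only, no regression. Passing ``branches`` for DRDCNN/FRDCNN/DDCNN
    transfers the branch weights and skips its feature stage.
    """
    if arch is None:
        h, w = split.S1.config.height, split.S1.config.width
        arch = ArchitectureConfig(input_height=h, input_width=w)
    model = build_model(kind, arch)
    model.stage_results = []

    supplied = _coerce_branches(branches)
    for name in model.branch_names():
        if name in supplied:
            _nn.set_weights(model.components[name], supplied[name],
                            prefix=name + "/")
            freeze(model, [name])

    if kind == "ERDCNN":
        missing = [n for n in model.branch_names() if n not in supplied]
        if missing:
            raise BranchWeightsMissingError(
                f"branch weights required for {missing}: train the DRDCNN "
                "and FRDCNN branches first and pass their weights")
    else:
        name = model.branch_names()[0]
        if name not in supplied:
            if stage1_cfg is None:
                raise ValueError("stage1_cfg required when no branch "
                                 "weights are supplied")
            if name == "density_branch":
                inputs, targets = split.S1.images(), split.S1.density_maps()
            else:
                inputs, targets = split.S2.images(), split.S2.masks()
            res = train_feature_stage(
                NetworkHandle(name, arch, {name: model.components[name]},
                              {name: True}),
                inputs, targets, stage1_cfg)
            model.stage_results.append(res)
            freeze(model, [name])

    if kind != "DDCNN":
        if stage2_cfg is None:
            raise ValueError("stage2_cfg required for regression models")
        res = train_regression_stage(model, split.combined_images(),
                                     split.combined_counts(), stage2_cfg)
        model.stage_results.append(res)
    return model


def _coerce_branches(branches):
    out = {}
    for name, val in (branches or {}).items():
        if isinstance(val, NetworkHandle):
            out[name] = _nn.get_weights(val.components[name], prefix=name + "/")
        elif isinstance(val, dict):
            out[name] = val
        else:
            raise TypeError("branch weights must be a NetworkHandle or a "
                            "weight dict")
    return out


# ---------------------------------------------------------------------------
# desk-scale end-to-end benchmark
# ---------------------------------------------------------------------------

def desk_benchmark(seed: int, n_train: int = 200, n_test: int = 50,
                   size: int = 96):
    """Train and evaluate all four models on an easy synthetic benchmark.

    One corpus carries both annotation types (96x96 scenes, counts
    uniform on [5, 50]); both branches train on the same ``n_train``
    scenes and each tail trains on them with the branch frozen, exactly
    as in the two-stage procedure, at reduced widths and epochs chosen
    to fit a single CPU. Returns ``{kind: MetricsReport}`` on the
    held-out ``n_test`` scenes.
    """
    from . import evaluation, models, preprocess, simdata

    scene = simdata.preset_config(
        "dot", height=size, width=size,
        count_law=simdata.DistSpec("uniform_int", low=5, high=50),
        cell_radius_law=simdata.DistSpec("uniform", low=2.0, high=4.0))
    ds = simdata.generate_dataset(scene, n_train + n_test, seed=seed)
    spec = preprocess.PreprocessSpec(target_height=size, target_width=size)
    ds = preprocess.harmonize(ds, spec)
    train = SyntheticDataset(ds.samples[:n_train], ds.config, name="train")
    test = SyntheticDataset(ds.samples[n_train:], ds.config, name="test")

    arch = ArchitectureConfig(input_height=size, input_width=size,
                              unet_depth=2, unet_base_filters=4,
                              ae_filters=(8, 8, 8),
                              tail_filters=(8, 12, 16, 16),
                              tail_dense_units=32, seed=seed)
    feat_cfg = TrainingConfig(epochs=16, batch_size=8, learning_rate=2e-3,
                              seed=seed + 1)
    reg_cfg = TrainingConfig(epochs=25, batch_size=8, learning_rate=2e-3,
                             seed=seed + 2)

    from .models import (build_density_branch, build_mask_branch, build_model,
                         NetworkHandle)

    unet = build_density_branch(arch, seed=seed)
    train_feature_stage(unet, train.images(), train.density_maps(), feat_cfg)
    ae = build_mask_branch(arch, seed=seed)
    train_feature_stage(ae, train.images(), train.masks().astype(float),
                        feat_cfg)

    reports = {}
    pairs = [("DRDCNN", {"density_branch": unet.components["density_branch"]}),
             ("FRDCNN", {"mask_branch": ae.components["mask_branch"]}),
             ("ERDCNN", {"density_branch": unet.components["density_branch"],
                         "mask_branch": ae.components["mask_branch"]})]
    for kind, parts in pairs:
        model = build_model(kind, arch, seed=seed + 3)
        for name, module in parts.items():
            model.components[name] = module
            freeze(model, [name])
        train_regression_stage(model, train.images(), train.counts(), reg_cfg)
        reports[kind] = evaluation.evaluate_model(model, test)
    ddcnn = NetworkHandle("DDCNN", arch,
                          {"density_branch": unet.components["density_branch"]},
                          {"density_branch": False})
    reports["DDCNN"] = evaluation.evaluate_model(ddcnn, test)
    return reports


# ---------------------------------------------------------------------------
# serialization: JSON descriptor + HDF5 weights
# ---------------------------------------------------------------------------

def save_model(handle: NetworkHandle, path) -> pathlib.Path:
    """Write ``model.json`` (architecture descriptor) and ``weights.h5``
    under ``path``; the round-trip is bit-exact."""
    out = pathlib.Path(path)
    out.mkdir(parents=True, exist_ok=True)
    desc = {
        "kind": handle.kind,
        "config": dataclasses.asdict(handle.config),
        "trainable": dict(handle.trainable),
    }
    (out / "model.json").write_text(json.dumps(desc, indent=2))
    with h5py.File(out / "weights.h5", "w") as fh:
        for name, arr in handle.get_weights().items():
            fh.create_dataset(name, data=arr)
    return out


def load_model(path) -> NetworkHandle:
    root = pathlib.Path(path)
    desc = json.loads((root / "model.json").read_text())
    cfg = dict(desc["config"])
    for key in ("ae_filters", "tail_filters"):
        cfg[key] = tuple(cfg[key])
    config = ArchitectureConfig(**cfg)
    kind = desc["kind"]
    if kind in ("density_branch", "mask_branch", "tail"):
        from .models import (build_density_branch, build_mask_branch,
                             build_regression_tail)
        builder = {"density_branch": build_density_branch,
                   "mask_branch": build_mask_branch,
                   "tail": build_regression_tail}[kind]
        handle = builder(config)
    else:
        handle = build_model(kind, config)
    with h5py.File(root / "weights.h5", "r") as fh:
        state = {}
        fh.visititems(lambda name, obj: state.__setitem__(name, obj[()])
                      if isinstance(obj, h5py.Dataset) else None)
    handle.set_weights(state)
    handle.trainable = dict(desc["trainable"])
    return handle
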