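"""Training loop, cross-validation folds and checkpointing.

The network is trained with Adam on the Focal Tversky loss for a fixed
number of epochs (default 25) over shuffled mini-batches; folds partition
samples at the whole-image level so no patch of a held-out image ever
reaches training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam
from .preprocess import AugmentConfig, PatchPair, augment_pair
from .unetr import LossParams, UNETR, UNETRConfig, build_unetr, focal_tversky_loss


@dataclass
class TrainConfig:
    epochs: int = 25
    batch_size: int = 8
    learning_rate: float = 1e-4
    loss: LossParams = field(default_factory=LossParams)
    seed: int = 0
    n_folds: int = 3

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")


def make_folds(
    sample_ids: list[str], n_folds: int, seed: int
) -> list[tuple[list[str], list[str]]]:
    """Whole-image k-fold split: ``[(train_ids, test_ids), ...]``.

    Test sets are disjoint, cover all ids, and differ in size by at most 1.
    """
    ids = list(sample_ids)
    if n_folds > len(ids):
        raise ValueError(f"cannot make {n_folds} folds from {len(ids)} samples")
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    test_sets = [shuffled[k::n_folds] for k in range(n_folds)]
    folds = []
    for test in test_sets:
        test_set = set(test)
        folds.append(([i for i in ids if i not in test_set], sorted(test)))
    return folds


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_model(
    patches: list[PatchPair],
    cfg: TrainConfig,
    net_cfg: UNETRConfig,
    augment: AugmentConfig | None = None,
    log=None,
) -> tuple[UNETR, list[float]]:
    """Train a UNETR on patch/mask pairs; returns the net and epoch losses.

    Runs exactly ``cfg.epochs`` passes over the data, recording the mean
    per-batch Focal Tversky loss of each epoch. With ``augment`` set, a
    fresh augmentation draw is applied to every patch in every epoch.
    Deterministic for a fixed ``cfg.seed`` under single-threaded numpy.
    """
    if not patches:
        raise ValueError("no training patches")
    rng = np.random.default_rng(cfg.seed)
    net = build_unetr(net_cfg, seed=int(rng.integers(2**31)))
    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    history: list[float] = []
    net.train(True)
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _batches(len(patches), cfg.batch_size, rng):
            batch = [patches[i] for i in idx]
            if augment is not None:
                batch = [augment_pair(p, augment, rng) for p in batch]
            x = np.stack([p.patch for p in batch]).transpose(0, 3, 1, 2)
            y = np.stack([p.mask for p in batch])[:, None].astype(float)
            opt.zero_grad()
            y_hat = net(x).sigmoid()
            loss = focal_tversky_loss(y, y_hat, cfg.loss)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite loss at epoch {epoch + 1}")
            loss.backward()
            opt.step()
            losses.append(value)
        history.append(float(np.mean(losses)))
        if log is not None:
            log(epoch + 1, history[-1])
    return net, history
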