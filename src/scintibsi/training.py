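"""Training loops for the two butterfly networks.

Both tasks use He-initialized weights and Adam. Skeleton segmentation
minimizes the generalized Dice loss (the sum of six GDL terms when deep
supervision is on) and selects the checkpoint with the best validation
mean Dice; hot-spot extraction minimizes the class-weighted softmax cross
entropy with random paired horizontal-flip augmentation and selects the
checkpoint with the fewest misclassified validation pixels.

The reference protocol trains with batch 6 for up to 1620 iterations
(step-size decay x0.1 at iteration 1350) for the skeleton task and batch
256 for up to 50000 iterations for hot spots; desk-scale schedules are
simply smaller instances of the same loop.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .losses import (DEFAULT_GDL_EPS, generalized_dice_grad_logits,
                     generalized_dice_loss, softmax,
                     weighted_softmax_cross_entropy,
                     weighted_softmax_cross_entropy_grad_logits)
from .networks import BtrflyNet

__all__ = ["OptimizerSchedule", "TrainingHistory", "he_initialize",
           "alpha_at", "apply_horizontal_flip", "train_skeleton",
           "train_hotspot"]


@dataclass
class OptimizerSchedule:
    """Adam parameters plus the iteration budget.

    The reference description's ``beta``/``gamma`` are Adam's ``beta1``/
    ``beta2``. ``alpha_decay_iteration`` of ``None`` disables step decay.
    """

    alpha: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    alpha_decay_iteration: int | None = None
    alpha_decay_factor: float = 0.1
    batch_size: int = 6
    max_iterations: int = 1620
    eval_every: int = 30
    seed: int = 0

    def __post_init__(self):
        if min(self.alpha, self.beta1, self.beta2, self.eps,
               self.alpha_decay_factor) <= 0:
            raise ValueError("schedule parameters must be positive")
        if self.batch_size <= 0 or self.max_iterations <= 0 or self.eval_every <= 0:
            raise ValueError("batch size and iteration counts must be positive")
        if (self.alpha_decay_iteration is not None
                and self.alpha_decay_iteration > self.max_iterations):
            raise ValueError("decay iteration must not exceed max iterations")


@dataclass
class TrainingHistory:
    losses: list = field(default_factory=list)           # optimized loss per iter
    output_gdl: list = field(default_factory=list)       # output-layer GDL per iter
    val_iterations: list = field(default_factory=list)
    val_metrics: list = field(default_factory=list)
    selected_iteration: int = 0
    selected_metric: float = float("nan")

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "loss", "output_gdl"])
            for i, (l, g) in enumerate(zip(self.losses, self.output_gdl), start=1):
                w.writerow([i, l, g])


def alpha_at(sched: OptimizerSchedule, iteration: int) -> float:
    """Step size in effect at a (1-based) iteration."""
    if (sched.alpha_decay_iteration is not None
            and iteration > sched.alpha_decay_iteration):
        return sched.alpha * sched.alpha_decay_factor
    return sched.alpha


def he_initialize(net: BtrflyNet, seed: int) -> BtrflyNet:
    """He initialization: zero-mean Gaussian weights with variance
    ``2/fan_in``; biases zero; batch-norm reset to identity."""
    rng = np.random.default_rng(seed)
    for mod in net.modules():
        if isinstance(mod, nn.Conv2d):
            cout, cin, k, _ = mod.weight.data.shape
            std = np.sqrt(2.0 / (cin * k * k))
            mod.weight.data = rng.normal(0.0, std, mod.weight.data.shape).astype(mod.weight.data.dtype)
            mod.bias.data = np.zeros_like(mod.bias.data)
        elif isinstance(mod, nn.Deconv2x2):
            cin = mod.weight.data.shape[0]
            std = np.sqrt(2.0 / cin)
            mod.weight.data = rng.normal(0.0, std, mod.weight.data.shape).astype(mod.weight.data.dtype)
            mod.bias.data = np.zeros_like(mod.bias.data)
        elif isinstance(mod, nn.BatchNorm2d):
            mod.gamma.data = np.ones_like(mod.gamma.data)
            mod.beta.data = np.zeros_like(mod.beta.data)
            mod.running_mean[...] = 0.0
            mod.running_var[...] = 1.0
    return net


def _onehot(labels: np.ndarray, C: int) -> np.ndarray:
    """Label maps ``(B, H, W)`` -> one-hot field ``(C, B*H*W)``."""
    flat = np.asarray(labels).ravel()
    t = np.zeros((C, flat.size))
    t[flat, np.arange(flat.size)] = 1.0
    return t


def _to_field(y: np.ndarray) -> np.ndarray:
    """Logits ``(B, C, H, W)`` -> ``(C, B*H*W)``."""
    B, C, H, W = y.shape
    return y.transpose(1, 0, 2, 3).reshape(C, B * H * W)


def _from_field(g: np.ndarray, shape: tuple) -> np.ndarray:
    B, C, H, W = shape
    return g.reshape(C, B, H, W).transpose(1, 0, 2, 3)


def apply_horizontal_flip(arrays: tuple[np.ndarray, ...], flip: np.ndarray
                          ) -> tuple[np.ndarray, ...]:
    """Mirror the selected batch entries of every array about the vertical
    axis (anterior and posterior views and their targets flip together)."""
    out = []
    for arr in arrays:
        arr = arr.copy()
        arr[flip] = arr[flip, :, ::-1]
        out.append(arr)
    return tuple(out)


def _forward_batch(net: BtrflyNet, ant: np.ndarray, post: np.ndarray):
    a = nn.Tensor(ant[:, None, :, :].astype(np.float64))
    p = nn.Tensor(post[:, None, :, :].astype(np.float64))
    return net.forward(a, p)


def train_skeleton(net: BtrflyNet, train_cases: list[dict], val_cases: list[dict],
                   sched: OptimizerSchedule, gdl_eps: float = DEFAULT_GDL_EPS,
                   log_path=None) -> tuple[BtrflyNet, TrainingHistory]:
    """Train on preprocessed whole-body pairs.

    Each case dict carries ``anterior``/``posterior`` (normalized rasters at
    the network input shape) and ``anterior_labels``/``posterior_labels``
    (per-pixel class maps). Deep supervision is used automatically when the
    network was built with it. Checkpoint selection maximizes the
    validation mean Dice over bone classes at the output layer.
    """
    if not val_cases:
        raise ValueError("empty validation set")
    if not train_cases:
        raise ValueError("empty training set")
    rng = np.random.default_rng(sched.seed)
    opt = nn.Adam(net.parameters(), alpha=sched.alpha, beta1=sched.beta1,
                  beta2=sched.beta2, eps=sched.eps)
    Ca = net.cfg.out_channels_anterior
    Cp = net.cfg.out_channels_posterior
    hist = TrainingHistory()
    best_metric, best_state, best_iter = -np.inf, None, 0

    for it in range(1, sched.max_iterations + 1):
        opt.alpha = alpha_at(sched, it)
        idx = rng.integers(len(train_cases), size=sched.batch_size)
        ant = np.stack([train_cases[i]["anterior"] for i in idx])
        post = np.stack([train_cases[i]["posterior"] for i in idx])
        t_ant = _onehot(np.stack([train_cases[i]["anterior_labels"] for i in idx]), Ca)
        t_post = _onehot(np.stack([train_cases[i]["posterior_labels"] for i in idx]), Cp)

        net.train()
        ya, yp, sides = _forward_batch(net, ant, post)
        out_gdl = 0.0
        total = 0.0
        heads = [(ya, t_ant, True), (yp, t_post, True)]
        if net.cfg.use_dsv:
            heads += [(sides[0], t_ant, False), (sides[1], t_ant, False),
                      (sides[2], t_post, False), (sides[3], t_post, False)]
        opt.zero_grad()
        pairs = []
        for y, t, is_output in heads:
            f = _to_field(y.data)
            loss = generalized_dice_loss(softmax(f, axis=0), t, gdl_eps)
            total += loss
            if is_output:
                out_gdl += loss
            g = generalized_dice_grad_logits(f, t, gdl_eps)
            pairs.append((y, _from_field(g, y.data.shape)))
        nn.gather_heads(pairs).backward(np.array(1.0))
        opt.step()
        hist.losses.append(float(total))
        hist.output_gdl.append(float(out_gdl))

        if it % sched.eval_every == 0 or it == sched.max_iterations:
            metric = _validation_mean_dice(net, val_cases)
            hist.val_iterations.append(it)
            hist.val_metrics.append(metric)
            if metric > best_metric:
                best_metric, best_iter = metric, it
                best_state = net.state_dict()

    hist.selected_iteration = best_iter
    hist.selected_metric = best_metric
    if best_state is not None:
        net.load_state_dict(best_state)
    if log_path is not None:
        hist.write_csv(log_path)
    return net, hist


def _validation_mean_dice(net: BtrflyNet, val_cases: list[dict]) -> float:
    """Mean Dice over bone classes (background excluded), both views."""
    net.eval()
    dices = []
    for case in val_cases:
        ya, yp, _ = _forward_batch(net, case["anterior"][None],
                                   case["posterior"][None])
        for y, labels in ((ya, case["anterior_labels"]),
                          (yp, case["posterior_labels"])):
            pred = np.argmax(y.data[0], axis=0)
            true = np.asarray(labels)
            for c in range(1, y.data.shape[1]):
                a, b = pred == c, true == c
                denom = a.sum() + b.sum()
                dices.append(1.0 if denom == 0 else 2.0 * (a & b).sum() / denom)
    return float(np.mean(dices))


def train_hotspot(net: BtrflyNet, train_patches: dict, val_patches: dict,
                  sched: OptimizerSchedule, flip_probability: float = 0.5,
                  log_path=None) -> tuple[BtrflyNet, TrainingHistory]:
    """Train on paired 64x64 patches with 3-class targets.

    ``train_patches``/``val_patches`` carry arrays ``anterior``/``posterior``
    ``(P, 64, 64)`` and ``anterior_labels``/``posterior_labels`` ``(P, 64, 64)``.
    Augmentation mirrors both views (and targets) together with the given
    probability. Checkpoint selection minimizes validation misclassified
    pixels (argmax rule).
    """
    P = len(train_patches["anterior"])
    if P == 0:
        raise ValueError("empty training patch set")
    if len(val_patches["anterior"]) == 0:
        raise ValueError("empty validation patch set")
    rng = np.random.default_rng(sched.seed)
    opt = nn.Adam(net.parameters(), alpha=sched.alpha, beta1=sched.beta1,
                  beta2=sched.beta2, eps=sched.eps)
    C = net.cfg.out_channels_anterior
    hist = TrainingHistory()
    best_metric, best_state, best_iter = np.inf, None, 0

    for it in range(1, sched.max_iterations + 1):
        opt.alpha = alpha_at(sched, it)
        idx = rng.integers(P, size=sched.batch_size)
        ant = train_patches["anterior"][idx]
        post = train_patches["posterior"][idx]
        la = train_patches["anterior_labels"][idx]
        lp = train_patches["posterior_labels"][idx]
        if flip_probability > 0:
            flip = rng.uniform(size=sched.batch_size) < flip_probability
            ant, post, la, lp = apply_horizontal_flip((ant, post, la, lp), flip)

        net.train()
        ya, yp, _ = _forward_batch(net, ant, post)
        opt.zero_grad()
        total = 0.0
        pairs = []
        for y, labels in ((ya, la), (yp, lp)):
            f = _to_field(y.data)
            t = _onehot(labels, C)
            total += weighted_softmax_cross_entropy(softmax(f, axis=0), t)
            g = weighted_softmax_cross_entropy_grad_logits(f, t)
            pairs.append((y, _from_field(g, y.data.shape)))
        nn.gather_heads(pairs).backward(np.array(1.0))
        opt.step()
        hist.losses.append(float(total))
        hist.output_gdl.append(float("nan"))

        if it % sched.eval_every == 0 or it == sched.max_iterations:
            metric = _validation_misclassified(net, val_patches)
            hist.val_iterations.append(it)
            hist.val_metrics.append(metric)
            if metric < best_metric:
                best_metric, best_iter = metric, it
                best_state = net.state_dict()

    hist.selected_iteration = best_iter
    hist.selected_metric = best_metric
    if best_state is not None:
        net.load_state_dict(best_state)
    if log_path is not None:
        hist.write_csv(log_path)
    return net, hist


def _validation_misclassified(net: BtrflyNet, val_patches: dict,
                              chunk: int = 64) -> int:
    """Total misclassified pixels on the validation patches (argmax rule)."""
    net.eval()
    wrong = 0
    P = len(val_patches["anterior"])
    for s in range(0, P, chunk):
        sl = slice(s, min(s + chunk, P))
        ya, yp, _ = _forward_batch(net, val_patches["anterior"][sl],
                                   val_patches["posterior"][sl])
        wrong += int((np.argmax(ya.data, axis=1)
                      != val_patches["anterior_labels"][sl]).sum())
        wrong += int((np.argmax(yp.data, axis=1)
                      != val_patches["posterior_labels"][sl]).sum())
    return wrong
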