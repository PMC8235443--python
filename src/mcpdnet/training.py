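"""End-to-end training, missing-modality inference, leave-one-pair-out
cross-validation, missing-data protocols, and metric reporting.

Training minimises alpha * (L_S + L_A) + beta * L_C + gamma * L_D with
Adam for a fixed number of epochs (default 5).  Variant semantics:

* ``MCPDNet``         - both VAEs, alignment loss on;
* ``VAE_noLD``        - both VAEs, gamma effectively 0;
* ``AE_LD`` / ``AE_noLD`` - deterministic bottlenecks (no sampling, no
  KL), with / without the alignment loss;
* ``Unimodal_Sil_VAE`` / ``Unimodal_Acl_VAE`` - one branch only.

At inference with a missing modality, the available branch's posterior
is sampled and the draw substitutes for the missing slot of the joint
representation, while the available slot carries the posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .losses import (
    LossBreakdown,
    LossWeights,
    classification_bce_t,
    cosine_distance_sq_t,
    kl_to_standard_normal_t,
    recon_sse_t,
    total_loss,
)
from .models import VARIANTS, MCPDNet, ModelConfig, Prediction, _clip_p
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Adam
from .preprocessing import PairedSample

__all__ = [
    "TrainConfig",
    "MissingScenario",
    "FoldResult",
    "CVResult",
    "MissingEvalResult",
    "TrainedModel",
    "train",
    "predict_full",
    "predict_missing",
    "impute_baseline",
    "run_cv",
    "run_missing_eval",
    "removal_mask",
    "compute_metrics",
    "mean_latent_cosine",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (5 epochs of Adam by default)."""

    epochs: int = 5
    learning_rate: float = 3e-3
    batch_size: int = 8
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    variant: str = "MCPDNet"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class MissingScenario:
    """A missing-modality evaluation protocol.

    ``fraction=0.5`` removes the named modality from an independent
    random half of the test samples in each of ``repeats`` repeats;
    ``fraction=1.0`` removes it everywhere (one pass).
    """

    missing_modality: str  # "silhouette" or "accelerometer"
    fraction: float = 1.0
    repeats: int = 1

    def __post_init__(self):
        if self.missing_modality not in ("silhouette", "accelerometer"):
            raise ValueError("missing_modality must be 'silhouette' or 'accelerometer'")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class FoldResult:
    """Per-fold predictions and metrics (PD is the positive class)."""

    held_out_pair: int
    y: np.ndarray
    p: np.ndarray
    c: np.ndarray
    precision: float
    recall: float
    f1: float


@dataclass
class CVResult:
    folds: list[FoldResult]
    precision: float  # macro averages over folds
    recall: float
    f1: float
    models: list["TrainedModel"]
    test_sets: list[list[PairedSample]]


@dataclass
class MissingEvalResult:
    rows: list[dict]  # fold, repeat, precision, recall, f1
    precision: float  # averaged over repeats within fold, then over folds
    recall: float
    f1: float


@dataclass
class TrainedModel:
    model: MCPDNet
    train_config: TrainConfig
    step_log: list[LossBreakdown]
    epoch_totals: list[float]  # mean total loss per epoch


def _stack_dataset(dataset: list[PairedSample], modalities: str):
    xs = xa = None
    if modalities in ("both", "sil"):
        xs = np.stack([s.sil.stack for s in dataset]).astype(np.float32)
    if modalities in ("both", "acc"):
        xa = np.stack([s.acc.window for s in dataset]).astype(np.float32)
    y = np.array([s.y for s in dataset], dtype=np.float32)
    return xs, xa, y


def train(
    dataset: list[PairedSample],
    cfg: TrainConfig,
    model_config: ModelConfig | None = None,
) -> TrainedModel:
    """Train a variant end-to-end on a paired dataset.

    Deterministic given ``(dataset, cfg, model_config)``: parameter
    initialisation, shuffling and posterior sampling all derive from
    ``cfg.seed``.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    labels = {s.y for s in dataset}
    if len(labels) < 2:
        raise ValueError(f"training requires both classes, got only label(s) {sorted(labels)}")
    variational, use_ld, modalities = VARIANTS[cfg.variant]
    if model_config is None:
        model_config = ModelConfig.from_sample(dataset[0], seed=cfg.seed)
    model = MCPDNet(model_config, cfg.variant)
    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    xs_all, xa_all, y_all = _stack_dataset(dataset, modalities)
    n = len(dataset)
    w = cfg.weights
    gamma_eff = w.gamma if (use_ld and modalities == "both") else 0.0

    step_log: list[LossBreakdown] = []
    epoch_totals: list[float] = []
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            yb = y_all[idx]
            opt.zero_grad()
            l_s = l_a = None
            mu_s = mu_a = None
            zero = Tensor(np.float32(0.0))
            if xs_all is not None:
                xb = xs_all[idx]
                mu_s, sig_s = model.encode_sil_t(Tensor(xb))
                z_s = _latent_draw(mu_s, sig_s, rng, variational)
                recon = model.sil_decoder(z_s)
                l_s = recon_sse_t(recon, xb)
                if variational:
                    l_s = l_s + kl_to_standard_normal_t(mu_s, sig_s)
            if xa_all is not None:
                ab = xa_all[idx]
                mu_a, sig_a = model.encode_acc_t(Tensor(ab))
                z_a = _latent_draw(mu_a, sig_a, rng, variational)
                recon = model.acc_decoder(z_a)
                l_a = recon_sse_t(recon, ab)
                if variational:
                    l_a = l_a + kl_to_standard_normal_t(mu_a, sig_a)
            if modalities == "both":
                r = ad.concat([mu_s, mu_a], axis=1)
            else:
                r = mu_s if mu_s is not None else mu_a
            logits = model.classify_joint_t(r)
            l_c = classification_bce_t(logits, yb)
            l_d = cosine_distance_sq_t(mu_a, mu_s) if modalities == "both" else zero
            l_s = l_s if l_s is not None else zero
            l_a = l_a if l_a is not None else zero
            loss = (
                w.alpha * (l_s + l_a) + w.beta * l_c + gamma_eff * l_d
            )
            loss.backward()
            opt.step()
            bd = total_loss(
                float(l_s.data),
                float(l_a.data),
                float(l_c.data),
                float(l_d.data),
                LossWeights(w.alpha, w.beta, gamma_eff),
            )
            step_log.append(bd)
            epoch_losses.append(bd.total)
        epoch_totals.append(float(np.mean(epoch_losses)))
    return TrainedModel(model=model, train_config=cfg, step_log=step_log, epoch_totals=epoch_totals)


def _latent_draw(mu: Tensor, sigma: Tensor, rng: np.random.Generator, variational: bool) -> Tensor:
    """Reparameterised draw z = mu + sigma * eps (AE variants: z = mu)."""
    if not variational:
        return mu
    eps = rng.standard_normal(mu.shape).astype(mu.data.dtype)
    return mu + sigma * Tensor(eps)


def predict_full(samples: list[PairedSample] | PairedSample, model: MCPDNet) -> list[Prediction]:
    """Classification from both (or, for unimodal variants, the one)
    present modality's posterior mean(s)."""
    single = isinstance(samples, PairedSample)
    batch = [samples] if single else list(samples)
    for s in batch:
        if model.modalities in ("both", "sil") and s.sil is None:
            raise ValueError("silhouette modality absent; use predict_missing")
        if model.modalities in ("both", "acc") and s.acc is None:
            raise ValueError("accelerometer modality absent; use predict_missing")
    xs, xa, _ = _stack_dataset(batch, model.modalities)
    parts = []
    if xs is not None:
        mu_s, _ = model.encode_sil_t(Tensor(xs))
        parts.append(mu_s.data)
    if xa is not None:
        mu_a, _ = model.encode_acc_t(Tensor(xa))
        parts.append(mu_a.data)
    r = np.concatenate(parts, axis=1).astype(np.float32)
    logits = model.classify_joint_t(Tensor(r)).data
    preds = [Prediction(p=_clip_p(p)) for p in expit(logits)]
    return preds


def predict_missing(
    sample: PairedSample,
    model: MCPDNet,
    seed_or_rng=0,
    n_draws: int = 1,
) -> Prediction:
    """Classification with one modality absent, by latent substitution.

    The available modality is encoded to (mu_N, sigma_N); a draw
    z_N ~ N(mu_N, sigma_N) fills the missing slot while the available
    slot carries mu_N, keeping the canonical (silhouette, accelerometer)
    order.  With ``n_draws > 1`` the probability is averaged over draws.
    """
    if model.modalities != "both":
        raise ValueError("predict_missing requires a bimodal model")
    if (sample.sil is None) == (sample.acc is None):
        raise ValueError("exactly one modality must be absent")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if sample.sil is None:
        g = model.acc_encode(sample.acc.window)
        order = "acc_available"
    else:
        g = model.sil_encode(sample.sil.stack)
        order = "sil_available"
    ps = []
    for _ in range(n_draws):
        z = g.mu + g.sigma * rng.standard_normal(g.mu.shape)
        if order == "acc_available":
            r = np.concatenate([z, g.mu])  # silhouette slot <- z, accel slot <- mu
        else:
            r = np.concatenate([g.mu, z])
        ps.append(model.classify_vector(r.astype(np.float32)).p)
    return Prediction(p=_clip_p(float(np.mean(ps))))


def impute_baseline(
    sample: PairedSample,
    model: MCPDNet,
    method: str,
    seed_or_rng=0,
) -> Prediction:
    """Reference strategies for the missing-modality comparison.

    ``AE_LD_copy`` (requires an ``AE_LD`` model): the available
    modality's deterministic embedding is copied into the missing slot.
    ``VAE_noLD_roundtrip`` (requires a ``VAE_noLD`` model): a standard
    normal draw is pushed through the missing modality's decoder and
    encoder and the resulting mean fills the missing slot.
    """
    if (sample.sil is None) == (sample.acc is None):
        raise ValueError("exactly one modality must be absent")
    if method == "AE_LD_copy":
        if model.variant != "AE_LD":
            raise ValueError(f"AE_LD_copy requires an AE_LD model, got {model.variant}")
    elif method == "VAE_noLD_roundtrip":
        if model.variant != "VAE_noLD":
            raise ValueError(f"VAE_noLD_roundtrip requires a VAE_noLD model, got {model.variant}")
    else:
        raise ValueError(f"unknown method {method!r}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    sil_missing = sample.sil is None
    g_avail = (
        model.acc_encode(sample.acc.window) if sil_missing else model.sil_encode(sample.sil.stack)
    )
    if method == "AE_LD_copy":
        fill = g_avail.mu
    else:
        z0 = rng.standard_normal(model.config.latent).astype(np.float32)
        if sil_missing:
            roundtrip = model.sil_encode(model.sil_decode(z0))
        else:
            roundtrip = model.acc_encode(model.acc_decode(z0))
        fill = roundtrip.mu
    if sil_missing:
        r = np.concatenate([fill, g_avail.mu])
    else:
        r = np.concatenate([g_avail.mu, fill])
    return model.classify_vector(r.astype(np.float32))


def compute_metrics(y, c) -> tuple[float, float, float]:
    """Precision, recall, F1 with PD (label 1) as the positive class.

    Zero-denominator cases are scored 0 by convention.
    """
    y = np.asarray(y, dtype=int)
    c = np.asarray(c, dtype=int)
    if y.size == 0:
        raise ValueError("cannot compute metrics on empty input")
    if y.shape != c.shape:
        raise ValueError("y and c must have equal length")
    tp = int(np.sum((y == 1) & (c == 1)))
    fp = int(np.sum((y == 0) & (c == 1)))
    fn = int(np.sum((y == 1) & (c == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def run_cv(
    dataset: list[PairedSample],
    cfg: TrainConfig,
    model_config: ModelConfig | None = None,
) -> CVResult:
    """Leave-one-pair-out cross-validation.

    One fold per pair id; the held-out pair (one PD + one HC subject)
    never contributes training samples.  Metrics are computed per fold
    and macro-averaged (arithmetic mean over folds, not pooled).
    """
    pair_ids = sorted({s.pair_id for s in dataset})
    if len(pair_ids) < 2:
        raise ValueError(f"leave-one-pair-out needs >= 2 pairs, got {len(pair_ids)}")
    folds: list[FoldResult] = []
    models: list[TrainedModel] = []
    test_sets: list[list[PairedSample]] = []
    for pair in pair_ids:
        train_set = [s for s in dataset if s.pair_id != pair]
        test_set = [s for s in dataset if s.pair_id == pair]
        trained = train(train_set, cfg, model_config)
        preds = predict_full(test_set, trained.model)
        y = np.array([s.y for s in test_set])
        p = np.array([pr.p for pr in preds])
        c = np.array([pr.c for pr in preds])
        precision, recall, f1 = compute_metrics(y, c)
        folds.append(FoldResult(pair, y, p, c, precision, recall, f1))
        models.append(trained)
        test_sets.append(test_set)
    return CVResult(
        folds=folds,
        precision=float(np.mean([f.precision for f in folds])),
        recall=float(np.mean([f.recall for f in folds])),
        f1=float(np.mean([f.f1 for f in folds])),
        models=models,
        test_sets=test_sets,
    )


def removal_mask(seed: int, fold: int, repeat: int, n: int, fraction: float) -> np.ndarray:
    """The reproducible boolean removal mask for one (fold, repeat)."""
    rng = np.random.default_rng([seed, fold, repeat])
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def run_missing_eval(
    cv: CVResult,
    scenario: MissingScenario,
    seed: int = 0,
    baseline_models: list["TrainedModel"] | None = None,
    baseline_method: str | None = None,
) -> MissingEvalResult:
    """Score trained folds under a missing-modality scenario.

    With ``fraction=1.0`` every test sample is scored by the latent
    substitution path; with ``fraction<1`` each repeat removes the named
    modality from a reproducible random subset and the remainder is
    scored with both modalities.  ``baseline_models``/``baseline_method``
    reroute the missing-sample predictions through
    :func:`impute_baseline` instead (for the reference strategies).
    """
    drop_sil = scenario.missing_modality == "silhouette"
    rows: list[dict] = []
    per_fold: list[tuple[float, float, float]] = []
    for fold_i, test_set in enumerate(cv.test_sets):
        model = cv.models[fold_i].model
        bmodel = baseline_models[fold_i].model if baseline_models is not None else None
        reps = []
        for repeat in range(scenario.repeats):
            n = len(test_set)
            if scenario.fraction >= 1.0:
                mask = np.ones(n, dtype=bool)
            else:
                mask = removal_mask(seed, fold_i, repeat, n, scenario.fraction)
            rng = np.random.default_rng([seed, fold_i, repeat, 7])
            c = np.empty(n, dtype=int)
            full_idx = np.flatnonzero(~mask)
            if full_idx.size:
                preds = predict_full([test_set[k] for k in full_idx], model)
                c[full_idx] = [pr.c for pr in preds]
            for k in np.flatnonzero(mask):
                s = test_set[k]
                reduced = PairedSample(
                    sil=None if drop_sil else s.sil,
                    acc=s.acc if drop_sil else None,
                    y=s.y,
                    subject_id=s.subject_id,
                    pair_id=s.pair_id,
                )
                if baseline_method is None:
                    c[k] = predict_missing(reduced, model, rng).c
                else:
                    c[k] = impute_baseline(reduced, bmodel, baseline_method, rng).c
            y = np.array([s.y for s in test_set])
            precision, recall, f1 = compute_metrics(y, c)
            rows.append(
                {
                    "fold": fold_i,
                    "repeat": repeat,
                    "precision": precision,
                    "recall": recall,
                    "f1": f1,
                }
            )
            reps.append((precision, recall, f1))
        per_fold.append(tuple(np.mean(reps, axis=0)))
    means = np.mean(per_fold, axis=0)
    return MissingEvalResult(
        rows=rows, precision=float(means[0]), recall=float(means[1]), f1=float(means[2])
    )


def mean_latent_cosine(model: MCPDNet, samples: list[PairedSample]) -> float:
    """Mean cosine similarity between the two posterior means over samples."""
    if model.modalities != "both":
        raise ValueError("latent cosine requires a bimodal model")
    xs, xa, _ = _stack_dataset(samples, "both")
    mu_s = model.encode_sil_t(Tensor(xs))[0].data
    mu_a = model.encode_acc_t(Tensor(xa))[0].data
    cos = (mu_s * mu_a).sum(axis=1) / (
        np.linalg.norm(mu_s, axis=1) * np.linalg.norm(mu_a, axis=1)
    )
    return float(cos.mean())
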