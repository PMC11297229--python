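"""Losses, optimization, hyperparameter search and cohort-wise cross-validation.

The evaluation protocol is leave-one-cohort-out: each cohort serves once as
the held-out test set while the remaining cohorts are pooled and split 75/25
into training and validation. Hyperparameters are chosen on the validation
split, and the winning configuration is retrained with ``n_seeds`` different
random seeds to expose the seed-dependence of both performance and
interpretation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import explained_variance_score, roc_auc_score

from .dataset import OmicsDataset
from .vnn_core import ModelState, NetworkEngine, NetworkSpec, init_output_bias, init_state

__all__ = [
    "HyperParams",
    "FoldResult",
    "CVResults",
    "InputPipeline",
    "weighted_bce",
    "mse_loss",
    "l1_term",
    "class_weights",
    "train",
    "cohort_cv",
    "evaluate",
    "default_grid",
]

# layers whose weights carry the sparsity penalty by default (when present):
# the combined gene layer and the gene->output weights; the CpG->gene layer can
# be penalized too via HyperParams.l1_layers
L1_LAYERS = ("gene", "output")

DEFAULT_LEARNING_RATES = (0.01, 0.001, 0.005, 0.0001)
DEFAULT_L1_LAMBDAS = (0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class HyperParams:
    """One grid point. ``omic_l1`` optionally adds (tag, strength) on top of
    the layer-wise penalty, applied only to edges carrying that omic tag."""

    learning_rate: float = 0.001
    l1_lambda: float = 0.001
    omic_l1: tuple[str, float] | None = None
    epochs: int = 100
    batch_size: int = 64
    patience: int = 10
    l1_layers: tuple[str, ...] = L1_LAYERS


def default_grid(epochs: int = 100, batch_size: int = 64, patience: int = 10):
    """The full learning-rate x L1 grid."""
    return [
        HyperParams(lr, lam, None, epochs, batch_size, patience)
        for lr, lam in itertools.product(DEFAULT_LEARNING_RATES, DEFAULT_L1_LAMBDAS)
    ]


# ---------------------------------------------------------------------------
# losses


def class_weights(y: np.ndarray) -> tuple[float, float]:
    """(w0, w1) inverse to class prevalence, normalized so w0*n0 + w1*n1 = n."""
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("training labels contain a single class; cannot weight BCE")
    n = len(y)
    return n / (2.0 * n0), n / (2.0 * n1)


def weighted_bce(
    y_true: np.ndarray, y_pred: np.ndarray, weights: tuple[float, float] | None = None
) -> float:
    """Class-weighted binary cross-entropy, mean over samples.

    With ``weights=None`` the weights are derived from ``y_true`` itself;
    balanced classes then reduce to the unweighted BCE.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.clip(np.asarray(y_pred, dtype=float), 1e-7, 1 - 1e-7)
    w0, w1 = class_weights(y) if weights is None else weights
    return float(-np.mean(w1 * y * np.log(p) + w0 * (1 - y) * np.log(1 - p)))


def mse_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    err = np.asarray(y_true, dtype=float) - np.asarray(y_pred, dtype=float)
    return float(np.mean(err**2))


def l1_term(state: ModelState, spec: NetworkSpec, lam: float, selector="penalized_layers") -> float:
    """lam * sum|w| over the selected edges.

    ``selector`` is ``"all"``, ``"penalized_layers"`` (the gene-level layers
    in :data:`L1_LAYERS`), ``("layers", [names])`` or ``("omic", tag)``.
    """
    return float(lam * sum(np.abs(w[m]).sum() for w, m in _l1_edge_masks(state, spec, selector)))


def _l1_edge_masks(state: ModelState, spec: NetworkSpec, selector):
    """Yield (weight_vector, boolean edge mask) pairs for a selector."""
    if selector == "all":
        names, tag = None, None
    elif selector == "penalized_layers":
        names, tag = [n for n in L1_LAYERS if any(l.name == n for l in spec.layers)], None
    elif isinstance(selector, tuple) and selector[0] == "layers":
        names, tag = list(selector[1]), None
    elif isinstance(selector, tuple) and selector[0] == "omic":
        names, tag = None, selector[1]
    else:
        raise ValueError(f"unknown L1 selector {selector!r}")
    for ly, w in zip(spec.layers, state.weights):
        if names is not None and ly.name not in names:
            continue
        if tag is None:
            yield w, np.ones(len(w), dtype=bool)
        elif ly.mask.tags is not None:
            sel = ly.mask.tags == tag
            if sel.any():
                yield w, sel


# ---------------------------------------------------------------------------
# input assembly / scaling


@dataclass
class InputPipeline:
    """Maps an OmicsDataset onto a spec's input blocks, with training-set scaling.

    Methylation betas are used raw (already in [0,1]); expression is
    optionally log1p-transformed and z-scored per gene with statistics from
    the training set only, so no information leaks from validation or test
    samples; covariates pass through unchanged.
    """

    spec: NetworkSpec
    scale_expression: bool = True
    log_expression: bool = True
    _stats: dict = field(default_factory=dict, repr=False)

    def fit(self, dataset: OmicsDataset) -> "InputPipeline":
        if "expression" in self.spec.input_blocks and self.scale_expression:
            X = dataset.expression[self.spec.block_features("expression")].to_numpy(float)
            if self.log_expression:
                X = np.log1p(X)
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            self._stats["expression"] = (mu, np.where(sd < 1e-8, 1.0, sd))
        return self

    def transform(self, dataset: OmicsDataset) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for block in self.spec.input_blocks:
            if block == "methylation":
                out[block] = dataset.methylation[self.spec.block_features(block)].to_numpy(float)
            elif block == "expression":
                X = dataset.expression[self.spec.block_features(block)].to_numpy(float)
                if self.scale_expression:
                    if "expression" not in self._stats:
                        raise RuntimeError("pipeline not fitted")
                    if self.log_expression:
                        X = np.log1p(X)
                    mu, sd = self._stats["expression"]
                    X = (X - mu) / sd
                out[block] = X
            elif block == "covariates":
                out[block] = dataset.covariates[self.spec.block_features(block)].to_numpy(float)
            elif block == "concat":
                feats = self.spec.block_features(block)
                both = dataset.methylation.join(dataset.expression)
                out[block] = both[feats].to_numpy(float)
            else:
                raise ValueError(f"unknown input block {block!r}")
        return out


# ---------------------------------------------------------------------------
# optimization


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _loss_and_dY(y: np.ndarray, yhat: np.ndarray, task: str, w: tuple[float, float]):
    n = len(y)
    if task == "classification":
        p = np.clip(yhat, 1e-7, 1 - 1e-7)
        w0, w1 = w
        loss = -np.mean(w1 * y * np.log(p) + w0 * (1 - y) * np.log(1 - p))
        dY = (-w1 * y / p + w0 * (1 - y) / (1 - p)) / n
    else:
        loss = np.mean((y - yhat) ** 2)
        dY = 2.0 * (yhat - y) / n
    return float(loss), dY


def train(
    spec: NetworkSpec,
    train_inputs: dict[str, np.ndarray],
    y_train: np.ndarray,
    hp: HyperParams,
    seed: int,
    val_inputs: dict[str, np.ndarray] | None = None,
    y_val: np.ndarray | None = None,
    engine: NetworkEngine | None = None,
) -> tuple[ModelState, TrainHistory]:
    """Minibatch Adam on the task loss plus L1, with early stopping.

    The output bias starts at the training-set phenotype mean; early stopping
    monitors the validation data loss with ``hp.patience`` epochs of grace and
    the best-validation-epoch parameters are returned. Without a validation
    set the final parameters are returned.
    """
    engine = engine or NetworkEngine(spec)
    y_train = np.asarray(y_train, dtype=float)
    rng = np.random.default_rng(seed)
    state = init_output_bias(init_state(spec, seed), y_train)
    theta = engine.pack(state)

    cw = class_weights(y_train) if spec.task == "classification" else (1.0, 1.0)

    # per-parameter L1 strength
    l1_vec = np.zeros(engine.n_params)
    dummy = engine.unpack(theta)
    for (w_sl, _), ly, w in zip(engine.slices, spec.layers, dummy.weights):
        if ly.name in hp.l1_layers:
            l1_vec[w_sl] = hp.l1_lambda
    if hp.omic_l1 is not None:
        tag, lam = hp.omic_l1
        for (w_sl, _), ly in zip(engine.slices, spec.layers):
            if ly.mask.tags is not None:
                sel = ly.mask.tags == tag
                if sel.any():
                    l1_vec[w_sl][sel] += lam  # view assignment on theta-sized vector
    has_val = val_inputs is not None and y_val is not None
    if has_val:
        y_val = np.asarray(y_val, dtype=float)

    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = len(y_train)
    history = TrainHistory()
    best_theta, best_val, since_best = theta.copy(), np.inf, 0

    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            batch = {k: X[idx] for k, X in train_inputs.items()}
            yhat, cache = engine.forward(theta, batch, cache=True)
            loss, dY = _loss_and_dY(y_train[idx], yhat, spec.task, cw)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}; aborting")
            grad = engine.backward(theta, cache, dY)
            grad += l1_vec * np.sign(theta)
            t += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            theta = theta - hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss * len(idx)
        history.train_loss.append(epoch_loss / n)

        if has_val:
            val_hat = engine.forward(theta, val_inputs)
            val_loss, _ = _loss_and_dY(y_val, val_hat, spec.task, cw)
            history.val_loss.append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val, best_theta, since_best = val_loss, theta.copy(), 0
                history.best_epoch = epoch
            else:
                since_best += 1
                if since_best >= hp.patience:
                    break
        else:
            best_theta = theta
            history.best_epoch = epoch

    final = engine.unpack(
        best_theta,
        metadata={
            "seed": int(seed),
            "hyperparams": hp.__dict__ | {"omic_l1": hp.omic_l1},
            "train_phenotype_mean": float(y_train.mean()),
        },
    )
    return final, history


def evaluate(y_true: np.ndarray, y_pred: np.ndarray, task: str) -> dict[str, float]:
    """AUC for classification; RMSE and explained variance for regression."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if task == "classification":
        return {"auc": float(roc_auc_score(y_true, y_pred))}
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return {"rmse": rmse, "explained_variance": float(explained_variance_score(y_true, y_pred))}


# ---------------------------------------------------------------------------
# cohort-wise cross-validation


@dataclass
class FoldResult:
    test_cohort: str
    best_hp: HyperParams
    seeds: list[int]
    val_metrics: list[dict[str, float]]
    test_metrics: list[dict[str, float]]
    states: list[ModelState]
    pipeline: InputPipeline
    train_samples: list[str]
    val_samples: list[str]
    test_samples: list[str]


@dataclass
class CVResults:
    folds: list[FoldResult]
    task: str

    def metric_name(self) -> str:
        return "auc" if self.task == "classification" else "rmse"

    def fold_means(self, metric: str | None = None, split: str = "test") -> np.ndarray:
        metric = metric or self.metric_name()
        return np.array(
            [
                np.mean([m[metric] for m in (f.test_metrics if split == "test" else f.val_metrics)])
                for f in self.folds
            ]
        )

    def aggregate(self, metric: str | None = None) -> dict[str, float]:
        """Mean with a normal-approximation 95% CI over fold means."""
        vals = self.fold_means(metric)
        mean = float(vals.mean())
        half = float(1.96 * vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        return {"mean": mean, "ci_low": mean - half, "ci_high": mean + half}


def _split_75_25(samples, rng) -> tuple[np.ndarray, np.ndarray]:
    n = len(samples)
    n_train = int(round(0.75 * n))
    perm = rng.permutation(n)
    return perm[:n_train], perm[n_train:]


def cohort_cv(
    spec_builder,
    dataset: OmicsDataset,
    grid: list[HyperParams] | None = None,
    n_seeds: int = 10,
    base_seed: int = 0,
    pipeline_options: dict | None = None,
) -> CVResults:
    """Leave-one-cohort-out CV with grid search and seed replication.

    For each fold: the held-out cohort is the test set; the pooled remainder
    is split 75/25 into train/validation with a fold-specific seeded RNG; the
    grid is searched on the validation metric (AUC maximized or RMSE
    minimized); the winning hyperparameters are retrained with
    ``base_seed + 0..n_seeds-1`` and each replicate is evaluated on the test
    cohort.
    """
    spec = spec_builder() if callable(spec_builder) else spec_builder
    grid = grid if grid is not None else default_grid()
    cohorts = sorted(dataset.cohort.unique())
    if len(cohorts) < 2:
        raise ValueError("cohort-wise CV needs at least two cohorts")
    engine = NetworkEngine(spec)
    folds: list[FoldResult] = []
    for fold_idx, test_cohort in enumerate(cohorts):
        is_test = (dataset.cohort == test_cohort).to_numpy()
        if is_test.sum() < 2:
            warnings.warn(f"cohort {test_cohort!r} has <2 samples; fold skipped", stacklevel=2)
            continue
        test_data = dataset.subset(np.where(is_test)[0])
        pool = dataset.subset(np.where(~is_test)[0])
        rng = np.random.default_rng([base_seed, fold_idx])
        tr_idx, va_idx = _split_75_25(pool.samples, rng)
        train_data, val_data = pool.subset(tr_idx), pool.subset(va_idx)

        pipe = InputPipeline(spec, **(pipeline_options or {})).fit(train_data)
        Xtr, Xva, Xte = (pipe.transform(d) for d in (train_data, val_data, test_data))
        ytr = train_data.phenotype.to_numpy(float)
        yva = val_data.phenotype.to_numpy(float)
        yte = test_data.phenotype.to_numpy(float)

        metric = "auc" if spec.task == "classification" else "rmse"
        sign = 1.0 if metric == "auc" else -1.0
        best_hp, best_score = None, -np.inf
        for hp in grid:
            st, _ = train(spec, Xtr, ytr, hp, base_seed, Xva, yva, engine=engine)
            score = sign * evaluate(yva, engine.predict(st, Xva), spec.task)[metric]
            if score > best_score:
                best_hp, best_score = hp, score

        seeds = [base_seed + s for s in range(n_seeds)]
        val_metrics, test_metrics, states = [], [], []
        for s in seeds:
            st, _ = train(spec, Xtr, ytr, best_hp, s, Xva, yva, engine=engine)
            val_metrics.append(evaluate(yva, engine.predict(st, Xva), spec.task))
            test_metrics.append(evaluate(yte, engine.predict(st, Xte), spec.task))
            states.append(st)
        folds.append(
            FoldResult(
                test_cohort=str(test_cohort),
                best_hp=best_hp,
                seeds=seeds,
                val_metrics=val_metrics,
                test_metrics=test_metrics,
                states=states,
                pipeline=pipe,
                train_samples=list(train_data.samples),
                val_samples=list(val_data.samples),
                test_samples=list(test_data.samples),
            )
        )
    return CVResults(folds=folds, task=spec.task)
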