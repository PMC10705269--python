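"""Baseline imputation methods: mean baselines and per-probe logistic regression.

The three mean baselines impute a combination mean sample as the
average of all training samples of the target species (ignoring
tissue), of the target tissue (ignoring species), or of the whole
training set.  The logistic baseline fits one L2-regularized logistic
regression per probe on the one-hot species/tissue labels, using a
soft-label scheme: every training row enters twice, once with label 1
weighted by its beta value and once with label 0 weighted by 1 - beta,
so the predicted positive-class probability is the methylation value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .data_model import (
    IMPUTED,
    Combo,
    CombinationGrid,
    LabelSpace,
    MethylationDataset,
    encode_labels,
)

# sklearn minimizes 0.5*||W||^2 + C * sum(losses); the loss written with an
# explicit lambda*||W||^2 penalty corresponds to C = 1 / (2*lambda).
_MAX_ITER = 10_000
_TOL = 1e-8

DEFAULT_LAMBDA_GRID = (1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass
class LogisticProbeModel:
    """One probe's logistic model: p = expit(X . W + c)."""

    weights: np.ndarray
    intercept: float
    lam: float

    def predict(self, y_onehot: np.ndarray) -> float | np.ndarray:
        y_onehot = np.asarray(y_onehot, float)
        return expit(y_onehot @ self.weights + self.intercept)


def species_baseline(train: MethylationDataset, species: str) -> np.ndarray:
    """Per-probe mean over all training samples of the species, any tissue."""
    mask = np.array([s == species for s in train.species])
    if not mask.any():
        raise ValueError(f"species {species!r} absent from training data")
    return train.beta[mask].mean(axis=0)


def tissue_baseline(train: MethylationDataset, tissue: str) -> np.ndarray:
    """Per-probe mean over all training samples of the tissue, any species."""
    mask = np.array([t == tissue for t in train.tissue])
    if not mask.any():
        raise ValueError(f"tissue {tissue!r} absent from training data")
    return train.beta[mask].mean(axis=0)


def global_baseline(train: MethylationDataset) -> np.ndarray:
    """Per-probe grand mean over every training sample."""
    if train.n_samples == 0:
        raise ValueError("training set is empty")
    return train.beta.mean(axis=0)


def mean_baseline_grid(
    train: MethylationDataset, targets: list[Combo], method: str
) -> CombinationGrid:
    """Impute all targets with one of the mean baselines
    (``species`` | ``tissue`` | ``global``)."""
    rows = []
    for s, t in targets:
        if method == "species":
            rows.append(species_baseline(train, s))
        elif method == "tissue":
            rows.append(tissue_baseline(train, t))
        elif method == "global":
            rows.append(global_baseline(train))
        else:
            raise ValueError(f"unknown mean baseline {method!r}")
    means = np.stack(rows) if rows else np.empty((0, train.n_probes))
    return CombinationGrid([tuple(t) for t in targets], means,
                           list(train.probe_ids), [IMPUTED] * len(targets))


def _duplicated_design(y_onehot: np.ndarray, beta_col: np.ndarray):
    """Soft-label duplication: each row twice, label 1 weighted by beta and
    label 0 weighted by 1 - beta."""
    x2 = np.vstack([y_onehot, y_onehot])
    labels = np.concatenate([np.ones(len(y_onehot)), np.zeros(len(y_onehot))])
    weights = np.concatenate([beta_col, 1.0 - beta_col])
    return x2, labels, weights


def fit_logistic_probe(
    train: MethylationDataset, space: LabelSpace, probe: int, lam: float
) -> LogisticProbeModel:
    """Fit one probe's logistic model by minimizing the weighted log loss
    plus lambda * ||W||^2 (intercept unpenalized)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    y_onehot = encode_labels(train, space)
    x2, labels, weights = _duplicated_design(y_onehot, train.beta[:, probe])
    clf = LogisticRegression(
        C=1.0 / (2.0 * max(lam, 1e-12)),
        solver="lbfgs",
        tol=_TOL,
        max_iter=_MAX_ITER,
        fit_intercept=True,
    )
    clf.fit(x2, labels, sample_weight=weights)
    if clf.n_iter_[0] >= _MAX_ITER:
        raise RuntimeError(f"logistic fit for probe index {probe} did not converge")
    return LogisticProbeModel(clf.coef_[0].copy(), float(clf.intercept_[0]), lam)


def logistic_baseline(
    train: MethylationDataset,
    space: LabelSpace,
    targets: list[Combo],
    lam: float,
) -> CombinationGrid:
    """Impute all targets by concatenating the per-probe model predictions.

    Probe models are independent, so the output is invariant to probe
    fitting order.
    """
    target_y = np.stack([space.encode_one(s, t) for s, t in targets]) if targets else \
        np.empty((0, space.width))
    means = np.empty((len(targets), train.n_probes))
    for j in range(train.n_probes):
        model = fit_logistic_probe(train, space, j, lam)
        means[:, j] = model.predict(target_y)
    return CombinationGrid([tuple(t) for t in targets], means,
                           list(train.probe_ids), [IMPUTED] * len(targets))


def tune_lambda(
    train: MethylationDataset,
    space: LabelSpace,
    validation_combos: CombinationGrid,
    grid=DEFAULT_LAMBDA_GRID,
) -> tuple[float, dict[float, float]]:
    """Pick the lambda whose imputed validation combos best correlate with
    the held-out means (mean sample-wise Pearson; ties -> smallest lambda)."""
    if not grid:
        raise ValueError("lambda grid is empty")
    scores: dict[float, float] = {}
    best_lam, best_score = None, -np.inf
    for lam in sorted(grid):
        imputed = logistic_baseline(train, space, validation_combos.combos, lam)
        cors = []
        for row_i, row_o in zip(imputed.means, validation_combos.means):
            if row_i.std() == 0 or row_o.std() == 0:
                continue
            cors.append(np.corrcoef(row_i, row_o)[0, 1])
        score = float(np.mean(cors)) if cors else np.nan
        scores[lam] = score
        if score > best_score:
            best_lam, best_score = lam, score
    if best_lam is None:
        best_lam = sorted(grid)[0]
    return best_lam, scores
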