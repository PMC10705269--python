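"""Cross-validation harness and leave-one-species-out lifespan regression.

Cross-validation operates on species-tissue combinations, not on
individual samples: combinations eligible for testing (species with >1
observed tissue and tissue with >1 observed species) are split into k
folds; within each fold the remaining combinations are divided into
training and validation sets such that every validation combination
keeps same-species and same-tissue coverage in training.  Test
combinations are imputed with every requested method and scored against
the held-out observed combination means; a test combination is dropped
from evaluation if its fold's training set lacks same-species or
same-tissue data.

The lifespan analysis regresses log maximum lifespan on combination
mean methylation in a leave-one-species-out scheme, either on one
species-average row per species (tissue-agnostic) or on the intact
combination rows with all rows of a species held out together
(tissue-specific).  With far more probes than species the least-squares
problem is underdetermined; the minimum-norm solution is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression

from .data_model import (
    Combo,
    CombinationGrid,
    MethylationDataset,
    observed_grid,
)
from . import baselines as bl
from .cvae import CVAEHyperparams, grid_search, train
from .evaluation import EvaluationReport, evaluate, _pearson
from .impute import impute_combination


# ---------------------------------------------------------------------------
# CV dataset construction
# ---------------------------------------------------------------------------

def eligible_combinations(grid: CombinationGrid) -> list[Combo]:
    """Combos whose species has >= 2 observed tissues and whose tissue has
    >= 2 observed species."""
    n_tissues_of = {}
    n_species_of = {}
    for s, t in grid.combos:
        n_tissues_of[s] = n_tissues_of.get(s, 0) + 1
        n_species_of[t] = n_species_of.get(t, 0) + 1
    return [
        (s, t)
        for s, t in grid.combos
        if n_tissues_of[s] >= 2 and n_species_of[t] >= 2
    ]


def build_cv_folds(eligible: list[Combo], k: int, seed: int) -> dict[Combo, int]:
    """Uniform random partition of combos into k near-equal folds (1..k)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(eligible) < k:
        raise ValueError("fewer eligible combinations than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eligible))
    assignment: dict[Combo, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k), start=1):
        for i in chunk:
            assignment[tuple(eligible[i])] = fold
    return assignment


def _has_coverage(combo: Combo, pool: set[Combo]) -> bool:
    s, t = combo
    return any(ps == s for ps, _ in pool) and any(pt == t for _, pt in pool)


def split_train_validation(
    non_test_combos: list[Combo],
    seed: int,
    validation_fraction: float = 0.2,
    min_fraction: float = 0.1,
    max_attempts: int = 1000,
) -> tuple[list[Combo], list[Combo]]:
    """Split non-test combos into training and validation sets.

    Iterative procedure: draw ``validation_fraction`` of the combos as
    candidate validation; any candidate lacking a same-species or
    same-tissue combo in the candidate training set migrates to
    training; if the surviving validation set is below
    ``min_fraction`` of the combos, reshuffle with a fresh sub-seed.
    Failing after ``max_attempts`` is an error, never a silent
    relaxation of the constraints.
    """
    combos = [tuple(c) for c in non_test_combos]
    if not combos:
        raise ValueError("no combinations to split")
    n = len(combos)
    n_val = max(1, int(round(validation_fraction * n)))
    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed, attempt))
        order = rng.permutation(n)
        candidate_val = [combos[i] for i in order[:n_val]]
        candidate_train = [combos[i] for i in order[n_val:]]
        train_set = set(candidate_train)
        val = []
        for c in candidate_val:
            if _has_coverage(c, train_set):
                val.append(c)
            else:
                train_set.add(c)
                candidate_train.append(c)
        if len(val) >= min_fraction * n:
            return candidate_train, val
    raise RuntimeError(
        f"could not build a valid training/validation split in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# CV harness
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-method concatenated evaluations plus split bookkeeping."""

    reports: dict[str, EvaluationReport]
    fold_assignments: dict[Combo, int]
    dropped: list[Combo]
    selected_hyper: dict[int, CVAEHyperparams] = field(default_factory=dict)
    selected_lambda: dict[int, float] = field(default_factory=dict)
    individual_variability: float = np.nan

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: rep.summary() for name, rep in self.reports.items()}
        ).T


ALL_METHODS = ("cvae", "species", "tissue", "global", "logistic")


def run_cv(
    dataset: MethylationDataset,
    k: int = 5,
    hyper_grid: list[CVAEHyperparams] | None = None,
    methods=ALL_METHODS,
    seed: int = 0,
    lambda_grid=bl.DEFAULT_LAMBDA_GRID,
    latent_seed: int = 0,
) -> CVResult:
    """k-fold cross-validated imputation with every requested method.

    Per fold: split remaining combos into training/validation, select
    CVAE hyperparameters by validation Pearson (grid search, skipped
    for a single-candidate grid), tune the logistic lambda the same
    way, impute the fold's test combos with each method, and evaluate
    against the observed combination means.  Per-combo metrics are
    concatenated across folds before summarizing.
    """
    methods = list(methods)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    space = dataset.label_space()
    grid = observed_grid(dataset)
    eligible = eligible_combinations(grid)
    folds = build_cv_folds(eligible, k, seed)

    all_combos = list(grid.combos)
    imputed_grids: dict[str, list[CombinationGrid]] = {m: [] for m in methods}
    observed_parts: list[CombinationGrid] = []
    dropped: list[Combo] = []
    selected_hyper: dict[int, CVAEHyperparams] = {}
    selected_lambda: dict[int, float] = {}

    for fold in range(1, k + 1):
        test_combos = [c for c in all_combos if folds.get(c) == fold]
        non_test = [c for c in all_combos if folds.get(c) != fold]
        train_combos, val_combos = split_train_validation(non_test, (seed, fold))
        train_ds = dataset.subset_combos(train_combos)
        train_pool = set(train_combos)

        kept = [c for c in test_combos if _has_coverage(c, train_pool)]
        dropped.extend(c for c in test_combos if c not in set(kept))
        if not kept:
            continue
        observed_test = grid.subset(kept)
        observed_parts.append(observed_test)

        val_grid = grid.subset(val_combos)
        if "cvae" in methods:
            if hyper_grid is None:
                hyper = CVAEHyperparams(seed=_subseed(seed, fold))
            elif len(hyper_grid) == 1:
                hyper = hyper_grid[0]
            else:
                hyper, _scores = grid_search(train_ds, val_grid, hyper_grid, space)
            selected_hyper[fold] = hyper
            model = train(train_ds, space, hyper)
            rows = [
                impute_combination(model, s, t, (latent_seed, fold, j))
                for j, (s, t) in enumerate(kept)
            ]
            imputed_grids["cvae"].append(
                CombinationGrid(kept, np.stack(rows), list(dataset.probe_ids),
                                ["imputed"] * len(kept))
            )
        if "logistic" in methods:
            lam, _scores = bl.tune_lambda(train_ds, space, val_grid, lambda_grid)
            selected_lambda[fold] = lam
            imputed_grids["logistic"].append(
                bl.logistic_baseline(train_ds, space, kept, lam)
            )
        for m in ("species", "tissue", "global"):
            if m in methods:
                imputed_grids[m].append(bl.mean_baseline_grid(train_ds, kept, m))

    if not observed_parts:
        raise RuntimeError("every test combination was dropped; nothing to evaluate")
    observed_all = _concat_grids(observed_parts)
    reports = {}
    for m in methods:
        imputed_all = _concat_grids(imputed_grids[m])
        reports[m] = evaluate(imputed_all, observed_all, with_auc=True)

    _ivar_series, ivar = _safe_individual_variability(dataset, observed_all.combos)
    return CVResult(
        reports=reports,
        fold_assignments=folds,
        dropped=dropped,
        selected_hyper=selected_hyper,
        selected_lambda=selected_lambda,
        individual_variability=ivar,
    )


def _subseed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence((seed, fold)).generate_state(1)[0] % (2**31))


def _concat_grids(parts: list[CombinationGrid]) -> CombinationGrid:
    combos, status = [], []
    means = []
    for g in parts:
        combos.extend(g.combos)
        status.extend(g.status)
        means.append(g.means)
    return CombinationGrid(combos, np.vstack(means), list(parts[0].probe_ids), status)


def _safe_individual_variability(dataset, combos):
    from .evaluation import individual_variability

    sub = dataset.subset_combos(combos)
    if sub.n_samples == 0:
        return pd.Series(dtype=float), np.nan
    return individual_variability(sub)


# ---------------------------------------------------------------------------
# Lifespan regression
# ---------------------------------------------------------------------------

def species_average(grid: CombinationGrid) -> pd.DataFrame:
    """Unweighted mean of each species' combination rows over its tissues."""
    rows = {}
    for s in grid.species():
        combos = [c for c in grid.combos if c[0] == s]
        rows[s] = grid.subset(combos).means.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=grid.probe_ids)


def load_lifespan_table(path) -> pd.Series:
    """2-column TSV/CSV (species, max_lifespan_years) -> species-indexed years."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if not {"species", "max_lifespan_years"}.issubset(df.columns):
        raise ValueError("lifespan table needs columns species, max_lifespan_years")
    series = df.set_index("species")["max_lifespan_years"].astype(float)
    if (series <= 0).any():
        raise ValueError("lifespans must be positive")
    if series.index.duplicated().any():
        raise ValueError("duplicate species in lifespan table")
    return series


def loso_lifespan(
    features,
    lifespans: pd.Series,
    mode: str = "tissue_agnostic",
) -> tuple[pd.DataFrame, float, float]:
    """Leave-one-species-out linear regression of log maximum lifespan.

    ``features`` is a species-indexed DataFrame (tissue-agnostic mode;
    build with :func:`species_average`) or a :class:`CombinationGrid`
    (tissue-specific mode, where every row of a species shares its
    log-lifespan and all are held out together).  Natural log is used.
    Returns (per-row predictions, Pearson r, MSE).
    """
    if mode not in ("tissue_agnostic", "tissue_specific"):
        raise ValueError("mode must be 'tissue_agnostic' or 'tissue_specific'")
    if mode == "tissue_agnostic":
        if isinstance(features, CombinationGrid):
            features = species_average(features)
        species_of_row = list(features.index)
        tissues_of_row = [None] * len(features)
        x = features.to_numpy(float)
    else:
        if not isinstance(features, CombinationGrid):
            raise ValueError("tissue_specific mode requires a CombinationGrid")
        species_of_row = [s for s, _ in features.combos]
        tissues_of_row = [t for _, t in features.combos]
        x = features.means

    have = [i for i, s in enumerate(species_of_row) if s in lifespans.index]
    x = x[have]
    species_of_row = [species_of_row[i] for i in have]
    tissues_of_row = [tissues_of_row[i] for i in have]
    y = np.log(np.array([lifespans[s] for s in species_of_row], dtype=float))

    uniq = sorted(set(species_of_row))
    if len(uniq) < 3:
        raise ValueError("need at least 3 species with lifespans for LOSO")

    preds = np.empty(len(y))
    for s in uniq:
        held = np.array([sp == s for sp in species_of_row])
        reg = LinearRegression()  # lstsq under the hood: minimum-norm when p >> n
        reg.fit(x[~held], y[~held])
        preds[held] = reg.predict(x[held])

    result = pd.DataFrame(
        {
            "species": species_of_row,
            "tissue": tissues_of_row,
            "predicted_log_lifespan": preds,
            "log_lifespan": y,
        }
    )
    r = _pearson(preds, y)
    mse = float(np.mean((preds - y) ** 2))
    return result, r, mse


def tissue_specific_summary(predictions: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Per-tissue Pearson/MSE for tissues predicted in >= 3 species, plus
    the unweighted means over included tissues."""
    rows = []
    for tissue, sub in predictions.groupby("tissue"):
        if sub["species"].nunique() < 3:
            continue
        rows.append(
            {
                "tissue": tissue,
                "n_species": sub["species"].nunique(),
                "pearson": _pearson(sub["predicted_log_lifespan"], sub["log_lifespan"]),
                "mse": float(
                    np.mean((sub["predicted_log_lifespan"] - sub["log_lifespan"]) ** 2)
                ),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table, np.nan, np.nan
    return table.set_index("tissue"), float(table["pearson"].mean()), float(table["mse"].mean())
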