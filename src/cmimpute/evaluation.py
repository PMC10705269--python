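"""Agreement statistics for imputed vs observed combination mean samples.

Two complementary views are computed: sample-wise metrics (per
combination, across probes) and probe-wise metrics (per probe, across
combinations), each as Pearson correlation and mean squared error.
Probe-level performance is additionally stratified by three probe
variances — inter-combination, mean inter-tissue and mean
inter-species — and species/tissue signal is quantified as the AUC for
predicting whether a pair of combination mean samples shares a species
(or tissue) from the pair's Pearson correlation.

Correlations that are undefined because one vector is constant are
reported as missing (NaN) and excluded from aggregate means.
Population (1/n) variance is used throughout the variance procedures.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon

from .data_model import (
    CombinationGrid,
    MethylationDataset,
    observed_grid,
)
from .baselines import species_baseline


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _combo_key(combo) -> str:
    return f"{combo[0]}|{combo[1]}"


def _select_probes(grid: CombinationGrid, probes) -> np.ndarray:
    if probes is None:
        return grid.means
    return grid.means[:, np.asarray(probes)]


# ---------------------------------------------------------------------------
# Sample-wise and probe-wise metrics
# ---------------------------------------------------------------------------

def samplewise_metrics(
    imputed: CombinationGrid, observed: CombinationGrid, probes=None
) -> pd.DataFrame:
    """Per-combination Pearson and MSE across probes.

    Rows are indexed by "species|tissue"; combos must cover the same
    set in both grids (imputed is aligned to the observed order).
    """
    imputed = imputed.align_to(observed)
    imp = _select_probes(imputed, probes)
    obs = _select_probes(observed, probes)
    rows = []
    for i, combo in enumerate(observed.combos):
        rows.append(
            {
                "combination": _combo_key(combo),
                "species": combo[0],
                "tissue": combo[1],
                "pearson": _pearson(imp[i], obs[i]),
                "mse": float(np.mean((imp[i] - obs[i]) ** 2)),
            }
        )
    return pd.DataFrame(rows).set_index("combination")


def probewise_metrics(
    imputed: CombinationGrid, observed: CombinationGrid, probes=None
) -> pd.DataFrame:
    """Per-probe Pearson and MSE across combinations (the transpose view)."""
    imputed = imputed.align_to(observed)
    idx = np.arange(len(observed.probe_ids)) if probes is None else np.asarray(probes)
    imp = imputed.means[:, idx]
    obs = observed.means[:, idx]
    rows = []
    for j, pj in enumerate(idx):
        rows.append(
            {
                "probe": observed.probe_ids[pj],
                "pearson": _pearson(imp[:, j], obs[:, j]),
                "mse": float(np.mean((imp[:, j] - obs[:, j]) ** 2)),
            }
        )
    return pd.DataFrame(rows).set_index("probe")


# ---------------------------------------------------------------------------
# Probe variances
# ---------------------------------------------------------------------------

@dataclass
class ProbeVariances:
    """The three per-probe variance vectors over combination means."""

    inter_combination: np.ndarray
    mean_inter_tissue: np.ndarray
    mean_inter_species: np.ndarray


def probe_variances(dataset: MethylationDataset) -> ProbeVariances:
    """Compute all three probe-variance vectors from individual samples.

    Combination means are computed first so unequal individual counts do
    not skew the variances.  ``mean_inter_tissue`` averages, over
    species with more than one tissue, the across-tissue variance of
    that species' combination means; ``mean_inter_species`` is the
    symmetric quantity over tissues.
    """
    grid = observed_grid(dataset)
    if len(grid) < 2:
        raise ValueError("need at least two combinations for variance calculations")
    inter_combination = grid.means.var(axis=0)

    per_species: dict[str, list[int]] = {}
    per_tissue: dict[str, list[int]] = {}
    for i, (s, t) in enumerate(grid.combos):
        per_species.setdefault(s, []).append(i)
        per_tissue.setdefault(t, []).append(i)

    multi_s = [idx for idx in per_species.values() if len(idx) > 1]
    if not multi_s:
        raise ValueError("no species with more than one tissue: mean inter-tissue variance undefined")
    mean_inter_tissue = np.mean([grid.means[idx].var(axis=0) for idx in multi_s], axis=0)

    multi_t = [idx for idx in per_tissue.values() if len(idx) > 1]
    if not multi_t:
        raise ValueError("no tissue with more than one species: mean inter-species variance undefined")
    mean_inter_species = np.mean([grid.means[idx].var(axis=0) for idx in multi_t], axis=0)

    return ProbeVariances(inter_combination, mean_inter_tissue, mean_inter_species)


def quartile_summary(metric: np.ndarray, variances: np.ndarray) -> pd.DataFrame:
    """Mean of a per-probe metric within variance quartiles.

    Probes are ranked by variance (ties broken by probe index) and cut
    into four near-equal groups; missing metric values are excluded
    from the group means.
    """
    metric = np.asarray(metric, float)
    variances = np.asarray(variances, float)
    if metric.shape != variances.shape:
        raise ValueError("metric and variances must have equal length")
    order = np.argsort(variances, kind="stable")
    groups = np.array_split(order, 4)
    rows = []
    for q, idx in enumerate(groups, start=1):
        vals = metric[idx]
        rows.append(
            {
                "quartile": q,
                "n_probes": len(idx),
                "mean_metric": float(np.nanmean(vals)) if len(idx) else np.nan,
                "mean_variance": float(variances[idx].mean()) if len(idx) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("quartile")


# ---------------------------------------------------------------------------
# Individual variability, signal AUC, species-signal removal, paired tests
# ---------------------------------------------------------------------------

def individual_variability(dataset: MethylationDataset) -> tuple[pd.Series, float]:
    """Average pairwise Pearson correlation between individuals of the same
    combination.

    Combinations with a single individual are excluded; the overall
    value is the unweighted mean over included combinations.
    """
    per_combo = {}
    for s, t in dataset.combos():
        sub = dataset.subset_combos([(s, t)])
        if sub.n_samples < 2:
            continue
        cors = [
            _pearson(sub.beta[i], sub.beta[j])
            for i, j in combinations(range(sub.n_samples), 2)
        ]
        per_combo[_combo_key((s, t))] = float(np.nanmean(cors))
    series = pd.Series(per_combo, dtype=float)
    overall = float(series.mean()) if len(series) else np.nan
    return series, overall


def signal_auc(grid: CombinationGrid, mode: str, probes=None) -> float:
    """AUC for predicting same-species (or same-tissue) pairs from pairwise
    correlations of combination mean samples.

    All unordered pairs of distinct rows are scored by Pearson
    correlation; the AUC uses the Mann-Whitney rank formulation with
    ties credited 0.5, so it is invariant to any strictly monotone
    transform of the scores.  Pairs with an undefined correlation are
    dropped; a fully degenerate grid scores 0.5 (pure ties).
    """
    if mode not in ("species", "tissue"):
        raise ValueError("mode must be 'species' or 'tissue'")
    which = 0 if mode == "species" else 1
    means = _select_probes(grid, probes)
    n = len(grid)
    labels, scores = [], []
    for i, j in combinations(range(n), 2):
        labels.append(grid.combos[i][which] == grid.combos[j][which])
        scores.append(_pearson(means[i], means[j]))
    labels = np.array(labels)
    scores = np.array(scores)
    if not labels.any() or labels.all():
        raise ValueError(f"need both same-{mode} and different-{mode} pairs")
    valid = np.isfinite(scores)
    labels, scores = labels[valid], scores[valid]
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(scores)  # average ranks => ties counted 0.5
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def remove_species_signal(
    grid: CombinationGrid, train: MethylationDataset
) -> CombinationGrid:
    """Subtract each row's same-species training average, leaving the
    tissue-specific residual (delta values in [-1, 1])."""
    deltas = np.stack(
        [grid.means[i] - species_baseline(train, s) for i, (s, _t) in enumerate(grid.combos)]
    )
    return CombinationGrid(list(grid.combos), deltas, list(grid.probe_ids),
                           list(grid.status))


def paired_comparison(metric_a, metric_b) -> tuple[float, float]:
    """Fraction of combos where a beats b, plus the two-sided Wilcoxon
    signed-rank p-value (zero differences dropped; exact distribution
    for n <= 25, normal approximation above).

    Returns (fraction, NaN) when every difference is zero.
    """
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if a.shape != b.shape:
        raise ValueError("metric vectors must be aligned")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    frac = float(np.mean(a > b)) if len(a) else np.nan
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return frac, np.nan
    method = "exact" if len(d) <= 25 else "approx"
    res = wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return frac, float(res.pvalue)


# ---------------------------------------------------------------------------
# Composite report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Bundle of the agreement statistics for one imputation method."""

    samplewise: pd.DataFrame
    probewise: pd.DataFrame
    mean_samplewise_pearson: float
    mean_samplewise_mse: float
    mean_probewise_pearson: float
    mean_probewise_mse: float
    auc_species: float | None = None
    auc_tissue: float | None = None

    def summary(self) -> dict:
        out = {
            "mean_samplewise_pearson": self.mean_samplewise_pearson,
            "mean_samplewise_mse": self.mean_samplewise_mse,
            "mean_probewise_pearson": self.mean_probewise_pearson,
            "mean_probewise_mse": self.mean_probewise_mse,
        }
        if self.auc_species is not None:
            out["auc_species"] = self.auc_species
        if self.auc_tissue is not None:
            out["auc_tissue"] = self.auc_tissue
        return out


def evaluate(
    imputed: CombinationGrid,
    observed: CombinationGrid,
    probes=None,
    with_auc: bool = False,
) -> EvaluationReport:
    """Compute the full report for one imputed grid vs held-out means."""
    sw = samplewise_metrics(imputed, observed, probes)
    pw = probewise_metrics(imputed, observed, probes)
    auc_s = auc_t = None
    if with_auc and len(imputed) >= 3:
        try:
            auc_s = signal_auc(imputed, "species", probes)
        except ValueError:
            pass
        try:
            auc_t = signal_auc(imputed, "tissue", probes)
        except ValueError:
            pass
    return EvaluationReport(
        samplewise=sw,
        probewise=pw,
        mean_samplewise_pearson=float(sw["pearson"].mean()),
        mean_samplewise_mse=float(sw["mse"].mean()),
        mean_probewise_pearson=float(pw["pearson"].mean()),
        mean_probewise_mse=float(pw["mse"].mean()),
        auc_species=auc_s,
        auc_tissue=auc_t,
    )
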