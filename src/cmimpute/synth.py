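"""Synthetic methylation data with known species/tissue effect structure.

The generator emulates a cross-species methylation-array compendium:
each probe m has a baseline logit g_m, each species s an additive logit
effect a_{s,m}, each tissue t an effect b_{t,m} (optionally plus a
phylogenetic-group effect shared by blocks of species).  The true
combination mean for (s, t) at probe m is

    mu = expit(g_m + a_{s,m} + b_{t,m} [+ c_{order(s),m}])

and each individual sample is drawn from Beta(mu*kappa, (1-mu)*kappa),
so betas stay in (0, 1) and the noise scale is governed by the
concentration kappa.  Species effects are drawn with a larger standard
deviation than tissue effects, reproducing the empirical pattern that
species identity dominates tissue identity in pairwise correlations of
real combination mean samples.

Only a subset of combinations is "observed"; the subset is drawn so
that every held-out combination still has at least one same-species and
one same-tissue observed combination — the eligibility condition the
imputation task requires.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .data_model import (
    OBSERVED,
    IMPUTED,
    Combo,
    CombinationGrid,
    LabelSpace,
    MethylationDataset,
)

_BETA_EPS = 1e-6  # clip Beta draws into the open interval


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic compendium.

    Defaults are sized for desk tests: 20 species x 6 tissues x 300
    probes with 3 individuals per observed combination and 70% of the
    grid observed.  Effect standard deviations are in logit units;
    species 1.5 vs tissue 0.5 keeps the species signal dominant.
    ``noise_concentration`` is the Beta precision kappa: 100 gives
    individual noise of roughly 0.05 at mid-range methylation.
    """

    n_species: int = 20
    n_tissues: int = 6
    n_probes: int = 300
    individuals_per_combo: int | tuple[int, int] = 3
    observed_fraction: float = 0.7
    baseline_sd: float = 1.5
    species_effect_sd: float = 1.5
    tissue_effect_sd: float = 0.5
    order_effect_sd: float = 0.0
    n_orders: int = 4
    noise_concentration: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_species, self.n_tissues, self.n_probes) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 < self.observed_fraction <= 1:
            raise ValueError("observed_fraction must be in (0, 1]")
        if min(self.species_effect_sd, self.tissue_effect_sd, self.order_effect_sd) < 0:
            raise ValueError("effect sds must be >= 0")
        if self.noise_concentration <= 0:
            raise ValueError("noise_concentration must be > 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as f:
            raw = yaml.safe_load(f)
        if isinstance(raw.get("individuals_per_combo"), list):
            raw["individuals_per_combo"] = tuple(raw["individuals_per_combo"])
        return cls(**raw)


def _draw_observed_combos(
    space: LabelSpace, n_observed: int, rng: np.random.Generator, max_tries: int = 1000
) -> tuple[list[Combo], list[Combo]]:
    """Pick observed combos so every held-out combo keeps same-species and
    same-tissue observed coverage."""
    combos = space.all_combos()
    if n_observed >= len(combos):
        return combos, []
    for _ in range(max_tries):
        idx = rng.choice(len(combos), size=n_observed, replace=False)
        observed = [combos[i] for i in sorted(idx)]
        obs_species = {s for s, _ in observed}
        obs_tissues = {t for _, t in observed}
        held = [c for c in combos if c not in set(observed)]
        if all(s in obs_species and t in obs_tissues for s, t in held):
            return observed, held
    raise ValueError(
        "could not draw an observed set satisfying the same-species/"
        "same-tissue eligibility condition; raise observed_fraction"
    )


def generate(
    spec: SyntheticSpec,
) -> tuple[MethylationDataset, CombinationGrid, CombinationGrid]:
    """Generate (individual dataset, full true-mean grid, held-out truth grid).

    The dataset contains individuals only for observed combinations.
    The full grid holds the *generating* (noise-free) means for every
    species-tissue pair, rows tagged observed/imputed by whether the
    pair was observed; the held-out grid is its imputed-row subset.
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    species = [f"sp{i:03d}" for i in range(spec.n_species)]
    tissues = [f"ti{i:02d}" for i in range(spec.n_tissues)]
    probes = [f"cg{i:05d}" for i in range(spec.n_probes)]
    space = LabelSpace(species, tissues)

    g = rng.normal(0.0, spec.baseline_sd, size=spec.n_probes)
    a = rng.normal(0.0, spec.species_effect_sd, size=(spec.n_species, spec.n_probes))
    b = rng.normal(0.0, spec.tissue_effect_sd, size=(spec.n_tissues, spec.n_probes))
    order_of = np.arange(spec.n_species) % max(spec.n_orders, 1)
    c = rng.normal(0.0, spec.order_effect_sd, size=(max(spec.n_orders, 1), spec.n_probes))

    combos = space.all_combos()
    s_idx = {s: i for i, s in enumerate(species)}
    t_idx = {t: i for i, t in enumerate(tissues)}
    true_means = np.stack(
        [
            expit(g + a[s_idx[s]] + b[t_idx[t]] + c[order_of[s_idx[s]]])
            for s, t in combos
        ]
    )

    n_observed = int(round(spec.observed_fraction * len(combos)))
    n_observed = max(n_observed, max(spec.n_species, spec.n_tissues))
    observed, held = _draw_observed_combos(space, n_observed, rng)

    obs_set = set(observed)
    status = [OBSERVED if c_ in obs_set else IMPUTED for c_ in combos]
    truth = CombinationGrid(combos, true_means, probes, status)
    heldout = truth.subset(held)

    if isinstance(spec.individuals_per_combo, tuple):
        lo, hi = spec.individuals_per_combo
        counts = rng.integers(lo, hi + 1, size=len(observed))
    else:
        counts = np.full(len(observed), int(spec.individuals_per_combo))

    rows, sample_ids, samp_species, samp_tissue = [], [], [], []
    kappa = spec.noise_concentration
    for (s, t), n_ind in zip(observed, counts):
        mu = truth.row(s, t)
        draws = rng.beta(mu * kappa, (1.0 - mu) * kappa, size=(n_ind, spec.n_probes))
        rows.append(np.clip(draws, _BETA_EPS, 1.0 - _BETA_EPS))
        for j in range(n_ind):
            sample_ids.append(f"{s}_{t}_ind{j}")
            samp_species.append(s)
            samp_tissue.append(t)

    dataset = MethylationDataset(
        np.vstack(rows), sample_ids, samp_species, samp_tissue, probes
    )
    return dataset, truth, heldout


def generate_lifespan(
    grid: CombinationGrid,
    signal_probes: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    coefficients: np.ndarray | None = None,
    intercept: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Synthesize a species -> maximum-lifespan table from a combination grid.

    Log-lifespan is a linear function of the species-average methylation
    at ``signal_probes`` randomly chosen probes plus Gaussian noise; the
    chosen probes and coefficients are returned so recovery can be
    checked against the known rule.
    """
    m = len(grid.probe_ids)
    if not 1 <= signal_probes <= m:
        raise ValueError(f"signal_probes must be in [1, {m}]")
    rng = np.random.default_rng(seed)
    probe_idx = np.sort(rng.choice(m, size=signal_probes, replace=False))
    if coefficients is None:
        coefficients = rng.normal(0.0, 2.0, size=signal_probes)
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (signal_probes,):
        raise ValueError("coefficients must match signal_probes")

    species = grid.species()
    rows = []
    for s in species:
        combos = [c for c in grid.combos if c[0] == s]
        avg = grid.subset(combos).means.mean(axis=0)
        log_life = intercept + float(avg[probe_idx] @ coefficients)
        log_life += rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        rows.append((s, float(np.exp(log_life))))
    table = pd.DataFrame(rows, columns=["species", "max_lifespan_years"])
    info = {"probe_indices": probe_idx, "coefficients": coefficients, "intercept": intercept}
    return table, info
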