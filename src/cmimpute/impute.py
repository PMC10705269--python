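"""Label-conditioned generation of species-tissue combination mean samples.

Imputation is individual-agnostic: instead of encoding an existing
sample, a latent vector is drawn from the standard normal prior (the
distribution the posterior is regularized toward) and decoded together
with the one-hot species/tissue label.  The logistic of the decoder
logits is the imputed combination mean sample, entries in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_model import (
    IMPUTED,
    Combo,
    CombinationGrid,
    missing_combinations,
)
from .cvae import CVAEModel


@dataclass
class ImputationRequest:
    """A batch of imputation targets with the seed policy applied to them."""

    targets: list[Combo]
    latent_seed: int = 0
    draws_per_target: int = 1

    def __post_init__(self):
        self.targets = [tuple(t) for t in self.targets]
        if self.draws_per_target < 1:
            raise ValueError("draws_per_target must be >= 1")


def impute_combination(
    model: CVAEModel,
    species: str,
    tissue: str,
    latent_seed=0,
    draws: int = 1,
) -> np.ndarray:
    """Impute one combination mean sample.

    Step 1: draw z ~ N(0, I_Z) with a generator seeded by
    ``latent_seed`` (independent of any training seed).  Step 2: decode
    (z, one-hot(species, tissue)) and apply the logistic function.
    With ``draws`` > 1 the decoded beta-scale outputs are averaged.
    """
    y = model.label_space.encode_one(species, tissue)
    rng = np.random.default_rng(latent_seed)
    z = rng.standard_normal((draws, model.hyper.latent_dim))
    betas = expit(model.decode(z, np.tile(y, (draws, 1))))
    return betas.mean(axis=0)


def impute_grid(
    model: CVAEModel,
    observed: CombinationGrid,
    targets="all-missing",
    latent_seed: int = 0,
    draws_per_target: int = 1,
) -> CombinationGrid:
    """Impute a grid of combination mean samples.

    With ``targets="all-missing"`` exactly the S x T pairs absent from
    ``observed`` are imputed, so observed and imputed rows together
    partition the full grid.  Each target gets a deterministic sub-seed
    derived from ``latent_seed`` and the target's position in the sorted
    full-grid order, making the output independent of target ordering.
    An explicit target that is already observed is imputed anyway, with
    a warning (cross-validation relies on this).
    """
    space = model.label_space
    full_order = {c: i for i, c in enumerate(space.all_combos())}
    if isinstance(targets, str):
        if targets != "all-missing":
            raise ValueError(f"unknown target specification {targets!r}")
        target_list = missing_combinations(observed, space)
    else:
        target_list = [tuple(t) for t in targets]
        already = [t for t in target_list if t in observed]
        if already:
            warnings.warn(
                f"{len(already)} imputation target(s) already observed "
                f"(e.g. {already[0]}); imputing anyway"
            )
    rows = []
    for combo in target_list:
        s, t = combo
        sub_seed = (int(latent_seed), full_order[combo])
        rows.append(impute_combination(model, s, t, sub_seed, draws_per_target))
    means = np.stack(rows) if rows else np.empty((0, model.n_probes))
    return CombinationGrid(target_list, means, model.probe_ids,
                           [IMPUTED] * len(target_list))
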