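"""Core domain types and tabular I/O for cross-species methylation matrices.

The central object is a beta-value matrix (samples x probes, values in
[0, 1]) with a species and a tissue label per sample.  Downstream code
works either on individual samples (:class:`MethylationDataset`) or on
species-tissue *combination mean samples* (:class:`CombinationGrid`): the
per-probe average over all individuals sharing a (species, tissue) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

OBSERVED = "observed"
IMPUTED = "imputed"

Combo = tuple[str, str]


def _read_table(path) -> pd.DataFrame:
    path = str(path)
    sep = "," if path.endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


@dataclass
class LabelSpace:
    """Ordered species and tissue vocabularies defining the one-hot encoding.

    Vocabularies are sorted lexicographically so the encoding is
    deterministic across runs; the one-hot width is S + T (species block
    first, tissue block second).
    """

    species_vocab: list[str]
    tissue_vocab: list[str]

    def __post_init__(self):
        self.species_vocab = sorted(set(self.species_vocab))
        self.tissue_vocab = sorted(set(self.tissue_vocab))
        self._s_index = {s: i for i, s in enumerate(self.species_vocab)}
        self._t_index = {t: i for i, t in enumerate(self.tissue_vocab)}

    @property
    def n_species(self) -> int:
        return len(self.species_vocab)

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_vocab)

    @property
    def width(self) -> int:
        return self.n_species + self.n_tissues

    def encode_one(self, species: str, tissue: str) -> np.ndarray:
        """One-hot encode a single (species, tissue) pair into an S+T vector."""
        if species not in self._s_index:
            raise ValueError(f"unknown species label: {species!r}")
        if tissue not in self._t_index:
            raise ValueError(f"unknown tissue label: {tissue!r}")
        y = np.zeros(self.width)
        y[self._s_index[species]] = 1.0
        y[self.n_species + self._t_index[tissue]] = 1.0
        return y

    def all_combos(self) -> list[Combo]:
        return [(s, t) for s in self.species_vocab for t in self.tissue_vocab]


@dataclass
class MethylationDataset:
    """N x M beta-value matrix with per-sample species/tissue labels."""

    beta: np.ndarray
    sample_ids: list[str]
    species: list[str]
    tissue: list[str]
    probe_ids: list[str]

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2:
            raise ValueError("beta must be a 2-D samples x probes matrix")
        n, m = self.beta.shape
        if n < 1 or m < 1:
            raise ValueError("beta must have at least one sample and one probe")
        for name, lst, expect in (
            ("sample_ids", self.sample_ids, n),
            ("species", self.species, n),
            ("tissue", self.tissue, n),
            ("probe_ids", self.probe_ids, m),
        ):
            if len(lst) != expect:
                raise ValueError(f"{name} has length {len(lst)}, expected {expect}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.probe_ids)) != m:
            raise ValueError("probe_ids must be unique")
        bad = ~np.isfinite(self.beta)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite beta value for sample {self.sample_ids[i]!r}, "
                f"probe {self.probe_ids[j]!r}"
            )
        out = (self.beta < 0) | (self.beta > 1)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ValueError(
                f"beta value {self.beta[i, j]} outside [0, 1] for sample "
                f"{self.sample_ids[i]!r}, probe {self.probe_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]

    def label_space(self) -> LabelSpace:
        return LabelSpace(list(self.species), list(self.tissue))

    def combos(self) -> list[Combo]:
        """Distinct (species, tissue) pairs present, in first-seen order."""
        seen: dict[Combo, None] = {}
        for s, t in zip(self.species, self.tissue):
            seen.setdefault((s, t), None)
        return list(seen)

    def subset_samples(self, mask: np.ndarray) -> "MethylationDataset":
        idx = np.flatnonzero(np.asarray(mask))
        return MethylationDataset(
            self.beta[idx],
            [self.sample_ids[i] for i in idx],
            [self.species[i] for i in idx],
            [self.tissue[i] for i in idx],
            list(self.probe_ids),
        )

    def subset_combos(self, combos) -> "MethylationDataset":
        wanted = set(combos)
        mask = np.array(
            [(s, t) in wanted for s, t in zip(self.species, self.tissue)]
        )
        return self.subset_samples(mask)

    def write(self, beta_path, metadata_path) -> None:
        save_dataset(self, beta_path, metadata_path)


@dataclass
class CombinationGrid:
    """Species-tissue combination mean samples: one row per (species, tissue).

    ``status`` tags each row as observed (averaged from individuals) or
    imputed (generated by a model); both share the same schema so every
    downstream consumer is agnostic.
    """

    combos: list[Combo]
    means: np.ndarray
    probe_ids: list[str]
    status: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.combos = [tuple(c) for c in self.combos]
        self.means = np.asarray(self.means, dtype=float)
        if not self.status:
            self.status = [OBSERVED] * len(self.combos)
        if len(set(self.combos)) != len(self.combos):
            raise ValueError("combination pairs must be unique")
        if self.means.shape != (len(self.combos), len(self.probe_ids)):
            raise ValueError(
                f"means shape {self.means.shape} does not match "
                f"{len(self.combos)} combos x {len(self.probe_ids)} probes"
            )
        if len(self.status) != len(self.combos):
            raise ValueError("status must align 1:1 with combos")
        self._index = {c: i for i, c in enumerate(self.combos)}

    def __len__(self) -> int:
        return len(self.combos)

    def __contains__(self, combo: Combo) -> bool:
        return tuple(combo) in self._index

    def row(self, species: str, tissue: str) -> np.ndarray:
        return self.means[self._index[(species, tissue)]]

    def species(self) -> list[str]:
        return sorted({s for s, _ in self.combos})

    def tissues(self) -> list[str]:
        return sorted({t for _, t in self.combos})

    def subset(self, combos) -> "CombinationGrid":
        idx = [self._index[tuple(c)] for c in combos]
        return CombinationGrid(
            [self.combos[i] for i in idx],
            self.means[idx],
            list(self.probe_ids),
            [self.status[i] for i in idx],
        )

    def align_to(self, other: "CombinationGrid") -> "CombinationGrid":
        """Reorder rows to match ``other``'s combo order (must be the same set)."""
        if set(self.combos) != set(other.combos):
            raise ValueError("grids do not cover the same combinations")
        return self.subset(other.combos)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.means,
            index=[f"{s}|{t}" for s, t in self.combos],
            columns=self.probe_ids,
        )
        df.insert(0, "status", self.status)
        df.index.name = "combination"
        return df

    def write(self, path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        self.to_frame().to_csv(path, sep=sep)

    @classmethod
    def read(cls, path) -> "CombinationGrid":
        df = _read_table(path)
        status = df.pop("status").tolist()
        combos = [tuple(k.split("|", 1)) for k in df.index]
        return cls(combos, df.to_numpy(float), list(df.columns), status)


@dataclass
class MappabilityTable:
    """Boolean probes x species table: does the probe map uniquely in species k."""

    table: np.ndarray
    probe_ids: list[str]
    species_ids: list[str]

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=bool)
        if self.table.size == 0:
            raise ValueError("mappability table is empty")
        if self.table.shape != (len(self.probe_ids), len(self.species_ids)):
            raise ValueError("mappability table dimensions inconsistent with ids")

    @classmethod
    def read(cls, path) -> "MappabilityTable":
        df = _read_table(path)
        return cls(df.to_numpy(bool), list(df.index), list(df.columns))

    def write(self, path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        pd.DataFrame(
            self.table.astype(int), index=self.probe_ids, columns=self.species_ids
        ).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_dataset(beta_path, metadata_path, fill_missing: bool = False) -> MethylationDataset:
    """Load a beta matrix plus sample metadata into a validated dataset.

    The beta file is TSV/CSV (probes as columns, sample ids as first
    column) or an HDF5 container with datasets ``beta``, ``samples`` and
    ``probes``.  Metadata is TSV/CSV with columns sample_id, species,
    tissue.  Sample order is reconciled by sample id; mismatched ids are
    an error.  Missing beta values are rejected unless ``fill_missing``
    is set, in which case they are replaced by the per-probe mean.
    """
    path = str(beta_path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            beta = np.asarray(f["beta"], dtype=float)
            sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["samples"][()]]
            probe_ids = [p.decode() if isinstance(p, bytes) else str(p) for p in f["probes"][()]]
        bdf = pd.DataFrame(beta, index=sample_ids, columns=probe_ids)
    else:
        bdf = _read_table(path)

    meta = pd.read_csv(str(metadata_path), sep="," if str(metadata_path).endswith(".csv") else "\t")
    required = {"sample_id", "species", "tissue"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")

    beta_ids = set(map(str, bdf.index))
    meta_ids = set(map(str, meta.index))
    if beta_ids != meta_ids:
        missing = sorted(beta_ids ^ meta_ids)
        raise ValueError(f"sample ids do not match between beta and metadata: {missing}")
    meta = meta.loc[bdf.index]

    values = bdf.to_numpy(float)
    if np.isnan(values).any():
        if fill_missing:
            col_mean = np.nanmean(values, axis=0)
            idx = np.where(np.isnan(values))
            values[idx] = np.take(col_mean, idx[1])
        else:
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing beta value for sample {bdf.index[i]!r}, probe {bdf.columns[j]!r}"
            )
    return MethylationDataset(
        values,
        [str(s) for s in bdf.index],
        [str(s) for s in meta["species"]],
        [str(t) for t in meta["tissue"]],
        [str(p) for p in bdf.columns],
    )


def save_dataset(dataset: MethylationDataset, beta_path, metadata_path) -> None:
    path = str(beta_path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.create_dataset("beta", data=dataset.beta)
            f.create_dataset("samples", data=np.array(dataset.sample_ids, dtype="S"))
            f.create_dataset("probes", data=np.array(dataset.probe_ids, dtype="S"))
    else:
        pd.DataFrame(
            dataset.beta, index=dataset.sample_ids, columns=dataset.probe_ids
        ).rename_axis("sample_id").to_csv(path, sep="," if path.endswith(".csv") else "\t")
    pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "species": dataset.species,
            "tissue": dataset.tissue,
        }
    ).to_csv(metadata_path, sep="," if str(metadata_path).endswith(".csv") else "\t", index=False)


# ---------------------------------------------------------------------------
# Label encoding and combination means
# ---------------------------------------------------------------------------

def encode_labels(dataset: MethylationDataset, space: LabelSpace) -> np.ndarray:
    """One-hot encode every sample's labels into an N x (S+T) matrix."""
    return np.stack(
        [space.encode_one(s, t) for s, t in zip(dataset.species, dataset.tissue)]
    )


def combination_mean(dataset: MethylationDataset, species: str, tissue: str) -> np.ndarray:
    """Per-probe mean over exactly the samples carrying both labels."""
    mask = np.array(
        [s == species and t == tissue for s, t in zip(dataset.species, dataset.tissue)]
    )
    if not mask.any():
        raise ValueError(f"no samples for combination ({species!r}, {tissue!r})")
    return dataset.beta[mask].mean(axis=0)


def observed_grid(dataset: MethylationDataset) -> CombinationGrid:
    """Collapse individuals to one combination mean sample per distinct pair."""
    combos = dataset.combos()
    means = np.stack([combination_mean(dataset, s, t) for s, t in combos])
    return CombinationGrid(combos, means, list(dataset.probe_ids), [OBSERVED] * len(combos))


def missing_combinations(observed: CombinationGrid, space: LabelSpace) -> list[Combo]:
    """The S x T grid complement: pairs with no observed row."""
    have = set(observed.combos)
    return [c for c in space.all_combos() if c not in have]


def highest_coverage_subset(mapp: MappabilityTable, fraction: float = 0.9) -> np.ndarray:
    """Indices of probes mappable in at least ``fraction`` of the species.

    The boundary is inclusive: a probe mappable in exactly
    ``fraction * K`` species is kept.  Raising the fraction can only
    shrink the subset.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = mapp.table.shape[1]
    return np.flatnonzero(mapp.table.sum(axis=1) / k >= fraction)
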