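"""Core containers shared across the pipeline.

Three objects move between stages:

``GenotypeTable``
    Diploid multi-allelic genotypes (microsatellite fragment lengths) for
    individuals grouped into sampling sites.  Allele codes are positive
    integers; 0 marks a missing allele.  Genotypes are unordered pairs —
    every statistic in the package ignores within-genotype allele order.

``PairwiseMatrix``
    A labelled, symmetric, zero-diagonal site-by-site matrix (FST,
    geographic distance, environmental distance, connectivity-derived
    distance) — the common currency of the Mantel machinery.

``SiteEnvironment``
    Per-site scalar covariates (salinity, temperature, latitude, distance
    to the basin entrance, fishing pressure), held as a pandas DataFrame
    indexed by site label and validated by :func:`validate_environment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = 0

ENV_COLUMNS = (
    "salinity_april",
    "temperature_april",
    "salinity_spawning",
    "temperature_spawning",
    "latitude",
    "distance_to_entrance",
    "fishing_pressure",
)


@dataclass
class GenotypeTable:
    """Diploid genotypes for individuals tagged with site labels.

    Parameters
    ----------
    individual_ids
        One identifier per individual.
    sites
        Site label per individual; individuals of the same site need not be
        contiguous, but site order (first appearance) is preserved.
    genotypes
        Integer array of shape ``(n_individuals, n_loci, 2)``.  Allele
        codes are strictly positive; ``0`` marks a missing allele.  A
        genotype is missing iff both entries are 0.
    locus_names
        Ordered locus names.
    locus_tags
        Optional per-locus class label (e.g. ``"transcriptome"`` vs
        ``"genome"``); used only for marker-class comparisons.
    """

    individual_ids: list[str]
    sites: np.ndarray
    genotypes: np.ndarray
    locus_names: list[str]
    locus_tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=object)
        self.genotypes = np.asarray(self.genotypes)
        n, L = len(self.individual_ids), len(self.locus_names)
        if self.genotypes.shape != (n, L, 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {L}, 2)"
            )
        if L < 1:
            raise ValueError("at least one locus required")
        if np.any(self.genotypes < 0):
            raise ValueError("allele codes must be positive (0 = missing)")
        half = (self.genotypes == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise ValueError("half-missing genotypes are not representable")
        if self.locus_tags is not None and len(self.locus_tags) != L:
            raise ValueError("locus_tags length mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def site_labels(self) -> list[str]:
        """Unique site labels in order of first appearance."""
        return list(dict.fromkeys(self.sites))

    def site_indices(self, site: str) -> np.ndarray:
        return np.flatnonzero(self.sites == site)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where genotype is missing."""
        return self.genotypes[:, :, 0] == MISSING

    def n_typed(self) -> np.ndarray:
        """Number of non-missing loci per individual."""
        return (~self.missing_mask()).sum(axis=1)

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            [self.individual_ids[i] for i in idx],
            self.sites[idx],
            self.genotypes[idx],
            list(self.locus_names),
            list(self.locus_tags) if self.locus_tags is not None else None,
        )

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        pos = {name: j for j, name in enumerate(self.locus_names)}
        missing = [l for l in loci if l not in pos]
        if missing:
            raise KeyError(f"unknown loci: {missing}")
        cols = [pos[l] for l in loci]
        return GenotypeTable(
            list(self.individual_ids),
            self.sites.copy(),
            self.genotypes[:, cols],
            list(loci),
            [self.locus_tags[c] for c in cols] if self.locus_tags is not None else None,
        )

    def subset_sites(self, keep: Sequence[str]) -> "GenotypeTable":
        keep_set = set(keep)
        idx = np.flatnonzero([s in keep_set for s in self.sites])
        return self.subset_individuals(idx)


@dataclass
class PairwiseMatrix:
    """Symmetric labelled site-by-site matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"  # fst | geo_distance | env_distance | conn_distance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("matrix is not symmetric")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle (off-diagonal) values as a flat vector."""
        iu = np.tril_indices(self.n, k=-1)
        return self.values[iu]

    def drop(self, sites: Sequence[str]) -> "PairwiseMatrix":
        keep = [i for i, l in enumerate(self.labels) if l not in set(sites)]
        return PairwiseMatrix(
            [self.labels[i] for i in keep],
            self.values[np.ix_(keep, keep)],
            self.kind,
        )

    def reorder(self, labels: Sequence[str]) -> "PairwiseMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = [pos[l] for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str = "generic") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), kind)


def validate_environment(env: pd.DataFrame, sites: Sequence[str] | None = None) -> pd.DataFrame:
    """Check a site-environment table: unique site index, expected columns.

    ``sites``, when given, must all be present in the table.
    """
    if env.index.has_duplicates:
        raise ValueError("duplicated site labels in environment table")
    missing_cols = [c for c in ENV_COLUMNS if c not in env.columns]
    if missing_cols:
        raise ValueError(f"environment table missing columns: {missing_cols}")
    if sites is not None:
        absent = [s for s in sites if s not in env.index]
        if absent:
            raise ValueError(f"environment table missing sites: {absent}")
    return env
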