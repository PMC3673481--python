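"""Forward Wright-Fisher simulation of microsatellite genotypes.

Demes correspond to sampling sites.  Each generation every deme is
refilled with Ne offspring: an offspring first draws its *source* deme
from the migration row of its destination deme, then two parents
uniformly at random from that source deme, inheriting one random allele
per parent per locus (free recombination).  Microsatellite mutation hits
each transmitted allele copy independently: under SMM the repeat count
steps +-1 (reflecting at the code bounds), under IAM a fresh code is
drawn uniformly from the allowed range (a bounded-range stand-in for
"every mutation is new").

An optional selected locus experiences viability selection in the
destination deme: an offspring carrying k copies of the target allele
survives in deme d with weight ``max(1 + s * z_d, eps)^k`` where z_d is
the deme's standardized salinity — the simplest scheme that builds
allele-frequency clines along the salinity gradient.

The simulation starts from a single panmictic founder pool and runs a
configurable number of generations toward migration-drift equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeTable

ALLELE_MIN, ALLELE_MAX = 50, 500


def island_migration(n_demes: int, m_total: float) -> np.ndarray:
    """Symmetric island-model migration matrix with total immigration m_total."""
    if not 0 <= m_total < 1:
        raise ValueError("m_total must be in [0, 1)")
    M = np.full((n_demes, n_demes), m_total / (n_demes - 1))
    np.fill_diagonal(M, 1.0 - m_total)
    return M


@dataclass
class DemographyConfig:
    """Demographic and genetic parameters of the forward simulation.

    Defaults are the package's calibration regime for a 15-site basin
    with weak background differentiation (multilocus theta around 0.008):
    Ne = 200 diploids per deme, total immigration 0.135 per generation
    (island model unless a migration matrix is supplied), 59 neutral
    microsatellites plus one salinity-selected locus, SMM mutation at
    5e-4 per locus per generation, 400 generations of burn-in, and 47
    sampled diploids per deme.
    """

    n_demes: int = 15
    Ne: int = 200
    migration: np.ndarray | None = None  # row = destination's source distribution
    m_total: float = 0.135
    n_neutral_loci: int = 59
    mutation_rate: float = 5e-4
    mutation_model: str = "SMM"  # SMM | IAM
    selected_locus: bool = True
    s: float = 0.1
    target_allele: int = 138
    n_generations: int = 400
    sample_size: int = 47

    def __post_init__(self) -> None:
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")
        if self.sample_size > self.Ne:
            raise ValueError("sample_size must be <= Ne")
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.mutation_model not in ("SMM", "IAM"):
            raise ValueError("mutation_model must be SMM or IAM")
        if self.migration is None:
            self.migration = island_migration(self.n_demes, self.m_total)
        self.migration = np.asarray(self.migration, dtype=float)
        if self.migration.shape != (self.n_demes, self.n_demes):
            raise ValueError("migration matrix dimension != n_demes")
        if not np.allclose(self.migration.sum(axis=1), 1.0):
            raise ValueError("migration rows must sum to 1")

    @property
    def n_loci(self) -> int:
        return self.n_neutral_loci + (1 if self.selected_locus else 0)

    @property
    def selected_index(self) -> int | None:
        return self.n_neutral_loci if self.selected_locus else None


def _mutate(alleles: np.ndarray, mask: np.ndarray, model: str, rng) -> None:
    if not mask.any():
        return
    if model == "SMM":
        step = rng.choice(np.array([-1, 1], dtype=alleles.dtype), size=int(mask.sum()))
        vals = alleles[mask] + step
        # reflect at the bounds
        vals = np.where(vals < ALLELE_MIN, ALLELE_MIN + 1, vals)
        vals = np.where(vals > ALLELE_MAX, ALLELE_MAX - 1, vals)
        alleles[mask] = vals
    else:  # IAM: fresh draw over the allowed code range
        alleles[mask] = rng.integers(ALLELE_MIN, ALLELE_MAX + 1, size=int(mask.sum()))


def simulate_genotypes(
    config: DemographyConfig,
    env: pd.DataFrame,
    seed: int = 0,
) -> GenotypeTable:
    """Run the forward simulation and sample genotypes per deme.

    ``env`` must have one row per deme (index = site labels, in deme
    order) and a ``salinity_april`` column when the selected locus is
    enabled.  Returns a GenotypeTable with individuals named
    ``<site>_<k>`` and loci ``L01..`` plus ``SEL`` for the selected
    locus.
    """
    if len(env) != config.n_demes:
        raise ValueError(
            f"environment has {len(env)} sites but config.n_demes = {config.n_demes}"
        )
    rng = np.random.default_rng(seed)
    D, Ne, L = config.n_demes, config.Ne, config.n_loci
    N = D * Ne
    deme_of = np.repeat(np.arange(D), Ne)

    # founder pool: narrow SMM-like ladders per locus (shared across demes)
    centers = rng.integers(90, 130, size=L)
    pop = (centers[None, :, None] + rng.integers(-2, 3, size=(N, L, 2))).astype(np.int16)
    sel = config.selected_index
    if sel is not None:
        # biallelic start at the selected locus: target vs target - 2
        t = config.target_allele
        pop[:, sel, :] = np.where(rng.random((N, 2)) < 0.5, t, t - 2)

    if sel is not None and config.s > 0:
        z = env["salinity_april"].to_numpy(float)
        z = (z - z.mean()) / z.std()
        w_base = np.maximum(1.0 + config.s * z, 1e-6)  # per-copy viability weight
    else:
        w_base = None

    cum_m = np.cumsum(config.migration, axis=1)
    parent_offset = np.arange(D) * Ne
    loc_idx = np.arange(L)[None, :]

    if w_base is not None:
        # per-deme acceptance scale: offspring carry 0-2 target copies
        w_max = np.maximum(w_base, 1.0) ** 2

    def draw_offspring(slots: np.ndarray) -> np.ndarray:
        """Propose offspring for the given destination slots."""
        dest = deme_of[slots]
        u = rng.random(len(slots))
        src = np.empty(len(slots), dtype=np.int64)
        for d in np.unique(dest):
            m = dest == d
            src[m] = np.searchsorted(cum_m[d], u[m])
        p1 = parent_offset[src] + rng.integers(0, Ne, size=len(slots))
        p2 = parent_offset[src] + rng.integers(0, Ne, size=len(slots))
        h1 = rng.integers(0, 2, size=(len(slots), L))
        h2 = rng.integers(0, 2, size=(len(slots), L))
        child = np.empty((len(slots), L, 2), dtype=np.int16)
        li = loc_idx
        child[:, :, 0] = pop[p1[:, None], li, h1]
        child[:, :, 1] = pop[p2[:, None], li, h2]
        mut = rng.random((len(slots), L, 2)) < config.mutation_rate
        _mutate(child, mut, config.mutation_model, rng)
        return child

    all_slots = np.arange(N)
    for _ in range(config.n_generations):
        new = np.empty((N, L, 2), dtype=np.int16)
        pending = all_slots
        # viability selection by rejection keeps the Wright-Fisher
        # offspring-number variance (no extra resampling noise)
        while len(pending):
            child = draw_offspring(pending)
            if w_base is None:
                new[pending] = child
                break
            dest = deme_of[pending]
            copies = (child[:, sel, 0] == config.target_allele).astype(int) + (
                child[:, sel, 1] == config.target_allele
            )
            w = w_base[dest] ** copies / w_max[dest]
            accept = rng.random(len(pending)) < w
            new[pending[accept]] = child[accept]
            pending = pending[~accept]
        pop = new

    # sample without replacement per deme
    ids: list[str] = []
    sites: list[str] = []
    rows: list[np.ndarray] = []
    labels = list(env.index.astype(str))
    for d, lab in enumerate(labels):
        pick = rng.choice(Ne, size=config.sample_size, replace=False)
        rows.append(pop[d * Ne + pick])
        ids.extend(f"{lab}_{k + 1:03d}" for k in range(config.sample_size))
        sites.extend([lab] * config.sample_size)
    locus_names = [f"L{j + 1:02d}" for j in range(config.n_neutral_loci)]
    tags = ["transcriptome"] * config.n_neutral_loci
    if sel is not None:
        locus_names.append("SEL")
        tags.append("transcriptome")
    geno = np.concatenate(rows).astype(np.int32)
    return GenotypeTable(ids, np.array(sites, dtype=object), geno, locus_names, tags)
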