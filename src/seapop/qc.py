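"""Data-quality filters and replicate concordance checks.

The QC stage mirrors standard microsatellite practice: drop loci flagged
by manual scoring review or null-allele screening, drop individuals with
too many failed genotypes, and quantify genotyping error by re-running a
subset of individuals and counting discordant genotype calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeTable


@dataclass
class RemovalReport:
    """Individuals removed by the completeness filter."""

    removed_ids: list[str]
    n_typed: dict[str, int]
    n_before: int
    n_after: int


def filter_individuals_by_completeness(
    table: GenotypeTable, min_typed: int
) -> tuple[GenotypeTable, RemovalReport]:
    """Drop individuals successfully genotyped at fewer than ``min_typed`` loci.

    Returns the filtered table and a report listing removed individuals
    with their typed-locus counts.  Idempotent: re-applying with the same
    threshold removes nothing further.
    """
    if not 0 <= min_typed <= table.n_loci + 1:
        raise ValueError("min_typed out of range")
    typed = table.n_typed()
    keep = np.flatnonzero(typed >= min_typed)
    removed = np.flatnonzero(typed < min_typed)
    report = RemovalReport(
        removed_ids=[table.individual_ids[i] for i in removed],
        n_typed={table.individual_ids[i]: int(typed[i]) for i in removed},
        n_before=table.n_individuals,
        n_after=len(keep),
    )
    return table.subset_individuals(keep), report


def filter_loci(table: GenotypeTable, drop: list[str]) -> GenotypeTable:
    """Remove the named loci, preserving the order of the remainder."""
    unknown = [l for l in drop if l not in table.locus_names]
    if unknown:
        raise KeyError(f"unknown loci: {unknown}")
    keep = [l for l in table.locus_names if l not in set(drop)]
    if not keep:
        raise ValueError("filter would remove every locus")
    return table.subset_loci(keep)


@dataclass
class ConcordanceReport:
    """Replicate-genotyping concordance between two runs."""

    n_compared: int
    n_discordant: int
    mismatch_rate: float
    per_locus_discordant: dict[str, int]
    n_missing_vs_typed: int = 0


def replicate_concordance(
    table_a: GenotypeTable, table_b: GenotypeTable
) -> ConcordanceReport:
    """Compare genotypes of shared individuals across two genotyping runs.

    A pair is compared when both runs typed the genotype; mismatch rate is
    discordant / compared.  Genotypes are unordered, so (a, b) vs (b, a)
    is concordant.  Missing-in-one-run-only pairs are counted separately.
    """
    shared_ids = [i for i in table_a.individual_ids if i in set(table_b.individual_ids)]
    shared_loci = [l for l in table_a.locus_names if l in set(table_b.locus_names)]
    if not shared_ids:
        raise ValueError("no shared individuals between replicate runs")
    if not shared_loci:
        raise ValueError("no shared loci between replicate runs")

    pos_a = {n: i for i, n in enumerate(table_a.individual_ids)}
    pos_b = {n: i for i, n in enumerate(table_b.individual_ids)}
    ga = table_a.subset_loci(shared_loci).genotypes
    gb = table_b.subset_loci(shared_loci).genotypes
    ia = [pos_a[n] for n in shared_ids]
    ib = [pos_b[n] for n in shared_ids]
    a = np.sort(ga[ia], axis=2)  # unordered genotypes
    b = np.sort(gb[ib], axis=2)

    miss_a = a[:, :, 0] == 0
    miss_b = b[:, :, 0] == 0
    both_typed = ~miss_a & ~miss_b
    one_missing = miss_a ^ miss_b
    discord = np.any(a != b, axis=2) & both_typed

    n_compared = int(both_typed.sum())
    n_disc = int(discord.sum())
    per_locus = {
        loc: int(discord[:, j].sum()) for j, loc in enumerate(shared_loci)
    }
    rate = n_disc / n_compared if n_compared else float("nan")
    return ConcordanceReport(
        n_compared=n_compared,
        n_discordant=n_disc,
        mismatch_rate=rate,
        per_locus_discordant=per_locus,
        n_missing_vs_typed=int(one_missing.sum()),
    )
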