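"""Multi-allelic F-statistics, diversity measures and differentiation tests.

The estimator at the core is Weir & Cockerham's theta: for each allele
at each locus, three variance components are computed from per-population
sample sizes n_i, allele frequencies p_i and observed heterozygote
frequencies h_i,

    a — among populations,
    b — among individuals within populations,
    c — within individuals (heterozygosity),

and theta is the ratio-of-sums a / (a + b + c), summed over alleles for
a per-locus estimate and over loci for the multilocus estimate.  The
ratio-of-sums (not an average of ratios) is what makes the multilocus
estimate well-behaved for weakly informative loci; negative estimates
are retained, as is standard for moments estimators.

Exact differentiation and Hardy-Weinberg tests are realised as
permutation tests on the same statistics (G on the site x allele table;
heterozygote deficiency on allele shuffles), which target the same null
hypotheses as the classical Markov-chain exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import GenotypeTable, PairwiseMatrix


# ---------------------------------------------------------------------------
# allele-count tabulation (shared by every estimator)


@dataclass
class AlleleCounts:
    """Per site x locus x allele counts underlying all statistics.

    ``counts[s, l, k]`` is the number of copies of allele k at locus l in
    site s; ``het[s, l, k]`` the number of heterozygous individuals
    carrying allele k; ``typed[s, l]`` the number of typed diploids.
    Allele axis is padded to the most allele-rich locus.
    """

    site_labels: list[str]
    locus_names: list[str]
    counts: np.ndarray
    het: np.ndarray
    typed: np.ndarray
    alleles: list[np.ndarray]  # per locus, the allele codes for axis k

    def subset_sites(self, sites: list[str]) -> "AlleleCounts":
        pos = [self.site_labels.index(s) for s in sites]
        return AlleleCounts(
            list(sites),
            self.locus_names,
            self.counts[pos],
            self.het[pos],
            self.typed[pos],
            self.alleles,
        )


def tabulate(table: GenotypeTable, sites: list[str] | None = None) -> AlleleCounts:
    """Count alleles and heterozygotes per site x locus."""
    if sites is None:
        sites = table.site_labels
    site_idx = {s: i for i, s in enumerate(sites)}
    rows = np.array([site_idx.get(s, -1) for s in table.sites])
    keep = rows >= 0
    geno = table.genotypes[keep]
    rows = rows[keep]
    S, L = len(sites), table.n_loci

    alleles: list[np.ndarray] = []
    kmax = 1
    coded = np.full((geno.shape[0], L, 2), -1, dtype=int)
    for l in range(L):
        g = geno[:, l, :]
        vals = np.unique(g[g > 0])
        alleles.append(vals)
        kmax = max(kmax, len(vals))
        if len(vals):
            coded[:, l, :] = np.searchsorted(vals, g)
            m = g[:, 0] == 0  # both alleles missing together (invariant)
            coded[m, l, :] = -1

    counts = np.zeros((S, L, kmax))
    het = np.zeros((S, L, kmax))
    typed = np.zeros((S, L))
    loc = np.broadcast_to(np.arange(L)[None, :], geno.shape[:2])
    ok = coded[:, :, 0] >= 0
    r = np.broadcast_to(rows[:, None], ok.shape)
    np.add.at(typed, (r[ok], loc[ok]), 1)
    for hap in range(2):
        c = coded[:, :, hap]
        np.add.at(counts, (r[ok], loc[ok], c[ok]), 1)
    is_het = ok & (coded[:, :, 0] != coded[:, :, 1])
    for hap in range(2):
        c = coded[:, :, hap]
        np.add.at(het, (r[is_het], loc[is_het], c[is_het]), 1)
    return AlleleCounts(list(sites), list(table.locus_names), counts, het, typed, alleles)


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components


@dataclass
class LocusVarianceComponents:
    """Per locus x allele a/b/c components plus validity mask."""

    locus_names: list[str]
    a: np.ndarray  # (L, K)
    b: np.ndarray
    c: np.ndarray
    valid: np.ndarray  # (L,) locus usable (>= 2 pops, polymorphic)


def _wc_components(ac: AlleleCounts) -> LocusVarianceComponents:
    counts, het, typed = ac.counts, ac.het, ac.typed
    with np.errstate(divide="ignore", invalid="ignore"):
        valid_pop = typed > 0  # (S, L)
        r = valid_pop.sum(axis=0)  # pops with data per locus
        n_tot = typed.sum(axis=0)
        nbar = np.where(r > 0, n_tot / np.maximum(r, 1), np.nan)
        sum_n2 = (typed**2).sum(axis=0)
        nc = np.where(
            r > 1,
            (n_tot - sum_n2 / np.maximum(n_tot, 1e-300)) / np.maximum(r - 1, 1),
            np.nan,
        )
        p = np.where(typed[:, :, None] > 0, counts / (2 * np.maximum(typed, 1)[:, :, None]), 0.0)
        h = np.where(typed[:, :, None] > 0, het / np.maximum(typed, 1)[:, :, None], 0.0)
        pbar = counts.sum(axis=0) / np.maximum(2 * n_tot, 1e-300)[:, None]  # (L, K)
        hbar = het.sum(axis=0) / np.maximum(n_tot, 1e-300)[:, None]
        dev = (p - pbar[None]) ** 2 * typed[:, :, None]
        s2 = dev.sum(axis=0) / (np.maximum(r - 1, 1) * nbar)[:, None]

        rr = r[:, None].astype(float)
        nb = nbar[:, None]
        inner = pbar * (1 - pbar) - (rr - 1) / np.maximum(rr, 1) * s2
        a = (nb / nc[:, None]) * (s2 - (inner - hbar / 4) / np.maximum(nb - 1, 1e-300))
        b = (nb / np.maximum(nb - 1, 1e-300)) * (inner - (2 * nb - 1) / (4 * nb) * hbar)
        c = hbar / 2

    poly = (pbar > 0).sum(axis=1) > 1
    valid = (r >= 2) & (nbar > 1) & poly
    a = np.where(valid[:, None], a, 0.0)
    b = np.where(valid[:, None], b, 0.0)
    c = np.where(valid[:, None], c, 0.0)
    return LocusVarianceComponents(list(ac.locus_names), a, b, c, valid)


@dataclass
class ThetaResult:
    per_locus: pd.Series  # NaN for skipped loci
    multilocus: float
    components: LocusVarianceComponents
    skipped: list[str]


def theta_wc(
    table: GenotypeTable | AlleleCounts, sites: list[str] | None = None
) -> ThetaResult:
    """Weir-Cockerham theta per locus and over all loci.

    Loci that are monomorphic, typed in fewer than two populations, or
    with mean sample size <= 1 are skipped (reported in ``skipped``) and
    excluded from the multilocus ratio of sums.
    """
    ac = table if isinstance(table, AlleleCounts) else tabulate(table, sites)
    if sites is not None and not isinstance(table, AlleleCounts):
        pass  # tabulate already restricted
    elif sites is not None:
        ac = ac.subset_sites(sites)
    if (ac.typed > 0).any(axis=1).sum() < 2:
        raise ValueError("theta requires at least two populations with data")
    comp = _wc_components(ac)
    num = comp.a.sum(axis=1)
    den = (comp.a + comp.b + comp.c).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus = np.where(comp.valid & (den != 0), num / den, np.nan)
    use = comp.valid & (den != 0)
    multilocus = float(num[use].sum() / den[use].sum()) if use.any() else float("nan")
    skipped = [n for n, v in zip(ac.locus_names, use) if not v]
    return ThetaResult(
        pd.Series(per_locus, index=ac.locus_names), multilocus, comp, skipped
    )


def pairwise_theta(table: GenotypeTable) -> PairwiseMatrix:
    """Multilocus theta for every unordered site pair (negatives retained)."""
    ac = tabulate(table)
    labels = ac.site_labels
    if len(labels) < 2:
        raise ValueError("need at least two sites")
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = theta_wc(ac.subset_sites([labels[i], labels[j]]))
            vals[i, j] = vals[j, i] = r.multilocus
    return PairwiseMatrix(labels, vals, kind="fst")


# ---------------------------------------------------------------------------
# diversity


def expected_het(table: GenotypeTable | AlleleCounts) -> pd.DataFrame:
    """Unbiased expected heterozygosity per site x locus.

    He = (2n / (2n - 1)) (1 - sum p_k^2), with n the typed diploids.
    NaN where a site has no typed individuals at a locus.
    """
    ac = table if isinstance(table, AlleleCounts) else tabulate(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        two_n = 2 * ac.typed
        p = ac.counts / np.maximum(two_n, 1e-300)[:, :, None]
        he = two_n / np.maximum(two_n - 1, 1e-300) * (1 - (p**2).sum(axis=2))
        he = np.where(ac.typed > 0, he, np.nan)
    return pd.DataFrame(he, index=ac.site_labels, columns=ac.locus_names)


def allelic_richness(
    table: GenotypeTable | AlleleCounts, g: int | None = None
) -> pd.DataFrame:
    """Rarefied allelic richness per site x locus.

    AR = sum_k [1 - C(2N - N_k, g) / C(2N, g)] — the expected number of
    distinct alleles in a hypergeometric subsample of g gene copies.
    ``g`` defaults to the smallest number of typed gene copies over all
    site x locus cells with data.
    """
    ac = table if isinstance(table, AlleleCounts) else tabulate(table)
    two_n = 2 * ac.typed
    if g is None:
        with_data = two_n[two_n > 0]
        if not len(with_data):
            raise ValueError("no typed genotypes")
        g = int(with_data.min())
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    if np.any((two_n > 0) & (two_n < g)):
        raise ValueError("g exceeds typed gene copies in some site x locus cell")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    N = two_n[:, :, None]
    Nk = ac.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            N - Nk >= g,
            np.exp(log_comb(np.maximum(N - Nk, 0), g) - log_comb(np.maximum(N, 1), g)),
            0.0,
        )
        ar = ((Nk > 0) * (1.0 - ratio)).sum(axis=2)
        ar = np.where(ac.typed > 0, ar, np.nan)
    return pd.DataFrame(ar, index=ac.site_labels, columns=ac.locus_names)


# ---------------------------------------------------------------------------
# FIS and Hardy-Weinberg (heterozygote deficiency)


@dataclass
class FisResult:
    per_site: pd.Series
    ci: pd.DataFrame  # columns lo, hi; NaN when only one locus
    deficiency_p: pd.DataFrame  # site x locus one-sided permutation p
    single_locus: bool


def _fis_from_counts(counts, het, typed):
    """Single-population b and c summed over alleles; returns (b_sum, c_sum) per locus."""
    with np.errstate(divide="ignore", invalid="ignore"):
        n = typed[:, None]
        p = counts / np.maximum(2 * n, 1e-300)
        h = het / np.maximum(n, 1e-300)
        b = n / np.maximum(n - 1, 1e-300) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2
    ok = (typed > 1)[:, None]
    return np.where(ok, b, 0.0).sum(axis=1), np.where(ok, c, 0.0).sum(axis=1)


def fis_wc(
    table: GenotypeTable,
    n_bootstrap: int = 1000,
    n_permutations: int = 999,
    seed: int = 0,
) -> FisResult:
    """Per-site FIS (f = b / (b + c) over alleles and loci) with a
    bootstrap-over-loci 95% CI and one-sided heterozygote-deficiency
    permutation p-values per site x locus.

    The deficiency null shuffles the 2n allele copies of a site x locus
    cell into new diploids; p is one-sided toward too few heterozygotes.
    """
    if n_bootstrap < 200:
        raise ValueError("n_bootstrap must be >= 200")
    rng = np.random.default_rng(seed)
    ac = tabulate(table)
    S, L = ac.typed.shape
    fis = np.full(S, np.nan)
    ci = np.full((S, 2), np.nan)
    single = L < 2
    for s in range(S):
        b, c = _fis_from_counts(ac.counts[s], ac.het[s], ac.typed[s])
        tot = b + c
        if tot.sum() != 0:
            fis[s] = b.sum() / tot.sum()
        if not single:
            idx = rng.integers(0, L, size=(n_bootstrap, L))
            bs_b = b[idx].sum(axis=1)
            bs_t = tot[idx].sum(axis=1)
            okb = bs_t != 0
            if okb.sum() >= 2:
                ci[s] = np.percentile(bs_b[okb] / bs_t[okb], [2.5, 97.5])

    pvals = np.full((S, L), np.nan)
    geno = np.sort(table.genotypes, axis=2)
    site_rows = {s: table.site_indices(s) for s in ac.site_labels}
    for s, lab in enumerate(ac.site_labels):
        rows = site_rows[lab]
        for l in range(L):
            g = geno[rows, l]
            g = g[g[:, 0] > 0]
            n = len(g)
            if n < 2 or len(np.unique(g)) < 2:
                continue
            obs_het = int((g[:, 0] != g[:, 1]).sum())
            pool = g.ravel().copy()
            count = 0
            for _ in range(n_permutations):
                rng.shuffle(pool)
                ph = pool.reshape(n, 2)
                count += int((ph[:, 0] != ph[:, 1]).sum()) <= obs_het
            pvals[s, l] = (1 + count) / (1 + n_permutations)
    return FisResult(
        pd.Series(fis, index=ac.site_labels),
        pd.DataFrame(ci, index=ac.site_labels, columns=["lo", "hi"]),
        pd.DataFrame(pvals, index=ac.site_labels, columns=ac.locus_names),
        single,
    )


# ---------------------------------------------------------------------------
# differentiation G-test (permutation analogue of the exact test)


def _g_stat(counts: np.ndarray) -> np.ndarray:
    """G = 2 sum O ln(O/E) per locus on (S, L, K) count arrays."""
    col = counts.sum(axis=0)  # (L, K)
    row = counts.sum(axis=2)  # (S, L)
    tot = np.maximum(col.sum(axis=1), 1e-300)  # (L,)
    E = row[:, :, None] * col[None, :, :] / tot[None, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / np.maximum(E, 1e-300)), 0.0)
    return 2 * term.sum(axis=(0, 2))


@dataclass
class GTestResult:
    per_locus_g: pd.Series
    per_locus_p: pd.Series
    combined_p: float  # Fisher's method across loci


def g_test_differentiation(
    table: GenotypeTable,
    sites: list[str] | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> GTestResult:
    """Genic differentiation test: G on the site x allele count table,
    with a null built by permuting individuals among sites.

    Per-locus permutation p-values are combined across loci with
    Fisher's method (chi-square on -2 sum ln p).
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    rng = np.random.default_rng(seed)
    sub = table if sites is None else table.subset_sites(sites)
    ac = tabulate(sub)
    S, L = ac.typed.shape
    if S < 2:
        raise ValueError("need at least two sites")
    g_obs = _g_stat(ac.counts)

    # compact coding of alleles for fast recounting under permutation
    labels = ac.site_labels
    site_code = np.array([labels.index(s) for s in sub.sites])
    K = ac.counts.shape[2]
    coded = np.full((sub.n_individuals, L, 2), -1, dtype=int)
    for l in range(L):
        vals = ac.alleles[l]
        g = sub.genotypes[:, l, :]
        if len(vals):
            coded[:, l, :] = np.searchsorted(vals, g)
            coded[g[:, 0] == 0, l, :] = -1
    ok = coded[:, :, 0] >= 0
    loc = np.broadcast_to(np.arange(L)[None, :], ok.shape)

    def count_for(assign: np.ndarray) -> np.ndarray:
        c = np.zeros((S, L, K))
        r = np.broadcast_to(assign[:, None], ok.shape)
        for hap in range(2):
            cd = coded[:, :, hap]
            np.add.at(c, (r[ok], loc[ok], cd[ok]), 1)
        return c

    exceed = np.zeros(L)
    assign = site_code.copy()
    for _ in range(n_permutations):
        rng.shuffle(assign)
        exceed += _g_stat(count_for(assign)) >= g_obs - 1e-12
    p = (1 + exceed) / (1 + n_permutations)
    with np.errstate(divide="ignore"):
        fisher = -2 * np.log(p).sum()
    combined = float(stats.chi2.sf(fisher, df=2 * L))
    return GTestResult(
        pd.Series(g_obs, index=ac.locus_names),
        pd.Series(p, index=ac.locus_names),
        combined,
    )


def ld_test(
    table: GenotypeTable,
    locus_pair: tuple[str, str],
    site: str,
    n_permutations: int = 999,
    seed: int = 0,
) -> float | None:
    """Permutation test of genotypic linkage disequilibrium at one site.

    Statistic: G on the two-locus genotype contingency table; the null
    permutes one locus's genotypes among individuals within the site.
    Returns the p-value, or None when fewer than 5 doubly-typed
    individuals or a monomorphic locus make the test meaningless.
    """
    rng = np.random.default_rng(seed)
    la, lb = locus_pair
    sub = table.subset_sites([site]).subset_loci([la, lb])
    geno = np.sort(sub.genotypes, axis=2)
    ok = (geno[:, 0, 0] > 0) & (geno[:, 1, 0] > 0)
    ga, gb = geno[ok, 0], geno[ok, 1]
    if len(ga) < 5:
        return None
    _, ca = np.unique(ga, axis=0, return_inverse=True)
    _, cb = np.unique(gb, axis=0, return_inverse=True)
    if ca.max() == 0 or cb.max() == 0:
        return None

    def g_of(x, y):
        tab = np.zeros((ca.max() + 1, cb.max() + 1))
        np.add.at(tab, (x, y), 1)
        E = tab.sum(1, keepdims=True) * tab.sum(0, keepdims=True) / tab.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(tab > 0, tab * np.log(tab / np.maximum(E, 1e-300)), 0.0)
        return 2 * t.sum()

    obs = g_of(ca, cb)
    perm = cb.copy()
    count = 0
    for _ in range(n_permutations):
        rng.shuffle(perm)
        count += g_of(ca, perm) >= obs - 1e-12
    return (1 + count) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# ordination and classical comparisons


def classical_mds(matrix: PairwiseMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (metric) MDS by double centering.

    B = -1/2 J D^2 J; coordinates come from the top-k non-negative
    eigenpairs (distance matrices from FST need not be Euclidean, so
    negative eigenvalues are dropped and returned for diagnostics).
    Axis signs are fixed so the first non-zero coordinate of each axis
    is positive.
    """
    n = matrix.n
    if k > n - 1:
        raise ValueError("k must be <= n_sites - 1")
    D2 = matrix.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = np.flatnonzero(w > 1e-12)[:k]
    coords = V[:, keep] * np.sqrt(w[keep])
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, j] = -col
    cols = [f"dim{j + 1}" for j in range(coords.shape[1])]
    return pd.DataFrame(coords, index=matrix.labels, columns=cols), w


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    degenerate: bool = False


def one_way_anova(values: pd.DataFrame) -> AnovaResult:
    """One-way ANOVA with rows as groups (sites) and columns as observations.

    Returns the between/within mean-square ratio with its F distribution
    p-value; NaN cells are dropped group-wise.
    """
    groups = [row.dropna().to_numpy() for _, row in values.iterrows()]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, N - k
    if ss_within == 0:
        return AnovaResult(float("inf"), (df1, df2), 0.0, degenerate=True)
    F = (ss_between / df1) / (ss_within / df2)
    return AnovaResult(float(F), (df1, df2), float(stats.f.sf(F, df1, df2)))


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t(a: np.ndarray, b: np.ndarray) -> WelchResult:
    """Welch's two-sample t-test (unequal variances, two-tailed)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return WelchResult(0.0, float(na + nb - 2), 1.0, degenerate=True)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def benjamini_hochberg(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH step-up: returns a boolean rejected mask (NaNs never rejected)."""
    p = np.asarray(pvals, float)
    ok = ~np.isnan(p)
    rej = np.zeros(len(p), dtype=bool)
    if ok.sum() == 0:
        return rej
    from statsmodels.stats.multitest import multipletests

    rej[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return rej
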