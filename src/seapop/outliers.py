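"""Fdist-style FST-outlier detection against a simulated neutral envelope.

Neutral loci are simulated under the Balding-Nichols island
approximation: ancestral allele frequencies p are drawn per locus (a
symmetric Dirichlet over K alleles under IAM; a discretized-Gaussian
ladder over repeat classes under SMM), deme frequencies are drawn from
Dirichlet(p (1 - F) / F) at the target mean FST, and diploid samples of
the study's sizes are drawn assuming Hardy-Weinberg within demes.  Each
simulated locus yields a (theta, He) pair estimated with the same
Weir-Cockerham machinery applied to the observed data, building a null
cloud of FST conditional on heterozygosity.

Observed loci are then placed in the cloud: the empirical quantile of a
locus's theta within its He stratum (equal-count He bins with linear
interpolation between bin quantiles) gives one-sided p-values toward
high FST (putative directional selection) and low FST (putative
balancing selection), an envelope classification at the confidence
level, and Benjamini-Hochberg q-values across loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeTable
from .popgen import AlleleCounts, _wc_components, benjamini_hochberg, tabulate, theta_wc


@dataclass
class NeutralSimConfig:
    """Parameters of the neutral-envelope simulation."""

    n_demes: int = 15
    sample_sizes: int | np.ndarray = 47  # diploids per deme
    target_fst: float = 0.008
    mutation_model: str = "IAM"  # IAM | SMM (shapes ancestral frequencies)
    n_sims: int = 100_000
    ci_level: float = 0.95
    fdr: float = 0.05
    he_bins: int = 20
    seed: int = 0
    max_alleles: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.target_fst < 1:
            raise ValueError("target_fst must be in (0, 1)")
        if self.n_sims < 1000:
            raise ValueError("n_sims must be >= 1000")
        if self.mutation_model not in ("IAM", "SMM"):
            raise ValueError("mutation_model must be IAM or SMM")
        self.sample_sizes = np.broadcast_to(
            np.asarray(self.sample_sizes, dtype=int), (self.n_demes,)
        ).copy()


@dataclass
class OutlierCall:
    """Classification of one observed locus against the null cloud."""

    locus: str
    theta: float
    he: float
    quantile: float
    direction: str  # positive | balancing | none
    p: float  # direction-consistent one-sided raw p (min of the two sides)
    p_positive: float
    p_balancing: float
    q: float = float("nan")
    significant: bool = False
    extrapolated: bool = False


def _ancestral_frequencies(config: NeutralSimConfig, n: int, rng) -> np.ndarray:
    """(n, K) ancestral frequency vectors, zero-padded to max_alleles."""
    K = config.max_alleles
    p = np.zeros((n, K))
    if config.mutation_model == "IAM":
        k = np.minimum(1 + rng.geometric(0.45, size=n), K)
        g = rng.gamma(1.0, size=(n, K))
        mask = np.arange(K)[None, :] < k[:, None]
        g *= mask
        p = g / g.sum(axis=1, keepdims=True)
    else:  # SMM: discretized-Gaussian ladder over repeat classes
        centre = rng.uniform(2.0, K - 3.0, size=n)
        sigma = rng.uniform(0.6, 2.5, size=n)
        grid = np.arange(K)[None, :]
        w = np.exp(-0.5 * ((grid - centre[:, None]) / sigma[:, None]) ** 2)
        p = w / w.sum(axis=1, keepdims=True)
    return p


def simulate_neutral_locus(config: NeutralSimConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Simulate the neutral (theta, He) cloud.

    Returns ``(theta, he, n_rejected)`` where monomorphic draws (no
    polymorphism left in the pooled sample) are rejected and redrawn.
    """
    rng = np.random.default_rng(config.seed)
    F = config.target_fst
    D = config.n_demes
    n_d = config.sample_sizes
    thetas = np.empty(0)
    hes = np.empty(0)
    rejected = 0
    chunk = 1000
    while len(thetas) < config.n_sims:
        need = min(chunk, config.n_sims - len(thetas)) * 2  # oversample for rejections
        p = _ancestral_frequencies(config, need, rng)
        alpha = p * (1.0 - F) / F
        # Dirichlet per deme via normalized gammas (zero alpha -> zero freq)
        g = rng.gamma(np.maximum(alpha[:, None, :], 1e-12), size=(need, D, p.shape[1]))
        g[np.broadcast_to(alpha[:, None, :], g.shape) <= 0] = 0.0
        q = g / np.maximum(g.sum(axis=2, keepdims=True), 1e-300)

        th, he, poly = _estimate_cloud(q, n_d, rng)
        rejected += int((~poly).sum())
        thetas = np.concatenate([thetas, th[poly]])
        hes = np.concatenate([hes, he[poly]])
    return thetas[: config.n_sims], hes[: config.n_sims], rejected


def _estimate_cloud(q: np.ndarray, n_d: np.ndarray, rng) -> tuple[np.ndarray, ...]:
    """Sample diploids at deme frequencies q (C, D, K) and estimate
    (theta, pooled He, polymorphic mask) per simulated locus."""
    C, D, K = q.shape
    n_max = int(n_d.max())
    cum = np.cumsum(q, axis=2)
    u = rng.random((C, D, 2 * n_max))
    alleles = (u[:, :, :, None] > cum[:, :, None, :]).sum(axis=3)  # (C, D, 2n)
    alleles = np.minimum(alleles, K - 1)
    # mask demes down to their own sample size
    copy_ok = np.arange(2 * n_max)[None, None, :] < (2 * n_d)[None, :, None]

    onehot = (alleles[:, :, :, None] == np.arange(K)[None, None, None, :]) & copy_ok[
        :, :, :, None
    ]
    counts = onehot.sum(axis=2).astype(float)  # (C, D, K)
    pairs = alleles.reshape(C, D, n_max, 2)
    ind_ok = np.arange(n_max)[None, None, :] < n_d[None, :, None]
    is_het = (pairs[:, :, :, 0] != pairs[:, :, :, 1]) & ind_ok
    het = np.zeros((C, D, K))
    for hap in range(2):
        oh = (pairs[:, :, :, hap, None] == np.arange(K)[None, None, None, :]) & is_het[
            :, :, :, None
        ]
        het += oh.sum(axis=2)

    typed = np.broadcast_to(n_d[None, :], (C, D)).astype(float)
    ac = AlleleCounts(
        site_labels=[f"d{i}" for i in range(D)],
        locus_names=[f"sim{i}" for i in range(C)],
        counts=np.transpose(counts, (1, 0, 2)),
        het=np.transpose(het, (1, 0, 2)),
        typed=typed.T,
        alleles=[np.arange(K)] * C,
    )
    comp = _wc_components(ac)
    num = comp.a.sum(axis=1)
    den = (comp.a + comp.b + comp.c).sum(axis=1)
    poly = comp.valid & (den != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(poly, num / den, np.nan)
    pooled = counts.sum(axis=1)  # (C, K)
    tot = pooled.sum(axis=1)
    pfreq = pooled / tot[:, None]
    he = tot / (tot - 1) * (1 - (pfreq**2).sum(axis=1))
    return theta, he, poly


def neutral_mean_fst(
    per_locus_theta: np.ndarray,
    config: NeutralSimConfig | None = None,
    bounds: tuple[float, float] | None = None,
    trim_sims: int = 5000,
) -> float:
    """Trimmed "neutral" mean FST: one trimming pass.

    A provisional envelope is built at the raw mean (quantiles of a
    small neutral simulation at that mean, or explicit ``bounds``); loci
    outside it are dropped and the mean of the survivors returned.  If
    every locus is trimmed, the raw mean is returned with a warning.
    """
    theta = np.asarray(per_locus_theta, float)
    theta = theta[~np.isnan(theta)]
    if len(theta) < 5:
        raise ValueError("need at least 5 loci")
    raw_mean = float(theta.mean())
    if bounds is None:
        cfg = config or NeutralSimConfig()
        prov = NeutralSimConfig(
            n_demes=cfg.n_demes,
            sample_sizes=cfg.sample_sizes,
            target_fst=min(max(raw_mean, 1e-4), 0.99),
            mutation_model=cfg.mutation_model,
            n_sims=max(trim_sims, 1000),
            ci_level=cfg.ci_level,
            seed=cfg.seed + 1,
        )
        null_theta, _, _ = simulate_neutral_locus(prov)
        alpha = 1.0 - prov.ci_level
        bounds = tuple(np.quantile(null_theta, [alpha / 2, 1 - alpha / 2]))
    lo, hi = bounds
    keep = theta[(theta >= lo) & (theta <= hi)]
    if len(keep) == 0:
        warnings.warn("all loci trimmed; falling back to untrimmed mean")
        return raw_mean
    return float(keep.mean())


def classify_outliers(
    observed_theta: np.ndarray,
    observed_he: np.ndarray,
    null_theta: np.ndarray,
    null_he: np.ndarray,
    config: NeutralSimConfig,
    locus_names: list[str] | None = None,
) -> list[OutlierCall]:
    """Place observed loci in the He-conditional neutral envelope.

    Quantiles and one-sided p-values are computed within equal-count He
    bins of the null cloud and linearly interpolated between adjacent
    bin centres; observed He outside the null support uses the nearest
    bin (flagged ``extrapolated``).  BH across loci at ``config.fdr``
    sets q-values; a locus is ``significant`` when BH rejects and its
    envelope direction is not "none".
    """
    if len(null_theta) < 1000:
        raise ValueError("null cloud must have >= 1000 points")
    observed_theta = np.asarray(observed_theta, float)
    observed_he = np.asarray(observed_he, float)
    if locus_names is None:
        locus_names = [f"locus{i + 1}" for i in range(len(observed_theta))]

    nb = max(1, min(config.he_bins, len(null_theta) // 50))
    order = np.argsort(null_he)
    edges = np.array_split(order, nb)
    bin_theta = [np.sort(null_theta[e]) for e in edges]
    bin_centre = np.array([null_he[e].mean() for e in edges])

    def bin_stats(b: int, th: float) -> tuple[float, float, float]:
        arr = bin_theta[b]
        n = len(arr)
        n_le = int(np.searchsorted(arr, th, side="right"))
        n_ge = n - int(np.searchsorted(arr, th, side="left"))
        quant = n_le / n
        p_pos = (1 + n_ge) / (1 + n)
        p_bal = (1 + n_le) / (1 + n)
        return quant, p_pos, p_bal

    alpha = 1.0 - config.ci_level
    calls: list[OutlierCall] = []
    for name, th, he in zip(locus_names, observed_theta, observed_he):
        if np.isnan(th) or np.isnan(he):
            calls.append(
                OutlierCall(name, th, he, float("nan"), "none", 1.0, 1.0, 1.0)
            )
            continue
        extrap = False
        if he <= bin_centre[0] or nb == 1:
            b_lo = b_hi = 0
            w = 0.0
            extrap = he < null_he.min()
        elif he >= bin_centre[-1]:
            b_lo = b_hi = nb - 1
            w = 0.0
            extrap = he > null_he.max()
        else:
            b_hi = int(np.searchsorted(bin_centre, he))
            b_lo = b_hi - 1
            span = bin_centre[b_hi] - bin_centre[b_lo]
            w = (he - bin_centre[b_lo]) / span if span > 0 else 0.0
        q0 = bin_stats(b_lo, th)
        q1 = bin_stats(b_hi, th) if b_hi != b_lo else q0
        quant, p_pos, p_bal = ((1 - w) * np.array(q0) + w * np.array(q1)).tolist()
        if quant > 1 - alpha / 2:
            direction = "positive"
        elif quant < alpha / 2:
            direction = "balancing"
        else:
            direction = "none"
        # outlier tests are directional: the working p is the one-sided
        # value on the locus's own side of the envelope
        p = min(p_pos, p_bal)
        calls.append(
            OutlierCall(name, float(th), float(he), quant, direction, p, p_pos, p_bal, extrapolated=extrap)
        )

    pvals = np.array([c.p for c in calls])
    rej = benjamini_hochberg(pvals, alpha=config.fdr)
    m = (~np.isnan(pvals)).sum()
    order = np.argsort(pvals)
    qv = np.full(len(pvals), np.nan)
    ranked = pvals[order]
    q_sorted = ranked * m / (np.arange(1, len(ranked) + 1))
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    qv[order] = np.minimum(q_sorted, 1.0)
    for c, q, r in zip(calls, qv, rej):
        c.q = float(q)
        c.significant = bool(r) and c.direction != "none"
    return calls


def scan_outliers(
    table: GenotypeTable, config: NeutralSimConfig
) -> tuple[list[OutlierCall], dict]:
    """End-to-end outlier scan on a genotype table.

    Estimates per-locus theta and pooled He, sets the simulation's
    target FST to the trimmed neutral mean of the observed thetas, draws
    the null cloud and classifies every locus.  Returns the calls plus a
    small metadata dict (neutral mean, rejection count).
    """
    res = theta_wc(table)
    ac = tabulate(table)
    pooled = ac.counts.sum(axis=0)  # (L, K)
    tot = pooled.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pfreq = pooled / np.maximum(tot, 1e-300)[:, None]
        he = np.where(tot > 1, tot / np.maximum(tot - 1, 1e-300) * (1 - (pfreq**2).sum(axis=1)), np.nan)
    neutral_mean = neutral_mean_fst(res.per_locus.to_numpy(), config)
    run_cfg = NeutralSimConfig(
        n_demes=config.n_demes,
        sample_sizes=config.sample_sizes,
        target_fst=min(max(neutral_mean, 1e-4), 0.99),
        mutation_model=config.mutation_model,
        n_sims=config.n_sims,
        ci_level=config.ci_level,
        fdr=config.fdr,
        he_bins=config.he_bins,
        seed=config.seed,
    )
    null_theta, null_he, n_rej = simulate_neutral_locus(run_cfg)
    calls = classify_outliers(
        res.per_locus.to_numpy(), he, null_theta, null_he, run_cfg, list(table.locus_names)
    )
    return calls, {"neutral_mean_fst": neutral_mean, "n_rejected_draws": n_rej}


def calls_to_frame(calls: list[OutlierCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": c.locus,
                "theta": c.theta,
                "he": c.he,
                "quantile": c.quantile,
                "direction": c.direction,
                "p": c.p,
                "q": c.q,
                "significant": c.significant,
                "extrapolated": c.extrapolated,
            }
            for c in calls
        ]
    )
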