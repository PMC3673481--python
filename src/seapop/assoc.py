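"""Matrix correlation tests and allele-environment association scans.

Mantel tests correlate the lower triangles of two site-by-site
distance-like matrices; significance comes from simultaneous row+column
permutation of the second matrix, with the p-value one-sided toward the
sign of the observed correlation.  The partial variant residualises
both matrices on a third (ordinary least squares on the pair vectors)
and permutes the residualised second matrix.

The allele-environment scan follows the spatial-analysis-method (SAM)
design: for every locus x allele x environmental variable, a univariate
logistic regression of individual allele presence/absence on the
individual's site value, assessed by the Wald statistic with Bonferroni
thresholds at several probability levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeTable, PairwiseMatrix


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    controlled_for: str | None = None
    note: str = ""


def _aligned_offdiag(
    A: PairwiseMatrix, B: PairwiseMatrix, drop_sites=None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    labels = [l for l in A.labels if l in set(B.labels)]
    if drop_sites:
        labels = [l for l in labels if l not in set(drop_sites)]
    if len(labels) < 4:
        raise ValueError("need at least 4 common sites")
    a = A.reorder(labels).values
    b = B.reorder(labels).values
    return a, b, labels


def _tri(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices(len(m), k=-1)]


def mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    n_permutations: int = 9999,
    seed: int = 0,
    drop_sites: list[str] | None = None,
) -> MantelResult:
    """Mantel test: Pearson correlation of matrix lower triangles.

    The null permutes rows and columns of B simultaneously; p is
    one-sided toward positive correlation (the convention of the common
    R implementations: a negative observed r yields a large p), with the
    +1 smoothing (1 + exceedances) / (1 + permutations).  ``drop_sites``
    removes sites before testing (for leave-one-out robustness runs).
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    a, b, labels = _aligned_offdiag(A, B, drop_sites)
    va, vb = _tri(a), _tri(b)
    if va.std() == 0 or vb.std() == 0:
        return MantelResult(float("nan"), float("nan"), n_permutations, note="constant matrix")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(labels)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        vp = _tri(b[np.ix_(perm, perm)])
        count += np.corrcoef(va, vp)[0, 1] >= r_obs - 1e-12
    return MantelResult(r_obs, (1 + count) / (1 + n_permutations), n_permutations)


def partial_mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    C: PairwiseMatrix,
    n_permutations: int = 9999,
    seed: int = 0,
    drop_sites: list[str] | None = None,
) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    Lower-triangle vectors of A and B are residualised on C by OLS; the
    Pearson correlation of the residuals is tested by permuting the
    residualised-B matrix (rows and columns simultaneously), one-sided
    toward positive correlation.  A constant C degrades to a plain
    Mantel test with a warning.
    """
    a, b, labels = _aligned_offdiag(A, B, drop_sites)
    c = C.reorder(labels).values
    vc = _tri(c)
    if vc.std() == 0:
        warnings.warn("control matrix is constant; running a plain Mantel test")
        res = mantel(A, B, n_permutations, seed, drop_sites)
        return MantelResult(res.r, res.p, n_permutations, controlled_for=C.kind, note="constant control")
    va, vb = _tri(a), _tri(b)
    if va.std() == 0 or vb.std() == 0:
        return MantelResult(float("nan"), float("nan"), n_permutations, C.kind, "constant matrix")

    def residual_matrix(m_vec: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones_like(vc), vc])
        beta, *_ = np.linalg.lstsq(X, m_vec, rcond=None)
        return m_vec - X @ beta

    ra = residual_matrix(va)
    rb_vec = residual_matrix(vb)
    if ra.std() <= 1e-12 * max(va.std(), 1e-300) or rb_vec.std() <= 1e-12 * max(
        vb.std(), 1e-300
    ):
        return MantelResult(0.0, 1.0, n_permutations, C.kind, "degenerate residuals")
    r_obs = float(np.corrcoef(ra, rb_vec)[0, 1])

    # rebuild the residualised B as a symmetric matrix for permutation
    n = len(labels)
    rb = np.zeros((n, n))
    rb[np.tril_indices(n, k=-1)] = rb_vec
    rb = rb + rb.T
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        vp = _tri(rb[np.ix_(perm, perm)])
        count += np.corrcoef(ra, vp)[0, 1] >= r_obs - 1e-12
    return MantelResult(r_obs, (1 + count) / (1 + n_permutations), n_permutations, C.kind)


def env_distance(env: pd.DataFrame, variable: str) -> PairwiseMatrix:
    """1-D environmental distance matrix: d(a, b) = |x_a - x_b|."""
    if variable not in env.columns:
        raise KeyError(f"unknown environment variable {variable!r}")
    x = env[variable]
    if x.isna().any():
        bad = list(x.index[x.isna()])
        raise ValueError(f"missing {variable} for sites {bad}")
    v = x.to_numpy(float)
    return PairwiseMatrix(
        list(env.index.astype(str)), np.abs(v[:, None] - v[None, :]), kind="env_distance"
    )


def geo_distance_matrix(labels: list[str], values: np.ndarray) -> PairwiseMatrix:
    """Wrap a user-supplied geographic distance matrix."""
    return PairwiseMatrix(list(labels), values, kind="geo_distance")


# ---------------------------------------------------------------------------
# SAM-style logistic allele-environment associations


@dataclass
class SamResult:
    locus: str
    allele: int
    variable: str
    beta: float
    se: float
    wald: float
    p: float
    sig_05: bool
    sig_1e4: bool
    sig_1e7: bool
    separation: bool = False


def _irls_logistic(x: np.ndarray, Y: np.ndarray, max_iter=50, tol=1e-8):
    """Univariate logistic fits (intercept + slope) for many responses.

    ``x`` is the shared predictor (n,), ``Y`` a (n, m) 0/1 response
    matrix.  Returns (beta, se, converged, separated) for the slope.
    """
    n, m = Y.shape
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros((2, m))
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (Y - mu) / W
        # per-response 2x2 weighted normal equations, solved analytically
        s00 = W.sum(axis=0)
        s01 = (W * x[:, None]).sum(axis=0)
        s11 = (W * x[:, None] ** 2).sum(axis=0)
        t0 = (W * z).sum(axis=0)
        t1 = (W * z * x[:, None]).sum(axis=0)
        det = s00 * s11 - s01**2
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        new0 = (s11 * t0 - s01 * t1) / det
        new1 = (s00 * t1 - s01 * t0) / det
        delta = np.nanmax(
            np.abs(np.vstack([new0, new1]) - beta), axis=0
        )
        beta = np.vstack([new0, new1])
        converged = delta < tol
        if converged.all():
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = np.maximum(mu * (1 - mu), 1e-10)
    s00 = W.sum(axis=0)
    s01 = (W * x[:, None]).sum(axis=0)
    s11 = (W * x[:, None] ** 2).sum(axis=0)
    det = s00 * s11 - s01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var1 = s00 / det
    se = np.sqrt(np.maximum(var1, 0))
    separated = (np.abs(beta[1]) > 25) | ~np.isfinite(beta[1])
    return beta, se, converged, separated


def sam_logistic(
    table: GenotypeTable,
    env: pd.DataFrame,
    variables: list[str],
    levels: tuple[float, float, float] = (0.05, 1e-4, 1e-7),
) -> list[SamResult]:
    """Univariate logistic allele-environment association scan.

    Response: whether an individual carries at least one copy of the
    allele (individuals typed at the locus only).  Predictor: the
    individual's site value of the environmental variable.  Wald =
    (beta/se)^2 against chi-square(1); the Bonferroni divisor is the
    total number of tests (alleles x variables).  Alleles carried by
    fewer than 2 individuals, or absent in fewer than 2, are skipped.
    Complete separation is flagged and its p set conservatively to 1.
    """
    missing_sites = [s for s in table.site_labels if s not in env.index]
    if missing_sites:
        raise ValueError(f"environment missing sites: {missing_sites}")
    site_vals = {v: env[v].to_dict() for v in variables}
    for v in variables:
        if len(set(site_vals[v][s] for s in table.site_labels)) < 2:
            raise ValueError(f"variable {v!r} constant across sites")

    # enumerate testable alleles first to fix the Bonferroni divisor
    jobs = []  # (locus_idx, allele, carrier_vector, typed_mask)
    geno = table.genotypes
    for l, locus in enumerate(table.locus_names):
        typed = geno[:, l, 0] > 0
        if typed.sum() < 4:
            continue
        alleles = np.unique(geno[typed, l, :])
        for al in alleles:
            carrier = ((geno[:, l, 0] == al) | (geno[:, l, 1] == al)) & typed
            n_car = int(carrier.sum())
            if n_car < 2 or (typed.sum() - n_car) < 2:
                continue
            jobs.append((l, int(al), carrier, typed))
    n_tests = len(jobs) * len(variables)
    if n_tests == 0:
        return []
    thr = {lev: lev / n_tests for lev in levels}

    results: list[SamResult] = []
    site_per_ind = table.sites
    by_locus: dict[int, list] = {}
    for job in jobs:
        by_locus.setdefault(job[0], []).append(job)
    for v in variables:
        xv = np.array([site_vals[v][s] for s in site_per_ind], dtype=float)
        for l, group in by_locus.items():
            typed = group[0][3]
            x = xv[typed]
            Y = np.column_stack([job[2][typed] for job in group]).astype(float)
            beta, se, conv, sep = _irls_logistic(x, Y)
            with np.errstate(divide="ignore", invalid="ignore"):
                wald = (beta[1] / se) ** 2
            p = stats.chi2.sf(wald, df=1)
            for j, job in enumerate(group):
                bad = sep[j] or not np.isfinite(p[j])
                pj = 1.0 if bad else float(p[j])
                results.append(
                    SamResult(
                        locus=table.locus_names[l],
                        allele=job[1],
                        variable=v,
                        beta=float(beta[1, j]),
                        se=float(se[j]),
                        wald=float(wald[j]) if np.isfinite(wald[j]) else float("inf"),
                        p=pj,
                        sig_05=pj < thr[levels[0]],
                        sig_1e4=pj < thr[levels[1]],
                        sig_1e7=pj < thr[levels[2]],
                        separation=bool(sep[j]),
                    )
                )
    return results


def sam_to_frame(results: list[SamResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# diversity ~ environment linear models


@dataclass
class GlmTermTest:
    term: str
    F: float
    p: float
    df: tuple[int, int]


@dataclass
class GlmResult:
    coefficients: pd.Series
    term_tests: list[GlmTermTest]
    residual_shapiro_p: float
    aliased: list[str]


def _design(env: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(env))]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(env[a].to_numpy(float) * env[b].to_numpy(float))
        else:
            cols.append(env[t].to_numpy(float))
    return np.column_stack(cols)


def diversity_glm(
    diversity: pd.Series,
    env: pd.DataFrame,
    terms: list[str],
) -> GlmResult:
    """OLS of a site-level diversity summary on environmental terms,
    with marginal (drop-one-term) F tests.

    ``diversity`` is indexed by site (e.g. mean He or allelic richness
    per site); ``terms`` may include interactions as ``"a:b"``.  Each
    term's F test compares the full model against the model without
    that term, so results do not depend on entry order.  Residual
    normality is summarised by a Shapiro-Wilk p-value.
    """
    y = diversity.reindex(env.index).to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("diversity values missing for some sites")
    n = len(y)
    if n <= len(terms) + 1:
        raise ValueError("more terms than sites allow")
    X = _design(env, terms)
    rank = np.linalg.matrix_rank(X)
    aliased: list[str] = []
    if rank < X.shape[1]:
        # identify terms whose removal does not reduce the rank
        for j, t in enumerate(terms):
            Xr = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                aliased.append(t)
        warnings.warn(f"collinear design; aliased terms: {aliased}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr_full = float(resid @ resid)
    df_res = n - rank
    tests: list[GlmTermTest] = []
    for j, t in enumerate(terms):
        Xr = np.delete(X, j + 1, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rr = y - Xr @ br
        ssr_red = float(rr @ rr)
        df_diff = rank - np.linalg.matrix_rank(Xr)
        if df_diff == 0 or df_res == 0 or ssr_full == 0:
            tests.append(GlmTermTest(t, float("nan"), float("nan"), (0, df_res)))
            continue
        F = ((ssr_red - ssr_full) / df_diff) / (ssr_full / df_res)
        p = float(stats.f.sf(F, df_diff, df_res))
        tests.append(GlmTermTest(t, float(F), p, (df_diff, df_res)))
    shapiro_p = float(stats.shapiro(resid)[1]) if 3 <= n <= 5000 and resid.std() > 0 else float("nan")
    coef = pd.Series(beta, index=["(intercept)"] + terms)
    return GlmResult(coef, tests, shapiro_p, aliased)
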