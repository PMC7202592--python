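"""Covariate-adjusted enrichment scanning with permutation FWER control.

The core model is a per-feature logistic regression

    group ~ feature + P(ER+) + HER2 + mutation load per Mb

with a two-sided Wald test on the feature coefficient. Family-wise error
across the feature panel is controlled by min-p (maxT) permutation: the
outcome labels are permuted against whole sample rows, the full scan is
re-run per permutation, and each observed raw p is compared with the
permutation distribution of the minimum p across features, using the
(1 + k) / (n_perm + 1) estimator.

Because a 1000-permutation scan over a ~300-feature panel re-fits hundreds
of thousands of logistic models, the scan uses a Newton solver batched
across features (all per-feature 5-parameter models advance in lock-step
via einsum); the stand-alone :func:`fit_logistic` is an IRLS implementation
with a Firth-penalized fallback for separated data.

Supporting tests: Fisher 2x2 (scipy), exact/Monte-Carlo r x c Fisher,
Mann-Whitney, and helpers shared by the ESR1 and tissue-of-origin modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

logger = logging.getLogger("metbc")

_SEPARATION_BOUND = 12.0


# ------------------------------------------------------------ single fits


@dataclass
class LogisticFit:
    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    iterations: int
    separation_flag: bool = False
    penalized: bool = False

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns via QR pivoting on the correlation pattern
        _, r = np.linalg.qr(arr)
        bad = [X.columns[j] for j in range(arr.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or list(X.columns)}")


def _irls(y, X, tol=1e-8, max_iter=100):
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, H, False, it
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            eta = X @ beta
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-12, None)
            H = (X * w[:, None]).T @ X
            return beta, H, True, it
    return beta, H, False, max_iter


def _firth(y, X, tol=1e-8, max_iter=200):
    """Firth-penalized logistic fit; finite for separated data."""
    n, p = X.shape
    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        WX = X * w[:, None]
        H = WX.T @ X
        Hinv = np.linalg.inv(H)
        # leverages of the weighted design
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(w)[:, None], Hinv,
                      X * np.sqrt(w)[:, None])
        g = X.T @ (y - mu + h * (0.5 - mu))
        delta = Hinv @ g
        step = 1.0
        while np.max(np.abs(step * delta)) > 5.0:
            step /= 2.0
        beta = beta + step * delta
        if np.max(np.abs(step * delta)) < tol:
            break
    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    return beta, H, it


def fit_logistic(y, X: pd.DataFrame, tol: float = 1e-8, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` must include its intercept column. Quasi-separation is detected by
    diverging coefficients; the fit then falls back to a Firth-penalized
    solution and sets ``separation_flag``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    _check_design(X)
    arr = X.to_numpy(float)
    beta, H, converged, it = _irls(y, arr, tol=tol, max_iter=max_iter)
    separated = (not converged) or np.max(np.abs(beta)) > _SEPARATION_BOUND
    penalized = False
    if separated:
        beta, H, it = _firth(y, arr, tol=tol)
        converged = True
        penalized = True
    cov = np.linalg.inv(H)
    return LogisticFit(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        converged=converged, iterations=it,
        separation_flag=separated, penalized=penalized,
    )


def wald_test(fit: LogisticFit, predictor: str) -> tuple[float, float]:
    """Two-sided Wald z test on one coefficient."""
    b = fit.params[predictor]
    se = fit.se()[predictor]
    if not se > 0:
        logger.warning("zero SE for %s; Wald p undefined", predictor)
        return np.nan, np.nan
    z = b / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ------------------------------------------------------ batched scan core


class _BatchedScan:
    """Newton logistic fits for every feature simultaneously.

    Each feature f has the design [1, feats[:, f], covariates]. All
    per-feature designs share the covariate block, so each Newton step
    reduces to a handful of (F x n) @ (n x k) matrix products over shared
    factors; this is what makes thousand-permutation min-p scans
    tractable. Construct once per (features, covariates) pair and call
    :meth:`wald` with each (possibly permuted) outcome vector.

    Features whose coefficients diverge are capped at +/-12 on the logit
    scale and flagged (quasi-separation); the Wald statistic is still
    reported, so permutation replicates are treated identically to the
    observed data.
    """

    def __init__(self, feats: np.ndarray, covars: np.ndarray,
                 dtype=np.float64):
        n, F = feats.shape
        self.n, self.F = n, F
        self.dtype = dtype
        self.Ft = np.ascontiguousarray(feats.T, dtype=dtype)   # (F, n) binary
        self.C = np.column_stack([np.ones(n), covars]).astype(dtype)
        k1 = self.C.shape[1]
        self.k1 = k1
        self.p_dim = k1 + 1
        # all pairwise covariate products, for the H covariate block
        iu = np.triu_indices(k1)
        self.iu = iu
        self.CC = self.C[:, iu[0]] * self.C[:, iu[1]]    # (n, k1*(k1+1)/2)

    def wald(self, y: np.ndarray, tol: float | None = None, max_iter: int = 30):
        F, n, k1 = self.F, self.n, self.k1
        dt = self.dtype
        if tol is None:
            tol = 1e-8 if dt == np.float64 else 1e-4
        Ft, C, CC = self.Ft, self.C, self.CC
        y = np.asarray(y, dtype=dt)
        gamma = np.zeros((F, k1), dtype=dt)              # coefs of [1, covars]
        ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        gamma[:, 0] = np.log(ybar / (1 - ybar))
        b = np.zeros(F, dtype=dt)                        # feature coefs
        flagged = np.zeros(F, dtype=bool)
        H = np.empty((F, self.p_dim, self.p_dim), dtype=dt)
        iu = self.iu

        def fill_H(w):
            wf = w * Ft
            blk = w @ CC                                 # (F, n_pairs)
            H[:, iu[0], iu[1]] = blk
            H[:, iu[1], iu[0]] = blk
            hb = wf @ C                                  # (F, k1)
            H[:, :k1, k1] = hb
            H[:, k1, :k1] = hb
            H[:, k1, k1] = wf.sum(axis=1)
            return H

        for _ in range(max_iter):
            eta = gamma @ C.T
            eta += b[:, None] * Ft
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-12, None)
            r = y[None, :] - mu
            g = np.empty((F, self.p_dim), dtype=dt)
            g[:, :k1] = r @ C
            g[:, k1] = (r * Ft).sum(axis=1)
            fill_H(w)
            try:
                delta = np.linalg.solve(H, g[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                delta = np.linalg.solve(
                    H + dt(1e-6) * np.eye(self.p_dim, dtype=dt)[None],
                    g[:, :, None])[:, :, 0]
            gamma += delta[:, :k1]
            b += delta[:, k1]
            big = (np.max(np.abs(gamma), axis=1) > _SEPARATION_BOUND) | (
                np.abs(b) > _SEPARATION_BOUND)
            flagged |= big
            if big.any():
                np.clip(gamma, -_SEPARATION_BOUND, _SEPARATION_BOUND, out=gamma)
                np.clip(b, -_SEPARATION_BOUND, _SEPARATION_BOUND, out=b)
            if np.max(np.abs(delta)[~flagged], initial=0.0) < tol:
                break

        # Wald SE from the last information matrix (evaluated one tolerance-
        # sized step before the final estimate, which is negligible)
        try:
            cov = np.linalg.inv(H.astype(np.float64))
        except np.linalg.LinAlgError:
            cov = np.linalg.inv(H.astype(np.float64) + 1e-8 * np.eye(self.p_dim)[None])
        se = np.sqrt(np.maximum(cov[:, k1, k1], 1e-300))
        z = np.asarray(b, np.float64) / se
        p = 2 * stats.norm.sf(np.abs(z))
        return np.asarray(b, np.float64).copy(), se, z, p, flagged.copy()


def _batched_wald(y: np.ndarray, feats: np.ndarray, covars: np.ndarray,
                  tol: float = 1e-8, max_iter: int = 30):
    """One-shot wrapper around :class:`_BatchedScan`."""
    return _BatchedScan(feats, covars).wald(y, tol=tol, max_iter=max_iter)


@dataclass
class EnrichmentResult:
    feature: str
    rate_group1: float
    rate_group0: float
    odds_ratio: float
    wald_z: float
    p_raw: float
    p_corrected: float | None
    n_tested: int
    context: str = "all_mets"
    variant_filter: str = "all_variants"
    note: str = ""


def _scan_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    return df.sort_values("p_raw", kind="mergesort").reset_index(drop=True)


def enrichment_scan(
    features: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    min_count: int = 10,
    context: str = "all_mets",
    variant_filter: str = "all_variants",
) -> pd.DataFrame:
    """Per-feature covariate-adjusted logistic Wald scan.

    ``outcome`` is the binary group indicator (1 = metastasis); features
    with fewer than ``min_count`` events among the tested samples are
    skipped. Returns a frame sorted by raw p.
    """
    y = np.asarray(outcome, float)
    feats = features.to_numpy(float)
    cov = np.asarray(covariates, float)
    counts = feats.sum(axis=0)
    variable = (feats.std(axis=0) > 0)
    keep = (counts >= min_count) & variable
    results: list[EnrichmentResult] = []
    names = list(features.columns)
    if keep.any():
        b, se, z, p, flagged = _batched_wald(y, feats[:, keep], cov)
        for i, j in enumerate(np.nonzero(keep)[0]):
            col = feats[:, j]
            r1 = col[y == 1].mean() if (y == 1).any() else np.nan
            r0 = col[y == 0].mean() if (y == 0).any() else np.nan
            results.append(EnrichmentResult(
                feature=names[j], rate_group1=float(r1), rate_group0=float(r0),
                odds_ratio=float(np.exp(b[i])), wald_z=float(z[i]),
                p_raw=float(p[i]), p_corrected=None, n_tested=len(y),
                context=context, variant_filter=variant_filter,
                note="quasi-separated" if flagged[i] else "",
            ))
    for j in np.nonzero(~keep)[0]:
        results.append(EnrichmentResult(
            feature=names[j], rate_group1=np.nan, rate_group0=np.nan,
            odds_ratio=np.nan, wald_z=np.nan, p_raw=np.nan, p_corrected=None,
            n_tested=len(y), context=context, variant_filter=variant_filter,
            note=f"skipped: fewer than {min_count} events" if variable[j]
            else "skipped: constant feature",
        ))
    return _scan_frame(results)


def maxt_permutation_correct(
    features: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_count: int = 10,
    **scan_kw,
) -> pd.DataFrame:
    """min-p permutation family-wise correction over the feature panel.

    The outcome vector is permuted ``n_perm`` times (covariates stay
    attached to their samples), the scan re-runs per permutation and the
    minimum raw p across features is recorded;
    p_corrected = (1 + #{min-p_perm <= p_raw}) / (n_perm + 1),
    which is always >= p_raw's own permutation estimate and guarantees
    p_corrected >= p_raw under the same estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs = enrichment_scan(features, outcome, covariates, min_count=min_count, **scan_kw)
    y = np.asarray(outcome, float)
    feats = features.to_numpy(float)
    cov = np.asarray(covariates, float)
    counts = feats.sum(axis=0)
    keep = (counts >= min_count) & (feats.std(axis=0) > 0)
    # single precision is ample for permutation p-values (MC resolution is
    # 1/(n_perm+1)) and roughly halves the wall time of the null scans
    scanner = _BatchedScan(feats[:, keep], cov, dtype=np.float32)
    min_ps = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        _, _, _, p, _ = scanner.wald(yp)
        min_ps[b] = np.nanmin(p) if scanner.F else 1.0
    p_corr = []
    for praw in obs["p_raw"]:
        if np.isnan(praw):
            p_corr.append(np.nan)
        else:
            k = int(np.sum(min_ps <= praw))
            p_corr.append(min(1.0, max((1 + k) / (n_perm + 1), praw)))
    out = obs.copy()
    out["p_corrected"] = p_corr
    return out


def site_specific_scan(
    features: pd.DataFrame,
    sites: pd.Series,
    groups: pd.Series,
    covariates: pd.DataFrame,
    min_count: int = 10,
    n_perm: int = 0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-site scans: each metastatic site vs all local samples.

    With ``n_perm > 0`` each site's scan gets its own min-p permutation
    correction.
    """
    sites = pd.Series(np.asarray(sites, dtype=object))
    groups = pd.Series(np.asarray(groups, dtype=object))
    local = groups.eq("local").to_numpy()
    out = {}
    for s in sorted(set(sites[groups.eq("metastasis")])):
        mask = (local | (sites.eq(s) & groups.eq("metastasis"))).to_numpy()
        if not (sites.eq(s) & groups.eq("metastasis")).any():
            logger.warning("site %s has no samples; skipped", s)
            continue
        y = groups[mask].eq("metastasis").to_numpy().astype(float)
        f = features.loc[mask]
        c = covariates.loc[mask]
        if n_perm > 0:
            out[s] = maxt_permutation_correct(
                f, y, c, n_perm=n_perm, seed=seed, min_count=min_count,
                context=f"site:{s}")
        else:
            out[s] = enrichment_scan(f, y, c, min_count=min_count, context=f"site:{s}")
    return out


# ------------------------------------------------------------ exact tests


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    t = np.asarray(table)
    if (t < 0).any():
        raise ValueError("negative counts")
    return float(stats.fisher_exact(t)[1])


def _log_table_prob(t, row_f, col_f, n_f):
    return row_f + col_f - n_f - gammaln(np.asarray(t, float) + 1).sum()


def _enumerate_tables(row_sums, col_sums):
    """All nonnegative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(i, cols_left):
        if i == r - 1:
            yield (tuple(cols_left),)
            return
        # enumerate row i cell-by-cell within remaining margins
        def row_rec(j, remaining, cols):
            if j == c - 1:
                if remaining <= cols[j]:
                    yield (remaining,)
                return
            for v in range(min(remaining, cols[j]) + 1):
                for rest in row_rec(j + 1, remaining - v, cols):
                    yield (v,) + rest
        for row in row_rec(0, row_sums[i], cols_left):
            new_left = tuple(cl - v for cl, v in zip(cols_left, row))
            for rest in rec(i + 1, new_left):
                yield (row,) + rest

    yield from rec(0, tuple(col_sums))


def fisher_exact_rxc(table, n_mc: int = 20000, seed: int = 0,
                     max_enumeration: int = 200000) -> float:
    """Fisher exact p for an r x c table.

    Small tables are enumerated exactly; larger ones use Monte Carlo with
    margins fixed (Patefield sampling) and the (1 + k)/(n + 1) estimator.
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("negative counts")
    if t.shape == (2, 2):
        return fisher_exact_2x2(t)
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if row_sums.sum() == 0:
        return 1.0
    row_f = gammaln(row_sums + 1).sum()
    col_f = gammaln(col_sums + 1).sum()
    n_f = gammaln(t.sum() + 1)
    lp_obs = _log_table_prob(t, row_f, col_f, n_f)

    # rough size bound for exact enumeration
    bound = 1
    for rs in row_sums[:-1]:
        bound *= int((rs + 1) ** (len(col_sums) - 1))
        if bound > max_enumeration:
            break
    if bound <= max_enumeration:
        p = 0.0
        for tab in _enumerate_tables(list(row_sums), list(col_sums)):
            lp = _log_table_prob(tab, row_f, col_f, n_f)
            if lp <= lp_obs + 1e-9:
                p += float(np.exp(lp))
        return min(1.0, p)

    rv = stats.random_table(row_sums, col_sums, seed=np.random.default_rng(seed))
    draws = rv.rvs(n_mc)
    lps = np.array([_log_table_prob(d, row_f, col_f, n_f) for d in draws])
    k = int(np.sum(lps <= lp_obs + 1e-9))
    return (1 + k) / (n_mc + 1)


def compare_counts(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (two-sided, tie-corrected normal approximation)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
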