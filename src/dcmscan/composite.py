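"""The de-correlated composite of multiple signals (DCMS).

Each raw statistic track is converted to one-tailed p-values by fractional
genome-wide rank. With p_lt the p-value of statistic t at SNP l, and R the
robust (minimum covariance determinant) correlation matrix among the raw
statistics, the composite is

    DCMS_l = sum_t  log[(1 - p_lt) / p_lt] / w_t,     w_t = sum_i |r_it|

so the weight factor 1/w_t lies in [1/n, 1]: mutually uncorrelated
statistics each contribute their full logit (DCMS is their sum), perfectly
correlated ones are averaged. Raw DCMS scores are calibrated against an
intercept-only Huber-robust normal fit; the upper-tail normal p-values are
converted to Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .popstats import STAT_TAILS, StatTrack


class DegenerateStatisticsError(ValueError):
    """Raised when the statistic matrix cannot support a scatter estimate."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PMatrix:
    """N_snps x n one-tailed fractional-rank p-values, columns = statistics."""

    P: np.ndarray
    stat_names: list[str]
    tails: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[1] != len(self.stat_names):
            raise ValueError("P must be N x n with one column per statistic")
        if np.any(self.P <= 0.0) or np.any(self.P >= 1.0):
            raise ValueError("p-values must lie strictly in (0, 1)")


@dataclass
class CorrMatrix:
    """n x n correlation among the combined statistics (r_it of the weights)."""

    R: np.ndarray
    stat_names: list[str]

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        n = len(self.stat_names)
        if R.shape != (n, n):
            raise ValueError(f"correlation matrix must be {n} x {n}")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(R) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
        self.R = np.clip(R, -1.0, 1.0)
        w = self.weights()
        # guaranteed by unit diagonal and |r| <= 1; asserted on every build
        if np.any(w < 1.0 - 1e-9) or np.any(w > n + 1e-9):
            raise AssertionError("weight bound 1/n <= 1/sum|r_it| <= 1 violated")

    def weights(self) -> np.ndarray:
        """w_t = sum_i |r_it|; the per-statistic weight factor is 1/w_t."""
        return np.sum(np.abs(self.R), axis=0)


@dataclass
class DcmsResult:
    """Per-SNP composite scores with their normal calibration and q-values."""

    dcms: np.ndarray
    mu: float
    sd: float
    p: np.ndarray
    q: np.ndarray


# ---------------------------------------------------------------------------
# fractional-rank p-values
# ---------------------------------------------------------------------------

def rank_pvalues(track: StatTrack | np.ndarray, tail: str) -> np.ndarray:
    """One-tailed empirical p-values from fractional ranks.

    With ascending mean-tie ranks r_l over N values, the left-tail p is
    r_l/(N+1) (small values significant) and the right-tail p is
    (N+1-r_l)/(N+1) (large values significant). The N+1 denominator keeps
    every p strictly inside (0, 1), as the logit transform requires.
    """
    values = track.values if isinstance(track, StatTrack) else np.asarray(track, float)
    if values.size == 0:
        raise ValueError("empty statistic track")
    if not np.all(np.isfinite(values)):
        raise ValueError("statistic track contains non-finite values")
    r = stats.rankdata(values, method="average")
    N = values.size
    if tail == "left":
        return r / (N + 1.0)
    if tail == "right":
        return (N + 1.0 - r) / (N + 1.0)
    raise ValueError(f"tail must be 'left' or 'right', got {tail!r}")


def build_pmatrix(tracks: list[StatTrack]) -> PMatrix:
    """Stack per-statistic rank p-values, tail chosen by statistic identity
    (right for FST/H1/H12, left for pi and Tajima's D)."""
    names = [t.stat_name for t in tracks]
    cols = [rank_pvalues(t, STAT_TAILS[t.stat_name]) for t in tracks]
    return PMatrix(np.column_stack(cols), names, {n: STAT_TAILS[n] for n in names})


# ---------------------------------------------------------------------------
# FAST-MCD robust correlation
# ---------------------------------------------------------------------------

def _c_step_converge(
    X: np.ndarray, support: np.ndarray, h: int, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Concentrate a candidate support set by repeated C-steps until the
    support no longer changes. Returns (mu, cov, support, det)."""
    support = np.sort(support)
    for _ in range(max_iter):
        mu = X[support].mean(axis=0)
        cov = np.cov(X[support], rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        det = float(np.linalg.det(cov))
        if det <= 0.0 or not np.isfinite(det):
            return mu, cov, support, det
        diff = X - mu
        d2 = np.einsum("ij,ij->i", diff @ np.linalg.inv(cov), diff)
        new = np.sort(np.argsort(d2, kind="stable")[:h])
        if np.array_equal(new, support):
            return mu, cov, support, det
        support = new
    return mu, cov, support, det


def fast_mcd(
    X: np.ndarray,
    alpha: float = 0.75,
    nsamp: int = 50_000,
    seed: int | None = None,
    h: int | None = None,
    reweight: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FAST-MCD estimate of multivariate location and scatter.

    ``nsamp`` random (n+1)-point elemental subsets are each concentrated by
    C-steps to convergence; the minimum-determinant solution is
    consistency-corrected and (by default) reweighted with the chi-square(n)
    0.975 cutoff. When all (n+1)-subsets number at most ``nsamp`` they are
    enumerated exhaustively instead of sampled.

    Returns (location, covariance, support mask of the raw h-subset).
    """
    X = np.asarray(X, dtype=float)
    N, n = X.shape
    if N <= n:
        raise ValueError("need more observations than variables")
    if not 0.5 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0.5, 1]")
    if h is None:
        h = int(math.ceil(alpha * N))
    h = max(min(h, N), n + 1)

    if h == N:  # classical estimate; nothing to concentrate
        mu = X.mean(axis=0)
        cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
        return mu, cov, np.ones(N, dtype=bool)

    n_total = math.comb(N, n + 1)
    if n_total <= nsamp:
        subsets = (np.array(c) for c in itertools.combinations(range(N), n + 1))
    else:
        rng = np.random.default_rng(seed)
        subsets = (rng.choice(N, size=n + 1, replace=False) for _ in range(nsamp))

    best_det = np.inf
    best: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    for sub in subsets:
        cov0 = np.atleast_2d(np.cov(X[sub], rowvar=False, ddof=1))
        if not np.isfinite(cov0).all() or np.linalg.det(cov0) <= 0.0:
            continue  # degenerate elemental subset
        mu, cov, support, det = _c_step_converge(X, np.asarray(sub), h)
        if det <= 0.0:
            # exact-fit: >= h points on a hyperplane; such a scatter cannot
            # yield a correlation, so keep the best non-singular solution
            continue
        if det < best_det:
            best_det = det
            best = (mu, cov, support)
    if best is None:
        raise DegenerateStatisticsError(
            "degenerate statistics: every concentrated subset was singular"
        )
    mu_raw, cov_raw, support = best

    # consistency factor for the h/N-trimmed covariance
    frac = h / N
    cov_raw = cov_raw * _mcd_consistency(frac, n)

    if not reweight or np.linalg.det(cov_raw) <= 0.0:
        mask = np.zeros(N, dtype=bool)
        mask[support] = True
        return mu_raw, cov_raw, mask

    diff = X - mu_raw
    d2 = np.einsum("ij,ij->i", diff @ np.linalg.inv(cov_raw), diff)
    w = d2 <= stats.chi2.ppf(0.975, df=n)
    if w.sum() <= n:
        w = np.zeros(N, dtype=bool)
        w[support] = True
    mu_rw = X[w].mean(axis=0)
    cov_rw = np.atleast_2d(np.cov(X[w], rowvar=False, ddof=1))
    cov_rw = cov_rw * _mcd_consistency(0.975, n)
    return mu_rw, cov_rw, w


def _mcd_consistency(frac: float, n: int) -> float:
    """Fisher consistency factor for an h/N-fraction trimmed normal scatter."""
    if frac >= 1.0:
        return 1.0
    q = stats.chi2.ppf(frac, df=n)
    return frac / stats.chi2.cdf(q, df=n + 2)


def cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0):
        raise DegenerateStatisticsError("zero variance in robust scatter")
    R = cov / np.outer(d, d)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return R


def mcd_correlation(
    S: np.ndarray,
    stat_names: list[str] | None = None,
    alpha: float = 0.75,
    nsamp: int = 50_000,
    seed: int | None = None,
    h: int | None = None,
) -> CorrMatrix:
    """Robust correlation among statistic columns via FAST-MCD.

    Rows containing non-finite values are dropped first; columns with zero
    spread are rejected (a constant statistic carries no rank information
    and makes the scatter singular).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2:
        raise ValueError("S must be an N x n matrix")
    finite = np.all(np.isfinite(S), axis=1)
    S = S[finite]
    N, n = S.shape
    if N <= n:
        raise ValueError("need more SNPs than statistics")
    spread = S.max(axis=0) - S.min(axis=0)
    if np.any(spread == 0.0):
        j = int(np.argmax(spread == 0.0))
        name = stat_names[j] if stat_names else f"column {j}"
        raise DegenerateStatisticsError(f"statistic {name} has zero spread")
    names = stat_names if stat_names is not None else [f"s{i}" for i in range(n)]

    # byte-identical columns make every scatter exactly singular; estimate on
    # the unique columns and patch r = 1 between duplicates
    rep = np.arange(n)
    for j in range(n):
        for i in range(j):
            if rep[i] == i and np.array_equal(S[:, i], S[:, j]):
                rep[j] = i
                break
    uniq = np.flatnonzero(rep == np.arange(n))
    _, cov, _ = fast_mcd(S[:, uniq], alpha=alpha, nsamp=nsamp, seed=seed, h=h)
    Ru = cov_to_corr(cov)
    pos = {int(u): k for k, u in enumerate(uniq)}
    R = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            R[i, j] = Ru[pos[int(rep[i])], pos[int(rep[j])]]
    return CorrMatrix(R, list(names))


# ---------------------------------------------------------------------------
# the composite and its calibration
# ---------------------------------------------------------------------------

def dcms_scores(P: PMatrix, R: CorrMatrix, log_base: float | None = None) -> np.ndarray:
    """Per-SNP composite: sum over statistics of logit(1 - p) scaled by the
    reciprocal total absolute correlation of that statistic.

    ``log_base`` defaults to the natural log; the base only rescales the
    scores and cancels after normal calibration.
    """
    if P.stat_names != R.stat_names:
        raise ValueError("P and R statistic orders differ")
    terms = np.log((1.0 - P.P) / P.P)
    if log_base is not None:
        terms = terms / math.log(log_base)
    return terms @ (1.0 / R.weights())


def huber_normal_fit(
    dcms: np.ndarray,
    k: float = 1.345,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Intercept-only Huber M-estimate of location with MAD scale.

    Initialization mu = median, s = 1.4826 * MAD; each iteration applies
    Huber weights w = min(1, k/|u|) with u = (x - mu)/s, updates mu as the
    weighted mean and re-estimates s = 1.4826 * median|x - mu|; converged
    when |delta mu| < tol * s. Mirrors an rlm(x ~ 1) fit. Returns (mu, sd).
    """
    x = np.asarray(dcms, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 finite scores")
    if x.max() == x.min():
        raise ValueError("degenerate scores: zero spread")
    mu = float(np.median(x))
    s = 1.4826 * float(np.median(np.abs(x - mu)))
    if s == 0.0:
        s = float(np.std(x))
    for _ in range(max_iter):
        u = (x - mu) / s
        au = np.abs(u)
        w = np.where(au > 0, np.minimum(1.0, k / np.maximum(au, 1e-300)), 1.0)
        mu_new = float(np.sum(w * x) / np.sum(w))
        s_new = 1.4826 * float(np.median(np.abs(x - mu_new)))
        if s_new == 0.0:
            s_new = s
        done = abs(mu_new - mu) < tol * s_new
        mu, s = mu_new, s_new
        if done:
            break
    return mu, s


def normal_pvalues(dcms: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Upper-tail normal p-values of the scores under N(mu, sd)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return stats.norm.sf((np.asarray(dcms, float) - mu) / sd)


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (adjusted p, FDR control)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def dcms_from_tracks(
    tracks: list[StatTrack],
    alpha: float = 0.75,
    nsamp: int = 50_000,
    seed: int | None = None,
    log_base: float | None = None,
) -> tuple[DcmsResult, PMatrix, CorrMatrix]:
    """Full composite stage: tracks -> rank p-values -> MCD correlation ->
    DCMS -> Huber-normal calibration -> BH q-values."""
    P = build_pmatrix(tracks)
    S = np.column_stack([t.values for t in tracks])
    R = mcd_correlation(S, stat_names=P.stat_names, alpha=alpha, nsamp=nsamp, seed=seed)
    scores = dcms_scores(P, R, log_base=log_base)
    mu, sd = huber_normal_fit(scores)
    p = normal_pvalues(scores, mu, sd)
    q = bh_qvalues(p)
    return DcmsResult(scores, mu, sd, p, q), P, R
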