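"""Rank tests for the number of ancestry streams and admixture-weight
estimation against an outgroup set (the qpWave/qpAdm computation).

The machinery works in the space of f4-statistics. For a *left* set of
populations (target and candidate sources) and a *right* set (outgroups
differentially related to the lefts), the matrix

    X[i, j] = f4(left_1, left_{i+1}; right_1, right_{j+1})

has rank equal to the number of independent ancestry streams relating the
left to the right set. A target that is a k-way mixture of the sources makes
the (k+1)-population left set span only k streams, which is what the fit
p-value tests. Weights are estimated by minimising the covariance-weighted
norm of

    e_j(w) = f4(T, base; R_j, base) − Σ_a w_a f4(S_a, base; R_j, base)

subject to Σ w = 1, where ``base`` is the first outgroup. Weights may leave
the simplex; infeasibility is reported, never clipped.

All covariances come from a weighted delete-one-block jackknife over genetic
blocks. Because desk-scale genomes yield modest block counts, the default
p-value convention maps the quadratic form through a Hotelling-T²/F
transformation, F = stat·(g−d)/(d·(g−1)) on (d, g−d) degrees of freedom with
g blocks and d residual dimensions; a plain chi-square convention is
available. The convention in force is recorded in result metadata and is
validated by null-simulation calibration in the test suite.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .fstats import BlockPartition, freq_and_count, make_blocks
from .panel import GenotypePanel

RIDGE_FACTOR = 1e-10


# ------------------------------------------------------------- f4 block sums

class BlockF4:
    """Per-block sums of f4 contributions over a set of populations.

    Computes population frequencies once, then serves arbitrary f4 quadruples
    (by population label) as per-entry estimates with per-block sums and
    variant counts, each entry using every variant where its four populations
    all have data ("allsnps" behaviour).
    """

    def __init__(self, panel: GenotypePanel, labels: Sequence,
                 blocks: BlockPartition | None = None, block_cm: float = 5.0):
        self.blocks = make_blocks(panel.variants, block_cm) if blocks is None else blocks
        self.labels = list(labels)
        self._idx = {self._key(lab): i for i, lab in enumerate(self.labels)}
        P, N = [], []
        for lab in self.labels:
            p, n = freq_and_count(panel, lab)
            P.append(p)
            N.append(n)
        self.P = np.vstack(P)
        self.N = np.vstack(N)

    @staticmethod
    def _key(lab):
        return lab if isinstance(lab, str) else tuple(lab)

    def stats(self, quads: Sequence[tuple]) -> "F4Set":
        g = self.blocks.n_blocks
        E = len(quads)
        S = np.zeros((g, E))
        M = np.zeros((g, E))
        est = np.zeros(E)
        for e, (a, b, c, d) in enumerate(quads):
            ia, ib, ic, id_ = (self._idx[self._key(x)] for x in (a, b, c, d))
            mask = ((self.N[ia] >= 1) & (self.N[ib] >= 1)
                    & (self.N[ic] >= 1) & (self.N[id_] >= 1))
            contrib = (self.P[ia] - self.P[ib]) * (self.P[ic] - self.P[id_])
            contrib = np.where(mask, contrib, 0.0)
            S[:, e] = np.bincount(self.blocks.index, weights=contrib, minlength=g)
            M[:, e] = np.bincount(self.blocks.index, weights=mask.astype(float),
                                  minlength=g)
            tot = M[:, e].sum()
            if tot == 0:
                raise ValueError(f"f4 quadruple {(a, b, c, d)} has no usable variants")
            est[e] = S[:, e].sum() / tot
        return F4Set(quads=list(quads), est=est, S=S, M=M)


@dataclasses.dataclass
class F4Set:
    """Estimates plus per-block sums/counts for a list of f4 quadruples."""
    quads: list
    est: np.ndarray
    S: np.ndarray  # (n_blocks, n_entries) contribution sums
    M: np.ndarray  # (n_blocks, n_entries) variant counts

    @property
    def n_blocks(self) -> int:
        return self.S.shape[0]

    def leave_one_out(self) -> np.ndarray:
        """Delete-one-block entry estimates, shape (n_blocks, n_entries)."""
        tot_s = self.S.sum(axis=0)
        tot_m = self.M.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            loo = (tot_s - self.S) / (tot_m - self.M)
        return np.where(np.isfinite(loo), loo, self.est)

    def jackknife_cov(self) -> np.ndarray:
        """Weighted block-jackknife covariance of the entry vector.

        Per-entry Busing pseudovalues scaled by 1/sqrt(h_j − 1); with equal
        block sizes this reduces to the standard delete-one jackknife
        covariance (g−1)/g · Σ (v_j − v̄)(v_j − v̄)ᵀ.
        """
        g = self.n_blocks
        n = self.M.sum(axis=0)
        loo = self.leave_one_out()
        with np.errstate(invalid="ignore", divide="ignore"):
            h = np.where(self.M > 0, n / np.maximum(self.M, 1e-300), np.inf)
        theta_j = g * self.est - ((1.0 - self.M / n) * loo).sum(axis=0)
        tau = h * self.est - (h - 1.0) * loo - theta_j
        scaled = np.where(self.M > 0, tau / np.sqrt(np.maximum(h - 1.0, 1e-300)), 0.0)
        return scaled.T @ scaled / g

    def block_weights(self) -> np.ndarray:
        """Scalar per-block weights (mean variant count across entries)."""
        return self.M.mean(axis=1)

    def delete_one(self, skip: int) -> tuple[np.ndarray, np.ndarray]:
        """Entry estimates and jackknife covariance with one block removed.

        Re-estimating the covariance inside each delete-one replicate lets a
        downstream jackknife propagate the noise of the estimated GLS metric
        itself, which is a real variance component at modest block counts.
        """
        g = self.S.shape[0]
        keep = np.arange(g) != skip
        S2, M2 = self.S[keep], self.M[keep]
        tot_s, tot_m = S2.sum(axis=0), M2.sum(axis=0)
        est = tot_s / tot_m
        with np.errstate(invalid="ignore", divide="ignore"):
            loo = (tot_s - S2) / (tot_m - M2)
        loo = np.where(np.isfinite(loo), loo, est)
        n = tot_m
        with np.errstate(invalid="ignore", divide="ignore"):
            h = np.where(M2 > 0, n / np.maximum(M2, 1e-300), np.inf)
        theta = (g - 1) * est - ((1.0 - M2 / n) * loo).sum(axis=0)
        tau = h * est - (h - 1.0) * loo - theta
        scaled = np.where(M2 > 0, tau / np.sqrt(np.maximum(h - 1.0, 1e-300)), 0.0)
        return est, scaled.T @ scaled / (g - 1)


# ----------------------------------------------------------------- utilities

def _solve_spd(C: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve C X = B for symmetric positive (semi)definite C.

    Falls back to ridge regularisation eps = 1e-10 · trace/dim when the
    Cholesky factorisation fails; returns (solution, eps_used).
    """
    eps = 0.0
    try:
        cf = np.linalg.cholesky(C)
        x = np.linalg.solve(cf.T, np.linalg.solve(cf, B))
        return x, eps
    except np.linalg.LinAlgError:
        eps = RIDGE_FACTOR * np.trace(C) / len(C)
        if eps <= 0:
            eps = RIDGE_FACTOR
        Creg = C + eps * np.eye(len(C))
        return np.linalg.solve(Creg, B), eps


def _quadratic_pvalue(stat: float, df: int, g: int, method: str) -> float:
    """Tail probability for a jackknife-covariance quadratic form.

    ``hotelling`` maps the statistic through the T²→F transformation with g
    blocks playing the role of the sample size; ``chisq`` uses the asymptotic
    chi-square. Falls back to chi-square when g ≤ df + 1.
    """
    if df <= 0:
        return 1.0
    if method == "hotelling" and g > df + 1:
        fstat = stat * (g - df) / (df * (g - 1))
        return float(sps.f.sf(fstat, df, g - df))
    return float(sps.chi2.sf(stat, df))


# ------------------------------------------------------------------ f4 matrix

def f4_matrix(panel: GenotypePanel, left: Sequence, right: Sequence,
              blocks: BlockPartition | None = None, block_cm: float = 5.0):
    """The (l−1)×(r−1) qpWave matrix with its jackknife covariance.

    Returns ``(X, C, f4set)`` with X[i, j] = f4(left_1, left_{i+2-1};
    right_1, right_{j+1}) and C the covariance of vec(X) (row-major).
    """
    bf = BlockF4(panel, list(left) + [r for r in right if r not in left],
                 blocks=blocks, block_cm=block_cm)
    quads = [(left[0], li, right[0], rj) for li in left[1:] for rj in right[1:]]
    f4set = bf.stats(quads)
    X = f4set.est.reshape(len(left) - 1, len(right) - 1)
    C = f4set.jackknife_cov()
    return X, C, f4set


# ------------------------------------------------------------------ rank test

@dataclasses.dataclass
class RankTestResult:
    left: tuple
    right: tuple
    stats: dict
    dfs: dict
    p_values: dict
    n_blocks: int
    method: str
    ridge_eps: float = 0.0


def _weighted_lowrank(x: np.ndarray, Cinv_mul, shape: tuple[int, int], k: int,
                      max_iter: int = 200, tol: float = 1e-12):
    """Best rank-k approximation of the matrix behind vec x under the
    covariance-weighted norm, by alternating generalised least squares."""
    l1, r1 = shape
    X = x.reshape(l1, r1)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    A = U[:, :k] * np.sqrt(s[:k])
    B = (Vt[:k].T) * np.sqrt(s[:k])

    def stat_of(vec_e):
        resid = x - vec_e
        return float(resid @ Cinv_mul(resid))

    prev = np.inf
    for _ in range(max_iter):
        # design for vec(A): d vec(AB^T)[i*r1+j] / dA[i,c] = B[j,c]
        MA = np.zeros((l1 * r1, l1 * k))
        for i in range(l1):
            MA[i * r1:(i + 1) * r1, i * k:(i + 1) * k] = B
        a = _gls(MA, x, Cinv_mul)
        A = a.reshape(l1, k)
        MB = np.zeros((l1 * r1, r1 * k))
        for i in range(l1):
            for j in range(r1):
                MB[i * r1 + j, j * k:(j + 1) * k] = A[i]
        b = _gls(MB, x, Cinv_mul)
        B = b.reshape(r1, k)
        cur = stat_of((A @ B.T).ravel())
        if abs(prev - cur) < tol * (1.0 + abs(cur)):
            break
        prev = cur
    return cur


def _gls(M: np.ndarray, x: np.ndarray, Cinv_mul) -> np.ndarray:
    W = Cinv_mul(M)
    lhs = M.T @ W
    rhs = M.T @ Cinv_mul(x)
    return np.linalg.lstsq(lhs, rhs, rcond=None)[0]


def rank_test(panel: GenotypePanel, left: Sequence, right: Sequence,
              blocks: BlockPartition | None = None, block_cm: float = 5.0,
              ranks: Sequence[int] | None = None,
              method: str = "hotelling") -> RankTestResult:
    """Test how many ancestry streams relate ``left`` to ``right``.

    For each candidate rank k the best rank-k approximation of the f4 matrix
    is fitted under the jackknife-covariance metric; the minimised quadratic
    form is referred to (l−1−k)(r−1−k) residual degrees of freedom. A high
    p-value means k streams suffice.
    """
    l1, r1 = len(left) - 1, len(right) - 1
    if l1 < 1 or r1 < 1:
        raise ValueError("need at least two left and two right populations")
    X, C, f4set = f4_matrix(panel, left, right, blocks=blocks, block_cm=block_cm)
    x = X.ravel()
    eps_used = 0.0

    def Cinv_mul(B):
        nonlocal eps_used
        out, eps = _solve_spd(C, B)
        eps_used = max(eps_used, eps)
        return out

    if ranks is None:
        ranks = range(min(l1, r1))
    stats_, dfs, ps = {}, {}, {}
    g = f4set.n_blocks
    for k in ranks:
        df = (l1 - k) * (r1 - k)
        if df <= 0:
            stats_[k], dfs[k], ps[k] = 0.0, 0, 1.0
            continue
        if k == 0:
            stat = float(x @ Cinv_mul(x))
        else:
            stat = _weighted_lowrank(x, Cinv_mul, (l1, r1), k)
        stats_[k] = stat
        dfs[k] = df
        ps[k] = _quadratic_pvalue(stat, df, g, method)
    return RankTestResult(left=tuple(left), right=tuple(right), stats=stats_,
                          dfs=dfs, p_values=ps, n_blocks=g, method=method,
                          ridge_eps=eps_used)


# ---------------------------------------------------------------- fit weights

@dataclasses.dataclass
class AdmixtureFit:
    target: object
    sources: tuple
    outgroups: tuple
    weights: np.ndarray
    weight_se: np.ndarray
    rank_p: dict
    fit_p: float
    fit_stat: float
    fit_df: int
    n_blocks: int
    method: str
    feasible: bool
    ridge_eps: float = 0.0

    def summary(self) -> str:
        rows = [f"target={self.target}  fit_p={self.fit_p:.4g} "
                f"(df={self.fit_df}, {self.method})"]
        for s, w, se in zip(self.sources, self.weights, self.weight_se):
            rows.append(f"  {s}: {w:.4f} ± {se:.4f}")
        if not self.feasible:
            rows.append("  (weights leave the simplex: model infeasible as a mixture)")
        return "\n".join(rows)


def _iterated_weights(est: np.ndarray, C: np.ndarray, k: int, r: int,
                      eps_box: list, max_iter: int = 30):
    """Constrained GLS for the weights, iterating the w-dependent residual
    metric to a fixed point; returns (w, final residual covariance)."""
    E = (k + 1) * (r - 1)
    F = est.reshape(k + 1, r - 1)
    y, A = F[0], F[1:].T

    def resid_cov(w: np.ndarray) -> np.ndarray:
        # e = M f with M (r-1, E): entry (L=0, j) coeff 1; (L=a+1, j) -w_a
        M = np.zeros((r - 1, E))
        for j in range(r - 1):
            M[j, j] = 1.0
            for a in range(k):
                M[j, (a + 1) * (r - 1) + j] = -w[a]
        return M @ C @ M.T

    w = np.full(k, 1.0 / k)
    Q = resid_cov(w)
    for _ in range(max_iter):
        def Qinv_mul(B, Q=Q):
            out, eps = _solve_spd(Q, B)
            eps_box[0] = max(eps_box[0], eps)
            return out

        w_new = _constrained_gls(y, A, Qinv_mul)
        Q = resid_cov(w_new)
        if np.max(np.abs(w_new - w)) < 1e-12:
            w = w_new
            break
        w = w_new
    return w, Q


def _constrained_gls(y: np.ndarray, A: np.ndarray, Qinv_mul) -> np.ndarray:
    """Minimise (y − Aw)' Q⁻¹ (y − Aw) subject to Σw = 1."""
    k = A.shape[1]
    if k == 1:
        return np.ones(1)
    ones = np.ones((k, 1))
    Z = np.linalg.svd(ones.T)[2][1:].T  # (k, k-1) basis of the sum-zero space
    w0 = np.full(k, 1.0 / k)
    y_adj = y - A @ w0
    Xz = A @ Z
    u = _gls(Xz, y_adj, Qinv_mul)
    return w0 + Z @ u


def fit_weights(panel: GenotypePanel, target, sources: Sequence,
                outgroups: Sequence, blocks: BlockPartition | None = None,
                block_cm: float = 5.0, method: str = "hotelling",
                compute_rank_p: bool = True, max_iter: int = 30) -> AdmixtureFit:
    """Estimate admixture weights of ``target`` as a mixture of ``sources``.

    Needs at least k+1 outgroups for k sources; the first outgroup is the
    base. The residual covariance depends on the weights, so the constrained
    GLS is iterated to a fixed point. Standard errors come from delete-one-
    block refits; the fit p-value refers the residual quadratic form to
    r − k degrees of freedom (r outgroups, k sources).
    """
    k, r = len(sources), len(outgroups)
    if k < 1:
        raise ValueError("need at least one source")
    if r <= k:
        raise ValueError(f"insufficient outgroups: need more than {k}, got {r}")
    base, rights = outgroups[0], list(outgroups[1:])
    lefts = [target] + list(sources)
    bf = BlockF4(panel, lefts + list(outgroups), blocks=blocks, block_cm=block_cm)
    quads = [(L, base, rj, base) for L in lefts for rj in rights]
    f4set = bf.stats(quads)
    C = f4set.jackknife_cov()  # covariance of vec(F), row-major
    g = f4set.n_blocks
    eps_box = [0.0]

    w, Qfin = _iterated_weights(f4set.est, C, k, r, eps_box, max_iter)
    F = f4set.est.reshape(k + 1, r - 1)
    resid = F[0] - F[1:].T @ w

    def Qinv_fin(B, Q=Qfin):
        out, eps = _solve_spd(Q, B)
        eps_box[0] = max(eps_box[0], eps)
        return out

    fit_stat = float(resid @ Qinv_fin(resid))
    fit_df = r - k
    fit_p = _quadratic_pvalue(fit_stat, fit_df, g, method)

    # delete-one-block refits of the *full* procedure: the covariance and
    # the residual metric are re-estimated inside each replicate, so the SE
    # also carries the noise of the estimated metric (material at modest
    # block counts)
    W = np.empty((g, k))
    for j in range(g):
        est_j, C_j = f4set.delete_one(j)
        W[j], _ = _iterated_weights(est_j, C_j, k, r, eps_box, max_iter)
    m = f4set.block_weights()
    n = m.sum()
    h = n / m
    se = np.empty(k)
    for a in range(k):
        theta_j = g * w[a] - ((1.0 - m / n) * W[:, a]).sum()
        tau = h * w[a] - (h - 1.0) * W[:, a] - theta_j
        se[a] = np.sqrt(((tau ** 2) / (h - 1.0)).sum() / g)

    rank_p = {}
    if compute_rank_p and k >= 1:
        rt = rank_test(panel, lefts, outgroups, blocks=bf.blocks,
                       ranks=range(k), method=method)
        rank_p = rt.p_values

    feasible = bool((w >= -1e-9).all() and (w <= 1 + 1e-9).all())
    return AdmixtureFit(target=target, sources=tuple(sources),
                        outgroups=tuple(outgroups), weights=w, weight_se=se,
                        rank_p=rank_p, fit_p=fit_p, fit_stat=fit_stat,
                        fit_df=fit_df, n_blocks=g, method=method,
                        feasible=feasible, ridge_eps=eps_box[0])


# ----------------------------------------------------------- model competition

def model_competition(panel: GenotypePanel, target, candidates: Sequence,
                      outgroups: Sequence, blocks: BlockPartition | None = None,
                      block_cm: float = 5.0, alpha: float = 0.05,
                      method: str = "hotelling"):
    """Rank candidate source sets for a target.

    ``candidates`` is a list of source sets (a bare label counts as a one-set).
    Single-population candidates additionally get an indistinguishability
    flag: a rank test of (target, candidate) against the outgroups that
    accepts one stream (p > alpha) means the candidate is consistent with
    being the target's own source population.

    Returns a list of row dicts sorted by fit p-value, best first.
    """
    rows = []
    for cand in candidates:
        srcs = [cand] if isinstance(cand, str) else list(cand)
        row = {"sources": tuple(srcs)}
        if len(outgroups) > len(srcs):
            fit = fit_weights(panel, target, srcs, outgroups, blocks=blocks,
                              block_cm=block_cm, method=method,
                              compute_rank_p=False)
            row.update(weights=fit.weights, fit_p=fit.fit_p,
                       feasible=fit.feasible)
        else:
            row.update(weights=None, fit_p=np.nan, feasible=False)
        if len(srcs) == 1:
            rt = rank_test(panel, [target, srcs[0]], outgroups, blocks=blocks,
                           block_cm=block_cm, ranks=[0], method=method)
            row["indistinguishable_p"] = rt.p_values[0]
            row["indistinguishable"] = bool(rt.p_values[0] > alpha)
        else:
            row["indistinguishable_p"] = np.nan
            row["indistinguishable"] = False
        rows.append(row)
    rows.sort(key=lambda r: -(r["fit_p"] if np.isfinite(r["fit_p"]) else -1.0))
    return rows
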