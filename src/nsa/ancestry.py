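"""Per-individual ancestry decomposition against fixed source populations.

Two sklearn-style estimators:

* :class:`SupervisedAncestry` — maximum-likelihood mixing proportions given
  fixed source allele frequencies (the supervised-clustering model). The
  haploid log-likelihood over observed alleles g ∈ {ref, alt},

      ℓ(q) = Σ_j [ a_j log Σ_k q_k f_kj + (c_j − a_j) log Σ_k q_k (1 − f_kj) ],

  with a_j alternate alleles out of c_j observed at variant j, is maximised
  over the simplex by expectation–maximisation from a fixed multi-start
  (each corner plus the barycenter). A pseudohaploid call contributes one
  allele, a diploid call both. Bootstrap resampling of variants gives
  per-individual standard errors.

* :class:`AncestryPCA` — principal components of a reference panel with
  least-squares projection of incomplete (ancient) individuals onto them,
  the behaviour of smartpca's ``lsqproject``.

Plus population summaries (mean ± s.e.m.), the 50%/95% ancestry
classification rule, and cross-method congruence correlations.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numba
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .fstats import freq_and_count, make_blocks
from .panel import MISSING, GenotypePanel

FREQ_CLIP = 1e-5


# -------------------------------------------------------------- EM internals
#
# The cohort formulation mirrors how the supervised clustering tool is run in
# practice: one EM over the mixing proportions Q of *all* target individuals
# and the source frequencies F, with reference individuals pinned to their
# label corner (entering through fixed allele counts X out of N). Including
# the targets' own alleles in the frequency M-step makes the frequency
# estimate orthogonal to each target's residual, which removes the
# errors-in-variables bias a plug-in empirical-frequency likelihood carries.

@numba.njit(cache=True, fastmath=True)
def _em_kernel(Q, F, A, C, has_ref, compute_ll):  # pragma: no cover - jitted
    n, V = A.shape
    K = Q.shape[1]
    Q_new = np.zeros((n, K))
    F_num = np.zeros((K, V)) if has_ref else np.zeros((1, 1))
    F_den = np.zeros((K, V)) if has_ref else np.zeros((1, 1))
    ll = 0.0
    for i in range(n):
        for j in range(V):
            c = C[i, j]
            if c == 0.0:
                continue
            a = A[i, j]
            r = c - a
            mix = 0.0
            for k in range(K):
                mix += Q[i, k] * F[k, j]
            if compute_ll:
                if a > 0.0:
                    ll += a * np.log(mix)
                if r > 0.0:
                    ll += r * np.log(1.0 - mix)
            wa = a / mix
            wr = r / (1.0 - mix)
            for k in range(K):
                ta = Q[i, k] * F[k, j] * wa
                tr = Q[i, k] * (1.0 - F[k, j]) * wr
                Q_new[i, k] += ta + tr
                if has_ref:
                    F_num[k, j] += ta
                    F_den[k, j] += ta + tr
    return Q_new, F_num, F_den, ll


def _cohort_em_step(Q: np.ndarray, F: np.ndarray, A: np.ndarray, C: np.ndarray,
                    X: np.ndarray | None, N: np.ndarray | None,
                    totals: np.ndarray, compute_ll: bool = True):
    """One EM update for a cohort; returns (Q', F', loglik at input).

    Q is (n, K); A and C are (n, V) observed alt-allele and total-allele
    counts (zero where missing); X/N are reference alt/total allele counts
    per source, or None to hold F fixed. The inner pass is a fused jitted
    kernel (one sweep over the data); the log-likelihood is skipped when the
    caller does not need it.
    """
    has_ref = X is not None
    Q_new, F_num, F_den, ll = _em_kernel(Q, F, A, C, has_ref, compute_ll)
    Q_new /= totals[:, None]
    if not compute_ll:
        ll = np.nan
    F_new = F
    if has_ref:
        if compute_ll:
            ll += float((X * np.log(F) + (N - X) * np.log1p(-F)).sum())
        F_new = np.clip((X + F_num) / (N + F_den), FREQ_CLIP, 1.0 - FREQ_CLIP)
    return Q_new, F_new, ll


def _project_rows(Q: np.ndarray) -> np.ndarray:
    Q = np.clip(Q, 1e-9, None)
    return Q / Q.sum(axis=1, keepdims=True)


def _project(q: np.ndarray) -> np.ndarray:
    q = np.clip(q, 1e-9, None)
    return q / q.sum()


def _cohort_em(A: np.ndarray, C: np.ndarray, F0: np.ndarray, Q0: np.ndarray,
               tol: float, max_iter: int,
               X: np.ndarray | None = None, N: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray, float]:
    """SQUAREM-accelerated (joint) EM from one start; returns (Q, F, loglik).

    Two EM steps, secant extrapolation over the concatenated parameters, one
    stabilising step; the safeguard falls back to the plain double step
    whenever extrapolation would lower the likelihood, so monotonicity is
    kept. Stops when the likelihood gains less than ``tol`` per cycle —
    or, in joint mode, when every mixing proportion moves by less than 1e-6
    (the frequency parameters keep gaining microscopically long after the
    proportions have stabilised).
    """
    Q, F = Q0.copy(), F0
    totals = C.sum(axis=1)
    joint = X is not None
    # the stopping rule is a per-individual likelihood gain below tol
    tol = tol * max(len(Q), 1)
    prev = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        Q1, F1, _ = _cohort_em_step(Q, F, A, C, X, N, totals, compute_ll=False)
        Q2, F2, ll1 = _cohort_em_step(Q1, F1, A, C, X, N, totals)
        r, v = Q1 - Q, Q2 - 2.0 * Q1 + Q
        rr, vv = float((r * r).sum()), float((v * v).sum())
        if joint:
            rF, vF = F1 - F, F2 - 2.0 * F1 + F
            rr += float((rF * rF).sum())
            vv += float((vF * vF).sum())
        if vv > 0:
            alpha = min(-1.0, -np.sqrt(rr / vv))
            Q_acc = _project_rows(Q - 2.0 * alpha * r + alpha * alpha * v)
            F_acc = (np.clip(F - 2.0 * alpha * rF + alpha * alpha * vF,
                             FREQ_CLIP, 1.0 - FREQ_CLIP) if joint else F)
            Q3, F3, ll_acc = _cohort_em_step(Q_acc, F_acc, A, C, X, N, totals)
            if np.isfinite(ll_acc) and ll_acc >= ll1:
                Q_next, F_next, ll = Q3, F3, ll_acc
            else:
                Q_next, F_next, ll = Q2, F2, ll1
        else:
            Q_next, F_next, ll = Q2, F2, ll1
        if ll - prev < tol:
            return Q_next, F_next, ll
        if joint and np.max(np.abs(Q_next - Q)) < 1e-6:
            return Q_next, F_next, ll
        prev = ll
        Q, F = Q_next, F_next
    return Q, F, ll


def _em_point(a: np.ndarray, c: np.ndarray, F0: np.ndarray, q0: np.ndarray,
              tol: float, max_iter: int,
              X: np.ndarray | None = None, N: np.ndarray | None = None
              ) -> tuple[np.ndarray, float]:
    """Single-individual EM (cohort of one); returns (q, loglik)."""
    Q, _, ll = _cohort_em(a[None, :], c[None, :], F0, q0[None, :].copy(),
                          tol, max_iter, X=X, N=N)
    return Q[0], ll


@dataclasses.dataclass
class AncestryEstimate:
    individual: str
    proportions: np.ndarray
    sources: tuple
    bootstrap_se: np.ndarray | None
    n_variants: int
    loglik: float
    flagged: bool = False       # below the variant minimum, no SE
    degenerate: bool = False    # sources indistinguishable; barycenter returned

    def as_dict(self) -> dict:
        d = {"id": self.individual, "n_variants": self.n_variants,
             "flagged": self.flagged}
        for s, q in zip(self.sources, self.proportions):
            d[f"q_{s}"] = q
        if self.bootstrap_se is not None:
            for s, e in zip(self.sources, self.bootstrap_se):
                d[f"se_{s}"] = e
        return d


class SupervisedAncestry(BaseEstimator, TransformerMixin):
    """Supervised ancestry proportions by EM on the haploid likelihood.

    Parameters
    ----------
    n_boot : bootstrap replicates for per-individual SEs (0 disables).
    block_boot : resample 5-cM blocks of variants instead of single variants
        (linked variants violate the independence the plain bootstrap
        assumes).
    min_variants : estimates from fewer non-missing variants are flagged and
        get no SE.
    update_freqs : supervised-mode semantics — source frequencies are model
        parameters whose M-step pools the reference allele counts with the
        target's responsibilities. With False the empirical reference
        frequencies are plugged in unchanged; that estimator carries an
        errors-in-variables bias away from the simplex boundary of order
        V/n_reference_alleles, so the joint update is the default.
    tol : EM stops when the log-likelihood gain drops below this.
    random_state : seeds the bootstrap; the multi-start itself is fixed.

    After :meth:`fit`: ``source_freqs_`` (K, V) clipped frequencies,
    ``ref_alt_``/``ref_n_`` reference allele counts (when available),
    ``sources_`` labels, ``degenerate_`` flag.
    """

    def __init__(self, n_boot: int = 1000, block_boot: bool = False,
                 block_cm: float = 5.0, min_variants: int = 1000,
                 update_freqs: bool = True, tol: float = 1e-6,
                 max_iter: int = 2000, random_state: int | None = 0):
        self.n_boot = n_boot
        self.block_boot = block_boot
        self.block_cm = block_cm
        self.min_variants = min_variants
        self.update_freqs = update_freqs
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- fitting = fixing the source frequency panels
    def fit(self, X, y=None, *, sources: Sequence[str] | None = None,
            variants: pd.DataFrame | None = None):
        """Fix source allele frequencies.

        ``X`` is either a (K, V) frequency matrix (with ``sources`` labels),
        or a :class:`GenotypePanel` whose populations named in ``sources``
        provide empirical frequencies.
        """
        if isinstance(X, GenotypePanel):
            if sources is None:
                raise ValueError("sources= is required when fitting from a panel")
            pn = [freq_and_count(X, s) for s in sources]
            F = np.vstack([p for p, _ in pn])
            counts = np.vstack([n for _, n in pn])
            self.ref_alt_ = np.nan_to_num(F) * counts
            self.ref_n_ = counts
            variants = X.variants
        else:
            F = np.asarray(X, dtype=float)
            self.ref_alt_ = None
            self.ref_n_ = None
            if sources is None:
                sources = [f"source{k}" for k in range(F.shape[0])]
        self.sources_ = tuple(sources)
        self.source_freqs_ = np.clip(np.nan_to_num(F, nan=0.5),
                                     FREQ_CLIP, 1.0 - FREQ_CLIP)
        self.variants_ = variants
        span = np.nanmax(np.abs(self.source_freqs_ - self.source_freqs_[0]), axis=0)
        self.degenerate_ = bool(np.nanmax(span) < 1e-12) if F.shape[0] > 1 else False
        return self

    # -- estimation
    def estimate_cohort(self, calls: np.ndarray, ploidy: Sequence[str],
                        individuals: Sequence[str] | None = None
                        ) -> list[AncestryEstimate]:
        """Estimate all individuals in one (joint) EM run.

        ``calls`` is (n, V) over {0, 1, 2, MISSING}; ``ploidy`` gives each
        row's mode. In joint mode the whole cohort shares the frequency
        parameters, as when the supervised clustering tool is run once on
        reference plus all ancient individuals together.
        """
        calls = np.atleast_2d(np.asarray(calls))
        n, V = calls.shape
        K = self.source_freqs_.shape[0]
        if individuals is None:
            individuals = [f"ind{i}" for i in range(n)]
        ploidy = np.asarray(list(ploidy), dtype=object)
        obs = calls != MISSING
        dip = (ploidy == "diploid")[:, None]
        C = np.where(obs, np.where(dip, 2.0, 1.0), 0.0)
        A = np.where(obs, calls.astype(float), 0.0)
        A = np.where(dip, A, A / 2.0)
        n_used = obs.sum(axis=1)
        if self.degenerate_:
            return [AncestryEstimate(ind, np.full(K, 1.0 / K), self.sources_,
                                     None, int(m), float("nan"), degenerate=True)
                    for ind, m in zip(individuals, n_used)]

        # fixed multi-start: each corner (pulled just inside) + the barycenter,
        # run on the fixed-frequency surface to pick the basin cheaply
        starts = [np.full(K, 1.0 / K)]
        for k in range(K):
            q0 = np.full(K, 0.02 / max(K - 1, 1))
            q0[k] = 0.98
            starts.append(q0)
        F = np.ascontiguousarray(self.source_freqs_)
        A = np.ascontiguousarray(A)
        C = np.ascontiguousarray(C)
        joint = self.update_freqs and self.ref_alt_ is not None
        # the multi-start picks the basin on a deterministic variant
        # subsample; the fixed-frequency surface is concave in each row of Q,
        # so the full-resolution run from the winning start loses nothing
        if V > 30_000:
            sub = np.arange(0, V, V // 10_000)
            As, Cs, Fs = (np.ascontiguousarray(A[:, sub]),
                          np.ascontiguousarray(C[:, sub]),
                          np.ascontiguousarray(F[:, sub]))
        else:
            As, Cs, Fs = A, C, F
        best_Q, best_ll = None, -np.inf
        for q0 in starts:
            Q0 = np.tile(q0, (n, 1))
            Q, _, ll = _cohort_em(As, Cs, Fs, Q0, self.tol, self.max_iter)
            if ll > best_ll:
                best_Q, best_ll = Q, ll
        best_Q, _, best_ll = _cohort_em(A, C, F, _project_rows(best_Q),
                                        self.tol, self.max_iter)
        F_hat = F
        if joint:
            best_Q, F_hat, best_ll = _cohort_em(
                A, C, F, _project_rows(best_Q), self.tol, self.max_iter,
                X=self.ref_alt_, N=self.ref_n_)

        rng = np.random.default_rng(self.random_state)
        out = []
        for i, ind in enumerate(individuals):
            flagged = n_used[i] < self.min_variants
            se = None
            if self.n_boot > 0 and not flagged:
                se = self._bootstrap(A[i], C[i], F_hat, best_Q[i], rng,
                                     joint=joint)
            out.append(AncestryEstimate(ind, best_Q[i], self.sources_, se,
                                        int(n_used[i]), best_ll,
                                        flagged=bool(flagged)))
        return out

    def estimate_one(self, calls: np.ndarray, ploidy: str = "pseudohaploid",
                     individual: str = "ind") -> AncestryEstimate:
        return self.estimate_cohort(np.atleast_2d(calls), [ploidy],
                                    [individual])[0]

    def _bootstrap(self, a, c, F_hat, q_hat, rng, joint: bool) -> np.ndarray:
        """Variant bootstrap, refitting the estimator per replicate.

        Each replicate resamples variants and re-runs the same estimator the
        point estimate used — including the joint frequency update when in
        supervised joint mode, whose frequency chasing is a real variance
        component — warm-started from the point estimate.
        """
        obs = c > 0
        ao, co, Fo = a[obs], c[obs], np.ascontiguousarray(F_hat[:, obs])
        Xo = np.ascontiguousarray(self.ref_alt_[:, obs]) if joint else None
        No = np.ascontiguousarray(self.ref_n_[:, obs]) if joint else None
        V = len(ao)
        if self.block_boot and self.variants_ is not None:
            blocks = make_blocks(self.variants_, self.block_cm).index[obs]
            uniq = np.unique(blocks)
            members = [np.nonzero(blocks == b)[0] for b in uniq]
        reps = np.empty((self.n_boot, len(q_hat)))
        for b in range(self.n_boot):
            if self.block_boot and self.variants_ is not None:
                pick = rng.integers(0, len(members), size=len(members))
                idx = np.concatenate([members[i] for i in pick])
            else:
                idx = rng.integers(0, V, size=V)
            # warm start from the point estimate: the resampled optimum is near
            q, _ = _em_point(ao[idx], co[idx],
                             np.ascontiguousarray(Fo[:, idx]),
                             _project(q_hat), self.tol, self.max_iter,
                             X=None if Xo is None else np.ascontiguousarray(Xo[:, idx]),
                             N=None if No is None else np.ascontiguousarray(No[:, idx]))
            reps[b] = q
        return reps.std(axis=0, ddof=1)

    def transform(self, X) -> np.ndarray:
        """Proportions matrix for a calls array (n, V) or a GenotypePanel."""
        if isinstance(X, GenotypePanel):
            ests = self.estimate_panel(X)
        else:
            X = np.atleast_2d(np.asarray(X))
            ests = self.estimate_cohort(X, ["pseudohaploid"] * X.shape[0])
        return np.vstack([e.proportions for e in ests])

    def estimate_panel(self, panel: GenotypePanel,
                       individuals: Sequence[str] | None = None
                       ) -> list[AncestryEstimate]:
        ids = list(individuals) if individuals is not None else panel.individuals["id"].tolist()
        idx = panel.individuals_in(ids)
        ploidy = panel.individuals["ploidy_mode"].to_numpy()[idx]
        return self.estimate_cohort(panel.calls[idx], ploidy, ids)


def supervised_proportions(panel: GenotypePanel, individuals: Sequence[str],
                           source_pops: Sequence[str], seed: int = 0,
                           n_boot: int = 1000, **kw) -> list[AncestryEstimate]:
    """Functional wrapper: empirical source frequencies from ``source_pops``
    in the panel, then EM estimates for ``individuals``."""
    est = SupervisedAncestry(n_boot=n_boot, random_state=seed, **kw)
    est.fit(panel, sources=source_pops)
    return est.estimate_panel(panel, individuals)


# ----------------------------------------------------------------- summaries

@dataclasses.dataclass(frozen=True)
class PopulationSummary:
    population: str
    source: str
    mean: float
    sem: float  # sigma/sqrt(n), nan when n == 1
    n: int


def summarize_population(values: Sequence[float], population: str = "",
                         source: str = "") -> PopulationSummary:
    """Mean of individual point estimates with s.e.m. = σ/√n (σ the n−1
    sample standard deviation). A single individual gives sem = nan."""
    v = np.asarray(list(values), dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("no estimates to summarize")
    sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return PopulationSummary(population=population, source=source,
                             mean=float(v.mean()), sem=sem, n=n)


def classify_ancestry(q_cne: float, majority: float = 0.5,
                      unadmixed: float = 0.95) -> tuple[str, bool]:
    """(label, unadmixed_flag): CNE iff q > 0.5 (strict), unadmixed iff q > 0.95."""
    label = "CNE" if q_cne > majority else "WBI"
    return label, q_cne > unadmixed


# ----------------------------------------------------------------------- PCA

class AncestryPCA(BaseEstimator, TransformerMixin):
    """Reference-panel PCA with least-squares projection of incomplete samples.

    Variants with reference missingness above ``max_ref_missing`` are
    dropped; residual missing reference calls are mean-imputed. Calls are
    centred by the reference mean and scaled by sqrt(p(1−p)) with p the
    reference allele frequency. Projection solves ordinary least squares for
    the coordinates over each individual's non-missing variants, so a
    complete-data reference individual reproduces its reference coordinates
    exactly.
    """

    def __init__(self, n_components: int = 2, max_ref_missing: float = 0.05,
                 min_proj_variants: int = 100):
        self.n_components = n_components
        self.max_ref_missing = max_ref_missing
        self.min_proj_variants = min_proj_variants

    def fit(self, X, y=None):
        calls = X.calls if isinstance(X, GenotypePanel) else np.asarray(X)
        missing_frac = (calls == MISSING).mean(axis=0)
        keep = missing_frac <= self.max_ref_missing
        if not keep.any():
            raise ValueError("no variants pass the reference missingness filter")
        self.variant_idx_ = np.nonzero(keep)[0]
        sub = calls[:, keep].astype(float)
        sub[sub == MISSING] = np.nan
        mean = np.nanmean(sub, axis=0)
        sub = np.where(np.isnan(sub), mean, sub)
        p = mean / 2.0
        scale = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
        Z = (sub - mean) / scale
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        k = min(self.n_components, len(s))
        self.mean_ = mean
        self.scale_ = scale
        self.components_ = Vt[:k]           # (k, V_used), orthonormal
        self.singular_values_ = s[:k]
        self.reference_coords_ = U[:, :k] * s[:k]
        return self

    def transform(self, X) -> np.ndarray:
        """Least-squares coordinates for each row of a calls matrix/panel.

        Rows with fewer than ``min_proj_variants`` usable variants get NaN
        coordinates (flagged projection).
        """
        calls = X.calls if isinstance(X, GenotypePanel) else np.atleast_2d(np.asarray(X))
        calls = calls[:, self.variant_idx_]
        out = np.full((calls.shape[0], self.components_.shape[0]), np.nan)
        for i, row in enumerate(calls):
            obs = row != MISSING
            if obs.sum() < self.min_proj_variants:
                continue
            z = (row[obs].astype(float) - self.mean_[obs]) / self.scale_[obs]
            A = self.components_[:, obs].T
            out[i] = np.linalg.lstsq(A, z, rcond=None)[0]
        return out


# --------------------------------------------------------------- congruence

def congruence(assessments: dict) -> pd.DataFrame:
    """Pairwise Pearson correlations between ancestry assessments.

    ``assessments`` maps method name to a pandas Series indexed by individual
    id (e.g. PC1 position, an f4 value, a supervised proportion); series are
    aligned on their common ids. An input with zero variance is an error
    naming the input.
    """
    names = list(assessments)
    df = pd.DataFrame(assessments).dropna()
    if len(df) < 3:
        raise ValueError("fewer than 3 jointly observed individuals")
    for name in names:
        if df[name].std() == 0:
            raise ValueError(f"assessment {name!r} has zero variance")
    out = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            r = sps.pearsonr(df[a], df[b])[0] if a != b else 1.0
            out.loc[a, b] = out.loc[b, a] = r
    return out
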