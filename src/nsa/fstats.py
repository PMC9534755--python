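"""Allele-frequency f-statistics (f2, f3, f4) and Hudson FST with
block-jackknife standard errors.

Frequencies are computed uniformly over mixed-ploidy populations: a diploid
call contributes its two alleles, a pseudohaploid call contributes one
sampled allele, so the per-variant allele count is ``2*n_diploid +
n_pseudohaploid`` over non-missing calls. The unbiased heterozygosity
correction ``h = p(1-p) n/(n-1)`` removes sampling noise from squared
frequency differences in f2, f3 and the FST numerator; it needs at least two
sampled alleles and is skipped (and flagged) at variants where a population
is down to a single allele.

Standard errors come from a weighted delete-one-block jackknife (Busing-style)
over genomic blocks of a fixed genetic length, 5 cM by default, which is
robust to linkage between nearby variants.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel


@dataclasses.dataclass(frozen=True)
class BlockPartition:
    """Assignment of variants to contiguous genetic-length blocks.

    ``index`` maps each variant to a block id in [0, n_blocks); blocks never
    cross a chromosome boundary.
    """
    index: np.ndarray
    n_blocks: int


@dataclasses.dataclass(frozen=True)
class FStatResult:
    kind: str
    pops: tuple
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_variants: int
    corrections_skipped: bool = False
    meta: dict = dataclasses.field(default_factory=dict)


def make_blocks(variants: pd.DataFrame, block_cm: float = 5.0) -> BlockPartition:
    """Partition variants into blocks spanning at most ``block_cm`` centimorgans.

    Variants with a missing genetic position fall back to physical position at
    1 cM/Mb. Variants are assumed sorted by position within chromosome (the
    panel invariant).
    """
    if block_cm <= 0:
        raise ValueError("block_cm must be positive")
    g = variants["genetic_pos"].to_numpy(dtype=float).copy()
    fallback = ~np.isfinite(g)
    if fallback.any():
        g[fallback] = variants["position"].to_numpy(dtype=float)[fallback] / 1e6
    chrom = variants["chrom"].to_numpy()
    raw = np.empty(len(variants), dtype=np.int64)
    offset = 0
    for c in pd.unique(chrom):
        sel = chrom == c
        gc = g[sel]
        local = np.floor((gc - gc.min()) / block_cm).astype(np.int64)
        raw[sel] = local + offset
        offset += local.max() + 1
    # relabel to consecutive ids in order of appearance
    _, index = np.unique(raw, return_inverse=True)
    return BlockPartition(index=index, n_blocks=int(index.max()) + 1)


# --------------------------------------------------------------- frequencies

def resolve_population(panel: GenotypePanel, pop) -> list[str]:
    """A population argument is a label (all members) or an iterable of ids."""
    if isinstance(pop, str):
        ids = panel.population_members(pop)
        if not ids:
            raise KeyError(f"no individuals in population {pop!r}")
        return ids
    return list(pop)


def freq_and_count(panel: GenotypePanel, pop) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant allele frequency and allele count for one population."""
    ids = resolve_population(panel, pop)
    idx = panel.individuals_in(ids)
    calls = panel.calls[idx]
    ploidy = panel.individuals["ploidy_mode"].to_numpy()[idx]
    dip = ploidy == "diploid"
    obs = calls != MISSING
    c = np.where(obs, calls, 0).astype(np.float64)
    alt = c[dip].sum(axis=0) + c[~dip].sum(axis=0) / 2.0
    n = 2.0 * obs[dip].sum(axis=0) + obs[~dip].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, np.nan)
    return p, n


def allele_freqs(panel: GenotypePanel, pops: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frequency and allele-count tables (populations × variants)."""
    ps, ns = {}, {}
    for label, members in pops.items():
        p, n = freq_and_count(panel, members)
        ps[label], ns[label] = p, n
    cols = panel.variants["id"]
    return (pd.DataFrame(ps, index=cols).T, pd.DataFrame(ns, index=cols).T)


def _het_correction(p: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, bool]:
    """h/n with h = p(1-p) n/(n-1); zero (skipped) where n < 2."""
    ok = n >= 2
    out = np.zeros_like(p)
    nn = np.where(ok, n, 2.0)
    out[ok] = (p[ok] * (1.0 - p[ok]) / (nn[ok] - 1.0))
    skipped = bool((~ok & (n >= 1)).any())
    return out, skipped


# ------------------------------------------------------------ block jackknife

def block_sums(values: np.ndarray, block_index: np.ndarray, n_blocks: int,
               mask: np.ndarray | None = None) -> np.ndarray:
    """Per-block sums of per-variant values (masked variants contribute 0)."""
    if mask is not None:
        values = np.where(mask, values, 0.0)
    return np.bincount(block_index, weights=values, minlength=n_blocks)


def block_jackknife(num: np.ndarray, den: np.ndarray, blocks: BlockPartition,
                    mask: np.ndarray | None = None,
                    weights: np.ndarray | None = None):
    """Weighted delete-one-block jackknife for a ratio-of-sums statistic.

    ``num`` and ``den`` are per-variant contributions; the statistic is
    ``sum(num)/sum(den)`` (a plain mean when den is an indicator). Block
    weights default to the per-block count of used variants. Returns
    ``(estimate, se, loo)`` where loo holds the delete-one-block estimates.

    Raises on a single usable block (SE undefined).
    """
    if mask is None:
        mask = np.isfinite(num) & np.isfinite(den)
    S = block_sums(num, blocks.index, blocks.n_blocks, mask)
    D = block_sums(den, blocks.index, blocks.n_blocks, mask)
    m = (block_sums(np.ones_like(num, dtype=float), blocks.index, blocks.n_blocks, mask)
         if weights is None else np.asarray(weights, dtype=float))
    used = m > 0
    S, D, m = S[used], D[used], m[used]
    g = len(m)
    if g < 2:
        raise ValueError("block jackknife needs at least two non-empty blocks")
    tot_s, tot_d = S.sum(), D.sum()
    if tot_d == 0:
        raise ValueError("no usable variants (zero denominator)")
    est = tot_s / tot_d
    loo = (tot_s - S) / (tot_d - D)
    est_j, se = _busing(est, loo, m)
    return est, se, loo


def _busing(est: float, loo: np.ndarray, m: np.ndarray) -> tuple[float, float]:
    """Busing weighted-jackknife bias-corrected estimate and SE."""
    g = len(m)
    n = m.sum()
    h = n / m
    theta_j = g * est - ((1.0 - m / n) * loo).sum()
    tau = h * est - (h - 1.0) * loo
    var = ((tau - theta_j) ** 2 / (h - 1.0)).sum() / g
    return theta_j, float(np.sqrt(var))


def _zscore(est: float, se: float) -> float:
    if se == 0.0:
        return 0.0 if est == 0.0 else float(np.sign(est) * np.inf)
    return est / se


# ------------------------------------------------------------------ statistics

def _result(kind, pops, contrib_num, contrib_den, blocks, mask, n_used, skipped,
            **meta) -> FStatResult:
    est, se, _ = block_jackknife(contrib_num, contrib_den, blocks, mask)
    return FStatResult(kind=kind, pops=tuple(pops), estimate=float(est),
                       se=float(se), z=_zscore(est, se),
                       n_blocks=blocks.n_blocks, n_variants=int(n_used),
                       corrections_skipped=skipped, meta=meta)


def f4(panel: GenotypePanel, a, b, c, d, block_cm: float = 5.0,
       blocks: BlockPartition | None = None) -> FStatResult:
    """f4(A, B; C, D) = mean over variants of (pA − pB)(pC − pD).

    Zero in expectation when ((A,B),(C,D)) is a tree; deviations measure
    correlated drift (shared ancestry) between the pairs. Each statistic uses
    every variant at which all four populations have at least one allele.
    """
    if blocks is None:
        blocks = make_blocks(panel.variants, block_cm)
    ps, ns = zip(*(freq_and_count(panel, x) for x in (a, b, c, d)))
    mask = np.ones(panel.n_variants, dtype=bool)
    for n in ns:
        mask &= n >= 1
    if not mask.any():
        raise ValueError("no usable variants: a population is missing everywhere")
    num = (ps[0] - ps[1]) * (ps[2] - ps[3])
    den = np.ones(panel.n_variants)
    return _result("f4", (a, b, c, d), num, den, blocks, mask, mask.sum(), False)


def f2(panel: GenotypePanel, a, b, block_cm: float = 5.0,
       blocks: BlockPartition | None = None, correction: bool = True) -> FStatResult:
    """f2(A, B) = mean (pA − pB)² − hA/nA − hB/nB (unbiased squared drift)."""
    if blocks is None:
        blocks = make_blocks(panel.variants, block_cm)
    (pa, na), (pb, nb) = freq_and_count(panel, a), freq_and_count(panel, b)
    mask = (na >= 1) & (nb >= 1)
    if not mask.any():
        raise ValueError("no usable variants: a population is missing everywhere")
    num = (pa - pb) ** 2
    skipped = False
    if correction:
        ca, sa = _het_correction(pa, na)
        cb, sb = _het_correction(pb, nb)
        num = num - ca - cb
        skipped = sa or sb
    return _result("f2", (a, b), num, np.ones_like(num), blocks, mask,
                   mask.sum(), skipped, correction=correction)


def f3(panel: GenotypePanel, target, a, b, block_cm: float = 5.0,
       blocks: BlockPartition | None = None, correction: bool = True) -> FStatResult:
    """f3(T; A, B) = mean (pT − pA)(pT − pB) − hT/nT.

    Significantly negative values indicate the target is admixed between
    populations related to A and B.
    """
    if blocks is None:
        blocks = make_blocks(panel.variants, block_cm)
    (pt, nt), (pa, na), (pb, nb) = (freq_and_count(panel, x) for x in (target, a, b))
    mask = (nt >= 1) & (na >= 1) & (nb >= 1)
    if not mask.any():
        raise ValueError("no usable variants: a population is missing everywhere")
    num = (pt - pa) * (pt - pb)
    skipped = False
    if correction:
        ct, skipped = _het_correction(pt, nt)
        num = num - ct
    return _result("f3", (target, a, b), num, np.ones_like(num), blocks, mask,
                   mask.sum(), skipped, correction=correction)


def fst(panel: GenotypePanel, a, b, block_cm: float = 5.0,
        blocks: BlockPartition | None = None) -> FStatResult:
    """Hudson FST, ratio of averages.

    Per-variant numerator (pA − pB)² − hA/nA − hB/nB and denominator
    pA(1 − pB) + pB(1 − pA); the estimate is the ratio of their sums, with
    the jackknife applied to the ratio. Pseudohaploid calls are treated as
    single allele draws (no within-individual allele pairing), which is the
    appropriate behaviour for random-draw ancient data.
    """
    if blocks is None:
        blocks = make_blocks(panel.variants, block_cm)
    (pa, na), (pb, nb) = freq_and_count(panel, a), freq_and_count(panel, b)
    mask = (na >= 1) & (nb >= 1)
    if not mask.any():
        raise ValueError("no usable variants: a population is missing everywhere")
    ca, sa = _het_correction(pa, na)
    cb, sb = _het_correction(pb, nb)
    num = (pa - pb) ** 2 - ca - cb
    den = pa * (1.0 - pb) + pb * (1.0 - pa)
    est, se, _ = block_jackknife(num, den, blocks, mask)
    return FStatResult(kind="fst", pops=(a, b), estimate=float(est), se=float(se),
                       z=_zscore(est, se), n_blocks=blocks.n_blocks,
                       n_variants=int(mask.sum()), corrections_skipped=sa or sb,
                       meta={"estimator": "hudson"})


def hudson_fst_from_freqs(pa: np.ndarray, pb: np.ndarray,
                          na: np.ndarray | None = None,
                          nb: np.ndarray | None = None) -> float:
    """Hudson ratio-of-averages FST directly from frequency arrays.

    With allele counts supplied, applies the finite-sample correction; without
    them the frequencies are treated as exact (population) frequencies.
    """
    pa, pb = np.asarray(pa, float), np.asarray(pb, float)
    num = (pa - pb) ** 2
    if na is not None:
        num = num - _het_correction(pa, np.asarray(na, float))[0]
    if nb is not None:
        num = num - _het_correction(pb, np.asarray(nb, float))[0]
    den = pa * (1.0 - pb) + pb * (1.0 - pa)
    return float(num.sum() / den.sum())
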