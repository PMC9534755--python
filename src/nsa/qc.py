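"""Sample quality control: coverage-based genetic sex determination and
mismatch-rate kinship classification.

Sex is called from sex-chromosome coverage normalised by autosomal coverage:
an XX individual is expected at an X rate of 1 and a Y rate of 0, an XY
individual at 0.5 for both. A complementary rule uses the fraction of sex-
chromosome reads mapping to Y: below 3% is consistent with XX, above 35%
with XY.

Kinship uses the pairwise mismatch rate (PMR, also called P0) between
pseudohaploid genotype vectors in non-overlapping 1-Mb windows. Normalised
by the cohort baseline (median pairwise PMR), the expectation is 0.5 for
duplicates/identical twins, 0.75 for first-degree and 0.875 for second-degree
relatives; classification uses the midpoint cutoffs 0.625 / 0.8125 / 0.90625.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

#: normalised-P0 upper cutoffs for identical, first and second degree
KINSHIP_CUTOFFS = (0.625, 0.8125, 0.90625)


# -------------------------------------------------------------------- sex

@dataclasses.dataclass(frozen=True)
class SexCall:
    x_rate: float
    y_rate: float
    x_rate_se: float
    y_rate_se: float
    call: str  # XX / XY / indeterminate


@dataclasses.dataclass(frozen=True)
class SexThresholds:
    """XX: x_rate >= xx_x_min and y_rate <= xx_y_max.
    XY: both rates within [xy_lo, xy_hi]."""
    xx_x_min: float = 0.8
    xx_y_max: float = 0.1
    xy_lo: float = 0.35
    xy_hi: float = 0.65


def determine_sex(counts, thresholds: SexThresholds = SexThresholds()) -> SexCall:
    """Autosome-normalised X/Y coverage rates with Poisson-propagated errors.

    ``counts`` carries read counts and targeted-site totals for autosomes, X
    and Y (a :class:`~nsa.simulate.ReadCounts` or anything with the same
    fields). The rate SE is rate·sqrt(1/n_chr + 1/n_aut).
    """
    if counts.n_aut <= 0:
        raise ValueError("cannot normalize: zero autosomal coverage")
    cov_aut = counts.n_aut / counts.sites_aut

    def rate_se(n, sites):
        rate = (n / sites) / cov_aut
        se = rate * np.sqrt(1.0 / max(n, 1) + 1.0 / counts.n_aut)
        return rate, se

    x_rate, x_se = rate_se(counts.n_x, counts.sites_x)
    y_rate, y_se = rate_se(counts.n_y, counts.sites_y)
    t = thresholds
    if x_rate >= t.xx_x_min and y_rate <= t.xx_y_max:
        call = "XX"
    elif t.xy_lo <= x_rate <= t.xy_hi and t.xy_lo <= y_rate <= t.xy_hi:
        call = "XY"
    else:
        call = "indeterminate"
    return SexCall(x_rate=x_rate, y_rate=y_rate, x_rate_se=x_se,
                   y_rate_se=y_se, call=call)


def y_fraction_sex(counts, female_max: float = 0.03,
                   male_min: float = 0.35) -> tuple[float, str]:
    """Sex from the fraction of sex-chromosome reads mapping to Y.

    Returns ``(ratio, call)``; zero sex-chromosome reads give an
    indeterminate call with ratio nan.
    """
    total = counts.n_x + counts.n_y
    if total == 0:
        return float("nan"), "indeterminate"
    ratio = counts.n_y / total
    if ratio < female_max:
        return ratio, "XX"
    if ratio > male_min:
        return ratio, "XY"
    return ratio, "indeterminate"


# ------------------------------------------------------------------ kinship

@dataclasses.dataclass
class KinshipResult:
    pair: tuple[str, str]
    pmr: float
    se: float
    n_overlap: int
    window_p0: np.ndarray
    window_sites: np.ndarray
    insufficient_overlap: bool = False
    normalized_p0: float | None = None
    baseline: float | None = None
    degree: str | None = None


def pairwise_mismatch(panel: GenotypePanel, pair: tuple[str, str],
                      window_mb: float = 1.0,
                      min_overlap: int = 3000) -> KinshipResult:
    """PMR between two individuals' pseudohaploid calls, with per-window P0.

    Windows are non-overlapping physical intervals (default 1 Mb) and never
    cross chromosomes; the SE is a delete-one-window jackknife. Pairs with
    fewer than ``min_overlap`` jointly covered variants are flagged and left
    unclassified.
    """
    i1, i2 = panel.individuals_in(pair)
    c1, c2 = panel.calls[i1], panel.calls[i2]
    joint = (c1 != MISSING) & (c2 != MISSING)
    n = int(joint.sum())
    mism = (c1 != c2) & joint

    win = (panel.variants["chrom"].astype(str) + ":" +
           (panel.variants["position"] // int(window_mb * 1e6)).astype(str))
    codes = pd.factorize(win)[0]
    g = codes.max() + 1
    sites = np.bincount(codes, weights=joint.astype(float), minlength=g)
    mm = np.bincount(codes, weights=mism.astype(float), minlength=g)
    used = sites > 0
    sites, mm = sites[used], mm[used]
    with np.errstate(invalid="ignore", divide="ignore"):
        window_p0 = mm / sites

    if n == 0:
        return KinshipResult(pair=tuple(pair), pmr=float("nan"), se=float("nan"),
                             n_overlap=0, window_p0=window_p0,
                             window_sites=sites, insufficient_overlap=True)
    pmr = mm.sum() / sites.sum()
    if len(sites) >= 2:
        loo = (mm.sum() - mm) / (sites.sum() - sites)
        gw = len(sites)
        h = sites.sum() / sites
        theta_j = gw * pmr - ((1.0 - sites / sites.sum()) * loo).sum()
        tau = h * pmr - (h - 1.0) * loo - theta_j
        se = float(np.sqrt(((tau ** 2) / (h - 1.0)).sum() / gw))
    else:
        se = float("nan")
    return KinshipResult(pair=tuple(pair), pmr=float(pmr), se=se, n_overlap=n,
                         window_p0=window_p0, window_sites=sites,
                         insufficient_overlap=n < min_overlap)


def classify_kinship(results: Sequence[KinshipResult],
                     baseline: float | None = None,
                     cutoffs: tuple = KINSHIP_CUTOFFS) -> list[KinshipResult]:
    """Classify pairs into identical / first / second / unrelated.

    The baseline is the cohort median PMR (robust to a minority of related
    pairs); with fewer than five classifiable pairs it must be supplied.
    Flagged (insufficient-overlap) pairs stay unclassified.
    """
    usable = [r for r in results if not r.insufficient_overlap]
    if baseline is None:
        if len(usable) < 5:
            raise ValueError("need >= 5 pairs to estimate the baseline; "
                             "supply baseline= explicitly")
        baseline = float(np.median([r.pmr for r in usable]))
    c_id, c_first, c_second = cutoffs
    for r in results:
        if r.insufficient_overlap:
            continue
        r.baseline = baseline
        r.normalized_p0 = r.pmr / baseline
        if r.normalized_p0 < c_id:
            r.degree = "identical"
        elif r.normalized_p0 < c_first:
            r.degree = "first"
        elif r.normalized_p0 < c_second:
            r.degree = "second"
        else:
            r.degree = "unrelated"
    return list(results)


def kinship_report(panel: GenotypePanel, window_mb: float = 1.0,
                   min_overlap: int = 3000,
                   baseline: float | None = None) -> pd.DataFrame:
    """All-pairs PMR scan over a panel, classified against the cohort baseline."""
    ids = panel.individuals["id"].tolist()
    results = [pairwise_mismatch(panel, (a, b), window_mb, min_overlap)
               for a, b in itertools.combinations(ids, 2)]
    classify_kinship(results, baseline=baseline)
    return pd.DataFrame([{
        "id1": r.pair[0], "id2": r.pair[1], "pmr": r.pmr, "se": r.se,
        "n_overlap": r.n_overlap, "normalized_p0": r.normalized_p0,
        "degree": r.degree, "flagged": r.insufficient_overlap,
    } for r in results])
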