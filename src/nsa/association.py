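"""Ancestry versus funerary-treatment association testing.

The battery contrasts grave furnishing (any goods, brooches, weapons, burial
configuration) between majority-continental (CNE, > 50%) and majority-local
(WBI) individuals — overall, within each sex, and per site — using Fisher's
exact test on 2×2 tables, and repeats the comparisons treating ancestry as a
continuous variable with the Wilcoxon rank-sum test. P-values are reported
unadjusted, matching standard practice for this kind of descriptive battery;
an optional Benjamini–Hochberg column is available.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ancestry import classify_ancestry


@dataclasses.dataclass(frozen=True)
class TestResult:
    test: str           # e.g. "goods~ancestry"
    stratum: str        # all / females / males
    scope: str          # overall or a site label
    kind: str           # fisher / ranksum
    statistic: float    # odds ratio (fisher) or U (ranksum)
    p_value: float
    n: int
    table: tuple | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test: (p, odds ratio).

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.
    The odds ratio is the sample odds ratio with the Haldane 0.5 correction
    applied when any cell is zero.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])
    tt = t.astype(float)
    if (tt == 0).any():
        tt = tt + 0.5
    odds = (tt[0, 0] * tt[1, 1]) / (tt[0, 1] * tt[1, 0])
    return p, float(odds)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test: (p, U statistic).

    Exact null distribution when the combined sample is small (≤ 20) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue), float(res.statistic)


# ------------------------------------------------------------------- battery

@dataclasses.dataclass(frozen=True)
class BatteryConfig:
    majority_threshold: float = 0.5
    include_bh: bool = False
    min_group: int = 2          # each ancestry class needs this many per test


def _crosstab(flag: pd.Series, is_cne: pd.Series) -> tuple:
    a = int((is_cne & flag).sum())
    b = int((is_cne & ~flag).sum())
    c = int((~is_cne & flag).sum())
    d = int((~is_cne & ~flag).sum())
    return ((a, b), (c, d))


def run_battery(burials: pd.DataFrame, estimates: pd.DataFrame,
                config: BatteryConfig = BatteryConfig()) -> pd.DataFrame:
    """The full association battery.

    ``burials`` needs columns id, sex, site, has_goods, has_brooch,
    has_weapon and optionally configuration; ``estimates`` needs id and
    q_CNE. Individuals are classified CNE when q_CNE > 50%. Flags may be
    missing (NaN); such individuals are excluded per-test, as are
    indeterminate-sex individuals from the sex strata. Output is one row per
    TestResult; deterministic given its inputs.
    """
    df = burials.merge(estimates[["id", "q_CNE"]], on="id", how="inner").copy()
    if df.empty:
        return pd.DataFrame(columns=[f.name for f in dataclasses.fields(TestResult)])
    df["is_cne"] = [classify_ancestry(q, config.majority_threshold)[0] == "CNE"
                    for q in df["q_CNE"]]

    strata = {
        "all": df,
        "females": df[df["sex"] == "XX"],
        "males": df[df["sex"] == "XY"],
    }
    plan = [("goods~ancestry", "has_goods", ("all", "females", "males")),
            ("brooch~ancestry", "has_brooch", ("females",)),
            ("weapon~ancestry", "has_weapon", ("males",))]

    results: list[TestResult] = []
    for test_name, col, which in plan:
        for stratum in which:
            sub_all = strata[stratum]
            scopes = [("overall", sub_all)]
            scopes += [(site, grp) for site, grp in sub_all.groupby("site")]
            for scope, sub in scopes:
                sub = sub.dropna(subset=[col])
                flag = sub[col].astype(bool)
                cne = sub["is_cne"]
                if (cne.sum() < config.min_group
                        or (~cne).sum() < config.min_group):
                    continue
                table = _crosstab(flag, cne)
                p, odds = fisher_exact_2x2(table)
                results.append(TestResult(test_name, stratum, scope, "fisher",
                                          odds, p, len(sub), table))
                # continuous-ancestry companion: q_CNE by flag status
                if flag.nunique() == 2:
                    with_flag = sub.loc[flag, "q_CNE"]
                    without = sub.loc[~flag, "q_CNE"]
                    p2, u = rank_sum_test(with_flag, without)
                    results.append(TestResult(test_name.replace("ancestry",
                                                                "q_continuous"),
                                              stratum, scope, "ranksum",
                                              u, p2, len(sub)))

    # burial configuration (e.g. orientation/location class A vs B)
    if "configuration" in burials.columns and burials["configuration"].notna().any():
        sub = df.dropna(subset=["configuration"])
        if sub["configuration"].nunique() == 2:
            labels = sorted(sub["configuration"].unique())
            in_a = sub["configuration"] == labels[0]
            cne = sub["is_cne"]
            if cne.sum() >= config.min_group and (~cne).sum() >= config.min_group:
                table = _crosstab(in_a, cne)
                p, odds = fisher_exact_2x2(table)
                results.append(TestResult("configuration~ancestry", "all",
                                          "overall", "fisher", odds, p,
                                          len(sub), table))

    out = pd.DataFrame([r.as_dict() for r in results])
    if config.include_bh and not out.empty:
        out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
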