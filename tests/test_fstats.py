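import numpy as np
import pytest

from nsa import fstats, simulate
from nsa.panel import MISSING
from conftest import freq_panel, make_panel, make_variants


# --------------------------------------------------- independent oracle
# Direct, loop-based evaluation of the statistics from first principles,
# deliberately sharing no code with the implementation.

def oracle_freq(calls, ploidy):
    """(freq, allele count) per variant by explicit loops."""
    n_var = calls.shape[1]
    p = np.full(n_var, np.nan)
    n = np.zeros(n_var)
    for j in range(n_var):
        alt = cnt = 0.0
        for i in range(calls.shape[0]):
            g = calls[i, j]
            if g == MISSING:
                continue
            if ploidy[i] == "diploid":
                alt += g
                cnt += 2
            else:
                alt += g / 2
                cnt += 1
        n[j] = cnt
        if cnt:
            p[j] = alt / cnt
    return p, n


def oracle_h_over_n(p, n):
    return np.array([pj * (1 - pj) / (nj - 1) if nj >= 2 else 0.0
                     for pj, nj in zip(p, n)])


def oracle_stat(kind, panel, pops):
    ploidy = panel.individuals["ploidy_mode"].tolist()
    sub = {}
    for label in pops:
        rows = [i for i, p in enumerate(panel.individuals["population"])
                if p == label]
        sub[label] = oracle_freq(panel.calls[rows], [ploidy[i] for i in rows])
    (p1, n1), (p2, n2) = sub[pops[0]], sub[pops[1]]
    if kind == "f2":
        mask = (n1 >= 1) & (n2 >= 1)
        vals = ((p1 - p2) ** 2 - oracle_h_over_n(p1, n1)
                - oracle_h_over_n(p2, n2))[mask]
        return vals.mean()
    if kind == "f3":
        (p3, n3) = sub[pops[2]]
        mask = (n1 >= 1) & (n2 >= 1) & (n3 >= 1)
        vals = ((p1 - p2) * (p1 - p3) - oracle_h_over_n(p1, n1))[mask]
        return vals.mean()
    if kind == "f4":
        (p3, n3), (p4, n4) = sub[pops[2]], sub[pops[3]]
        mask = (n1 >= 1) & (n2 >= 1) & (n3 >= 1) & (n4 >= 1)
        return ((p1 - p2) * (p3 - p4))[mask].mean()
    if kind == "fst":
        mask = (n1 >= 1) & (n2 >= 1)
        num = ((p1 - p2) ** 2 - oracle_h_over_n(p1, n1)
               - oracle_h_over_n(p2, n2))[mask]
        den = (p1 * (1 - p2) + p2 * (1 - p1))[mask]
        return num.sum() / den.sum()
    raise ValueError(kind)


def random_small_panel(seed):
    rng = np.random.default_rng(seed)
    n_var = int(rng.integers(4, 11))
    pops, ploidy, rows = [], [], []
    for label in ("A", "B", "C", "D"):
        for i in range(int(rng.integers(2, 5))):
            is_dip = bool(rng.integers(0, 2))
            g = rng.integers(0, 3, size=n_var) if is_dip \
                else 2 * rng.integers(0, 2, size=n_var)
            g = np.where(rng.random(n_var) < 0.15, MISSING, g)
            rows.append(g)
            pops.append(label)
            ploidy.append("diploid" if is_dip else "pseudohaploid")
    variants = make_variants(n_var, n_chrom=2)
    return make_panel(np.array(rows, dtype=np.int8), pops, ploidy=ploidy,
                      variants=variants)


@pytest.mark.parametrize("seed", range(12))
def test_statistics_match_bruteforce_oracle(seed):
    panel = random_small_panel(seed)
    assert fstats.f2(panel, "A", "B").estimate == pytest.approx(
        oracle_stat("f2", panel, ("A", "B")), abs=1e-10)
    assert fstats.f3(panel, "A", "B", "C").estimate == pytest.approx(
        oracle_stat("f3", panel, ("A", "B", "C")), abs=1e-10)
    assert fstats.f4(panel, "A", "B", "C", "D").estimate == pytest.approx(
        oracle_stat("f4", panel, ("A", "B", "C", "D")), abs=1e-10)
    assert fstats.fst(panel, "A", "B").estimate == pytest.approx(
        oracle_stat("fst", panel, ("A", "B")), abs=1e-10)


# ------------------------------------------------------------ hand values

def test_f4_hand_computed_value():
    # A=(1,0,.5) B=(0,1,.5) C=(1,0,0) D=(0,0,1): mean of (1, 0, 0) = 1/3
    panel = freq_panel({"A": [1, 0, 0.5], "B": [0, 1, 0.5],
                        "C": [1, 0, 0], "D": [0, 0, 1]})
    r = fstats.f4(panel, "A", "B", "C", "D")
    assert r.estimate == pytest.approx(1 / 3, abs=1e-12)


def test_allele_freqs_mixed_ploidy_hand_fixture():
    # 4 individuals, 2 variants: 2 diploids (calls 1, 2) and 2 pseudohaploids
    # (calls 2, 0) -> alt counts (1+2+1+0) of (2+2+1+1) = 4/6 at variant 0
    calls = np.array([[1, 0], [2, 1], [2, MISSING], [0, 2]], dtype=np.int8)
    panel = make_panel(calls, ["P"] * 4,
                       ploidy=["diploid", "diploid",
                               "pseudohaploid", "pseudohaploid"])
    freq, n = fstats.allele_freqs(panel, {"P": "P"})
    assert freq.loc["P"].tolist() == pytest.approx([4 / 6, 2 / 5])
    assert n.loc["P"].tolist() == [6, 5]


def test_monomorphic_and_singleton_frequencies():
    calls = np.array([[0, 2]], dtype=np.int8)
    panel = make_panel(calls, ["P"], ploidy="pseudohaploid")
    p, n = fstats.freq_and_count(panel, "P")
    assert p.tolist() == [0.0, 1.0]
    assert n.tolist() == [1.0, 1.0]


# ------------------------------------------------------------- identities

def test_f4_algebraic_identities():
    rng = np.random.default_rng(5)
    calls = (2 * rng.integers(0, 2, size=(15, 40))).astype(np.int8)
    pops = ["A"] * 3 + ["B"] * 3 + ["C"] * 3 + ["D"] * 3 + ["E"] * 3
    panel = make_panel(calls, pops, ploidy="pseudohaploid",
                       variants=make_variants(40, n_chrom=2))
    f4 = lambda *args: fstats.f4(panel, *args).estimate
    assert fstats.f4(panel, "A", "A", "C", "D").estimate == 0.0
    assert f4("A", "B", "C", "D") == pytest.approx(-f4("B", "A", "C", "D"),
                                                   abs=1e-12)
    assert f4("A", "B", "C", "D") + f4("A", "B", "D", "E") == pytest.approx(
        f4("A", "B", "C", "E"), abs=1e-10)


def test_f4_equals_f2_on_true_frequencies():
    panel = freq_panel({"A": [1, 0, 0.5, 1], "B": [0, 1, 0.5, 0]})
    f4 = fstats.f4(panel, "A", "B", "A", "B").estimate
    f2 = fstats.f2(panel, "A", "B", correction=False).estimate
    assert f4 == pytest.approx(f2, abs=1e-12)


def test_f3_decomposes_into_f2_sum():
    panel = random_small_panel(99)
    blocks = fstats.make_blocks(panel.variants)
    # identity requires a common variant set: restrict to complete columns
    keep = np.nonzero((panel.calls != MISSING).all(axis=0))[0]
    panel = panel.subset(variant_idx=keep)
    f3 = fstats.f3(panel, "A", "B", "C").estimate
    f2 = lambda x, y: fstats.f2(panel, x, y).estimate
    assert f3 == pytest.approx((f2("A", "B") + f2("A", "C") - f2("B", "C")) / 2,
                               abs=1e-12)


def test_f2_of_population_with_itself_is_zero():
    panel = freq_panel({"A": [1, 0, 0.5], "B": [1, 0, 0.5]})
    assert fstats.f2(panel, "A", "B", correction=False).estimate == 0.0


# -------------------------------------------------------------- jackknife

def test_jackknife_se_matches_closed_form_for_iid_mean():
    rng = np.random.default_rng(21)
    n, g = 2_000, 40
    ratios = []
    blocks = fstats.BlockPartition(index=np.repeat(np.arange(g), n // g),
                                   n_blocks=g)
    for _ in range(200):
        x = rng.normal(0.3, 1.0, size=n)
        _, se, _ = fstats.block_jackknife(x, np.ones(n), blocks)
        ratios.append(se / (1.0 / np.sqrt(n)))
    assert abs(np.mean(ratios) - 1.0) < 0.15


def test_jackknife_single_block_errors():
    blocks = fstats.BlockPartition(index=np.zeros(10, dtype=int), n_blocks=1)
    with pytest.raises(ValueError, match="two"):
        fstats.block_jackknife(np.ones(10), np.ones(10), blocks)


def test_jackknife_constant_contributions_zero_se():
    blocks = fstats.BlockPartition(index=np.repeat(np.arange(5), 4), n_blocks=5)
    est, se, _ = fstats.block_jackknife(np.full(20, 0.7), np.ones(20), blocks)
    assert est == pytest.approx(0.7)
    assert se == pytest.approx(0.0, abs=1e-12)


def test_blocks_respect_chromosomes_and_length():
    variants = make_variants(100, n_chrom=4)  # 10 Mb = 10 cM per chromosome
    bp = fstats.make_blocks(variants, block_cm=5.0)
    chrom = variants["chrom"].to_numpy()
    assert bp.n_blocks == 8  # 2 blocks of 5 cM per 10-cM chromosome
    for b in range(bp.n_blocks):
        assert len(set(chrom[bp.index == b])) == 1


# -------------------------------------------------------------------- FST

def test_fst_identical_populations_consistent_with_zero():
    rng = np.random.default_rng(31)
    freq = rng.uniform(0.05, 0.95, 10_000)
    calls = (2 * (rng.random((20, 10_000)) < freq)).astype(np.int8)
    panel = make_panel(calls, ["A"] * 10 + ["B"] * 10, ploidy="pseudohaploid",
                       variants=make_variants(10_000, n_chrom=4))
    r = fstats.fst(panel, "A", "B")
    assert abs(r.z) < 3


def test_fst_fixed_differences_is_one():
    calls = np.array([[2, 0, 2], [2, 0, 2], [0, 2, 0], [0, 2, 0]],
                     dtype=np.int8)
    panel = make_panel(calls, ["A", "A", "B", "B"], ploidy="pseudohaploid")
    assert fstats.fst(panel, "A", "B").estimate == pytest.approx(1.0)


def test_fst_recovers_simulated_drift():
    # panel-based estimate at per-branch F = 0.01 each: the Hudson ratio of
    # averages converges to F (see the generator oracle test)
    model = simulate.star_model([("P1", 0.01), ("P2", 0.01)], 100_000)
    freqs, variants = simulate.simulate_source_freqs(model, 17)
    scen = simulate.AdmixtureScenario((simulate.unadmixed("P1", "P1", 20),
                                       simulate.unadmixed("P2", "P2", 20)))
    panel = simulate.simulate_genotypes(freqs, variants, scen, 18)
    r = fstats.fst(panel, "P1", "P2")
    assert 0.008 < r.estimate < 0.012


# ------------------------------------------------- outgroup-f4 linearity

def test_outgroup_f4_interpolates_admixture_gradient():
    """f4(deep outgroup, X; WBI, CNE) is linear in X's continental fraction."""
    model = simulate.north_sea_model(20_000)
    freqs, variants = simulate.simulate_source_freqs(model, 23)
    fracs = np.linspace(0, 1, 11)
    groups = [simulate.unadmixed("CNE", "CNE", 20),
              simulate.unadmixed("WBI", "WBI", 20),
              simulate.unadmixed("O_YRI", "O_YRI", 10)]
    for i, w in enumerate(fracs):
        groups.append(simulate.SampleGroup(f"X{i}", 10,
                                           {"CNE": w, "WBI": 1 - w}))
    panel = simulate.simulate_genotypes(
        freqs, variants, simulate.AdmixtureScenario(tuple(groups)), 24)
    blocks = fstats.make_blocks(panel.variants)
    vals = [fstats.f4(panel, "O_YRI", f"X{i}", "WBI", "CNE",
                      blocks=blocks).estimate for i in range(11)]
    r = np.corrcoef(fracs, vals)[0, 1]
    assert abs(r) > 0.99
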