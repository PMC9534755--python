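import numpy as np
import pandas as pd
import pytest

from nsa.panel import (MISSING, GenotypePanel, NoDataError, PanelFormatError,
                       PileupSite, filter_panel, merge_panels,
                       pseudohaploid_call, read_panel, write_panel)
from nsa import simulate
from conftest import make_panel, make_variants


# ------------------------------------------------------------------ I/O

def test_roundtrip_identity(tmp_path):
    calls = np.array([[0, 1, 2, MISSING], [2, 2, 0, 0], [MISSING, 0, 2, 2]])
    panel = make_panel(calls, ["A", "A", "B"],
                       ploidy=["diploid", "pseudohaploid", "pseudohaploid"])
    write_panel(panel, tmp_path / "p")
    back = read_panel(tmp_path / "p")
    assert back == panel


def test_simulated_panel_roundtrips(tmp_path):
    model = simulate.star_model([("P1", 0.02), ("P2", 0.02)], 500)
    freqs, variants = simulate.simulate_source_freqs(model, 5)
    scenario = simulate.AdmixtureScenario((
        simulate.unadmixed("P1", "P1", 4, missing_rate=0.1),
        simulate.unadmixed("P2", "P2", 4, ploidy="diploid"),
    ))
    panel = simulate.simulate_genotypes(freqs, variants, scenario, 6)
    write_panel(panel, tmp_path / "sim")
    back = read_panel(tmp_path / "sim")
    assert np.array_equal(back.calls, panel.calls)
    assert back.variants["position"].tolist() == panel.variants["position"].tolist()
    # genetic positions survive the Morgan <-> centimorgan conversion
    np.testing.assert_allclose(back.variants["genetic_pos"],
                               panel.variants["genetic_pos"], rtol=1e-6)


def test_missing_code_decoded(tmp_path):
    (tmp_path / "p.geno").write_text("09\n22\n20\n")
    (tmp_path / "p.snp").write_text(
        "v0 1 0.0001 100 A G\nv1 1 0.0002 200 A G\nv2 1 0.0003 300 A G\n")
    (tmp_path / "p.ind").write_text("i1 U Pop\ni2 U Pop\n")
    panel = read_panel(tmp_path / "p")
    assert (panel.calls == MISSING).sum() == 1
    assert panel.calls[1, 0] == MISSING


def test_illegal_genotype_code_raises(tmp_path):
    (tmp_path / "p.geno").write_text("03\n")
    (tmp_path / "p.snp").write_text("v0 1 0.0001 100 A G\n")
    (tmp_path / "p.ind").write_text("i1 U Pop\ni2 U Pop\n")
    with pytest.raises(PanelFormatError, match="line 1"):
        read_panel(tmp_path / "p")


def test_dimension_mismatch_raises(tmp_path):
    (tmp_path / "p.geno").write_text("002\n")  # 3 genotypes, 2 individuals
    (tmp_path / "p.snp").write_text("v0 1 0.0001 100 A G\n")
    (tmp_path / "p.ind").write_text("i1 U Pop\ni2 U Pop\n")
    with pytest.raises(PanelFormatError):
        read_panel(tmp_path / "p")


def test_pseudohaploid_rows_reject_hets():
    with pytest.raises(PanelFormatError, match="heterozygous"):
        make_panel(np.array([[1, 0]]), ["A"], ploidy="pseudohaploid")


# ------------------------------------------------------- pseudohaploid calls

def _variants_ct():
    # C/T and G/A pairs are the damage-prone classes; A/C is unaffected
    v = make_variants(3)
    v.loc[0, ["ref", "alt"]] = ["C", "T"]
    v.loc[1, ["ref", "alt"]] = ["G", "A"]
    v.loc[2, ["ref", "alt"]] = ["A", "C"]
    return v


def test_single_alt_read_gives_call_2():
    v = _variants_ct()
    sites = [PileupSite("i1", 2, (("C", "forward"),))]
    calls = pseudohaploid_call(sites, v, ["i1"], seed=0)
    assert calls[0, 2] == 2


def test_single_strand_mode_drops_damage_prone_strand():
    v = _variants_ct()
    sites = [
        # C/T variant covered only by forward reads: all removed -> missing
        PileupSite("i1", 0, (("T", "forward"), ("C", "forward"))),
        # G/A variant covered only by reverse reads: all removed -> missing
        PileupSite("i1", 1, (("A", "reverse"),)),
        # A/C variant unaffected by the strand rule
        PileupSite("i1", 2, (("A", "reverse"),)),
    ]
    calls = pseudohaploid_call(sites, v, ["i1"], mode="single_strand", seed=0)
    assert calls[0, 0] == MISSING
    assert calls[0, 1] == MISSING
    assert calls[0, 2] == 0
    # in standard mode the same reads are usable
    std = pseudohaploid_call(sites, v, ["i1"], mode="standard", seed=0)
    assert std[0, 0] in (0, 2) and std[0, 1] in (0, 2)


def test_non_allelic_bases_dropped_before_draw():
    v = _variants_ct()
    sites = [PileupSite("i1", 2, (("T", "forward"), ("C", "reverse")))]
    calls = pseudohaploid_call(sites, v, ["i1"], seed=1)
    assert calls[0, 2] == 2  # the non-allelic T read can never be drawn


def test_random_draw_is_binomial_at_even_coverage():
    n = 10_000
    v = make_variants(n)
    sites = [PileupSite("i1", j, (("A", "forward"), ("G", "reverse")))
             for j in range(n)]
    calls = pseudohaploid_call(sites, v, ["i1"], seed=7)
    alt_frac = (calls[0] == 2).mean()
    sd = 0.5 / np.sqrt(n)
    assert abs(alt_frac - 0.5) < 3 * sd


def test_draws_reproducible_and_order_independent():
    n = 200
    v = make_variants(n)
    sites = [PileupSite("i1", j, (("A", "forward"), ("G", "reverse")))
             for j in range(n)]
    a = pseudohaploid_call(sites, v, ["i1"], seed=3)
    b = pseudohaploid_call(list(reversed(sites)), v, ["i1"], seed=3)
    c = pseudohaploid_call(sites, v, ["i1"], seed=4)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)  # different seed re-draws some sites


# ---------------------------------------------------------------------- merge

def test_merge_identical_panel_doubles_individuals():
    calls = np.array([[0, 2, 2], [2, 0, MISSING]])
    a = make_panel(calls, ["P", "P"], ploidy="pseudohaploid")
    merged, report = merge_panels(a, a)
    assert merged.n_individuals == 4
    assert merged.n_variants == 3
    assert np.array_equal(merged.calls, np.vstack([calls, calls]))
    assert report["n_dropped_ambiguous"] == 0
    assert merged.individuals["id"].is_unique


def test_merge_recodes_swapped_alleles():
    a = make_panel(np.array([[0, 2]]), ["P"], ploidy="pseudohaploid")
    b = make_panel(np.array([[0, MISSING]]), ["Q"], ploidy="pseudohaploid")
    b.variants.loc[0, ["ref", "alt"]] = ["G", "A"]  # swapped vs a's A/G
    merged, report = merge_panels(a, b)
    assert report["n_flipped"] == 1
    assert merged.calls[1, 0] == 2      # 0 recoded to 2
    assert merged.calls[1, 1] == MISSING  # missing stays missing


def test_merge_strand_complement_matched():
    a = make_panel(np.array([[2]]), ["P"], ploidy="pseudohaploid")
    b = make_panel(np.array([[2]]), ["Q"], ploidy="pseudohaploid")
    b.variants.loc[0, ["ref", "alt"]] = ["T", "C"]  # complement of A/G
    merged, report = merge_panels(a, b)
    assert merged.n_variants == 1
    assert merged.calls[1, 0] == 2


def test_merge_drops_ambiguous_strand_variants():
    a = make_panel(np.array([[0, 0]]), ["P"], ploidy="pseudohaploid")
    a.variants.loc[0, ["ref", "alt"]] = ["A", "T"]
    b = make_panel(np.array([[0, 0]]), ["Q"], ploidy="pseudohaploid")
    b.variants.loc[0, ["ref", "alt"]] = ["A", "T"]
    merged, report = merge_panels(a, b)
    assert merged.n_variants == 1
    assert report["n_dropped_ambiguous"] == 1
    kept, _ = merge_panels(a, b, ambiguous="keep")
    assert kept.n_variants == 2


def test_merge_commutative_up_to_individual_order():
    rng = np.random.default_rng(0)
    calls_a = (2 * rng.integers(0, 2, size=(3, 20))).astype(np.int8)
    calls_b = (2 * rng.integers(0, 2, size=(2, 20))).astype(np.int8)
    a = make_panel(calls_a, ["A"] * 3, ploidy="pseudohaploid")
    b = make_panel(calls_b, ["B"] * 2, ploidy="pseudohaploid")
    ab, _ = merge_panels(a, b)
    ba, _ = merge_panels(b, a)
    assert np.array_equal(np.vstack([ab.calls[3:], ab.calls[:3]]), ba.calls)


# --------------------------------------------------------------------- filter

def test_filter_identity_when_complete():
    panel = make_panel(np.full((3, 10), 2), ["P"] * 3, ploidy="pseudohaploid")
    out = filter_panel(panel, 0.95, 0.95)
    assert out == panel


def test_filter_removes_low_call_rate_individual():
    calls = np.full((2, 20), 2, dtype=np.int8)
    calls[1, :2] = MISSING  # 90% call rate
    panel = make_panel(calls, ["P", "P"], ploidy="pseudohaploid")
    out = filter_panel(panel, min_individual_call_rate=0.95)
    assert out.n_individuals == 1
    assert out.individuals["id"].tolist() == [panel.individuals["id"].iat[0]]


def test_filter_variant_call_rate_computed_after_individual_removal():
    # variant 0 is missing only in the low-coverage individual; once that
    # individual is gone the variant is complete and must survive
    calls = np.full((2, 20), 2, dtype=np.int8)
    calls[1, :10] = MISSING
    panel = make_panel(calls, ["P", "P"], ploidy="pseudohaploid")
    out = filter_panel(panel, min_individual_call_rate=0.95,
                       min_variant_call_rate=0.95)
    assert out.n_individuals == 1
    assert out.n_variants == 20


def test_region_mask_is_half_open_zero_based():
    panel = make_panel(np.full((1, 5), 2), ["P"], ploidy="pseudohaploid")
    positions = panel.variants["position"].tolist()
    # mask exactly the first variant: [pos0-1, pos0)
    out = filter_panel(panel, region_mask=[("1", positions[0] - 1, positions[0])])
    assert out.n_variants == 4


def test_mask_covering_everything_errors():
    panel = make_panel(np.full((1, 5), 2), ["P"], ploidy="pseudohaploid")
    with pytest.raises(NoDataError, match="no data"):
        filter_panel(panel, region_mask=[("1", 0, 10_000_001)])


def test_pileup_tsv_to_calls(tmp_path):
    v = _variants_ct()
    tsv = tmp_path / "pileup.tsv"
    lines = ["individual\tchrom\tposition\tbase\tstrand"]
    pos = v["position"].tolist()
    lines.append(f"i1\t1\t{pos[2]}\tC\tforward")
    lines.append(f"i1\t1\t{pos[2]}\tC\treverse")
    lines.append(f"i1\t1\t{pos[0]}\tT\treverse")
    lines.append(f"i2\t1\t{pos[1]}\tG\tforward")
    lines.append(f"i1\t2\t999999\tA\tforward")  # not a panel coordinate
    tsv.write_text("\n".join(lines) + "\n")
    from nsa.panel import locate_pileup_sites, read_pileup
    sites = locate_pileup_sites(read_pileup(tsv), v)
    calls = pseudohaploid_call(sites, v, ["i1", "i2"], seed=0)
    assert calls[0, 2] == 2      # alt C drawn from two concordant reads
    assert calls[0, 0] == 2      # alt T on the C/T variant
    assert calls[1, 1] == 0      # ref G
    assert calls[1, 0] == MISSING


# ------------------------------------------------------ property (hypothesis)

from hypothesis import given, settings, strategies as st


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.lists(st.sampled_from([0, 2, MISSING]), min_size=3,
                         max_size=3), min_size=1, max_size=6))
def test_roundtrip_property_arbitrary_pseudohaploid_panels(rows):
    import tempfile
    from pathlib import Path
    calls = np.array(rows, dtype=np.int8)
    panel = make_panel(calls, ["P"] * len(rows), ploidy="pseudohaploid")
    with tempfile.TemporaryDirectory() as d:
        write_panel(panel, Path(d) / "p")
        back = read_panel(Path(d) / "p", ploidy="pseudohaploid")
    assert np.array_equal(back.calls, panel.calls)
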