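import numpy as np
import pandas as pd
import pytest

from nsa.panel import MISSING, GenotypePanel
from nsa import simulate


def make_variants(n, chrom_length_bp=10_000_000, n_chrom=1, ref="A", alt="G"):
    """Evenly spaced variant table on one or more chromosomes."""
    per = [n // n_chrom + (1 if i < n % n_chrom else 0) for i in range(n_chrom)]
    rows = []
    j = 0
    for c, k in enumerate(per):
        for pos in np.linspace(1, chrom_length_bp, k, dtype=int):
            rows.append({"id": f"v{j}", "chrom": str(c + 1),
                         "genetic_pos": pos / 1e6, "position": int(pos),
                         "ref": ref, "alt": alt})
            j += 1
    return pd.DataFrame(rows)


def make_panel(calls, populations, ploidy="diploid", variants=None, sexes=None):
    """Panel from a call matrix and per-individual population labels."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_var = calls.shape
    if variants is None:
        variants = make_variants(n_var)
    if isinstance(ploidy, str):
        ploidy = [ploidy] * n_ind
    individuals = pd.DataFrame({
        "id": [f"{p}_{i}" for i, p in enumerate(populations)],
        "sex": sexes if sexes is not None else ["U"] * n_ind,
        "population": populations,
        "ploidy_mode": ploidy,
    })
    return GenotypePanel(variants, individuals, calls)


def freq_panel(freqs_by_pop, variants=None):
    """Single-individual diploid populations realising exact frequencies.

    Frequencies must be in {0, 0.5, 1}: one diploid individual with calls
    0/1/2 carries them exactly, so statistics on the panel equal direct
    formula evaluation on the frequency table.
    """
    pops, rows = [], []
    for pop, freqs in freqs_by_pop.items():
        pops.append(pop)
        rows.append([int(round(2 * f)) for f in freqs])
    return make_panel(np.array(rows), pops, variants=variants)


@pytest.fixture(scope="session")
def two_source_panel_20k():
    """CNE/WBI sources, 11 outgroups and a 70/30 target at 20k variants."""
    model = simulate.north_sea_model(20_000)
    freqs, variants = simulate.simulate_source_freqs(model, 4221)
    groups = [simulate.unadmixed(s, s, 20) for s in ("CNE", "WBI")]
    groups += [simulate.unadmixed(o, o, 10) for o in simulate.OUTGROUPS]
    groups.append(simulate.SampleGroup("Target", 20, {"CNE": 0.7, "WBI": 0.3}))
    panel = simulate.simulate_genotypes(
        freqs, variants, simulate.AdmixtureScenario(tuple(groups)), 4222)
    return panel


@pytest.fixture(scope="session")
def source_freq_pair_5k():
    """True frequency arrays for a two-population star at modest drift."""
    model = simulate.star_model([("P1", 0.01), ("P2", 0.01)], 5_000)
    freqs, variants = simulate.simulate_source_freqs(model, 99)
    return freqs, variants
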