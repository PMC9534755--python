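"""Synthetic data with the statistical structure the analysis assumes.

Allele frequencies follow a hierarchical Balding–Nichols model: each
population-tree branch draws its frequency from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around its parent's frequency ``p``, so every
branch has a drift parameter ``F`` with ``E[(p_child - p)^2] = F p(1-p)``.
Closed-form expectations make every downstream statistic checkable: two
populations that split from a common node with per-branch drift F have Hudson
FST ≈ 2F/(1+F) in expectation (numerator 2F·p(1−p), denominator 2p(1−p)(1−F)
per variant, before ascertainment of the ancestral law).

A star tree (all populations drifting independently off the root) makes every
population exchangeable with respect to every other, which is useless for
admixture-weight estimation — the outgroups must be *differentially* related
to the sources. The default North-Sea scenario therefore hangs outgroups off
the source clades (a CNE-like clade, a WBI-like clade, a southern France-IA
clade and a deep African-like outgroup), mimicking the differential
relatedness of the real reference panel.

Genotypes, sex-chromosome read counts, relative pairs and burial tables are
generated in the formats the rest of the package consumes, with known ground
truth (drift, admixture weights, karyotype, kinship degree, effect sizes).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

ROOT = "ROOT"

_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                 ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]


# ----------------------------------------------------------------- the model

@dataclasses.dataclass(frozen=True)
class DriftNode:
    """One branch of the population tree: ``label`` drifts off ``parent`` with F."""
    label: str
    parent: str
    f: float

    def __post_init__(self):
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"drift F must be in [0, 1), got {self.f}")


@dataclasses.dataclass(frozen=True)
class ChromosomeLayout:
    """Desk-scale genome: variants spread uniformly over equal chromosomes."""
    n_chromosomes: int = 22
    chromosome_length_bp: int = 10_000_000
    cm_per_mb: float = 1.0


@dataclasses.dataclass(frozen=True)
class SourceModel:
    """Population tree plus variant layout and ancestral-frequency law."""
    n_variants: int
    nodes: tuple[DriftNode, ...]
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    layout: ChromosomeLayout = ChromosomeLayout()

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        known = {ROOT}
        for node in self.nodes:
            if node.parent not in known:
                raise ValueError(f"node {node.label}: parent {node.parent} not defined "
                                 "before it (nodes must be topologically ordered)")
            if node.label in known:
                raise ValueError(f"duplicate node label {node.label}")
            known.add(node.label)

    @property
    def populations(self) -> list[str]:
        """Leaf labels (nodes that are no other node's parent)."""
        parents = {n.parent for n in self.nodes}
        return [n.label for n in self.nodes if n.label not in parents]


def star_model(populations: Sequence[tuple[str, float]], n_variants: int,
               **kwargs) -> SourceModel:
    """All populations drift independently off the root (exchangeable)."""
    nodes = tuple(DriftNode(label, ROOT, f) for label, f in populations)
    return SourceModel(n_variants=n_variants, nodes=nodes, **kwargs)


#: the 11 outgroup labels of the default scenario, named for the real panel
OUTGROUPS = ("O_YRI", "O_Denmark", "O_Sweden", "O_Poland", "O_Finland",
             "O_Netherlands", "O_Ireland", "O_Wales", "O_Italy", "O_Spain",
             "O_Belgium")


def north_sea_model(n_variants: int = 100_000, *, three_way: bool = False,
                    source_drift: float = 0.005, clade_drift: float = 0.015,
                    outgroup_drift: float = 0.02, extra_source_drift: float = 0.0,
                    layout: ChromosomeLayout = ChromosomeLayout()) -> SourceModel:
    """The default admixture scenario: CNE-like and WBI-like sources, 11 outgroups.

    The tree places five outgroups on the northern (CNE) clade, two on the
    western (WBI) clade, three on a southern clade and one deep outgroup, so
    the outgroup set is differentially related to the sources. With
    ``three_way=True`` a ``FranceIA`` source is added on the southern clade.
    ``extra_source_drift`` adds post-split drift to the source terminal
    branches (ancient-proxy panels).
    """
    sd = source_drift + extra_source_drift
    nodes = [
        DriftNode("O_YRI", ROOT, 0.15),
        DriftNode("EUR", ROOT, 0.05),
        DriftNode("NORTH", "EUR", clade_drift),
        DriftNode("WEST", "EUR", clade_drift),
        DriftNode("SOUTH", "EUR", clade_drift),
        DriftNode("CNE", "NORTH", sd),
        DriftNode("O_Denmark", "NORTH", outgroup_drift),
        DriftNode("O_Sweden", "NORTH", 1.5 * outgroup_drift),
        DriftNode("O_Poland", "NORTH", 2.0 * outgroup_drift),
        DriftNode("O_Finland", "NORTH", 3.0 * outgroup_drift),
        DriftNode("O_Netherlands", "NORTH", outgroup_drift),
        DriftNode("WBI", "WEST", sd),
        DriftNode("O_Ireland", "WEST", outgroup_drift),
        DriftNode("O_Wales", "WEST", outgroup_drift),
        DriftNode("O_Italy", "SOUTH", 2.0 * outgroup_drift),
        DriftNode("O_Spain", "SOUTH", 2.0 * outgroup_drift),
        DriftNode("O_Belgium", "SOUTH", outgroup_drift),
    ]
    if three_way:
        nodes.append(DriftNode("FranceIA", "SOUTH", sd))
    return SourceModel(n_variants=n_variants, nodes=tuple(nodes), layout=layout)


# ----------------------------------------------------------- frequency tables

def _variant_table(n_variants: int, layout: ChromosomeLayout,
                   rng: np.random.Generator) -> pd.DataFrame:
    per = np.full(layout.n_chromosomes, n_variants // layout.n_chromosomes)
    per[: n_variants % layout.n_chromosomes] += 1
    chroms, positions = [], []
    for c in range(layout.n_chromosomes):
        k = int(per[c])
        if k == 0:
            continue
        pos = np.linspace(1, layout.chromosome_length_bp, k, dtype=np.int64)
        pos = np.unique(pos)
        chroms.append(np.full(len(pos), str(c + 1), dtype=object))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    position = np.concatenate(positions)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=len(position))
    refs = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    alts = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    return pd.DataFrame({
        "id": [f"var{j}" for j in range(len(position))],
        "chrom": chrom,
        "genetic_pos": position / 1e6 * layout.cm_per_mb,
        "position": position,
        "ref": refs,
        "alt": alts,
    })


def _drift(parent: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    if f <= 0.0:
        return parent.copy()
    scale = (1.0 - f) / f
    a = np.clip(parent * scale, 1e-12, None)
    b = np.clip((1.0 - parent) * scale, 1e-12, None)
    child = rng.beta(a, b)
    child[parent <= 0.0] = 0.0
    child[parent >= 1.0] = 1.0
    return child


def simulate_source_freqs(model: SourceModel, seed: int):
    """Draw per-population allele frequencies and the variant table.

    Returns ``(freqs, variants)`` where freqs maps every node label (internal
    nodes included) to an array of length n_variants. The ancestral frequency
    is Uniform(ancestral_low, ancestral_high) per variant.
    """
    rng = np.random.default_rng(seed)
    n = model.n_variants
    variants = _variant_table(n, model.layout, rng)
    n = len(variants)  # may shrink slightly after position de-duplication
    freqs = {ROOT: rng.uniform(model.ancestral_low, model.ancestral_high, size=n)}
    for node in model.nodes:
        freqs[node.label] = _drift(freqs[node.parent], node.f, rng)
    return freqs, variants


# ----------------------------------------------------------------- genotypes

@dataclasses.dataclass(frozen=True)
class SampleGroup:
    """One simulated population sample: label, size, mixing weights, ploidy."""
    label: str
    n: int
    weights: dict
    ploidy: str = "pseudohaploid"
    missing_rate: float = 0.0
    era: str | None = None

    def __post_init__(self):
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights for {self.label} must lie on the simplex")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.ploidy not in ("pseudohaploid", "diploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")


@dataclasses.dataclass(frozen=True)
class AdmixtureScenario:
    groups: tuple[SampleGroup, ...]


def unadmixed(label: str, source: str, n: int, **kw) -> SampleGroup:
    return SampleGroup(label, n, {source: 1.0}, **kw)


def simulate_genotypes(freqs: dict, variants: pd.DataFrame,
                       scenario: AdmixtureScenario, seed: int) -> GenotypePanel:
    """Sample a genotype panel under an admixture scenario.

    Every allele of every individual independently picks a source population
    according to the group's weights, then is Bernoulli(source frequency).
    Pseudohaploid individuals carry a single sampled allele stored as {0, 2};
    diploid individuals sum two alleles. Calls are masked missing at the
    group's missing rate.
    """
    rng = np.random.default_rng(seed)
    n_var = len(variants)
    rows, ind_rows = [], []
    for group in scenario.groups:
        labels = list(group.weights.keys())
        for lab in labels:
            if lab not in freqs:
                raise KeyError(f"scenario references unknown source {lab!r}")
        w = np.array([group.weights[k] for k in labels], dtype=float)
        fmat = np.stack([np.asarray(freqs[k]) for k in labels])  # (K, V)
        cum = np.cumsum(w)
        n_alleles = 1 if group.ploidy == "pseudohaploid" else 2
        calls = np.zeros((group.n, n_var), dtype=np.int8)
        for _ in range(n_alleles):
            src = np.searchsorted(cum, rng.random((group.n, n_var)), side="right")
            src = np.minimum(src, len(labels) - 1)
            p = fmat[src, np.arange(n_var)[None, :]]
            calls += (rng.random((group.n, n_var)) < p).astype(np.int8)
        if group.ploidy == "pseudohaploid":
            calls *= 2
        if group.missing_rate > 0.0:
            mask = rng.random((group.n, n_var)) < group.missing_rate
            calls[mask] = MISSING
        rows.append(calls)
        for i in range(group.n):
            ind_rows.append({"id": f"{group.label}_{i}", "sex": "U",
                             "population": group.label,
                             "ploidy_mode": group.ploidy, "era": group.era})
    individuals = pd.DataFrame(ind_rows)
    return GenotypePanel(variants, individuals, np.vstack(rows))


# --------------------------------------------------------------- read counts

@dataclasses.dataclass(frozen=True)
class ReadCountProfile:
    """Targeted-site counts and depth for sex-chromosome coverage simulation.

    Site counts default to the rough scale of the 1240K capture panel. X and Y
    sites are covered at half the autosomal per-site depth in an XY individual
    and at full/near-zero depth in an XX individual; ``mismap_rate`` is the
    fraction of autosomal depth spilling onto the Y of an XX individual
    through mismapping.
    """
    n_sites_aut: int = 1_150_000
    n_sites_x: int = 49_000
    n_sites_y: int = 32_000
    depth: float = 1.0
    karyotype: str = "XX"
    mismap_rate: float = 0.001

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.karyotype not in ("XX", "XY"):
            raise ValueError(f"karyotype must be XX or XY, got {self.karyotype!r}")


@dataclasses.dataclass(frozen=True)
class ReadCounts:
    n_aut: int
    n_x: int
    n_y: int
    sites_aut: int
    sites_x: int
    sites_y: int


def simulate_read_counts(profile: ReadCountProfile, seed: int) -> ReadCounts:
    """Poisson read counts on autosomes, X and Y under the given karyotype."""
    rng = np.random.default_rng(seed)
    d = profile.depth
    if profile.karyotype == "XX":
        lam_x, lam_y = d, d * profile.mismap_rate
    else:
        lam_x = lam_y = d / 2.0
    return ReadCounts(
        n_aut=int(rng.poisson(profile.n_sites_aut * d)),
        n_x=int(rng.poisson(profile.n_sites_x * lam_x)),
        n_y=int(rng.poisson(profile.n_sites_y * lam_y)),
        sites_aut=profile.n_sites_aut,
        sites_x=profile.n_sites_x,
        sites_y=profile.n_sites_y,
    )


# -------------------------------------------------------------- relative pairs

IBD_FRACTION = {"identical": 1.0, "first": 0.5, "second": 0.25, "unrelated": 0.0}


def simulate_relative_pair(freq: np.ndarray, variants: pd.DataFrame, degree: str,
                           seed: int, window_mb: float = 1.0,
                           missing_rate: float = 0.0):
    """Two pseudohaploid genotype vectors sharing IBD genome fractions 1, 1/2,
    1/4 or 0 for identical/first/second/unrelated.

    IBD is laid down in physical windows (default 1 Mb): in a shared window
    the second individual's underlying *diploid* genotype is a copy of the
    first's; pseudohaploid sampling then draws one allele independently for
    each individual, so even duplicates mismatch at heterozygous sites half
    the time.
    """
    if degree not in IBD_FRACTION:
        raise ValueError(f"unknown degree {degree!r}")
    rng = np.random.default_rng(seed)
    freq = np.asarray(freq)
    n = len(freq)
    g1 = (rng.random((2, n)) < freq).astype(np.int8)  # two alleles, individual 1
    g2 = (rng.random((2, n)) < freq).astype(np.int8)

    frac = IBD_FRACTION[degree]
    if frac > 0.0:
        win = (variants["chrom"].astype(str) + ":" +
               (variants["position"] // int(window_mb * 1e6)).astype(str))
        codes = pd.factorize(win)[0]
        shared_windows = rng.random(codes.max() + 1) < frac
        shared = shared_windows[codes]
        g2[:, shared] = g1[:, shared]

    def draw(g):
        pick = rng.integers(0, 2, size=n)
        allele = g[pick, np.arange(n)]
        v = (2 * allele).astype(np.int8)
        if missing_rate > 0.0:
            v[rng.random(n) < missing_rate] = MISSING
        return v

    return draw(g1), draw(g2)


# -------------------------------------------------------------------- burials

@dataclasses.dataclass(frozen=True)
class LogisticEffect:
    """Log-odds model for one grave-good flag:
    logit P = intercept + b_ancestry*q + b_female*1[female] + b_interaction*q*1[female].
    """
    intercept: float = 0.0
    beta_ancestry: float = 0.0
    beta_female: float = 0.0
    beta_interaction: float = 0.0

    def prob(self, q: np.ndarray, female: np.ndarray) -> np.ndarray:
        z = (self.intercept + self.beta_ancestry * q
             + self.beta_female * female + self.beta_interaction * q * female)
        return 1.0 / (1.0 + np.exp(-z))


@dataclasses.dataclass(frozen=True)
class BurialEffects:
    goods: LogisticEffect = LogisticEffect(intercept=-0.5)
    brooch: LogisticEffect = LogisticEffect(intercept=-3.0, beta_female=2.0)
    weapon: LogisticEffect = LogisticEffect(intercept=-1.5, beta_female=-2.0)
    configuration: LogisticEffect | None = None


def simulate_burials(ancestry: np.ndarray, sexes: Sequence[str],
                     effects: BurialEffects, seed: int,
                     ids: Sequence[str] | None = None,
                     n_sites: int = 4) -> pd.DataFrame:
    """Burial-metadata table with grave-good flags drawn from logistic models.

    ``ancestry`` is the per-individual continental (CNE-like) fraction in
    [0, 1]; ``sexes`` are "XX"/"XY"/"unknown". Brooch or weapon presence
    implies the any-goods flag. Sites are assigned round-robin; an A/B burial
    configuration label is drawn when ``effects.configuration`` is given.
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(ancestry, dtype=float)
    sexes = np.asarray(sexes, dtype=object)
    n = len(q)
    if ids is None:
        ids = [f"ind_{i}" for i in range(n)]
    female = (sexes == "XX").astype(float)
    goods = rng.random(n) < effects.goods.prob(q, female)
    brooch = rng.random(n) < effects.brooch.prob(q, female)
    weapon = rng.random(n) < effects.weapon.prob(q, female)
    goods = goods | brooch | weapon
    df = pd.DataFrame({
        "id": list(ids),
        "sex": sexes,
        "site": [f"S{(i % n_sites) + 1}" for i in range(n)],
        "has_goods": goods,
        "has_brooch": brooch,
        "has_weapon": weapon,
    })
    if effects.configuration is not None:
        df["configuration"] = np.where(
            rng.random(n) < effects.configuration.prob(q, female), "A", "B")
    else:
        df["configuration"] = None
    return df
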