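"""Genotype panels: data model, EIGENSTRAT-dialect I/O, pseudohaploid calling,
merging and filtering.

A :class:`GenotypePanel` holds an individuals × variants matrix of alternate-allele
counts. Diploid individuals use {0, 1, 2}; pseudohaploid individuals (a single
allele sampled at random from the read pileup, the standard representation for
low-coverage ancient DNA) use {0, 2}, interpreted as one sampled allele. Missing
data is the sentinel :data:`MISSING` (−1) internally and the digit 9 on disk.

Coordinates are 1-based inclusive for variants. Genetic positions are stored in
centimorgans; EIGENSTRAT .snp files carry Morgans and are converted on the way
in and out. Region masks are half-open ``[start, end)`` 0-based intervals.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1
_FILE_MISSING = 9

#: strand complement for allele reconciliation at merge
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

VARIANT_COLUMNS = ["id", "chrom", "genetic_pos", "position", "ref", "alt"]
INDIVIDUAL_COLUMNS = ["id", "sex", "population"]


class PanelFormatError(ValueError):
    """Raised when a genotype file triplet is malformed or inconsistent."""


class NoDataError(ValueError):
    """Raised when filtering removes every individual or variant."""


@dataclasses.dataclass(frozen=True)
class PileupSite:
    """Quality-filtered read observations for one individual at one variant.

    ``observations`` is a sequence of ``(base, strand)`` with base in ACGT and
    strand ``"forward"`` or ``"reverse"``. Bases are assumed already filtered
    for base/mapping quality upstream.
    """

    individual: str
    variant_index: int
    observations: tuple[tuple[str, str], ...]


class GenotypePanel:
    """Individuals × variants call matrix with variant and individual metadata.

    Parameters
    ----------
    variants
        DataFrame with columns id, chrom, genetic_pos (cM), position (bp,
        1-based), ref, alt; one row per variant, in matrix column order.
    individuals
        DataFrame with columns id, sex, population and optional columns
        ploidy_mode ({"pseudohaploid", "diploid"}) and era.
    calls
        int array of shape (n_individuals, n_variants) over {0, 1, 2, MISSING}.
    """

    def __init__(self, variants: pd.DataFrame, individuals: pd.DataFrame,
                 calls: np.ndarray):
        variants = variants.reset_index(drop=True).copy()
        individuals = individuals.reset_index(drop=True).copy()
        calls = np.asarray(calls, dtype=np.int8)
        if "ploidy_mode" not in individuals.columns:
            individuals["ploidy_mode"] = "diploid"
        if "era" not in individuals.columns:
            individuals["era"] = None
        if calls.shape != (len(individuals), len(variants)):
            raise PanelFormatError(
                f"calls shape {calls.shape} does not match "
                f"{len(individuals)} individuals x {len(variants)} variants")
        if individuals["id"].duplicated().any():
            dupes = individuals.loc[individuals["id"].duplicated(), "id"].tolist()
            raise PanelFormatError(f"duplicate individual ids: {dupes}")
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelFormatError("calls contain values outside {0,1,2,missing}")
        ph = (individuals["ploidy_mode"] == "pseudohaploid").to_numpy()
        if ph.any() and (calls[ph] == 1).any():
            raise PanelFormatError("pseudohaploid individual has a heterozygous call")
        if (variants["ref"] == variants["alt"]).any():
            raise PanelFormatError("variant with ref == alt")
        self.variants = variants
        self.individuals = individuals
        self.calls = calls

    # ------------------------------------------------------------------ basics

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def individual_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def variant_call_rates(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def subset(self, individual_idx=None, variant_idx=None) -> "GenotypePanel":
        ii = np.arange(self.n_individuals) if individual_idx is None else np.asarray(individual_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypePanel(self.variants.iloc[vi], self.individuals.iloc[ii],
                             self.calls[np.ix_(ii, vi)])

    def individuals_in(self, ids: Iterable[str]) -> np.ndarray:
        """Row indices for the given individual ids (order preserved)."""
        pos = pd.Index(self.individuals["id"])
        idx = pos.get_indexer(list(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"individuals not in panel: {missing}")
        return idx

    def population_members(self, population: str) -> list[str]:
        sel = self.individuals["population"] == population
        return self.individuals.loc[sel, "id"].tolist()

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        exact = [c for c in VARIANT_COLUMNS if c != "genetic_pos"]
        return (np.array_equal(self.calls, other.calls)
                and self.variants[exact].equals(other.variants[exact])
                and np.allclose(self.variants["genetic_pos"],
                                other.variants["genetic_pos"], atol=1e-9)
                and self.individuals[INDIVIDUAL_COLUMNS + ["ploidy_mode"]].equals(
                    other.individuals[INDIVIDUAL_COLUMNS + ["ploidy_mode"]]))

    def __repr__(self) -> str:
        return (f"GenotypePanel({self.n_individuals} individuals, "
                f"{self.n_variants} variants)")


# ---------------------------------------------------------------------- I/O

def _triplet_paths(prefix_or_paths) -> tuple[Path, Path, Path]:
    if isinstance(prefix_or_paths, (tuple, list)):
        g, s, i = map(Path, prefix_or_paths)
    else:
        p = Path(prefix_or_paths)
        g, s, i = p.with_suffix(".geno"), p.with_suffix(".snp"), p.with_suffix(".ind")
    return g, s, i


def read_panel(prefix_or_paths, ploidy: str | Sequence[str] = "auto") -> GenotypePanel:
    """Read an EIGENSTRAT-dialect triplet (.geno/.snp/.ind).

    The .geno file holds one ASCII digit per call, one line per variant
    (columns are individuals); 9 encodes missing. The .snp file has columns
    (id, chrom, genetic position in Morgans, physical position, ref, alt); the
    genetic position is converted to centimorgans. The .ind file has
    (id, sex code, population).

    ``ploidy`` assigns each individual's ploidy_mode: ``"diploid"``,
    ``"pseudohaploid"``, a per-individual sequence, or ``"auto"`` (an
    individual whose row contains no heterozygous call is marked
    pseudohaploid — the usual situation for random-draw-called ancient
    samples).
    """
    geno_path, snp_path, ind_path = _triplet_paths(prefix_or_paths)
    for p in (geno_path, snp_path, ind_path):
        if not p.exists():
            raise FileNotFoundError(p)

    snp = pd.read_csv(snp_path, sep=r"\s+", header=None,
                      names=["id", "chrom", "genetic_pos", "position", "ref", "alt"],
                      dtype={"id": str, "chrom": str, "ref": str, "alt": str})
    snp["genetic_pos"] = snp["genetic_pos"].astype(float) * 100.0  # Morgans -> cM
    snp["position"] = snp["position"].astype(int)
    snp = snp[VARIANT_COLUMNS]

    ind = pd.read_csv(ind_path, sep=r"\s+", header=None,
                      names=["id", "sex", "population"], dtype=str)

    n_ind, n_var = len(ind), len(snp)
    calls = np.full((n_ind, n_var), MISSING, dtype=np.int8)
    n_lines = 0
    with open(geno_path) as fh:
        for j, line in enumerate(fh):
            n_lines = j + 1
            line = line.rstrip("\n")
            if j >= n_var:
                raise PanelFormatError(
                    f"{geno_path}: more genotype lines than .snp rows (line {j + 1})")
            if len(line) != n_ind:
                raise PanelFormatError(
                    f"{geno_path} line {j + 1}: {len(line)} genotypes for {n_ind} individuals")
            row = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
            legal = np.isin(row, (0, 1, 2, _FILE_MISSING))
            if not legal.all():
                col = int(np.nonzero(~legal)[0][0])
                raise PanelFormatError(
                    f"{geno_path} line {j + 1}: illegal genotype code {line[col]!r}")
            out = row.astype(np.int8)
            out[row == _FILE_MISSING] = MISSING
            calls[:, j] = out
    if n_lines != n_var:
        raise PanelFormatError(
            f"{geno_path}: {n_lines} genotype lines for {n_var} .snp rows")

    if isinstance(ploidy, str) and ploidy == "auto":
        has_het = (calls == 1).any(axis=1)
        ind["ploidy_mode"] = np.where(has_het, "diploid", "pseudohaploid")
    elif isinstance(ploidy, str):
        ind["ploidy_mode"] = ploidy
    else:
        ind["ploidy_mode"] = list(ploidy)
    return GenotypePanel(snp, ind, calls)


def write_panel(panel: GenotypePanel, prefix_or_paths) -> None:
    """Write an EIGENSTRAT-dialect triplet (inverse of :func:`read_panel`)."""
    geno_path, snp_path, ind_path = _triplet_paths(prefix_or_paths)
    out = panel.calls.astype(np.int16).copy()
    out[out == MISSING] = _FILE_MISSING
    chars = (out + ord("0")).astype(np.uint8)
    with open(geno_path, "wb") as fh:
        for j in range(panel.n_variants):
            fh.write(chars[:, j].tobytes())
            fh.write(b"\n")
    v = panel.variants
    with open(snp_path, "w") as fh:
        for row in v.itertuples(index=False):
            fh.write(f"{row.id}\t{row.chrom}\t{row.genetic_pos / 100.0:.8f}\t"
                     f"{row.position}\t{row.ref}\t{row.alt}\n")
    with open(ind_path, "w") as fh:
        for row in panel.individuals.itertuples(index=False):
            fh.write(f"{row.id}\t{row.sex}\t{row.population}\n")


def read_pileup(path) -> list[PileupSite]:
    """Read a pileup summary TSV (individual, chrom, position, base, strand).

    Sites are grouped per (individual, chrom, position); the variant index is
    assigned later by matching against a variant table.
    """
    df = pd.read_csv(path, sep="\t",
                     names=["individual", "chrom", "position", "base", "strand"],
                     dtype={"individual": str, "chrom": str, "base": str, "strand": str},
                     header=0 if _has_header(path) else None)
    sites = []
    for (ind, chrom, pos), grp in df.groupby(["individual", "chrom", "position"], sort=False):
        obs = tuple(zip(grp["base"], grp["strand"]))
        sites.append((ind, str(chrom), int(pos), obs))
    return sites


def _has_header(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.lower().startswith("individual")


def locate_pileup_sites(raw_sites, variants: pd.DataFrame) -> list[PileupSite]:
    """Attach variant indices to raw pileup tuples from :func:`read_pileup`.

    Observations at coordinates absent from the variant table are dropped.
    """
    lookup = {(c, p): j for j, (c, p) in
              enumerate(zip(variants["chrom"], variants["position"]))}
    out = []
    for ind, chrom, pos, obs in raw_sites:
        j = lookup.get((chrom, pos))
        if j is not None:
            out.append(PileupSite(ind, j, tuple(obs)))
    return out


# ------------------------------------------------------- pseudohaploid calling

def _site_uniform(seed: int, ind_idx: int, var_idx: int, n: int) -> int:
    """Deterministic draw in [0, n) keyed on (seed, individual, variant).

    Counter-based: independent of the order in which sites are visited.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(ind_idx, var_idx))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % n)


def pseudohaploid_call(sites: Iterable[PileupSite], variants: pd.DataFrame,
                       individual_ids: Sequence[str], mode: str = "standard",
                       seed: int = 0) -> np.ndarray:
    """Random-draw pseudohaploid calling from pileup observations.

    For each covered site one read is drawn uniformly at random among the
    retained observations and the individual is treated as homozygous for its
    allele (call 0 or 2). Observations whose base is neither the ref nor the
    alt allele are dropped before the draw.

    In ``single_strand`` mode — appropriate for non-UDG single-stranded
    libraries — forward-strand reads are ignored at C/T polymorphisms and
    reverse-strand reads at G/A polymorphisms, removing the strand that can
    carry post-mortem deamination artefacts. A site with no retained
    observation is missing, never an error.

    Returns an (n_individuals, n_variants) array over {0, 2, MISSING}.
    """
    if mode not in ("standard", "single_strand"):
        raise ValueError(f"unknown mode {mode!r}")
    ind_index = {i: k for k, i in enumerate(individual_ids)}
    refs = variants["ref"].to_numpy()
    alts = variants["alt"].to_numpy()
    calls = np.full((len(individual_ids), len(variants)), MISSING, dtype=np.int8)
    for site in sites:
        i = ind_index[site.individual]
        j = site.variant_index
        ref, alt = refs[j], alts[j]
        pair = {ref, alt}
        obs = [(b, s) for b, s in site.observations if b in pair]
        if mode == "single_strand":
            if pair == {"C", "T"}:
                obs = [(b, s) for b, s in obs if s != "forward"]
            elif pair == {"G", "A"}:
                obs = [(b, s) for b, s in obs if s != "reverse"]
        if not obs:
            continue
        pick = obs[_site_uniform(seed, i, j, len(obs))][0]
        calls[i, j] = 2 if pick == alt else 0
    return calls


# ---------------------------------------------------------------------- merge

def merge_panels(a: GenotypePanel, b: GenotypePanel,
                 ambiguous: str = "drop") -> tuple[GenotypePanel, dict]:
    """Merge two panels on (chromosome, position), reconciling alleles.

    Variants are intersected. Where ``b``'s ref/alt are swapped relative to
    ``a``, b's calls are recoded 0↔2; where b's alleles are the strand
    complement of a's they are complemented before matching. Strand-ambiguous
    variants (A/T or C/G) cannot be told apart from an allele flip and are
    dropped by default (``ambiguous="drop"``) or kept as-is
    (``ambiguous="keep"``). Irreconcilable allele pairs are dropped and
    counted, never fatal.

    Individual ids colliding between the panels get a ``.dup<n>`` suffix on
    the ``b`` side.

    Returns ``(panel, report)`` where report counts dropped variants.
    """
    if ambiguous not in ("drop", "keep"):
        raise ValueError(f"ambiguous must be 'drop' or 'keep', got {ambiguous!r}")
    key_a = pd.MultiIndex.from_frame(a.variants[["chrom", "position"]])
    key_b = pd.MultiIndex.from_frame(b.variants[["chrom", "position"]])
    pos_b = {k: j for j, k in enumerate(key_b)}

    idx_a, idx_b, flip = [], [], []
    n_ambiguous = n_incompatible = 0
    refs_b = b.variants["ref"].to_numpy()
    alts_b = b.variants["alt"].to_numpy()
    for ja, key in enumerate(key_a):
        jb = pos_b.get(key)
        if jb is None:
            continue
        ra, aa = a.variants["ref"].iat[ja], a.variants["alt"].iat[ja]
        rb, ab = refs_b[jb], alts_b[jb]
        if {ra, aa} in ({"A", "T"}, {"C", "G"}):
            if ambiguous == "drop":
                n_ambiguous += 1
                continue
        if (rb, ab) == (ra, aa):
            f = False
        elif (rb, ab) == (aa, ra):
            f = True
        else:
            crb, cab = _COMPLEMENT.get(rb), _COMPLEMENT.get(ab)
            if (crb, cab) == (ra, aa):
                f = False
            elif (crb, cab) == (aa, ra):
                f = True
            else:
                n_incompatible += 1
                continue
        idx_a.append(ja)
        idx_b.append(jb)
        flip.append(f)

    calls_b = b.calls[:, idx_b].copy()
    flip = np.asarray(flip, dtype=bool)
    if flip.any():
        col = calls_b[:, flip]
        recoded = (2 - col).astype(np.int8)
        recoded[col == MISSING] = MISSING
        calls_b[:, flip] = recoded

    ind_b = b.individuals.copy()
    taken = set(a.individuals["id"])
    new_ids = []
    for iid in ind_b["id"]:
        out, n = iid, 0
        while out in taken:
            n += 1
            out = f"{iid}.dup{n}"
        taken.add(out)
        new_ids.append(out)
    ind_b["id"] = new_ids

    merged = GenotypePanel(
        a.variants.iloc[idx_a],
        pd.concat([a.individuals, ind_b], ignore_index=True),
        np.vstack([a.calls[:, idx_a], calls_b]),
    )
    report = {"n_merged_variants": len(idx_a),
              "n_dropped_ambiguous": n_ambiguous,
              "n_dropped_incompatible": n_incompatible,
              "n_flipped": int(flip.sum())}
    return merged, report


# --------------------------------------------------------------------- filter

def filter_panel(panel: GenotypePanel,
                 min_individual_call_rate: float = 0.0,
                 min_variant_call_rate: float = 0.0,
                 region_mask: Sequence[tuple] | None = None) -> GenotypePanel:
    """Call-rate and region filtering.

    Order is fixed: (1) variants inside masked regions are removed; (2)
    individuals below ``min_individual_call_rate`` — computed on the masked
    variant set — are removed; (3) variants below ``min_variant_call_rate``,
    computed on the remaining individuals, are removed.

    ``region_mask`` is a list of ``(chrom, start, end)`` half-open 0-based
    intervals (1-based variant position p is masked when start <= p-1 < end),
    e.g. for excluding HLA-scale or long-range-LD regions.
    """
    for r in (min_individual_call_rate, min_variant_call_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("call-rate thresholds must be in [0, 1]")
    keep_var = np.ones(panel.n_variants, dtype=bool)
    if region_mask:
        chroms = panel.variants["chrom"].to_numpy()
        pos0 = panel.variants["position"].to_numpy() - 1
        for chrom, start, end in region_mask:
            keep_var &= ~((chroms == str(chrom)) & (pos0 >= start) & (pos0 < end))
    p = panel.subset(variant_idx=np.nonzero(keep_var)[0]) if not keep_var.all() else panel
    if p.n_variants == 0:
        raise NoDataError("no data after filtering: region mask removed all variants")

    keep_ind = p.individual_call_rates() >= min_individual_call_rate
    if not keep_ind.any():
        raise NoDataError("no data after filtering: every individual below call rate")
    p = p.subset(individual_idx=np.nonzero(keep_ind)[0]) if not keep_ind.all() else p

    keep_var2 = p.variant_call_rates() >= min_variant_call_rate
    if not keep_var2.any():
        raise NoDataError("no data after filtering: every variant below call rate")
    if not keep_var2.all():
        p = p.subset(variant_idx=np.nonzero(keep_var2)[0])
    return p


def read_bed_mask(path) -> list[tuple[str, int, int]]:
    """Read a BED file (chrom, start, end; 0-based half-open) as a region mask."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start), int(end)))
    return out
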