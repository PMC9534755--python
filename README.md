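# nsa — North Sea ancestry decomposition for low-coverage ancient DNA

`nsa` is a Python toolkit for the population-genetic workflow used to
quantify migration-driven ancestry change from genome-wide ancient DNA — the
kind of analysis that asks how much of an early-medieval English gene pool
derives from continental northern European (CNE-like) versus local western
British/Irish (WBI-like) sources, and whether that ancestry co-varies with
funerary treatment. It is aimed at population geneticists who want the full
chain — pseudohaploid genotypes, f-statistics, qpWave/qpAdm-style admixture
models, supervised ancestry proportions, PCA projection, sex/kinship QC and
burial-association tests — as one tested, scriptable library with a
synthetic-data generator that provides ground truth for every stage.

## What it computes

- **Genotype panels** (`nsa.panel`): EIGENSTRAT-dialect I/O, random-read
  pseudohaploid calling (with the single-strand damage rule), allele-aware
  panel merging, call-rate and region filtering.
- **f-statistics** (`nsa.fstats`): f2, f3, f4 and Hudson F_ST from
  allele-count-weighted frequencies, f4(A,B;C,D) = mean (p_A−p_B)(p_C−p_D),
  with weighted 5-cM block-jackknife standard errors.
- **Admixture models** (`nsa.admixture`): the rank of the f4 matrix
  X[i,j] = f4(L₁,L_i; R₁,R_j) counts the ancestry streams relating a left
  set to an outgroup set; a k-way target is fitted by covariance-weighted
  least squares of f4(T,base;R_j,base) = Σ_a w_a f4(S_a,base;R_j,base)
  subject to Σw = 1, with jackknife SEs and calibrated rank/fit p-values.
- **Supervised ancestry** (`nsa.ancestry.SupervisedAncestry`): per-individual
  mixing proportions by maximum likelihood over the haploid genotype
  likelihood, with reference individuals pinned to their source labels and
  source frequencies updated jointly (sklearn-style estimator: `fit` on the
  reference, `transform` individuals to proportions); bootstrap SEs;
  population means ± s.e.m.; the >50% / >95% ancestry classification rule.
- **PCA** (`nsa.ancestry.AncestryPCA`): reference-panel components with
  least-squares projection of incomplete ancient individuals.
- **QC** (`nsa.qc`): genetic sex from autosome-normalised X/Y coverage
  (XX ≈ 1/0, XY ≈ 0.5/0.5) and the Y-fraction rule; duplicate/first/second
  degree kinship from normalised pairwise mismatch rates in 1-Mb windows.
- **Associations** (`nsa.association`): the Fisher-exact / Wilcoxon battery
  of grave-good versus ancestry-class tests, overall, by sex and by site.
- **Synthetic data** (`nsa.simulate`): hierarchical Balding–Nichols
  population trees (a North-Sea scenario with CNE/WBI/France-IA-like sources
  and 11 clade-structured outgroups), admixed pseudohaploid panels,
  sex-chromosome read counts, relative pairs and burial tables — all
  deterministic under a seed.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import numpy as np
from nsa import simulate, fit_weights
from nsa.ancestry import SupervisedAncestry, summarize_population

# a North-Sea scenario: two sources, 11 outgroups, a 70/30 admixed target
model = simulate.north_sea_model(50_000)
freqs, variants = simulate.simulate_source_freqs(model, seed=1)
groups = [simulate.unadmixed(s, s, 20) for s in ("CNE", "WBI")]
groups += [simulate.unadmixed(o, o, 10) for o in simulate.OUTGROUPS]
groups.append(simulate.SampleGroup("Target", 20, {"CNE": 0.7, "WBI": 0.3},
                                   missing_rate=0.1))
panel = simulate.simulate_genotypes(
    freqs, variants, simulate.AdmixtureScenario(tuple(groups)), seed=2)

fit = fit_weights(panel, "Target", ["CNE", "WBI"], list(simulate.OUTGROUPS))
print(fit.summary())

est = SupervisedAncestry(n_boot=0).fit(panel, sources=["CNE", "WBI"])
q = [r.proportions[0]
     for r in est.estimate_panel(panel, [f"Target_{i}" for i in range(20)])]
s = summarize_population(q, "Target", "CNE")
print(f"supervised CNE: {s.mean:.3f} ± {s.sem:.3f} (n={s.n})")
```

prints

```
target=Target  fit_p=0.1668 (df=9, hotelling)
  CNE: 0.6991 ± 0.0131
  WBI: 0.3009 ± 0.0131
supervised CNE: 0.681 ± 0.008 (n=20)
```

The two-way weight fit recovers the simulated 70% continental fraction within
one standard error and the fit p-value accepts the two-source model (df = 9:
eleven outgroups minus one base minus one free weight); the supervised
decomposition agrees to within about two points of s.e.m. on this single
panel realisation (the summary is the mean ± s.e.m. over the 20 target
individuals, whose errors share the reference-panel noise).

The same flow runs from the shell: `nsa run --out demo/` executes the bundled
simulate → QC → f-statistics → admixture → ancestry → association demo and
writes TSV reports plus a manifest with seeds and output hashes (rerunning is
bit-identical); `nsa simulate`, `nsa qc`, `nsa fstat`, `nsa admix`,
`nsa ancestry` and `nsa assoc` expose the individual stages.

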