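"""Config-driven orchestration: simulate → QC → f-statistics → admixture
models → ancestry decomposition → association testing.

A run is driven by a YAML/dict config with one global seed; each stage
derives its own seed as a stable hash of (global seed, stage name), so adding
or removing later stages never perturbs earlier ones. Every stage writes TSV
outputs plus an entry in a JSON manifest (parameters hash, seed, output file
hashes); a rerun with the same config is bit-identical. A failing stage
halts the run and the manifest records partial completion.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture, ancestry, association, fstats, qc, simulate
from .panel import read_panel, write_panel

log = logging.getLogger("nsa.pipeline")

STAGES = ("simulate", "qc", "fstats", "admix", "ancestry", "assoc")

DEFAULT_CONFIG = {
    "seed": 7,
    "stages": list(STAGES),
    "simulate": {
        "n_variants": 20_000,
        "n_source": 20,
        "n_outgroup": 10,
        "n_target": 20,
        "gradient": True,          # target individuals span 0..100% CNE
        "missing_rate": 0.05,
        "three_way": False,
    },
    "qc": {"depth": 1.0},
    "fstats": {"block_cm": 5.0},
    "admix": {"block_cm": 5.0},
    "ancestry": {"n_boot": 0, "min_variants": 1000},
    "assoc": {"beta_ancestry": 2.0},
}


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def demo_config() -> dict:
    return json.loads(json.dumps(DEFAULT_CONFIG))


def _validate(config: dict) -> None:
    unknown = [s for s in config.get("stages", []) if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = config.get("stages", [])
    needs_panel = {"qc", "fstats", "admix", "ancestry", "assoc"}
    if needs_panel & set(stages) and "simulate" not in stages \
            and "panel" not in config.get("input", {}):
        raise ValueError("stages need a genotype panel: add the simulate stage "
                         "or an input.panel path")
    if "input" in config:
        for key, path in config["input"].items():
            probe = Path(str(path) + (".geno" if key == "panel" else ""))
            if not probe.exists():
                raise ValueError(f"input.{key}: {probe} does not exist")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config, outdir) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = demo_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    _validate(cfg)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg["seed"], "stages": {}, "complete": False,
                "config_hash": hashlib.sha256(
                    json.dumps(cfg, sort_keys=True).encode()).hexdigest()}
    state: dict = {}
    try:
        for stage in cfg["stages"]:
            t0 = time.monotonic()
            seed = stage_seed(cfg["seed"], stage)
            log.info("stage %s (seed %d)", stage, seed)
            outputs = _STAGE_FNS[stage](cfg, seed, outdir, state)
            manifest["stages"][stage] = {
                "seed": seed,
                "params": cfg.get(stage, {}),
                "outputs": {name: _hash_file(outdir / name) for name in outputs},
                "wall_s": round(time.monotonic() - t0, 3),
            }
            log.info("stage %s done in %.1fs", stage,
                     manifest["stages"][stage]["wall_s"])
        manifest["complete"] = True
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         sort_keys=True))
    return manifest


# ------------------------------------------------------------------- stages

def _stage_simulate(cfg, seed, outdir, state):
    p = cfg["simulate"]
    model = simulate.north_sea_model(p["n_variants"], three_way=p["three_way"])
    freqs, variants = simulate.simulate_source_freqs(model, seed)
    sources = ["CNE", "WBI"] + (["FranceIA"] if p["three_way"] else [])
    groups = [simulate.unadmixed(s, s, p["n_source"]) for s in sources]
    groups += [simulate.unadmixed(o, o, p["n_outgroup"]) for o in simulate.OUTGROUPS]
    truth = {}
    if p["gradient"]:
        n = p["n_target"]
        for i in range(n):
            q = i / max(n - 1, 1)
            w = {"CNE": q, "WBI": 1.0 - q}
            groups.append(simulate.SampleGroup(f"Target{i}", 1, w,
                                               missing_rate=p["missing_rate"]))
            truth[f"Target{i}_0"] = q
    else:
        w = p.get("target_weights", {"CNE": 0.7, "WBI": 0.3})
        groups.append(simulate.SampleGroup("Target", p["n_target"], w,
                                           missing_rate=p["missing_rate"]))
        truth.update({f"Target_{i}": w.get("CNE", 0.0)
                      for i in range(p["n_target"])})
    panel = simulate.simulate_genotypes(
        freqs, variants, simulate.AdmixtureScenario(tuple(groups)), seed + 1)
    write_panel(panel, outdir / "panel")
    rng = np.random.default_rng(seed + 2)
    target_ids = list(truth)
    karyo = rng.choice(["XX", "XY"], size=len(target_ids))
    reads = []
    for ind, k in zip(target_ids, karyo):
        counts = simulate.simulate_read_counts(
            simulate.ReadCountProfile(depth=cfg["qc"]["depth"], karyotype=k),
            int(rng.integers(2 ** 31)))
        reads.append({"id": ind, "true_karyotype": k,
                      **counts.__dict__})
    pd.DataFrame(reads).to_csv(outdir / "read_counts.tsv", sep="\t", index=False)
    pd.DataFrame({"id": target_ids, "true_q_CNE": [truth[i] for i in target_ids]}
                 ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    state.update(panel=panel, target_ids=target_ids, truth=truth,
                 sources=sources)
    return ["panel.geno", "panel.snp", "panel.ind", "read_counts.tsv", "truth.tsv"]


def _load_panel(cfg, state):
    if "panel" not in state:
        state["panel"] = read_panel(cfg["input"]["panel"])
        ids = state["panel"].individuals
        state["target_ids"] = ids.loc[ids["population"].str.startswith("Target"),
                                      "id"].tolist()
        state["sources"] = ["CNE", "WBI"]
    return state["panel"]


def _stage_qc(cfg, seed, outdir, state):
    _load_panel(cfg, state)
    reads = pd.read_csv(outdir / "read_counts.tsv", sep="\t")
    rows = []
    for rec in reads.itertuples(index=False):
        call = qc.determine_sex(rec)
        ratio, ycall = qc.y_fraction_sex(rec)
        rows.append({"id": rec.id, "x_rate": call.x_rate, "y_rate": call.y_rate,
                     "sex": call.call, "y_fraction": ratio, "y_fraction_sex": ycall})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "sex_calls.tsv", sep="\t", index=False)
    state["sex_calls"] = df
    panel = state["panel"]
    idx = panel.individuals_in(state["target_ids"])
    kin = qc.kinship_report(panel.subset(individual_idx=idx), min_overlap=500,
                            baseline=None if len(idx) >= 4 else 0.25)
    kin.to_csv(outdir / "kinship.tsv", sep="\t", index=False)
    return ["sex_calls.tsv", "kinship.tsv"]


def _stage_fstats(cfg, seed, outdir, state):
    panel = _load_panel(cfg, state)
    bcm = cfg["fstats"]["block_cm"]
    rows = []
    for r in (fstats.f2(panel, "CNE", "WBI", block_cm=bcm),
              fstats.fst(panel, "CNE", "WBI", block_cm=bcm),
              fstats.f4(panel, "O_YRI", "CNE", "WBI", "CNE", block_cm=bcm)):
        rows.append({"kind": r.kind, "pops": "|".join(map(str, r.pops)),
                     "estimate": r.estimate, "se": r.se, "z": r.z,
                     "n_blocks": r.n_blocks, "n_variants": r.n_variants})
    # per-individual shared-drift statistic f4(O_YRI, X; WBI, CNE)
    blocks = fstats.make_blocks(panel.variants, bcm)
    for ind in state["target_ids"]:
        r = fstats.f4(panel, "O_YRI", [ind], "WBI", "CNE", blocks=blocks)
        rows.append({"kind": "f4_individual", "pops": ind, "estimate": r.estimate,
                     "se": r.se, "z": r.z, "n_blocks": r.n_blocks,
                     "n_variants": r.n_variants})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "fstats.tsv", sep="\t", index=False)
    state["fstats"] = df
    return ["fstats.tsv"]


def _stage_admix(cfg, seed, outdir, state):
    panel = _load_panel(cfg, state)
    sources = state["sources"]
    pooled = [i for i in state["target_ids"]]
    fit = admixture.fit_weights(panel, pooled, sources, list(simulate.OUTGROUPS),
                                block_cm=cfg["admix"]["block_cm"])
    rows = [{"target": "Target(pooled)", "source": s, "weight": w, "se": e,
             "fit_p": fit.fit_p, "feasible": fit.feasible}
            for s, w, e in zip(fit.sources, fit.weights, fit.weight_se)]
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "admixture_fit.tsv", sep="\t", index=False)
    state["admix_fit"] = fit
    return ["admixture_fit.tsv"]


def _stage_ancestry(cfg, seed, outdir, state):
    panel = _load_panel(cfg, state)
    p = cfg["ancestry"]
    est = ancestry.SupervisedAncestry(n_boot=p["n_boot"],
                                      min_variants=p["min_variants"],
                                      random_state=seed)
    est.fit(panel, sources=state["sources"])
    results = est.estimate_panel(panel, state["target_ids"])
    rows = []
    for r in results:
        d = r.as_dict()
        label, unadmixed_flag = ancestry.classify_ancestry(
            d.get("q_CNE", float("nan")))
        d["class"] = label
        d["unadmixed_CNE"] = unadmixed_flag
        rows.append(d)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "ancestry.tsv", sep="\t", index=False)
    summ = ancestry.summarize_population(df["q_CNE"], "Target", "CNE")
    pd.DataFrame([summ.__dict__]).to_csv(outdir / "ancestry_summary.tsv",
                                         sep="\t", index=False)
    state["ancestry"] = df
    return ["ancestry.tsv", "ancestry_summary.tsv"]


def _stage_assoc(cfg, seed, outdir, state):
    if "ancestry" not in state:
        raise ValueError("assoc stage needs the ancestry stage before it")
    est = state["ancestry"][["id", "q_CNE"]]
    sex = state.get("sex_calls")
    sexes = (sex.set_index("id").loc[est["id"], "sex"].tolist()
             if sex is not None else ["unknown"] * len(est))
    effects = simulate.BurialEffects(
        goods=simulate.LogisticEffect(intercept=-1.0,
                                      beta_ancestry=cfg["assoc"]["beta_ancestry"]),
        configuration=simulate.LogisticEffect(beta_ancestry=1.0),
    )
    truth = state.get("truth", {})
    q_true = np.array([truth.get(i, q) for i, q in zip(est["id"], est["q_CNE"])])
    burials = simulate.simulate_burials(q_true, sexes, effects, seed,
                                        ids=est["id"].tolist())
    burials.to_csv(outdir / "burials.tsv", sep="\t", index=False)
    battery = association.run_battery(burials, est)
    battery.to_csv(outdir / "association.tsv", sep="\t", index=False)
    return ["burials.tsv", "association.tsv"]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "fstats": _stage_fstats,
    "admix": _stage_admix,
    "ancestry": _stage_ancestry,
    "assoc": _stage_assoc,
}
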