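"""End-to-end orchestration: simulate -> preprocess -> train-vae -> train-surv
-> evaluate -> interpret, driven by one YAML config and a master seed.

Each stage reads from and writes to a fixed run-directory layout, so stages
can be run individually from the CLI or chained by ``run_pipeline``.  A run
manifest records the config hash, derived per-stage seeds, input file hashes,
feature orderings, and per-stage key metrics; re-running an identical config
and seed reproduces identical numeric outputs.

Supported cases: ``entangle`` (joint two-omics VAE), ``gene_only``,
``mirna_only``, ``concatenate`` (two single-omics VAEs, latent means
concatenated), and ``clinical_only`` (no VAE; the survival network sees the
encoded clinical covariates alone).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import (
    explain_latent,
    explain_pi,
    identify_key_factors,
    percent_contributions,
)
from .data import (
    ClinicalEncoder,
    MinMaxNormalizer,
    SplitPlan,
    VarianceFilter,
    make_splits,
    minmax_normalize,
    read_clinical_csv,
    read_expression_tsv,
)
from .metrics import assign_risk, c_index, km_curve, logrank_test
from .pathways import PathwayMask, build_mask, read_gmt
from .simulate import SyntheticSpec, generate
from .survnet import LFSurv, SurvConfig
from .train import AnnealingSchedule
from .vae import KLPMVAE, VAEConfig

__all__ = ["DEFAULT_CONFIG", "load_config", "derive_seeds", "run_pipeline",
           "CASES", "STAGES"]

CASES = ("entangle", "gene_only", "mirna_only", "concatenate", "clinical_only")

DEFAULT_CONFIG: dict = {
    "case": "entangle",
    "seed": 0,
    "data": {"source": "synthetic", "synthetic": {}},
    "preprocess": {
        "variance_threshold": 0.02,
        "min_pathway_size": 15,
        "max_pathway_size": 300,
        "normalization": "per-split",  # literal protocol; or "tuning-stats"
        "stratify": True,
    },
    "clinical": {"numeric": ["age"], "categorical": ["stage", "race"],
                 "standardize": True},
    "vae": {
        "n_latent": 16,
        "trunk_hidden": 64,
        "mirna_hidden": None,
        "lambda1": 1e-4,
        "learning_rate": 2e-3,
        "epochs": 120,
        "batch_size": 128,
        "annealing": {"n_cycles": 3, "cutting_ratio": 0.5},
    },
    "surv": {
        "hidden_width": 16,
        "dropout_rate": 0.2,
        "lambda2": 1e-3,
        "learning_rate": 0.01,
        "epochs": 400,
    },
    "interpret": {
        "n_top_latent": 6,
        "top_k": 10,
        "min_frequency": 2,
        "max_samples": 100,
    },
}

STAGES = ("simulate", "preprocess", "train_vae", "train_surv", "evaluate", "interpret")


# ---------------------------------------------------------------------------
# config / manifest helpers

def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source: str | Path | dict | None = None) -> dict:
    """Merge a YAML file or dict over the defaults and validate."""
    override = {}
    if isinstance(source, (str, Path)):
        override = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        override = source
    cfg = _deep_merge(DEFAULT_CONFIG, override)
    if cfg["case"] not in CASES:
        raise ValueError(f"case must be one of {CASES}, got {cfg['case']!r}")
    if cfg["data"]["source"] not in ("synthetic", "files"):
        raise ValueError("data.source must be 'synthetic' or 'files'")
    if cfg["data"]["source"] == "files":
        needed = ["clinical"]
        if cfg["case"] != "clinical_only":
            if cfg["case"] != "mirna_only":
                needed += ["gene", "gmt"]
            if cfg["case"] != "gene_only":
                needed += ["mirna"]
        missing = [k for k in needed if k not in cfg["data"]]
        if missing:
            raise ValueError(f"data.source=files but missing paths: {missing}")
        absent = [k for k in needed if not Path(cfg["data"][k]).exists()]
        if absent:
            raise FileNotFoundError(
                f"missing input files: {[cfg['data'][k] for k in absent]}"
            )
    if cfg["preprocess"]["normalization"] not in ("per-split", "tuning-stats"):
        raise ValueError("preprocess.normalization must be per-split or tuning-stats")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def derive_seeds(master: int) -> dict[str, int]:
    """Fan one master seed out to named per-stage seeds (all < 2^31)."""
    ss = np.random.SeedSequence(master)
    names = ("simulate", "splits", "vae", "surv", "shap")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        for name, child in zip(names, children)
    }


def _update_manifest(run_dir: Path, stage: str, entry: dict) -> dict:
    path = run_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "version": __version__, "stages": {},
    }
    manifest["stages"][stage] = entry
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: dict, run_dir: Path) -> dict:
    run_dir = Path(run_dir)
    seeds = derive_seeds(cfg["seed"])
    data_dir = run_dir / "data"
    if cfg["data"]["source"] == "synthetic":
        opts = dict(cfg["data"].get("synthetic") or {})
        opts.setdefault("seed", seeds["simulate"])
        if "genes_per_pathway_range" in opts:
            opts["genes_per_pathway_range"] = tuple(opts["genes_per_pathway_range"])
        spec = SyntheticSpec(**opts)
        generate(spec).to_directory(data_dir)
    else:
        data_dir.mkdir(parents=True, exist_ok=True)
        import shutil

        names = {"gene": "gene_expression.tsv", "mirna": "mirna_expression.tsv",
                 "clinical": "clinical.csv", "gmt": "pathways.gmt"}
        for key, name in names.items():
            if key in cfg["data"]:
                shutil.copy(cfg["data"][key], data_dir / name)
    hashes = {p.name: _file_hash(p) for p in sorted(data_dir.iterdir())
              if p.suffix in (".tsv", ".csv", ".gmt")}
    entry = {"seed": seeds["simulate"], "file_hashes": hashes}
    _update_manifest(run_dir, "simulate", entry)
    return entry


def _load_data(run_dir: Path, cfg: dict):
    data_dir = Path(run_dir) / "data"
    gene = mirna = gmt = None
    case = cfg["case"]
    clinical = read_clinical_csv(data_dir / "clinical.csv")
    ids = list(clinical.index)
    if case in ("entangle", "gene_only", "concatenate"):
        gene = read_expression_tsv(data_dir / "gene_expression.tsv", sample_ids=ids)
        gmt = read_gmt(data_dir / "pathways.gmt")
    if case in ("entangle", "mirna_only", "concatenate"):
        mirna = read_expression_tsv(data_dir / "mirna_expression.tsv", sample_ids=ids)
    return gene, mirna, clinical, gmt


def _normalize_and_filter(df: pd.DataFrame, split: SplitPlan, mode: str,
                          threshold: float):
    """Per-split min-max plus tuning-set variance filter; frozen feature list."""
    tuning = df.loc[split.tuning_ids]
    test = df.loc[split.test_ids]
    if mode == "per-split":
        norm_tuning = minmax_normalize(tuning)
        norm_test = minmax_normalize(test)
    else:  # leakage-safe deployment mode: tuning statistics + clipping
        normalizer = MinMaxNormalizer().fit(tuning)
        norm_tuning = normalizer.transform(tuning, clip=False)
        norm_test = normalizer.transform(test, clip=True)
    vfilter = VarianceFilter(threshold).fit(norm_tuning)
    return vfilter.transform(norm_tuning), vfilter.transform(norm_test)


def stage_preprocess(cfg: dict, run_dir: Path) -> dict:
    run_dir = Path(run_dir)
    seeds = derive_seeds(cfg["seed"])
    pre = cfg["preprocess"]
    out = run_dir / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    gene, mirna, clinical, gmt = _load_data(run_dir, cfg)

    split = make_splits(
        clinical.index, clinical["event"].to_numpy(), seed=seeds["splits"],
        stratify=pre["stratify"],
    )
    split.to_json(out / "splits.json")

    features: dict[str, list[str]] = {}
    if gene is not None:
        g_tuning, g_test = _normalize_and_filter(
            gene, split, pre["normalization"], pre["variance_threshold"]
        )
        mask = build_mask(gmt, g_tuning.columns, pre["min_pathway_size"],
                          pre["max_pathway_size"])
        g_tuning = g_tuning[mask.gene_ids]
        g_test = g_test[mask.gene_ids]
        g_tuning.to_csv(out / "gene_tuning.tsv", sep="\t")
        g_test.to_csv(out / "gene_test.tsv", sep="\t")
        mask.to_triplets().to_csv(out / "mask.csv", index=False)
        features["genes"] = mask.gene_ids
        features["pathways"] = mask.pathway_ids
    if mirna is not None:
        m_tuning, m_test = _normalize_and_filter(
            mirna, split, pre["normalization"], pre["variance_threshold"]
        )
        m_tuning.to_csv(out / "mirna_tuning.tsv", sep="\t")
        m_test.to_csv(out / "mirna_test.tsv", sep="\t")
        features["mirnas"] = list(m_tuning.columns)
    (out / "features.json").write_text(json.dumps(features, indent=1))

    entry = {
        "seed": seeds["splits"],
        "n_test": len(split.test_ids),
        "n_tuning": len(split.tuning_ids),
        "n_divisions": len(split.divisions),
        "normalization": pre["normalization"],
        "n_features": {k: len(v) for k, v in features.items()},
    }
    _update_manifest(run_dir, "preprocess", entry)
    return entry


def _load_mask(run_dir: Path) -> PathwayMask:
    feats = json.loads((Path(run_dir) / "preprocess" / "features.json").read_text())
    trip = pd.read_csv(Path(run_dir) / "preprocess" / "mask.csv")
    gene_ids, pathway_ids = feats["genes"], feats["pathways"]
    gi = {g: i for i, g in enumerate(gene_ids)}
    pj = {p: j for j, p in enumerate(pathway_ids)}
    mask = np.zeros((len(gene_ids), len(pathway_ids)))
    mask[[gi[g] for g in trip["gene"]], [pj[p] for p in trip["pathway"]]] = 1.0
    return PathwayMask(gene_ids=gene_ids, pathway_ids=pathway_ids, mask=mask)


def _read_split_tsv(run_dir: Path, block: str, part: str) -> pd.DataFrame:
    return read_expression_tsv(Path(run_dir) / "preprocess" / f"{block}_{part}.tsv",
                               orientation="samples")


def _vae_config(cfg: dict, mode: str, mask, n_mirnas) -> VAEConfig:
    v = cfg["vae"]
    return VAEConfig(
        n_latent=v["n_latent"],
        integration_mode=mode,
        lambda1=v["lambda1"],
        mirna_hidden=v.get("mirna_hidden"),
        trunk_hidden=v["trunk_hidden"],
        learning_rate=v["learning_rate"],
        epochs=v["epochs"],
        batch_size=v["batch_size"],
    )


def _train_one_vae(cfg, mode, mask, tuning_inputs, seed):
    n_mirnas = tuning_inputs[1].shape[1] if tuning_inputs[1] is not None else None
    vcfg = _vae_config(cfg, mode, mask, n_mirnas)
    model = KLPMVAE(mask if mode != "mirna_only" else None, n_mirnas, vcfg, seed=seed)
    ann = cfg["vae"]["annealing"]
    schedule = None
    if ann:
        schedule = AnnealingSchedule(
            n_cycles=ann["n_cycles"], cutting_ratio=ann["cutting_ratio"],
            total_steps=vcfg.epochs,
        )
    history = model.fit(tuning_inputs[0], tuning_inputs[1],
                        beta_schedule=schedule, seed=seed)
    return model, history


def stage_train_vae(cfg: dict, run_dir: Path) -> dict:
    run_dir = Path(run_dir)
    case = cfg["case"]
    if case == "clinical_only":
        entry = {"skipped": "clinical_only case has no VAE stage"}
        _update_manifest(run_dir, "train_vae", entry)
        return entry
    seeds = derive_seeds(cfg["seed"])
    out = run_dir / "vae"
    out.mkdir(parents=True, exist_ok=True)

    parts = {}
    mask = None
    gene = {"tuning": None, "test": None}
    mirna = {"tuning": None, "test": None}
    if case in ("entangle", "gene_only", "concatenate"):
        mask = _load_mask(run_dir)
        for part in ("tuning", "test"):
            gene[part] = _read_split_tsv(run_dir, "gene", part)[mask.gene_ids]
    if case in ("entangle", "mirna_only", "concatenate"):
        for part in ("tuning", "test"):
            mirna[part] = _read_split_tsv(run_dir, "mirna", part)

    def _extract(model, part, prefix="mu"):
        xg = gene[part] if model.mode != "mirna_only" else None
        xm = mirna[part] if model.mode != "gene_only" else None
        mu = model.extract_latent(xg, xm)
        idx = (xg if xg is not None else xm).index
        cols = [f"{prefix}_{i + 1}" for i in range(mu.shape[1])]
        return pd.DataFrame(mu, index=idx, columns=cols)

    entry = {"seed": seeds["vae"], "case": case}
    if case == "concatenate":
        model_g, hist_g = _train_one_vae(
            cfg, "gene_only", mask, (gene["tuning"], None), seeds["vae"])
        model_m, hist_m = _train_one_vae(
            cfg, "mirna_only", None, (None, mirna["tuning"]), seeds["vae"] + 1)
        model_g.save(out / "vae_gene.npz")
        model_m.save(out / "vae_mirna.npz")
        hist_g.assign(model="gene").to_csv(out / "history.csv", index=False)
        mu = {
            part: pd.concat(
                [_extract(model_g, part, "mu_gene"), _extract(model_m, part, "mu_mirna")],
                axis=1,
            )
            for part in ("tuning", "test")
        }
        entry["final_loss"] = {"gene": float(hist_g["loss"].iloc[-1]),
                               "mirna": float(hist_m["loss"].iloc[-1])}
    else:
        mode = case
        model, hist = _train_one_vae(
            cfg, mode, mask,
            (gene["tuning"] if mode != "mirna_only" else None,
             mirna["tuning"] if mode != "gene_only" else None),
            seeds["vae"],
        )
        model.save(out / "vae.npz")
        hist.to_csv(out / "history.csv", index=False)
        mu = {part: _extract(model, part) for part in ("tuning", "test")}
        entry["final_loss"] = float(hist["loss"].iloc[-1])
        entry["final_recon"] = float(
            hist["recon_gene"].iloc[-1] + hist["recon_mirna"].iloc[-1])
    for part in ("tuning", "test"):
        mu[part].to_csv(out / f"mu_{part}.csv", index_label="sample_id")
    entry["n_latent_columns"] = mu["tuning"].shape[1]
    _update_manifest(run_dir, "train_vae", entry)
    return entry


def _load_mu(run_dir: Path, part: str) -> pd.DataFrame | None:
    path = Path(run_dir) / "vae" / f"mu_{part}.csv"
    if not path.exists():
        return None
    return pd.read_csv(path, index_col="sample_id")


def _surv_features(cfg: dict, run_dir: Path, clinical: pd.DataFrame,
                   split: SplitPlan):
    """[mu || encoded clinical] per part; encoder fitted on the tuning set."""
    enc = ClinicalEncoder(
        numeric=cfg["clinical"]["numeric"],
        categorical=cfg["clinical"]["categorical"],
        standardize=cfg["clinical"]["standardize"],
    ).fit(clinical.loc[split.tuning_ids])
    feats = {}
    for part, ids in (("tuning", split.tuning_ids), ("test", split.test_ids)):
        cov = enc.transform(clinical.loc[ids])
        mu = _load_mu(run_dir, part)
        if cfg["case"] == "clinical_only":
            feats[part] = cov
        else:
            feats[part] = pd.concat([mu.loc[ids], cov], axis=1)
    return feats, enc


def stage_train_surv(cfg: dict, run_dir: Path) -> dict:
    run_dir = Path(run_dir)
    seeds = derive_seeds(cfg["seed"])
    out = run_dir / "surv"
    out.mkdir(parents=True, exist_ok=True)
    clinical = read_clinical_csv(run_dir / "data" / "clinical.csv")
    split = SplitPlan.from_json(run_dir / "preprocess" / "splits.json")
    feats, _ = _surv_features(cfg, run_dir, clinical, split)

    s = cfg["surv"]
    scfg = SurvConfig(hidden_width=s["hidden_width"], dropout_rate=s["dropout_rate"],
                      lambda2=s["lambda2"], learning_rate=s["learning_rate"],
                      epochs=s["epochs"])
    model = LFSurv(feats["tuning"].shape[1], scfg, seed=seeds["surv"])
    tune_cl = clinical.loc[split.tuning_ids]
    history = model.fit(feats["tuning"], tune_cl["time"], tune_cl["event"],
                        seed=seeds["surv"])
    model.save(out / "surv.npz")
    history.to_csv(out / "history.csv", index=False)

    pis = {}
    for part in ("tuning", "test"):
        pi = pd.Series(model.forward(feats[part]), index=feats[part].index, name="PI")
        pi.to_csv(out / f"pi_{part}.csv", index_label="sample_id")
        feats[part].to_csv(out / f"features_{part}.csv", index_label="sample_id")
        pis[part] = pi
    entry = {
        "seed": seeds["surv"],
        "n_features": feats["tuning"].shape[1],
        "feature_names": list(feats["tuning"].columns),
        "final_loss": float(history["loss"].iloc[-1]),
        "pi_med_tuning": float(np.median(pis["tuning"])),
    }
    _update_manifest(run_dir, "train_surv", entry)
    return entry


def stage_evaluate(cfg: dict, run_dir: Path, make_plot: bool = True) -> dict:
    run_dir = Path(run_dir)
    out = run_dir / "eval"
    out.mkdir(parents=True, exist_ok=True)
    clinical = read_clinical_csv(run_dir / "data" / "clinical.csv")
    pi_tuning = pd.read_csv(run_dir / "surv" / "pi_tuning.csv", index_col="sample_id")["PI"]
    pi_test = pd.read_csv(run_dir / "surv" / "pi_test.csv", index_col="sample_id")["PI"]
    cl_test = clinical.loc[pi_test.index]

    pi_med = float(np.median(pi_tuning))
    risk = assign_risk(pi_test, pi_med)
    cidx = c_index(pi_test.to_numpy(), cl_test["time"].to_numpy(),
                   cl_test["event"].to_numpy())
    stat, pval = logrank_test(risk.group.to_numpy(), cl_test["time"].to_numpy(),
                              cl_test["event"].to_numpy())
    metrics = {
        "c_index_test": cidx,
        "pi_med_tuning": pi_med,
        "n_high": int((risk.group == "high").sum()),
        "n_low": int((risk.group == "low").sum()),
        "logrank_statistic": stat,
        "logrank_p": pval,
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    risk.group.rename("risk_group").to_csv(out / "risk_groups.csv",
                                           index_label="sample_id")
    if make_plot:
        _km_plot(cl_test, risk.group, out / "km.png")
    _update_manifest(run_dir, "evaluate", metrics)
    return metrics


def _km_plot(cl_test: pd.DataFrame, groups: pd.Series, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, color in (("high", "tab:red"), ("low", "tab:blue")):
        ids = groups.index[groups == label]
        if len(ids) == 0:
            continue
        km = km_curve(cl_test.loc[ids, "time"], cl_test.loc[ids, "event"])
        ax.step(km.index, km["survival"], where="post",
                label=f"{label}-risk (n={len(ids)})", color=color)
        ax.fill_between(km.index, km["lower"], km["upper"], step="post",
                        alpha=0.2, color=color)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("proportion surviving")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def stage_interpret(cfg: dict, run_dir: Path) -> dict:
    run_dir = Path(run_dir)
    seeds = derive_seeds(cfg["seed"])
    icfg = cfg["interpret"]
    out = run_dir / "interpret"
    out.mkdir(parents=True, exist_ok=True)
    case = cfg["case"]

    surv = LFSurv.load(run_dir / "surv" / "surv.npz")
    feats = pd.read_csv(run_dir / "surv" / "features_tuning.csv",
                        index_col="sample_id")
    pi = pd.read_csv(run_dir / "surv" / "pi_tuning.csv", index_col="sample_id")["PI"]
    pi_med = float(np.median(pi))
    high_ids = pi.index[pi > pi_med]
    low_ids = pi.index[pi <= pi_med]

    # (a) contributions of LFSurv inputs to PI, low-risk group as reference
    attr_pi = explain_pi(surv, feats.loc[high_ids], feats.loc[low_ids],
                         seed=seeds["shap"], max_samples=icfg["max_samples"])
    overall = attr_pi.overall
    table = pd.DataFrame({
        "overall_contribution": overall,
        "percent_contribution": percent_contributions(overall),
    }).sort_values("overall_contribution", ascending=False)
    table.to_csv(out / "pi_contributions.csv", index_label="feature")

    entry: dict = {
        "seed": seeds["shap"],
        "n_high": int(len(high_ids)),
        "n_low": int(len(low_ids)),
        "summation_to_delta_error": attr_pi.summation_to_delta_error(),
        "top_features": table.index[:10].tolist(),
    }

    if case == "clinical_only":
        _update_manifest(run_dir, "interpret", entry)
        return entry

    # (b) contributions of genes/miRNAs and pathway nodes to the top latent
    # features, through the trained VAE encoder
    latent_cols = [c for c in feats.columns if c.startswith("mu")]
    top_latent = [c for c in table.index if c in latent_cols][: icfg["n_top_latent"]]
    entry["top_latent"] = top_latent

    models: dict[str, KLPMVAE] = {}
    if case == "concatenate":
        models["mu_gene"] = KLPMVAE.load(run_dir / "vae" / "vae_gene.npz")
        models["mu_mirna"] = KLPMVAE.load(run_dir / "vae" / "vae_mirna.npz")
    else:
        models["mu"] = KLPMVAE.load(run_dir / "vae" / "vae.npz")

    def _inputs(model, ids):
        xg = xm = None
        if model.mode != "mirna_only":
            xg = _read_split_tsv(run_dir, "gene", "tuning").loc[ids, model.mask.gene_ids]
        if model.mode != "gene_only":
            xm = _read_split_tsv(run_dir, "mirna", "tuning").loc[ids]
        return xg, xm

    per_latent_inputs: dict = {}
    per_latent_pathways: dict = {}
    for col in top_latent:
        prefix, idx = col.rsplit("_", 1)
        model = models[prefix]
        latent_index = int(idx) - 1
        xg_h, xm_h = _inputs(model, high_ids)
        xg_l, xm_l = _inputs(model, low_ids)
        kwargs = dict(seed=seeds["shap"], max_samples=icfg["max_samples"])
        per_latent_inputs[col] = explain_latent(
            model, latent_index, xg_h, xm_h, xg_l, xm_l, level="inputs", **kwargs)
        if model.mode != "mirna_only":
            per_latent_pathways[col] = explain_latent(
                model, latent_index, xg_h, xm_h, xg_l, xm_l, level="pathways", **kwargs)

    kif = identify_key_factors(per_latent_inputs, top_k=icfg["top_k"],
                               min_frequency=icfg["min_frequency"])
    kif.table.to_csv(out / "kif.csv", index=False)
    entry["kif"] = kif.key_factors()
    pd.DataFrame({c: a.overall for c, a in per_latent_inputs.items()}).to_csv(
        out / "latent_input_contributions.csv", index_label="factor")
    if per_latent_pathways:
        kpf = identify_key_factors(per_latent_pathways, top_k=icfg["top_k"],
                                   min_frequency=icfg["min_frequency"])
        kpf.table.to_csv(out / "kpf.csv", index=False)
        entry["kpf"] = kpf.key_factors()
        pd.DataFrame({c: a.overall for c, a in per_latent_pathways.items()}).to_csv(
            out / "latent_pathway_contributions.csv", index_label="factor")
    _update_manifest(run_dir, "interpret", entry)
    return entry


# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str | Path | None, run_dir: str | Path,
                 make_plot: bool = True) -> dict:
    """Execute all stages for the configured case; returns the run manifest."""
    cfg = load_config(config)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    _update_manifest(run_dir, "config", {
        "hash": _config_hash(cfg), "case": cfg["case"], "seed": cfg["seed"],
        "seeds": derive_seeds(cfg["seed"]),
    })
    stage_simulate(cfg, run_dir)
    stage_preprocess(cfg, run_dir)
    stage_train_vae(cfg, run_dir)
    stage_train_surv(cfg, run_dir)
    stage_evaluate(cfg, run_dir, make_plot=make_plot)
    stage_interpret(cfg, run_dir)
    return json.loads((run_dir / "manifest.json").read_text())
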