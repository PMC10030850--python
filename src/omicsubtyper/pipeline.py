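"""End-to-end orchestration: preprocess -> stack -> autoencoder -> consensus
clustering -> characterization -> classifier fusion, driven by one YAML
config with a master seed from which per-stage seeds are derived."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autoencoder import AEArchitecture, AETrainConfig, encode, pca_reduce, train_autoencoder
from .characterize import anova_tukey_de, fisher_enrichment, km_estimate, logrank_test
from .consensus import build_pac_profile, final_labels, select_k
from .fusion import BaseLearnerSpec, evaluate_accuracy, split_train_test, train_fused
from .preprocess import PreprocessConfig, preprocess_omic, stack_omics
from .simulate import SimConfig, simulate_clinical, simulate_multiomics
from .types import ClusterAssignment, OmicKind, read_omic_tsv, write_omic_tsv

log = logging.getLogger("omicsubtyper")

STAGES = ("simulate", "preprocess", "integrate", "cluster", "characterize", "classify")


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: low 32 bits of blake2b('<stage>:<master>')."""
    digest = hashlib.blake2b(f"{stage}:{master_seed}".encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "little")


DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "run_out",
    "inputs": {},  # omics: {F1: path, ...}; clinical/mutations/cnv paths
    "simulate": None,  # SimConfig overrides, or None to require inputs
    "preprocess": {},
    "autoencoder": {"encoder_widths": [64, 32], "latent_width": 16,
                    "max_epochs": 100, "patience": 5, "batch_size": 24},
    "integration_method": "ae",  # or "pca"
    "pca_components": 16,
    "consensus": {"k_min": 2, "k_max": 8, "n_resamples": 100, "fraction": 0.8,
                  "u1": 0.1, "u2": 0.9},
    "characterize": {"q_threshold": 0.05},
    "classify": {"enabled": True, "mode": "linear", "holdout": False,
                 "test_fraction": 0.1, "cv_repeats": 2, "rf_trees": [100],
                 "ffnn_epochs": 60, "single_omic": ["F3_methylation"]},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        try:
            user = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"unparseable config {path}: {exc}") from exc
    return _merge(DEFAULT_CONFIG, user)


def validate_config(cfg: dict) -> list[str]:
    """Collect every problem without executing anything; empty list = valid."""
    problems = []
    cons = cfg.get("consensus", {})
    u1, u2 = cons.get("u1", 0.1), cons.get("u2", 0.9)
    if not (0 <= u1 < u2 <= 1):
        problems.append(f"consensus thresholds invalid: need 0 <= u1 < u2 <= 1, got u1={u1}, u2={u2}")
    frac = cons.get("fraction", 0.8)
    if not 0 < frac <= 1:
        problems.append(f"consensus.fraction out of range (0, 1]: {frac}")
    if cons.get("k_min", 2) < 2:
        problems.append("consensus.k_min must be >= 2")
    if cons.get("k_max", 8) < cons.get("k_min", 2):
        problems.append("consensus.k_max must be >= k_min")
    for key, path in (cfg.get("inputs") or {}).get("omics", {}).items():
        if not Path(path).exists():
            problems.append(f"missing omic input {key}: {path}")
    for key in ("clinical", "mutations", "cnv"):
        path = (cfg.get("inputs") or {}).get(key)
        if path and not Path(path).exists():
            problems.append(f"missing {key} input: {path}")
    if cfg.get("simulate") is None and not (cfg.get("inputs") or {}).get("omics"):
        problems.append("either 'simulate' or 'inputs.omics' must be provided")
    tf = cfg.get("classify", {}).get("test_fraction", 0.1)
    if not 0 < tf < 1:
        problems.append(f"classify.test_fraction out of range (0, 1): {tf}")
    return problems


def _load_or_simulate(cfg: dict, out: Path):
    sim_cfg = cfg.get("simulate")
    clinical = mutations = segmeans = None
    if sim_cfg is not None:
        fields = {k: v for k, v in (sim_cfg or {}).items()}
        fields.setdefault("seed", stage_seed(cfg["seed"], "simulate"))
        sc = SimConfig(**fields)
        omics, truth = simulate_multiomics(sc)
        surv, mutations, segmeans = simulate_clinical(truth, sc)
        clinical = surv
        pd.Series(truth, index=omics[OmicKind.F1_MRNA].sample_ids, name="true_cluster").to_csv(
            out / "truth.tsv", sep="\t", index_label="sample_id"
        )
        return omics, clinical, mutations, segmeans
    inputs = cfg["inputs"]
    omics = {
        OmicKind.from_string(k): read_omic_tsv(p, OmicKind.from_string(k))
        for k, p in inputs["omics"].items()
    }
    if inputs.get("clinical"):
        clin = pd.read_csv(inputs["clinical"], sep="\t", index_col=0)
        clinical = clin
    if inputs.get("mutations"):
        mutations = pd.read_csv(inputs["mutations"], sep="\t", index_col=0)
    if inputs.get("cnv"):
        segmeans = pd.read_csv(inputs["cnv"], sep="\t", index_col=0)
    return omics, clinical, mutations, segmeans


def run_pipeline(config: dict, force: bool = False) -> Path:
    """Execute every stage; returns the artifact directory.

    Refuses to reuse a non-empty output directory unless ``force``.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config["out_dir"])
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {"version": __version__, "seed": seed, "stages": {}, "config": config}

    log.info("stage: load/simulate")
    omics, clinical, mutations, segmeans = _load_or_simulate(config, out)

    log.info("stage: preprocess")
    pp_fields = {k: v for k, v in config.get("preprocess", {}).items()}
    pp_cfg = PreprocessConfig(**pp_fields)
    processed, minmax = {}, {}
    for kind, m in omics.items():
        pm, st = preprocess_omic(m, pp_cfg, return_stats=True)
        processed[kind], minmax[kind] = pm, st
        write_omic_tsv(pm, out / f"processed_{kind.value}.tsv")
    stack = stack_omics(list(processed.values()))
    manifest["stages"]["preprocess"] = {
        "widths": {k.value: v.n_features for k, v in processed.items()},
        "n_samples": stack.n_samples,
    }

    log.info("stage: integrate")
    ae_cfg = config["autoencoder"]
    if config.get("integration_method", "ae") == "pca":
        latent = pca_reduce(stack, config.get("pca_components", 16))
        manifest["stages"]["integrate"] = {"method": "pca"}
    else:
        arch = AEArchitecture(
            encoder_widths=list(ae_cfg.get("encoder_widths", [64, 32])),
            latent_width=int(ae_cfg.get("latent_width", 16)),
        )
        train_cfg = AETrainConfig(
            max_epochs=int(ae_cfg.get("max_epochs", 100)),
            patience=int(ae_cfg.get("patience", 5)),
            batch_size=int(ae_cfg.get("batch_size", 24)),
            seed=stage_seed(seed, "integrate"),
        )
        enc = train_autoencoder(stack, arch, train_cfg)
        latent = encode(enc, stack)
        manifest["stages"]["integrate"] = {
            "method": "ae",
            "epochs_run": len(enc.loss_history),
            "final_train_loss": enc.final_train_loss,
            "final_val_loss": enc.final_val_loss,
        }
    pd.DataFrame(latent.values, index=latent.sample_ids).to_csv(
        out / "latent.tsv", sep="\t", index_label="sample_id"
    )

    log.info("stage: cluster")
    cons = config["consensus"]
    profile = build_pac_profile(
        latent,
        k_range=range(int(cons["k_min"]), int(cons["k_max"]) + 1),
        n_resamples=int(cons["n_resamples"]),
        subsample_fraction=float(cons["fraction"]),
        u1=float(cons["u1"]),
        u2=float(cons["u2"]),
        seed=stage_seed(seed, "cluster"),
    )
    best_k = select_k(profile)
    labels = final_labels(profile.records[best_k].consensus, best_k,
                          seed=stage_seed(seed, "cluster-labels"))
    labels.to_series().to_csv(out / "labels.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(
        [(k, r.pac) for k, r in sorted(profile.records.items())], columns=["K", "PAC"]
    ).to_csv(out / "pac_profile.tsv", sep="\t", index=False)
    manifest["stages"]["cluster"] = {
        "selected_k": best_k,
        "pac": {k: r.pac for k, r in profile.records.items()},
    }

    if clinical is not None:
        log.info("stage: characterize")
        chz = {}
        if isinstance(clinical, dict):  # simulated SurvivalTables
            for endpoint, surv in clinical.items():
                idx = [surv.sample_ids.index(s) for s in labels.sample_ids]
                surv = type(surv)(
                    sample_ids=list(labels.sample_ids),
                    time=surv.time[idx], event=surv.event[idx],
                    cluster=labels.labels, endpoint=endpoint,
                )
                stat, df, p = logrank_test(surv)
                chz[endpoint] = {"logrank_chi2": stat, "df": df, "p": p}
                rows = []
                for k in range(1, labels.K + 1):
                    km = km_estimate(surv, k)
                    for t, s, r in zip(km.times, km.survival, km.at_risk):
                        rows.append((k, t, s, r))
                pd.DataFrame(rows, columns=["cluster", "time", "survival", "at_risk"]).to_csv(
                    out / f"km_{endpoint}.tsv", sep="\t", index=False
                )
        if mutations is not None:
            enr = fisher_enrichment(mutations, labels,
                                    q_threshold=config["characterize"]["q_threshold"])
            pd.DataFrame(
                [(r.feature_id, r.cluster, r.p, r.q, r.selected) for r in enr],
                columns=["gene", "cluster", "p", "q", "selected"],
            ).to_csv(out / "mutation_enrichment.tsv", sep="\t", index=False)
            chz["n_enriched_mutations"] = int(sum(r.selected for r in enr))
        manifest["stages"]["characterize"] = chz
    else:
        log.warning("clinical table missing; characterization skipped")
        manifest["stages"]["characterize"] = "skipped (no clinical table)"

    cls_cfg = config["classify"]
    if cls_cfg.get("enabled", True):
        log.info("stage: classify")
        spec = BaseLearnerSpec(
            kind="svm_rbf",
            cv_repeats=int(cls_cfg.get("cv_repeats", 2)),
            rf_trees=tuple(cls_cfg.get("rf_trees", [100])),
            ffnn_epochs=int(cls_cfg.get("ffnn_epochs", 60)),
            seed=stage_seed(seed, "classify"),
        )
        x = stack.values
        y = labels.labels
        tr, te = split_train_test(x, y, float(cls_cfg.get("test_fraction", 0.1)),
                                  seed=stage_seed(seed, "classify-split"))
        model = train_fused(
            x[tr], y[tr], spec, mode=cls_cfg.get("mode", "linear"),
            holdout=bool(cls_cfg.get("holdout", False)),
            seed=stage_seed(seed, "classify"),
        )
        acc = evaluate_accuracy(model.predict(x[te]), y[te])
        cls_manifest = {"test_accuracy": acc, "mode": model.mode}
        if model.weights is not None:
            cls_manifest["fusion_weights"] = list(model.weights.as_tuple())
            pd.DataFrame([model.weights.as_tuple()],
                         columns=["alpha", "beta", "gamma"]).to_csv(
                out / "fusion_weights.tsv", sep="\t", index=False
            )
        manifest["stages"]["classify"] = cls_manifest

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
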