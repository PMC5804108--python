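"""End-to-end orchestration of the three experimental arms.

From one configuration and one master seed: generate (or load) the patch
dataset, train the coding network once, extract the fused multiscale
features once, then run each selected reduction arm —

* ``cn``   — the coding network end-to-end (its own softmax head),
* ``mpca`` — fused features -> PCA -> fresh softmax classifier,
* ``msae`` — fused features -> sparse autoencoder -> fresh softmax classifier,

evaluate all arms on the identical test split, and emit per-arm reports plus
a comparison table.  The master seed deterministically spawns per-stage
seeds so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import evaluation, fusion, network, pca, sae, synthetic

logger = logging.getLogger("histofusion.pipeline")

ARMS = ("cn", "mpca", "msae")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    spec: synthetic.SyntheticSpec
    net: network.NetworkConfig
    train: network.TrainConfig
    arms: tuple[str, ...] = ARMS
    sae_hidden: int = 256
    sae_rho: float = 0.05
    sae_beta: float = 3.0
    sae_opt: sae.SAEOptConfig = dataclasses.field(default_factory=sae.SAEOptConfig)
    pca_k: int | None = None  # None: match sae_hidden
    protocol: str = "holdout"  # holdout | kfold
    kfold_k: int = 10
    split_ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    out_dir: str | None = None
    master_seed: int = 0

    def __post_init__(self):
        if not self.arms or any(a not in ARMS for a in self.arms):
            raise synthetic.ConfigurationError(
                f"arms must be a non-empty subset of {ARMS}"
            )
        if self.protocol not in {"holdout", "kfold"}:
            raise synthetic.ConfigurationError("protocol must be holdout or kfold")

    def hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


def desk_scale_config(
    scale: float = 32 / 140,
    patches_per_image: int = 3,
    epochs: int = 15,
    master_seed: int = 0,
    arms: tuple[str, ...] = ARMS,
    sae_hidden: int = 32,
) -> PipelineConfig:
    """The default desk-scale study: the six-class dataset shrunk so the
    network input is 32 pixels, a proportionally shrunk network, 15 training
    epochs.  Runs in minutes on one CPU."""
    spec = synthetic.SyntheticSpec().scaled(scale)
    spec = dataclasses.replace(spec, patches_per_image=patches_per_image)
    net_cfg = network.scaled_network_config(input_size=spec.target_size)
    train_cfg = network.TrainConfig(
        batch_size=50, epochs=epochs, initial_lr=0.01, momentum=0.9
    )
    return PipelineConfig(
        spec=spec,
        net=net_cfg,
        train=train_cfg,
        arms=arms,
        sae_hidden=sae_hidden,
        sae_opt=sae.SAEOptConfig(epochs=300),
        master_seed=master_seed,
    )


def spawn_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds below 2**31."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def _proba_matrix(clf, X, C: int) -> np.ndarray:
    """Class-probability matrix with columns 1..C regardless of which
    classes the classifier saw."""
    out = np.zeros((len(X), C))
    out[:, np.asarray(clf.classes_, dtype=int) - 1] = clf.predict_proba(X)
    return out


def run_reduction_arms(
    fused_train: fusion.FusedFeatureMatrix,
    fused_test: fusion.FusedFeatureMatrix,
    config: PipelineConfig,
    seeds: dict[str, int],
) -> dict[str, evaluation.EvalReport]:
    """MPCA and MSAE arms from fused feature matrices (in memory or re-read
    from disk; the report is identical either way)."""
    C = config.net.n_classes
    reports: dict[str, evaluation.EvalReport] = {}
    y_train, y_test = fused_train.labels, fused_test.labels
    if "mpca" in config.arms:
        k = config.pca_k or config.sae_hidden
        model = pca.fit_pca(fused_train.values, k)
        Ztr = pca.pca_transform(model, fused_train.values)
        Zte = pca.pca_transform(model, fused_test.values)
        clf = evaluation.train_softmax_classifier(Ztr, y_train, seed=seeds["clf"])
        reports["mpca"] = evaluation.evaluate(_proba_matrix(clf, Zte, C), y_test, C)
    if "msae" in config.arms:
        lo, rng = sae.fit_minmax(fused_train.values)
        Xtr = sae.apply_minmax(fused_train.values, lo, rng)
        Xte = sae.apply_minmax(fused_test.values, lo, rng)
        model = sae.train_sae(
            Xtr,
            s2=config.sae_hidden,
            rho=config.sae_rho,
            beta=config.sae_beta,
            opt=config.sae_opt,
            seed=seeds["sae"],
        )
        model.scale_min, model.scale_range = lo, rng
        Ztr = sae.encode(model, Xtr)
        Zte = sae.encode(model, Xte)
        clf = evaluation.train_softmax_classifier(Ztr, y_train, seed=seeds["clf"])
        reports["msae"] = evaluation.evaluate(_proba_matrix(clf, Zte, C), y_test, C)
    return reports


def _run_holdout(config: PipelineConfig, data: synthetic.ImageDataset, seeds):
    t0 = time.time()
    net = network.build_network(config.net, seed=seeds["init"])
    train_cfg = dataclasses.replace(config.train, seed=seeds["train"])
    network.train_network(net, data, train_cfg)
    logger.info("network trained in %.1fs", time.time() - t0)

    train = data.subset(data.split == "train")
    test = data.subset(data.split == "test")
    C = config.net.n_classes
    reports: dict[str, evaluation.EvalReport] = {}
    if "cn" in config.arms:
        reports["cn"] = evaluation.evaluate(
            network.predict_proba(net, test.images), test.labels, C
        )
    if {"mpca", "msae"} & set(config.arms):
        fused_train = fusion.extract_fused(net, train.images, labels=train.labels)
        fused_test = fusion.extract_fused(net, test.images, labels=test.labels)
        logger.info(
            "fused features: %d + %d = %d wide",
            fused_train.d_cfr,
            fused_train.d_ffr,
            fused_train.values.shape[1],
        )
        reports.update(run_reduction_arms(fused_train, fused_test, config, seeds))
    else:
        fused_train = fused_test = None
    return net, reports, (fused_train, fused_test)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured arms; returns the comparison report as a plain
    dict (JSON-serializable, byte-stable for a fixed config and seed)."""
    s = spawn_seeds(config.master_seed)
    seeds = {
        "data": s[0],
        "split": s[1],
        "init": s[2],
        "train": s[3],
        "sae": s[4],
        "clf": s[5],
        "fold": s[6],
    }
    spec = dataclasses.replace(config.spec, seed=seeds["data"])
    t0 = time.time()
    data = synthetic.make_patch_dataset(spec, ratios=config.split_ratios)
    logger.info("generated %d patches in %.1fs", len(data), time.time() - t0)

    fused = None
    if config.protocol == "holdout":
        net, reports, fused = _run_holdout(config, data, seeds)
        comparison = evaluation.compare_pipelines(reports)
        result = {
            "config_hash": config.hash(),
            "master_seed": config.master_seed,
            "stage_seeds": seeds,
            "protocol": "holdout",
            "n_patches": len(data),
            "arms": {k: r.to_dict() for k, r in reports.items()},
            "comparison": comparison,
        }
    else:
        result = _run_kfold(config, data, seeds)

    if config.out_dir is not None:
        _write_artifacts(config, result, fused)
    return result


def _run_kfold(config: PipelineConfig, data: synthetic.ImageDataset, seeds) -> dict:
    """k-fold protocol: each fold serves as the test split once; the
    remainder is re-split 4:1 into train/validation (largest-remainder,
    stratified, so every class keeps a validation sample even at small n).
    The network is retrained per fold (costly; intended for reduced-scale
    studies)."""
    folds = synthetic.kfold_indices(len(data), config.kfold_k, seeds["fold"])
    per_fold = []
    all_idx = np.arange(len(data))
    for f, test_idx in enumerate(folds):
        mask = np.isin(all_idx, test_idx)
        rest = data.subset(~mask)
        rest = synthetic.split_dataset(rest, (0.8, 0.2, 0.0), seeds["split"] + f)
        test = data.subset(mask)
        merged = synthetic.ImageDataset(
            images=rest.images + test.images,
            labels=np.concatenate([rest.labels, test.labels]),
            split=np.concatenate([rest.split, np.full(len(test), "test", dtype="U10")]),
            seed=data.seed,
        )
        fold_seeds = dict(seeds, init=seeds["init"] + f, train=seeds["train"] + f)
        _, reports, _ = _run_holdout(config, merged, fold_seeds)
        per_fold.append(evaluation.compare_pipelines(reports))
        logger.info("fold %d/%d done", f + 1, len(folds))
    mean_acc = {
        arm: float(np.mean([pf["overall_accuracy"][arm] for pf in per_fold]))
        for arm in per_fold[0]["overall_accuracy"]
    }
    mean_auc = {
        arm: float(np.mean([pf["mean_auc"][arm] for pf in per_fold]))
        for arm in per_fold[0]["mean_auc"]
    }
    return {
        "config_hash": config.hash(),
        "master_seed": config.master_seed,
        "stage_seeds": seeds,
        "protocol": f"{config.kfold_k}-fold",
        "n_patches": len(data),
        "per_fold": per_fold,
        "comparison": {"overall_accuracy": mean_acc, "mean_auc": mean_auc},
    }


def report_json(result: dict) -> str:
    """Canonical (byte-stable) JSON serialization of a pipeline report."""
    return json.dumps(result, indent=1, sort_keys=True)


def _write_artifacts(config: PipelineConfig, result: dict, fused) -> None:
    out = Path(config.out_dir)
    (out / "arms").mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        fh.write(report_json(result))
    if "comparison" in result and "per_class_accuracy" in result["comparison"]:
        with open(out / "comparison.md", "w") as fh:
            fh.write(evaluation.comparison_markdown(result["comparison"]) + "\n")
    if fused is not None and fused[0] is not None:
        (out / "features").mkdir(exist_ok=True)
        fusion.write_features(fused[0], out / "features" / "train.tsv")
        fusion.write_features(fused[1], out / "features" / "test.tsv")
    logger.info("artifacts written to %s", out)
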