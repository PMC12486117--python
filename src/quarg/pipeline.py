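"""End-to-end orchestration: simulate -> preprocess -> split -> select ->
encode -> train -> evaluate, with content-addressed stage caching.

Every stage writes its artifacts plus a hash of (its config slice + the
hashes of its inputs) into the run directory; rerunning with an unchanged
config reloads from disk, so reruns are idempotent and any stage can be
redone in isolation.  The run directory ends up holding split indices,
seeds, the selected-feature JSON, the QUBO export, training history, the
best checkpoint, metrics JSON and ROC/reliability CSVs for both evaluation
protocols.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from skimage.transform import resize as _resize

from . import evalsplit, preprocess, qenc, qfs, synthetic
from .encoders import GenomicEncoderConfig, ImageEncoderConfig
from .train import FusionModel, TrainConfig, TrainData, save_history_csv, train


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Defaults follow the reported ablation optima: circuit depth L=6,
    qubits Q=10, QAOA layers p=3.
    """

    seed: int = 1
    outdir: str = "runs/default"
    # synthetic cohort
    synthetic: synthetic.SyntheticConfig = field(default_factory=lambda: synthetic.SyntheticConfig(
        n_patients=400, n_img_features=8, n_gen_features=8, n_informative_img=2,
        n_informative_gen=2, n_redundant=2, effect_size=2.0, site_count=3,
        site_shift_sd=0.3, missing_rate=0.05, class_balance=0.5, seed=0,
    ))
    patch_size: int = 32
    patch_bias: bool = True
    save_patch_pngs: bool = False
    # preprocessing
    bias_order: int = 2
    roi_margin: int = 2
    roi_size: int = 16
    var_quantile: float = 0.05
    knn_k: int = 5
    # feature selection
    p: int = 3
    alpha: float = 0.25
    beta: float | None = None
    qaoa_restarts: int = 6
    k_select: int | None = None  # defaults to Q
    # quantum encoding
    Q: int = 10
    L: int = 6
    entangler: str = "ring"
    # encoders + training
    image: ImageEncoderConfig = field(default_factory=lambda: ImageEncoderConfig(
        n_res_blocks=2, base_channels=6, d_img=12))
    genomic: GenomicEncoderConfig = field(default_factory=lambda: GenomicEncoderConfig(
        token_size=4, d_model=16, n_heads=2, n_layers=2, d_gen=12))
    head_hidden: int = 32
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        max_epochs=10, patience=4, batch_size=96))
    # splits
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    held_site: str | None = None  # default: first site alphabetically

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("synthetic", synthetic.SyntheticConfig),
            ("image", ImageEncoderConfig),
            ("genomic", GenomicEncoderConfig),
            ("train", TrainConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_overrides(self, overrides: dict[str, object]) -> "RunConfig":
        """Dotted-key overrides, e.g. {"train.max_epochs": 5, "L": 2}."""
        d = self.to_dict()
        for dotted, value in overrides.items():
            node = d
            *parents, leaf = dotted.split(".")
            for part in parents:
                node = node[part]
            node[leaf] = value
        return RunConfig.from_dict(d)


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Stage:
    """Content-addressed stage directory: skip work when the hash matches."""

    def __init__(self, outdir: Path, name: str, cfg_slice: dict, parent_hashes: list[str], log):
        self.dir = outdir / name
        self.dir.mkdir(parents=True, exist_ok=True)
        self.hash = config_hash({"cfg": cfg_slice, "parents": parent_hashes})
        self.name = name
        self._log = log

    def cached(self) -> bool:
        f = self.dir / "stage_hash.txt"
        hit = f.exists() and f.read_text().strip() == self.hash
        self._log({"stage": self.name, "hash": self.hash, "cached": hit})
        return hit

    def mark(self) -> None:
        (self.dir / "stage_hash.txt").write_text(self.hash + "\n")


def preprocess_patches(
    patches: np.ndarray, masks: np.ndarray, bias_order: int, margin: int, out_size: int
) -> np.ndarray:
    """Bias-correct, crop to the lesion ROI, resample each crop onto a
    common out_size grid, and z-score per patch."""
    out = np.empty((len(patches), out_size, out_size))
    for i, (pix, mask) in enumerate(zip(patches, masks)):
        corrected = preprocess.correct_bias_field(preprocess.ImagePatch(pix), order=bias_order)
        roi = preprocess.extract_roi(corrected, mask, margin=margin)
        resized = _resize(roi.pixels, (out_size, out_size), order=1, anti_aliasing=False)
        harmonized = preprocess.harmonize([preprocess.ImagePatch(resized)], 1.0)[0]
        out[i] = harmonized.pixels
    return out


def _pin_subset_size(subset: list[int], relevance: np.ndarray, size: int) -> list[int]:
    """Force |S| = size: drop the least relevant / add the most relevant."""
    chosen = sorted(subset, key=lambda i: (-relevance[i], i))
    if len(chosen) > size:
        chosen = chosen[:size]
    else:
        rest = [i for i in np.argsort(-relevance, kind="stable") if i not in set(chosen)]
        chosen += rest[: size - len(chosen)]
    return sorted(chosen)


def run_pipeline(
    config: RunConfig, outdir: str | Path | None = None, stop_after: str | None = None
) -> dict:
    """Execute the full workflow; returns a summary dict of artifact paths
    and test metrics for both evaluation protocols.

    ``stop_after`` (simulate | preprocess | split | select | encode) stops
    the run once that stage's artifacts are on disk, for stage-wise reruns.
    """
    t0 = time.time()
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "log.jsonl"

    def log(record: dict) -> None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"t": round(time.time() - t0, 3), **record}, sort_keys=True) + "\n")

    resolved = config.to_dict()
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    run_hash = config_hash(resolved)
    log({"stage": "start", "config_hash": run_hash, "seed": config.seed})

    # ---- stage: simulate -------------------------------------------------
    syn_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
    sim = _Stage(outdir, "cohort", {"synthetic": asdict(syn_cfg), "patch_size": config.patch_size,
                                    "patch_bias": config.patch_bias}, [], log)
    if sim.cached():
        cohort = synthetic.SyntheticCohort.load(sim.dir)
        with np.load(sim.dir / "patches.npz") as npz:
            patches, masks = npz["patches"], npz["masks"]
    else:
        cohort = synthetic.generate_cohort(syn_cfg)
        patches, masks = synthetic.cohort_patches(
            cohort, size=config.patch_size, bias=config.patch_bias, seed=config.seed + 10000
        )
        cohort.save(sim.dir)
        np.savez_compressed(sim.dir / "patches.npz", patches=patches, masks=masks)
        if config.save_patch_pngs:
            png_dir = sim.dir / "patches"
            png_dir.mkdir(exist_ok=True)
            for pid, patch, mask in zip(cohort.patient_ids, patches, masks):
                synthetic.save_patch_png(png_dir / f"{pid}.png", patch)
                synthetic.save_mask_png(png_dir / f"{pid}_mask.png", mask)
        sim.mark()
    if stop_after == "simulate":
        return {"outdir": str(outdir), "config_hash": run_hash, "stopped_after": "simulate"}

    # ---- stage: split ----------------------------------------------------
    split_seed = config.seed + 3
    spl = _Stage(outdir, "splits", {"fractions": list(config.split_fractions),
                                    "held_site": config.held_site, "seed": split_seed}, [sim.hash], log)
    if spl.cached():
        split_pl = evalsplit.SplitIndices.from_json(spl.dir / "patient_level.json")
        split_sh = evalsplit.SplitIndices.from_json(spl.dir / "site_held_out.json")
    else:
        split_pl = evalsplit.patient_split(
            cohort.patient_ids, cohort.labels, config.split_fractions, seed=split_seed
        )
        held = config.held_site or sorted(set(cohort.site_ids))[0]
        split_sh = evalsplit.site_holdout_split(
            cohort.patient_ids, cohort.labels, cohort.site_ids, held, seed=split_seed
        )
        split_pl.to_json(spl.dir / "patient_level.json")
        split_sh.to_json(spl.dir / "site_held_out.json")
        with open(spl.dir / "seeds.json", "w") as fh:
            json.dump({"global_seed": config.seed, "split_seed": split_seed,
                       "qaoa_seed": config.seed + 1, "train_seed": config.seed + 2,
                       "patch_seed": config.seed + 10000}, fh, indent=2, sort_keys=True)
        spl.mark()
    if stop_after == "split":
        return {"outdir": str(outdir), "config_hash": run_hash, "stopped_after": "split"}

    id_to_row = {pid: i for i, pid in enumerate(cohort.patient_ids)}
    rows = lambda ids: np.array([id_to_row[p] for p in ids], dtype=int)

    # ---- stage: preprocess ----------------------------------------------
    pre = _Stage(outdir, "preprocess", {"bias_order": config.bias_order, "margin": config.roi_margin,
                                        "roi_size": config.roi_size, "var_q": config.var_quantile,
                                        "knn_k": config.knn_k}, [sim.hash, spl.hash], log)
    if pre.cached():
        with np.load(pre.dir / "processed.npz") as npz:
            proc_patches, gvec_by_protocol = npz["patches"], {
                "patient_level": npz["gvec_patient_level"], "site_held_out": npz["gvec_site_held_out"]}
    else:
        proc_patches = preprocess_patches(
            patches, masks, config.bias_order, config.roi_margin, config.roi_size
        )
        gvec_by_protocol = {}
        gm_imputed = None
        for split, key in ((split_pl, "patient_level"), (split_sh, "site_held_out")):
            if gm_imputed is None:
                gm = preprocess.GenomicMatrix(
                    values=cohort.X_gen.T, gene_lengths_kb=np.ones(cohort.X_gen.shape[1]),
                    stage="normalized", sample_ids=cohort.patient_ids,
                )
                gm_imputed = preprocess.impute_knn(gm, k=config.knn_k)
            # variance filter + z-score fitted on this protocol's training split
            train_mat = dataclasses.replace(gm_imputed, values=gm_imputed.values[:, rows(split.train)])
            _, stats = preprocess.filter_and_standardize(train_mat, config.var_quantile)
            full, _ = preprocess.filter_and_standardize(gm_imputed, config.var_quantile, stats=stats)
            gvec_by_protocol[key] = full.values.T
        np.savez_compressed(pre.dir / "processed.npz", patches=proc_patches,
                            gvec_patient_level=gvec_by_protocol["patient_level"],
                            gvec_site_held_out=gvec_by_protocol["site_held_out"])
        pre.mark()
    if stop_after == "preprocess":
        return {"outdir": str(outdir), "config_hash": run_hash, "stopped_after": "preprocess"}

    # ---- per-protocol: select, encode, train, evaluate -------------------
    metrics_out: dict[str, dict] = {}
    for split, key in ((split_pl, "patient_level"), (split_sh, "site_held_out")):
        gvec = gvec_by_protocol[key]
        pool = np.concatenate([cohort.X_img, gvec], axis=1)
        tr = rows(split.train)

        sel = _Stage(outdir, f"select_{key}",
                     {"p": config.p, "alpha": config.alpha, "beta": config.beta,
                      "restarts": config.qaoa_restarts, "k": config.k_select, "Q": config.Q},
                     [pre.hash, spl.hash], log)
        sel_path = sel.dir / "selected.json"
        if not sel.cached():
            k = config.k_select or config.Q
            qcfg = qfs.QaoaConfig(p=config.p, restarts=config.qaoa_restarts,
                                  seed=config.seed + 1, mode="exact")
            scores = qfs.score_features(pool[tr], cohort.labels[tr])
            qubo = qfs.build_qubo(scores, k=min(k, pool.shape[1]), alpha=config.alpha, beta=config.beta)
            gammas, betas, _ = qfs.optimize_qaoa(qubo, qcfg)
            state = qfs.qaoa_state(qubo, gammas, betas)
            subset = qfs.sample_subset(qubo, state, qcfg)
            selected = _pin_subset_size(subset.indices, scores.relevance, config.Q)
            qubo.to_csv(sel.dir / "qubo.csv")
            subset.to_json(sel_path, seed=config.seed + 1,
                           config={"p": config.p, "k": k, "alpha": config.alpha,
                                   "pinned_to_Q": selected})
            sel.mark()
        with open(sel_path) as fh:
            selected = json.load(fh)["config"]["pinned_to_Q"]

        scaler = qenc.AngleScaler.fit(pool[tr][:, selected])
        angles = qenc.scale_to_angles(pool[:, selected], scaler)
        if stop_after == "select":
            continue
        if stop_after == "encode":
            vqc_cfg = qenc.VqcConfig(Q=config.Q, L=config.L, entangler=config.entangler,
                                     seed=config.seed + 2)
            zq = qenc.quantum_embed(angles, qenc.init_params(vqc_cfg), vqc_cfg)
            enc_dir = outdir / f"encode_{key}"
            enc_dir.mkdir(exist_ok=True)
            with open(enc_dir / "zq.csv", "w") as fh:
                fh.write("patient_id," + ",".join(f"zq{i}" for i in range(config.Q)) + "\n")
                for pid, row in zip(cohort.patient_ids, zq):
                    fh.write(pid + "," + ",".join(repr(float(v)) for v in row) + "\n")
            continue

        trn = _Stage(outdir, f"train_{key}",
                     {"Q": config.Q, "L": config.L, "entangler": config.entangler,
                      "image": asdict(config.image), "genomic": asdict(config.genomic),
                      "head_hidden": config.head_hidden, "train": asdict(config.train)},
                     [sel.hash], log)
        ckpt = trn.dir / "checkpoint.npz"
        if trn.cached():
            model = FusionModel.load(ckpt)
        else:
            vqc_cfg = qenc.VqcConfig(Q=config.Q, L=config.L, entangler=config.entangler,
                                     seed=config.seed + 2)
            model = FusionModel(
                dataclasses.replace(config.image, seed=config.seed + 2),
                dataclasses.replace(config.genomic, seed=config.seed + 2),
                vqc_cfg, head_hidden=config.head_hidden, seed=config.seed + 2,
            )
            tcfg = dataclasses.replace(config.train, seed=config.seed + 2)
            data = {
                name: TrainData(proc_patches[rows(idset)], gvec[rows(idset)],
                                angles[rows(idset)], cohort.labels[rows(idset)])
                for name, idset in (("train", split.train), ("val", split.val))
            }
            model, history = train(model, data["train"], data["val"], tcfg)
            model.save(ckpt)
            save_history_csv(trn.dir / "history.csv", history)
            trn.mark()

        te = rows(split.test)
        probs = model.predict_proba(proc_patches[te], gvec[te], angles[te])
        report = evalsplit.compute_metrics(probs, cohort.labels[te], M=config.train.ece_bins)
        eval_dir = outdir / "eval"
        eval_dir.mkdir(exist_ok=True)
        report.to_json(eval_dir / f"metrics_{key}.json")
        curve = evalsplit.roc_curve(probs, cohort.labels[te])
        evalsplit.save_curve_csv(eval_dir / f"roc_{key}.csv", curve, ["fpr", "tpr", "threshold"])
        rel = evalsplit.reliability_curve(probs, cohort.labels[te], M=config.train.ece_bins)
        evalsplit.save_curve_csv(eval_dir / f"reliability_{key}.csv", rel,
                                 ["lo", "hi", "count", "accuracy", "confidence"])
        metrics_out[key] = {"acc": report.acc, "auc": report.auc, "ece": report.ece,
                            "precision": report.precision, "recall": report.recall, "f1": report.f1}
        log({"stage": f"eval_{key}", **metrics_out[key]})

    if stop_after in ("select", "encode"):
        return {"outdir": str(outdir), "config_hash": run_hash, "stopped_after": stop_after}

    summary = {"outdir": str(outdir), "config_hash": run_hash, "metrics": metrics_out,
               "n_parameters": model.n_parameters()}
    with open(outdir / "eval" / "metrics.json", "w") as fh:
        json.dump(summary["metrics"], fh, indent=2, sort_keys=True)
    log({"stage": "done"})
    return summary


def run_ablation(
    config: RunConfig,
    grid: dict[str, list],
    seeds: list[int] | None = None,
    outdir: str | Path | None = None,
) -> list[dict]:
    """One-factor-at-a-time sweep over {"L": [...], "Q": [...], "p": [...]},
    holding the other factors at the config defaults; one pipeline run per
    (factor, value, seed).  Writes ablation.csv keyed by factor/value/seed."""
    seeds = seeds or [1, 2, 3, 4, 5]
    outdir = Path(outdir or config.outdir) / "ablation"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for factor, values in grid.items():
        if factor not in ("L", "Q", "p"):
            raise ValueError(f"unknown ablation factor {factor!r}")
        for value in values:
            for seed in seeds:
                sub = config.with_overrides({factor: value, "seed": seed})
                run_dir = outdir / f"{factor}{value}_seed{seed}"
                summary = run_pipeline(sub, run_dir)
                m = summary["metrics"]["patient_level"]
                rows.append({"factor": factor, "value": value, "seed": seed,
                             "acc": m["acc"], "auc": m["auc"], "ece": m["ece"]})
    with open(outdir / "ablation.csv", "w") as fh:
        fh.write("factor,value,seed,acc,auc,ece\n")
        for r in rows:
            fh.write(f"{r['factor']},{r['value']},{r['seed']},{r['acc']!r},{r['auc']!r},{r['ece']!r}\n")
    return rows
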