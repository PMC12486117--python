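"""Reference experiments: end-to-end training runs at fixed study designs.

These are the designed experiments the package's own validation rests on;
the acceptance script and the test suite run them unchanged.

``strong_signal_training_run`` trains the fusion model on a strongly
signaled cohort (additive effect size 2) and reports the best validation
AUC reached, probing that the hybrid model learns the planted structure
quickly.

``calibration_comparison`` is a paired, seeded comparison of the calibrated
loss (lambda > 0) against plain cross-entropy (lambda = 0) on cohorts with
irreducible class overlap (effect size 1), a small training split that the
encoders can overfit, and a large test split so the hard-ECE difference is
measurable.  Both arms checkpoint on validation AUC alone so the only
difference between them is the loss being minimized.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from . import evalsplit, qenc, qfs, synthetic
from .encoders import GenomicEncoderConfig, ImageEncoderConfig
from .pipeline import preprocess_patches
from .train import FusionModel, TrainConfig, TrainData, train


def _prepare(seed: int, *, n_patients: int, effect_size: float, fractions, k: int):
    """Cohort -> preprocessed arrays + QAOA-selected angle features."""
    scfg = synthetic.SyntheticConfig(
        n_patients=n_patients, n_img_features=6, n_gen_features=6,
        n_informative_img=2, n_informative_gen=2, n_redundant=2,
        effect_size=effect_size, site_count=3, site_shift_sd=0.3,
        missing_rate=0.0, seed=seed,
    )
    cohort = synthetic.generate_cohort(scfg)
    patches, masks = synthetic.cohort_patches(cohort, size=20, bias=True, seed=seed + 10000)
    proc = preprocess_patches(patches, masks, bias_order=2, margin=2, out_size=16)
    split = evalsplit.patient_split(cohort.patient_ids, cohort.labels, fractions, seed=seed + 3)
    row_of = {p: i for i, p in enumerate(cohort.patient_ids)}
    rows = lambda ids: np.array([row_of[p] for p in ids])
    pool = cohort.pooled_features()
    tr = rows(split.train)
    subset, _ = qfs.select_features(
        pool[tr], cohort.labels[tr], k=k,
        config=qfs.QaoaConfig(p=3, restarts=3, seed=seed + 1),
    )
    sel = subset.indices[:k]
    sel += [i for i in np.argsort(-np.abs(pool[tr].std(0))) if i not in sel][: k - len(sel)]
    scaler = qenc.AngleScaler.fit(pool[tr][:, sel])
    angles = qenc.scale_to_angles(pool[:, sel], scaler)
    gvec = (cohort.X_gen - cohort.X_gen[tr].mean(0)) / cohort.X_gen[tr].std(0)

    def split_data(ids):
        r = rows(ids)
        return TrainData(proc[r], gvec[r], angles[r], cohort.labels[r])

    return cohort, split, split_data, rows, proc, gvec, angles


def strong_signal_training_run(seed: int = 1, max_epochs: int = 30) -> dict:
    """Train on a strongly-signaled cohort; report validation AUC progress."""
    cohort, split, split_data, rows, proc, gvec, angles = _prepare(
        seed, n_patients=400, effect_size=2.0, fractions=(0.70, 0.15, 0.15), k=6
    )
    vqc = qenc.VqcConfig(Q=6, L=2, seed=seed + 2)
    model = FusionModel(
        ImageEncoderConfig(2, 4, 8, seed + 2),
        GenomicEncoderConfig(3, 16, 2, 1, 8, seed + 2),
        vqc, head_hidden=16, seed=seed + 2,
    )
    cfg = TrainConfig(lambda_cal=0.1, max_epochs=max_epochs, patience=max_epochs,
                      batch_size=64, seed=seed + 2)
    model, history = train(model, split_data(split.train), split_data(split.val), cfg)
    te = rows(split.test)
    probs = model.predict_proba(proc[te], gvec[te], angles[te])
    return {
        "best_val_auc": max(h["val_auc"] for h in history),
        "epochs_run": len(history),
        "test_auc": evalsplit.auc(probs, cohort.labels[te]),
        "test_acc": float((np.round(probs) == cohort.labels[te]).mean()),
        "test_ece": evalsplit.expected_calibration_error(probs, cohort.labels[te], 10),
        "history": history,
    }


def _calibration_arm(seed: int, lambda_cal: float, max_epochs: int) -> dict:
    cohort, split, split_data, rows, proc, gvec, angles = _prepare(
        seed, n_patients=600, effect_size=1.0, fractions=(0.20, 0.13, 0.67), k=4
    )
    vqc = qenc.VqcConfig(Q=4, L=1, seed=seed + 2)
    model = FusionModel(
        ImageEncoderConfig(2, 6, 8, seed + 2),
        GenomicEncoderConfig(3, 12, 2, 1, 6, seed + 2),
        vqc, head_hidden=16, seed=seed + 2,
    )
    cfg = TrainConfig(lambda_cal=lambda_cal, max_epochs=max_epochs, patience=max_epochs,
                      batch_size=32, lr=0.02, early_stop_weight=0.0, seed=seed + 2)
    model, _ = train(model, split_data(split.train), split_data(split.val), cfg)
    te = rows(split.test)
    probs = model.predict_proba(proc[te], gvec[te], angles[te])
    return {
        "auc": evalsplit.auc(probs, cohort.labels[te]),
        "ece": evalsplit.expected_calibration_error(probs, cohort.labels[te], 10),
        "mean_confidence": float(np.maximum(probs, 1 - probs).mean()),
    }


def calibration_comparison(
    seeds: Iterable[int] = range(1, 11),
    lambda_cal: float = 0.1,
    max_epochs: int = 25,
) -> dict:
    """Paired lambda>0 vs lambda=0 runs; counts seeds where the calibrated
    loss gives test hard-ECE no worse than plain cross-entropy."""
    pairs = []
    wins = 0
    for seed in seeds:
        with_cal = _calibration_arm(seed, lambda_cal, max_epochs)
        without = _calibration_arm(seed, 0.0, max_epochs)
        wins += with_cal["ece"] <= without["ece"]
        pairs.append({"seed": seed, "with": with_cal, "without": without})
    return {
        "wins": wins,
        "n": len(pairs),
        "lambda": lambda_cal,
        "mean_ece_with": float(np.mean([p["with"]["ece"] for p in pairs])),
        "mean_ece_without": float(np.mean([p["without"]["ece"] for p in pairs])),
        "pairs": pairs,
    }
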