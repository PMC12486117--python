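"""Synthetic paired radiogenomic cohorts with planted ground truth.

The generator emulates, at feature-table scale, the structure a paired
mammography + expression study presents to the model: a handful of truly
class-separating features (additive mean shift between classes), noisy
duplicates of some of them (redundancy for the selector to penalise),
per-site batch offsets (making site-held-out evaluation strictly harder),
missing genomic entries (MCAR), and per-patient lesion image patches whose
blob intensity tracks the label and which optionally carry a smooth
multiplicative bias field for the correction stage to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

REDUNDANT_NOISE_SD = 0.5  # redundant feature = parent + N(0, 0.25) variance


@dataclass
class SyntheticConfig:
    n_patients: int = 400
    n_img_features: int = 6
    n_gen_features: int = 6
    n_informative_img: int = 2
    n_informative_gen: int = 2
    n_redundant: int = 2
    effect_size: float = 2.0
    site_count: int = 3
    site_shift_sd: float = 0.3
    missing_rate: float = 0.05
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative_img > self.n_img_features:
            raise ValueError("n_informative_img exceeds n_img_features")
        if self.n_informative_gen > self.n_gen_features:
            raise ValueError("n_informative_gen exceeds n_gen_features")
        if self.n_redundant > self.n_informative_img + self.n_informative_gen:
            raise ValueError("n_redundant exceeds the number of informative features")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.site_count < 1:
            raise ValueError("site_count must be >= 1")


@dataclass
class SyntheticCohort:
    patient_ids: list[str]
    site_ids: list[str]
    labels: np.ndarray  # (n,) in {0,1}
    X_img: np.ndarray  # (n, n_img_features)
    X_gen: np.ndarray  # (n, n_gen_features), NaN marks missing
    truth: dict  # planted informative / redundant indices per modality
    config: SyntheticConfig | None = None

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def pooled_features(self) -> np.ndarray:
        """Imaging then genomic columns, the QAOA candidate pool ordering."""
        return np.concatenate([self.X_img, self.X_gen], axis=1)

    def informative_pool_indices(self) -> list[int]:
        off = self.X_img.shape[1]
        return sorted(self.truth["informative_img"]) + [off + j for j in sorted(self.truth["informative_gen"])]

    # ---- disk round trip (CSV tables + JSON truth) ----

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, X in (("imaging", self.X_img), ("genomic", self.X_gen)):
            cols = {f"f{j + 1:04d}": X[:, j] for j in range(X.shape[1])}
            df = pd.DataFrame(
                {"patient_id": self.patient_ids, "site_id": self.site_ids, "label": self.labels, **cols}
            )
            df.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump({k: sorted(int(i) for i in v) for k, v in self.truth.items()}, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, outdir) -> "SyntheticCohort":
        outdir = Path(outdir)
        img = pd.read_csv(outdir / "imaging.csv")
        gen = pd.read_csv(outdir / "genomic.csv")
        with open(outdir / "truth.json") as fh:
            truth = json.load(fh)
        feat = lambda df: df[[c for c in df.columns if c.startswith("f")]].to_numpy(float)
        return cls(
            patient_ids=img["patient_id"].tolist(),
            site_ids=img["site_id"].tolist(),
            labels=img["label"].to_numpy(int),
            X_img=feat(img),
            X_gen=feat(gen),
            truth=truth,
        )


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort; bit-identical for identical config (seeded)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    labels = (rng.random(n) < config.class_balance).astype(int)
    sites = rng.integers(0, config.site_count, size=n)

    def modality(n_feat: int, informative: np.ndarray) -> np.ndarray:
        X = rng.normal(0.0, 1.0, size=(n, n_feat))
        X[:, informative] += config.effect_size * labels[:, None]
        return X

    info_img = np.arange(config.n_informative_img)
    info_gen = np.arange(config.n_informative_gen)
    X_img = modality(config.n_img_features, info_img)
    X_gen = modality(config.n_gen_features, info_gen)

    # redundant features: noisy copies of informative ones, overwriting the
    # trailing noise columns; parents cycle through the informative pool
    parents = [("img", int(i)) for i in info_img] + [("gen", int(i)) for i in info_gen]
    red_img: list[int] = []
    red_gen: list[int] = []
    free_img = [j for j in range(config.n_img_features - 1, -1, -1) if j not in set(info_img)]
    free_gen = [j for j in range(config.n_gen_features - 1, -1, -1) if j not in set(info_gen)]
    for r in range(config.n_redundant):
        mod, parent = parents[r % len(parents)]
        source = X_img[:, parent] if mod == "img" else X_gen[:, parent]
        noise = rng.normal(0.0, REDUNDANT_NOISE_SD, size=n)
        # place the copy in the same modality if room remains, else the other
        if (mod == "img" and free_img) or (mod == "gen" and not free_gen):
            col = free_img.pop(0)
            X_img[:, col] = source + noise
            red_img.append(col)
        else:
            col = free_gen.pop(0)
            X_gen[:, col] = source + noise
            red_gen.append(col)

    # additive per-site offset, shared by all features of a site's patients
    if config.site_shift_sd > 0:
        offsets = rng.normal(0.0, config.site_shift_sd, size=config.site_count)
        X_img += offsets[sites][:, None]
        X_gen += offsets[sites][:, None]
    else:
        rng.normal(0.0, 1.0, size=config.site_count)  # keep the stream aligned

    if config.missing_rate > 0:
        mask = rng.random(X_gen.shape) < config.missing_rate
        X_gen = X_gen.copy()
        X_gen[mask] = np.nan

    return SyntheticCohort(
        patient_ids=[f"P{i + 1:04d}" for i in range(n)],
        site_ids=[f"S{s + 1}" for s in sites],
        labels=labels,
        X_img=X_img,
        X_gen=X_gen,
        truth={
            "informative_img": info_img.tolist(),
            "informative_gen": info_gen.tolist(),
            "redundant_img": sorted(red_img),
            "redundant_gen": sorted(red_gen),
        },
        config=config,
    )


# --------------------------------------------------------------------------
# image fixtures
# --------------------------------------------------------------------------


def planted_bias_field(size: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive quadratic multiplicative field, range about [0.7, 1.3]."""
    yy, xx = np.mgrid[0:size, 0:size] / (size - 1)  # in [0, 1]
    cx, cy = rng.uniform(0.3, 0.7, size=2)
    a, b = rng.uniform(0.6, 1.2, size=2)
    quad = a * (xx - cx) ** 2 + b * (yy - cy) ** 2
    quad = (quad - quad.min()) / max(quad.max() - quad.min(), 1e-12)  # [0, 1]
    return 0.7 + 0.6 * quad


def generate_image_patch(
    label: int, size: int = 32, bias: bool = False, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """One lesion patch and its binary mask.

    An elliptical blob sits on positive Gaussian background noise; malignant
    (label 1) blobs are brighter and larger.  With ``bias`` the patch is
    multiplied by a smooth quadratic field, the fixture the bias-correction
    stage is tested against.
    """
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = np.random.default_rng(seed)
    patch = 1.0 + 0.05 * rng.normal(size=(size, size))
    patch = np.clip(patch, 0.05, None)

    radius = size * (0.20 if label == 0 else 0.28)
    intensity = 0.5 if label == 0 else 1.0
    cy, cx = (size - 1) / 2 + rng.uniform(-size * 0.05, size * 0.05, size=2)
    ecc = rng.uniform(0.7, 1.0)
    ang = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    u = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
    v = -(xx - cx) * np.sin(ang) + (yy - cy) * np.cos(ang)
    mask = (u / radius) ** 2 + (v / (ecc * radius)) ** 2 <= 1.0
    profile = np.exp(-((u / radius) ** 2 + (v / (ecc * radius)) ** 2))
    patch = patch + intensity * profile * mask

    if bias:
        patch = patch * planted_bias_field(size, rng)
    return patch, mask.astype(np.uint8)


def generate_counts(n_genes: int, n_samples: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Negative-binomial-like RNA-seq counts plus gene lengths in kilobases.

    Per-sample library-size factors are log-uniform over [0.5, 4], forcing at
    least a 4x spread between the smallest and largest library.
    """
    if n_genes < 1 or n_samples < 1:
        raise ValueError("n_genes and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    lengths_kb = rng.uniform(0.2, 20.0, size=n_genes)
    base = rng.lognormal(mean=3.0, sigma=1.2, size=n_genes)  # per-gene abundance
    lib = np.exp(np.linspace(np.log(0.5), np.log(4.0), n_samples))
    lib = rng.permutation(lib)
    mu = np.outer(base, lib)
    # NB via gamma-Poisson mixture, dispersion 0.3
    shape = 1.0 / 0.3
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.int64)
    return counts, lengths_kb


# --------------------------------------------------------------------------
# PNG export (16-bit grayscale)
# --------------------------------------------------------------------------


def save_patch_png(path, patch: np.ndarray) -> None:
    lo, hi = float(patch.min()), float(patch.max())
    scaled = np.zeros_like(patch) if hi == lo else (patch - lo) / (hi - lo)
    Image.fromarray((scaled * 65535).astype(np.uint16)).save(path)


def save_mask_png(path, mask: np.ndarray) -> None:
    Image.fromarray((mask.astype(np.uint16)) * 65535).save(path)


def cohort_patches(
    cohort: SyntheticCohort, size: int = 32, bias: bool = True, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient patches/masks; patient i's patch is seeded by seed + i."""
    patches = np.empty((cohort.n, size, size))
    masks = np.empty((cohort.n, size, size), dtype=np.uint8)
    for i, label in enumerate(cohort.labels):
        patches[i], masks[i] = generate_image_patch(int(label), size=size, bias=bias, seed=seed + i)
    return patches, masks
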