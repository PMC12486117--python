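"""Imaging and genomics preprocessing.

Imaging: log-domain polynomial bias-field correction, mask-driven ROI
cropping, spacing/intensity harmonization, and a fixed 10-descriptor
radiomic vector (intensity, shape, co-occurrence texture).

Genomics: TPM/FPKM normalization with log2(1+x), k-nearest-neighbour
imputation over co-observed genes, variance filtering and z-scoring with
training-split statistics.  A forward-only stage tag (raw -> normalized ->
imputed -> standardized) guards the pipeline order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import kurtosis, skew
from skimage.measure import perimeter as _weighted_perimeter

STAGES = ("raw", "normalized", "imputed", "standardized")


# --------------------------------------------------------------------------
# imaging
# --------------------------------------------------------------------------


@dataclass
class ImagePatch:
    pixels: np.ndarray
    pixel_spacing: float = 1.0  # mm / pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


def _poly_design(shape: tuple[int, int], order: int) -> np.ndarray:
    """Columns x^i * y^j for i + j <= order, coordinates scaled to [-1, 1]."""
    h, w = shape
    y = np.linspace(-1, 1, h)[:, None] * np.ones((1, w))
    x = np.ones((h, 1)) * np.linspace(-1, 1, w)[None, :]
    cols = [
        (x**i * y**j).ravel()
        for total in range(order + 1)
        for i in range(total + 1)
        for j in [total - i]
    ]
    return np.stack(cols, axis=1)


def fit_bias_field(patch: ImagePatch, order: int = 2) -> np.ndarray:
    """Least-squares polynomial fit to log-intensity; returns the log-field."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    pix = patch.pixels
    if np.any(pix <= 0):
        pix = pix - pix.min() + 1e-6
    logi = np.log(pix)
    A = _poly_design(pix.shape, order)
    coef, *_ = np.linalg.lstsq(A, logi.ravel(), rcond=None)
    return (A @ coef).reshape(pix.shape)


def correct_bias_field(patch: ImagePatch, order: int = 2) -> ImagePatch:
    """Remove the fitted smooth field in the log domain, preserving the
    mean log-brightness: out = exp(log I - field + mean(field))."""
    pix = patch.pixels
    if np.any(pix <= 0):
        pix = pix - pix.min() + 1e-6
    field = fit_bias_field(ImagePatch(pix, patch.pixel_spacing), order)
    corrected = np.exp(np.log(pix) - field + field.mean())
    return ImagePatch(corrected, patch.pixel_spacing)


def extract_roi(patch: ImagePatch, mask: np.ndarray, margin: int = 0) -> ImagePatch:
    """Crop to the mask's bounding box dilated by ``margin`` pixels.

    0-based, half-open boxes [r0, r1) x [c0, c1), clipped to the image.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != patch.pixels.shape:
        raise ValueError("mask shape must match patch shape")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask: no lesion to extract")
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + 1 + margin, patch.pixels.shape[0])
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + 1 + margin, patch.pixels.shape[1])
    return ImagePatch(patch.pixels[r0:r1, c0:c1], patch.pixel_spacing)


def harmonize(patches: Sequence[ImagePatch], target_spacing: float = 1.0) -> list[ImagePatch]:
    """Bilinear resample to a common spacing, then per-patch z-score.

    A zero-variance patch maps to all zeros rather than dividing by zero.
    """
    out = []
    for p in patches:
        factor = p.pixel_spacing / target_spacing
        pix = p.pixels if abs(factor - 1.0) < 1e-12 else ndimage.zoom(p.pixels, factor, order=1)
        sd = pix.std()
        # resampling a constant patch can leave femto-scale jitter; treat it
        # as zero variance rather than amplifying it through the z-score
        if sd <= 1e-12 * max(1.0, np.abs(pix).max()):
            pix = np.zeros_like(pix)
        else:
            pix = (pix - pix.mean()) / sd
        out.append(ImagePatch(pix, target_spacing))
    return out


RADIOMIC_NAMES = (
    "intensity_mean",
    "intensity_sd",
    "intensity_skewness",
    "intensity_kurtosis",
    "area",
    "perimeter",
    "circularity",
    "glcm_contrast",
    "glcm_homogeneity",
    "glcm_energy",
)


@dataclass
class RadiomicVector:
    values: np.ndarray  # length 10, ordered as RADIOMIC_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(RADIOMIC_NAMES),):
            raise ValueError("radiomic vector must have length 10")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("radiomic values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(RADIOMIC_NAMES, self.values.tolist()))


def _glcm_summaries(pix: np.ndarray, mask: np.ndarray, levels: int = 8) -> tuple[float, float, float]:
    """Contrast/homogeneity/energy from an 8-level, distance-1, 0-degree
    co-occurrence matrix restricted to pixel pairs inside the mask."""
    vals = pix[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        quant = np.zeros_like(pix, dtype=int)
    else:
        quant = np.clip(((pix - lo) / (hi - lo) * levels).astype(int), 0, levels - 1)
    left = mask[:, :-1] & mask[:, 1:]
    i = quant[:, :-1][left]
    j = quant[:, 1:][left]
    glcm = np.zeros((levels, levels))
    np.add.at(glcm, (i, j), 1.0)
    if glcm.sum() == 0:  # mask with no horizontal neighbour pairs
        return 0.0, 1.0, 1.0
    p = glcm / glcm.sum()
    ii, jj = np.mgrid[0:levels, 0:levels]
    contrast = float(np.sum(p * (ii - jj) ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    energy = float(np.sum(p**2))
    return contrast, homogeneity, energy


def radiomic_descriptors(patch: ImagePatch, mask: np.ndarray) -> RadiomicVector:
    """Fixed 10-descriptor vector over the masked region.

    Shape terms use physical units: area = pixel count * spacing^2,
    perimeter = weighted boundary length * spacing (the standard estimator;
    a raw boundary-edge count overshoots curved outlines so badly that a
    disc's circularity 4*pi*A/P^2 would land near 0.6 instead of 1),
    circularity = 4*pi*area / perimeter^2.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != patch.pixels.shape:
        raise ValueError("mask shape must match patch shape")
    if not mask.any():
        raise ValueError("empty mask: no region to describe")
    vals = patch.pixels[mask]
    spacing = patch.pixel_spacing
    sd = float(vals.std())
    skewness = 0.0 if sd == 0 else float(skew(vals))
    kurt = 0.0 if sd == 0 else float(kurtosis(vals))  # Fisher (normal -> 0)
    area = float(mask.sum()) * spacing**2
    perim = float(_weighted_perimeter(mask, neighborhood=4)) * spacing
    circ = 0.0 if perim == 0 else float(4.0 * np.pi * area / perim**2)
    contrast, homog, energy = _glcm_summaries(patch.pixels, mask)
    return RadiomicVector(
        np.array([vals.mean(), sd, skewness, kurt, area, perim, circ, contrast, homog, energy])
    )


# --------------------------------------------------------------------------
# genomics
# --------------------------------------------------------------------------


@dataclass
class GenomicMatrix:
    """Genes x samples expression matrix with a forward-only stage tag."""

    values: np.ndarray  # (genes, samples), NaN marks missing
    gene_lengths_kb: np.ndarray  # (genes,)
    stage: str = "raw"
    sample_ids: list[str] | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_lengths_kb = np.asarray(self.gene_lengths_kb, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (genes x samples)")
        if self.gene_lengths_kb.shape != (self.values.shape[0],):
            raise ValueError("gene_lengths_kb must match the gene count")
        if np.any(self.gene_lengths_kb <= 0):
            raise ValueError("gene lengths must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def _require_stage(self, stage: str, op: str) -> None:
        if self.stage != stage:
            raise ValueError(f"{op} requires stage {stage!r}, matrix is {self.stage!r}")

    # ---- CSV round trip (genes x samples; separate 2-column lengths file) ----

    def to_csv(self, values_path, lengths_path) -> None:
        import pandas as pd

        genes = self.gene_ids or [f"g{i + 1:04d}" for i in range(self.values.shape[0])]
        samples = self.sample_ids or [f"s{j + 1:04d}" for j in range(self.values.shape[1])]
        pd.DataFrame(self.values, index=genes, columns=samples).to_csv(
            values_path, index_label="gene_id"
        )
        pd.DataFrame({"gene_id": genes, "length_kb": self.gene_lengths_kb}).to_csv(
            lengths_path, index=False
        )

    @classmethod
    def from_csv(cls, values_path, lengths_path, stage: str = "raw") -> "GenomicMatrix":
        import pandas as pd

        df = pd.read_csv(values_path, index_col="gene_id")
        lengths = pd.read_csv(lengths_path).set_index("gene_id")
        return cls(
            values=df.to_numpy(float),
            gene_lengths_kb=lengths.loc[df.index, "length_kb"].to_numpy(float),
            stage=stage,
            sample_ids=list(df.columns),
            gene_ids=list(df.index),
        )


def normalize_expression(m: GenomicMatrix, method: str = "TPM") -> GenomicMatrix:
    """TPM or FPKM, then log2(1 + x).

    TPM: per-sample length-normalized rates rescaled to sum 1e6.
    FPKM: counts * 1e9 / (length_bp * library_size).
    """
    m._require_stage("raw", "normalize_expression")
    counts = m.values
    if np.any(np.nan_to_num(counts) < 0):
        raise ValueError("raw counts must be nonnegative")
    libsize = np.nansum(counts, axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        name = m.sample_ids[zero[0]] if m.sample_ids else f"sample {zero[0]}"
        raise ValueError(f"zero library size for {name}")
    if method.upper() == "TPM":
        rate = counts / m.gene_lengths_kb[:, None]
        norm = rate / np.nansum(rate, axis=0) * 1e6
    elif method.upper() == "FPKM":
        norm = counts * 1e9 / (m.gene_lengths_kb[:, None] * 1000.0 * libsize)
    else:
        raise ValueError(f"unknown method {method!r}")
    return replace(m, values=np.log2(1.0 + norm), stage="normalized")


def impute_knn(m: GenomicMatrix, k: int = 5) -> GenomicMatrix:
    """Fill each missing cell with the gene's mean over the k nearest samples.

    Distance between two samples is plain Euclidean over the genes both
    observe; neighbours are ranked among samples that observe the target
    gene, ties broken by sample order.
    """
    m._require_stage("normalized", "impute_knn")
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.values.copy()
    observed = ~np.isnan(X)
    never = np.flatnonzero(~observed.any(axis=1))
    if never.size:
        name = m.gene_ids[never[0]] if m.gene_ids else f"gene {never[0]}"
        raise ValueError(f"{name} is missing in every sample; cannot impute")
    n_samples = X.shape[1]
    if not np.isnan(X).any():
        return replace(m, stage="imputed")

    # pairwise sample distances over co-observed genes
    dist = np.zeros((n_samples, n_samples))
    for a in range(n_samples):
        for b in range(a + 1, n_samples):
            co = observed[:, a] & observed[:, b]
            if co.any():
                d = float(np.sqrt(np.sum((X[co, a] - X[co, b]) ** 2)))
            else:
                d = np.inf
            dist[a, b] = dist[b, a] = d

    filled = X.copy()
    for g, s in zip(*np.where(~observed)):
        donors = np.flatnonzero(observed[g])  # sample order = tie-break order
        order = np.argsort(dist[s, donors], kind="stable")
        chosen = donors[order[:k]]
        filled[g, s] = X[g, chosen].mean()
    return replace(m, values=filled, stage="imputed")


@dataclass
class StandardizeStats:
    """Training-split statistics reused on held-out samples (leakage guard)."""

    keep: np.ndarray  # indices of retained genes
    mean: np.ndarray
    sd: np.ndarray


def filter_and_standardize(
    m: GenomicMatrix,
    var_quantile: float = 0.05,
    stats: StandardizeStats | None = None,
) -> tuple[GenomicMatrix, StandardizeStats]:
    """Drop low-variance genes and z-score the rest.

    Without ``stats`` the threshold (the ``var_quantile`` quantile of gene
    variances), the retained-gene set, and the mean/sd are all computed from
    this matrix — the training split; pass the returned stats to transform
    validation/test samples with the same parameters.
    """
    m._require_stage("imputed", "filter_and_standardize")
    if stats is None:
        var = m.values.var(axis=1)
        thresh = float(np.quantile(var, var_quantile)) if var_quantile > 0 else 0.0
        keep = np.flatnonzero((var > 0) & (var >= thresh))
        if keep.size == 0:
            raise ValueError("variance filter removed every gene")
        mean = m.values[keep].mean(axis=1)
        sd = m.values[keep].std(axis=1)
        stats = StandardizeStats(keep=keep, mean=mean, sd=sd)
    z = (m.values[stats.keep] - stats.mean[:, None]) / stats.sd[:, None]
    out = replace(
        m,
        values=z,
        gene_lengths_kb=m.gene_lengths_kb[stats.keep],
        stage="standardized",
        gene_ids=[m.gene_ids[i] for i in stats.keep] if m.gene_ids else None,
    )
    return out, stats
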