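"""Detected-gene filtering, normalization, VST, z-scores and PCA.

Conventions:

* Detection filter: a gene is "detected" with at least ``min_count`` reads in
  at least ``min_samples`` samples (defaults 2 and 2).
* Size factors: median-of-ratios over genes with all-positive counts,
  rescaled so the factors have geometric mean 1.
* VST: shifted log2 of size-factor-normalized counts.  This is not the
  fitted-dispersion transform of the reference DE packages; its contract here
  is the variance-stabilization property (per-gene SD approximately
  independent of mean on NB data), which the tests check directly.
* PCA: on the sample × gene matrix after centering genes, no gene scaling
  (the VST already equalizes variances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .core_io import CountExperiment, ValidationError


@dataclass
class NormalizedMatrix:
    """A real-valued gene × sample matrix in stated units."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    kind: str  # one of {"vst", "zscore", "tpm", "cpm"}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.genes, columns=self.samples)
        df.index.name = "gene"
        return df


def filter_detected(experiment: CountExperiment, min_count: int = 2,
                    min_samples: int = 2) -> CountExperiment:
    """Keep genes with >= min_count reads in >= min_samples samples."""
    keep = (experiment.counts >= min_count).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValidationError(
            "no gene passes the detection filter; review min_count/min_samples")
    return experiment.subset_genes(keep)


def size_factors(experiment: CountExperiment) -> pd.Series:
    """Median-of-ratios library size factors, geometric mean 1.

    Uses only genes expressed (count > 0) in every sample as the reference
    set; the ratio of each sample to the per-gene geometric mean is summarized
    by its median.
    """
    counts = experiment.counts.astype(float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no gene has nonzero counts in all samples; cannot form the "
            "median-of-ratios reference (consider a pseudo-reference fallback)")
    ref = counts[all_pos]
    log_geo_mean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.log(ref) - log_geo_mean
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=experiment.samples, name="size_factor")


def tpm(experiment: CountExperiment, gene_lengths: pd.Series) -> NormalizedMatrix:
    """Transcripts per million given per-gene lengths (bp); columns sum to 1e6."""
    missing = [g for g in experiment.genes if g not in gene_lengths.index]
    if missing:
        raise ValidationError(f"missing gene lengths for: {missing[:10]}")
    lengths = gene_lengths.loc[experiment.genes].to_numpy(float)
    rate = experiment.counts / lengths[:, None]
    denom = rate.sum(axis=0, keepdims=True)
    denom[denom == 0] = np.nan
    values = 1e6 * rate / denom
    return NormalizedMatrix(experiment.genes, experiment.samples, values, "tpm")


def vst(experiment: CountExperiment, sf: pd.Series,
        pseudocount: float = 1.0) -> NormalizedMatrix:
    """Shifted-log variance-stabilizing transform: log2(count / sf + c)."""
    factors = sf.loc[experiment.samples].to_numpy(float)
    if (factors <= 0).any():
        raise ValidationError("size factors must be positive")
    values = np.log2(experiment.counts / factors[None, :] + pseudocount)
    return NormalizedMatrix(experiment.genes, experiment.samples, values, "vst")


def zscore_rows(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Row-standardize: mean 0, sample SD 1 (ddof=1); constant rows dropped."""
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant gene(s) before "
                      "z-scoring", stacklevel=2)
    values = values[keep]
    mean = values.mean(axis=1, keepdims=True)
    z = (values - mean) / values.std(axis=1, ddof=1, keepdims=True)
    genes = [g for g, k in zip(matrix.genes, keep) if k]
    return NormalizedMatrix(genes, matrix.samples, z, "zscore")


def pca(matrix: NormalizedMatrix, n_components: int = 3
        ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples in gene space (genes centered, not scaled).

    Returns per-sample component scores and the variance fraction of each
    returned component (fractions of the *total* variance).
    """
    n_samples = len(matrix.samples)
    if n_samples < n_components:
        raise ValidationError(
            f"n_components={n_components} exceeds {n_samples} samples")
    X = matrix.values.T  # samples x genes
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X - X.mean(axis=0, keepdims=True))
    frame = pd.DataFrame(
        scores, index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)])
    return frame, model.explained_variance_ratio_
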