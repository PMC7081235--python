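"""Two-group negative-binomial differential expression with BH correction.

The model per gene: counts ``y_i ~ NB(mu_i, alpha)`` with
``mu_i = s_i * exp(beta_g(i))`` where ``s_i`` is the sample's size factor and
``beta`` has one level per contrast group (log link, offset ``log s_i``).
Because the two-group design is saturated, the GLM splits into two
independent one-parameter MLE problems; the Wald statistic for the log
fold-change is

    z = (beta_B - beta_A) / sqrt(1/I_A + 1/I_B),

with ``I_g = sum_i mu_i / (1 + alpha * mu_i)`` the Fisher information of each
group's log-mean, referred to the standard normal (two-sided).  Fitting
groups independently makes swapping contrast sides an exact sign flip.

Dispersions are method-of-moments estimates on normalized counts, shrunk
50/50 in log space toward a ``a0 + a1/mu`` trend fitted across genes.

DEG calls use the thresholds adjusted p <= 0.01 and |log2FC| >= 0.5,
boundary inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountExperiment, GeneSet, ValidationError

LN2 = float(np.log(2.0))

DEFAULT_ALPHA = 0.01   # BH-adjusted p threshold
DEFAULT_LFC = 0.5      # |log2 fold-change| threshold

DISPERSION_FLOOR = 1e-4
DISPERSION_CEIL = 10.0


@dataclass(frozen=True)
class Contrast:
    """Two disjoint sample selections; B is tested over A.

    Each side is a (genotype, stress, timepoint) triple; ``None`` entries
    match anything.
    """

    group_a: tuple[str | None, str | None, str | None]
    group_b: tuple[str | None, str | None, str | None]
    label: str = ""

    def masks(self, experiment: CountExperiment) -> tuple[np.ndarray, np.ndarray]:
        mask_a = experiment.sample_mask(*self.group_a)
        mask_b = experiment.sample_mask(*self.group_b)
        if not mask_a.any() or not mask_b.any():
            raise ValidationError(
                f"contrast {self.label or self.group_a}: empty group")
        if (mask_a & mask_b).any():
            raise ValidationError(
                f"contrast {self.label or self.group_a}: groups overlap")
        return mask_a, mask_b

    def swapped(self) -> "Contrast":
        return Contrast(self.group_b, self.group_a,
                        label=f"{self.label}_swapped" if self.label else "")


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(experiment: CountExperiment, sf: pd.Series) -> pd.Series:
    """Per-gene NB dispersion on normalized counts, trend-shrunk.

    Raw estimate: ``alpha = (s^2 - mu) / mu^2`` with ``s^2`` the pooled
    within-condition variance (conditions = genotype x stress x timepoint
    cells) and ``mu`` the overall mean of normalized counts.  Raw values are
    shrunk halfway (in log space) toward the trend ``a0 + a1 / mu`` fitted
    across genes, then clipped to [1e-4, 10].  All-zero genes get the trend
    value at the smallest observed mean.
    """
    counts = experiment.counts.astype(float)
    factors = sf.loc[experiment.samples].to_numpy(float)
    y = counts / factors[None, :]

    cells = experiment.design.groupby(
        ["genotype", "stress", "timepoint"], sort=False).indices
    for key, idx in cells.items():
        if len(idx) < 2:
            raise ValidationError(f"design cell {key} has <2 replicates")

    mu = y.mean(axis=1)
    n_total = y.shape[1]
    ss_within = np.zeros(y.shape[0])
    for idx in cells.values():
        sub = y[:, idx]
        ss_within += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss_within / max(n_total - len(cells), 1)

    expressed = mu > 0
    raw = np.full(y.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw[expressed] = (s2[expressed] - mu[expressed]) / mu[expressed] ** 2
    raw = np.maximum(raw, DISPERSION_FLOOR)

    # trend a0 + a1/mu by least squares over genes with informative estimates
    fit_mask = expressed & np.isfinite(raw) & (raw > DISPERSION_FLOOR)
    if fit_mask.sum() >= 10:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask]])
        coef, *_ = np.linalg.lstsq(X, raw[fit_mask], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:  # too few genes to fit a trend: flat fallback at the median
        a0 = float(np.nanmedian(raw[expressed])) if expressed.any() else 0.1
        a1 = 0.0

    min_mu = mu[expressed].min() if expressed.any() else 1.0
    mu_for_trend = np.where(expressed, mu, min_mu)
    trend = np.clip(a0 + a1 / mu_for_trend, DISPERSION_FLOOR, DISPERSION_CEIL)

    alpha = np.exp(0.5 * np.log(np.where(expressed, raw, trend))
                   + 0.5 * np.log(trend))
    alpha = np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CEIL)
    return pd.Series(alpha, index=experiment.genes, name="dispersion")


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

_BETA_MIN, _BETA_MAX = np.log(1e-8), np.log(1e12)


def _fit_group_log_means(y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                         max_iter: int = 100, tol: float = 1e-12
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Newton solve of the one-group NB log-mean MLE with offsets.

    Solves ``sum_i (y_i - mu_i) / (1 + alpha*mu_i) = 0`` with
    ``mu_i = s_i * exp(beta)`` per gene.  Genes whose group total is zero get
    a half-count pseudo-fit (deterministic, keeps the Wald statistic finite).
    Returns (beta, fisher_information).
    """
    y = np.asarray(y, float)
    total = y.sum(axis=1)
    s_total = s.sum()
    beta = np.log(np.maximum(total, 0.5) / s_total)
    for _ in range(max_iter):
        mu = s[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        f = ((y - mu) / denom).sum(axis=1)
        fprime = -(mu * (1.0 + alpha[:, None] * y) / denom ** 2).sum(axis=1)
        step = f / np.where(fprime == 0, -1.0, fprime)
        beta_new = np.clip(beta - step, _BETA_MIN, _BETA_MAX)
        moved = np.abs(beta_new - beta)
        beta = beta_new
        if moved.max(initial=0.0) < tol:
            break
    mu = s[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, info


def nb_wald(experiment: CountExperiment, contrast: Contrast,
            dispersions: pd.Series, sf: pd.Series) -> pd.DataFrame:
    """Per-gene NB Wald test of group B over group A.

    Returns a table with columns gene / base_mean / log2fc / se / p.  Genes
    with all-zero counts in both groups get log2fc 0 and p 1.
    """
    mask_a, mask_b = contrast.masks(experiment)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValidationError(
            f"contrast {contrast.label}: need >=2 replicates per side")
    factors = sf.loc[experiment.samples].to_numpy(float)
    alpha = dispersions.loc[experiment.genes].to_numpy(float)
    counts = experiment.counts

    ya, sa = counts[:, mask_a].astype(float), factors[mask_a]
    yb, sb = counts[:, mask_b].astype(float), factors[mask_b]

    beta_a, info_a = _fit_group_log_means(ya, sa, alpha)
    beta_b, info_b = _fit_group_log_means(yb, sb, alpha)

    with np.errstate(divide="ignore"):
        var = 1.0 / info_a + 1.0 / info_b
    se_ln = np.sqrt(var)
    diff = beta_b - beta_a
    z = np.where(se_ln > 0, diff / se_ln, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = (ya.sum(axis=1) == 0) & (yb.sum(axis=1) == 0)
    log2fc = diff / LN2
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0

    norm = counts / factors[None, :]
    base_mean = norm[:, mask_a | mask_b].mean(axis=1)

    return pd.DataFrame({
        "gene": experiment.genes,
        "base_mean": base_mean,
        "log2fc": log2fc,
        "se": se_ln / LN2,
        "p": p,
    })


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    arr = np.asarray(p, float)
    if np.isnan(arr).any():
        raise ValidationError("NaN p-values passed to bh_adjust")
    if arr.size == 0:
        return arr.copy()
    if (arr < 0).any() or (arr > 1).any():
        raise ValidationError("p-values outside [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def call_degs(results: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
              lfc: float = DEFAULT_LFC, label: str = ""
              ) -> tuple[pd.DataFrame, GeneSet, GeneSet]:
    """Apply the DEG thresholds (boundary inclusive) and build up/down sets.

    Adds ``padj`` (if absent) and ``deg_call`` columns; returns the table and
    the up- and down-regulated GeneSets.
    """
    out = results.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["p"].to_numpy())
    sig = out["padj"] <= alpha
    up = sig & (out["log2fc"] >= lfc)
    down = sig & (out["log2fc"] <= -lfc)
    out["deg_call"] = np.select([up, down], ["up", "down"], default="ns")
    up_set = GeneSet(name=f"{label}_up" if label else "up",
                     genes=frozenset(out.loc[up, "gene"]), direction="up")
    down_set = GeneSet(name=f"{label}_down" if label else "down",
                       genes=frozenset(out.loc[down, "gene"]), direction="down")
    return out, up_set, down_set
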