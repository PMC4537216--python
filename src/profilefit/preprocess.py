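"""Filtering and normalization ladder from raw counts to fit-ready profiles.

The fitting path mirrors the study design for both RNA-seq and
spectral-count data: drop molecules with low total counts, normalize each
sample to its read depth, keep molecules with at least a 1.5-fold change,
then max-normalize each profile.  The RNA significance path instead uses
median-of-ratios size factors and a per-time-point test against the first
sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProfileMatrix",
    "AveragedProfile",
    "filter_low_counts",
    "depth_normalize",
    "size_factors_median_ratio",
    "fold_change_filter",
    "significance_filter_rna",
    "average_replicates",
    "max_normalize",
    "length_normalize",
]


@dataclass
class ProfileMatrix:
    """Gene x time x replicate count (or level) matrix with gene metadata.

    ``meta`` is indexed by gene and may carry ``length`` (bp) and
    ``rna_class`` columns.
    """

    counts: np.ndarray  # (G, T, R), nonnegative
    genes: list[str]
    times: np.ndarray  # hours, strictly increasing
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be gene x time x replicate")
        if self.counts.shape[0] != len(self.genes):
            raise ValueError("gene axis does not match gene names")
        if self.counts.shape[1] != self.times.size:
            raise ValueError("time axis does not match the time grid")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[2]

    def subset(self, mask: np.ndarray) -> "ProfileMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        genes = [self.genes[i] for i in idx]
        meta = self.meta.loc[genes] if self.meta is not None else None
        return ProfileMatrix(self.counts[idx], genes, self.times, meta)

    def flat_samples(self) -> tuple[np.ndarray, list[str]]:
        """Collapse (time, replicate) to a gene x sample 2-D matrix."""
        g, t, r = self.counts.shape
        mat = self.counts.reshape(g, t * r)
        names = [f"t{self.times[j]:g}_r{k + 1}" for j in range(t) for k in range(r)]
        return mat, names


@dataclass
class AveragedProfile:
    """Replicate-averaged profile d with per-time replicate SD sigma."""

    gene: str
    d: np.ndarray
    sigma: np.ndarray
    times: np.ndarray
    normalization: str = "depth"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not (len(self.d) == len(self.sigma) == len(self.times)):
            raise ValueError("d, sigma and times must have equal length")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")


def filter_low_counts(matrix: ProfileMatrix, min_total: float = 10) -> ProfileMatrix:
    """Drop genes whose total count over all times and replicates is below
    ``min_total`` (boundary retained)."""
    totals = matrix.counts.sum(axis=(1, 2))
    mask = totals >= min_total
    if not mask.any():
        warnings.warn("all genes fall below the low-count threshold", stacklevel=2)
    return matrix.subset(mask)


def depth_normalize(matrix: ProfileMatrix) -> ProfileMatrix:
    """Divide every sample (time x replicate) by its total count so each
    sample's values sum to one."""
    totals = matrix.counts.sum(axis=0)  # (T, R)
    if np.any(totals <= 0):
        j, k = np.argwhere(totals <= 0)[0]
        raise ValueError(
            f"sample at time {matrix.times[j]:g} h, replicate {k + 1} has zero total count"
        )
    return replace(matrix, counts=matrix.counts / totals[None, :, :])


def size_factors_median_ratio(counts: np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Median-of-ratios size factors for a gene x sample count matrix.

    Per sample, the factor is the median over reference genes of
    ``count / geometric-mean-across-samples``; reference genes are those
    with nonzero counts in every sample.  A ``pseudocount`` can rescue
    matrices without any all-nonzero gene.
    """
    counts = np.asarray(counts, dtype=float) + pseudocount
    if counts.ndim != 2:
        raise ValueError("expected a 2-D gene x sample matrix")
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; "
            "pass pseudocount > 0 to include all genes"
        )
    ref_counts = counts[ref]
    geomean = np.exp(np.mean(np.log(ref_counts), axis=1))
    return np.median(ref_counts / geomean[:, None], axis=0)


def fold_change_filter(
    matrix: ProfileMatrix, threshold: float = 1.5, floor: float = 1e-9
) -> tuple[ProfileMatrix, np.ndarray]:
    """Keep genes whose replicate-mean profile spans at least ``threshold``
    fold between its maximum and (floored) minimum over time."""
    mean_levels = matrix.counts.mean(axis=2)  # (G, T)
    lo = np.maximum(mean_levels.min(axis=1), floor)
    fc = mean_levels.max(axis=1) / lo
    mask = fc >= threshold
    return matrix.subset(mask), mask


def significance_filter_rna(
    matrix: ProfileMatrix,
    alpha: float = 0.05,
    baseline_index: int = 0,
    pseudocount: float = 0.5,
    bh: bool = False,
    size_factor_pseudocount: float = 0.0,
) -> tuple[ProfileMatrix, np.ndarray, np.ndarray]:
    """Keep genes that differ significantly from the first time point at
    one or more later time points.

    Counts are scaled by median-of-ratios size factors; each later time is
    compared against the baseline with a Welch t-test on
    ``log(normalized count + pseudocount)`` across replicates.  A gene is
    retained if any comparison has p < ``alpha`` (optionally BH-adjusted
    across all gene x time comparisons first).

    Returns the filtered matrix, the retention mask and the p-value matrix
    (genes x non-baseline times).
    """
    if matrix.n_replicates < 2:
        raise ValueError("need >=2 replicates to estimate within-time variance")
    flat, _ = matrix.flat_samples()
    try:
        factors = size_factors_median_ratio(flat, pseudocount=size_factor_pseudocount)
    except ValueError:
        factors = size_factors_median_ratio(flat, pseudocount=0.5)
    g, t, r = matrix.counts.shape
    norm = (flat / factors[None, :]).reshape(g, t, r)
    logn = np.log(norm + pseudocount)

    base = logn[:, baseline_index, :]
    other = [j for j in range(t) if j != baseline_index]
    pvals = np.empty((g, len(other)))
    for col, j in enumerate(other):
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(logn[:, j, :], base, axis=1, equal_var=False)
        p = np.asarray(res.pvalue)
        # identical values in both groups give 0/0 -> no evidence of change
        pvals[:, col] = np.where(np.isnan(p), 1.0, p)

    if bh:
        from statsmodels.stats.multitest import multipletests

        flat_p = pvals.ravel()
        q = multipletests(flat_p, method="fdr_bh")[1].reshape(pvals.shape)
        mask = (q < alpha).any(axis=1)
    else:
        mask = (pvals < alpha).any(axis=1)
    return matrix.subset(mask), mask, pvals


def average_replicates(
    matrix: ProfileMatrix, sigma_floor: str | float = "auto"
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate mean ``d`` and sample SD ``sigma`` per gene and time.

    The SD is floored because the fit cost divides by sigma^2 and
    replicates can coincide: with ``sigma_floor="auto"`` the floor is
    ``max(1e-6, 0.01 * mean_t(d))`` per gene; a float applies a fixed
    absolute floor.
    """
    if matrix.n_replicates < 2:
        raise ValueError("need >=2 replicates to compute a standard deviation")
    d = matrix.counts.mean(axis=2)
    sigma = matrix.counts.std(axis=2, ddof=1)
    if sigma_floor == "auto":
        floor = np.maximum(1e-6, 0.01 * d.mean(axis=1))[:, None]
    else:
        floor = float(sigma_floor)
    return d, np.maximum(sigma, floor)


def max_normalize(profile: np.ndarray, axis: int = -1) -> np.ndarray:
    """Scale each profile so its maximum over time is exactly 1."""
    profile = np.asarray(profile, dtype=float)
    peak = profile.max(axis=axis, keepdims=True)
    if np.any(peak <= 0):
        raise ValueError("cannot max-normalize an all-zero profile")
    return profile / peak


def length_normalize(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Counts per base: divide each gene's counts by its length in bp."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    shape = (-1,) + (1,) * (counts.ndim - 1)
    return counts / lengths.reshape(shape)
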