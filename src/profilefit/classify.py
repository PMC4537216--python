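"""Behavioral classification of fitted profiles and gene-set analysis.

A fitted profile is sorted by its amplitude changes: up-regulated genes
increase at some point and never significantly decrease later,
down-regulated genes are the mirror image, transient genes do one then
the other, and genes whose changes never exceed the significance margin
delta are flat.  A gene's call aggregates the calls of all ensemble
members that fit the data well; if they do not agree strongly enough the
gene is labeled ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profile_model import FitEnsemble, PiecewiseParams, good_fit_mask

__all__ = [
    "CATEGORIES",
    "BehaviorCall",
    "call_member_behavior",
    "call_gene_behavior",
    "enrich_categories",
    "pathway_average",
]

CATEGORIES = ("up", "down", "transient_up", "transient_down", "flat", "ambiguous")


def _member_calls(amplitudes: np.ndarray, delta: float) -> np.ndarray:
    """Vectorized category call from an (M, 3) amplitude array.

    With D12 = A2 - A1 and D23 = A3 - A2: changes beyond +-delta are
    significant; increase-then-decrease is transient_up, the mirror is
    transient_down, significant changes in one direction only are
    up/down, and no significant change at all is flat.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    a = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    d12 = a[:, 1] - a[:, 0]
    d23 = a[:, 2] - a[:, 1]
    inc1, dec1 = d12 > delta, d12 < -delta
    inc2, dec2 = d23 > delta, d23 < -delta
    out = np.full(len(a), "flat", dtype=object)
    out[(inc1 | inc2) & ~(dec1 | dec2)] = "up"
    out[(dec1 | dec2) & ~(inc1 | inc2)] = "down"
    out[inc1 & dec2] = "transient_up"
    out[dec1 & inc2] = "transient_down"
    return out


def call_member_behavior(params: PiecewiseParams, delta: float) -> str:
    """Category of a single parameter set (see :func:`_member_calls`)."""
    return str(_member_calls(params.as_array()[None, 4:7], delta)[0])


@dataclass(frozen=True)
class BehaviorCall:
    """Ensemble-aggregated behavioral call for one gene."""

    category: str
    agreement: float  # fraction of good-fit members voting for category
    delta: float
    n_good: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.agreement <= 1.0:
            raise ValueError("agreement must lie in [0, 1]")


def call_gene_behavior(
    ensemble: FitEnsemble,
    d: np.ndarray,
    sigma: np.ndarray,
    delta: float | None = None,
    agreement_min: float = 0.9,
) -> BehaviorCall:
    """Majority category among good-fit ensemble members.

    ``delta`` defaults to the median replicate SD of the profile, tying
    "significant change" to the measured noise on the same normalized
    scale.  The gene is ambiguous when no member fits well or when the
    majority falls below ``agreement_min``.
    """
    if delta is None:
        delta = float(np.median(sigma))
    mask = good_fit_mask(ensemble, d, sigma)
    n_good = int(mask.sum())
    if n_good == 0:
        return BehaviorCall("ambiguous", 0.0, delta, 0)
    calls = _member_calls(ensemble.params[mask][:, 4:7], delta)
    cats, counts = np.unique(calls, return_counts=True)
    top = int(np.argmax(counts))
    agreement = counts[top] / n_good
    category = cats[top] if agreement >= agreement_min else "ambiguous"
    return BehaviorCall(str(category), float(agreement), float(delta), n_good)


def enrich_categories(
    calls: pd.DataFrame,
    gene_sets: dict[str, set[str] | list[str]],
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in each category.

    ``calls`` needs columns ``gene`` and ``category``.  The universe
    defaults to all genes in ``calls`` (i.e. everything that survived
    preprocessing, not the whole genome).  q-values are BH-adjusted
    across sets within each category.
    """
    from statsmodels.stats.multitest import multipletests

    if universe is None:
        universe = list(calls["gene"])
    universe_set = set(universe)
    m_total = len(universe_set)
    rows = []
    for category, sub in calls.groupby("category"):
        cat_genes = set(sub["gene"]) & universe_set
        for set_name, members in gene_sets.items():
            members_in = set(members) & universe_set
            overlap = len(cat_genes & members_in)
            p = float(
                stats.hypergeom.sf(overlap - 1, m_total, len(members_in), len(cat_genes))
            )
            rows.append(
                {
                    "category": category,
                    "set": set_name,
                    "overlap": overlap,
                    "category_size": len(cat_genes),
                    "set_size": len(members_in),
                    "universe_size": m_total,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    for category in table["category"].unique():
        idx = table["category"] == category
        table.loc[idx, "q"] = multipletests(table.loc[idx, "p"], method="fdr_bh")[1]
    return table


def pathway_average(
    profiles: pd.DataFrame,
    gene_sets: dict[str, set[str] | list[str]],
    flat_threshold: float = 0.2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Time-wise mean profile per gene set, with a flatness flag.

    ``profiles`` is a gene x time frame of max-normalized levels.  Sets
    whose members respond incoherently average out to a flat curve; a set
    is flagged flat when its mean profile's range falls below
    ``flat_threshold`` (on the normalized 0-1 scale) and is typically
    filtered from displays.
    """
    means = {}
    for name, members in gene_sets.items():
        hit = profiles.index.intersection(list(members))
        if len(hit) == 0:
            continue
        means[name] = profiles.loc[hit].mean(axis=0)
    mean_df = pd.DataFrame(means).T
    if mean_df.empty:
        return mean_df, pd.Series(dtype=bool)
    flat = (mean_df.max(axis=1) - mean_df.min(axis=1)) < flat_threshold
    return mean_df, flat
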