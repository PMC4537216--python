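"""Operon co-expression coherence, profile clustering and RNA-class accounting.

Genes in an operon are co-transcribed on one mRNA, so their transcript
profiles should agree almost perfectly while their protein profiles can
diverge through translational and post-translational regulation --
increasingly so the farther apart two coding regions sit on the operon.
This module quantifies that coherence (mean or median pairwise Spearman
correlation within each operon), relates protein pair correlation to
inter-gene distance, clusters max-normalized profiles with K-means, and
tallies per-sample read fractions over RNA classes.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "validate_operon_table",
    "intergene_distance",
    "operon_coherence",
    "distance_vs_correlation",
    "kmeans_profiles",
    "rna_fractions",
]

RNA_CLASSES = ("mRNA", "tRNA", "rRNA", "ncRNA")

OPERON_COLUMNS = ("operon_id", "gene", "start", "end", "strand")


def validate_operon_table(operons: pd.DataFrame) -> pd.DataFrame:
    """Check the BED-like operon table: required columns, 1-based inclusive
    coordinates, members ordered and non-overlapping within each operon."""
    missing = [c for c in OPERON_COLUMNS if c not in operons.columns]
    if missing:
        raise ValueError(f"operon table is missing columns: {missing}")
    if (operons["end"] < operons["start"]).any():
        raise ValueError("operon table has end < start")
    for oid, sub in operons.groupby("operon_id", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(starts[1:] <= ends[:-1]):
            raise ValueError(f"operon {oid}: members overlap or are out of order")
    return operons


def intergene_distance(end_a: int, start_b: int) -> int:
    """Gap in bp between two coding regions (1-based inclusive coordinates);
    overlapping or abutting genes get distance 0."""
    return max(0, int(start_b) - int(end_a) - 1)


def _pairwise_rho(profiles: np.ndarray) -> list[tuple[int, int, float]]:
    out = []
    for i, j in combinations(range(len(profiles)), 2):
        if np.ptp(profiles[i]) == 0 or np.ptp(profiles[j]) == 0:
            rho = float("nan")
        else:
            rho = float(stats.spearmanr(profiles[i], profiles[j]).statistic)
        out.append((i, j, rho))
    return out


def operon_coherence(
    profiles: pd.DataFrame, operons: pd.DataFrame, stat: str = "mean"
) -> pd.DataFrame:
    """Summary of all pairwise Spearman correlations within each operon.

    ``profiles`` is a gene x time frame (RNA or protein).  Operons with
    fewer than two profiled members are skipped and reported with
    ``n_profiled`` but NaN coherence.  ``stat`` selects mean (default) or
    median of the C(n,2) pairwise correlations.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    agg = np.nanmean if stat == "mean" else np.nanmedian
    rows = []
    for oid, sub in operons.groupby("operon_id", sort=False):
        members = [g for g in sub["gene"] if g in profiles.index]
        row = {"operon_id": oid, "n_members": len(sub), "n_profiled": len(members)}
        if len(members) < 2:
            row.update(n_pairs=0, coherence=float("nan"))
        else:
            pairs = _pairwise_rho(profiles.loc[members].to_numpy())
            rhos = np.array([r for _, _, r in pairs])
            summary = float(agg(rhos)) if np.isfinite(rhos).any() else float("nan")
            row.update(n_pairs=len(pairs), coherence=summary)
        rows.append(row)
    return pd.DataFrame(rows)


def distance_vs_correlation(
    protein_profiles: pd.DataFrame,
    operons: pd.DataFrame,
    adjacent_only: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Within-operon protein pair correlations against inter-gene distance.

    Emits one row per profiled gene pair (all pairs by default, optionally
    only adjacent neighbours) with the bp gap between their coding regions
    and the Spearman correlation of their protein profiles.  The trend
    statistic is the Spearman correlation of pair rho against distance
    (negative when nearby genes co-vary more).  Two alternative
    explanations are scored as well: the correlation of a gene's mean
    protein level with its distance from the transcript start and with its
    coding length.
    """
    validate_operon_table(operons)
    pair_rows = []
    level_rows = []
    for oid, sub in operons.groupby("operon_id", sort=False):
        sub = sub.reset_index(drop=True)
        profiled = [
            (i, row) for i, row in sub.iterrows() if row["gene"] in protein_profiles.index
        ]
        tx_start = int(sub.iloc[0]["start"])
        for i, row in profiled:
            level_rows.append(
                {
                    "gene": row["gene"],
                    "dist_from_tx_start": int(row["start"]) - tx_start,
                    "length": int(row["end"]) - int(row["start"]) + 1,
                    "mean_level": float(protein_profiles.loc[row["gene"]].mean()),
                }
            )
        for (i, ra), (j, rb) in combinations(profiled, 2):
            if adjacent_only and j != i + 1:
                continue
            # gap accumulated over every skipped coding region boundary
            dist = int(sub.iloc[j]["start"]) - int(sub.iloc[i]["end"]) - 1
            dist = max(0, dist)
            pa = protein_profiles.loc[ra["gene"]].to_numpy()
            pb = protein_profiles.loc[rb["gene"]].to_numpy()
            if np.ptp(pa) == 0 or np.ptp(pb) == 0:
                rho = float("nan")
            else:
                rho = float(stats.spearmanr(pa, pb).statistic)
            pair_rows.append(
                {
                    "operon_id": oid,
                    "gene_a": ra["gene"],
                    "gene_b": rb["gene"],
                    "distance_bp": dist,
                    "rho": rho,
                }
            )
    pairs = pd.DataFrame(pair_rows)
    levels = pd.DataFrame(level_rows)

    def _safe_spearman(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            return float("nan")
        return float(stats.spearmanr(x[ok], y[ok]).statistic)

    trend = {
        "rho_vs_distance": _safe_spearman(pairs["distance_bp"], pairs["rho"])
        if len(pairs)
        else float("nan"),
        "level_vs_dist_from_start": _safe_spearman(
            levels["dist_from_tx_start"], levels["mean_level"]
        )
        if len(levels)
        else float("nan"),
        "level_vs_length": _safe_spearman(levels["length"], levels["mean_level"])
        if len(levels)
        else float("nan"),
        "n_pairs": len(pairs),
    }
    return pairs, trend


def kmeans_profiles(
    profiles: np.ndarray, k: int, seed: int | None = None, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Euclidean K-means on complete max-normalized profiles.

    Runs ``n_init`` seeded restarts and keeps the one with the lowest
    within-cluster sum of squares.  Centroids are reordered for stable
    heat-map display (by time of maximum, then overall mean) and labels
    remapped accordingly.  Returns (centroids, labels, sse).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be a gene x time matrix")
    if not np.all(np.isfinite(profiles)):
        raise ValueError("profiles must be complete (no missing values)")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of profiles ({len(profiles)})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(profiles)
    centroids = km.cluster_centers_
    order = np.lexsort((centroids.mean(axis=1), centroids.argmax(axis=1)))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return centroids[order], remap[labels], float(km.inertia_)


def rna_fractions(
    counts: pd.DataFrame, rna_class: pd.Series, drop_residual_rrna: bool = False
) -> pd.DataFrame:
    """Per-sample fraction of reads in each RNA class.

    ``counts`` is a gene x sample frame; every gene must carry a class
    label in {mRNA, tRNA, rRNA, ncRNA}.  With ``drop_residual_rrna`` the
    leftover rRNA reads of a depleted library are discarded before the
    remaining classes are renormalized.
    """
    unlabeled = counts.index.difference(rna_class.index)
    if len(unlabeled):
        raise ValueError(f"gene(s) without an RNA class label: {list(unlabeled)[:5]}")
    bad = set(rna_class.loc[counts.index]) - set(RNA_CLASSES)
    if bad:
        raise ValueError(f"unknown RNA class label(s): {sorted(bad)}")
    totals = counts.groupby(rna_class.loc[counts.index]).sum()
    totals = totals.reindex(list(RNA_CLASSES), fill_value=0.0)
    if drop_residual_rrna:
        totals = totals.drop(index="rRNA")
    frac = totals / totals.sum(axis=0)
    return frac.T  # samples x classes
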