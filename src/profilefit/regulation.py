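"""Proportional vs integral mRNA-to-protein regulation.

Protein dynamics dp/dt = k_s * m(t) - k_d * p have two limiting regimes:
fast degradation (protein tracks its transcript, "proportional") and
negligible degradation (protein tracks the running time integral of its
transcript, "integral").  Each gene gets two Spearman correlations over
the time course -- protein vs mRNA (rho_prop) and protein vs the
trapezoidal cumulative integral of mRNA (rho_int) -- and is labeled by
whichever exceeds the threshold (default 0.70); genes exceeding neither
fall in the intermediate regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "RegulationCall",
    "cumulative_integral",
    "regulation_correlations",
    "classify_regulation",
    "regulation_table",
    "crosssection_correlation",
]

REGULATION_LABELS = ("proportional", "integral", "intermediate")


@dataclass(frozen=True)
class RegulationCall:
    """Per-gene dynamic-correlation pair and its regime label."""

    rho_prop: float
    rho_int: float
    label: str
    threshold: float = 0.70

    def __post_init__(self) -> None:
        for rho in (self.rho_prop, self.rho_int):
            if np.isfinite(rho) and not -1.0 - 1e-12 <= rho <= 1.0 + 1e-12:
                raise ValueError("Spearman rho must lie in [-1, 1]")
        if self.label not in REGULATION_LABELS:
            raise ValueError(f"unknown regulation label {self.label!r}")


def cumulative_integral(profile: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Running trapezoidal integral from the first time point.

    M(t_0) = 0 and M(t_j) accumulates trapezoid areas; exact for
    piecewise-linear inputs sampled at their knots.  Works on a single
    profile or a gene x time matrix (integration along the last axis).
    """
    profile = np.asarray(profile, dtype=float)
    times = np.asarray(times, dtype=float)
    if profile.shape[-1] != times.size:
        raise ValueError("profile and time grid lengths differ")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return cumulative_trapezoid(profile, times, axis=-1, initial=0.0)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks for ties; NaN for constant input."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def regulation_correlations(
    protein: np.ndarray, mrna: np.ndarray, times: np.ndarray, min_points: int = 4
) -> tuple[float, float]:
    """(rho_prop, rho_int) for one gene's paired time courses.

    rho_prop ranks protein against mRNA, rho_int against the cumulative
    mRNA integral.  Fewer than ``min_points`` finite pairs, or a constant
    series, yields NaN (the gene is then excluded from histograms).
    """
    protein = np.asarray(protein, dtype=float)
    mrna = np.asarray(mrna, dtype=float)
    if protein.shape != mrna.shape or protein.shape[-1] != times.size:
        raise ValueError("protein and mRNA profiles must share the time grid")
    integral = cumulative_integral(mrna, times)
    ok = np.isfinite(protein) & np.isfinite(mrna)
    if ok.sum() < min_points:
        return float("nan"), float("nan")
    return _spearman(protein[ok], mrna[ok]), _spearman(protein[ok], integral[ok])


def classify_regulation(
    rho_prop: float, rho_int: float, threshold: float = 0.70
) -> RegulationCall:
    """Label a gene from its correlation pair.

    Proportional and integral calls require their rho to exceed the
    threshold; when both do, the larger rho wins (the two regimes are
    nearly mutually exclusive in practice).  Everything else -- including
    genes with undefined correlations -- is intermediate.
    """
    rp = rho_prop if np.isfinite(rho_prop) else -np.inf
    ri = rho_int if np.isfinite(rho_int) else -np.inf
    if rp > threshold and rp >= ri:
        label = "proportional"
    elif ri > threshold and ri > rp:
        label = "integral"
    else:
        label = "intermediate"
    return RegulationCall(float(rho_prop), float(rho_int), label, threshold)


def regulation_table(
    protein: np.ndarray,
    mrna: np.ndarray,
    times: np.ndarray,
    genes: list[str],
    threshold: float = 0.70,
) -> pd.DataFrame:
    """Per-gene regulation calls for matched gene x time matrices."""
    protein = np.atleast_2d(protein)
    mrna = np.atleast_2d(mrna)
    rows = []
    for g, gene in enumerate(genes):
        rp, ri = regulation_correlations(protein[g], mrna[g], times)
        call = classify_regulation(rp, ri, threshold)
        rows.append(
            {"gene": gene, "rho_prop": rp, "rho_int": ri, "label": call.label}
        )
    return pd.DataFrame(rows)


def crosssection_correlation(
    protein_by_gene: pd.Series | dict,
    mrna_by_gene: pd.Series | dict,
    min_genes: int = 10,
) -> tuple[float, int, int]:
    """Spearman correlation across genes of absolute protein vs mRNA level
    at a single time point.

    Inputs map gene -> level (length-normalized mRNA; scaled protein).
    Genes present in only one table are dropped and counted.  Returns
    (rho, n_shared, n_dropped).
    """
    p = pd.Series(protein_by_gene, dtype=float)
    m = pd.Series(mrna_by_gene, dtype=float)
    shared = p.index.intersection(m.index)
    n_dropped = (len(p) - len(shared)) + (len(m) - len(shared))
    if len(shared) < min_genes:
        raise ValueError(
            f"only {len(shared)} genes shared between tables (need >= {min_genes})"
        )
    rho = _spearman(p.loc[shared].to_numpy(), m.loc[shared].to_numpy())
    return rho, len(shared), n_dropped
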