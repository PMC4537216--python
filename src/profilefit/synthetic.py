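"""Synthetic RNA/protein count time courses with known ground truth.

The generator emulates the structure of a starvation time-course
experiment in *E. coli*: nine sampling times spanning three hours to two
weeks, three biological replicates, negative-binomial count noise on
both RNA-seq reads and protein spectral counts, operons whose members
share one transcript profile, and protein kinetics
``dp/dt = k_s * m(t) - k_d * p`` spanning the proportional
(fast-degradation) and integral (no-degradation) limits.

Every gene's transcript trajectory is a draw from the piecewise
plateau-ramp model, with knots anchored to sampling times so the drawn
parameters are identifiable from the grid.  Ground truth (category,
kinetic regime, operon layout, rates) is returned alongside the counts
so every downstream stage can be scored without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ProfileMatrix
from .profile_model import PiecewiseParams, evaluate_piecewise

__all__ = [
    "DEFAULT_TIME_GRID",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "sample_true_profiles",
    "simulate_protein_dynamics",
    "simulate_counts",
    "simulate_replicate_levels",
    "build_operon_structure",
    "make_gene_sets",
    "generate_dataset",
]

#: sampling times in hours: 3 h to two weeks
DEFAULT_TIME_GRID = (3.0, 4.0, 5.0, 6.0, 8.0, 24.0, 48.0, 168.0, 336.0)

BEHAVIOR_CATEGORIES = ("up", "down", "transient_up", "transient_down", "flat")
REGULATION_REGIMES = ("proportional", "integral", "intermediate")

#: category mix emulating entry to stationary phase, where the large
#: majority of differentially expressed transcripts shut off; this is the
#: composition under which the proportional/integral rank statistics
#: discriminate (a transcript that only ever rises has a protein whose
#: ranks match both the transcript and its integral)
STARVATION_CATEGORY_MIX = {
    "down": 0.55,
    "transient_down": 0.20,
    "up": 0.10,
    "transient_up": 0.10,
    "flat": 0.05,
}

#: cohort composition for regulation-regime benchmarks: only declining
#: transcripts, because for a transcript that never declines the protein
#: ranks of the proportional and integral regimes coincide (the cumulative
#: integral is strictly increasing), so no classifier could separate them
DECLINING_CATEGORY_MIX = {"down": 0.70, "transient_down": 0.30}

# per-gene random streams are derived from the master seed with disjoint
# purpose keys so adding genes or skipping a stage never perturbs another
_STREAM_PROFILE = 1
_STREAM_KINETICS = 2
_STREAM_RNA_COUNTS = 3
_STREAM_PROTEIN_COUNTS = 4
_STREAM_OPERON = 5
_STREAM_SETS = 6


def _gene_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


@dataclass
class SyntheticConfig:
    """Study-design knobs of the generator.

    Defaults are the emulated experiment: 2000 genes on the nine-point
    grid with three biological replicates, sequencing depth of two
    million counts per sample, and negative-binomial overdispersion 0.05
    (which puts replicate profile correlations in the low-0.9 range).
    """

    n_genes: int = 2000
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    n_replicates: int = 3
    category_mix: dict[str, float] = field(
        default_factory=lambda: {
            "up": 0.20,
            "down": 0.30,
            "transient_up": 0.15,
            "transient_down": 0.15,
            "flat": 0.20,
        }
    )
    regulation_mix: dict[str, float] = field(
        default_factory=lambda: {
            "proportional": 0.20,
            "integral": 0.15,
            "intermediate": 0.65,
        }
    )
    depth: float = 2e6
    dispersion: float = 0.05
    operon_size_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.05}
    )
    #: lognormal SD of the distance-coupled translation noise at 1 kb gap
    distance_noise_sd_at_1kb: float = 0.35
    #: fraction of genes per RNA class (non-mRNA genes carry no protein)
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"mRNA": 0.90, "tRNA": 0.04, "rRNA": 0.03, "ncRNA": 0.03}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (
            ("category_mix", self.category_mix),
            ("regulation_mix", self.regulation_mix),
            ("class_mix", self.class_mix),
            ("operon_size_dist", self.operon_size_dist),
        ):
            total = float(sum(mix.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative probabilities")
        unknown = set(self.category_mix) - set(BEHAVIOR_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in category_mix: {sorted(unknown)}")
        unknown = set(self.regulation_mix) - set(REGULATION_REGIMES)
        if unknown:
            raise ValueError(f"unknown regimes in regulation_mix: {sorted(unknown)}")
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.size < 4 or np.any(np.diff(grid) <= 0):
            raise ValueError("time_grid must be strictly increasing with >=4 points")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates so sigma is estimable")
        if self.dispersion < 0 or self.depth <= 0:
            raise ValueError("depth must be > 0 and dispersion >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.time_grid, dtype=float)


@dataclass
class GroundTruth:
    """Per-gene truth: transcript parameters, category, kinetics, operon."""

    table: pd.DataFrame  # indexed by gene
    mrna_params: list[PiecewiseParams]

    def __post_init__(self) -> None:
        t = self.table
        for col in ("k_s", "k_d", "p0"):
            if col in t.columns and (t[col].dropna() < 0).any():
                raise ValueError(f"ground truth {col} must be >= 0")


@dataclass
class SyntheticDataset:
    """Everything one simulated experiment produces."""

    config: SyntheticConfig
    rna: ProfileMatrix
    protein: ProfileMatrix
    truth: GroundTruth
    operons: pd.DataFrame
    gene_sets: dict[str, list[str]]
    protein_levels: pd.DataFrame  # noiseless protein level per mRNA gene x time
    rna_levels: pd.DataFrame  # noiseless transcript level per gene x time


def _draw_category_params(
    rng: np.random.Generator, category: str, times: np.ndarray
) -> PiecewiseParams:
    """Draw piecewise parameters whose knots sit on sampling times.

    Anchoring knots to grid indices keeps every segment observable, so
    the drawn parameters are recoverable from the nine samples.  The
    first inflection lands at 4-6 h, matching a culture that starves
    around 6-8 h.
    """
    t0 = times[0]
    n = times.size
    j1 = int(rng.integers(1, 4))  # first inflection at grid point 1..3
    j2 = int(rng.integers(j1 + 1, 6))  # first ramp ends by 24 h
    j3 = int(rng.integers(j2, 7))
    j4 = int(rng.integers(j3 + 1, n))
    t1 = times[j1] - t0
    t2 = times[j2] - times[j1]
    t3 = times[j3] - times[j2]
    t4 = times[j4] - times[j3]

    u = rng.uniform
    if category == "flat":
        a = u(0.5, 1.5)
        A1 = A2 = A3 = a
    elif category == "up":
        A1 = u(0.1, 0.4)
        A2 = A1 * u(3.0, 8.0)
        A3 = A2 * u(1.0, 1.5)
    elif category == "down":
        A1 = u(1.0, 2.0)
        A2 = A1 * u(0.1, 0.35)
        A3 = A2 * u(0.7, 1.0)
    elif category == "transient_up":
        A1 = u(0.1, 0.4)
        A2 = A1 * u(4.0, 8.0)
        A3 = A1 * u(0.8, 1.2)
    elif category == "transient_down":
        A1 = u(1.0, 2.0)
        A2 = A1 * u(0.1, 0.3)
        A3 = A1 * u(0.7, 1.1)
    else:
        raise ValueError(f"unknown category {category!r}")
    return PiecewiseParams(t0, t1, t2, t3, t4, A1, A2, A3)


def sample_true_profiles(
    config: SyntheticConfig,
) -> tuple[list[PiecewiseParams], list[str]]:
    """Draw one true transcript profile per gene, i.i.d. from category_mix."""
    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    times = config.times
    params, labels = [], []
    for g in range(config.n_genes):
        rng = _gene_rng(config.seed, _STREAM_PROFILE, g)
        category = cats[rng.choice(len(cats), p=probs)]
        params.append(_draw_category_params(rng, category, times))
        labels.append(category)
    return params, labels


def simulate_protein_dynamics(
    m_params: PiecewiseParams,
    k_s: float,
    k_d: float,
    p0: float,
    times: np.ndarray,
) -> np.ndarray:
    """Exact protein trajectory for dp/dt = k_s * m(t) - k_d * p.

    ``m`` is the piecewise-linear transcript curve, so the linear ODE has
    a closed form on every segment: for m(t) = m_a + b (t - a),

    * k_d > 0: p(t) = p_part(t) + (p(a) - p_part(a)) exp(-k_d (t-a)) with
      p_part(t) = (k_s/k_d) m(t) - k_s b / k_d^2;
    * k_d = 0: p(t) = p(a) + k_s [m_a (t-a) + b (t-a)^2 / 2].

    The trajectory is advanced over the union of model knots and sampling
    times, so the returned values are exact (up to float rounding).
    """
    if k_s < 0 or k_d < 0 or p0 < 0:
        raise ValueError("k_s, k_d and p0 must be >= 0")
    times = np.asarray(times, dtype=float)
    if np.any(times < m_params.t0 - 1e-12):
        raise ValueError("times must not precede the profile origin t0")
    knots = m_params.knots
    breaks = np.unique(np.concatenate([[m_params.t0], knots, times]))
    breaks = breaks[(breaks >= m_params.t0) & (breaks <= times[-1] + 1e-12)]

    p = float(p0)
    out = {float(breaks[0]): p}
    for a, b_t in zip(breaks[:-1], breaks[1:]):
        dt = b_t - a
        m_a = float(evaluate_piecewise(m_params, a))
        m_b = float(evaluate_piecewise(m_params, b_t))
        slope = (m_b - m_a) / dt if dt > 0 else 0.0
        if k_d == 0:
            p = p + k_s * (m_a * dt + 0.5 * slope * dt * dt)
        else:
            part_a = (k_s / k_d) * m_a - k_s * slope / k_d**2
            part_b = (k_s / k_d) * m_b - k_s * slope / k_d**2
            p = part_b + (p - part_a) * np.exp(-k_d * dt)
        p = max(p, 0.0)  # guard float round-off at tiny levels
        out[float(b_t)] = p
    return np.array([out[float(t)] for t in times])


def simulate_replicate_levels(
    levels: np.ndarray, cv: float, n_replicates: int, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal replicate noise with the given coefficient of variation.

    A light-weight noise layer for tests that need a controlled
    signal-to-noise ratio on the level scale rather than full count
    resampling: returns (genes, times, replicates).
    """
    levels = np.atleast_2d(np.asarray(levels, dtype=float))
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.repeat(levels[:, :, None], n_replicates, axis=2)
    sd = np.sqrt(np.log1p(cv**2))
    mu = -0.5 * sd**2  # unit-mean lognormal
    noise = rng.lognormal(mu, sd, size=levels.shape + (n_replicates,))
    return levels[:, :, None] * noise


def simulate_counts(
    true_levels: np.ndarray,
    config: SyntheticConfig,
    stream: int = _STREAM_RNA_COUNTS,
) -> np.ndarray:
    """Negative-binomial counts around depth-scaled relative levels.

    ``true_levels`` is (genes, times); per sample, a gene's expected
    count is ``depth * level / sum(levels at that time)``.  Replicates
    are independent; variance is mu + dispersion * mu^2 (Poisson when
    dispersion is ~0).  Per-gene random streams derive from the master
    seed, so adding genes leaves existing counts untouched.
    """
    levels = np.atleast_2d(np.asarray(true_levels, dtype=float))
    if np.any(levels < 0):
        raise ValueError("true levels must be >= 0")
    totals = levels.sum(axis=0)
    rel = np.divide(levels, totals, out=np.zeros_like(levels), where=totals > 0)
    mu = config.depth * rel
    g, t = levels.shape
    counts = np.zeros((g, t, config.n_replicates), dtype=np.int64)
    alpha = config.dispersion
    for i in range(g):
        rng = _gene_rng(config.seed, stream, i)
        mu_i = np.repeat(mu[i][:, None], config.n_replicates, axis=1)
        pos = mu_i > 0
        if not pos.any():
            continue
        if alpha < 1e-12:
            counts[i][pos] = rng.poisson(mu_i[pos])
        else:
            n = 1.0 / alpha
            p = n / (n + mu_i[pos])
            counts[i][pos] = rng.negative_binomial(n, p)
    return counts


def build_operon_structure(config: SyntheticConfig) -> pd.DataFrame:
    """Group genes into operons and lay them out on a coordinate axis.

    Operon sizes come from ``operon_size_dist``; members are consecutive
    genes on the same strand with inter-gene gaps drawn uniformly from
    [0, 2000] bp and coding lengths from [300, 3000] bp.  Returns the
    BED-like table (operon_id, gene, start, end, strand) with one row per
    gene, in transcription order.
    """
    sizes = sorted(config.operon_size_dist)
    probs = np.array([config.operon_size_dist[s] for s in sizes])
    rng = _gene_rng(config.seed, _STREAM_OPERON, 0)
    rows = []
    g = 0
    op = 0
    cursor = 1
    while g < config.n_genes:
        size = int(sizes[rng.choice(len(sizes), p=probs)])
        size = min(size, config.n_genes - g)
        strand = "+" if rng.random() < 0.5 else "-"
        op += 1
        cursor += int(rng.integers(500, 5000))  # spacer between operons
        for pos in range(size):
            length = int(rng.integers(300, 3001))
            gap = 0 if pos == 0 else int(rng.integers(0, 2001))
            start = cursor + gap
            end = start + length - 1
            rows.append(
                {
                    "operon_id": f"op{op:05d}",
                    "gene": f"g{g:05d}",
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "position": pos,
                    "gap_prev_bp": gap,
                }
            )
            cursor = end + 1
            g += 1
    return pd.DataFrame(rows)


def make_gene_sets(
    truth_table: pd.DataFrame, seed: int, n_random: int = 5, coverage: float = 0.6
) -> dict[str, list[str]]:
    """Gene sets for enrichment and pathway-averaging demonstrations.

    One set per behavioral category (a random ``coverage`` fraction of
    its genes, standing in for a functional term that responds
    coherently) plus ``n_random`` size-matched random sets that should
    show no enrichment.
    """
    rng = _gene_rng(seed, _STREAM_SETS, 0)
    genes = np.asarray(truth_table.index)
    sets: dict[str, list[str]] = {}
    for category in BEHAVIOR_CATEGORIES:
        members = genes[truth_table["category"].to_numpy() == category]
        if len(members) < 3:
            continue
        k = max(3, int(round(coverage * len(members))))
        sets[f"{category}_module"] = sorted(
            rng.choice(members, size=min(k, len(members)), replace=False).tolist()
        )
    for i in range(n_random):
        k = int(rng.integers(10, max(11, len(genes) // 10)))
        sets[f"random_set_{i + 1}"] = sorted(
            rng.choice(genes, size=min(k, len(genes)), replace=False).tolist()
        )
    return sets


#: growth rate during the pre-starvation exponential phase (h^-1); dilution
#: by division dominates degradation for stable proteins and sets their
#: initial level at the first sample
GROWTH_RATE = 0.7


def _draw_kinetics(
    rng: np.random.Generator,
    regime: str,
    m_params: PiecewiseParams,
    times: np.ndarray,
    max_tries: int = 40,
) -> tuple[float, float, float]:
    """(k_s, k_d, p0) for one gene given its kinetic regime.

    Proportional proteins turn over at least ten times faster than the
    gene's fastest transcript ramp; integral proteins do not degrade on
    the experiment's time scale; intermediate degradation timescales are
    log-uniform between the fastest sampling interval and the experiment
    duration, strictly between the two limits.  The initial protein
    level is the balanced-growth steady state k_s*m0/(k_d + mu), where
    dilution by division (mu = GROWTH_RATE) dominates degradation for
    stable proteins before starvation.

    A regime label is only meaningful if the gene's noiseless dynamics
    actually classify that way, so k_d is redrawn (up to ``max_tries``)
    until the noiseless correlation pair lands in the assigned regime;
    transcript shapes for which no k_d can achieve it (e.g. a monotone
    rise, where protein and integral ranks coincide) keep the last draw.
    """
    from .regulation import classify_regulation, regulation_correlations

    span = float(times[-1] - times[0])
    min_gap = float(np.min(np.diff(times)))
    ramps = [dur for dur in (m_params.t2, m_params.t4) if dur > 0]
    fastest = min(ramps) if ramps else min_gap
    k_s = float(rng.lognormal(0.0, 0.5))
    for _ in range(max_tries):
        if regime == "proportional":
            k_d = (10.0 / fastest) * float(rng.uniform(1.0, 2.0))
        elif regime == "integral":
            k_d = 0.0
        elif regime == "intermediate":
            k_d = float(np.exp(rng.uniform(np.log(1.0 / span), np.log(1.0 / min_gap))))
        else:
            raise ValueError(f"unknown regulation regime {regime!r}")
        m0 = float(m_params.A1)
        p0 = k_s * m0 / (k_d + GROWTH_RATE)
        p = simulate_protein_dynamics(m_params, k_s, k_d, p0, times)
        m = np.asarray(evaluate_piecewise(m_params, times), dtype=float)
        rp, ri = regulation_correlations(p, m, times)
        if regime == "intermediate":
            # an intermediate label is only robust if both correlations sit
            # clearly below the classification threshold in the noiseless
            # limit; otherwise replicate noise flips the call
            if np.isnan(rp) or max(np.nan_to_num(rp, nan=-1), np.nan_to_num(ri, nan=-1)) < 0.55:
                break
        elif classify_regulation(rp, ri).label == regime:
            break
    return k_s, k_d, p0


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Simulate one complete experiment.

    Pipeline: operon layout -> per-operon transcript profile (members
    share the shape up to a positive per-gene scale) -> per-gene kinetic
    regime and exact protein trajectory -> distance-coupled translation
    noise along each operon -> negative-binomial counts for RNA and
    protein.  Non-mRNA genes (tRNA/rRNA/ncRNA per ``class_mix``) appear
    in the RNA table only.
    """
    config = config or SyntheticConfig()
    times = config.times
    operons = build_operon_structure(config)

    cats = list(config.category_mix)
    cat_probs = np.array([config.category_mix[c] for c in cats])
    regimes = list(config.regulation_mix)
    reg_probs = np.array([config.regulation_mix[r] for r in regimes])
    classes = list(config.class_mix)
    class_probs = np.array([config.class_mix[c] for c in classes])

    genes = operons["gene"].tolist()
    n = len(genes)
    mrna_params: list[PiecewiseParams] = [None] * n  # type: ignore[list-item]
    records: list[dict] = [None] * n  # type: ignore[list-item]
    rna_levels = np.zeros((n, times.size))
    protein_levels = np.full((n, times.size), np.nan)

    for oid, sub in operons.groupby("operon_id", sort=False):
        idx = sub.index.to_numpy()
        lead = int(idx[0])
        rng_op = _gene_rng(config.seed, _STREAM_PROFILE, lead)
        category = cats[rng_op.choice(len(cats), p=cat_probs)]
        shape = _draw_category_params(rng_op, category, times)
        m_shape = np.asarray(evaluate_piecewise(shape, times), dtype=float)
        walk = np.zeros(times.size)  # distance-coupled noise random walk
        for i in idx:
            row = operons.loc[i]
            rng_g = _gene_rng(config.seed, _STREAM_KINETICS, int(i))
            scale = float(rng_g.lognormal(0.0, 0.3))
            params_g = PiecewiseParams(
                shape.t0, shape.t1, shape.t2, shape.t3, shape.t4,
                scale * shape.A1, scale * shape.A2, scale * shape.A3,
            )
            mrna_params[int(i)] = params_g
            rna_levels[int(i)] = scale * m_shape
            rna_class = classes[rng_g.choice(len(classes), p=class_probs)]
            regime = regimes[rng_g.choice(len(regimes), p=reg_probs)]

            gap = float(row["gap_prev_bp"])
            step_var = (config.distance_noise_sd_at_1kb**2 / 1000.0) * gap
            if step_var > 0:
                walk = walk + rng_g.normal(0.0, np.sqrt(step_var), size=times.size)

            rec = {
                "gene": row["gene"],
                "category": category,
                "rna_class": rna_class,
                "operon_id": oid,
                "operon_pos": int(row["position"]),
                "gap_prev_bp": int(row["gap_prev_bp"]),
                "length": int(row["end"] - row["start"] + 1),
                "scale": scale,
                "t1": params_g.t1,
                "t2": params_g.t2,
                "t3": params_g.t3,
                "t4": params_g.t4,
                "A1": params_g.A1,
                "A2": params_g.A2,
                "A3": params_g.A3,
                "regime": None,
                "k_s": np.nan,
                "k_d": np.nan,
                "p0": np.nan,
                "translation_efficiency": np.nan,
            }
            if rna_class == "mRNA":
                efficiency = float(rng_g.lognormal(0.0, 0.8))
                k_s, k_d, p0 = _draw_kinetics(rng_g, regime, params_g, times)
                k_s *= efficiency
                p0 *= efficiency
                p = simulate_protein_dynamics(params_g, k_s, k_d, p0, times)
                protein_levels[int(i)] = p * np.exp(walk)
                rec.update(
                    regime=regime,
                    k_s=k_s,
                    k_d=k_d,
                    p0=p0,
                    translation_efficiency=efficiency,
                )
            records[int(i)] = rec

    truth_table = pd.DataFrame(records).set_index("gene")
    meta = truth_table[["length", "rna_class"]].copy()

    rna_counts = simulate_counts(rna_levels, config, stream=_STREAM_RNA_COUNTS)
    rna = ProfileMatrix(rna_counts, genes, times, meta)

    is_protein = truth_table["rna_class"].to_numpy() == "mRNA"
    prot_lv = protein_levels[is_protein]
    prot_genes = [g for g, keep in zip(genes, is_protein) if keep]
    prot_counts = simulate_counts(prot_lv, config, stream=_STREAM_PROTEIN_COUNTS)
    protein = ProfileMatrix(prot_counts, prot_genes, times, meta.loc[prot_genes])

    truth = GroundTruth(table=truth_table, mrna_params=mrna_params)
    gene_sets = make_gene_sets(truth_table, config.seed)
    protein_level_df = pd.DataFrame(prot_lv, index=prot_genes, columns=times)
    rna_level_df = pd.DataFrame(rna_levels, index=genes, columns=times)
    return SyntheticDataset(
        config=config,
        rna=rna,
        protein=protein,
        truth=truth,
        operons=operons[["operon_id", "gene", "start", "end", "strand"]].copy(),
        gene_sets=gene_sets,
        protein_levels=protein_level_df,
        rna_levels=rna_level_df,
    )
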