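"""End-to-end orchestration: simulate/load -> preprocess -> fit -> classify
-> regulation -> operon/cluster/fractions -> enrichment.

A :class:`RunConfig` (usually loaded from YAML) names either input files
or a synthetic-data block, toggles stages, and carries every stage
parameter plus one global seed that is fanned out deterministically.
``run_pipeline`` writes the stage tables into the output directory along
with a JSON manifest (versions, seed, parameters, and the gene count
after every filter step); rerunning the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import call_gene_behavior, enrich_categories, pathway_average
from .io import (
    read_counts_tsv,
    read_gmt,
    read_operons_tsv,
    write_counts_tsv,
    write_gmt,
    write_operons_tsv,
    write_table,
)
from .operons import distance_vs_correlation, kmeans_profiles, operon_coherence, rna_fractions
from .preprocess import (
    ProfileMatrix,
    average_replicates,
    depth_normalize,
    filter_low_counts,
    fold_change_filter,
    length_normalize,
    significance_filter_rna,
)
from .profile_model import DEConfig, fit_profiles, good_fit_mask, summarize_timescales
from .regulation import crosssection_correlation, regulation_table
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("profilefit")

ALL_STAGES = (
    "preprocess",
    "fit",
    "classify",
    "regulation",
    "operon",
    "cluster",
    "fractions",
    "enrichment",
)


def _sub_seed(seed: int, *key: int) -> int:
    """Deterministic stage seed below 2**31 derived from the global seed."""
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one of ``inputs`` /
    ``synthetic`` must be present."""

    outdir: str = "profilefit_out"
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None  # rna_counts, protein_counts, operons, gene_sets
    stages: dict = field(default_factory=dict)  # stage name -> bool
    min_total: float = 10
    fold_change: float = 1.5
    alpha: float = 0.05
    sigma_floor: str | float = "auto"
    fit: dict = field(default_factory=dict)  # DEConfig overrides
    fit_chunk: int = 64
    delta: float | None = None
    agreement_min: float = 0.9
    flat_threshold: float = 0.2
    regulation_threshold: float = 0.70
    k_rna: int = 15
    k_protein: int = 25
    n_init: int = 10
    drop_residual_rrna: bool = True
    save_ensembles: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be given")
        if self.inputs is not None:
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"input {key!r}: {path} does not exist")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggle(s): {sorted(unknown)}")

    def stage_on(self, name: str) -> bool:
        return bool(self.stages.get(name, True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _prep_for_fitting(
    matrix: ProfileMatrix, cfg: RunConfig, *, rna: bool
) -> tuple[ProfileMatrix, np.ndarray, np.ndarray, dict]:
    """The filtering/normalization ladder shared by both molecule types.

    Low-count filter, then (RNA) per-time significance vs the first
    sample on size-factor scale or (protein) nothing, then depth
    normalization, then (protein) the fold-change filter, and finally
    replicate averaging with the floored SD and max normalization of
    both d and sigma.
    """
    counts = {"input": matrix.n_genes}
    m = filter_low_counts(matrix, cfg.min_total)
    counts["low_count_filter"] = m.n_genes
    if rna:
        m, _, _ = significance_filter_rna(m, alpha=cfg.alpha)
        counts["significance_filter"] = m.n_genes
    m = depth_normalize(m)
    if not rna:
        depth = float(np.median(matrix.counts.sum(axis=0)))
        m, _ = fold_change_filter(m, cfg.fold_change, floor=0.5 / depth)
        counts["fold_change_filter"] = m.n_genes
    d, sigma = average_replicates(m, cfg.sigma_floor)
    peak = d.max(axis=1, keepdims=True)
    keep = peak[:, 0] > 0
    if not keep.all():
        m = m.subset(keep)
        d, sigma, peak = d[keep], sigma[keep], peak[keep]
        counts["nonzero_profile"] = m.n_genes
    d_norm = d / peak
    sigma_norm = sigma / peak
    counts["fit_ready"] = m.n_genes
    return m, d_norm, sigma_norm, counts


def _fit_cohort(d, sigma, times, cfg: RunConfig, seed_key: int):
    de = DEConfig(seed=_sub_seed(cfg.seed, seed_key), **cfg.fit)
    ensembles = []
    for lo in range(0, len(d), cfg.fit_chunk):
        chunk_cfg = dataclasses.replace(de, seed=_sub_seed(cfg.seed, seed_key, lo))
        ensembles.extend(fit_profiles(d[lo : lo + cfg.fit_chunk], sigma[lo : lo + cfg.fit_chunk], times, chunk_cfg))
    return ensembles


def _fit_table(genes, ensembles, d, sigma) -> pd.DataFrame:
    rows = []
    for g, (gene, ens) in enumerate(zip(genes, ensembles)):
        mask = good_fit_mask(ens, d[g], sigma[g])
        best = ens.best
        rows.append(
            {
                "gene": gene,
                "cost": ens.best_cost,
                "good_fit_fraction": float(mask.mean()),
                "t1": best.t1,
                "t2": best.t2,
                "t3": best.t3,
                "t4": best.t4,
                "A1": best.A1,
                "A2": best.A2,
                "A3": best.A3,
                "t_change": best.t_change,
                "n_iter": ens.n_iter,
            }
        )
    return pd.DataFrame(rows)


def _classify_cohort(genes, ensembles, d, sigma, cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for g, (gene, ens) in enumerate(zip(genes, ensembles)):
        call = call_gene_behavior(
            ens, d[g], sigma[g], delta=cfg.delta, agreement_min=cfg.agreement_min
        )
        rows.append(
            {
                "gene": gene,
                "category": call.category,
                "agreement": call.agreement,
                "delta": call.delta,
                "n_good": call.n_good,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "profilefit_version": __version__,
        "versions": _library_versions(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "gene_counts": {},
        "outputs": [],
    }

    def emit(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        manifest["outputs"].append(name)

    # ---- acquire data -------------------------------------------------
    gene_sets: dict[str, list[str]] = {}
    operons = None
    if cfg.synthetic is not None:
        syn_cfg = SyntheticConfig(**{**cfg.synthetic, "seed": cfg.synthetic.get("seed", cfg.seed)})
        ds = generate_dataset(syn_cfg)
        rna_matrix, protein_matrix = ds.rna, ds.protein
        operons, gene_sets = ds.operons, ds.gene_sets
        emit("rna_counts.tsv", write_counts_tsv, rna_matrix)
        emit("protein_counts.tsv", write_counts_tsv, protein_matrix)
        emit("operons.tsv", write_operons_tsv, operons)
        emit("gene_sets.gmt", write_gmt, gene_sets)
        truth_out = ds.truth.table.reset_index()
        emit("truth.tsv", lambda df, p: write_table(df, p), truth_out)
    else:
        rna_matrix = read_counts_tsv(cfg.inputs["rna_counts"])
        protein_matrix = read_counts_tsv(cfg.inputs["protein_counts"])
        if "operons" in cfg.inputs:
            operons = read_operons_tsv(cfg.inputs["operons"])
        if "gene_sets" in cfg.inputs:
            gene_sets = read_gmt(cfg.inputs["gene_sets"])
        if "gene_meta" in cfg.inputs:
            meta = pd.read_csv(cfg.inputs["gene_meta"], sep="\t", index_col=0)
            rna_matrix.meta = meta.loc[rna_matrix.genes]
            protein_matrix.meta = meta.reindex(protein_matrix.genes)
    times = rna_matrix.times
    manifest["gene_counts"]["rna_input"] = rna_matrix.n_genes
    manifest["gene_counts"]["protein_input"] = protein_matrix.n_genes

    # ---- RNA-class fractions on the raw pool --------------------------
    if cfg.stage_on("fractions") and rna_matrix.meta is not None and "rna_class" in rna_matrix.meta:
        flat, names = rna_matrix.flat_samples()
        counts_df = pd.DataFrame(flat, index=rna_matrix.genes, columns=names)
        frac = rna_fractions(counts_df, rna_matrix.meta["rna_class"])
        emit("rna_fractions.csv", lambda df, p: write_table(df, p, index=True), frac)
        if cfg.drop_residual_rrna:
            frac_depleted = rna_fractions(
                counts_df, rna_matrix.meta["rna_class"], drop_residual_rrna=True
            )
            emit(
                "rna_fractions_rrna_dropped.csv",
                lambda df, p: write_table(df, p, index=True),
                frac_depleted,
            )

    # residual rRNA reads are disregarded before relative RNA analysis
    if rna_matrix.meta is not None and "rna_class" in rna_matrix.meta:
        not_rrna = (rna_matrix.meta["rna_class"] != "rRNA").to_numpy()
        rna_matrix = rna_matrix.subset(not_rrna)
        manifest["gene_counts"]["rna_after_rrna_drop"] = rna_matrix.n_genes

    if not cfg.stage_on("preprocess"):
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest

    # ---- preprocess ----------------------------------------------------
    rna_m, rna_d, rna_s, rna_counts_log = _prep_for_fitting(rna_matrix, cfg, rna=True)
    prot_m, prot_d, prot_s, prot_counts_log = _prep_for_fitting(protein_matrix, cfg, rna=False)
    manifest["gene_counts"]["rna"] = rna_counts_log
    manifest["gene_counts"]["protein"] = prot_counts_log
    for tag, m, d_, s_ in (("rna", rna_m, rna_d, rna_s), ("protein", prot_m, prot_d, prot_s)):
        prof = pd.DataFrame(d_, index=m.genes, columns=times)
        prof.index.name = "gene"
        emit(f"{tag}_profiles.tsv", lambda df, p: write_table(df, p, index=True), prof)
        sd = pd.DataFrame(s_, index=m.genes, columns=times)
        sd.index.name = "gene"
        emit(f"{tag}_profile_sd.tsv", lambda df, p: write_table(df, p, index=True), sd)

    results: dict = {"times": times}
    # ---- fit + classify ------------------------------------------------
    ensembles = {}
    if cfg.stage_on("fit"):
        for key, (m, d_, s_) in {
            "rna": (rna_m, rna_d, rna_s),
            "protein": (prot_m, prot_d, prot_s),
        }.items():
            log.info("fitting %d %s profiles", m.n_genes, key)
            ens = _fit_cohort(d_, s_, times, cfg, seed_key={"rna": 11, "protein": 12}[key])
            ensembles[key] = ens
            emit(f"{key}_fits.tsv", lambda df, p: write_table(df, p), _fit_table(m.genes, ens, d_, s_))
            if cfg.save_ensembles:
                payload = {g: e.to_dict() for g, e in zip(m.genes, ens)}
                path = outdir / f"{key}_ensembles.json"
                path.write_text(json.dumps(payload, sort_keys=True))
                manifest["outputs"].append(path.name)

        if cfg.stage_on("classify"):
            for key, (m, d_, s_) in {
                "rna": (rna_m, rna_d, rna_s),
                "protein": (prot_m, prot_d, prot_s),
            }.items():
                calls = _classify_cohort(m.genes, ensembles[key], d_, s_, cfg)
                results[f"{key}_calls"] = calls
                emit(f"{key}_categories.csv", lambda df, p: write_table(df, p), calls)
                # good-fit-averaged timescales (flat/ambiguous genes carry
                # no inflection and are excluded)
                exclude = calls["category"].isin(["flat", "ambiguous"]).to_numpy()
                ts = summarize_timescales(ensembles[key], d_, s_, exclude=exclude)
                kept = [m.genes[i] for i in ts["gene_index"]]
                ts_df = pd.DataFrame(
                    {"gene": kept, "t1": ts["t1"], "t_change": ts["t_change"]}
                )
                emit(f"{key}_timescales.csv", lambda df, p: write_table(df, p), ts_df)

    # ---- enrichment + pathway averaging -------------------------------
    if cfg.stage_on("enrichment") and gene_sets and "protein_calls" in results:
        for key in ("rna", "protein"):
            calls = results.get(f"{key}_calls")
            if calls is None:
                continue
            definite = calls[~calls["category"].isin(["ambiguous"])]
            enr = enrich_categories(definite, gene_sets, universe=list(calls["gene"]))
            emit(f"{key}_enrichment.csv", lambda df, p: write_table(df, p), enr)
        prot_profiles = pd.DataFrame(prot_d, index=prot_m.genes, columns=times)
        means, flat = pathway_average(prot_profiles, gene_sets, cfg.flat_threshold)
        means["flat"] = flat
        emit("pathway_averages.csv", lambda df, p: write_table(df, p, index=True), means)

    # ---- regulation -----------------------------------------------------
    if cfg.stage_on("regulation"):
        shared = [g for g in prot_m.genes if g in set(rna_m.genes)]
        rna_idx = {g: i for i, g in enumerate(rna_m.genes)}
        prot_idx = {g: i for i, g in enumerate(prot_m.genes)}
        if shared:
            P = prot_d[[prot_idx[g] for g in shared]]
            M = rna_d[[rna_idx[g] for g in shared]]
            reg = regulation_table(P, M, times, shared, cfg.regulation_threshold)
            emit("regulation.csv", lambda df, p: write_table(df, p), reg)
            results["regulation"] = reg
            manifest["gene_counts"]["regulation_shared_genes"] = len(shared)
            # 1-D and 2-D histogram data of the correlation pair
            edges = np.linspace(-1, 1, 41)
            ok = reg["rho_prop"].notna() & reg["rho_int"].notna()
            h_prop, _ = np.histogram(reg.loc[ok, "rho_prop"], bins=edges)
            h_int, _ = np.histogram(reg.loc[ok, "rho_int"], bins=edges)
            h2d, _, _ = np.histogram2d(
                reg.loc[ok, "rho_prop"], reg.loc[ok, "rho_int"], bins=[edges, edges]
            )
            hist = pd.DataFrame(
                {"bin_left": edges[:-1], "bin_right": edges[1:],
                 "n_rho_prop": h_prop, "n_rho_int": h_int}
            )
            emit("regulation_histograms.csv", lambda df, p: write_table(df, p), hist)
            h2d_df = pd.DataFrame(h2d.astype(int), index=edges[:-1], columns=edges[:-1])
            h2d_df.index.name = "rho_prop_bin_left"
            emit(
                "regulation_histogram2d.csv",
                lambda df, p: write_table(df, p, index=True),
                h2d_df,
            )
        # cross-sectional absolute correlation per time point
        xs_rows = []
        if rna_matrix.meta is not None and "length" in rna_matrix.meta.columns:
            rna_mean = rna_matrix.counts.mean(axis=2)
            rna_abs = length_normalize(rna_mean, rna_matrix.meta["length"].to_numpy())
            prot_mean = protein_matrix.counts.mean(axis=2)
            for j, t in enumerate(times):
                try:
                    rho, n_shared, n_drop = crosssection_correlation(
                        pd.Series(prot_mean[:, j], index=protein_matrix.genes),
                        pd.Series(rna_abs[:, j], index=rna_matrix.genes),
                    )
                except ValueError:
                    continue
                xs_rows.append(
                    {"time_h": t, "rho": rho, "n_genes": n_shared, "n_dropped": n_drop}
                )
        if xs_rows:
            emit("crosssection_correlation.csv", lambda df, p: write_table(df, p), pd.DataFrame(xs_rows))

    # ---- operon coherence ----------------------------------------------
    if cfg.stage_on("operon") and operons is not None:
        rna_prof = pd.DataFrame(rna_d, index=rna_m.genes, columns=times)
        prot_prof = pd.DataFrame(prot_d, index=prot_m.genes, columns=times)
        for tag, prof in (("rna", rna_prof), ("protein", prot_prof)):
            coh = operon_coherence(prof, operons)
            emit(f"{tag}_operon_coherence.csv", lambda df, p: write_table(df, p), coh)
        pairs, trend = distance_vs_correlation(prot_prof, operons)
        emit("protein_pair_distance.csv", lambda df, p: write_table(df, p), pairs)
        manifest["operon_trend"] = trend

    # ---- K-means clustering --------------------------------------------
    if cfg.stage_on("cluster"):
        for tag, (m, d_) in {"rna": (rna_m, rna_d), "protein": (prot_m, prot_d)}.items():
            k = cfg.k_rna if tag == "rna" else cfg.k_protein
            if m.n_genes < k:
                log.warning("skipping %s clustering: %d genes < k=%d", tag, m.n_genes, k)
                continue
            cent, labels, sse = kmeans_profiles(
                d_, k, seed=_sub_seed(cfg.seed, 77, k), n_init=cfg.n_init
            )
            cent_df = pd.DataFrame(cent, columns=times)
            cent_df.index.name = "cluster"
            emit(f"{tag}_cluster_centroids.csv", lambda df, p: write_table(df, p, index=True), cent_df)
            emit(
                f"{tag}_cluster_assignments.csv",
                lambda df, p: write_table(df, p),
                pd.DataFrame({"gene": m.genes, "cluster": labels}),
            )
            manifest[f"{tag}_kmeans_sse"] = sse

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"].append("manifest.json")
    return manifest


def _library_versions() -> dict:
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
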