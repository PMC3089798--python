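"""End-to-end orchestration: simulate -> normalize -> DE -> orthology -> CHX -> DRE.

``run_all`` executes every stage from a single :class:`~ahrcross.io.ConfigBundle`
and writes all tables plus a run manifest (config hash, per-file SHA-256
digests) to an output directory.  All randomness derives from the single
config seed through fixed per-stage offsets, so a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .io import (
    ConfigBundle,
    file_digest,
    write_dendrogram,
    write_dre_hits,
    write_expression,
    write_ortholog_table,
    write_promoters,
    write_sample_sheet,
)
from . import simulate
from .simulate import write_training_fasta
from .chx import FactorialCHXModel
from .dre import build_pwm, cluster_orthologous_dres, scan_promoter
from .expression import DifferentialExpressionModel, cluster_de_profiles
from .orthology import category_counts, map_calls, overlap_matrix, venn_partition

log = logging.getLogger("ahrcross")

STAGE_SEED_OFFSETS = {"experiment": 11, "chx": 23, "promoters": 37, "training": 41}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1009 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def run_all(config: ConfigBundle, outdir: str | Path) -> dict:
    """Run every pipeline stage; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = dict(config.fixtures)
    t0 = time.time()
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    # --- stage: simulate the cross-species time course -------------------
    log.info("stage simulate: generating expression experiment")
    exp_kwargs = dict(
        n_genes=fx.get("n_genes", 120),
        frac_3way=fx.get("frac_3way", 0.5),
        frac_2way=fx.get("frac_2way", 0.2),
        noise_sd=fx.get("noise_sd", 0.2),
        n_reps=fx.get("n_reps", 3),
        times=tuple(fx.get("times", simulate.DEFAULT_TIMES)),
        seed=_stage_seed(config.seed, "experiment"),
    )
    if "proportions" in fx:
        exp_kwargs["proportions"] = fx["proportions"]
    table, sheet, orth, truth = simulate.generate_experiment(**exp_kwargs)
    emit("expression_raw.tsv", lambda p: write_expression(table, p))
    emit("sample_sheet.tsv", lambda p: write_sample_sheet(sheet, p))
    emit("orthologs.tsv", lambda p: write_ortholog_table(orth, p))
    emit("truth_experiment.tsv", lambda p: truth.genes.to_csv(p, sep="\t", index=False))

    # --- stage: normalize + differential expression ----------------------
    log.info("stage de: normalization and empirical-Bayes fitting")
    model = DifferentialExpressionModel(
        table,
        sheet,
        prior_active=config.prior_active,
        signal_variance_ratio=config.signal_variance_ratio,
        lowess_frac=config.lowess_frac,
    )
    results = model.fit()
    calls = results.calls(config.p1_min, config.abs_fc_min)
    emit("de_stats.tsv", lambda p: calls.to_csv(p, sep="\t", index=False))
    any_time = results.any_time_calls(config.p1_min, config.abs_fc_min)
    emit("de_any_time.tsv", lambda p: any_time.to_csv(p, sep="\t", index=False))
    de_summary = results.summary(config.p1_min, config.abs_fc_min)
    emit("de_summary.tsv", lambda p: de_summary.to_csv(p, sep="\t", index=False))

    # --- stage: cluster DE profiles per species --------------------------
    for species in sorted(sheet["species"].unique()):
        sp_any = any_time[(any_time["species"] == species) & any_time["any_time"]]
        sp_calls = calls[calls["species"] == species]
        de_genes = sorted(sp_any["gene_id"])
        if len(de_genes) < 2:
            continue
        prof = (
            sp_calls[sp_calls["gene_id"].isin(de_genes)]
            .pivot_table(index="gene_id", columns="time_hr", values="m_bar")
        )
        link, labels, _order = cluster_de_profiles(prof)
        emit(
            f"de_dendrogram_{species}.nwk",
            lambda p, link=link, labels=labels: write_dendrogram(link, labels, p),
        )

    # --- stage: cross-species orthology ----------------------------------
    log.info("stage compare: ortholog mapping and overlap")
    species_list = sorted(sheet["species"].unique())
    species_calls = {
        sp: any_time[any_time["species"] == sp] for sp in species_list
    }
    cross = map_calls(species_calls, orth)
    emit("cross_species_calls.tsv", lambda p: cross.to_csv(p, sep="\t", index=False))
    omat = overlap_matrix(cross, species_list)
    emit("overlap_matrix.tsv", lambda p: omat.to_csv(p, sep="\t", index=False))
    venn = venn_partition(cross, species_list) if len(species_list) == 3 else {}
    emit(
        "venn_counts.tsv",
        lambda p: pd.Series(venn, name="n_groups")
        .rename_axis("region")
        .reset_index()
        .to_csv(p, sep="\t", index=False),
    )

    # --- stage: CHX factorial ---------------------------------------------
    log.info("stage chx: factorial simulation and classification")
    chx_table, chx_sheet, chx_truth = simulate.generate_chx_experiment(
        n_genes=fx.get("chx_n_genes", 150),
        noise_sd=fx.get("noise_sd", 0.2),
        n_reps=fx.get("n_reps", 3),
        times=tuple(config.chx_times_hr),
        seed=_stage_seed(config.seed, "chx"),
    )
    chx_model = FactorialCHXModel(
        chx_table,
        chx_sheet,
        times_hr=tuple(config.chx_times_hr),
        p1_min=config.p1_min,
        abs_fc_min=config.abs_fc_min,
        retention_alpha=config.retention_alpha,
        prior_active=config.prior_active,
        signal_variance_ratio=config.signal_variance_ratio,
    )
    chx_results = chx_model.fit()
    chx_out = chx_results.table.merge(
        chx_results.overall.reset_index(), on="gene_id", how="left"
    )
    emit("chx_classes.tsv", lambda p: chx_out.to_csv(p, sep="\t", index=False))
    emit(
        "truth_chx.tsv", lambda p: chx_truth.genes.to_csv(p, sep="\t", index=False)
    )

    # --- stage: DRE promoter analysis -------------------------------------
    log.info("stage dre: promoter scan and conservation clustering")
    upstream = fx.get("promoter_upstream_bp", 2000)
    downstream = fx.get("promoter_downstream_bp", 500)
    rng_seed = _stage_seed(config.seed, "promoters")
    import numpy as np

    prng = np.random.default_rng(rng_seed)
    base = simulate.DRE_CONSENSUS_19MER
    planted = [
        simulate.PlantedDre("mouse", "GstaX", -5, "+", base),
        simulate.PlantedDre(
            "rat", "GstaX", -22, "+", simulate.mutate_19mer(base, 2, prng)
        ),
        simulate.PlantedDre(
            "human", "GSTAX", -480, "+", simulate.mutate_19mer(base, 8, prng)
        ),
        simulate.PlantedDre(
            "human", "GSTAX", 120, "-", simulate.mutate_19mer(base, 7, prng)
        ),
    ]
    promoters, prom_truth = simulate.generate_promoters(
        planted, upstream_bp=upstream, downstream_bp=downstream, seed=rng_seed
    )
    emit("promoters.fa", lambda p: write_promoters(promoters, p))
    emit(
        "truth_promoters.tsv",
        lambda p: prom_truth.planted.to_csv(p, sep="\t", index=False),
    )
    training = simulate.generate_dre_training_set(
        consensus=base,
        substitution_rates=fx.get("training_substitution_rate", 0.08),
        n=fx.get("training_n", 200),
        seed=_stage_seed(config.seed, "training"),
    )
    emit("dre_training.fa", lambda p: write_training_fasta(training, p))
    pwm = build_pwm(training)
    emit("dre_pwm.tsv", lambda p: pwm.write_tsv(p))
    hits = []
    for rec in promoters:
        hits.extend(
            scan_promoter(rec, pwm=pwm, core=config.dre_core, ms_min=config.ms_min)
        )
    emit("dre_hits.tsv", lambda p: write_dre_hits(hits, p, dialect="tsv"))
    clusters = cluster_orthologous_dres(hits, theta=config.distance_threshold)
    cluster_rows = []
    for k, cl in enumerate(clusters):
        for h in cl.members:
            cluster_rows.append(
                dict(
                    cluster=k,
                    orthologous=cl.orthologous,
                    max_distance=round(cl.max_distance, 4),
                    species=h.species,
                    gene_id=h.gene_id,
                    core_center=h.core_center,
                    strand=h.strand,
                    seq19=h.seq19,
                    ms=None if h.ms is None else round(h.ms, 6),
                )
            )
    emit(
        "dre_clusters.tsv",
        lambda p: pd.DataFrame(cluster_rows).to_csv(p, sep="\t", index=False),
    )

    # --- stage: summary report --------------------------------------------
    report = summarize(de_summary, cross, omat, venn, chx_out, hits, clusters)
    emit("summary.tsv", lambda p: report.to_csv(p, sep="\t", index=False))

    config_text = json.dumps(
        {k: v for k, v in vars(config).items()}, sort_keys=True, default=str
    )
    manifest = {
        "tool_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "elapsed_s": round(time.time() - t0, 2),
        "files": {p.name: file_digest(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.info("run complete in %.1fs", time.time() - t0)
    return manifest


def summarize(de_summary, cross, omat, venn, chx_out, hits, clusters) -> pd.DataFrame:
    """Flat key/value report of counts and percentages across all stages."""
    rows: list[dict] = []

    def add(metric: str, value) -> None:
        rows.append(dict(metric=metric, value=value))

    for _, r in de_summary.iterrows():
        key = f"de_genes[{r['species']},t={r['time_hr']:g}h]"
        add(key, int(r["de_genes"]))
    for sp, grp in de_summary.groupby("species"):
        add(f"genes_on_platform[{sp}]", int(grp["n_genes"].iloc[0]))
    cats = category_counts(cross)
    for cat, n in cats.items():
        add(f"ortholog_category[{cat}]", int(n))
    for _, r in omat.iterrows():
        pair = f"{r['species_a']}-{r['species_b']}"
        add(f"shared_orthologs[{pair}]", int(r["n_shared_orthologs"]))
        add(f"shared_de[{pair}]", int(r["n_shared_de"]))
        add(f"shared_de_pct[{pair}]", r["pct_shared_de"])
    for region, n in venn.items():
        add(f"venn[{region}]", int(n))
    if len(chx_out):
        counts = chx_out.drop_duplicates("gene_id")["overall_class"].value_counts()
        for cls, n in counts.items():
            add(f"chx_class[{cls}]", int(n))
    add("dre_hits", len(hits))
    add("dre_clusters", len(clusters))
    add("dre_orthologous_clusters", sum(c.orthologous for c in clusters))
    return pd.DataFrame(rows)
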