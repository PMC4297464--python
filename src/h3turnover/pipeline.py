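"""End-to-end pipeline driver: simulate -> count -> rates -> classify -> report.

`run_pipeline` executes the whole analysis from a YAML/dict config,
either on a synthetic TET-OFF dataset (``synthetic: true``) or on user
BED inputs, and writes tab-delimited report tables plus a JSON manifest
of inputs, parameters and seeds. Runs are deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome import ChromSizes, FeatureSet, read_reads_bed
from .signal import WindowGrid, count_dyads, call_enriched
from .turnover import TurnoverModel, scaled_dissociation
from .synthio import (
    GeneratorParams, TruthTable, build_annotation, simulate_reads, default_chroms,
)
from .features import classify_repeats, classify_proximity, binding_summary
from .profiles import profile_matrix, mean_profile, region_summary, profile_peak
from .stats import pearson, chisq_2x2, spearman, replicate_concordance

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "synthetic": True,
    "seed": 0,
    "window": 250,
    "resample": 10,
    "fine_window": 10,
    "profile_bin": 50,
    "extension": 150,
    "dt": 6.0,
    "eps": 0.5,
    "alpha": 0.05,
    "min_fold": 2.0,
    "depth": 1.0,
    "n_replicates": 2,
    "proximal_cutoff": 5000,
    "genic_cutoff": 2000,
    "timepoints": [0, 6],
}


def _load_config(config) -> dict:
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    if cfg["dt"] <= 0:
        raise ValueError("config error: dt must be positive")
    if cfg["window"] <= 0 or cfg["resample"] <= 0:
        raise ValueError("config error: window sizes must be positive")
    if not cfg.get("synthetic"):
        for key in ("chrom_sizes", "reads_t0", "reads_t6", "reads_input"):
            if key not in cfg:
                raise ValueError(f"config error: missing required input {key!r}")
            if not os.path.exists(cfg[key]):
                raise FileNotFoundError(f"config input {key!r}: {cfg[key]} not found")
    return cfg


def _locus_dyad_counts(truth: TruthTable, chroms: ChromSizes, reads,
                       extension: int) -> np.ndarray:
    """Extended-read dyads falling inside each (non-overlapping) locus."""
    from .signal import _dyads_vector

    counts = np.zeros(len(truth))
    loci = truth.df.reset_index()
    for chrom, sub in reads.groupby("chrom", sort=False):
        lsub = loci[loci["chrom"] == chrom].sort_values("start")
        if not len(lsub):
            continue
        starts = lsub["start"].to_numpy(np.int64)
        ends = lsub["end"].to_numpy(np.int64)
        rows = lsub["index"].to_numpy()
        dyads = _dyads_vector(
            sub["five_prime"].to_numpy(np.int64), sub["strand"].to_numpy(),
            chroms[chrom], extension,
        )
        idx = np.searchsorted(starts, dyads, side="right") - 1
        ok = (idx >= 0) & (dyads < ends[np.maximum(idx, 0)])
        np.add.at(counts, rows[idx[ok]], 1)
    return counts


def locus_estimates(truth: TruthTable, chroms: ChromSizes, reads_t0, reads_t6,
                    extension: int = 150, dt: float = 6.0,
                    eps: float = 0.5) -> pd.DataFrame:
    """Per-locus dissociation estimates from pooled within-locus dyad counts."""
    n0 = _locus_dyad_counts(truth, chroms, reads_t0, extension)
    n6 = _locus_dyad_counts(truth, chroms, reads_t6, extension)
    out = truth.df.copy()
    out["n0"] = n0
    out["n6"] = n6
    out["lambda_out_hat"] = scaled_dissociation(n0, n6, dt=dt, eps=eps)
    return out


def uniform_rate_truth(
    n_loci: int = 2000,
    lambda_range: tuple = (0.0, 0.5),
    occupancy: float = 100.0,
    width: int = 200,
    spacing: int = 500,
    seed: int = 0,
) -> tuple[TruthTable, ChromSizes]:
    """A flat truth table with decay rates uniform over ``lambda_range``.

    Loci of equal occupancy are laid on one synthetic chromosome at a
    fixed spacing — the standard configuration for stochastic
    parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    lam = rng.uniform(*lambda_range, size=n_loci)
    starts = np.arange(n_loci, dtype=np.int64) * spacing
    df = pd.DataFrame({
        "chrom": "chrU", "start": starts, "end": starts + width,
        "archetype": "distal_site", "occupancy0": occupancy, "true_lambda": lam,
    })
    chroms = ChromSizes({"chrU": int(n_loci * spacing + 10_000)})
    return TruthTable(df), chroms


def parameter_recovery(
    n_loci: int = 2000,
    lambda_range: tuple = (0.0, 0.5),
    occupancy: float = 100.0,
    seed: int = 0,
    spacing: int = 500,
) -> tuple[pd.DataFrame, float]:
    """Simulate, re-estimate and rank-correlate per-locus decay rates.

    Returns the per-locus table and Spearman(true lambda, estimated
    scaled dissociation rate).
    """
    truth, chroms = uniform_rate_truth(
        n_loci, lambda_range, occupancy, spacing=spacing, seed=seed
    )
    reads = simulate_reads(truth, chroms, timepoints=(0, 6), seed=seed)
    est = locus_estimates(truth, chroms, reads.library(0), reads.library(6))
    rho = spearman(est["true_lambda"], est["lambda_out_hat"])
    return est, rho


def _fit_replicate(reads, chroms, cfg, rep):
    model = TurnoverModel.from_reads(
        reads.library(0, rep), reads.library(6, rep), reads.input[rep],
        chroms, window=cfg["window"], extension=cfg["extension"],
        dt=cfg["dt"], eps=cfg["eps"], alpha=cfg["alpha"],
        min_fold=cfg["min_fold"],
    )
    return model.fit()


def run_pipeline(config=None, outdir=None) -> dict:
    """Run the full analysis; write reports under ``outdir``.

    Returns a summary dict with the headline statistics (also written to
    ``summary.json``): replicate concordance, rate-vs-equilibrium
    correlation, parameter recovery, repeat-binding enrichment, and the
    archetype region summary.
    """
    cfg = _load_config(config)
    outdir = outdir or cfg.get("outdir") or "h3turnover_out"
    os.makedirs(outdir, exist_ok=True)
    t_start = time.time()
    summary: dict = {"config": {k: v for k, v in cfg.items()}}

    if cfg["synthetic"]:
        gp = GeneratorParams(**cfg.get("generator", {}))
        annotation, truth = build_annotation(
            cfg.get("chroms") or default_chroms(), gp, seed=cfg["seed"]
        )
        reads = simulate_reads(
            truth, annotation.chroms, timepoints=cfg["timepoints"],
            depth=cfg["depth"], seed=cfg["seed"],
            n_replicates=cfg["n_replicates"],
        )
        chroms = annotation.chroms
        transcripts_fs = FeatureSet("transcripts", annotation.transcripts)
        repeats = annotation.repeats
        tf_peaks = annotation.tf_peaks
    else:
        chroms = ChromSizes.read(cfg["chrom_sizes"])
        annotation = truth = None
        reads = None
        transcripts_fs = repeats = None
        tf_peaks = []
        if cfg.get("transcripts"):
            transcripts_fs = FeatureSet(
                "transcripts", pd.read_csv(cfg["transcripts"], sep="\t")
            )
        if cfg.get("repeats"):
            repeats = FeatureSet.read_bed(cfg["repeats"], "repeats")
        for p in cfg.get("tf_peaks", []):
            tf_peaks.append(FeatureSet.read_bed(p, os.path.basename(p)))

    logger.info("stage counts+rates: %.1fs", time.time() - t_start)
    if cfg["synthetic"]:
        results = [_fit_replicate(reads, chroms, cfg, r)
                   for r in range(cfg["n_replicates"])]
    else:
        model = TurnoverModel.from_reads(
            read_reads_bed(cfg["reads_t0"]), read_reads_bed(cfg["reads_t6"]),
            read_reads_bed(cfg["reads_input"]), chroms,
            window=cfg["window"], extension=cfg["extension"],
            dt=cfg["dt"], eps=cfg["eps"], alpha=cfg["alpha"],
            min_fold=cfg["min_fold"],
        )
        results = [model.fit()]
    res0 = results[0]
    res0.to_frame().to_csv(
        os.path.join(outdir, "rates_windows.tsv"), sep="\t", index=False,
        float_format="%.6f",
    )
    res0.lambda_out.write_bedgraph(os.path.join(outdir, "lambda_out.bedgraph"))
    res0.lambda_raw.write_bedgraph(os.path.join(outdir, "lambda_raw.bedgraph"))
    res0.lambda_equ.write_bedgraph(os.path.join(outdir, "lambda_equ.bedgraph"))

    # headline correlations on the enriched universe
    cor_tables = []
    rate_equ = pearson(res0.lambda_out, res0.lambda_equ, res0.mask)
    summary["rate_vs_equilibrium_pcc"] = rate_equ.r
    summary["rate_vs_equilibrium_n"] = rate_equ.n
    cor_tables.append({"comparison": "lambda_out_vs_lambda_equ",
                       "r": rate_equ.r, "n": rate_equ.n, "p": rate_equ.p})
    if len(results) > 1:
        cor, density = replicate_concordance(
            results[0].lambda_out, results[1].lambda_out,
            resolution=cfg["resample"],
        )
        summary["replicate_pcc"] = cor.r
        summary["replicate_n_windows"] = cor.n
        cor_tables.append({"comparison": "replicate_lambda_out",
                           "r": cor.r, "n": cor.n, "p": cor.p})
        density.to_csv(os.path.join(outdir, "replicate_density.tsv"),
                       sep="\t", index=False)
    pd.DataFrame(cor_tables).to_csv(
        os.path.join(outdir, "correlations.tsv"), sep="\t", index=False
    )

    if repeats is not None and transcripts_fs is not None and len(repeats):
        rep_class = classify_repeats(
            repeats, transcripts_fs, cutoff=cfg["genic_cutoff"]
        )
        if tf_peaks:
            binding = binding_summary(repeats, rep_class, tf_peaks)
            binding.to_csv(os.path.join(outdir, "repeat_binding.tsv"),
                           sep="\t", index=False)
            ng = binding[(binding["repeat_class"] == "non_genic")
                         & (binding["peak_set"] == "any_tf")]
            sat = ng[ng["family"] == "Satellite"]
            oth = ng[ng["family"] != "Satellite"]
            if len(sat) and len(oth):
                table = [
                    [int(sat["n_bound"].sum()),
                     int(sat["n_total"].sum() - sat["n_bound"].sum())],
                    [int(oth["n_bound"].sum()),
                     int(oth["n_total"].sum() - oth["n_bound"].sum())],
                ]
                enr = chisq_2x2(table)
                summary["satellite_tf_chi2"] = enr.chi2
                summary["satellite_tf_p"] = enr.p
                summary["satellite_bound_fraction"] = (
                    sat["n_bound"].sum() / sat["n_total"].sum()
                )
                summary["other_bound_fraction"] = (
                    oth["n_bound"].sum() / oth["n_total"].sum()
                )

    if cfg["synthetic"]:
        # parameter recovery against the generator's truth table
        est = locus_estimates(
            truth, chroms, reads.library(0), reads.library(6),
            extension=cfg["extension"], dt=cfg["dt"], eps=cfg["eps"],
        )
        est.to_csv(os.path.join(outdir, "truth_recovery.tsv"), sep="\t",
                   index=False, float_format="%.6f")
        summary["truth_spearman"] = spearman(
            est["true_lambda"], est["lambda_out_hat"]
        )

        # archetype region summary (heatmap input)
        arche_sets = []
        for a, sub in annotation.loci.intervals.groupby("archetype"):
            arche_sets.append(FeatureSet(a, sub[["chrom", "start", "end"]]))
        reg = region_summary(
            {"lambda_out": res0.lambda_out, "lambda_equ": res0.lambda_equ},
            arche_sets, flank=cfg.get("region_flank", 500),
        )
        reg.to_csv(os.path.join(outdir, "region_summary.tsv"), sep="\t")
        summary["region_summary"] = {
            a: {c: (None if pd.isna(v) else float(v)) for c, v in row.items()}
            for a, row in reg.iterrows()
        }

        # promoter-resolution TSS profile: sliding windows, unfiltered rates
        fine = TurnoverModel.from_reads(
            reads.library(0), reads.library(6), reads.input[0], chroms,
            window=cfg["profile_bin"], step=cfg["fine_window"],
            extension=cfg["extension"], dt=cfg["dt"], eps=cfg["eps"],
            apply_filter=False,
        ).fit()
        anchors = annotation.tss_anchors()
        pm = profile_matrix(
            fine.lambda_out, anchors, flank=500, bin=cfg["profile_bin"],
            oriented=True,
        )
        curves = mean_profile(pm)
        curves.to_csv(os.path.join(outdir, "tss_profile.tsv"), sep="\t",
                      index=False)
        peak_offset, peak_value = profile_peak(curves)
        summary["tss_profile_peak_offset_bp"] = peak_offset
        summary["tss_profile_peak_lambda_out"] = peak_value

    summary["n_enriched_windows"] = res0.n_enriched
    if cfg["synthetic"]:
        summary["n_loci"] = len(truth)
        summary["n_transcripts"] = len(annotation.transcripts)
        summary["n_repeats"] = len(repeats)
        summary["n_satellite_repeats"] = int(
            (annotation.repeats.intervals["name"] == "Satellite").sum()
        )
    summary["runtime_s"] = round(time.time() - t_start, 2)

    manifest = {
        "package": "h3turnover",
        "version": __version__,
        "seed": cfg["seed"],
        "parameters": {k: v for k, v in cfg.items()
                       if isinstance(v, (int, float, str, bool, list, type(None)))},
        "library_versions": _library_versions(),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def _library_versions() -> dict:
    import numpy, pandas, scipy

    return {"numpy": numpy.__version__, "pandas": pandas.__version__,
            "scipy": scipy.__version__}
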