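"""Synthetic TET-OFF time-course data with known per-locus decay rates.

A small genome is tiled with loci of archetypes that mirror the
qualitative regimes seen in embryonic stem cell chromatin: promoter NDRs
with the fastest tagged-histone loss, distal regulatory sites, TSS
flanks, gene bodies, heterochromatin with near-zero turnover, satellite
repeats, and low-signal background. Each locus carries a true decay rate
``true_lambda`` (h^-1) and a t=0 occupancy; reads at timepoint t are
drawn Poisson with mean ``occupancy0 * depth * exp(-true_lambda * t)``.

Nucleosome dyads are placed uniformly within each locus and the read 5′
end is derived from the dyad (plus strand: dyad-75; minus: dyad+74), so
that the standard 150-bp extension downstream recovers the dyad inside
the locus — the geometry a nucleosome-footprint ChIP produces.

The truth table is the parameter-recovery oracle for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genome import ChromSizes, FeatureSet, write_reads_bed, read_reads_bed
from .signal import SignalTrack, WindowGrid

ARCHETYPES = (
    "ndr",
    "tss_flank",
    "gene_body",
    "heterochromatin",
    "distal_site",
    "satellite_repeat",
    "background",
)

# half the 150-bp nucleosome footprint; extension downstream inverts this
_DYAD_SHIFT = 75


class CapacityError(ValueError):
    """Requested loci do not fit in the synthetic genome."""


@dataclass
class GeneratorParams:
    """Study-condition knobs for the synthetic genome.

    Rate ranges are ordered ndr > distal_site > tss_flank > gene_body >
    heterochromatin, matching the observed regime of fast turnover at
    active regulatory chromatin and slow turnover at heterochromatin.
    Occupancies are expected dyad counts per locus at t=0 and unit depth.
    """

    n_genes: int = 40
    counts: dict = field(default_factory=lambda: {
        "ndr": 40, "tss_flank": 40, "gene_body": 40,
        "heterochromatin": 30, "distal_site": 30,
        "satellite_repeat": 30, "background": 20,
    })
    lambda_ranges: dict = field(default_factory=lambda: {
        "ndr": (0.2, 0.5), "tss_flank": (0.1, 0.25), "gene_body": (0.02, 0.08),
        "heterochromatin": (0.0, 0.02), "distal_site": (0.15, 0.35),
        "satellite_repeat": (0.1, 0.3), "background": (0.01, 0.05),
    })
    occupancy_ranges: dict = field(default_factory=lambda: {
        "ndr": (80, 160), "tss_flank": (80, 160), "gene_body": (40, 100),
        "heterochromatin": (30, 80), "distal_site": (60, 140),
        "satellite_repeat": (40, 100), "background": (5, 20),
    })
    widths: dict = field(default_factory=lambda: {
        "ndr": 50, "tss_flank": 250, "gene_body": 500,
        "heterochromatin": 1000, "distal_site": 200,
        "satellite_repeat": 300, "background": 500,
    })
    gene_length: tuple = (2000, 6000)
    spacing: tuple = (800, 2000)
    n_other_repeats: int = 90
    other_repeat_families: tuple = ("SINE", "LINE", "LTR")
    genic_repeat_fraction: float = 0.35
    # per-factor binding probabilities; with three independent factors the
    # union rates are ~32% of non-genic satellites and ~19% of other repeats
    tf_names: tuple = ("Nanog", "Oct4", "Klf4")
    tf_p_satellite: float = 0.12
    tf_p_other_repeat: float = 0.068
    tf_p_distal: float = 0.5

    def validate(self):
        for a in self.counts:
            if a not in ARCHETYPES:
                raise ValueError(f"unknown archetype {a!r}")
        for a in ("ndr", "tss_flank"):
            if self.counts.get(a, 0) > self.n_genes:
                raise ValueError(f"cannot place more {a} loci than genes")
        for a, (lo, hi) in self.lambda_ranges.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"bad lambda range for {a}")


class TruthTable:
    """Per-locus ground truth: archetype, t=0 occupancy and decay rate."""

    COLUMNS = ["chrom", "start", "end", "archetype", "occupancy0", "true_lambda"]

    def __init__(self, df: pd.DataFrame):
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"truth table missing column {col!r}")
        if (df["occupancy0"] < 0).any() or (df["true_lambda"] < 0).any():
            raise ValueError("occupancy0 and true_lambda must be non-negative")
        self.df = df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    def expected_counts(self, t: float, depth: float = 1.0) -> np.ndarray:
        """Expected dyad count per locus: occupancy0 * depth * exp(-lambda*t)."""
        return (
            self.df["occupancy0"].to_numpy()
            * depth
            * np.exp(-self.df["true_lambda"].to_numpy() * t)
        )

    def with_expectations(self, timepoints, depth: float = 1.0) -> pd.DataFrame:
        out = self.df.copy()
        for t in timepoints:
            out[f"expected_n_{t:g}h"] = self.expected_counts(t, depth)
        return out

    def write(self, path, timepoints=(0, 6), depth: float = 1.0) -> None:
        self.with_expectations(timepoints, depth).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class SyntheticAnnotation:
    """Generated gene models, loci, repeats and factor-binding peaks."""

    chroms: ChromSizes
    loci: FeatureSet                 # all archetype loci, archetype column
    transcripts: pd.DataFrame        # transcript_id/chrom/start/end/strand/exons/fpkm
    repeats: FeatureSet              # family label in 'name'
    tf_peaks: list                   # FeatureSet per transcription factor

    def tss_anchors(self) -> pd.DataFrame:
        """TSS point anchors (chrom, pos, strand) for profile aggregation."""
        tx = self.transcripts
        pos = np.where(tx["strand"] == "+", tx["start"], tx["end"])
        return pd.DataFrame(
            {"chrom": tx["chrom"], "pos": pos.astype(int), "strand": tx["strand"]}
        )


def default_chroms() -> ChromSizes:
    return ChromSizes({"chrS1": 600_000, "chrS2": 400_000})


class _Placer:
    """Sequential non-overlapping placement with random inter-locus gaps."""

    def __init__(self, chroms: ChromSizes, rng, spacing, margin: int = 500):
        self.chroms = chroms
        self.rng = rng
        self.spacing = spacing
        self.order = chroms.names
        self.idx = 0
        self.cursor = margin
        self.margin = margin

    def take(self, width: int) -> tuple[str, int]:
        while self.idx < len(self.order):
            chrom = self.order[self.idx]
            gap = int(self.rng.integers(self.spacing[0], self.spacing[1] + 1))
            start = self.cursor + gap
            if start + width + self.margin <= self.chroms[chrom]:
                self.cursor = start + width
                return chrom, start
            self.idx += 1
            self.cursor = self.margin
        raise CapacityError("requested loci exceed genome capacity")


def build_annotation(
    chroms: ChromSizes | None = None,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> tuple[SyntheticAnnotation, TruthTable]:
    """Lay out genes, archetype loci, repeats and TF peaks; emit ground truth.

    Deterministic for a fixed (params, seed). NDR loci occupy exactly the
    band 50-100 bp upstream of their gene's TSS; TSS flanks sit on the
    first 250 bp downstream; gene-body loci sit inside the gene span.
    """
    chroms = chroms or default_chroms()
    params = params or GeneratorParams()
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    placer = _Placer(chroms, rng, params.spacing)

    loci_rows = []
    tx_rows = []

    def draw(archetype):
        lo, hi = params.lambda_ranges[archetype]
        olo, ohi = params.occupancy_ranges[archetype]
        return rng.uniform(lo, hi), rng.uniform(olo, ohi)

    n_body = params.counts.get("gene_body", 0)
    for g in range(params.n_genes):
        glen = int(rng.integers(params.gene_length[0], params.gene_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        # reserve room for the promoter flanks on both sides of the cassette
        chrom, start = placer.take(glen + 800)
        gs, ge = start + 400, start + 400 + glen
        tss = gs if strand == "+" else ge
        n_ex = int(rng.integers(2, 4))
        bounds = np.sort(rng.choice(np.arange(gs + 200, ge - 200), 2 * (n_ex - 1), replace=False))
        ex_starts = [gs] + list(bounds[1::2])
        ex_ends = list(bounds[0::2]) + [ge]
        fpkm = float(np.round(rng.lognormal(mean=1.0, sigma=1.8), 4))
        tx_rows.append({
            "transcript_id": f"synTx{g:04d}", "chrom": chrom, "start": gs,
            "end": ge, "strand": strand,
            "exon_starts": ",".join(map(str, ex_starts)),
            "exon_ends": ",".join(map(str, ex_ends)),
            "fpkm": fpkm,
        })
        if g < params.counts.get("ndr", 0):
            lam, occ = draw("ndr")
            s = tss - 100 if strand == "+" else tss + 50
            loci_rows.append((chrom, s, s + 50, "ndr", occ, lam, strand))
        if g < params.counts.get("tss_flank", 0):
            # promoter chromatin flanking the NDR on both sides: the +1
            # nucleosome territory downstream of the TSS and the -1 side
            # upstream of the NDR
            w = params.widths["tss_flank"]
            lam, occ = draw("tss_flank")
            s = tss if strand == "+" else tss - w
            loci_rows.append((chrom, s, s + w, "tss_flank", occ, lam, strand))
            lam, occ = draw("tss_flank")
            s = tss - 100 - w if strand == "+" else tss + 100
            loci_rows.append((chrom, s, s + w, "tss_flank", occ, lam, strand))
        if g < n_body:
            lam, occ = draw("gene_body")
            w = min(params.widths["gene_body"], glen - 600)
            s = gs + 400
            loci_rows.append((chrom, s, s + w, "gene_body", occ, lam, strand))

    standalone = ("heterochromatin", "distal_site", "satellite_repeat", "background")
    for archetype in standalone:
        w = params.widths[archetype]
        for _ in range(params.counts.get(archetype, 0)):
            chrom, s = placer.take(w)
            lam, occ = draw(archetype)
            loci_rows.append((chrom, s, s + w, archetype, occ, lam, "."))

    loci = pd.DataFrame(
        loci_rows,
        columns=["chrom", "start", "end", "archetype", "occupancy0",
                 "true_lambda", "strand"],
    )
    truth = TruthTable(
        loci[["chrom", "start", "end", "archetype", "occupancy0", "true_lambda"]]
    )
    transcripts = pd.DataFrame(
        tx_rows,
        columns=["transcript_id", "chrom", "start", "end", "strand",
                 "exon_starts", "exon_ends", "fpkm"],
    )

    rep_rows = []
    sat = loci[loci["archetype"] == "satellite_repeat"]
    for _, r in sat.iterrows():
        rep_rows.append((r["chrom"], r["start"], r["end"], "Satellite"))
    for _ in range(params.n_other_repeats):
        w = int(rng.integers(150, 500))
        fam = params.other_repeat_families[
            int(rng.integers(len(params.other_repeat_families)))
        ]
        # a share of non-satellite repeats sit inside gene spans (genic);
        # the rest go to intergenic space via the placer
        if tx_rows and rng.random() < params.genic_repeat_fraction:
            host = tx_rows[int(rng.integers(len(tx_rows)))]
            hs, he = host["start"] + 300, host["end"] - 300 - w
            if he > hs:
                s = int(rng.integers(hs, he))
                rep_rows.append((host["chrom"], s, s + w, fam))
                continue
        chrom, s = placer.take(w)
        rep_rows.append((chrom, s, s + w, fam))
    repeats = FeatureSet(
        "repeats",
        pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "name"]),
    )

    tf_peaks = []
    distal = loci[loci["archetype"] == "distal_site"]
    other_rep = repeats.intervals[repeats.intervals["name"] != "Satellite"]
    for tf in params.tf_names:
        peaks = []
        for source, p in ((sat, params.tf_p_satellite),
                          (other_rep, params.tf_p_other_repeat),
                          (distal, params.tf_p_distal)):
            for _, r in source.iterrows():
                if rng.random() < p:
                    mid = (int(r["start"]) + int(r["end"])) // 2
                    half = int(rng.integers(50, 150))
                    peaks.append((r["chrom"], max(0, mid - half), mid + half, tf))
        tf_peaks.append(FeatureSet(
            tf, pd.DataFrame(peaks, columns=["chrom", "start", "end", "name"])
        ))

    annotation = SyntheticAnnotation(chroms, FeatureSet("loci", loci),
                                     transcripts, repeats, tf_peaks)
    return annotation, truth


@dataclass
class SimulatedReads:
    """Read libraries per (timepoint, replicate) plus matched input libraries."""

    chip: dict          # (timepoint, replicate) -> read DataFrame
    input: dict         # replicate -> read DataFrame
    timepoints: tuple
    n_replicates: int

    def library(self, t: float, rep: int = 0) -> pd.DataFrame:
        return self.chip[(t, rep)]


def _reads_from_dyads(rng, chrom, dyads, chrom_len) -> pd.DataFrame:
    strand = np.where(rng.random(len(dyads)) < 0.5, "+", "-")
    five = np.where(strand == "+", dyads - _DYAD_SHIFT, dyads + _DYAD_SHIFT - 1)
    five = np.clip(five, 0, chrom_len - 1)
    return pd.DataFrame({"chrom": chrom, "five_prime": five.astype(int),
                         "strand": strand})


def simulate_reads(
    truth: TruthTable,
    chroms: ChromSizes,
    timepoints=(0, 6),
    depth: float = 1.0,
    seed: int = 0,
    n_replicates: int = 1,
    input_rate: float = 0.02,
) -> SimulatedReads:
    """Draw TET-OFF ChIP read libraries from the truth table.

    Per-locus counts at time t are Poisson with mean
    ``occupancy0 * depth * exp(-true_lambda * t)``; dyads are uniform
    within the locus. Input libraries are uniform over the genome at
    ``input_rate`` expected reads per bp. Each (timepoint, replicate)
    library uses its own deterministic sub-seed of ``seed``.
    """
    timepoints = tuple(float(t) for t in timepoints)
    if any(t < 0 for t in timepoints):
        raise ValueError("timepoints must be non-negative")
    if depth <= 0 or input_rate < 0:
        raise ValueError("depth must be positive and input_rate non-negative")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(timepoints) * n_replicates + n_replicates)
    chip = {}
    k = 0
    for t in timepoints:
        mean = truth.expected_counts(t, depth)
        for rep in range(n_replicates):
            rng = np.random.default_rng(children[k]); k += 1
            counts = rng.poisson(mean)
            parts = []
            for (chrom, start, end), cnt in zip(
                truth.df[["chrom", "start", "end"]].itertuples(index=False), counts
            ):
                if cnt == 0:
                    continue
                dyads = rng.integers(start, end, size=cnt)
                parts.append(_reads_from_dyads(rng, chrom, dyads, chroms[chrom]))
            chip[(t, rep)] = (
                pd.concat(parts, ignore_index=True)
                if parts
                else pd.DataFrame(columns=["chrom", "five_prime", "strand"])
            )
    inputs = {}
    for rep in range(n_replicates):
        rng = np.random.default_rng(children[k]); k += 1
        parts = []
        for chrom, length in chroms.items():
            cnt = rng.poisson(length * input_rate)
            dyads = rng.integers(0, length, size=cnt)
            parts.append(_reads_from_dyads(rng, chrom, dyads, length))
        inputs[rep] = pd.concat(parts, ignore_index=True)
    return SimulatedReads(chip, inputs, timepoints, n_replicates)


def expected_track(
    truth: TruthTable,
    grid: WindowGrid,
    t: float,
    depth: float = 1.0,
) -> SignalTrack:
    """Noiseless expectation counts on a window grid.

    Each locus's expected count at time t is apportioned to windows in
    proportion to overlap, so per-window count ratios between timepoints
    equal the per-locus ratios exactly.
    """
    if grid.overlapping:
        raise ValueError("expected_track requires a non-overlapping grid")
    values = np.zeros(grid.n_windows)
    means = truth.expected_counts(t, depth)
    for (chrom, start, end), mean in zip(
        truth.df[["chrom", "start", "end"]].itertuples(index=False), means
    ):
        off = grid.chrom_offset(chrom)
        w0, w1 = start // grid.width, (end - 1) // grid.width
        for w in range(w0, w1 + 1):
            ws, we = w * grid.width, min((w + 1) * grid.width, grid.chroms[chrom])
            overlap = min(end, we) - max(start, ws)
            values[off + w] += mean * overlap / (end - start)
    return SignalTrack(grid, values, library_size=float(values.sum()))


def write_fixture(
    outdir,
    annotation: SyntheticAnnotation,
    truth: TruthTable,
    reads: SimulatedReads,
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> None:
    """Write the synthetic dataset as plain-text BED/TSV/YAML files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    annotation.chroms.write(os.path.join(outdir, "chrom.sizes"))
    truth.write(os.path.join(outdir, "truth.tsv"), timepoints=reads.timepoints)
    annotation.loci.write_bed(os.path.join(outdir, "loci.bed"))
    annotation.repeats.write_bed(os.path.join(outdir, "repeats.bed"))
    annotation.transcripts.to_csv(
        os.path.join(outdir, "transcripts.tsv"), sep="\t", index=False
    )
    annotation.transcripts[["transcript_id", "fpkm"]].to_csv(
        os.path.join(outdir, "expression.tsv"), sep="\t", index=False
    )
    for fs in annotation.tf_peaks:
        fs.write_bed(os.path.join(outdir, f"peaks_{fs.name}.bed"))
    for (t, rep), df in reads.chip.items():
        write_reads_bed(df, os.path.join(outdir, f"reads_t{t:g}h_rep{rep}.bed"))
    for rep, df in reads.input.items():
        write_reads_bed(df, os.path.join(outdir, f"input_rep{rep}.bed"))
    config = {
        "seed": seed,
        "timepoints": list(reads.timepoints),
        "n_replicates": reads.n_replicates,
        "params": asdict(params) if params is not None else None,
    }
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_fixture_reads(path) -> pd.DataFrame:
    """Round-trip counterpart of the BED read files written by write_fixture."""
    return read_reads_bed(path)
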