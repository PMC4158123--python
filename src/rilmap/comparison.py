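"""Genetic-map vs physical-genome comparison and recombination landscape.

Marker physical positions (chromosome/scaffold + bp) are an input; each
mapped marker is classified exactly once:

syntenic
    physical chromosome equals the majority chromosome of its linkage
    group;
non-syntenic
    physically placed on a different chromosome (runs of >= 2 sharing a
    chromosome form non-syntenic clusters, candidate assembly errors or
    translocations);
unplaced-scaffold
    placed on a scaffold without a chromosome assignment — these inherit
    a (linkage group, cM interval) anchor from their map position;
no-physical-hit
    no physical placement at all.

Collinearity is measured per linkage group as Spearman's rank
correlation between map order and bp position over syntenic markers;
each group's orientation is normalised against the physical order (a
group with negative rho is flipped) since linkage-map orientation is
arbitrary.  Local inversions are flagged by sliding-window Spearman
correlations at or below a negative threshold and merged into maximal
segments.

The recombination landscape assigns each adjacent syntenic marker pair a
rate of delta-cM / delta-Mb, classified as hot (> 20 cM/Mb), moderate
(10 to < 20), cold (exactly 0) or normal.  Interval composition (gene
count by the midpoint rule, gene density, GC fraction) comes from a
:class:`GenomeAnnotation` built from BED/GFF3 and FASTA inputs.
Coordinates are 0-based half-open internally; outputs are labelled
1-based closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .mapping import LinkageGroup, OrderedMap

__all__ = [
    "GenomeAnnotation",
    "ComparisonReport",
    "anchor_markers",
    "spearman_per_lg",
    "orient_map",
    "detect_local_inversions",
    "interval_rate",
    "classify_rate",
    "interval_rates",
    "gene_density",
    "interval_composition",
    "genome_wide_rates",
    "read_gene_annotation",
]

HOT_THRESHOLD = 20.0
MODERATE_LOW = 10.0


# ----------------------------------------------------------------------
# annotation container
# ----------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Gene intervals (0-based half-open) and optional genome sequence.

    ``genes`` has columns chrom, start, end.  ``fasta`` is a pyfaidx
    Fasta (or None when no sequence is available).
    """

    genes: pd.DataFrame
    fasta: object = None
    assembly_span_bp: int | None = None

    @property
    def total_genes(self) -> int:
        return len(self.genes)


def read_gene_annotation(path: str, fasta_path: str | None = None) -> GenomeAnnotation:
    """Load gene intervals from BED (0-based half-open) or GFF3 (1-based
    closed, ``gene`` features) plus an optional FASTA."""
    path = str(path)
    if path.endswith((".bed", ".bed.txt")):
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
    elif path.endswith((".gff", ".gff3")):
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "source", "type", "start", "end", "score",
                   "strand", "phase", "attributes"],
        )
        genes = raw[raw["type"] == "gene"]
        df = pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": genes["start"].astype(int) - 1,  # to 0-based half-open
                "end": genes["end"].astype(int),
            }
        )
    else:
        raise ValueError(f"unrecognised annotation format: {path}")
    fasta = None
    span = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(fasta_path))
        span = int(sum(len(rec) for rec in fasta.values()))
    return GenomeAnnotation(genes=df.reset_index(drop=True), fasta=fasta,
                            assembly_span_bp=span)


# ----------------------------------------------------------------------
# marker classification
# ----------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Marker classification, collinearity and inversion results."""

    markers: pd.DataFrame  # per mapped marker: group, rank, cum_cm, chrom, bp, class
    majority_chrom: dict
    per_group_rho: pd.DataFrame
    nonsyntenic_clusters: pd.DataFrame
    scaffold_anchors: pd.DataFrame
    inversions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def class_counts(self) -> pd.Series:
        return self.markers["klass"].value_counts()


def _marker_frame(omap: OrderedMap, marker_info: pd.DataFrame) -> pd.DataFrame:
    df = omap.to_frame()
    info = marker_info.reindex(df["marker"])
    for col in ("scaffold", "chrom", "bp"):
        df[col] = info[col].to_numpy() if col in info.columns else np.nan
    return df


def anchor_markers(omap: OrderedMap, marker_info: pd.DataFrame) -> ComparisonReport:
    """Classify every mapped marker and anchor unplaced scaffolds.

    Linkage groups with no physically placed marker have an undefined
    majority chromosome; their markers are reported as ``unclassifiable``.
    """
    df = _marker_frame(omap, marker_info)
    majority = {}
    for label, sub in df.groupby("group"):
        placed = sub["chrom"].dropna()
        majority[label] = placed.mode().iloc[0] if not placed.empty else None

    def classify(row):
        maj = majority[row["group"]]
        if maj is None:
            return "unclassifiable"
        if pd.isna(row["chrom"]) and pd.isna(row["scaffold"]):
            return "no-physical-hit"
        if pd.isna(row["chrom"]):
            return "unplaced-scaffold"
        return "syntenic" if row["chrom"] == maj else "non-syntenic"

    df["klass"] = df.apply(classify, axis=1)

    # non-syntenic clusters: consecutive map runs sharing a physical chromosome
    clusters = []
    for label, sub in df.groupby("group", sort=False):
        sub = sub.sort_values("rank")
        run: list = []
        run_chrom = None
        for _, row in sub.iterrows():
            if row["klass"] == "non-syntenic" and (
                not run or row["chrom"] == run_chrom
            ):
                run.append(row)
                run_chrom = row["chrom"]
            else:
                if len(run) >= 2:
                    clusters.append((label, run_chrom, len(run),
                                     [r["marker"] for r in run]))
                run, run_chrom = [], None
                if row["klass"] == "non-syntenic":
                    run = [row]
                    run_chrom = row["chrom"]
        if len(run) >= 2:
            clusters.append((label, run_chrom, len(run),
                             [r["marker"] for r in run]))
    cluster_df = pd.DataFrame(
        clusters, columns=["group", "physical_chrom", "n_markers", "members"]
    )

    anchors = []
    unplaced = df[df["klass"] == "unplaced-scaffold"]
    for scaffold, sub in unplaced.groupby("scaffold"):
        for label, lg_sub in sub.groupby("group"):
            anchors.append(
                (scaffold, label, float(lg_sub["cum_cm"].min()),
                 float(lg_sub["cum_cm"].max()), len(lg_sub))
            )
    anchor_df = pd.DataFrame(
        anchors, columns=["scaffold", "group", "start_cm", "end_cm", "n_markers"]
    )

    rho = spearman_per_lg(omap, marker_info)
    return ComparisonReport(
        markers=df,
        majority_chrom=majority,
        per_group_rho=rho,
        nonsyntenic_clusters=cluster_df,
        scaffold_anchors=anchor_df,
    )


# ----------------------------------------------------------------------
# collinearity
# ----------------------------------------------------------------------

def _syntenic_positions(group: LinkageGroup, marker_info: pd.DataFrame):
    """(ranks, bp) for the group's markers placed on its majority chromosome."""
    info = marker_info.reindex(group.markers)
    chrom = info["chrom"].dropna()
    if chrom.empty:
        return None, None, None
    maj = chrom.mode().iloc[0]
    mask = (info["chrom"] == maj).to_numpy() & info["bp"].notna().to_numpy()
    ranks = np.nonzero(mask)[0]
    bp = info["bp"].to_numpy(dtype=float)[mask]
    return ranks, bp, maj


def spearman_per_lg(omap: OrderedMap, marker_info: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho between map order and physical bp per linkage group.

    Syntenic markers only; groups with fewer than 3 such markers get NaN.
    Reported after orientation normalisation, i.e. as |rho| with the
    flip recorded in column ``flipped``.
    """
    rows = []
    for g in omap.groups:
        ranks, bp, maj = _syntenic_positions(g, marker_info)
        if ranks is None or len(ranks) < 3:
            rows.append((g.label, None, np.nan, 0, False))
            continue
        rho = float(spearmanr(ranks, bp).statistic)
        flipped = rho < 0
        rows.append((g.label, maj, abs(rho) if flipped else rho, len(ranks),
                     flipped))
    return pd.DataFrame(
        rows, columns=["group", "chrom", "rho", "n_syntenic", "flipped"]
    )


def orient_map(omap: OrderedMap, marker_info: pd.DataFrame) -> OrderedMap:
    """Flip every linkage group whose map order runs against physical order."""
    rho = spearman_per_lg(omap, marker_info).set_index("group")
    groups = [
        g.reversed() if bool(rho.loc[g.label, "flipped"]) else g
        for g in omap.groups
    ]
    return OrderedMap(groups=groups, unplaced=list(omap.unplaced))


def detect_local_inversions(
    omap: OrderedMap,
    marker_info: pd.DataFrame,
    window: int = 10,
    rho_threshold: float = -0.8,
) -> pd.DataFrame:
    """Flag map segments whose local order runs against the assembly.

    A sliding window of ``window`` consecutive syntenic markers is
    scored by Spearman rho between map rank and bp; windows with
    rho <= ``rho_threshold`` are flagged and overlapping flags merged
    into maximal segments.  Linkage groups are orientation-normalised
    first.  Returns one row per segment with cM and bp extents,
    segment-wide rho and marker count.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    if rho_threshold >= 0:
        raise ValueError("rho_threshold must be negative")
    omap = orient_map(omap, marker_info)
    segments = []
    for g in omap.groups:
        ranks, bp, maj = _syntenic_positions(g, marker_info)
        if ranks is None or len(ranks) < window:
            continue
        k = len(ranks)
        flagged = np.zeros(k, dtype=bool)
        for s in range(k - window + 1):
            rho = spearmanr(np.arange(window), bp[s:s + window]).statistic
            if rho <= rho_threshold:
                flagged[s:s + window] = True
        # maximal runs of flagged syntenic markers
        s = 0
        while s < k:
            if not flagged[s]:
                s += 1
                continue
            e = s
            while e + 1 < k and flagged[e + 1]:
                e += 1
            seg_rho = float(spearmanr(np.arange(e - s + 1), bp[s:e + 1]).statistic)
            first, last = ranks[s], ranks[e]
            segments.append(
                (
                    g.label,
                    maj,
                    float(g.cum_cm[first]),
                    float(g.cum_cm[last]),
                    int(min(bp[s], bp[e])),
                    int(max(bp[s], bp[e])),
                    seg_rho,
                    int(e - s + 1),
                    [g.markers[j] for j in ranks[s:e + 1]],
                )
            )
            s = e + 1
    return pd.DataFrame(
        segments,
        columns=["group", "chrom", "start_cm", "end_cm", "start_bp", "end_bp",
                 "rho", "n_markers", "members"],
    )


# ----------------------------------------------------------------------
# recombination landscape
# ----------------------------------------------------------------------

def interval_rate(delta_cm: float, delta_bp: float) -> float:
    """Recombination rate in cM/Mb for a genetic/physical span."""
    if delta_bp <= 0:
        raise ValueError("physical span must be positive")
    return delta_cm / (delta_bp / 1e6)


def classify_rate(rate: float) -> str:
    """hot (> 20 cM/Mb), cold (exactly 0), moderate (10 to < 20), normal."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return "cold"
    if rate > HOT_THRESHOLD:
        return "hot"
    if MODERATE_LOW <= rate < HOT_THRESHOLD:
        return "moderate"
    return "normal"


def interval_rates(omap: OrderedMap, marker_info: pd.DataFrame):
    """Adjacent-pair, per-chromosome and genome-wide recombination rates.

    Linkage groups are orientation-normalised, then every adjacent pair
    of syntenic markers contributes one interval with rate
    delta-cM / delta-Mb.  Intervals whose physical positions run
    backwards (out-of-order assembly) are skipped and returned in the
    third element.  Returns ``(intervals, per_chrom, genome_rate)``.
    """
    omap = orient_map(omap, marker_info)
    rows, skipped = [], []
    chrom_spans = []
    for g in omap.groups:
        ranks, bp, maj = _syntenic_positions(g, marker_info)
        if ranks is None or len(ranks) < 2:
            continue
        cm = g.cum_cm[ranks]
        for i in range(len(ranks) - 1):
            d_bp = bp[i + 1] - bp[i]
            d_cm = float(cm[i + 1] - cm[i])
            left, right = g.markers[ranks[i]], g.markers[ranks[i + 1]]
            if d_bp <= 0:
                skipped.append((g.label, left, right, d_cm, float(d_bp)))
                continue
            rate = interval_rate(d_cm, d_bp)
            rows.append(
                (g.label, maj, left, right, float(cm[i]), float(cm[i + 1]),
                 int(bp[i]), int(bp[i + 1]), d_cm, float(d_bp), rate,
                 classify_rate(rate))
            )
        span_bp = float(bp.max() - bp.min())
        span_cm = float(cm.max() - cm.min())
        if span_bp > 0:
            chrom_spans.append(
                (g.label, maj, span_cm, span_bp / 1e6,
                 interval_rate(span_cm, span_bp))
            )
    intervals = pd.DataFrame(
        rows,
        columns=["group", "chrom", "left", "right", "start_cm", "end_cm",
                 "start_bp", "end_bp", "delta_cm", "delta_bp", "rate_cm_per_mb",
                 "klass"],
    )
    per_chrom = pd.DataFrame(
        chrom_spans, columns=["group", "chrom", "span_cm", "span_mb",
                              "rate_cm_per_mb"]
    )
    genome_rate = (
        interval_rate(per_chrom["span_cm"].sum(),
                      per_chrom["span_mb"].sum() * 1e6)
        if len(per_chrom)
        else float("nan")
    )
    skipped_df = pd.DataFrame(
        skipped, columns=["group", "left", "right", "delta_cm", "delta_bp"]
    )
    return intervals, per_chrom, genome_rate, skipped_df


def gene_density(n_genes: int, delta_bp: float) -> float:
    """Genes per Mb over a physical span."""
    if delta_bp <= 0:
        raise ValueError("physical span must be positive")
    return n_genes / (delta_bp / 1e6)


def interval_composition(
    chrom: str, start_bp: int, end_bp: int, annotation: GenomeAnnotation
) -> dict:
    """Gene count (midpoint rule), gene density and GC of one interval.

    ``start_bp``/``end_bp`` are 0-based half-open.  A gene belongs to
    the interval when its midpoint lies inside, so genes are never
    double-counted across interval boundaries.  GC is computed over
    unambiguous bases; None when no FASTA was loaded.
    """
    if end_bp <= start_bp:
        raise ValueError("interval must have positive length")
    genes = annotation.genes
    sub = genes[genes["chrom"] == chrom]
    mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
    count = int(((mid >= start_bp) & (mid < end_bp)).sum())
    gc = None
    if annotation.fasta is not None and chrom in annotation.fasta:
        seq = str(annotation.fasta[chrom][start_bp:end_bp]).upper()
        counts = {b: seq.count(b) for b in "ACGT"}
        denom = sum(counts.values())
        gc = (counts["G"] + counts["C"]) / denom if denom else float("nan")
    return {
        "gene_count": count,
        "gene_density_per_mb": gene_density(count, end_bp - start_bp),
        "gc_fraction": gc,
    }


def genome_wide_rates(
    total_cm: float,
    span_mb: float,
    n_markers: int,
    total_genes: int | None = None,
) -> dict:
    """Genome-scale summary rates.

    Returns cM/Mb over the marker-flanked genome span, genes per cM
    (when a gene total is given) and kbp per marker.
    """
    out = {
        "cm_per_mb": interval_rate(total_cm, span_mb * 1e6),
        "kbp_per_marker": span_mb * 1e3 / n_markers,
    }
    if total_genes is not None:
        out["genes_per_cm"] = total_genes / total_cm
    return out
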