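"""Readers and writers for the pipeline's plain-text formats.

Genotype matrices travel as TSV/CSV with lines as rows and markers as
columns, calls A/B/H/U (configurable aliases, e.g. 0/1/2/NA).  A VCF
subset dialect maps sample GT fields onto the four-symbol alphabet
against a declared parent-1 allele (REF by default).  Marker metadata,
QC reports, maps and all diagnostic tables are plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .matrix import GenotypeMatrix, CALL_SYMBOLS
from .mapping import OrderedMap, LinkageGroup

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_marker_info",
    "write_marker_info",
    "read_vcf_genotypes",
    "write_map",
    "read_map",
    "PipelineConfig",
]


def read_genotypes(
    path,
    dialect: str = "tsv",
    aliases: dict | None = None,
    parent1_allele: str = "ref",
) -> GenotypeMatrix:
    """Read a genotype matrix.

    ``dialect`` is ``tsv``, ``csv`` or ``vcf`` (a read-only VCF subset:
    GT fields are mapped to A/H/B/U with parent 1 declared as the REF or
    ALT allele).  ``aliases`` maps file symbols to A/B/H/U, e.g.
    ``{"0": "A", "2": "B", "1": "H", "NA": "U"}``.  Unknown symbols
    raise a ``ValueError`` listing the offending cells.
    """
    if dialect == "vcf":
        return read_vcf_genotypes(path, parent1_allele=parent1_allele)
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect: {dialect}")
    sep = "\t" if dialect == "tsv" else ","
    # keep_default_na so symbols like "NA" survive for alias mapping
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    if df.empty:
        raise ValueError(f"empty genotype file: {path}")
    if aliases:
        df = df.replace(aliases)
    bad = ~df.isin(CALL_SYMBOLS)
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        cells = [
            f"({df.index[r]}, {df.columns[c]}) = {df.iat[r, c]!r}"
            for r, c in zip(rows[:10], cols[:10])
        ]
        raise ValueError("unknown genotype symbols: " + "; ".join(cells))
    return GenotypeMatrix(df, validate=False)


def write_genotypes(matrix: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    sep = "\t" if dialect == "tsv" else ","
    matrix.calls.to_csv(path, sep=sep, index_label="line")


def read_vcf_genotypes(path, parent1_allele: str = "ref") -> GenotypeMatrix:
    """Map VCF sample genotypes to A/H/B/U calls.

    With ``parent1_allele="ref"``: 0/0 -> A, 1/1 -> B, 0/1 -> H,
    ./. -> U (swapped for ``"alt"``).  Marker ids are the VCF ID field
    when set, else chrom:pos.
    """
    if parent1_allele not in ("ref", "alt"):
        raise ValueError("parent1_allele must be 'ref' or 'alt'")
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    hom_ref, hom_alt = ("A", "B") if parent1_allele == "ref" else ("B", "A")
    lut = {0: hom_ref, 1: "H", 2: "U", 3: hom_alt}
    markers, columns = [], []
    for rec in vcf:
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        markers.append(mid)
        columns.append([lut[t] for t in rec.gt_types])
    vcf.close()
    if not markers:
        raise ValueError(f"no variant records in {path}")
    values = np.array(columns, dtype="U1").T  # samples x markers
    return GenotypeMatrix.from_values(values, samples, markers)


def read_marker_info(path) -> pd.DataFrame:
    """Marker metadata TSV: columns marker, scaffold, chrom, bp (+extras),
    indexed by marker id."""
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "chrom": str})
    if "marker" not in df.columns:
        raise ValueError("marker info must have a 'marker' column")
    return df.set_index("marker")


def write_marker_info(info: pd.DataFrame, path) -> None:
    info.to_csv(path, sep="\t", index_label="marker")


def write_map(omap: OrderedMap, path) -> None:
    """Write an ordered map as tidy TSV (group, rank, marker, adj_rf,
    adj_cm, cum_cm); unplaced markers get group 'unplaced'."""
    df = omap.to_frame()
    if omap.unplaced:
        extra = pd.DataFrame(
            {
                "group": "unplaced",
                "rank": range(1, len(omap.unplaced) + 1),
                "marker": omap.unplaced,
                "adj_rf": np.nan,
                "adj_cm": np.nan,
                "cum_cm": np.nan,
            }
        )
        df = pd.concat([df, extra], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)


def read_map(path) -> OrderedMap:
    """Rebuild an :class:`OrderedMap` from :func:`write_map` output."""
    df = pd.read_csv(path, sep="\t")
    groups = []
    unplaced: list = []
    for label, sub in df.groupby("group", sort=False):
        sub = sub.sort_values("rank")
        if label == "unplaced":
            unplaced = sub["marker"].tolist()
            continue
        adj_cm = sub["adj_cm"].to_numpy(dtype=float)[1:]
        adj_rf = sub["adj_rf"].to_numpy(dtype=float)[1:]
        groups.append(
            LinkageGroup(
                label=str(label),
                markers=sub["marker"].tolist(),
                adjacent_rf=adj_rf,
                adjacent_cm=adj_cm,
                cum_cm=np.concatenate([[0.0], np.cumsum(adj_cm)]),
            )
        )
    return OrderedMap(groups=groups, unplaced=unplaced)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults are the standard thresholds
    used throughout the package (RAD filters 0.66/0.10/0.2-0.8, grouping
    cutoff 0.2, rippling window 5, distortion alpha 0.05 with 0.4/0.6
    band, hot > 20 / cold = 0 cM/Mb)."""

    genotypes: str = ""
    marker_info: str | None = None
    annotation: str | None = None
    fasta: str | None = None
    out_dir: str = "rilmap_out"
    dialect: str = "tsv"
    seed: int = 0
    profile: str = "rad"
    max_line_het: float = 0.10
    max_line_missing: float | None = 0.25
    bin_scope: str = "genome"
    cutoff: float = 0.2
    min_informative: int = 20
    window: int = 5
    n_starts: int = 30
    ril_correction: bool = False
    split_gap_cm: float | None = None
    generations: int = 7
    alpha: float = 0.05
    af_band: tuple = (0.4, 0.6)
    bonferroni: bool = False
    sdr_max_gap: int = 0
    inversion_window: int = 10
    inversion_rho: float = -0.8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "af_band" in raw:
            raw["af_band"] = tuple(raw["af_band"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["af_band"] = list(d["af_band"])
        return d
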