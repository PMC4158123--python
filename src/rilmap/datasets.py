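"""Packaged summary statistics of the published CPR-01 chickpea map.

CPR-01 is an intraspecific chickpea RIL population (ICCV 96029 x
CDC Frontier, 92 F7-derived lines) whose high-density genetic map was
aligned to the CDC Frontier draft genome.  The raw sequencing data
behind that map are not shipped here; what is shipped are the published
per-linkage-group summaries, per-chromosome genetic/physical spans, the
flanking-marker hotspot/coldspot intervals and a handful of population
constants.  They serve as worked-example inputs for the arithmetic
stages of the pipeline (spacing, coverage, recombination rates, gene
density) and as reference points for its outputs.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = [
    "load_map_summary",
    "load_chromosome_rates",
    "load_recombination_intervals",
    "load_constants",
]


def _path(name: str):
    return resources.files("rilmap.data").joinpath(name)


def load_map_summary() -> pd.DataFrame:
    """Per-linkage-group bin/marker counts and map lengths (cM)."""
    with resources.as_file(_path("cpr01_map_summary.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_chromosome_rates() -> pd.DataFrame:
    """Per-linkage-group genetic length (cM) and marker-flanked span (Mb)."""
    with resources.as_file(_path("cpr01_chromosome_rates.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_recombination_intervals() -> pd.DataFrame:
    """Published hotspot/coldspot intervals: flanking markers, cM bounds,
    bp span, GC percentage and gene count."""
    with resources.as_file(_path("cpr01_recombination_intervals.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_constants() -> dict:
    """Population-level constants (lines, generation, marker and gene
    totals, whole-population heterozygosity, genome span)."""
    with resources.as_file(_path("cpr01_constants.json")) as p:
        return json.loads(p.read_text())
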