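"""End-to-end pipeline orchestration: QC -> impute/bin -> map ->
diagnostics -> genome comparison, with every intermediate written to
disk and a machine-readable run manifest."""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, binning, comparison, diagnostics, qc
from .io import (
    PipelineConfig,
    read_genotypes,
    read_marker_info,
    write_genotypes,
    write_map,
)
from .mapping import build_map

__all__ = ["run_pipeline"]


def _log(stage: str, msg: str) -> None:
    print(f"[rilmap:{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured inputs; returns the manifest.

    Writes, under ``config.out_dir``: filtered genotypes, QC reports,
    imputation log, bin membership, the map, diagnostic and comparison
    tables, and ``manifest.json``.  A stage failure raises with the
    stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "rilmap",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }

    stage = "qc"
    try:
        matrix = read_genotypes(config.genotypes, dialect=config.dialect)
        _log(stage, f"loaded {matrix.n_lines} lines x {matrix.n_markers} markers")
        marker_info = (
            read_marker_info(config.marker_info) if config.marker_info else None
        )
        filtered, mreport = qc.filter_markers(matrix, profile=config.profile)
        filtered, lreport = qc.filter_lines(
            filtered,
            max_line_het=config.max_line_het,
            max_line_missing=config.max_line_missing,
        )
        mreport.per_marker.to_csv(out / "qc_markers.tsv", sep="\t")
        lreport.per_line.to_csv(out / "qc_lines.tsv", sep="\t")
        removed = pd.concat(
            [mreport.removed_markers, lreport.removed_lines], ignore_index=True
        )
        removed.to_csv(out / "qc_removed.tsv", sep="\t", index=False)
        write_genotypes(filtered, out / "genotypes_filtered.tsv")
        manifest["stages"][stage] = {
            "lines_in": matrix.n_lines,
            "markers_in": matrix.n_markers,
            "markers_removed": len(mreport.removed_markers),
            "markers_retained": filtered.n_markers,
            "lines_removed": len(lreport.removed_lines),
            "lines_retained": filtered.n_lines,
        }
        _log(stage, f"retained {filtered.n_lines} lines x {filtered.n_markers} markers")
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    stage = "bin"
    try:
        if marker_info is not None:
            imputed, imp_log = binning.impute_flanking(filtered, marker_info)
        else:
            imputed, imp_log = filtered, pd.DataFrame(
                columns=["line", "marker", "call"]
            )
        imp_log.to_csv(out / "imputation_log.tsv", sep="\t", index=False)
        reduced, bins = binning.bin_identical(
            imputed, marker_info, scope=config.bin_scope
        )
        members = pd.DataFrame(
            [
                (b.bin_id, b.representative, mk)
                for b in bins
                for mk in b.members
            ],
            columns=["bin", "representative", "marker"],
        )
        members.to_csv(out / "bins.tsv", sep="\t", index=False)
        write_genotypes(reduced, out / "genotypes_binned.tsv")
        manifest["stages"][stage] = {
            "markers_in": imputed.n_markers,
            "imputed_calls": len(imp_log),
            "bins": len(bins),
        }
        _log(stage, f"{len(imp_log)} calls imputed; {len(bins)} bins")
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    stage = "map"
    try:
        omap = build_map(
            reduced,
            marker_info,
            cutoff=config.cutoff,
            min_informative=config.min_informative,
            window=config.window,
            n_starts=config.n_starts,
            seed=config.seed,
            ril_correction=config.ril_correction,
            generations=config.generations if config.ril_correction else None,
            split_gap_cm=config.split_gap_cm,
        )
        write_map(omap, out / "map.tsv")
        manifest["stages"][stage] = {
            "markers_in": reduced.n_markers,
            "linkage_groups": len(omap.groups),
            "markers_placed": omap.n_markers,
            "markers_unplaced": len(omap.unplaced),
            "total_length_cm": round(omap.total_length_cm, 3),
        }
        _log(stage, f"{len(omap.groups)} groups, {omap.total_length_cm:.1f} cM")
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    stage = "diagnose"
    try:
        summary = diagnostics.map_summary(omap)
        summary.to_csv(out / "map_summary.tsv", sep="\t", index=False)
        cov = diagnostics.chakravarti_estimate(omap)
        cov.per_group.to_csv(out / "coverage.tsv", sep="\t", index=False)
        het = diagnostics.residual_heterozygosity(filtered, config.generations)
        dist = diagnostics.distortion_table(
            reduced, alpha=config.alpha, af_bounds=config.af_band,
            bonferroni=config.bonferroni,
        )
        dist.to_csv(out / "distortion.tsv", sep="\t")
        sdr = diagnostics.detect_sdr(omap, dist, max_gap_markers=config.sdr_max_gap)
        sdr.to_csv(out / "sdr.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "coverage": round(cov.coverage, 4),
            "estimated_length_cm": round(cov.estimated_total_cm, 2),
            "population_het": round(het["population"], 5),
            "het_fold_vs_expected": round(het["fold"], 3),
            "distorted_markers": int(dist["distorted"].sum()),
            "sdr_regions": len(sdr),
        }
        _log(stage, f"{int(dist['distorted'].sum())} distorted markers, "
                    f"{len(sdr)} SDRs")
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    stage = "compare"
    if marker_info is not None and "chrom" in marker_info.columns:
        try:
            report = comparison.anchor_markers(omap, marker_info)
            report.markers.to_csv(out / "comparison_markers.tsv", sep="\t",
                                  index=False)
            report.per_group_rho.to_csv(out / "comparison_rho.tsv", sep="\t",
                                        index=False)
            inversions = comparison.detect_local_inversions(
                omap, marker_info,
                window=config.inversion_window,
                rho_threshold=config.inversion_rho,
            )
            inv_bed = inversions.assign(
                start0=lambda d: d["start_bp"] - 1
            )[["chrom", "start0", "end_bp", "group"]]
            inv_bed.to_csv(out / "inversions.bed", sep="\t", index=False,
                           header=False)
            inversions.drop(columns=["members"]).to_csv(
                out / "inversions.tsv", sep="\t", index=False
            )
            intervals, per_chrom, genome_rate, skipped = comparison.interval_rates(
                omap, marker_info
            )
            intervals.to_csv(out / "interval_rates.tsv", sep="\t", index=False)
            per_chrom.to_csv(out / "chromosome_rates.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "syntenic": int((report.markers["klass"] == "syntenic").sum()),
                "non_syntenic": int(
                    (report.markers["klass"] == "non-syntenic").sum()
                ),
                "unplaced_scaffold": int(
                    (report.markers["klass"] == "unplaced-scaffold").sum()
                ),
                "no_physical_hit": int(
                    (report.markers["klass"] == "no-physical-hit").sum()
                ),
                "inversion_segments": len(inversions),
                "genome_rate_cm_per_mb": round(float(genome_rate), 3),
                "hot_intervals": int((intervals["klass"] == "hot").sum()),
                "cold_intervals": int((intervals["klass"] == "cold").sum()),
            }
            _log(stage, f"genome rate {genome_rate:.2f} cM/Mb, "
                        f"{len(inversions)} inversion segments")
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    else:
        manifest["stages"][stage] = {"skipped": "no physical marker positions"}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
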