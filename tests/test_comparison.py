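import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rilmap.comparison import (
    GenomeAnnotation,
    anchor_markers,
    classify_rate,
    detect_local_inversions,
    gene_density,
    genome_wide_rates,
    interval_composition,
    interval_rate,
    interval_rates,
    read_gene_annotation,
    spearman_per_lg,
)
from rilmap.mapping import LinkageGroup, OrderedMap


def lg_with_physical(bp_order, label="LG1", chrom="Ca1", spacing=1.0):
    """Map of len(bp_order) markers at `spacing` cM whose physical bp
    follow bp_order (a permutation of ranks)."""
    n = len(bp_order)
    markers = [f"{label}_m{i:02d}" for i in range(n)]
    adj = np.full(n - 1, spacing)
    group = LinkageGroup(
        label=label, markers=markers,
        adjacent_rf=np.full(n - 1, 0.01),
        adjacent_cm=adj,
        cum_cm=np.concatenate([[0.0], np.cumsum(adj)]),
    )
    info = pd.DataFrame(
        {
            "scaffold": [f"s{i}" for i in range(n)],
            "chrom": chrom,
            "bp": (np.asarray(bp_order) + 1) * 100_000,
        },
        index=pd.Index(markers, name="marker"),
    )
    return OrderedMap(groups=[group]), info


class TestSpearman:
    def test_collinear_is_one(self):
        omap, info = lg_with_physical(range(10))
        rho = spearman_per_lg(omap, info)
        assert rho.iloc[0]["rho"] == pytest.approx(1.0)

    def test_single_swap_rank_formula(self):
        # ranks (1,2,3,5,4): rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 0.9
        omap, info = lg_with_physical([0, 1, 2, 4, 3])
        rho = spearman_per_lg(omap, info)
        assert rho.iloc[0]["rho"] == pytest.approx(0.9)

    def test_reversal_normalised(self):
        omap, info = lg_with_physical(list(range(10))[::-1])
        rho = spearman_per_lg(omap, info)
        assert rho.iloc[0]["rho"] == pytest.approx(1.0)
        assert bool(rho.iloc[0]["flipped"])

    def test_matches_rank_oracle_with_ties(self):
        rng = np.random.default_rng(4)
        bp = rng.integers(0, 50, size=30)  # ties likely
        omap, info = lg_with_physical(range(30))
        info["bp"] = bp
        rho = spearman_per_lg(omap, info)
        expected = abs(spearmanr(np.arange(30), bp).statistic)
        assert rho.iloc[0]["rho"] == pytest.approx(expected)


class TestAnchorMarkers:
    def test_majority_rule_flags_minority(self):
        omap, info = lg_with_physical(range(10))
        info.loc[info.index[3], "chrom"] = "Ca6"
        report = anchor_markers(omap, info)
        counts = report.class_counts()
        assert counts["syntenic"] == 9
        assert counts["non-syntenic"] == 1
        assert report.majority_chrom["LG1"] == "Ca1"

    def test_cluster_of_five_detected(self):
        omap, info = lg_with_physical(range(12))
        info.loc[info.index[4:9], "chrom"] = "Ca6"
        report = anchor_markers(omap, info)
        assert len(report.nonsyntenic_clusters) == 1
        row = report.nonsyntenic_clusters.iloc[0]
        assert row["n_markers"] == 5
        assert row["physical_chrom"] == "Ca6"

    def test_unplaced_scaffold_and_no_hit(self):
        omap, info = lg_with_physical(range(8))
        info.loc[info.index[2], "chrom"] = np.nan  # scaffold only
        info.loc[info.index[5], ["chrom", "scaffold", "bp"]] = np.nan
        report = anchor_markers(omap, info)
        counts = report.class_counts()
        assert counts["unplaced-scaffold"] == 1
        assert counts["no-physical-hit"] == 1
        anchors = report.scaffold_anchors
        assert list(anchors["scaffold"]) == ["s2"]
        assert anchors.iloc[0]["group"] == "LG1"

    def test_every_marker_classified_once(self):
        omap, info = lg_with_physical(range(15))
        info.loc[info.index[4], "chrom"] = "Ca2"
        report = anchor_markers(omap, info)
        assert len(report.markers) == 15
        assert report.markers["klass"].notna().all()


class TestLocalInversions:
    def test_reversed_block_found_once(self):
        order = list(range(40))
        order[12:27] = order[12:27][::-1]  # 15-marker inversion
        omap, info = lg_with_physical(order)
        seg = detect_local_inversions(omap, info, window=10,
                                      rho_threshold=-0.8)
        assert len(seg) == 1
        members = seg.iloc[0]["members"]
        core = [f"LG1_m{i:02d}" for i in range(12, 27)]
        assert set(core) <= set(members)

    def test_collinear_has_no_segments(self):
        omap, info = lg_with_physical(range(40))
        seg = detect_local_inversions(omap, info)
        assert seg.empty

    def test_two_blocks_found_separately(self):
        order = list(range(60))
        order[5:20] = order[5:20][::-1]
        order[35:50] = order[35:50][::-1]
        omap, info = lg_with_physical(order)
        seg = detect_local_inversions(omap, info, window=10)
        assert len(seg) == 2

    def test_short_group_skipped(self):
        omap, info = lg_with_physical(range(6))
        seg = detect_local_inversions(omap, info, window=10)
        assert seg.empty


class TestIntervalRates:
    def test_rate_arithmetic(self):
        assert interval_rate(77.4, 16.1e6) == pytest.approx(4.8, abs=0.01)
        assert interval_rate(1.2, 22262) == pytest.approx(53.9, abs=0.01)

    @pytest.mark.parametrize(
        "rate, klass",
        [(0.0, "cold"), (5.0, "normal"), (10.0, "moderate"),
         (19.99, "moderate"), (20.0, "normal"), (20.01, "hot"), (53.9, "hot")],
    )
    def test_classes(self, rate, klass):
        assert classify_rate(rate) == klass

    def test_zero_cm_interval_is_cold(self):
        omap, info = lg_with_physical(range(5))
        omap.groups[0].adjacent_cm[2] = 0.0
        omap.groups[0].cum_cm = np.concatenate(
            [[0.0], np.cumsum(omap.groups[0].adjacent_cm)])
        intervals, _, _, _ = interval_rates(omap, info)
        assert intervals.iloc[2]["klass"] == "cold"

    def test_out_of_order_bp_skipped(self):
        omap, info = lg_with_physical([0, 1, 2, 3, 4])
        info.loc[info.index[2], "bp"] = info.iloc[1]["bp"]  # zero span
        intervals, _, _, skipped = interval_rates(omap, info)
        assert len(skipped) == 1
        assert len(intervals) == 3

    def test_chromosome_rate_is_weighted_mean(self):
        rng = np.random.default_rng(8)
        omap, info = lg_with_physical(range(20))
        omap.groups[0].adjacent_cm = rng.uniform(0.1, 3.0, 19)
        omap.groups[0].cum_cm = np.concatenate(
            [[0.0], np.cumsum(omap.groups[0].adjacent_cm)])
        intervals, per_chrom, _, _ = interval_rates(omap, info)
        w = intervals["delta_bp"]
        weighted = (intervals["rate_cm_per_mb"] * w).sum() / w.sum()
        assert per_chrom.iloc[0]["rate_cm_per_mb"] == pytest.approx(weighted)

    def test_genome_wide_summary(self):
        out = genome_wide_rates(total_cm=652.9, span_mb=321.9, n_markers=1336,
                                total_genes=28269)
        assert out["cm_per_mb"] == pytest.approx(2.0, abs=0.05)
        assert out["kbp_per_marker"] == pytest.approx(240.9, abs=0.1)
        assert out["genes_per_cm"] == pytest.approx(43.3, abs=0.05)


class TestComposition:
    def test_midpoint_rule_and_density(self):
        genes = pd.DataFrame(
            {"chrom": "c1", "start": [100, 900, 1900], "end": [300, 1100, 2100]}
        )
        ann = GenomeAnnotation(genes=genes)
        out = interval_composition("c1", 0, 1000, ann)
        # midpoints 200, 1000, 2000 -> only the first is inside [0, 1000)
        assert out["gene_count"] == 1
        assert out["gene_density_per_mb"] == pytest.approx(1000.0)
        assert out["gc_fraction"] is None

    def test_empty_interval(self):
        ann = GenomeAnnotation(genes=pd.DataFrame(
            {"chrom": [], "start": [], "end": []}))
        out = interval_composition("c1", 0, 10_000, ann)
        assert out["gene_count"] == 0
        assert out["gene_density_per_mb"] == 0.0

    def test_gc_from_fasta(self, tmp_path):
        fasta = tmp_path / "toy.fa"
        fasta.write_text(">c1\nGGCCGGCCAT\n")
        bed = tmp_path / "genes.bed"
        bed.write_text("c1\t0\t4\n")
        ann = read_gene_annotation(str(bed), fasta_path=str(fasta))
        out = interval_composition("c1", 0, 8, ann)
        assert out["gc_fraction"] == pytest.approx(1.0)
        out2 = interval_composition("c1", 0, 10, ann)
        assert out2["gc_fraction"] == pytest.approx(0.8)

    def test_gff3_gene_features(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "c1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=t1\n"
            "c1\tsrc\tgene\t501\t700\t.\t-\t.\tID=g2\n"
        )
        ann = read_gene_annotation(str(gff))
        assert ann.total_genes == 2
        assert ann.genes.iloc[0]["start"] == 100  # converted to 0-based
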