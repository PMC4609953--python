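"""Sliding-window calling, breakpoint placement, consensus-bin grid and
bin genotyping, checked against hand enumerations and the simulation truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skimqtl import binning
from skimqtl.binning import UNRESOLVED, BinningParams, Breakpoint, SegmentCall
from skimqtl.core import A, B, MISSING, GeneAnnotation


class TestWindowGenotypes:
    def make_calls(self, pattern):
        calls = np.array(pattern, dtype=np.int8)
        positions = np.arange(1, len(calls) + 1) * 1000
        return positions, calls

    def test_majority_nine_of_fifteen(self):
        pos, calls = self.make_calls([A] * 12 + [B] * 3)
        win = binning.window_genotypes(pos, calls, BinningParams())
        assert win["call"].tolist() == [A]

    def test_unanimous(self):
        pos, calls = self.make_calls([A] * 15)
        win = binning.window_genotypes(pos, calls, BinningParams())
        assert win["call"].tolist() == [A]

    def test_eight_seven_unresolved(self):
        pos, calls = self.make_calls([A] * 8 + [B] * 7)
        win = binning.window_genotypes(pos, calls, BinningParams())
        assert win["call"].tolist() == [UNRESOLVED]

    def test_windows_skip_missing_calls(self):
        pattern = [A, MISSING] * 15  # 15 informative SNPs at odd indices
        pos, calls = self.make_calls(pattern)
        win = binning.window_genotypes(pos, calls, BinningParams())
        assert len(win) == 1
        assert win.loc[0, "first_pos"] == 1000
        assert win.loc[0, "last_pos"] == 29 * 1000

    def test_too_few_calls_warns_empty(self):
        pos, calls = self.make_calls([A] * 10)
        with pytest.warns(UserWarning, match="unresolved"):
            win = binning.window_genotypes(pos, calls, BinningParams())
        assert win.empty

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=15, max_size=40), st.data())
    def test_monotone_in_evidence(self, pattern, data):
        # flipping one B to A never turns a called A into B
        calls = np.array(pattern, dtype=np.int8)
        b_sites = np.flatnonzero(calls == B)
        if len(b_sites) == 0:
            return
        flip = data.draw(st.sampled_from(b_sites.tolist()))
        pos = np.arange(1, len(calls) + 1) * 100
        before = binning.window_genotypes(pos, calls, BinningParams())["call"]
        flipped = calls.copy()
        flipped[flip] = A
        after = binning.window_genotypes(pos, flipped, BinningParams())["call"]
        moved_away_from_a = (before == A) & (after == B)
        assert not moved_away_from_a.any()


class TestDetectBreakpoints:
    def runs_frame(self, spec):
        """spec: list of (call, first_pos, last_pos) windows."""
        return pd.DataFrame(
            [{"first_pos": f, "last_pos": l, "n_a": 0, "call": c} for c, f, l in spec]
        )

    def test_single_transition_interval_and_midpoint(self):
        win = self.runs_frame(
            [(A, 1_000_000, 4_800_000), (A, 1_200_000, 5_000_000),
             (B, 5_200_000, 8_800_000), (B, 5_400_000, 9_000_000)]
        )
        seg = binning.detect_breakpoints(win, BinningParams(), chrom="Ca1")
        assert len(seg.breakpoints) == 1
        bp = seg.breakpoints[0]
        assert (bp.lo, bp.hi) == (5_000_000, 5_200_000)
        assert bp.point == pytest.approx(5_100_000)

    def test_parental_line_no_breakpoints(self):
        win = self.runs_frame([(A, 1000, 16_000), (A, 2000, 17_000)])
        seg = binning.detect_breakpoints(win, BinningParams(), chrom="Ca1")
        assert seg.breakpoints == []
        assert seg.segments[0][0] == A

    def test_unresolved_windows_widen_interval(self):
        win = self.runs_frame(
            [(A, 1000, 15_000), (UNRESOLVED, 2000, 16_000), (B, 20_000, 35_000)]
        )
        seg = binning.detect_breakpoints(win, BinningParams(), chrom="Ca1")
        assert len(seg.breakpoints) == 1
        assert seg.breakpoints[0].lo == 15_000
        assert seg.breakpoints[0].hi == 20_000

    def test_single_window_blip_collapsed(self):
        win = self.runs_frame(
            [(A, 1000, 15_000), (A, 2000, 16_000), (B, 3000, 17_000),
             (A, 4000, 18_000), (A, 5000, 19_000)]
        )
        seg = binning.detect_breakpoints(win, BinningParams(), chrom="Ca1")
        assert seg.breakpoints == []

    def test_no_resolved_windows_warns(self):
        win = self.runs_frame([(UNRESOLVED, 1000, 15_000)])
        with pytest.warns(UserWarning, match="no breakpoints"):
            seg = binning.detect_breakpoints(win, BinningParams(), chrom="Ca1")
        assert seg.breakpoints == []

    def test_recovery_on_synthetic_line(self, truth, skim, segments, genome):
        # detected breakpoints on the fixture population should rarely be
        # spurious; detailed recall accounting lives in the acceptance suite
        n_det = n_false = 0
        for line in skim.lines:
            for chrom in genome.chromosomes:
                true_bp = truth.breakpoints[line][chrom.name]
                for bp in segments[line][chrom.name].breakpoints:
                    n_det += 1
                    if not any(bp.lo <= t <= bp.hi for t in true_bp):
                        n_false += 1
        assert n_det > 1000
        assert n_false / n_det < 0.05


class TestConsensusBins:
    def population(self, breakpoints_by_line, length=1_000_000, n_snps=50):
        """Fabricate segment calls with given breakpoint point estimates."""
        segs = {}
        for line, pts in breakpoints_by_line.items():
            bps = [Breakpoint(lo=p - 1, hi=p + 1) for p in pts]
            genotypes = [A if k % 2 == 0 else B for k in range(len(pts) + 1)]
            bounds = [1.0] + [p for p in pts] + [float(length)]
            seg_list = [
                (genotypes[k], bounds[k], bounds[k + 1]) for k in range(len(pts) + 1)
            ]
            segs[line] = {"Ca1": SegmentCall("Ca1", seg_list, bps)}
        pos = np.linspace(1, length, n_snps, dtype=np.int64)
        from skimqtl.core import GenotypeMatrix

        matrix = GenotypeMatrix(
            sites=pd.DataFrame({"chrom": "Ca1", "pos": pos}),
            lines=list(breakpoints_by_line),
            calls=np.zeros((len(breakpoints_by_line), n_snps), dtype=np.int8),
        )
        return segs, matrix

    def test_hand_enumerated_grid(self):
        # hits in the 300-400 kb and 700-800 kb cells -> 5 bins
        segs, matrix = self.population({"L1": [350_000.0], "L2": [750_000.0]})
        bins = binning.consensus_bins(segs, matrix, chrom_lengths={"Ca1": 1_000_000})
        assert len(bins) == 5
        assert bins["start"].tolist() == [1, 300_001, 400_001, 700_001, 800_001]
        assert bins["end"].tolist() == [300_000, 400_000, 700_000, 800_000, 1_000_000]

    def test_no_breakpoints_single_bin(self):
        segs, matrix = self.population({"L1": [], "L2": []})
        bins = binning.consensus_bins(segs, matrix, chrom_lengths={"Ca1": 1_000_000})
        assert len(bins) == 1
        assert bins.loc[0, "start"] == 1 and bins.loc[0, "end"] == 1_000_000

    def test_every_cell_hit_bins_equal_cells(self):
        pts = [k * 100_000.0 + 50_000 for k in range(10)]
        segs, matrix = self.population({"L1": pts[::2], "L2": pts[1::2]})
        bins = binning.consensus_bins(segs, matrix, chrom_lengths={"Ca1": 1_000_000})
        assert len(bins) == 10

    def test_bins_tile_fixture_chromosomes(self, bins):
        for _, grp in bins.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] == ends[:-1] + 1).all()

    def test_bin_id_encodes_start(self, bins):
        for row in bins.itertuples(index=False):
            assert row.bin_id == f"bin_{row.chrom[-1]}_{row.start}"

    def test_consensus_bound_on_bin_count(self, bins, segments, skim):
        # every hit grid cell is its own bin and unhit runs merge, so the
        # bin count is bracketed by the number of distinct hit cells
        hits = set()
        for per_chrom in segments.values():
            for chrom, seg in per_chrom.items():
                for bp in seg.breakpoints:
                    hits.add((chrom, int((bp.point - 1) // 100_000)))
        n_chrom = bins["chrom"].nunique()
        assert len(hits) <= len(bins) <= 2 * len(hits) + n_chrom


class TestGenotypeBins:
    def test_parental_line_all_a(self):
        segs = {
            "L1": {"Ca1": SegmentCall("Ca1", [(A, 1.0, 1e6)], [])},
            "L2": {"Ca1": SegmentCall("Ca1", [(B, 1.0, 1e6)], [])},
        }
        bins = pd.DataFrame(
            {"bin_id": ["bin_1_1"], "chrom": ["Ca1"], "start": [1], "end": [1_000_000],
             "n_snps": [10]}
        )
        bmat = binning.genotype_bins(bins, segs)
        assert bmat.calls[0, 0] == A and bmat.calls[1, 0] == B

    def test_strict_masking_blanks_breakpoint_bin(self):
        bp = Breakpoint(lo=450_000, hi=550_000)
        segs = {
            "L1": {
                "Ca1": SegmentCall(
                    "Ca1", [(A, 1.0, 450_000.0), (B, 550_000.0, 1e6)], [bp]
                )
            },
            "L2": {"Ca1": SegmentCall("Ca1", [(A, 1.0, 1e6)], [])},
        }
        bins = pd.DataFrame(
            {
                "bin_id": ["bin_1_1", "bin_1_400001", "bin_1_600001"],
                "chrom": "Ca1",
                "start": [1, 400_001, 600_001],
                "end": [400_000, 600_000, 1_000_000],
                "n_snps": 5,
            }
        )
        bmat = binning.genotype_bins(bins, segs, mask_breakpoint_bins=True)
        assert bmat.calls[0].tolist() == [A, MISSING, B]
        assert bmat.calls[1].tolist() == [A, A, A]

    def test_midpoint_rule_matches_truth(self, truth, bin_matrix):
        # resolved (line, bin) values agree with the true segment at the
        # bin midpoint almost everywhere (junction bins can be off by a
        # point-estimate error)
        agree = total = 0
        sites = truth.matrix.sites
        for chrom, grp in bin_matrix.bins.groupby("chrom", sort=False):
            mask = (sites["chrom"] == chrom).to_numpy()
            pos = sites["pos"].to_numpy()[mask]
            cols = np.flatnonzero(mask)
            mids = ((grp["start"] + grp["end"]) // 2).to_numpy()
            nearest = cols[np.argmin(np.abs(pos[None, :] - mids[:, None]), axis=1)]
            truth_calls = truth.matrix.calls[:, nearest]
            obs = bin_matrix.calls[:, grp.index.to_numpy()]
            scored = obs != MISSING
            agree += (obs[scored] == truth_calls[scored]).sum()
            total += scored.sum()
        assert total > 0
        assert agree / total > 0.95


class TestBinStatistics:
    def annotation(self, intervals):
        return GeneAnnotation(
            pd.DataFrame(
                [
                    {"gene_id": f"g{k}", "chrom": "Ca1", "start": s, "end": e,
                     "strand": "+"}
                    for k, (s, e) in enumerate(intervals)
                ]
            )
        )

    def bins(self):
        return pd.DataFrame(
            {
                "bin_id": ["bin_1_1", "bin_1_101"],
                "chrom": "Ca1",
                "start": [1, 101],
                "end": [100, 200],
                "n_snps": 3,
            }
        )

    def test_containment_counts(self):
        stats = binning.bin_statistics(self.bins(), self.annotation([(150, 160)]))
        assert stats["genes_per_bin"] == [0, 1]

    def test_boundary_spanning_gene_counted_in_both_and_flagged(self):
        stats = binning.bin_statistics(self.bins(), self.annotation([(90, 110)]))
        assert stats["genes_per_bin"] == [1, 1]
        assert stats["boundary_spanning_genes"] == ["g0"]

    def test_empty_annotation(self):
        stats = binning.bin_statistics(self.bins(), GeneAnnotation())
        assert stats["genes_per_bin"] == [0, 0]
        assert stats["n_bins_no_gene"] == 2
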