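"""Segment-mean arithmetic, focal calls, recurrence sweep, gene CNV status."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvlnc import (
    Segment,
    SegmentProfile,
    call_focal_events,
    cn_from_segment_mean,
    gene_cnv_status,
    gene_segment_mean,
    recurrence_map,
    segment_mean_from_cn,
)
from cnvlnc.screen import GeneAnnotation


def profile(sample, segs):
    return SegmentProfile(sample, [Segment(sample, c, s, e, sm) for c, s, e, sm in segs])


class TestSegmentMean:
    @pytest.mark.parametrize(
        "cn,sm", [(2, 0.0), (4, 1.0), (1, -1.0), (8, 2.0), (0.5, -2.0)]
    )
    def test_known_values(self, cn, sm):
        assert segment_mean_from_cn(cn) == pytest.approx(sm)

    @pytest.mark.parametrize("cn", [0, -1, -0.5])
    def test_nonpositive_copy_number_rejected(self, cn):
        with pytest.raises(ValueError):
            segment_mean_from_cn(cn)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_inverse_roundtrip(self, cn):
        assert cn_from_segment_mean(segment_mean_from_cn(cn)) == pytest.approx(
            cn, abs=1e-12, rel=1e-12
        )


class TestFocalCalls:
    @pytest.mark.parametrize(
        "sm,status",
        [(0.31, "gain"), (0.30, "neutral"), (-0.45, "loss"), (-0.30, "neutral"), (0.0, "neutral")],
    )
    def test_strict_thresholds(self, sm, status):
        prof = profile("S1", [("chr1", 0, 100, sm)])
        (seg, call), = call_focal_events(prof)
        assert call.status == status

    def test_every_segment_called_once(self):
        prof = profile("S1", [("chr1", 0, 100, 0.5), ("chr1", 200, 300, -0.5), ("chr2", 0, 50, 0.1)])
        calls = call_focal_events(prof)
        assert len(calls) == 3
        assert [c.status for _, c in calls] == ["gain", "loss", "neutral"]

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            profile("S1", [("chr1", 0, 100, 0.5), ("chr1", 50, 150, 0.4)])

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="start"):
            Segment("S1", "chr1", 100, 100, 0.5)


def brute_force_recurrence(profiles, direction, min_support):
    """Per-base counting oracle: group consecutive bases by supporting set."""
    cover = {}
    for prof in profiles:
        for seg, call in call_focal_events(prof):
            if call.status == direction:
                for b in range(seg.start, seg.end):
                    cover.setdefault((seg.chrom, b), set()).add(prof.sample_id)
    regions = []
    for chrom in sorted({c for c, _ in cover}):
        bases = sorted(b for c, b in cover if c == chrom)
        run = None
        for b in bases:
            sset = frozenset(cover[(chrom, b)])
            if len(sset) < min_support:
                if run:
                    regions.append(run)
                    run = None
                continue
            if run and run[2] == b and run[3] == sset:
                run = (run[0], run[1], b + 1, sset)
            else:
                if run:
                    regions.append(run)
                run = (chrom, b, b + 1, sset)
        if run:
            regions.append(run)
    return [(c, s, e, set(ss)) for c, s, e, ss in regions]


class TestRecurrenceMap:
    def test_three_sample_overlap(self):
        profs = [
            profile("A", [("chr1", 100, 500, 0.8)]),
            profile("B", [("chr1", 300, 700, 0.9)]),
            profile("C", [("chr1", 900, 1000, 0.7)]),
        ]
        regions = recurrence_map(profs, "gain", min_support=2)
        assert len(regions) == 1
        r = regions[0]
        assert (r.chrom, r.start, r.end, r.support) == ("chr1", 300, 500, 2)
        assert r.supporting_samples == ("A", "B")

    def test_single_sample_identity(self):
        prof = profile("A", [("chr1", 10, 50, 0.8), ("chr2", 0, 30, 0.9)])
        regions = recurrence_map([prof], "gain", min_support=1)
        assert [(r.chrom, r.start, r.end) for r in regions] == [("chr1", 10, 50), ("chr2", 0, 30)]

    def test_disjoint_gains_no_region(self):
        profs = [profile("A", [("chr1", 0, 100, 0.8)]), profile("B", [("chr1", 200, 300, 0.8)])]
        assert recurrence_map(profs, "gain", min_support=2) == []

    def test_min_support_above_n_warns_empty(self):
        profs = [profile("A", [("chr1", 0, 100, 0.8)])]
        with pytest.warns(UserWarning, match="min_support"):
            assert recurrence_map(profs, "gain", min_support=2) == []

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        """Sweep output must equal brute-force per-base counting."""
        for _ in range(40):
            n_samples = int(rng.integers(2, 6))
            profs = []
            for i in range(n_samples):
                segs = []
                for chrom in ["chr1", "chr2"][: int(rng.integers(1, 3))]:
                    cuts = np.sort(rng.choice(500, size=2 * int(rng.integers(0, 4)), replace=False))
                    for s, e in zip(cuts[::2], cuts[1::2]):
                        if e > s:
                            segs.append((chrom, int(s), int(e), float(rng.normal(0, 0.6))))
                profs.append(profile(f"S{i}", segs))
            min_support = int(rng.integers(1, n_samples + 1))
            for direction in ("gain", "loss"):
                got = [
                    (r.chrom, r.start, r.end, set(r.supporting_samples))
                    for r in recurrence_map(profs, direction, min_support)
                ]
                assert got == brute_force_recurrence(profs, direction, min_support)

    def test_regions_sorted_and_disjoint(self, rng):
        starts = np.arange(8) * 60
        profs = [
            profile(f"S{i}", [("chr1", int(s), int(s) + 50, 0.8) for s in rng.choice(starts, 3, replace=False)])
            for i in range(4)
        ]
        regions = recurrence_map(profs, "gain", min_support=2)
        for a, b in zip(regions, regions[1:]):
            assert (a.chrom, a.end) <= (b.chrom, b.start) or a.chrom < b.chrom


def gene(chrom, start, end):
    return GeneAnnotation("G1", "lncRNA", chrom, start, end)


class TestGeneCnvStatus:
    def test_fully_inside_gain_segment(self):
        prof = profile("S1", [("chr1", 0, 1000, 0.8)])
        assert gene_cnv_status(gene("chr1", 100, 200), prof).status == "gain"

    def test_half_covered_weighted_mean_is_neutral(self):
        # half the gene in SM 0.6, half uncovered -> weighted mean 0.3, strict > keeps neutral
        prof = profile("S1", [("chr1", 0, 100, 0.6)])
        g = gene("chr1", 50, 150)
        assert gene_segment_mean(g, prof) == pytest.approx(0.3)
        assert gene_cnv_status(g, prof).status == "neutral"

    def test_two_segment_weighted_mean(self):
        # 25% of the gene at SM 0.4, 75% at SM 0.0 -> mean 0.1 -> neutral
        prof = profile("S1", [("chr1", 0, 25, 0.4), ("chr1", 25, 100, 0.0)])
        g = gene("chr1", 0, 100)
        assert gene_segment_mean(g, prof) == pytest.approx(0.1)
        assert gene_cnv_status(g, prof).status == "neutral"

    def test_absent_chromosome_neutral_with_warning(self):
        prof = profile("S1", [("chr1", 0, 100, 0.8)])
        with pytest.warns(UserWarning, match="absent"):
            assert gene_cnv_status(gene("chrX", 0, 50), prof).status == "neutral"

    def test_any_overlap_rule(self):
        prof = profile("S1", [("chr1", 0, 10, 0.6)])
        g = gene("chr1", 5, 1000)
        assert gene_cnv_status(g, prof).status == "neutral"
        assert gene_cnv_status(g, prof, overlap_rule="any").status == "gain"
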