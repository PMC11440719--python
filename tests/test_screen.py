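"""Directional concordance screen: probe filtering, aggregation, full pipeline."""

import pandas as pd
import pytest

from cnvlnc import (
    PipelineConfig,
    SimulationConfig,
    aggregate_candidates,
    concordant_probes,
    gene_cnv_status,
    run_screen,
    simulate_cohort,
)
from cnvlnc.screen import GeneAnnotation
from cnvlnc.segments import RecurrentRegion


def region(chrom, start, end, direction, support=3):
    return RecurrentRegion(chrom, start, end, direction, support, tuple(f"S{i}" for i in range(support)))


def de_row(probe, direction, log2fc=1.5, p_adj=0.001):
    return {"probe_id": probe, "log2fc": log2fc if direction == "up" else -log2fc,
            "t": 5.0, "p": p_adj / 10, "p_adj": p_adj, "direction": direction, "degenerate": False}


def make_annotation(entries):
    """entries: gene_id -> (biotype, chrom, start, end, probes)."""
    return {
        g: GeneAnnotation(g, bt, c, s, e, "+", tuple(probes))
        for g, (bt, c, s, e, probes) in entries.items()
    }


class TestConcordantProbes:
    annotation = make_annotation(
        {
            "L1": ("lncRNA", "chr1", 100, 200, ["L1_p1", "L1_p2", "L1_p3"]),
            "L2": ("lncRNA", "chr1", 5000, 5100, ["L2_p1", "L2_p2"]),
            "L3": ("lncRNA", "chr2", 100, 200, ["L3_p1", "L3_p2"]),
            "L4": ("lncRNA", "chr2", 5000, 5100, ["L4_p1", "L4_p2"]),
            "M1": ("mRNA", "chr1", 100, 200, ["M1_p1"]),
        }
    )
    gains = [region("chr1", 50, 300, "gain")]
    losses = [region("chr2", 50, 300, "loss")]

    def test_up_probe_in_gain_region_retained(self):
        de = pd.DataFrame([de_row("L1_p1", "up")])
        up, down, _ = concordant_probes(de, self.annotation, self.gains, self.losses)
        assert list(up["probe_id"]) == ["L1_p1"] and down.empty

    def test_discordant_up_probe_in_loss_region_excluded(self):
        de = pd.DataFrame([de_row("L3_p1", "up")])  # L3 sits in the loss region
        up, down, _ = concordant_probes(de, self.annotation, self.gains, self.losses)
        assert up.empty and down.empty

    def test_mrna_probes_ignored(self):
        de = pd.DataFrame([de_row("M1_p1", "up")])
        up, down, _ = concordant_probes(de, self.annotation, self.gains, self.losses)
        assert up.empty and down.empty

    def test_toy_counts(self):
        # 5 up probes, 3 of which sit in the gain region; 4 down, 2 in the loss region
        de = pd.DataFrame(
            [de_row(p, "up") for p in ["L1_p1", "L1_p2", "L1_p3", "L2_p1", "L2_p2"]]
            + [de_row(p, "down") for p in ["L3_p1", "L3_p2", "L4_p1", "L4_p2"]]
        )
        up, down, _ = concordant_probes(de, self.annotation, self.gains, self.losses)
        assert len(up) == 3 and len(down) == 2

    def test_unmapped_probe_warns(self):
        de = pd.DataFrame([de_row("orphan_p1", "up")])
        with pytest.warns(UserWarning, match="no gene mapping"):
            _, _, n_unmapped = concordant_probes(de, self.annotation, self.gains, self.losses)
        assert n_unmapped == 1


class TestAggregateCandidates:
    def probes(self, gene, direction, n, region_dir=None):
        reg = region("chr1", 0, 1000, region_dir or ("gain" if direction == "up" else "loss"))
        return pd.DataFrame(
            [
                {"probe_id": f"{gene}_p{i}", "gene_id": gene, "direction": direction,
                 "log2fc": 1.5, "p_adj": 0.01, "region": reg}
                for i in range(n)
            ]
        )

    def test_two_probe_gene_is_candidate(self):
        cands, conflicts = aggregate_candidates(self.probes("L1", "up", 2), self.probes("X", "down", 0))
        assert [c.gene_id for c in cands] == ["L1"] and cands[0].n_probes == 2

    def test_single_probe_gene_is_not(self):
        cands, _ = aggregate_candidates(self.probes("L1", "up", 1), self.probes("X", "down", 0))
        assert cands == []

    def test_bidirectional_gene_is_conflict(self):
        up = self.probes("L1", "up", 2)
        down = self.probes("L1", "down", 1)
        cands, conflicts = aggregate_candidates(up, down)
        assert cands == [] and conflicts == ["L1"]

    def test_exclude_list_removes_after_counting(self):
        cands, _ = aggregate_candidates(
            self.probes("L1", "up", 3), self.probes("X", "down", 0), exclude=("L1",)
        )
        assert cands == []


class TestRunScreen:
    def test_recovers_planted_drivers(self, default_cohort):
        co = default_cohort
        report = run_screen(co.expression, co.pairing, co.profiles, co.genes, co.probe_map)
        truth = set(co.truth["gene_id"])
        found = {c.gene_id for c in report.candidates}
        assert len(found & truth) >= 9
        directions = dict(zip(co.truth["gene_id"], co.truth["direction"]))
        for cand in report.candidates:
            if cand.gene_id in directions:
                assert cand.direction == directions[cand.gene_id]

    def test_stage_counts_form_a_funnel(self, default_cohort):
        co = default_cohort
        report = run_screen(co.expression, co.pairing, co.profiles, co.genes, co.probe_map)
        sc = report.stage_counts
        assert sc["n_candidates"] <= sc["n_concordant_genes"] <= sc["n_de_lnc_genes"]
        assert sc["n_de_lnc_probes"] <= sc["n_de_probes"] <= sc["n_probes"]

    def test_null_cohort_yields_no_candidates(self, null_cohort):
        co = null_cohort
        report = run_screen(co.expression, co.pairing, co.profiles, co.genes, co.probe_map)
        assert len(report.candidates) <= 1

    def test_deterministic_rerun(self, default_cohort):
        co = default_cohort
        r1 = run_screen(co.expression, co.pairing, co.profiles, co.genes, co.probe_map)
        r2 = run_screen(co.expression, co.pairing, co.profiles, co.genes, co.probe_map)
        assert r1.stage_counts == r2.stage_counts
        assert [c.gene_id for c in r1.candidates] == [c.gene_id for c in r2.candidates]

    def test_candidates_overlap_concordant_region(self, default_cohort):
        """Re-check every candidate against the segment model independently."""
        co = default_cohort
        report = run_screen(co.expression, co.pairing, co.profiles, co.genes, co.probe_map)
        genes = co.genes.set_index("gene_id")
        for cand in report.candidates:
            g = genes.loc[cand.gene_id]
            reg = cand.region
            assert reg.direction == ("gain" if cand.direction == "up" else "loss")
            assert reg.chrom == g["chrom"]
            assert min(reg.end, g["end"]) - max(reg.start, g["start"]) > 0
            # the supporting samples' profiles really do alter this gene
            ann = GeneAnnotation(cand.gene_id, "lncRNA", g["chrom"], g["start"], g["end"])
            n_altered = sum(
                gene_cnv_status(ann, p).status == reg.direction
                for p in co.profiles
                if p.sample_id in reg.supporting_samples
            )
            assert n_altered >= 2

    @pytest.mark.parametrize("param,values", [("min_probes", [1, 2, 3]), ("min_support", [2, 4, 8])])
    def test_raising_thresholds_shrinks_candidates(self, default_cohort, param, values):
        co = default_cohort
        previous = None
        for v in values:
            cfg = PipelineConfig(**{param: v})
            report = run_screen(co.expression, co.pairing, co.profiles, co.genes, co.probe_map, cfg)
            current = {c.gene_id for c in report.candidates}
            if previous is not None:
                assert current <= previous
            previous = current
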