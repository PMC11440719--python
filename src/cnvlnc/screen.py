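"""Directional concordance screen for SCNA-driven lncRNAs.

The screen intersects differentially expressed lncRNA probes with recurrent
copy-number regions, keeping a probe only when its gene's interval overlaps
(>= 1 bp) a recurrent region whose direction matches the probe's DE call
(up <-> gain, down <-> loss). Probe support is then aggregated per gene and
genes with at least ``min_probes`` concordant probes, all in one direction,
become candidates. Genes with passing probes in both directions are conflicts
and are dropped; an explicit exclude list (e.g. already-characterized
lncRNAs) is removed after the counting stage.

Concordance is evaluated at the gene interval: probes inherit their gene's
locus, since probe-level genomic coordinates are often absent from array
annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import de as de_mod
from . import segments as seg_mod
from .config import PipelineConfig
from .segments import GAIN, LOSS, RecurrentRegion, SegmentProfile

LNCRNA = "lncRNA"
MRNA = "mRNA"


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene locus with its biotype and the probes that measure it."""

    gene_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    probe_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start must be < end, got [{self.start}, {self.end})"
            )


@dataclass
class CandidateLncRNA:
    """One screen hit: a lncRNA with concordant probe support in a recurrent region."""

    gene_id: str
    direction: str
    supporting_probes: tuple[str, ...]
    region: RecurrentRegion
    locus: str = ""

    @property
    def n_probes(self) -> int:
        return len(self.supporting_probes)


@dataclass
class ScreenReport:
    """Per-stage counts (the Venn-style funnel) plus the candidate table."""

    stage_counts: dict = field(default_factory=dict)
    de_table: pd.DataFrame | None = None
    gain_regions: list = field(default_factory=list)
    loss_regions: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    conflicts: list = field(default_factory=list)

    def candidate_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": c.gene_id,
                "direction": c.direction,
                "n_probes": c.n_probes,
                "probe_ids": ",".join(c.supporting_probes),
                "region": f"{c.region.chrom}:{c.region.start}-{c.region.end}",
                "region_support": c.region.support,
                "locus": c.locus,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id",
                "direction",
                "n_probes",
                "probe_ids",
                "region",
                "region_support",
                "locus",
            ],
        )


def annotation_from_frames(genes: pd.DataFrame, probe_map: pd.DataFrame) -> dict[str, GeneAnnotation]:
    """Build GeneAnnotation records from a gene table + probe map."""
    probes_by_gene: dict[str, list[str]] = {}
    for probe_id, gene_id in zip(probe_map["probe_id"], probe_map["gene_id"]):
        probes_by_gene.setdefault(gene_id, []).append(probe_id)
    out = {}
    for row in genes.itertuples(index=False):
        out[row.gene_id] = GeneAnnotation(
            gene_id=row.gene_id,
            biotype=row.biotype,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=getattr(row, "strand", "+"),
            probe_ids=tuple(probes_by_gene.get(row.gene_id, ())),
        )
    return out


def _overlapping_region(gene: GeneAnnotation, regions: list[RecurrentRegion]):
    """Best-overlap recurrent region for a gene (None when disjoint)."""
    best = None
    best_overlap = 0
    for region in regions:
        if region.chrom != gene.chrom:
            continue
        overlap = min(region.end, gene.end) - max(region.start, gene.start)
        if overlap > 0 and overlap > best_overlap:
            best, best_overlap = region, overlap
    return best


def concordant_probes(
    de_table: pd.DataFrame,
    annotation: dict[str, GeneAnnotation],
    gain_regions: list[RecurrentRegion],
    loss_regions: list[RecurrentRegion],
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Split DE lncRNA probes into (up-in-gain, down-in-loss) concordant sets.

    Returns the two probe tables plus the count of probes skipped for lacking
    a gene mapping. Only lncRNA-biotype probes are considered.
    """
    probe_to_gene = {
        probe: gene.gene_id for gene in annotation.values() for probe in gene.probe_ids
    }
    up_rows, down_rows = [], []
    n_unmapped = 0
    for row in de_table.itertuples(index=False):
        if row.direction == de_mod.NS:
            continue
        gene_id = probe_to_gene.get(row.probe_id)
        if gene_id is None:
            n_unmapped += 1
            continue
        gene = annotation[gene_id]
        if gene.biotype != LNCRNA:
            continue
        regions = gain_regions if row.direction == de_mod.UP else loss_regions
        region = _overlapping_region(gene, regions)
        if region is None:
            continue
        rec = {
            "probe_id": row.probe_id,
            "gene_id": gene_id,
            "direction": row.direction,
            "log2fc": row.log2fc,
            "p_adj": row.p_adj,
            "region": region,
        }
        (up_rows if row.direction == de_mod.UP else down_rows).append(rec)
    if n_unmapped:
        warnings.warn(f"{n_unmapped} DE probes had no gene mapping and were skipped", stacklevel=2)
    cols = ["probe_id", "gene_id", "direction", "log2fc", "p_adj", "region"]
    return (
        pd.DataFrame(up_rows, columns=cols),
        pd.DataFrame(down_rows, columns=cols),
        n_unmapped,
    )


def aggregate_candidates(
    up_in_gain: pd.DataFrame,
    down_in_loss: pd.DataFrame,
    min_probes: int = 2,
    exclude: tuple[str, ...] = (),
) -> tuple[list[CandidateLncRNA], list[str]]:
    """Group concordant probes per gene and apply the indicative-probe rule.

    Genes with >= ``min_probes`` passing probes in a single direction become
    candidates; genes passing in both directions are dropped as conflicts;
    excluded genes are removed after counting.
    """
    if min_probes < 1:
        raise ValueError(f"min_probes must be >= 1, got {min_probes}")
    both = pd.concat([up_in_gain, down_in_loss], ignore_index=True)
    candidates: list[CandidateLncRNA] = []
    conflicts: list[str] = []
    if both.empty:
        return candidates, conflicts
    for gene_id, grp in both.groupby("gene_id", sort=True):
        directions = set(grp["direction"])
        if len(directions) > 1:
            conflicts.append(gene_id)
            continue
        if len(grp) < min_probes:
            continue
        if gene_id in set(exclude):
            continue
        direction = directions.pop()
        # probes of one gene share the gene locus, hence the same best region
        region = grp["region"].iloc[0]
        candidates.append(
            CandidateLncRNA(
                gene_id=gene_id,
                direction=direction,
                supporting_probes=tuple(sorted(grp["probe_id"])),
                region=region,
            )
        )
    return candidates, sorted(conflicts)


def run_screen(
    expression: pd.DataFrame,
    pairing: pd.DataFrame,
    profiles: list[SegmentProfile],
    genes: pd.DataFrame,
    probe_map: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> ScreenReport:
    """Full pipeline: paired DE -> focal calls -> recurrence -> concordance -> candidates."""
    config = config or PipelineConfig()
    annotation = annotation_from_frames(genes, probe_map)

    de_table = de_mod.paired_de(expression, pairing, fc_thr=config.fc_thr, alpha=config.alpha)
    gain_regions = seg_mod.recurrence_map(
        profiles, GAIN, config.min_support, config.amp_thr, config.del_thr
    )
    loss_regions = seg_mod.recurrence_map(
        profiles, LOSS, config.min_support, config.amp_thr, config.del_thr
    )
    up_in_gain, down_in_loss, n_unmapped = concordant_probes(
        de_table, annotation, gain_regions, loss_regions
    )
    candidates, conflicts = aggregate_candidates(
        up_in_gain, down_in_loss, min_probes=config.min_probes, exclude=config.exclude_genes
    )

    lnc_probe_ids = {
        p for g in annotation.values() if g.biotype == LNCRNA for p in g.probe_ids
    }
    de_lnc = de_table[
        (de_table["direction"] != de_mod.NS) & de_table["probe_id"].isin(lnc_probe_ids)
    ]
    stage_counts = {
        "n_probes": int(len(de_table)),
        "n_de_probes": int((de_table["direction"] != de_mod.NS).sum()),
        "n_de_lnc_probes": int(len(de_lnc)),
        "n_de_lnc_genes": int(
            de_lnc["probe_id"].map({p: g.gene_id for g in annotation.values() for p in g.probe_ids}).nunique()
        ),
        "n_gain_regions": len(gain_regions),
        "n_loss_regions": len(loss_regions),
        "n_up_in_gain_probes": int(len(up_in_gain)),
        "n_down_in_loss_probes": int(len(down_in_loss)),
        "n_concordant_genes": int(
            pd.concat([up_in_gain, down_in_loss])["gene_id"].nunique()
            if len(up_in_gain) + len(down_in_loss)
            else 0
        ),
        "n_conflict_genes": len(conflicts),
        "n_unmapped_probes": n_unmapped,
        "n_candidates": len(candidates),
    }
    return ScreenReport(
        stage_counts=stage_counts,
        de_table=de_table,
        gain_regions=gain_regions,
        loss_regions=loss_regions,
        candidates=candidates,
        conflicts=conflicts,
    )
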