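"""Copy-number segment model.

A tumor genome is summarized as per-sample segments carrying a *segment mean*
(SM), the log2 ratio of the local copy number to the diploid state::

    SM = log2(CN / 2)

so SM = 0 for two copies, 1 for four, and -1 for a hemizygous loss. Focal
gains and losses are called by thresholding SM (strictly ``> amp_thr`` /
``< del_thr``, default +/-0.3), and cross-sample recurrence is computed by a
breakpoint sweep that emits maximal genomic runs covered by an identical set
of supporting samples.

Coordinates are 0-based half-open throughout this module; the on-disk SEG
dialect (1-based inclusive) is converted at the I/O boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"

#: default focal-event thresholds on the segment mean (strict inequalities)
AMP_THR = 0.3
DEL_THR = -0.3


@dataclass(frozen=True)
class Segment:
    """One copy-number segment of one sample, [start, end) on ``chrom``."""

    sample_id: str
    chrom: str
    start: int
    end: int
    seg_mean: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"segment start must be < end, got [{self.start}, {self.end}) "
                f"for sample {self.sample_id!r} on {self.chrom}"
            )
        if not math.isfinite(self.seg_mean):
            raise ValueError(f"seg_mean must be finite, got {self.seg_mean!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    """All segments of one sample, sorted and non-overlapping per chromosome."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start, s.end))
        self._validate()

    def _validate(self) -> None:
        prev: Segment | None = None
        for seg in self.segments:
            if seg.sample_id != self.sample_id:
                raise ValueError(
                    f"segment sample {seg.sample_id!r} does not match "
                    f"profile sample {self.sample_id!r}"
                )
            if prev is not None and seg.chrom == prev.chrom and seg.start < prev.end:
                raise ValueError(
                    f"overlapping segments in sample {self.sample_id!r} on "
                    f"{seg.chrom}: [{prev.start},{prev.end}) and [{seg.start},{seg.end})"
                )
            prev = seg

    def chromosomes(self) -> list[str]:
        return sorted({s.chrom for s in self.segments})


@dataclass(frozen=True)
class CNCall:
    """Gain/loss/neutral call for a segment or a gene, with the thresholds used."""

    status: str
    amp_thr: float = AMP_THR
    del_thr: float = DEL_THR

    def __post_init__(self) -> None:
        if self.status not in (GAIN, LOSS, NEUTRAL):
            raise ValueError(f"unknown CN status {self.status!r}")


@dataclass
class RecurrentRegion:
    """Maximal interval gained (or lost) in an identical set of >= min_support samples."""

    chrom: str
    start: int
    end: int
    direction: str
    support: int
    supporting_samples: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


def segment_mean_from_cn(copy_number: float) -> float:
    """SM = log2(copy_number / 2). Domain error for non-positive copy number."""
    if copy_number <= 0:
        raise ValueError(f"copy number must be > 0, got {copy_number}")
    return math.log2(copy_number / 2.0)


def cn_from_segment_mean(seg_mean: float) -> float:
    """Inverse of :func:`segment_mean_from_cn`: CN = 2 * 2**SM."""
    return 2.0 * 2.0 ** seg_mean


def classify_seg_mean(seg_mean: float, amp_thr: float = AMP_THR, del_thr: float = DEL_THR) -> str:
    if not (amp_thr > 0 > del_thr):
        raise ValueError(f"thresholds must satisfy amp_thr > 0 > del_thr, got {amp_thr}, {del_thr}")
    if seg_mean > amp_thr:
        return GAIN
    if seg_mean < del_thr:
        return LOSS
    return NEUTRAL


def call_focal_events(
    profile: SegmentProfile, amp_thr: float = AMP_THR, del_thr: float = DEL_THR
) -> list[tuple[Segment, CNCall]]:
    """Assign exactly one gain/loss/neutral call to every segment of a profile.

    Thresholds are strict: SM must exceed ``amp_thr`` (fall below ``del_thr``)
    to be called; a segment exactly at a threshold is neutral.
    """
    return [
        (seg, CNCall(classify_seg_mean(seg.seg_mean, amp_thr, del_thr), amp_thr, del_thr))
        for seg in profile.segments
    ]


def recurrence_map(
    profiles: Sequence[SegmentProfile],
    direction: str,
    min_support: int,
    amp_thr: float = AMP_THR,
    del_thr: float = DEL_THR,
) -> list[RecurrentRegion]:
    """Cross-sample recurrent gain (or loss) regions by a breakpoint sweep.

    At every genomic base, the samples whose called events of ``direction``
    cover it are counted; maximal runs with an identical supporting-sample set
    and support >= ``min_support`` are emitted. Regions of one direction are
    therefore non-overlapping, sorted, and their support counts reconstruct the
    per-base coverage function exactly.
    """
    if direction not in (GAIN, LOSS):
        raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
    if not profiles:
        raise ValueError("at least one segment profile is required")
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    if min_support > len(profiles):
        warnings.warn(
            f"min_support={min_support} exceeds the number of profiles "
            f"({len(profiles)}); no recurrent region can exist",
            stacklevel=2,
        )
        return []

    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for profile in profiles:
        for seg, call in call_focal_events(profile, amp_thr, del_thr):
            if call.status == direction:
                by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end, profile.sample_id))

    regions: list[RecurrentRegion] = []
    for chrom in sorted(by_chrom):
        events = by_chrom[chrom]
        breakpoints = sorted({x for s, e, _ in events for x in (s, e)})
        run_start: int | None = None
        run_end: int | None = None
        run_set: frozenset[str] = frozenset()
        for lo, hi in zip(breakpoints, breakpoints[1:]):
            # elementary interval [lo, hi) is covered by exactly the events
            # spanning it (breakpoints subdivide every event boundary)
            covering = frozenset(sid for s, e, sid in events if s <= lo and e >= hi)
            if len(covering) >= min_support:
                if run_start is not None and covering == run_set and lo == run_end:
                    run_end = hi
                else:
                    if run_start is not None:
                        regions.append(
                            _make_region(chrom, run_start, run_end, direction, run_set)
                        )
                    run_start, run_end, run_set = lo, hi, covering
            else:
                if run_start is not None:
                    regions.append(_make_region(chrom, run_start, run_end, direction, run_set))
                run_start = None
        if run_start is not None:
            regions.append(_make_region(chrom, run_start, run_end, direction, run_set))
    return regions


def _make_region(
    chrom: str, start: int, end: int, direction: str, samples: frozenset[str]
) -> RecurrentRegion:
    return RecurrentRegion(
        chrom=chrom,
        start=start,
        end=end,
        direction=direction,
        support=len(samples),
        supporting_samples=tuple(sorted(samples)),
    )


def gene_segment_mean(gene, profile: SegmentProfile) -> float:
    """Length-weighted mean SM over the gene body; uncovered bases count as SM 0."""
    glen = gene.end - gene.start
    if glen <= 0:
        raise ValueError(f"invalid gene interval [{gene.start}, {gene.end})")
    if gene.chrom not in profile.chromosomes():
        warnings.warn(
            f"chromosome {gene.chrom!r} absent from profile {profile.sample_id!r}; "
            "gene treated as copy-neutral",
            stacklevel=2,
        )
        return 0.0
    weighted = 0.0
    for seg in profile.segments:
        if seg.chrom != gene.chrom:
            continue
        overlap = min(seg.end, gene.end) - max(seg.start, gene.start)
        if overlap > 0:
            weighted += overlap * seg.seg_mean
    return weighted / glen


def gene_cnv_status(
    gene,
    profile: SegmentProfile,
    amp_thr: float = AMP_THR,
    del_thr: float = DEL_THR,
    overlap_rule: str = "weighted",
) -> CNCall:
    """Copy-number call for a gene interval against one sample's profile.

    ``overlap_rule='weighted'`` (default) thresholds the length-weighted mean
    SM over the gene body, with uncovered bases contributing 0; ``'any'``
    calls the gene if any overlapping segment (>= 1 bp) passes the threshold,
    gains taking precedence over losses.
    """
    if overlap_rule == "weighted":
        mean_sm = gene_segment_mean(gene, profile)
        return CNCall(classify_seg_mean(mean_sm, amp_thr, del_thr), amp_thr, del_thr)
    if overlap_rule == "any":
        statuses = set()
        for seg in profile.segments:
            if seg.chrom != gene.chrom:
                continue
            if min(seg.end, gene.end) - max(seg.start, gene.start) > 0:
                statuses.add(classify_seg_mean(seg.seg_mean, amp_thr, del_thr))
        for status in (GAIN, LOSS):
            if status in statuses:
                return CNCall(status, amp_thr, del_thr)
        return CNCall(NEUTRAL, amp_thr, del_thr)
    raise ValueError(f"unknown overlap rule {overlap_rule!r}")
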