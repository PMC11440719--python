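"""Deterministic assay quantification.

Four small, exactly specified computations: the semi-quantitative in situ
hybridization (ISH) score, the caliper tumor-volume formula L x W^2 / 2, the
first-order mRNA decay half-life fit under transcriptional arrest
(actinomycin D), and AU-rich element (ARE) scanning/mutation in 3'UTR
sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

ARE_PENTAMER = "AUUUA"
RNA_ALPHABET = set("ACGU")


@dataclass(frozen=True)
class IshScore:
    """Proportion bin (0-4) x staining intensity (0-3), range 0-12."""

    proportion_bin: int
    intensity: int

    @property
    def score(self) -> int:
        return self.proportion_bin * self.intensity


@dataclass
class DecayCurve:
    """Relative mRNA abundance over hours after transcription arrest."""

    timepoints: np.ndarray
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.timepoints.shape != self.abundance.shape:
            raise ValueError("timepoints and abundance must have equal length")


@dataclass
class DecayFit:
    """First-order decay rate k (1/h), half-life ln2/k, and fit R^2."""

    k: float
    half_life: float | None
    r_squared: float
    decaying: bool


@dataclass(frozen=True)
class AREHit:
    """A maximal cluster of overlapping AUUUA pentamers.

    ``position`` is the 0-based start of the cluster, ``length`` its span,
    and ``klass`` the number of pentamer starts inside it.
    """

    position: int
    length: int
    klass: int

    @property
    def end(self) -> int:
        return self.position + self.length


# proportion-of-positive-cells rubric: upper bound (inclusive, in percent) -> bin
_ISH_BINS = ((5, 0), (25, 1), (50, 2), (75, 3), (100, 4))


def ish_score(percent_positive: float, intensity: int) -> IshScore:
    """Semi-quantitative ISH score.

    Percentages are rounded to the nearest integer before binning
    (<=5% -> 0; 6-25% -> 1; 26-50% -> 2; 51-75% -> 3; 76-100% -> 4) and
    multiplied by the staining intensity (0 none ... 3 strong).
    """
    if not 0 <= percent_positive <= 100:
        raise ValueError(f"percent_positive must be in [0, 100], got {percent_positive}")
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be an integer 0-3, got {intensity}")
    pct = round(percent_positive)
    for upper, b in _ISH_BINS:
        if pct <= upper:
            return IshScore(proportion_bin=b, intensity=intensity)
    raise AssertionError("unreachable")


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume (mm^3): length x width^2 / 2."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be positive")
    if width > length:
        import warnings

        warnings.warn(
            f"width ({width}) exceeds length ({length}); computing anyway", stacklevel=2
        )
    return length * width * width / 2.0


def decay_halflife(curve: DecayCurve) -> DecayFit:
    """Least-squares log-linear fit of first-order decay.

    Abundances are pre-normalized to the t=0 value, ln(abundance) is
    regressed on time and k = -slope. Non-decaying input (k <= 0) is flagged
    with an undefined half-life.
    """
    t = curve.timepoints
    y = curve.abundance
    if t.size < 3:
        raise ValueError("need >= 3 timepoints")
    if 0.0 not in t:
        raise ValueError("timepoints must include t=0 for normalization")
    if np.any(y <= 0):
        raise ValueError("abundances must be positive")
    y = y / y[t == 0.0][0]
    slope, _, r, _, _ = stats.linregress(t, np.log(y))
    k = -float(slope)
    decaying = k > 0
    return DecayFit(
        k=k,
        half_life=math.log(2) / k if decaying else None,
        r_squared=float(r) ** 2,
        decaying=decaying,
    )


def _normalize_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    for i, base in enumerate(seq):
        if base not in RNA_ALPHABET:
            raise ValueError(f"invalid nucleotide {sequence[i]!r} at position {i}")
    return seq


def are_scan(sequence: str) -> list[AREHit]:
    """All maximal clusters of overlapping AUUUA pentamers.

    DNA input is accepted (T is read as U, case-insensitive). Overlapping
    pentamer occurrences are merged; a cluster's class is its number of
    pentamer starts (ARED-style, e.g. AUUUAUUUA is one class-2 cluster).
    """
    seq = _normalize_rna(sequence)
    starts = []
    pos = seq.find(ARE_PENTAMER)
    while pos != -1:
        starts.append(pos)
        pos = seq.find(ARE_PENTAMER, pos + 1)
    hits: list[AREHit] = []
    i = 0
    while i < len(starts):
        cluster_start = starts[i]
        cluster_end = cluster_start + len(ARE_PENTAMER)
        count = 1
        j = i + 1
        while j < len(starts) and starts[j] < cluster_end:
            cluster_end = starts[j] + len(ARE_PENTAMER)
            count += 1
            j += 1
        hits.append(AREHit(position=cluster_start, length=cluster_end - cluster_start, klass=count))
        i = j
    return hits


_MUTATION = str.maketrans({"A": "C", "U": "G", "T": "G", "a": "c", "u": "g", "t": "g"})


def mutate_are(sequence: str, hits: list[AREHit]) -> str:
    """Destroy ARE motifs by A>C and U>G substitution within hit spans.

    Bases outside the spans are untouched; overlapping spans are merged
    before substitution; output length equals input length. On DNA input the
    substitution reads T as U (T>G).
    """
    _normalize_rna(sequence)  # validates characters
    spans = sorted((h.position, h.end) for h in hits)
    merged: list[list[int]] = []
    for s, e in spans:
        if s < 0 or e > len(sequence):
            raise ValueError(f"hit span [{s}, {e}) outside sequence of length {len(sequence)}")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = list(sequence)
    for s, e in merged:
        out[s:e] = sequence[s:e].translate(_MUTATION)
    return "".join(out)
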