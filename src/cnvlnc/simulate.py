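"""Synthetic paired tumor/normal cohort with planted, recoverable truth.

The generator emulates the study design every downstream stage consumes: a
small cohort of paired tumor/normal samples with probe-level log2 expression,
per-tumor copy-number segment profiles containing planted recurrent gain and
loss regions, a chosen subset of lncRNAs whose expression is dosage-driven by
those regions, lncRNA->mRNA co-expression structure, clinical covariates with
proportional-hazards survival tied to the driver lncRNAs, and first-order
mRNA decay time courses.

Dosage logic: a driven lncRNA inside a planted region is shifted by
``direction x dosage_effect`` (log2) in exactly the tumor samples that carry
the region; non-driven genes have no systematic tumor/normal shift. Because
the paired log2 fold change of a driven gene then scales as
``(k/n_patients) x dosage_effect`` for a region carried by k samples, the
regions hosting drivers are modeled as near-ubiquitous (k in
{n_patients-1, n_patients}) — an |log2FC| >= 1 screen at effect 1.5 can only
see high-penetrance events, mirroring the broad chromosome-arm gains that
motivate this kind of screen — while background planted regions draw their
support uniformly from {region_recurrence, ..., n_patients}.

Randomness uses one master integer seed with named substreams per component,
so regenerating one component never perturbs the others; a fixed seed and
config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import DecayCurve
from .segments import GAIN, LOSS, Segment, SegmentProfile, segment_mean_from_cn

_STREAMS = {
    "regions": 0,
    "segments": 1,
    "annotation": 2,
    "expression": 3,
    "clinical": 4,
    "genesets": 5,
}

DEFAULT_CHROMOSOMES = (
    ("chr1", 60_000_000),
    ("chr2", 50_000_000),
    ("chr3", 40_000_000),
    ("chr4", 30_000_000),
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the cohort the screen targets."""

    seed: int = 0
    n_patients: int = 9
    chromosome_lengths: tuple = DEFAULT_CHROMOSOMES
    n_lnc_genes: int = 200
    n_mrna_genes: int = 800
    probes_per_gene: tuple[int, int] = (1, 4)
    n_gain_regions: int = 8
    n_loss_regions: int = 8
    region_recurrence: int = 2
    dosage_effect: float = 1.5
    n_driven_lnc: int = 10
    coexpression_targets_per_driver: int = 5
    coexpression_strength: float = 0.8
    #: log2 shift of a target mRNA per log2 unit of its driver's dosage effect;
    #: the default gives a 1.0 log2 tumor shift (|FC| = 2) at dosage 1.5 and
    #: no downstream response at all when the dosage effect is zero
    target_response: float = 1.0 / 1.5
    noise_sd: float = 0.4
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_private_events_per_sample: int = 2
    survival_hr: float = 3.7
    censoring_rate: float = 0.2
    median_survival_months: float = 36.0
    study_horizon_months: float = 120.0
    metastasis_odds_ratio: float = 3.0
    n_background_gene_sets: int = 10
    background_set_size: int = 20

    def __post_init__(self) -> None:
        positive = (
            "n_patients",
            "n_lnc_genes",
            "n_mrna_genes",
            "n_gain_regions",
            "n_loss_regions",
            "region_recurrence",
            "n_driven_lnc",
            "noise_sd",
            "median_survival_months",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive, got {getattr(self, name)}")
        if self.region_recurrence > self.n_patients:
            raise ValueError("config field 'region_recurrence' exceeds n_patients")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ValueError(f"config field 'probes_per_gene' must be a valid range, got {self.probes_per_gene}")
        if not 0 < self.coexpression_strength < 1:
            raise ValueError("config field 'coexpression_strength' must be in (0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("config field 'censoring_rate' must be in [0, 1)")
        if self.survival_hr <= 0:
            raise ValueError("config field 'survival_hr' must be positive")
        if self.dosage_effect < 0:
            raise ValueError("config field 'dosage_effect' must be >= 0")
        if self.n_driven_lnc > self.n_lnc_genes:
            raise ValueError("config field 'n_driven_lnc' exceeds n_lnc_genes")
        if self.n_driven_lnc > self.n_gain_regions + self.n_loss_regions:
            raise ValueError("config field 'n_driven_lnc' exceeds the number of planted regions")
        if self.n_driven_lnc * self.coexpression_targets_per_driver > self.n_mrna_genes:
            raise ValueError("config field 'coexpression_targets_per_driver' requires more mRNA genes")
        self.chromosome_lengths = tuple((str(c), int(l)) for c, l in self.chromosome_lengths)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromosome_lengths"] = [list(x) for x in d["chromosome_lengths"]]
        d["probes_per_gene"] = list(d["probes_per_gene"])
        return d


@dataclass
class PlantedRegion:
    chrom: str
    start: int
    end: int
    direction: str  # gain | loss
    carriers: tuple[str, ...]  # tumor sample ids
    hosts_driver: bool = False


@dataclass
class SyntheticCohort:
    """Everything a full screen run needs, plus the planted truth table."""

    config: SimulationConfig
    genes: pd.DataFrame  # gene_id, biotype, chrom, start, end, strand
    probe_map: pd.DataFrame  # probe_id, gene_id, biotype
    profiles: list[SegmentProfile]
    expression: pd.DataFrame  # probes x samples, log2
    pairing: pd.DataFrame  # tumor_sample, normal_sample, patient_id
    clinical: pd.DataFrame
    truth: pd.DataFrame  # planted drivers with direction, region, targets
    gene_sets: dict[str, set] = field(default_factory=dict)
    planted_regions: list[PlantedRegion] = field(default_factory=list)

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.pairing["tumor_sample"])

    def write(self, outdir) -> None:
        from . import io as io_mod

        io_mod.write_cohort(self, outdir)


def _place_intervals(
    rng: np.random.Generator,
    chroms: tuple,
    n: int,
    min_len: int,
    max_len: int,
    occupied: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Rejection-sample n intervals disjoint from ``occupied`` and each other."""
    names = [c for c, _ in chroms]
    lengths = np.array([l for _, l in chroms], dtype=float)
    weights = lengths / lengths.sum()
    placed: list[tuple[str, int, int]] = []
    taken = list(occupied)
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place non-overlapping intervals; genome too small")
        ci = rng.choice(len(names), p=weights)
        chrom, clen = names[ci], int(lengths[ci])
        span = int(rng.integers(min_len, min(max_len, max(min_len + 1, clen // 4))))
        start = int(rng.integers(0, clen - span))
        end = start + span
        if any(c == chrom and start < e and s < end for c, s, e in taken):
            continue
        placed.append((chrom, start, end))
        taken.append((chrom, start, end))
    return placed


def _plant_regions(
    config: SimulationConfig, tumor_samples: list[str]
) -> tuple[list[PlantedRegion], list[PlantedRegion]]:
    rng = _rng(config.seed, "regions")
    n_regions = config.n_gain_regions + config.n_loss_regions
    spots = _place_intervals(
        rng, config.chromosome_lengths, n_regions, 1_000_000, 4_000_000, []
    )
    directions = [GAIN] * config.n_gain_regions + [LOSS] * config.n_loss_regions

    # round-robin drivers over regions of the matching direction
    gain_idx = [i for i, d in enumerate(directions) if d == GAIN]
    loss_idx = [i for i, d in enumerate(directions) if d == LOSS]
    hosts: list[int] = []
    gi = li = 0
    for k in range(config.n_driven_lnc):
        if k % 2 == 0 and gi < len(gain_idx):
            hosts.append(gain_idx[gi]); gi += 1
        elif li < len(loss_idx):
            hosts.append(loss_idx[li]); li += 1
        else:
            hosts.append(gain_idx[gi]); gi += 1
    host_set = set(hosts)

    n = config.n_patients
    regions = []
    for i, ((chrom, start, end), direction) in enumerate(zip(spots, directions)):
        if i in host_set:
            k = int(rng.integers(max(config.region_recurrence, n - 1), n + 1))
        else:
            k = int(rng.integers(config.region_recurrence, n + 1))
        carriers = tuple(sorted(rng.choice(tumor_samples, size=k, replace=False)))
        regions.append(
            PlantedRegion(chrom, start, end, direction, carriers, hosts_driver=i in host_set)
        )
    # host list in driver order for gene placement
    regions_in_driver_order = [regions[i] for i in hosts]
    return regions, regions_in_driver_order


def _build_profiles(
    config: SimulationConfig,
    regions: list[PlantedRegion],
    tumor_samples: list[str],
    rng: np.random.Generator,
) -> list[SegmentProfile]:
    gain_cn = (3, 4, 5)
    occupied = [(r.chrom, r.start, r.end) for r in regions]
    profiles = []
    for sid in tumor_samples:
        segs = []
        for r in regions:
            if sid in r.carriers:
                cn = int(rng.choice(gain_cn)) if r.direction == GAIN else 1
                segs.append(Segment(sid, r.chrom, r.start, r.end, segment_mean_from_cn(cn)))
        private = _place_intervals(
            rng, config.chromosome_lengths, config.n_private_events_per_sample,
            200_000, 2_000_000, occupied,
        )
        for chrom, start, end in private:
            cn = int(rng.choice((1, 3)))
            segs.append(Segment(sid, chrom, start, end, segment_mean_from_cn(cn)))
        profiles.append(SegmentProfile(sample_id=sid, segments=segs))
    return profiles


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic study. Deterministic in (config, seed)."""
    n = config.n_patients
    patient_ids = [f"P{i + 1:02d}" for i in range(n)]
    tumor_samples = [f"{p}_T" for p in patient_ids]
    normal_samples = [f"{p}_N" for p in patient_ids]
    pairing = pd.DataFrame(
        {"tumor_sample": tumor_samples, "normal_sample": normal_samples, "patient_id": patient_ids}
    )

    regions, driver_hosts = _plant_regions(config, tumor_samples)
    seg_rng = _rng(config.seed, "segments")
    profiles = _build_profiles(config, regions, tumor_samples, seg_rng)

    # ---- annotation -------------------------------------------------------
    ann_rng = _rng(config.seed, "annotation")
    driver_indices = sorted(ann_rng.choice(config.n_lnc_genes, size=config.n_driven_lnc, replace=False))
    driver_of_index = {idx: d for d, idx in enumerate(driver_indices)}

    gene_rows = []
    lo, hi = config.probes_per_gene
    occupied_regions = [(r.chrom, r.start, r.end) for r in regions]
    for i in range(config.n_lnc_genes):
        gene_id = f"LNC{i + 1:04d}"
        if i in driver_of_index:
            host = driver_hosts[driver_of_index[i]]
            glen = int(ann_rng.integers(5_000, 50_000))
            start = int(ann_rng.integers(host.start, host.end - glen))
            chrom, end = host.chrom, start + glen
            n_probes = int(ann_rng.integers(max(2, lo), hi + 1))
        else:
            chrom, start, end = _place_intervals(
                ann_rng, config.chromosome_lengths, 1, 5_000, 100_000, []
            )[0]
            n_probes = int(ann_rng.integers(lo, hi + 1))
        strand = str(ann_rng.choice(["+", "-"]))
        gene_rows.append((gene_id, "lncRNA", chrom, start, end, strand, n_probes))
    for i in range(config.n_mrna_genes):
        gene_id = f"MRNA{i + 1:04d}"
        chrom, start, end = _place_intervals(
            ann_rng, config.chromosome_lengths, 1, 5_000, 100_000, []
        )[0]
        strand = str(ann_rng.choice(["+", "-"]))
        n_probes = int(ann_rng.integers(lo, hi + 1))
        gene_rows.append((gene_id, "mRNA", chrom, start, end, strand, n_probes))

    genes = pd.DataFrame(
        [r[:6] for r in gene_rows],
        columns=["gene_id", "biotype", "chrom", "start", "end", "strand"],
    )
    probe_rows = []
    for r in gene_rows:
        gene_id, biotype, n_probes = r[0], r[1], r[6]
        for j in range(n_probes):
            probe_rows.append((f"{gene_id}_p{j + 1}", gene_id, biotype))
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id", "biotype"])

    # co-expression targets, drawn disjointly across drivers
    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(config.n_mrna_genes)]
    n_targets = config.n_driven_lnc * config.coexpression_targets_per_driver
    target_pool = list(ann_rng.choice(mrna_ids, size=n_targets, replace=False))
    targets_of_driver = [
        target_pool[d * config.coexpression_targets_per_driver:(d + 1) * config.coexpression_targets_per_driver]
        for d in range(config.n_driven_lnc)
    ]

    # ---- expression -------------------------------------------------------
    expr_rng = _rng(config.seed, "expression")
    probe_ids = list(probe_map["probe_id"])
    probe_gene = list(probe_map["gene_id"])
    gene_base = {
        g: expr_rng.normal(config.baseline_mean, config.baseline_sd) for g in genes["gene_id"]
    }
    base = np.array([gene_base[g] for g in probe_gene]) + expr_rng.normal(0, 0.25, len(probe_ids))

    P = len(probe_ids)
    normal = base[:, None] + expr_rng.normal(0, config.noise_sd, (P, n))
    tumor = base[:, None] + expr_rng.normal(0, config.noise_sd, (P, n))

    probe_rows_of_gene: dict[str, list[int]] = {}
    for idx, g in enumerate(probe_gene):
        probe_rows_of_gene.setdefault(g, []).append(idx)

    carrier_mask = {}
    driver_sign = {}
    driver_ids = []
    for d, idx in enumerate(driver_indices):
        gene_id = f"LNC{idx + 1:04d}"
        driver_ids.append(gene_id)
        host = driver_hosts[d]
        sign = 1.0 if host.direction == GAIN else -1.0
        driver_sign[gene_id] = sign
        mask = np.array([t in host.carriers for t in tumor_samples])
        carrier_mask[gene_id] = mask
        rows = probe_rows_of_gene[gene_id]
        tumor[np.ix_(rows, np.flatnonzero(mask))] += sign * config.dosage_effect

    # correlated targets: share the driver's standardized tumor profile and
    # shift in proportion to the driver's dosage effect (no driver
    # overexpression -> no downstream response)
    s = config.coexpression_strength
    target_shift = config.target_response * config.dosage_effect
    for d, gene_id in enumerate(driver_ids):
        rows = probe_rows_of_gene[gene_id]
        dvec = tumor[rows].mean(axis=0)
        sd = dvec.std()
        z = (dvec - dvec.mean()) / sd if sd > 0 else np.zeros_like(dvec)
        for tgt in targets_of_driver[d]:
            trows = probe_rows_of_gene[tgt]
            eps = expr_rng.normal(0, 1, (len(trows), n))
            tumor[trows] = (
                base[trows][:, None]
                + target_shift
                + config.noise_sd * (s * z[None, :] + np.sqrt(1 - s * s) * eps)
            )

    expression = pd.DataFrame(
        np.hstack([tumor, normal]), index=pd.Index(probe_ids, name="probe_id"),
        columns=tumor_samples + normal_samples,
    )

    # ---- clinical ---------------------------------------------------------
    clin_rng = _rng(config.seed, "clinical")
    score = np.zeros(n)
    for gene_id in driver_ids:
        rows = probe_rows_of_gene[gene_id]
        gvec = tumor[rows].mean(axis=0)
        sd = gvec.std()
        z = (gvec - gvec.mean()) / sd if sd > 0 else np.zeros(n)
        score += driver_sign[gene_id] * z
    score /= len(driver_ids)

    from .clinical import dichotomize  # local import avoids cycle at module load

    group = dichotomize(score) if np.ptp(score) > 0 else np.array(["low"] * n, dtype=object)
    lam0 = np.log(2) / config.median_survival_months
    lam = lam0 * np.where(group == "high", config.survival_hr, 1.0)
    t_event = clin_rng.exponential(1.0 / lam)
    if config.censoring_rate > 0:
        lam_c = lam0 * config.censoring_rate / (1 - config.censoring_rate)
        t_cens = clin_rng.exponential(1.0 / lam_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.study_horizon_months)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    p0 = 0.15
    logit0 = np.log(p0 / (1 - p0))
    p_met = 1.0 / (1.0 + np.exp(-(logit0 + np.log(config.metastasis_odds_ratio) * (group == "high"))))
    metastasis = (clin_rng.uniform(size=n) < p_met).astype(int)
    age = np.round(clin_rng.normal(62, 10, n)).astype(int)
    sex = clin_rng.choice(["M", "F"], size=n)

    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "time": np.round(time, 3),
            "event": event,
            "expression_group": group,
            "driver_score": np.round(score, 4),
            "age": age,
            "sex": sex,
            "metastasis": metastasis,
        }
    )

    # ---- truth + gene sets ------------------------------------------------
    truth_rows = []
    for d, gene_id in enumerate(driver_ids):
        host = driver_hosts[d]
        truth_rows.append(
            {
                "gene_id": gene_id,
                "direction": "up" if host.direction == GAIN else "down",
                "chrom": host.chrom,
                "region_start": host.start,
                "region_end": host.end,
                "region_support": len(host.carriers),
                "targets": ",".join(targets_of_driver[d]),
            }
        )
    truth = pd.DataFrame(truth_rows)

    set_rng = _rng(config.seed, "genesets")
    gene_sets: dict[str, set] = {
        f"TARGETS_{gid}": set(targets_of_driver[d]) for d, gid in enumerate(driver_ids)
    }
    for i in range(config.n_background_gene_sets):
        members = set_rng.choice(mrna_ids, size=min(config.background_set_size, len(mrna_ids)), replace=False)
        gene_sets[f"RANDOM_SET_{i + 1:02d}"] = set(members)

    return SyntheticCohort(
        config=config,
        genes=genes,
        probe_map=probe_map,
        profiles=profiles,
        expression=expression,
        pairing=pairing,
        clinical=clinical,
        truth=truth,
        gene_sets=gene_sets,
        planted_regions=regions,
    )


def simulate_decay_curve(
    half_life: float, timepoints, noise_sd: float = 0.0, seed: int = 0
) -> DecayCurve:
    """First-order decay time course: 2^(-t/half_life) with multiplicative noise.

    ``noise_sd`` is the coefficient of variation of the lognormal measurement
    noise; the t=0 abundance is fixed to 1 before noise.
    """
    if half_life <= 0:
        raise ValueError(f"half_life must be positive, got {half_life}")
    t = np.asarray(list(timepoints), dtype=float)
    if 0.0 not in t:
        raise ValueError("timepoints must include 0")
    abundance = np.power(2.0, -t / half_life)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        abundance = abundance * np.exp(rng.normal(0.0, noise_sd, size=t.size))
    return DecayCurve(timepoints=t, abundance=abundance)
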