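"""Readers and writers for the pipeline's plain-text formats.

Dialects: SEG-like TSV is 1-based inclusive on disk and converted to the
internal 0-based half-open convention at this boundary; BED is native
0-based half-open; GMT is the standard set-name / description / tab-separated
gene list; expression matrices are TSV with probe rows and sample columns.
Every writer/reader pair round-trips to an identical object.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .segments import Segment, SegmentProfile

SEG_COLUMNS = ["sample", "chrom", "start", "end", "seg_mean"]


def read_seg(path) -> list[SegmentProfile]:
    """Read a SEG-like TSV (1-based inclusive coordinates) into profiles."""
    path = Path(path)
    segments_by_sample: dict[str, list[Segment]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.lower() for h in header] != SEG_COLUMNS:
            raise ValueError(f"{path}: expected header {SEG_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            sample, chrom, start_s, end_s, sm_s = fields
            try:
                start_1b, end_1b, sm = int(start_s), int(end_s), float(sm_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
            if start_1b > end_1b:
                raise ValueError(f"{path}:{lineno}: start > end ({start_1b} > {end_1b})")
            try:
                seg = Segment(sample, chrom, start_1b - 1, end_1b, sm)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            segments_by_sample.setdefault(sample, []).append(seg)
    profiles = []
    for sample in sorted(segments_by_sample):
        try:
            profiles.append(SegmentProfile(sample, segments_by_sample[sample]))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
    return profiles


def write_seg(profiles: list[SegmentProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for profile in profiles:
            for s in profile.segments:
                fh.write(f"{s.sample_id}\t{s.chrom}\t{s.start + 1}\t{s.end}\t{s.seg_mean!r}\n")


def read_bed(path) -> pd.DataFrame:
    """BED6 genes (0-based half-open) -> gene table (biotype via probe map)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs >= 4 fields")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) >= 6 else "+"
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            rows.append((name, chrom, start, end, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_bed(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t.\t{row.strand}\n")


def read_probe_map(path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_id", "biotype"}
    if not required.issubset(pm.columns):
        raise ValueError(f"{path}: probe map needs columns {sorted(required)}")
    dup = pm["probe_id"][pm["probe_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate probe ids: {sorted(set(dup))[:5]}")
    return pm


def write_probe_map(probe_map: pd.DataFrame, path) -> None:
    probe_map.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0)
    if m.index.duplicated().any():
        dups = sorted(set(m.index[m.index.duplicated()]))
        raise ValueError(f"{path}: duplicate probe ids: {dups[:5]}")
    m.index.name = "probe_id"
    return m


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")


def read_pairing(path, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    pairing = pd.read_csv(path, sep="\t", dtype=str)
    required = {"tumor_sample", "normal_sample", "patient_id"}
    if not required.issubset(pairing.columns):
        raise ValueError(f"{path}: pairing needs columns {sorted(required)}")
    if matrix is not None:
        listed = set(pairing["tumor_sample"]) | set(pairing["normal_sample"])
        missing = sorted(listed - set(matrix.columns))
        if missing:
            raise ValueError(f"{path}: samples absent from matrix: {missing}")
    return pairing


def read_clinical(path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time", "event"}
    if not required.issubset(clin.columns):
        raise ValueError(f"{path}: clinical table needs columns {sorted(required)}")
    if (clin["time"] < 0).any():
        raise ValueError(f"{path}: negative survival time")
    if not set(clin["event"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: event must be binary 0/1")
    return clin


def read_gmt(path) -> dict[str, set]:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT needs name, description, >=1 gene")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(gene_sets: dict[str, set], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader for short 3'UTR-style sequences."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_cohort(cohort, outdir) -> None:
    """Write every component of a synthetic cohort to a directory."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_seg(cohort.profiles, outdir / "segments.seg.tsv")
    write_bed(cohort.genes, outdir / "genes.bed")
    write_probe_map(cohort.probe_map, outdir / "probe_map.tsv")
    write_matrix(cohort.expression, outdir / "expression.tsv")
    cohort.pairing.to_csv(outdir / "pairing.tsv", sep="\t", index=False)
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_gmt(cohort.gene_sets, outdir / "gene_sets.gmt")
    (outdir / "config.yaml").write_text(yaml.safe_dump(cohort.config.to_dict(), sort_keys=True))


def read_cohort_inputs(indir):
    """Load the screen inputs written by :func:`write_cohort`.

    Returns (expression, pairing, profiles, genes, probe_map). The gene table
    regains its biotype column from the probe map.
    """
    indir = Path(indir)
    expression = read_matrix(indir / "expression.tsv")
    pairing = read_pairing(indir / "pairing.tsv", matrix=expression)
    profiles = read_seg(indir / "segments.seg.tsv")
    genes = read_bed(indir / "genes.bed")
    probe_map = read_probe_map(indir / "probe_map.tsv")
    biotype = probe_map.drop_duplicates("gene_id").set_index("gene_id")["biotype"]
    genes = genes.assign(biotype=genes["gene_id"].map(biotype))
    genes = genes[["gene_id", "biotype", "chrom", "start", "end", "strand"]]
    return expression, pairing, profiles, genes, probe_map
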