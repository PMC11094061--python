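"""Per-base 3'UTR coverage: reading, normalization, aggregation.

Coordinates are 0-based half-open (UCSC convention).  Depth vectors are
stored in transcript orientation: for a minus-strand gene, ``depth[0]``
corresponds to the highest genomic coordinate of the UTR.  Positions
absent from a bedGraph are depth 0, matching genome-browser semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd


class BedParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class UTRAnnotation:
    """One gene's 3'UTR interval; ``distal_site`` is the transcript 3' end."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")

    @property
    def distal_site(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-base depth over one UTR for one sample, transcript-oriented."""

    gene_id: str
    sample_id: str
    condition: str
    replicate: int | None
    depth: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValidationError("depth must be one-dimensional")
        if np.any(self.depth < 0):
            raise ValidationError(f"{self.gene_id}: negative depth")


def read_utr_bed(path: str | Path) -> list[UTRAnnotation]:
    """Parse a BED6 file of 3'UTRs; the name field is the gene id.

    Raises :class:`BedParseError` with the line number on malformed
    input and :class:`ValidationError` on duplicated gene ids.
    """
    annotations: list[UTRAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"{path}:{lineno}: expected >=6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                ann = UTRAnnotation(name, chrom, int(start), int(end), strand)
            except (ValueError, ValidationError) as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if name in seen:
                raise ValidationError(f"duplicate gene_id {name!r} in {path}")
            seen.add(name)
            annotations.append(ann)
    return annotations


def _expand_bedgraph(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Expand interval rows to sorted per-base (position, value) arrays."""
    starts = df["start"].to_numpy(np.int64)
    ends = df["end"].to_numpy(np.int64)
    vals = df["value"].to_numpy(float)
    lengths = ends - starts
    if np.any(lengths <= 0):
        raise ValidationError("bedGraph interval with end <= start")
    total = int(lengths.sum())
    # positions = start_i + (0 .. length_i - 1), concatenated
    reps = np.repeat(np.arange(starts.size), lengths)
    offset = np.arange(total) - np.repeat(np.cumsum(lengths) - lengths, lengths)
    pos = starts[reps] + offset
    val = vals[reps]
    order = np.argsort(pos, kind="stable")
    return pos[order], val[order]


def load_coverage(
    bedgraph_path: str | Path,
    annotations: list[UTRAnnotation],
    sample_id: str = "",
    condition: str = "",
    replicate: int | None = None,
) -> dict[str, CoverageTrack]:
    """Dense per-gene depth vectors from a 4-column bedGraph.

    bedGraph values are treated as constant over their interval and
    expanded per base; intervals may partially overlap the UTRs.
    Minus-strand vectors are reversed into transcript orientation.
    """
    try:
        df = pd.read_csv(bedgraph_path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    if len(df) and (df["value"] < 0).any():
        raise ValidationError(f"{bedgraph_path}: negative coverage value")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        by_chrom[str(chrom)] = _expand_bedgraph(sub)

    tracks: dict[str, CoverageTrack] = {}
    for ann in annotations:
        depth = np.zeros(ann.length, dtype=float)
        if ann.chrom in by_chrom:
            pos, val = by_chrom[ann.chrom]
            lo = np.searchsorted(pos, ann.start, side="left")
            hi = np.searchsorted(pos, ann.end, side="left")
            depth[pos[lo:hi] - ann.start] = val[lo:hi]
        if ann.strand == "-":
            depth = depth[::-1].copy()
        tracks[ann.gene_id] = CoverageTrack(
            gene_id=ann.gene_id, sample_id=sample_id, condition=condition,
            replicate=replicate, depth=depth, normalized=False)
    return tracks


def normalize_rpm(track: CoverageTrack, total_mapped_reads: float) -> CoverageTrack:
    """Scale depth to reads per million: depth * 1e6 / total_mapped_reads."""
    if total_mapped_reads <= 0:
        raise ValidationError("total_mapped_reads must be > 0")
    if track.normalized:
        raise ValidationError(f"{track.gene_id}: track already normalized")
    return replace(track, depth=track.depth * (1e6 / total_mapped_reads),
                   normalized=True)


def average_replicates(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Position-wise mean of replicate tracks of one gene and condition."""
    if not tracks:
        raise ValidationError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if t.gene_id != first.gene_id:
            raise ValidationError("cannot average tracks of different genes")
        if t.depth.size != first.depth.size:
            raise ValidationError(f"{first.gene_id}: unequal track lengths")
    if not all(t.normalized for t in tracks):
        raise ValidationError("average_replicates requires normalized tracks")
    mean = np.mean([t.depth for t in tracks], axis=0)
    return CoverageTrack(gene_id=first.gene_id,
                         sample_id=f"{first.condition}_mean",
                         condition=first.condition, replicate=None,
                         depth=mean, normalized=True)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Sample manifest: sample_id, condition, replicate, total_mapped_reads, path.

    Relative paths are resolved against the manifest's directory.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "condition", "replicate", "total_mapped_reads", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("manifest contains duplicated sample_ids")
    base = Path(path).parent
    df["path"] = [str(p) if Path(p).is_absolute() else str(base / p)
                  for p in df["path"]]
    return df


def write_bedgraph(tracks: dict[str, CoverageTrack],
                   annotations: list[UTRAnnotation],
                   path: str | Path) -> Path:
    """Write per-gene tracks back to a genomic-coordinate bedGraph.

    Used to export averaged per-condition browser tracks.  Depth runs
    with equal values are merged.
    """
    ann_by_id = {a.gene_id: a for a in annotations}
    rows: list[tuple[str, int, int, float]] = []
    for gene_id, track in tracks.items():
        ann = ann_by_id[gene_id]
        vals = track.depth[::-1] if ann.strand == "-" else track.depth
        n = vals.size
        change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
        bounds = np.concatenate(([0], change, [n]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((ann.chrom, ann.start + int(s), ann.start + int(e),
                         float(vals[s])))
    rows.sort(key=lambda r: (r[0], r[1]))
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, s, e, v in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
    return path
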