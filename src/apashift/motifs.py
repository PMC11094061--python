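"""PAS-strength scoring and positional motif density maps.

Sequence windows are extracted around the proximal (fitted breakpoint)
and distal (annotated UTR end) cleavage sites, in transcript
orientation with DNA T transliterated to RNA U.  Two analyses run on
them:

* **PAS strength** — presence of the core polyadenylation hexamer
  AAUAAA or the upstream CFI element UGUA within a fixed flank
  (100 nt by default) strictly upstream of the cleavage position.
* **Positional motif maps** — for a target hexamer (the RBM3 motif
  AAUAUA by default), the fraction of events whose 10-nt window at each
  offset relative to the cleavage site contains the motif, smoothed
  with a running mean of 5 offsets.  Matches whose 6-mer equals the
  core PAS hexamer are excluded from the target scan.

Matching is exact substring matching (the motifs are literal hexamers);
an event counts once per offset regardless of multiple matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .coverage import UTRAnnotation, ValidationError

SITE_PROXIMAL = "pPAS"
SITE_DISTAL = "dPAS"

_TO_RNA = str.maketrans("Tt", "Uu")
_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PASWindow:
    """RNA-alphabet sequence around one cleavage site.

    ``site_offset`` is the index of the cleavage position within
    ``sequence``; offsets relative to the site are negative upstream.
    """

    gene_id: str
    site_kind: str
    sequence: str
    site_offset: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.site_offset <= len(self.sequence)):
            raise ValidationError(f"{self.gene_id}: site_offset out of bounds")
        alphabet = set(self.sequence.upper())
        if not alphabet <= set("ACGUN"):
            raise ValidationError(
                f"{self.gene_id}: non-RNA characters {alphabet - set('ACGUN')}")


@dataclass
class MotifProfile:
    """Per-offset motif incidence around a cleavage site."""

    offsets: np.ndarray
    raw_fraction: np.ndarray
    smoothed_fraction: np.ndarray
    n_events: int
    flags: list[str] = field(default_factory=list)


def load_sequences(fasta_path: str | Path) -> dict[str, str]:
    """FASTA records keyed by id (per-gene records or whole chromosomes)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}


def extract_pas_windows(
    annotations: list[UTRAnnotation],
    breakpoints: dict[str, int],
    sequences: dict[str, str],
    flank_up: int = 200,
    flank_down: int = 120,
) -> list[PASWindow]:
    """Windows around the fitted pPAS and annotated dPAS of each gene.

    ``sequences`` may hold per-gene records (keyed by gene id, covering
    the UTR plus a 3' flank on the genomic strand) or chromosome-level
    records (keyed by chrom).  Minus-strand sequence is
    reverse-complemented into transcript orientation; windows that would
    extend past the available sequence are truncated and flagged.
    Genes without a fitted breakpoint contribute only a dPAS window.
    """
    windows: list[PASWindow] = []
    for ann in annotations:
        L = ann.length
        if ann.gene_id in sequences:
            gseq = sequences[ann.gene_id]
            tseq = gseq if ann.strand == "+" else _revcomp_dna(gseq)
        elif ann.chrom in sequences:
            chrom_seq = sequences[ann.chrom]
            if ann.strand == "+":
                lo = ann.start
                hi = min(len(chrom_seq), ann.end + flank_down)
                tseq = chrom_seq[lo:hi]
            else:
                lo = max(0, ann.start - flank_down)
                hi = ann.end
                tseq = _revcomp_dna(chrom_seq[lo:hi])
        else:
            raise ValidationError(
                f"no sequence for {ann.gene_id} (or {ann.chrom}) in FASTA")
        if len(tseq) < L:
            raise ValidationError(f"{ann.gene_id}: sequence shorter than UTR")
        tseq = tseq.upper().translate(_TO_RNA)

        sites = []
        bp = breakpoints.get(ann.gene_id)
        if bp is not None and not (isinstance(bp, float) and np.isnan(bp)):
            sites.append((SITE_PROXIMAL, int(bp)))
        sites.append((SITE_DISTAL, L))
        for kind, site in sites:
            lo = site - flank_up
            hi = site + flank_down
            truncated = lo < 0 or hi > len(tseq)
            lo_c, hi_c = max(0, lo), min(len(tseq), hi)
            windows.append(PASWindow(
                gene_id=ann.gene_id, site_kind=kind,
                sequence=tseq[lo_c:hi_c], site_offset=site - lo_c,
                truncated=truncated))
    return windows


def pas_signal_presence(window: PASWindow, flank: int = 100
                        ) -> tuple[bool, bool]:
    """(has AAUAAA, has UGUA) within ``flank`` nt strictly upstream."""
    lo = max(0, window.site_offset - flank)
    region = window.sequence[lo:window.site_offset]
    return "AAUAAA" in region, "UGUA" in region


def pas_strength_summary(
    windows: list[PASWindow],
    gene_filter: set[str] | None = None,
    flank: int = 100,
) -> pd.DataFrame:
    """Fraction of pPAS / dPAS windows carrying each signal element.

    ``gene_filter`` restricts the event set (e.g. to events confirmed by
    an independent proximal-site caller); an empty filter yields a table
    with zero counts.  Duplicate (gene, site) windows count once.
    """
    seen: set[tuple[str, str]] = set()
    counts: dict[str, dict[str, int]] = {
        SITE_PROXIMAL: {"n": 0, "AAUAAA": 0, "UGUA": 0},
        SITE_DISTAL: {"n": 0, "AAUAAA": 0, "UGUA": 0},
    }
    for w in windows:
        if gene_filter is not None and w.gene_id not in gene_filter:
            continue
        key = (w.gene_id, w.site_kind)
        if key in seen:
            continue
        seen.add(key)
        has_a, has_u = pas_signal_presence(w, flank=flank)
        c = counts.setdefault(w.site_kind, {"n": 0, "AAUAAA": 0, "UGUA": 0})
        c["n"] += 1
        c["AAUAAA"] += has_a
        c["UGUA"] += has_u
    rows = []
    for kind, c in counts.items():
        n = c["n"]
        rows.append({
            "site_kind": kind, "n": n,
            "frac_AAUAAA": c["AAUAAA"] / n if n else np.nan,
            "frac_UGUA": c["UGUA"] / n if n else np.nan,
        })
    return pd.DataFrame(rows, columns=["site_kind", "n", "frac_AAUAAA",
                                       "frac_UGUA"])


def _match_positions(seq: str, motif: str, exclude: str | None) -> list[int]:
    """Start positions of exact motif matches, skipping excluded 6-mers."""
    positions = []
    start = seq.find(motif)
    while start != -1:
        if exclude is None or seq[start:start + len(exclude)] != exclude:
            positions.append(start)
        start = seq.find(motif, start + 1)
    return positions


def running_mean(values: np.ndarray, width: int) -> np.ndarray:
    """Centered running mean with shrinking windows at the edges."""
    half = width // 2
    out = np.empty_like(values, dtype=float)
    for i in range(values.size):
        lo = max(0, i - half)
        hi = min(values.size, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def motif_positional_map(
    windows: list[PASWindow],
    motif: str = "AAUAUA",
    exclude: str | None = "AAUAAA",
    window_nt: int = 10,
    smooth_nt: int = 5,
    span: tuple[int, int] = (-100, 100),
) -> MotifProfile:
    """Fraction of events with the motif in a sliding window per offset.

    At each offset ``o`` (0 = the cleavage position, windows advance
    1 nt at a time) an event counts if its subsequence
    ``[o, o + window_nt)`` relative to the site contains at least one
    exact occurrence of ``motif`` whose 6-mer does not equal
    ``exclude``.  The requested span is intersected with the offsets
    covered by every window (flagged when narrowed); the smoothed curve
    is a centered running mean of ``smooth_nt`` offsets with shrinking
    edges.
    """
    if not windows:
        raise ValidationError("no windows supplied")
    if len(motif) > window_nt:
        raise ValidationError("motif longer than the sliding window")

    # one window per gene
    unique: dict[str, PASWindow] = {}
    for w in windows:
        unique.setdefault(w.gene_id, w)
    ws = list(unique.values())

    flags: list[str] = []
    lo_req, hi_req = span
    lo_ok = max(-w.site_offset for w in ws)
    hi_ok = min(len(w.sequence) - w.site_offset - window_nt for w in ws)
    lo, hi = max(lo_req, lo_ok), min(hi_req, hi_ok)
    if (lo, hi) != (lo_req, hi_req):
        flags.append(f"span_truncated_to_({lo},{hi})")
    if lo > hi:
        raise ValidationError("requested span lies outside the windows")

    offsets = np.arange(lo, hi + 1)
    hit_counts = np.zeros(offsets.size, dtype=int)
    reach = window_nt - len(motif)
    for w in ws:
        seq = w.sequence.upper()
        covered = np.zeros(offsets.size, dtype=bool)
        for pos in _match_positions(seq, motif.upper(), exclude):
            rel = pos - w.site_offset
            a = max(lo, rel - reach)
            b = min(hi, rel)
            if a <= b:
                covered[a - lo:b - lo + 1] = True
        hit_counts += covered
    raw = hit_counts / len(ws)
    return MotifProfile(offsets=offsets, raw_fraction=raw,
                        smoothed_fraction=running_mean(raw, smooth_nt),
                        n_events=len(ws), flags=flags)


def compare_profiles(
    windows: list[PASWindow],
    groups: dict[str, set[str]],
    **map_kwargs,
) -> dict[tuple[str, str], MotifProfile]:
    """One positional profile per (group, site kind).

    ``groups`` maps a group name (e.g. shortened_8h, shortened_48h_only,
    non_changing) to its gene ids.  Empty groups yield a profile with
    ``n_events=0`` and NaN fractions, flagged rather than raising.
    """
    by_kind: dict[str, list[PASWindow]] = {}
    for w in windows:
        by_kind.setdefault(w.site_kind, []).append(w)

    out: dict[tuple[str, str], MotifProfile] = {}
    for group, members in groups.items():
        for kind, ws in by_kind.items():
            sel = [w for w in ws if w.gene_id in members]
            if not sel:
                span = map_kwargs.get("span", (-100, 100))
                offsets = np.arange(span[0], span[1] + 1)
                nan = np.full(offsets.size, np.nan)
                out[(group, kind)] = MotifProfile(
                    offsets=offsets, raw_fraction=nan.copy(),
                    smoothed_fraction=nan.copy(), n_events=0,
                    flags=["empty_group"])
                continue
            out[(group, kind)] = motif_positional_map(sel, **map_kwargs)
    return out


def profiles_to_frame(profiles: dict[tuple[str, str], MotifProfile]
                      ) -> pd.DataFrame:
    rows = []
    for (group, kind), prof in profiles.items():
        for i, off in enumerate(prof.offsets):
            rows.append({"site_kind": kind, "group": group, "offset": int(off),
                         "raw_fraction": prof.raw_fraction[i],
                         "smoothed_fraction": prof.smoothed_fraction[i],
                         "n_events": prof.n_events})
    return pd.DataFrame(rows, columns=["site_kind", "group", "offset",
                                       "raw_fraction", "smoothed_fraction",
                                       "n_events"])
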