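"""Synthetic two-isoform 3'UTR datasets with known ground truth.

Each simulated gene expresses a mixture of two transcript isoforms that
share a 3'UTR 5' end: a short isoform cleaved at a proximal
polyadenylation site (pPAS, an interior breakpoint) and a long isoform
cleaved at the distal UTR end (dPAS).  The per-base expected coverage at
transcript position ``x`` is

    depth * expression * ( PDUI/100 + (1 - PDUI/100) * 1[x < pPAS] )

where PDUI is the percentage of transcripts using the distal site
(PDUI = 100: uniform coverage across the whole UTR; PDUI = 0: a step to
zero at the breakpoint).  Replicate tracks jitter the condition-level
PDUI with truncated-normal noise and apply per-position count noise.

The generator also writes UTR annotations (BED6), UTR+flank sequences
(FASTA, genomic strand) with polyadenylation-signal hexamers planted
upstream of each cleavage site with configurable fidelity, and AAUAUA
motifs planted near the distal PAS of an "RBM3-regulated" gene subset.
Minus-strand genes are simulated in transcript orientation and written
reverse-complemented, so strand handling downstream is exercised for
real.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ConfigError, SimConfig

CHROM = "chrS"
GENE_GAP = 100

# DNA-alphabet motifs; analysis modules transliterate T -> U.
CORE_PAS = "AATAAA"
RBM3_MOTIF = "AATATA"
# Permutations of AATAAA (the U/T moved) that do not match the consensus.
SCRAMBLED_PAS = ("TAAAAA", "ATAAAA", "AAATAA", "AAAATA", "AAAAAT")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TruthRecord:
    """Ground truth for one simulated gene.

    ``true_pdui`` and ``expression`` map condition label -> value;
    PDUI is in [0, 100], expression is a dimensionless multiplier of
    ``SimConfig.mean_depth``.
    """

    gene_id: str
    utr_length: int
    proximal_offset: int
    true_pdui: dict[str, float]
    expression: dict[str, float]
    rbm3_regulated: bool
    pas_fidelity_p: float
    pas_fidelity_d: float
    strand: str = "+"
    regime: str = "unchanged"        # shortened | lengthened | unchanged
    onset: str = ""                  # "8h" | "48h" | "" for unchanged
    cd28_enhanced: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.proximal_offset < self.utr_length):
            raise ConfigError(
                f"{self.gene_id}: proximal_offset must be strictly interior")
        for cond, p in self.true_pdui.items():
            if not (0.0 <= p <= 100.0):
                raise ConfigError(f"{self.gene_id}/{cond}: PDUI outside [0,100]")
        for cond, e in self.expression.items():
            if e <= 0:
                raise ConfigError(f"{self.gene_id}/{cond}: expression must be > 0")


def _label_stage(label: str) -> str:
    """Early/late classification of a condition label.

    Labels with no recognizable time token behave like the late time
    point (fully developed effect), so two-condition designs such as
    ("naive", "stim") still plant the configured changes.
    """
    if "48" in label:
        return "late"
    if "8" in label:
        return "early"
    return "late"


def generate_truth(config: SimConfig) -> list[TruthRecord]:
    """Draw the ground-truth table for a simulated dataset.

    Gene regimes are assigned deterministically by count
    (``round(n_genes * frac)``), so the planted fractions are exact up
    to rounding.  To-be-shortened genes start from a high basal PDUI
    (Uniform(66, 100)): genes that shorten upon stimulation
    predominantly express long 3'UTRs at baseline.  Effect sizes are
    drawn so the planted change always exceeds the 20-point
    significance threshold, and for costimulation-enhanced genes so
    that the amplified change still fits inside the PDUI range.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_short = round(n * config.frac_shortened)
    n_long = round(n * config.frac_lengthened)
    if n_short + n_long > n:
        raise ConfigError("rounded shortened+lengthened fractions exceed n_genes")
    regimes = (["shortened"] * n_short + ["lengthened"] * n_long
               + ["unchanged"] * (n - n_short - n_long))

    lo, hi = config.utr_length_range
    sep = config.min_pas_separation
    ref = config.conditions[0]
    width = len(str(n))
    records: list[TruthRecord] = []
    for i, regime in enumerate(regimes):
        gene_id = f"gene{i:0{width}d}"
        L = int(rng.integers(lo, hi + 1))
        off = int(rng.integers(sep, L - sep + 1))
        strand = "+" if rng.random() < 0.5 else "-"

        if regime == "shortened":
            basal = float(rng.uniform(66.0, 100.0))
            sign = -1.0
            headroom = basal
        elif regime == "lengthened":
            basal = float(rng.uniform(0.0, 34.0))
            sign = +1.0
            headroom = 100.0 - basal
        else:
            basal = float(rng.uniform(10.0, 90.0))
            sign = 0.0
            headroom = 0.0

        onset = ""
        enhanced = False
        delta = 0.0
        if regime != "unchanged":
            onset = "8h" if rng.random() < config.frac_early else "48h"
            enhanced = rng.random() < config.frac_cd28_enhanced
            # Keep the (possibly amplified) change clearly significant and
            # inside [0, 100] without truncation.
            upper = min(55.0, headroom / config.cd28_enhancement) if enhanced \
                else min(55.0, headroom)
            upper = max(upper, 25.0 + 1e-9)
            delta = float(rng.uniform(25.0, upper))

        rbm3 = bool(regime == "shortened" and onset == "8h"
                    and rng.random() < config.frac_rbm3)

        pdui = {ref: basal}
        for cond in config.conditions[1:]:
            active = regime != "unchanged" and (
                _label_stage(cond) == "late" or onset == "8h")
            factor = config.cd28_enhancement if ("CD28" in cond and enhanced) else 1.0
            value = basal + sign * delta * factor if active else basal
            pdui[cond] = float(min(100.0, max(0.0, value)))

        expression = {cond: 1.0 for cond in config.conditions}
        records.append(TruthRecord(
            gene_id=gene_id, utr_length=L, proximal_offset=off,
            true_pdui=pdui, expression=expression, rbm3_regulated=rbm3,
            pas_fidelity_p=config.pas_fidelity_p,
            pas_fidelity_d=config.pas_fidelity_d,
            strand=strand, regime=regime, onset=onset, cd28_enhanced=enhanced,
        ))
    return records


@dataclass(frozen=True)
class GeneLayout:
    """Genomic placement of one gene block on the synthetic chromosome.

    The block covers the UTR plus a 3' flank of ``flank`` nt past the
    distal cleavage site (upstream in genomic coordinates for minus
    strand genes).
    """

    gene_id: str
    chrom: str
    utr_start: int
    utr_end: int
    strand: str
    block_start: int
    block_end: int


def gene_layout(truth: list[TruthRecord], flank: int) -> list[GeneLayout]:
    """Lay gene blocks end-to-end (with gaps) on one synthetic chromosome."""
    out = []
    pos = GENE_GAP
    for rec in truth:
        L = rec.utr_length
        if rec.strand == "+":
            utr_start, utr_end = pos, pos + L
            block = (pos, pos + L + flank)
        else:
            utr_start, utr_end = pos + flank, pos + flank + L
            block = (pos, pos + flank + L)
        out.append(GeneLayout(rec.gene_id, CHROM, utr_start, utr_end,
                              rec.strand, *block))
        pos = block[1] + GENE_GAP
    return out


def _transcript_sequence(rec: TruthRecord, config: SimConfig,
                         rng: np.random.Generator) -> str:
    """Random background with planted PAS / RBM3 hexamers.

    Transcript orientation: position 0 is the UTR 5' end, the proximal
    cleavage site is at ``proximal_offset``, the distal one at
    ``utr_length``; ``flank`` extra nt follow the distal site.
    """
    L, off = rec.utr_length, rec.proximal_offset
    seq = _BASES[rng.integers(0, 4, size=L + config.flank)]

    def plant(start: int, motif: str) -> None:
        seq[start:start + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")

    def scrub_context(start: int) -> None:
        # A scrambled hexamer must not combine with its flanking
        # background bases into an accidental consensus AATAAA, which
        # would distort the planted fidelity beyond binomial error.
        lo = max(0, start - 5)
        hi = min(seq.size, start + 11)
        region = seq[lo:hi].tobytes().decode()
        q = region.find(CORE_PAS)
        while q != -1:
            for j in range(q, q + 6):
                pos = lo + j
                if not (start <= pos < start + 6):
                    seq[pos] = b"C"
                    break
            region = seq[lo:hi].tobytes().decode()
            q = region.find(CORE_PAS)

    planted: list[tuple[int, int]] = []
    for site, fidelity in ((off, rec.pas_fidelity_p), (L, rec.pas_fidelity_d)):
        # Hexamer fully within 100 nt upstream of the cleavage site; the
        # 16-96 nt start range mimics the typical PAS-to-cleavage spacing
        # while keeping proximal and distal scan windows disjoint.
        start = site - int(rng.integers(16, 97))
        start = max(start, 0)
        if rng.random() < fidelity:
            plant(start, CORE_PAS)
        else:
            plant(start, SCRAMBLED_PAS[int(rng.integers(0, len(SCRAMBLED_PAS)))])
            scrub_context(start)
        planted.append((start, start + 6))

    if rec.rbm3_regulated:
        w = config.rbm3_window
        for _ in range(100):
            start = L - w + int(rng.integers(0, 2 * w - 6 + 1))
            if all(start + 6 <= s or start >= e for s, e in planted):
                break
        plant(start, RBM3_MOTIF)

    return seq.tobytes().decode()


def write_annotation_and_sequence(
    truth: list[TruthRecord],
    config: SimConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write BED6 annotations, UTR+flank FASTA and the truth table.

    FASTA records carry the genomic-strand sequence of each gene block
    (minus-strand genes reverse-complemented), one record per gene with
    the gene_id as header.  Coordinates are 0-based half-open.
    """
    if not truth:
        raise ConfigError("truth table is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 1])
    layouts = gene_layout(truth, config.flank)

    bed_path = outdir / "utr.bed"
    fasta_path = outdir / "sequences.fa"
    truth_path = outdir / "truth.tsv"
    rbm3_path = outdir / "rbm3_regulated.txt"

    with open(bed_path, "w") as bed, open(fasta_path, "w") as fa:
        for rec, lay in zip(truth, layouts):
            bed.write(f"{lay.chrom}\t{lay.utr_start}\t{lay.utr_end}\t"
                      f"{rec.gene_id}\t0\t{rec.strand}\n")
            tseq = _transcript_sequence(rec, config, rng)
            gseq = tseq if rec.strand == "+" else reverse_complement(tseq)
            fa.write(f">{rec.gene_id}\n")
            for i in range(0, len(gseq), 80):
                fa.write(gseq[i:i + 80] + "\n")

    with open(truth_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "utr_length", "proximal_offset", "condition",
                    "true_pdui", "expression", "rbm3_regulated", "strand",
                    "regime", "onset", "cd28_enhanced"])
        for rec in truth:
            for cond in config.conditions:
                w.writerow([rec.gene_id, rec.utr_length, rec.proximal_offset,
                            cond, f"{rec.true_pdui[cond]:.6g}",
                            f"{rec.expression[cond]:.6g}",
                            int(rec.rbm3_regulated), rec.strand, rec.regime,
                            rec.onset, int(rec.cd28_enhanced)])

    with open(rbm3_path, "w") as fh:
        fh.write("# genes with AAUAUA planted near the distal PAS\n")
        for rec in truth:
            if rec.rbm3_regulated:
                fh.write(rec.gene_id + "\n")

    return {"bed": bed_path, "fasta": fasta_path, "truth": truth_path,
            "rbm3": rbm3_path}


def _expected_profile(rec: TruthRecord, cond: str, pdui_r: float,
                      depth: float) -> np.ndarray:
    frac_long = pdui_r / 100.0
    expr = rec.expression[cond]
    prof = np.full(rec.utr_length, depth * expr * frac_long)
    prof[: rec.proximal_offset] = depth * expr
    return prof


def _runlength_rows(chrom: str, start: int, values: np.ndarray,
                    as_int: bool) -> list[tuple[str, int, int, str]]:
    """Merge consecutive equal values into bedGraph intervals."""
    n = values.size
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    bounds = np.concatenate(([0], change, [n]))
    rows = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        v = values[s]
        txt = str(int(v)) if as_int else f"{v:.17g}"  # .17g round-trips floats
        rows.append((chrom, start + int(s), start + int(e), txt))
    return rows


def simulate_coverage(
    truth: list[TruthRecord],
    config: SimConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one bedGraph per sample plus the sample manifest.

    For each sample the replicate-level PDUI of every gene is the
    condition PDUI plus truncated-normal jitter; count noise is applied
    per position per the configured model.  Tracks are emitted in
    genomic coordinates (minus-strand profiles reversed), sorted, with
    equal-valued runs merged.  The manifest reports
    ``total_mapped_reads = 1e6`` per sample: simulated depths are
    already on the reads-per-million scale, so RPM normalization is the
    identity for synthetic data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 2])
    layouts = gene_layout(truth, config.flank)
    as_int = config.noise_model != "none"

    paths: dict[str, Path] = {}
    manifest_path = outdir / "manifest.tsv"
    with open(manifest_path, "w", newline="") as mh:
        mw = csv.writer(mh, delimiter="\t", lineterminator="\n")
        mw.writerow(["sample_id", "condition", "replicate",
                     "total_mapped_reads", "path"])
        for cond in config.conditions:
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{cond}_{rep}"
                path = outdir / f"{sample_id}.bedGraph"
                rows: list[tuple[str, int, int, str]] = []
                for rec, lay in zip(truth, layouts):
                    pdui_r = rec.true_pdui[cond]
                    if config.replicate_pdui_sd > 0:
                        pdui_r += rng.normal(0.0, config.replicate_pdui_sd)
                    pdui_r = min(100.0, max(0.0, pdui_r))
                    lam = _expected_profile(rec, cond, pdui_r, config.mean_depth)
                    if config.noise_model == "poisson":
                        vals = rng.poisson(lam).astype(float)
                    elif config.noise_model == "negative_binomial":
                        k = config.nb_dispersion
                        shaped = rng.gamma(k, lam / k)
                        vals = rng.poisson(shaped).astype(float)
                    else:
                        vals = lam
                    if rec.strand == "-":
                        vals = vals[::-1]
                    rows.extend(_runlength_rows(lay.chrom, lay.utr_start,
                                                vals, as_int))
                with open(path, "w") as fh:
                    for chrom, s, e, v in rows:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
                mw.writerow([sample_id, cond, rep, 1000000, path.name])
                paths[sample_id] = path
    paths["manifest"] = manifest_path
    return paths


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Full synthetic dataset: truth + annotations + sequences + coverage."""
    truth = generate_truth(config)
    paths = write_annotation_and_sequence(truth, config, outdir)
    paths.update(simulate_coverage(truth, config, outdir))
    return paths
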