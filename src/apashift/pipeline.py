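"""End-to-end orchestration: simulate -> quantify -> call -> classify ->
motifs -> enrich, with reproducible seeds and a machine-readable run
manifest.

Each stage writes TSV outputs carrying a header block (config hash,
seed, version) so every threshold in an output is traceable to the
:class:`~apashift.config.RunConfig` that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .coverage import (UTRAnnotation, average_replicates, load_coverage,
                       normalize_rpm, read_manifest, read_utr_bed,
                       write_bedgraph)
from .enrichment import batch_enrichment, read_gene_list
from .events import (SIGNIFICANT_CALLS, TEMPORAL_48H_ONLY, basal_pdui_bin,
                     cd28_ratio_table, comparison_table, condition_correlation,
                     correlation_pairs, direction_summary, temporal_classify)
from .motifs import (compare_profiles, extract_pas_windows, load_sequences,
                     pas_strength_summary, profiles_to_frame)
from .quant import (QC_OK, adjust_and_call, call_events, fit_two_segment,
                    fits_to_frame)
from .simulate import generate_truth, simulate_coverage, \
    write_annotation_and_sequence


class StageError(RuntimeError):
    """A stage's upstream inputs are missing."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig,
               index: bool = False) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# apashift {__version__} config={cfg.config_hash()} "
                 f"seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def _read_tsv(path: Path, **kwargs) -> pd.DataFrame:
    if not path.exists():
        raise StageError(f"missing upstream output {path.name}; "
                         "run the producing stage first")
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def _temporal_pairs(comparisons: list[str]) -> list[tuple[str, str, str]]:
    """(stimulus, early comparison, late comparison) pairs by label token."""
    pairs = []
    early = {c for c in comparisons if "8" in c and "48" not in c}
    late = {c for c in comparisons if "48" in c}
    for e in sorted(early):
        stim = e.replace("_8h", "").replace("8h", "")
        for l in sorted(late):
            if l.replace("_48h", "").replace("48h", "") == stim:
                pairs.append((stim or "stim", e, l))
    return pairs


def _cd28_pairs(comparisons: list[str]) -> list[tuple[str, str, str]]:
    """(time label, CD3-alone comparison, costimulated comparison) pairs."""
    pairs = []
    for c in sorted(comparisons):
        if "CD28" not in c:
            partner = c.replace("CD3", "CD3CD28", 1)
            if partner in comparisons:
                time = "48h" if "48" in c else "8h"
                pairs.append((time, c, partner))
    return pairs


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written as ``manifest.json``):
    inputs, outputs and checksums per stage.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_dir = outdir / "sim"
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config_hash": cfg.config_hash(),
                      "config": cfg.to_dict(), "stages": {}}
    outputs: dict[str, Path] = {}

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in paths.items()}
        outputs.update(paths)

    sim = replace(cfg.sim, seed=cfg.seed)

    if "simulate" in cfg.stages:
        truth = generate_truth(sim)
        paths = write_annotation_and_sequence(truth, sim, sim_dir)
        paths.update(simulate_coverage(truth, sim, sim_dir))
        record("simulate", paths)

    bed_path = sim_dir / "utr.bed"
    manifest_path = sim_dir / "manifest.tsv"
    fasta_path = sim_dir / "sequences.fa"
    truth_path = sim_dir / "truth.tsv"

    fits_path = outdir / "fits.tsv"
    if "quantify" in cfg.stages:
        if not bed_path.exists() or not manifest_path.exists():
            raise StageError("quantify: missing simulate outputs "
                             "(utr.bed / manifest.tsv)")
        annotations = read_utr_bed(bed_path)
        samples = read_manifest(manifest_path)
        tracks_by_gene: dict[str, list] = {a.gene_id: [] for a in annotations}
        for row in samples.itertuples():
            tracks = load_coverage(row.path, annotations,
                                   sample_id=row.sample_id,
                                   condition=row.condition,
                                   replicate=int(row.replicate))
            for gene_id, track in tracks.items():
                tracks_by_gene[gene_id].append(
                    normalize_rpm(track, float(row.total_mapped_reads)))
        fits = [fit_two_segment(tracks, search_min=cfg.search_min,
                                min_mean_depth=cfg.min_mean_depth,
                                min_fit_gain=cfg.min_fit_gain)
                for tracks in tracks_by_gene.values()]
        fits_df = fits_to_frame(fits, samples)
        _write_tsv(fits_df, fits_path, cfg)

        # Averaged per-condition browser tracks of the reference condition.
        avg_dir = outdir / "tracks"
        avg_dir.mkdir(exist_ok=True)
        track_paths = {}
        for cond, sub in samples.groupby("condition"):
            per_gene = {}
            for gene_id in tracks_by_gene:
                reps = [t for t in tracks_by_gene[gene_id]
                        if t.condition == cond]
                if reps:
                    per_gene[gene_id] = average_replicates(reps)
            p = write_bedgraph(per_gene, annotations,
                               avg_dir / f"{cond}_mean.bedGraph")
            track_paths[f"track_{cond}"] = p
        record("quantify", {"fits": fits_path, **track_paths})

    events_path = outdir / "events.tsv"
    if "call" in cfg.stages:
        fits_df = _read_tsv(fits_path)
        ref = cfg.sim.conditions[0]
        pieces = []
        for stim in cfg.sim.conditions[1:]:
            ev = call_events(fits_df, ref, stim, method=cfg.test_method)
            ev = adjust_and_call(ev, dpdui_threshold=cfg.dpdui_threshold,
                                 alpha=cfg.alpha,
                                 nonchange_band=cfg.nonchange_band)
            pieces.append(ev)
        events_df = pd.concat(pieces, ignore_index=True)
        _write_tsv(events_df, events_path, cfg)
        record("call", {"events": events_path})

    summary_path = outdir / "summary.tsv"
    classes_path = outdir / "classification.tsv"
    if "classify" in cfg.stages:
        events_df = _read_tsv(events_path)
        by_comp = {name.split("_vs_")[0]: sub
                   for name, sub in events_df.groupby("comparison")}
        summary_rows = []
        for name, ev in by_comp.items():
            counts = direction_summary(ev)
            summary_rows.append({"metric": f"n_shortened_{name}",
                                 "value": counts["shortened"]})
            summary_rows.append({"metric": f"n_lengthened_{name}",
                                 "value": counts["lengthened"]})

        basal = (events_df.groupby("gene_id")["mean_pdui_ref"].first())
        table = comparison_table(by_comp, basal=basal)
        table["basal_bin"] = [
            basal_pdui_bin(v, cfg.pdui_long_cut, cfg.pdui_short_cut)
            if pd.notna(v) else "na" for v in table["basal_pdui"]]

        for stim, e_name, l_name in _temporal_pairs(list(by_comp)):
            ce = table.get(f"call_{e_name}")
            cl = table.get(f"call_{l_name}")
            if ce is None or cl is None:
                continue
            labels = temporal_classify(ce.fillna("missing"),
                                       cl.fillna("missing"))
            table[f"temporal_{stim}"] = labels
            for lab in ("8h_only", "48h_only", "both", "other"):
                summary_rows.append({
                    "metric": f"temporal_{stim}_{lab}",
                    "value": int((labels == lab).sum())})

        ratio_paths = {}
        for time, c3, cc in _cd28_pairs(list(by_comp)):
            ratios = cd28_ratio_table(by_comp[cc], by_comp[c3],
                                      floor=cfg.ratio_floor,
                                      threshold=cfg.ratio_threshold)
            p = _write_tsv(ratios, outdir / f"cd28_ratio_{time}.tsv", cfg)
            ratio_paths[f"cd28_ratio_{time}"] = p
            if len(ratios):
                frac = float(ratios["enhanced"].mean())
                summary_rows.append({"metric": f"cd28_enhanced_frac_{time}",
                                     "value": round(frac, 6)})
            x, y = correlation_pairs(by_comp[c3], by_comp[cc],
                                     mode=cfg.correlation_set)
            if x.size >= 3:
                r, slope, intercept = condition_correlation(x, y)
                summary_rows.append({"metric": f"pearson_r_{time}",
                                     "value": round(r, 6)})
                summary_rows.append({"metric": f"regression_slope_{time}",
                                     "value": round(slope, 6)})

        _write_tsv(pd.DataFrame(summary_rows), summary_path, cfg)
        _write_tsv(table.reset_index(), classes_path, cfg)
        record("classify", {"summary": summary_path,
                            "classification": classes_path, **ratio_paths})

    profiles_path = outdir / "motif_profiles.tsv"
    strength_path = outdir / "pas_strength.tsv"
    if "motifs" in cfg.stages:
        fits_df = _read_tsv(fits_path)
        events_df = _read_tsv(events_path)
        annotations = read_utr_bed(bed_path)
        sequences = load_sequences(fasta_path)
        bp = (fits_df[fits_df["qc_flag"] == QC_OK]
              .groupby("gene_id")["breakpoint"].first())
        windows = extract_pas_windows(annotations, bp.to_dict(), sequences,
                                      flank_up=cfg.flank_up,
                                      flank_down=cfg.flank_down)
        strength = pas_strength_summary(windows, flank=cfg.pas_flank)
        _write_tsv(strength, strength_path, cfg)

        by_comp = {name.split("_vs_")[0]: sub
                   for name, sub in events_df.groupby("comparison")}
        groups: dict[str, set[str]] = {}
        early = [c for c in by_comp if "8" in c and "48" not in c]
        late = [c for c in by_comp if "48" in c]
        if early:
            groups["shortened_8h"] = set().union(*[
                set(by_comp[c].loc[by_comp[c]["call"] == "shortened",
                                   "gene_id"]) for c in early])
        if late:
            groups["shortened_48h"] = set().union(*[
                set(by_comp[c].loc[by_comp[c]["call"] == "shortened",
                                   "gene_id"]) for c in late])
            groups["non_changing"] = set.intersection(*[
                set(by_comp[c].loc[by_comp[c]["call"] == "non_changing",
                                   "gene_id"]) for c in late])
        if early and late:
            groups["shortened_48h_only"] = groups["shortened_48h"] - set().union(
                *[set(by_comp[c].loc[by_comp[c]["call"].isin(SIGNIFICANT_CALLS),
                                     "gene_id"]) for c in early])
        profiles = compare_profiles(
            windows, groups, motif=cfg.motif, exclude=cfg.exclude_motif,
            window_nt=cfg.motif_window, smooth_nt=cfg.smooth, span=cfg.span)
        _write_tsv(profiles_to_frame(profiles), profiles_path, cfg)
        record("motifs", {"profiles": profiles_path, "pas_strength": strength_path})

    enrich_path = outdir / "enrichment.tsv"
    if "enrich" in cfg.stages:
        fits_df = _read_tsv(fits_path)
        events_df = _read_tsv(events_path)
        background = set(fits_df.loc[fits_df["qc_flag"] == QC_OK, "gene_id"])
        queries: dict[str, set[str]] = {}
        for name, sub in events_df.groupby("comparison"):
            short = set(sub.loc[sub["call"] == "shortened", "gene_id"])
            if short:
                queries[f"shortened_{name.split('_vs_')[0]}"] = short & background
        sets: dict[str, set[str]] = {}
        rbm3_path = sim_dir / "rbm3_regulated.txt"
        if rbm3_path.exists():
            sets["rbm3_regulated"] = read_gene_list(rbm3_path)
        if queries and sets:
            table = batch_enrichment(queries, sets, background,
                                     alpha=cfg.enrich_alpha,
                                     fold_threshold=cfg.enrich_fold)
        else:
            table = batch_enrichment({}, sets, background)
        _write_tsv(table, enrich_path, cfg)
        record("enrich", {"enrichment": enrich_path})

    manifest_file = outdir / "manifest.json"
    with open(manifest_file, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
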