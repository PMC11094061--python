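import numpy as np
import pandas as pd
import pytest

import apashift as a
from apashift.config import SimConfig


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=30, utr_length_range=(600, 1200), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    """A 30-gene synthetic dataset written once per session."""
    outdir = tmp_path_factory.mktemp("sim30")
    paths = a.simulate_dataset(small_config, outdir)
    return small_config, paths


@pytest.fixture(scope="session")
def small_truth(small_config):
    return a.generate_truth(small_config)


def load_normalized_tracks(paths):
    """All samples of a simulated dataset, RPM-normalized, keyed by gene."""
    annotations = a.read_utr_bed(paths["bed"])
    manifest = a.read_manifest(paths["manifest"])
    by_gene = {ann.gene_id: [] for ann in annotations}
    for row in manifest.itertuples():
        tracks = a.load_coverage(row.path, annotations,
                                 sample_id=row.sample_id,
                                 condition=row.condition,
                                 replicate=int(row.replicate))
        for gene_id, track in tracks.items():
            by_gene[gene_id].append(
                a.normalize_rpm(track, float(row.total_mapped_reads)))
    return annotations, manifest, by_gene


def quantify_dataset(paths, **fit_kwargs):
    """Fits for every gene of a simulated dataset, as a long DataFrame."""
    annotations, manifest, by_gene = load_normalized_tracks(paths)
    fits = [a.fit_two_segment(tracks, **fit_kwargs)
            for tracks in by_gene.values()]
    return a.fits_to_frame(fits, manifest), fits
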