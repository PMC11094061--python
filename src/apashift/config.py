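"""Configuration objects for simulation and pipeline runs.

All thresholds that drive event calling and classification live in
:class:`RunConfig`, so every number that appears in an output file is
traceable to a single configuration object.  Simulation parameters live
in :class:`SimConfig`; identical configurations (including the seed)
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

DEFAULT_CONDITIONS = ("naive", "CD3_8h", "CD3CD28_8h", "CD3_48h", "CD3CD28_48h")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-isoform 3'UTR dataset.

    The generator emulates a T-cell activation study design: a reference
    (naive) condition plus stimulated conditions at two time points, with
    or without costimulation, three replicates each.

    Parameters
    ----------
    n_genes:
        Number of simulated genes (one 3'UTR each).
    utr_length_range:
        Inclusive (min, max) 3'UTR length in nt.
    min_pas_separation:
        Minimum distance (nt) of the proximal cleavage site from either
        UTR end; keeps the breakpoint strictly interior.
    conditions:
        Condition labels; the first is the unstimulated reference.
        Labels containing ``"48"`` are treated as the late time point,
        labels containing ``"8"`` (but not ``"48"``) as the early one,
        and labels containing ``"CD28"`` as costimulated.  Labels with
        no time token behave like the late time point (fully developed
        effect).
    n_replicates:
        Replicates (donors) per condition.
    mean_depth:
        Expected coverage (reads per base) over the region covered by
        both isoforms, at expression 1.  Simulated tracks are written on
        this scale directly, i.e. they are already library-size
        comparable; the accompanying sample manifest therefore reports a
        total of 1e6 so that RPM normalization is the identity.
    noise_model:
        ``"poisson"``, ``"negative_binomial"`` or ``"none"`` (noiseless
        expectation, useful for exact checks).
    nb_dispersion:
        Gamma shape for the negative-binomial model (variance =
        mean + mean^2 / dispersion).
    replicate_pdui_sd:
        SD (percentage points) of the truncated-normal replicate-level
        jitter added to the condition PDUI.
    frac_shortened, frac_lengthened:
        Proportions of genes whose 3'UTR shortens / lengthens upon
        stimulation; the remainder are unchanged.
    frac_early:
        Among changing genes, the proportion whose change is already
        present at the early (8 h-like) time point; the rest change only
        at the late time point.
    frac_rbm3:
        Proportion of early-shortening genes that carry the RBM3 motif
        AAUAUA planted near the distal PAS.
    frac_cd28_enhanced:
        Proportion of changing genes whose effect is amplified by
        ``cd28_enhancement`` under costimulation.
    cd28_enhancement:
        Fold amplification of the PDUI change under costimulation for
        enhanced genes.
    pas_fidelity_p, pas_fidelity_d:
        Probability that the canonical AAUAAA hexamer is planted within
        100 nt upstream of the proximal / distal cleavage site (a
        scrambled non-matching permutation is planted otherwise).
    flank:
        Sequence written past the distal cleavage site (nt), so motif
        windows downstream of the dPAS are fully covered.
    rbm3_window:
        The planted AAUAUA lies entirely within +/- this many nt of the
        distal cleavage site.
    seed:
        Master seed; every random draw derives from it.
    """

    n_genes: int = 200
    utr_length_range: tuple[int, int] = (600, 2000)
    min_pas_separation: int = 150
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    mean_depth: float = 30.0
    noise_model: str = "poisson"
    nb_dispersion: float = 10.0
    replicate_pdui_sd: float = 5.0
    frac_shortened: float = 0.6
    frac_lengthened: float = 0.1
    frac_early: float = 0.4
    frac_rbm3: float = 0.8
    frac_cd28_enhanced: float = 0.3
    cd28_enhancement: float = 2.5
    pas_fidelity_p: float = 0.4
    pas_fidelity_d: float = 0.9
    flank: int = 120
    rbm3_window: int = 25
    seed: int = 0

    def validate(self) -> "SimConfig":
        lo, hi = self.utr_length_range
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not (0 < lo <= hi):
            raise ConfigError("utr_length_range must satisfy 0 < min <= max")
        if not (0 < self.min_pas_separation < lo):
            raise ConfigError("min_pas_separation must be in (0, min UTR length)")
        if 2 * self.min_pas_separation > lo:
            raise ConfigError(
                "2 * min_pas_separation must not exceed the minimum UTR length"
            )
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if len(self.conditions) < 2:
            raise ConfigError("need a reference plus at least one other condition")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("condition labels must be unique")
        for name in ("frac_shortened", "frac_lengthened", "frac_early",
                     "frac_rbm3", "frac_cd28_enhanced"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.frac_shortened + self.frac_lengthened > 1.0 + 1e-12:
            raise ConfigError("frac_shortened + frac_lengthened must be <= 1")
        for name in ("pas_fidelity_p", "pas_fidelity_d"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.noise_model not in ("poisson", "negative_binomial", "none"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if self.replicate_pdui_sd < 0:
            raise ConfigError("replicate_pdui_sd must be >= 0")
        if self.flank < self.rbm3_window + 6:
            raise ConfigError("flank must cover the RBM3 planting window")
        return self

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **kwargs).validate()


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Thresholds mirror the event-calling conventions of the analysis:
    a significant APA event needs |dPDUI| >= ``dpdui_threshold`` at
    BH-adjusted p < ``alpha``; a non-changing event needs
    |dPDUI| < ``nonchange_band`` with raw p > ``alpha``.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    outdir: str = "apashift_run"
    seed: int = 0

    # event calling
    dpdui_threshold: float = 20.0
    alpha: float = 0.05
    nonchange_band: float = 3.0
    test_method: str = "fisher"  # or "welch"

    # classification
    ratio_floor: float = 1.0
    ratio_threshold: float = 2.0
    pdui_long_cut: float = 66.0
    pdui_short_cut: float = 33.0
    correlation_set: str = "union"  # or "intersection"

    # breakpoint fitting
    search_min: int = 100
    min_mean_depth: float = 1.0
    min_fit_gain: float = 0.05

    # motif analysis
    pas_flank: int = 100
    motif: str = "AAUAUA"
    exclude_motif: str = "AAUAAA"
    motif_window: int = 10
    smooth: int = 5
    span: tuple[int, int] = (-100, 100)
    flank_up: int = 200
    flank_down: int = 120

    # enrichment thresholds
    enrich_alpha: float = 0.05
    enrich_fold: float = 2.0

    stages: tuple[str, ...] = (
        "simulate", "quantify", "call", "classify", "motifs", "enrich",
    )

    def validate(self) -> "RunConfig":
        self.sim.validate()
        for name in ("dpdui_threshold", "alpha", "nonchange_band", "ratio_floor",
                     "ratio_threshold", "pdui_long_cut", "pas_flank",
                     "motif_window", "smooth", "enrich_fold", "enrich_alpha"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.test_method not in ("fisher", "welch"):
            raise ConfigError(f"unknown test_method {self.test_method!r}")
        if self.correlation_set not in ("union", "intersection"):
            raise ConfigError(f"unknown correlation_set {self.correlation_set!r}")
        if self.pdui_short_cut >= self.pdui_long_cut:
            raise ConfigError("pdui_short_cut must be below pdui_long_cut")
        unknown = set(self.stages) - {
            "simulate", "quantify", "call", "classify", "motifs", "enrich"}
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            for key in ("utr_length_range",):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            if "conditions" in sim and isinstance(sim["conditions"], list):
                sim["conditions"] = tuple(sim["conditions"])
            sim = SimConfig(**sim)
        for key in ("span", "stages"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(sim=sim, **d).validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
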