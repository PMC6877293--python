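"""End-to-end orchestration: synthetic data -> coverage -> normalization
-> peaks -> orientation -> profiles (-> k-mer LASSO).

Every stage writes plain-text intermediates (FASTA / BED / bedGraph /
TSV / JSON) so each step is independently inspectable and re-runnable,
and the whole bundle is a pure function of the run configuration and
its global seed (no timestamps in outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import covtrack, dyadasym, kmerlasso, nucprof, peakcall, seqio, synthgen


@dataclass
class RunConfig:
    """Serializable configuration of a full (synthetic) run."""

    seed: int = 0
    genome_length: int = 50_000
    gc_profile: list | None = None          # [[start, end, gc], ...]
    kmer_weights: dict = field(default_factory=lambda: {"GC": 3.0, "GG": 1.5, "AA": -1.5})
    occupancy_window: int = 51
    occupancy_intercept: float = 1.0
    n_fragments: int = 60_000
    p_small: float = 0.5
    duplicate_rate: float = 0.05
    gradient_origin: int | None = 0
    gradient_max_ratio: float = 2.0
    effective_genome_size: int | None = None
    input_smooth_window: int = 10_000
    keep_component_fraction: float = 0.04
    score_threshold: float = 2.5
    flank: int = 100
    profile_length: int = 50
    run_lasso: bool = False
    lasso_top_n: int = 80
    lasso_subsample: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        if self.genome_length < 2 * self.occupancy_window:
            raise ValueError("genome too short for the occupancy window")
        if self.gradient_origin is not None and not (
            0 <= self.gradient_origin < self.genome_length
        ):
            raise ValueError("gradient origin outside genome")
        if self.effective_genome_size is not None and self.effective_genome_size <= 0:
            raise ValueError("effective genome size must be positive")


def run_full_analysis(config: RunConfig, outdir) -> dict:
    """Run the full synthetic pipeline; returns a result summary dict
    (also written as ``run_report.json``). All stage parameters and the
    config hash are logged in the report."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name: str, **params) -> None:
        log.append({"stage": name, **params})

    # --- synthesis ---------------------------------------------------
    gc_profile = (
        tuple(tuple(seg) for seg in config.gc_profile)
        if config.gc_profile
        else ((0, config.genome_length, 0.5),)
    )
    gspec = synthgen.GenomeSpec(
        length=config.genome_length, gc_profile=gc_profile, seed=config.seed
    )
    genome = synthgen.generate_genome(gspec)
    seqio.write_genome(genome, out / "genome.fa")

    model = synthgen.PlantedOccupancyModel(
        kmer_weights=dict(config.kmer_weights),
        window=config.occupancy_window,
        intercept=config.occupancy_intercept,
    )
    occupancy = synthgen.plant_occupancy(genome, model)
    seqio.write_track(occupancy.values, genome.id, out / "planted_occupancy.bedGraph")
    stage("synthgen", genome_length=config.genome_length, seed=config.seed,
          kmer_weights=dict(config.kmer_weights))

    gradient = (
        synthgen.ReplicationGradientSpec(
            origin=config.gradient_origin, max_ratio=config.gradient_max_ratio
        )
        if config.gradient_origin is not None
        else None
    )
    mix = synthgen.FragmentMixtureSpec(
        p_small=config.p_small,
        n_fragments=config.n_fragments,
        duplicate_rate=config.duplicate_rate,
        seed=config.seed,
    )
    fragments = synthgen.sample_fragments(occupancy, mix, gradient)
    seqio.write_fragments(fragments, out / "fragments.bed",
                          size_class_of=lambda L: covtrack.size_class_of(L) or "other")

    # sonicated input: flat occupancy, same copy-number gradient
    flat = covtrack.CoverageTrack(genome_id=genome.id,
                                  values=np.ones(len(genome)), size_class="all")
    input_mix = dataclasses.replace(mix, p_small=0.0, large_mode=150, large_sd=20.0,
                                    seed=config.seed + 1)
    input_fragments = synthgen.sample_fragments(flat, input_mix, gradient)
    seqio.write_fragments(input_fragments, out / "input.bed")
    stage("fragments", n=config.n_fragments, duplicate_rate=config.duplicate_rate,
          gradient_max_ratio=config.gradient_max_ratio)

    # --- coverage & normalization ------------------------------------
    eff_size = config.effective_genome_size or len(genome)
    tracks: dict[str, covtrack.CoverageTrack] = {}
    for size_class in ("small", "large", "all"):
        raw = covtrack.compute_coverage(fragments, genome, size_class)
        rpgc = covtrack.rpgc_normalize(raw, eff_size)
        tracks[size_class] = rpgc
        seqio.write_track(rpgc.values, genome.id, out / f"coverage_{size_class}.bedGraph")
    input_cov = covtrack.compute_coverage(input_fragments, genome, "all")
    normalized = covtrack.normalize_by_input(
        tracks["all"], input_cov, smooth_window=min(config.input_smooth_window, len(genome) - 1)
    )
    seqio.write_track(normalized.values, genome.id, out / "coverage_normalized.bedGraph")
    stage("coverage", effective_genome_size=eff_size,
          input_smooth_window=config.input_smooth_window)

    # --- peak calling -------------------------------------------------
    pconfig = peakcall.PeakCallConfig(
        keep_component_fraction=config.keep_component_fraction,
        score_threshold=config.score_threshold,
    )
    filtered = peakcall.fourier_filter(tracks["all"], pconfig.keep_component_fraction)
    peaks = peakcall.detect_peaks(filtered, tracks["all"], pconfig)
    broad = [p for p in peaks if p.width_class == "broad"]
    stage("peaks", n_peaks=len(peaks), n_broad=len(broad),
          keep_component_fraction=pconfig.keep_component_fraction,
          score_threshold=pconfig.score_threshold)

    # --- orientation & profiles --------------------------------------
    oriented_broad, orientation = dyadasym.orient_peaks(broad, tracks["small"])
    dyadasym.write_orientation_table(orientation, out / "orientation.tsv")
    all_oriented = oriented_broad + [p for p in peaks if p.width_class != "broad"]
    peakcall.write_peaks(all_oriented, out / "peaks.bed")
    if oriented_broad:
        profile = dyadasym.reoriented_aggregate(oriented_broad, tracks["small"], config.flank)
        np.savetxt(out / "reoriented_profile.tsv", profile, fmt="%.6f")
        gc_prof = nucprof.peak_gc_profile(oriented_broad, genome, config.flank)
        np.savetxt(out / "peak_gc_profile.tsv", gc_prof, fmt="%.6f")
    L = config.profile_length
    frag_L = [f for f in fragments if f.length == L]
    filtered_frags = nucprof.filter_reads(frag_L, peaks)
    profile_counts = {}
    if filtered_frags:
        for cls in ("SS", "WW"):
            offs, props = nucprof.positional_class_profile(filtered_frags, genome, cls)
            nucprof.write_profile(offs, props, cls, len(filtered_frags),
                                  out / f"profile_{cls}.tsv")
            profile_counts[cls] = len(filtered_frags)
        bg_ss = nucprof.background_expectation(genome, L, "SS", seed=config.seed)
    else:
        bg_ss = None
    stage("profiles", length=L, n_reads=len(filtered_frags), background_SS=bg_ss)

    # --- k-mer LASSO (optional, slow at large scale) ------------------
    lasso_summary = None
    if config.run_lasso:
        fs = kmerlasso.kmer_features(genome)
        response = normalized
        selected = kmerlasso.select_features(fs, response, top_n=config.lasso_top_n)
        fitted = kmerlasso.fit_lasso(fs, selected, response,
                                     subsample=config.lasso_subsample)
        fitted.to_json(out / "lasso_model.json")
        predicted = kmerlasso.predict_coverage(fitted, fs)
        rho_un = kmerlasso.evaluate_prediction(predicted, response, "untrained")
        rho_tr = kmerlasso.evaluate_prediction(predicted, response, "trained")
        lasso_summary = {"rho_untrained": rho_un, "rho_trained": rho_tr,
                         "penalty": fitted.penalty,
                         "n_nonzero": int(np.sum(np.abs(fitted.weights) > 0))}
        stage("lasso", **lasso_summary)

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": log,
        "n_peaks": len(peaks),
        "n_broad_peaks": len(broad),
        "n_flipped": sum(r.flipped for r in orientation),
        "background_SS": bg_ss,
        "lasso": lasso_summary,
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def demo_config(seed: int = 0) -> RunConfig:
    """The packaged demonstration dataset: a 50 kb circular genome,
    GC-driven occupancy, 60k fragments with a 2:1 replication gradient."""
    return RunConfig(seed=seed)
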