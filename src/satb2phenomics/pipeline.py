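"""End-to-end demo orchestration: configuration, logging, manifest.

``run_demo`` exercises every stage on synthetic or packaged inputs and
writes composites, spectrum tables/plots, photobleach summaries, phenotype
outputs and a JSON manifest (seeds, per-stage output checksums) to a run
directory.  Runs are deterministic given the seeds in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .face_average import compose_group
from .face_geometry import build_target, load_role_map
from .flip_quant import estimate_trace, summarize_constructs
from .phenotype_stats import (
    compare_groups,
    feature_fractions,
    load_study_phenotypes,
    recurrent_terms,
)
from .plots import plot_phenotype_heatmap, plot_recovery_curves, plot_spectrum
from .synthetic_data import CohortSpec, construct_panel, make_cohort, simulate_flip
from .variant_spectrum import (
    classify_variant,
    find_depleted_intervals,
    load_gene_model,
    load_study_variants,
    missense_density,
    summarize_spectrum,
)


@dataclass
class PipelineConfig:
    seed: int = 0
    # stage toggles
    faces: bool = True
    spectrum: bool = True
    flip: bool = True
    phenotypes: bool = True
    # face demo sizes
    n_groups: int = 2
    subjects_per_group: int = 5
    images_per_subject: int = 2
    n_reference: int = 200  # healthy constellations behind the target mesh
    # parameters
    bandwidth: float = 15.0
    min_len: int = 25
    min_n: int = 21
    cells_per_construct: int = 21
    flip_noise_sd: float = 0.02

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(stage: str, msg: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] {stage}: {msg}", file=sys.stderr)


def run_demo(config: PipelineConfig, out_dir) -> dict:
    """Run the enabled stages; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    rng = np.random.default_rng(config.seed)

    if config.faces:
        _log("faces", "building reference target and group composites")
        roles = load_role_map()
        from .synthetic_data import sample_constellations
        ref = sample_constellations(config.n_reference, CohortSpec(),
                                    seed=int(rng.integers(2**31)))
        target = build_target(ref)
        files = []
        for gi in range(config.n_groups):
            spec = CohortSpec(asymmetry_mean=2.0 * gi, asymmetry_sd=1.0)
            faces = make_cohort(config.subjects_per_group,
                                config.images_per_subject, spec,
                                seed=int(rng.integers(2**31)))
            comp = compose_group(faces, target, roles, f"group{gi}")
            png = out / f"composite_group{gi}.png"
            io.write_png(png, comp.average_image)
            csv = out / f"composite_group{gi}_constellation.csv"
            io.write_landmarks_csv(csv, type(faces[0].constellation)(
                comp.mean_points, f"group{gi}", "composite"))
            prov = out / f"composite_group{gi}.json"
            prov.write_text(json.dumps({
                "group": comp.group_label, "n_subjects": comp.n_subjects,
                "n_images": comp.n_images,
                "normalization_reference": comp.normalization_reference,
            }, indent=1))
            files += [png, csv, prov]
        manifest["stages"]["faces"] = {p.name: _sha256(p) for p in files}

    if config.spectrum:
        _log("spectrum", "classifying study variants and building density")
        gene = load_gene_model()
        variants = load_study_variants()
        summary = summarize_spectrum(variants, gene, cohort=(14, 4294))
        calls = [classify_variant(v, gene) for v in variants]
        import pandas as pd
        calls_df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
        calls_path = out / "consequence_calls.tsv"
        calls_df.to_csv(calls_path, sep="\t", index=False)
        positions = [v.protein_pos for v in variants
                     if v.raw_class == "missense"]
        track = missense_density(positions, gene, config.bandwidth)
        track_path = out / "missense_density.tsv"
        pd.DataFrame({"pos": track.positions.astype(int),
                      "density": track.density}).to_csv(
            track_path, sep="\t", index=False, float_format="%.6g")
        gaps = find_depleted_intervals(positions, gene, config.min_len)
        summary_path = out / "spectrum_summary.json"
        summary_path.write_text(json.dumps({
            "class_counts": summary.class_counts,
            "lof_total": summary.lof_total,
            "missense_by_domain": summary.missense_by_domain,
            "cohort_percent": summary.cohort_percent,
            "depleted_intervals": gaps,
        }, indent=1))
        plot_path = out / "spectrum.png"
        plot_spectrum(variants, track, gene, plot_path)
        manifest["stages"]["spectrum"] = {
            p.name: _sha256(p)
            for p in [calls_path, track_path, summary_path, plot_path]}

    if config.flip:
        _log("flip", "simulating photobleach panel and estimating kinetics")
        panel = construct_panel(noise_sd=config.flip_noise_sd)
        traces_by_construct, ests = {}, []
        for construct, params in panel.items():
            traces = [simulate_flip(params, seed=int(rng.integers(2**31)),
                                    cell_id=f"{construct}_c{i}",
                                    construct=construct)
                      for i in range(config.cells_per_construct)]
            traces_by_construct[construct] = traces
            ests.extend(estimate_trace(t) for t in traces)
        summary = summarize_constructs(ests, min_n=config.min_n)
        flip_path = out / "flip_summary.tsv"
        summary.to_csv(flip_path, sep="\t", index=False,
                       float_format="%.5g")
        plot_path = out / "flip_recovery.png"
        plot_recovery_curves(traces_by_construct, plot_path)
        manifest["stages"]["flip"] = {p.name: _sha256(p)
                                      for p in [flip_path, plot_path]}

    if config.phenotypes:
        _log("phenotypes", "tabulating study phenotype fixture")
        m = load_study_phenotypes()
        counts = recurrent_terms(m)
        fractions = feature_fractions(m)
        comparison = compare_groups(m)
        counts_path = out / "recurrent_terms.tsv"
        counts.rename("count").to_frame().to_csv(counts_path, sep="\t")
        frac_path = out / "feature_fractions.tsv"
        fractions.to_csv(frac_path, sep="\t", float_format="%.4g")
        comp_path = out / "group_comparison.tsv"
        comparison.table.to_csv(comp_path, sep="\t", float_format="%.5g")
        verdict_path = out / "comparison_verdict.json"
        verdict_path.write_text(json.dumps({
            "no_significant_differences": comparison.no_significant_differences,
            "alpha": comparison.alpha,
            "skipped_terms": comparison.skipped,
        }, indent=1))
        heat_path = out / "phenotype_heatmap.png"
        plot_phenotype_heatmap(m, counts, heat_path)
        manifest["stages"]["phenotypes"] = {
            p.name: _sha256(p)
            for p in [counts_path, frac_path, comp_path, verdict_path,
                      heat_path]}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    _log("done", f"outputs in {out}")
    return manifest
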