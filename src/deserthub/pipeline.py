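"""End-to-end orchestration of the condition-comparison analysis.

One configuration drives: locus simulation per condition, viewpoint
profiles and their subtraction, contact matrices (bin / filter / balance),
matrix subtraction, insulation and boundary calls, binomial interaction
calls, the enhancer catalog, and motif scanning.  Outputs are plain-text
(BED / bedGraph / TSV / narrowPeak); a JSON manifest records every file
with a checksum plus the full parameter and seed echo, and re-running an
identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import GenomicInterval
from .io import (
    write_bed,
    write_bedgraph,
    write_bedpe,
    write_expression_table,
    write_fasta,
    write_fragment_bed,
    write_narrowpeak,
)
from .catalog import build_catalog, catalog_to_frame
from .contacts import (
    balance_matrix,
    bin_pairs,
    filter_bins,
    insulation_and_boundaries,
    subtract_matrices,
    write_matrix,
)
from .interactions import call_interactions, calls_to_regions
from .motifs import (
    PWM,
    annotate_conservation,
    filter_expressed_tfs,
    hits_to_frame,
    prune_contained_motifs,
    scan_sequence,
    write_meme,
)
from .simulate import (
    PROMOTER_VIEWPOINT,
    default_locus_model,
    default_peak_landscape_model,
    default_tss,
    simulate_conservation_track,
    simulate_expression,
    simulate_fragment_map,
    simulate_pairs,
    simulate_peak_landscape,
    simulate_sequence_with_motifs,
)
from .v4c import profile_to_bedgraph, subtract_profiles, viewpoint_profile

__all__ = ["RunConfig", "StageError", "run_pipeline"]

_STAGES = ("simulate", "v4c", "matrix", "interactions", "catalog", "motifs")


class StageError(RuntimeError):
    """A stage cannot run; the message names the stage."""


@dataclass
class RunConfig:
    outdir: str = "deserthub_run"
    seed: int = 0
    conditions: tuple[str, ...] = ("heart", "limb")
    n_pairs: int = 200_000
    mean_fragment_len: int = 256
    v4c_binsize: int = 3_000
    v4c_window_bins: int = 3
    v4c_exclusion: int = 5_000
    matrix_binsize: int = 5_000
    min_window: int = 50_000
    q_threshold: float = 0.1
    call_binsize: int = 10_000
    stitch_gap: int = 1_000
    tss_radius: int = 2_500
    min_fpkm: float = 2.0
    motif_p_cutoff: float = 1e-4
    stages: dict = field(
        default_factory=lambda: {name: True for name in _STAGES}
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            if key == "stages":
                cfg.stages.update(value)
            elif key == "conditions":
                cfg.conditions = tuple(value)
            else:
                setattr(cfg, key, type(getattr(cfg, key))(value))
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _check_inputs(cfg: RunConfig, outdir: Path) -> None:
    """Fail before any computation if an enabled stage lacks its inputs."""
    on = cfg.stages
    produces_pairs = on.get("simulate", False)
    for stage in ("v4c", "matrix", "interactions"):
        if on.get(stage, False) and not produces_pairs:
            missing = [
                str(outdir / f"pairs_{c}.bedpe")
                for c in cfg.conditions
                if not (outdir / f"pairs_{c}.bedpe").exists()
            ]
            if missing:
                raise StageError(
                    f"stage '{stage}': missing input pair files "
                    f"{missing} and the simulate stage is disabled"
                )
    if on.get("catalog", False) and not on.get("simulate", False):
        raise StageError(
            "stage 'catalog': requires the simulate stage for peak landscapes"
        )
    if on.get("motifs", False) and not on.get("simulate", False):
        raise StageError(
            "stage 'motifs': requires the simulate stage for sequence inputs"
        )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages; return (and write) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_inputs(cfg, outdir)
    manifest: dict = {
        "version": __version__,
        "config": {**asdict(cfg), "conditions": list(cfg.conditions)},
        "seeds": {"root": cfg.seed},
        "stages": {},
        "files": {},
        "log": [],
    }
    files: dict[str, Path] = {}

    def _log(msg: str) -> None:
        manifest["log"].append(msg)

    model = default_locus_model(seed=cfg.seed, n_pairs=cfg.n_pairs)
    fragmap = simulate_fragment_map(
        model.region, cfg.mean_fragment_len, seed=cfg.seed
    )
    pairs_by_condition = {}

    if cfg.stages.get("simulate", False):
        write_fragment_bed(outdir / "fragments.bed", fragmap)
        files["fragments.bed"] = outdir / "fragments.bed"
        truth = [model.tad, *model.subdomains] + (
            [model.hcd] if model.hcd else []
        )
        write_bed(outdir / "truth_domains.bed", truth)
        files["truth_domains.bed"] = outdir / "truth_domains.bed"
        for cond in cfg.conditions:
            pairs = simulate_pairs(model, cond)
            pairs_by_condition[cond] = pairs
            path = outdir / f"pairs_{cond}.bedpe"
            write_bedpe(path, pairs)
            files[f"pairs_{cond}.bedpe"] = path
            _log(f"simulate: {len(pairs)} pairs for condition {cond}")
        manifest["stages"]["simulate"] = {
            "n_pairs": cfg.n_pairs,
            "n_fragments": fragmap.n_fragments,
        }

    needs_pairs = any(
        cfg.stages.get(s, False) for s in ("v4c", "matrix", "interactions")
    )
    if needs_pairs and not pairs_by_condition:
        from .io import read_bedpe

        for cond in cfg.conditions:
            pairs_by_condition[cond] = read_bedpe(outdir / f"pairs_{cond}.bedpe")

    viewpoint = PROMOTER_VIEWPOINT
    if cfg.stages.get("v4c", False):
        profiles = {}
        for cond in cfg.conditions:
            prof = viewpoint_profile(
                pairs_by_condition[cond],
                fragmap,
                viewpoint,
                binsize=cfg.v4c_binsize,
                window_bins=cfg.v4c_window_bins,
                exclusion=cfg.v4c_exclusion,
            )
            profiles[cond] = prof
            path = outdir / f"v4c_{cond}.bedgraph"
            write_bedgraph(path, profile_to_bedgraph(prof))
            files[f"v4c_{cond}.bedgraph"] = path
        for a in cfg.conditions:
            for b in cfg.conditions:
                if a < b:
                    sub = subtract_profiles(profiles[a], profiles[b])
                    path = outdir / f"v4c_sub_{a}_minus_{b}.bedgraph"
                    write_bedgraph(path, profile_to_bedgraph(sub))
                    files[path.name] = path
        manifest["stages"]["v4c"] = {
            "viewpoint": str(viewpoint),
            "binsize": cfg.v4c_binsize,
        }
        _log(f"v4c: profiles for {len(profiles)} conditions")

    balanced = {}
    if cfg.stages.get("matrix", False):
        for cond in cfg.conditions:
            raw = bin_pairs(
                pairs_by_condition[cond], model.region, cfg.matrix_binsize
            )
            masked = filter_bins(raw)
            bal = balance_matrix(masked)
            balanced[cond] = bal
            write_matrix(
                outdir / f"bins_{cond}.tsv",
                outdir / f"matrix_{cond}.tsv",
                bal,
            )
            files[f"bins_{cond}.tsv"] = outdir / f"bins_{cond}.tsv"
            files[f"matrix_{cond}.tsv"] = outdir / f"matrix_{cond}.tsv"
            ins = insulation_and_boundaries(bal, min_window=cfg.min_window)
            edges = bal.bin_edges()
            finite = np.isfinite(ins.tad_separation)
            from .io import BedGraph

            track = BedGraph(
                model.region.chrom,
                edges[:-1][finite],
                edges[1:][finite],
                ins.tad_separation[finite],
            )
            path = outdir / f"tad_separation_{cond}.bedgraph"
            write_bedgraph(path, track)
            files[path.name] = path
            called = ins.called()
            write_bed(
                outdir / f"boundaries_{cond}.bed",
                [
                    GenomicInterval(
                        b.interval.chrom,
                        b.interval.start,
                        b.interval.end,
                        name=b.cls,
                    )
                    for b in called
                ],
                scores=[round(-np.log10(max(b.pvalue, 1e-300)), 3) for b in called],
            )
            files[f"boundaries_{cond}.bed"] = outdir / f"boundaries_{cond}.bed"
            _log(
                f"matrix: {cond}: {int((~bal.mask).sum())} bins masked, "
                f"{len(called)} boundaries called"
            )
        for a in cfg.conditions:
            for b in cfg.conditions:
                if a < b:
                    diff = subtract_matrices(balanced[a], balanced[b])
                    write_matrix(
                        outdir / f"bins_diff_{a}_minus_{b}.tsv",
                        outdir / f"matrix_diff_{a}_minus_{b}.tsv",
                        diff,
                    )
                    files[f"matrix_diff_{a}_minus_{b}.tsv"] = (
                        outdir / f"matrix_diff_{a}_minus_{b}.tsv"
                    )
        manifest["stages"]["matrix"] = {"binsize": cfg.matrix_binsize}

    if cfg.stages.get("interactions", False):
        for cond in cfg.conditions:
            raw = bin_pairs(
                pairs_by_condition[cond], model.region, cfg.call_binsize
            )
            calls = call_interactions(raw, q_threshold=cfg.q_threshold)
            path = outdir / f"interactions_{cond}.tsv"
            with open(path, "w") as fh:
                fh.write("bin_i\tbin_j\tobserved\texpected_p\tpvalue\tqvalue\n")
                for c in calls:
                    fh.write(
                        f"{c.bin_i}\t{c.bin_j}\t{c.observed}\t"
                        f"{c.expected_p:.6g}\t{c.pvalue:.6g}\t{c.qvalue:.6g}\n"
                    )
            files[path.name] = path
            regions = calls_to_regions(calls, viewpoint)
            write_bed(outdir / f"contacting_regions_{cond}.bed", regions)
            files[f"contacting_regions_{cond}.bed"] = (
                outdir / f"contacting_regions_{cond}.bed"
            )
            _log(f"interactions: {cond}: {len(calls)} calls at q<{cfg.q_threshold}")
        manifest["stages"]["interactions"] = {
            "q_threshold": cfg.q_threshold,
            "binsize": cfg.call_binsize,
        }

    if cfg.stages.get("catalog", False):
        landscape_model = default_peak_landscape_model(seed=cfg.seed)
        landscape = simulate_peak_landscape(landscape_model)
        for combo, peaks in landscape.peaks.items():
            if peaks:
                path = outdir / f"peaks_{combo}.narrowPeak"
                write_narrowpeak(path, sorted(peaks))
                files[path.name] = path
        tss = default_tss()
        write_bed(outdir / "tss.bed", tss)
        files["tss.bed"] = outdir / "tss.bed"
        regions = build_catalog(
            landscape.peaks,
            tss,
            signal_by_combo=landscape.signal,
            stitch_gap=cfg.stitch_gap,
            tss_radius=cfg.tss_radius,
        )
        frame = catalog_to_frame(regions, landscape_model.combos)
        path = outdir / "catalog.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        files["catalog.tsv"] = path
        distal = [r.interval for r in regions if r.tss_distal]
        write_bed(outdir / "catalog_distal.bed", distal)
        files["catalog_distal.bed"] = outdir / "catalog_distal.bed"
        _log(
            f"catalog: {len(regions)} regions stitched, {len(distal)} TSS-distal"
        )
        manifest["stages"]["catalog"] = {
            "n_regions": len(regions),
            "n_distal": len(distal),
        }

    if cfg.stages.get("motifs", False):
        tbx = PWM(
            "TBX_core",
            "Tbx5",
            np.array(
                [
                    [0.05, 0.9, 0.05, 0.05, 0.05, 0.05, 0.9, 0.05],
                    [0.05, 0.03, 0.05, 0.05, 0.85, 0.05, 0.03, 0.05],
                    [0.85, 0.04, 0.85, 0.05, 0.05, 0.05, 0.04, 0.05],
                    [0.05, 0.03, 0.05, 0.85, 0.05, 0.85, 0.03, 0.85],
                ]
            ),
        )
        nkx = PWM(
            "NKX_core",
            "Nkx2-5",
            np.array(
                [
                    [0.1, 0.8, 0.05, 0.05, 0.8, 0.1],
                    [0.1, 0.05, 0.05, 0.05, 0.05, 0.1],
                    [0.1, 0.05, 0.05, 0.85, 0.05, 0.1],
                    [0.7, 0.1, 0.85, 0.05, 0.1, 0.7],
                ]
            ),
        )
        pwms = [tbx, nkx]
        write_meme(outdir / "motifs.meme", pwms)
        files["motifs.meme"] = outdir / "motifs.meme"
        seq, truth = simulate_sequence_with_motifs(
            20_000,
            gc=0.45,
            plants=[(tbx, 6_000, "+"), (tbx, 12_000, "-")],
            seed=cfg.seed,
            name="enhancer_core",
        )
        write_fasta(outdir / "enhancer_core.fa", {"enhancer_core": seq})
        files["enhancer_core.fa"] = outdir / "enhancer_core.fa"
        cons = simulate_conservation_track(
            "enhancer_core",
            GenomicInterval("enhancer_core", 0, 20_000),
            [
                GenomicInterval("enhancer_core", t["start"], t["end"])
                for t in truth
            ],
        )
        write_bedgraph(outdir / "conservation.bedgraph", cons)
        files["conservation.bedgraph"] = outdir / "conservation.bedgraph"
        expression = simulate_expression(
            ["Tbx5", "Nkx2-5", "Isl1"], expressed={"Tbx5"}, seed=cfg.seed
        )
        write_expression_table(outdir / "expression.tsv", expression)
        files["expression.tsv"] = outdir / "expression.tsv"
        kept = filter_expressed_tfs(pwms, expression, min_fpkm=cfg.min_fpkm)
        hits = scan_sequence(
            seq, kept, p_cutoff=cfg.motif_p_cutoff, chrom="enhancer_core"
        )
        hits = annotate_conservation(prune_contained_motifs(hits), cons)
        frame = hits_to_frame(hits)
        path = outdir / "motif_hits.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        files["motif_hits.tsv"] = path
        _log(
            f"motifs: {len(kept)}/{len(pwms)} PWMs expressed, "
            f"{len(hits)} hits reported"
        )
        manifest["stages"]["motifs"] = {
            "n_pwms_kept": len(kept),
            "n_hits": len(hits),
        }

    manifest["files"] = {
        name: _sha256(path) for name, path in sorted(files.items())
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
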