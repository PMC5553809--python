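"""End-to-end pipeline orchestration and the run manifest.

Stages: read prep -> anchoring -> scaling/window/ratio tracks -> peak and
unbound-region calling (per experiment) -> replicate combination -> repeat
scan -> overlap enrichment.  Every threshold is echoed verbatim into a
machine-readable manifest together with input checksums, so a rerun with the
same config and seed is byte-identical.
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

from . import __version__
from .anchoring import anchor_reads, build_index
from .enrichment import fold_enrichment, repeat_enrichment
from .genome import Genome
from .intervals import IntervalSet
from .peaks import (PeakCallParams, call_peaks, call_unbound,
                    combine_experiments, merge_regions, peak_report)
from .read_prep import ReadLibrary, quality_filter, trim_to_center
from .repeats import scan_repeats
from .simulate import (PlantedRepeat, PlantedSite, SyntheticSpec, make_genome,
                       simulate_reads)
from .tracks import ratio_track, scale_normalize, window_counts
from .anchoring import AnchorProfile


@dataclass
class ExperimentInput:
    id: str
    control_fastq: str = ""
    ip_fastq: str = ""


@dataclass
class PipelineConfig:
    outdir: str = "occupeak_out"
    genome_fasta: str = ""
    circular: bool = True
    experiments: list[ExperimentInput] = field(default_factory=list)
    simulate: SyntheticSpec | None = None
    q_min: int = 20
    read_length: int = 50
    trim: float = 0.02
    w: int = 35
    pseudocount: float = 1.0
    policy: str = "all-occurrences"
    r_min: float = 1.5
    min_frac: float = 0.5
    min_len: int = 60
    merge_gap: int = 30
    merge_max_r: float = 1.1
    ur_max_r: float = 1.0
    merge_peaks: bool = False
    repeat_types: list[str] = field(default_factory=lambda: ["inverted"])
    repeat_i_range: list[int] | None = None
    repeat_j_range: list[int] | None = None
    maximality: str = "none"
    overlap_convention: str = "multiplicity"
    exclusion_beds: list[str] = field(default_factory=list)
    external_beds: list[str] = field(default_factory=list)

    def peak_params(self) -> PeakCallParams:
        return PeakCallParams(
            r_min=self.r_min, min_frac=self.min_frac, min_len=self.min_len,
            merge_gap=self.merge_gap, merge_max_r=self.merge_max_r,
            ur_max_r=self.ur_max_r, w=self.w,
        )

    def validate(self) -> None:
        self.peak_params()  # raises on inconsistent thresholds
        if not self.experiments and self.simulate is None:
            raise ValueError("config needs either experiments or a simulate block")
        if self.simulate is None and not self.genome_fasta:
            raise ValueError("genome_fasta required unless simulating")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "experiments" in data:
            data["experiments"] = [
                ExperimentInput(**e) if isinstance(e, dict) else e
                for e in data["experiments"]
            ]
        if data.get("simulate") is not None and isinstance(data["simulate"], dict):
            sim = dict(data["simulate"])
            sim["planted_repeats"] = [
                PlantedRepeat(**r) for r in sim.get("planted_repeats", [])
            ]
            sim["planted_sites"] = [
                PlantedSite(**s) for s in sim.get("planted_sites", [])
            ]
            if sim.get("gradient") is not None:
                sim["gradient"] = tuple(sim["gradient"])
            if "fragment_range" in sim:
                sim["fragment_range"] = tuple(sim["fragment_range"])
            data["simulate"] = SyntheticSpec(**sim)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _log(msg: str) -> None:
    print(f"[occupeak {time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _prep_and_anchor(
    lib: ReadLibrary, cfg: PipelineConfig, index, tallies: dict
) -> AnchorProfile:
    filtered, qrep = quality_filter(lib, cfg.q_min)
    trimmed, trep = trim_to_center(filtered, cfg.read_length)
    profile = anchor_reads(trimmed, index, policy=cfg.policy)
    tallies.update(
        q_retained=qrep.retained, q_discarded=qrep.discarded,
        trim_retained=trep.retained, trim_discarded=trep.discarded,
        n_anchored=profile.n_anchored, n_unanchored=profile.n_unanchored,
        n_multi=profile.n_multi,
    )
    return profile


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.peak_params()
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items()
            if not isinstance(v, (list, dict)) or k in
            ("repeat_types", "repeat_i_range", "repeat_j_range")
        },
        "stages": [],
        "inputs": {},
    }

    # --- inputs / simulation ---------------------------------------------
    truth = None
    libraries: list[tuple[str, ReadLibrary, ReadLibrary]] = []
    if cfg.simulate is not None:
        _log("stage simulate: generating genome and libraries")
        genome, truth = make_genome(cfg.simulate)
        ctrl, ip = simulate_reads(genome, truth, cfg.simulate)
        genome.to_fasta(out / "genome.fasta")
        truth.site_intervals(len(genome)).to_bed(out / "truth_sites.bed")
        (out / "truth_factors.tsv").write_text(truth.factors_tsv())
        libraries.append(("sim", ctrl, ip))
        manifest["stages"].append("simulate")
    else:
        genome = Genome.from_fasta(cfg.genome_fasta, circular=cfg.circular)
        manifest["inputs"][cfg.genome_fasta] = _sha256(Path(cfg.genome_fasta))
        for exp in cfg.experiments:
            ctrl = ReadLibrary.from_fastq(exp.control_fastq, "control", exp.id)
            ip = ReadLibrary.from_fastq(exp.ip_fastq, "ip", exp.id)
            for p in (exp.control_fastq, exp.ip_fastq):
                manifest["inputs"][p] = _sha256(Path(p))
            libraries.append((exp.id, ctrl, ip))

    # --- per-experiment tracks and calls ---------------------------------
    index = build_index(genome, cfg.read_length)
    manifest["stages"].append("index")
    tracks = {}
    peak_sets = {}
    for exp_id, ctrl, ip in libraries:
        _log(f"stage prep+anchor: experiment {exp_id}")
        tallies_c: dict = {}
        tallies_i: dict = {}
        ctrl_prof = _prep_and_anchor(ctrl, cfg, index, tallies_c)
        ip_prof = _prep_and_anchor(ip, cfg, index, tallies_i)
        manifest[f"tallies_{exp_id}"] = {"control": tallies_c, "ip": tallies_i}
        _log(f"stage tracks: experiment {exp_id}")
        ip_scaled, ctrl_scaled, scaling = scale_normalize(ip_prof, ctrl_prof, cfg.trim)
        (out / f"scaling_{exp_id}.tsv").write_text(scaling.to_tsv())
        ipw = window_counts(ip_scaled, cfg.w, circular=genome.circular,
                            genome_id=genome.id)
        ctw = window_counts(ctrl_scaled, cfg.w, circular=genome.circular,
                            genome_id=genome.id)
        rt = ratio_track(ipw, ctw, cfg.pseudocount, experiment=exp_id)
        rt.to_bedgraph(out / f"ratio_{exp_id}.bedgraph")
        tracks[exp_id] = rt
        _log(f"stage callpeaks: experiment {exp_id}")
        pk = call_peaks(rt, params)
        if cfg.merge_peaks:
            pk = merge_regions(pk, rt, params.merge_gap, params.merge_max_r)
        pk.to_bed(out / f"peaks_{exp_id}.bed", name="peak")
        (out / f"peaks_{exp_id}.tsv").write_text(peak_report(pk, rt, params))
        peak_sets[exp_id] = pk
    manifest["stages"] += ["prep", "anchor", "tracks", "callpeaks"]

    # --- replicate combination -------------------------------------------
    exclusions = [
        IntervalSet.from_bed(p, genome_length=len(genome), label=Path(p).stem)
        for p in cfg.exclusion_beds
    ]
    for p in cfg.exclusion_beds:
        manifest["inputs"][p] = _sha256(Path(p))
    exp_ids = [e[0] for e in libraries]
    if len(exp_ids) >= 2:
        rt1, rt2 = tracks[exp_ids[0]], tracks[exp_ids[1]]
        ur = call_unbound(rt1, rt2, exclusions, params)
        # merging across gaps must respect the <=1.1 ceiling in both tracks
        ur = merge_regions(
            ur,
            dataclasses.replace(rt1, r=np.maximum(rt1.r, rt2.r)),
            params.merge_gap, params.merge_max_r,
        )
        cs = combine_experiments(peak_sets[exp_ids[1]], ur)
        target = cs
    else:
        rt = tracks[exp_ids[0]]
        ur = call_unbound(rt, rt, exclusions, params)
        ur = merge_regions(ur, rt, params.merge_gap, params.merge_max_r)
        target = peak_sets[exp_ids[0]]
        target.label = "CS"
    ur.to_bed(out / "unbound.bed", name="UR")
    target.to_bed(out / "combined_set.bed", name="CS")
    manifest["stages"].append("combine")
    manifest["n_peaks"] = {k: len(v) for k, v in peak_sets.items()}
    manifest["n_unbound"] = len(ur)
    manifest["n_combined"] = len(target)

    # --- truth recall ------------------------------------------------------
    if truth is not None and truth.sites:
        sites = truth.site_intervals(len(genome))
        recovered = int(target.contains_points(sites.midpoints()).sum())
        manifest["truth_recall"] = {
            "n_planted": len(sites),
            "n_recovered_midpoint": recovered,
            "recall": recovered / len(sites),
        }
        (out / "truth_recall.tsv").write_text(
            "n_planted\tn_recovered\trecall\n"
            f"{len(sites)}\t{recovered}\t{recovered / len(sites):.4f}\n"
        )

    # --- repeats and enrichment -------------------------------------------
    _log("stage repeats")
    enrich_rows = []
    for rtype in cfg.repeat_types:
        cat = scan_repeats(genome, rtype, cfg.repeat_i_range, cfg.repeat_j_range,
                           maximality=cfg.maximality)
        (out / f"repeats_{rtype}.tsv").write_text(cat.summary_tsv())
        for (t, i, j) in sorted(cat.positions):
            res = repeat_enrichment(cat, t, i, j, target,
                                    convention=cfg.overlap_convention)
            enrich_rows.append(res.to_tsv_row())
    _log("stage enrich")
    for p in cfg.external_beds:
        ext = IntervalSet.from_bed(p, genome_length=len(genome), label=Path(p).stem)
        manifest["inputs"][p] = _sha256(Path(p))
        enrich_rows.append(fold_enrichment(ext, target, len(genome)).to_tsv_row())
    (out / "enrichment.tsv").write_text(
        "element\ttarget\tobserved\texpected\tk\tconvention\n"
        + "\n".join(enrich_rows) + ("\n" if enrich_rows else "")
    )
    manifest["stages"] += ["repeats", "enrich"]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    _log("pipeline complete")
    return manifest
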