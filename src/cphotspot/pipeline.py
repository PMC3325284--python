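"""End-to-end orchestration: (simulate|load) -> separate inversions ->
sliding-window scan -> hotspot loci -> cross-genus intersection -> primer
design, as one configured, logged, reproducible run.

Every run directory contains the resolved configuration, per-genus profile
and locus tables, the shared-locus matrix with its cumulative retention
breakdown, primer tables, and a machine-readable manifest with per-stage
row counts.  Rerunning with an identical configuration reproduces
byte-identical outputs (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .crossgenus import (
    intersect_loci,
    rank_loci,
    retain_shared,
    write_breakdown_json,
)
from .hotspots import find_hotspot_loci, write_loci_bed, write_loci_tsv
from .io_formats import (
    FeatureTable,
    GenusAlignment,
    apply_inversions,
    read_features,
    read_genus_alignment,
    read_inversions,
    write_features,
    write_genus_alignment,
    write_inversions,
)
from .primers import PrimerConstraints, design_primers, primer_table
from .scan import scan_windows
from .simulate import SimConfig, simulate_study

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass(frozen=True)
class GenusInput:
    genus: str
    fasta: str
    gff: str
    reference_id: Optional[str] = None
    inversions: Optional[str] = None


@dataclass(frozen=True)
class SimulateSpec:
    n_genera: int = 3
    private_hotspot_count: int = 0
    config: SimConfig = field(default_factory=SimConfig)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a discovery run; defaults follow the study
    design: 600 bp windows, 50 bp steps, S > mean + 2*stdev, retention in
    at least 3 genera."""

    window: int = 600
    step: int = 50
    policy: str = "complete"
    k: float = 2.0
    max_gap: Optional[int] = None  # None -> step
    min_genera: int = 3
    primer_constraints: PrimerConstraints = field(
        default_factory=PrimerConstraints
    )
    seed: int = 0
    inputs: tuple[GenusInput, ...] = ()
    simulate: Optional[SimulateSpec] = None

    def __post_init__(self) -> None:
        if self.window < 1 or not 1 <= self.step <= self.window:
            raise ValueError("need window >= 1 and 1 <= step <= window")
        if self.k < 0 or self.min_genera < 1:
            raise ValueError("need k >= 0 and min_genera >= 1")
        if not self.inputs and self.simulate is None:
            raise ValueError("configure either inputs or simulate")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inputs"] = [dataclasses.asdict(gi) for gi in self.inputs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "primer_constraints" in d and isinstance(d["primer_constraints"], dict):
            d["primer_constraints"] = PrimerConstraints(**d["primer_constraints"])
        if d.get("simulate") is not None and isinstance(d["simulate"], dict):
            sim = dict(d["simulate"])
            if isinstance(sim.get("config"), dict):
                sim["config"] = SimConfig(**sim["config"])
            d["simulate"] = SimulateSpec(**sim)
        d["inputs"] = tuple(
            GenusInput(**gi) if isinstance(gi, dict) else gi
            for gi in d.get("inputs", ())
        )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _load_genera(
    config: RunConfig,
) -> dict[str, tuple[GenusAlignment, FeatureTable]]:
    """Stage 1: obtain per-genus alignments with inversions separated."""
    genera: dict[str, tuple[GenusAlignment, FeatureTable]] = {}
    if config.simulate is not None:
        spec = config.simulate
        study = simulate_study(
            spec.config,
            n_genera=spec.n_genera,
            seed=config.seed,
            private_hotspot_count=spec.private_hotspot_count,
        )
        for label, (aln, features, truth) in study.items():
            aln, n_inv = apply_inversions(aln, truth.inversions)
            if n_inv:
                log.info("%s: separated %d simulated inversion(s)", label, n_inv)
            genera[label] = (aln, features)
    for gi in config.inputs:
        aln = read_genus_alignment(gi.fasta, gi.genus, gi.reference_id)
        features = read_features(gi.gff)
        if gi.inversions:
            inv = read_inversions(gi.inversions)
            aln, n_inv = apply_inversions(aln, inv)
            log.info("%s: separated %d declared inversion(s)", gi.genus, n_inv)
        genera[gi.genus] = (aln, features)
    return genera


def run_discovery(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full discovery pipeline into ``out_dir``; returns it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "_INCOMPLETE"
    marker.write_text("run in progress or aborted\n")
    config.to_yaml(out / "config.yaml")
    counts: dict[str, dict[str, int]] = {}

    stage = "load"
    try:
        genera = _load_genera(config)
        counts["load"] = {g: aln.n_sequences for g, (aln, _f) in genera.items()}

        stage = "scan"
        profiles = {}
        for genus, (aln, _features) in genera.items():
            profile = scan_windows(
                aln, window=config.window, step=config.step, policy=config.policy
            )
            profile.write_tsv(out / f"{genus}.profile.tsv")
            write_genus_alignment(aln, out / f"{genus}.aln.fasta")
            profiles[genus] = profile
        counts["scan"] = {g: len(p.windows) for g, p in profiles.items()}

        stage = "hotspots"
        loci_by_genus = {}
        for genus, (aln, features) in genera.items():
            loci = find_hotspot_loci(
                profiles[genus], aln, features, k=config.k,
                max_gap=config.max_gap,
            )
            write_loci_tsv(loci, out / f"{genus}.loci.tsv")
            write_loci_bed(loci, out / f"{genus}.loci.bed", chrom=genus)
            write_features(features, out / f"{genus}.gff3", seqid=genus)
            loci_by_genus[genus] = loci
        counts["hotspots"] = {g: len(l) for g, l in loci_by_genus.items()}

        stage = "crossgenus"
        table = intersect_loci(loci_by_genus, min_genera=config.min_genera)
        table.write_tsv(out / "shared_loci.tsv")
        write_breakdown_json(table, out / "breakdown.json")
        retained = retain_shared(table, m=config.min_genera)
        ranking = rank_loci(retained)
        ranking.to_csv(out / "ranked_loci.tsv", sep="\t", index=False)
        counts["crossgenus"] = {
            "loci_total": len(table),
            "loci_retained": len(retained),
        }

        stage = "primers"
        retained_names = set(retained.pi.index)
        n_pairs = {}
        frames = []
        for genus, loci in loci_by_genus.items():
            aln, _features = genera[genus]
            pairs_by_locus = {}
            for lc in loci:
                if lc.name not in retained_names:
                    continue
                pairs = design_primers(
                    aln, (lc.start, lc.end), config.primer_constraints
                )
                if pairs:
                    pairs_by_locus[lc.name] = pairs
            df = primer_table(pairs_by_locus)
            if not df.empty:
                df.insert(0, "genus", genus)
                frames.append(df)
            n_pairs[genus] = len(pairs_by_locus)
        if frames:
            import pandas as pd

            pd.concat(frames, ignore_index=True).to_csv(
                out / "primers.tsv", sep="\t", index=False
            )
        else:
            (out / "primers.tsv").write_text(
                "genus\tlocus\tprimer\tsequence_5to3\n"
            )
        counts["primers"] = n_pairs
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "tool": "cphotspot",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stage_counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    marker.unlink()
    return out
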