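"""End-to-end driver: simulate or load counts, profile, detect, master list."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .detection import (
    detect_asrt,
    genetic_mask_from_pure_strains,
    genetic_regions_from_pure_strains,
    subtract_genetic,
)
from .genome import GenomeSpec
from .io import write_bed, write_count_track, write_rt_profile
from .profiling import RTConfig, profile_counts
from .simulate import (
    SimParams,
    simulate_counts,
    simulate_pure_strain_counts,
    simulate_rt_landscape,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineResult"]


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs.

    Round-trips losslessly through YAML (:meth:`to_yaml` / :meth:`from_yaml`).
    """

    genome: GenomeSpec
    sim: SimParams = field(default_factory=SimParams)
    rt: RTConfig = field(default_factory=RTConfig)
    q_seed: float = 0.01
    q_extend: float = 0.05
    min_delta: float = 0.5
    out_dir: str = "asrt_out"
    write_outputs: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.q_seed <= self.q_extend <= 1:
            raise ValueError("need 0 < q_seed <= q_extend <= 1")
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")

    def to_dict(self) -> dict:
        d = {
            "genome": {
                "chromosomes": dict(self.genome.chromosomes),
                "window_size": self.genome.window_size,
                "snp_density": self.genome.snp_density,
            },
            "sim": dataclasses.asdict(self.sim),
            "rt": dataclasses.asdict(self.rt),
            "q_seed": self.q_seed,
            "q_extend": self.q_extend,
            "min_delta": self.min_delta,
            "out_dir": str(self.out_dir),
            "write_outputs": self.write_outputs,
        }
        d["sim"]["alleles"] = list(self.sim.alleles)
        d["sim"]["sc_mid_s_range"] = list(self.sim.sc_mid_s_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = dict(d.get("sim", {}))
        if "alleles" in sim:
            sim["alleles"] = tuple(sim["alleles"])
        if "sc_mid_s_range" in sim:
            sim["sc_mid_s_range"] = tuple(sim["sc_mid_s_range"])
        return cls(
            genome=GenomeSpec(**d["genome"]),
            sim=SimParams(**sim),
            rt=RTConfig(**d.get("rt", {})),
            q_seed=d.get("q_seed", 0.01),
            q_extend=d.get("q_extend", 0.05),
            min_delta=d.get("min_delta", 0.5),
            out_dir=d.get("out_dir", "asrt_out"),
            write_outputs=d.get("write_outputs", True),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("write_outputs", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    truth: object
    clone_tests: dict
    clone_regions: dict
    genetic_regions: pd.DataFrame
    genetic_mask: pd.DataFrame
    master: pd.DataFrame
    log: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Simulate counts, profile every clone, call regions, build the master
    list, and (optionally) write all outputs plus a provenance log."""
    stage = "simulate"
    try:
        truth = simulate_rt_landscape(config.genome, config.sim)
        counts = simulate_counts(truth)
        pure_counts = simulate_pure_strain_counts(truth)

        clone_tests, clone_regions = {}, {}
        stage = "profile/detect"
        for clone, track in counts.items():
            profile = profile_counts(track, config.rt)
            tests, regions = detect_asrt(
                profile, q_seed=config.q_seed, q_extend=config.q_extend,
                min_delta=config.min_delta)
            clone_tests[clone] = tests
            clone_regions[clone] = regions

        stage = "genetic"
        pure_profile = profile_counts(pure_counts, config.rt)
        genetic = genetic_regions_from_pure_strains(
            pure_profile, q_seed=config.q_seed, q_extend=config.q_extend,
            min_delta=config.min_delta)
        genetic_mask = genetic_mask_from_pure_strains(pure_profile)

        stage = "master"
        master = subtract_genetic(clone_regions, genetic_mask,
                                  pure_profile=pure_profile)

        log = {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.sim.seed,
            "thresholds": {"q_seed": config.q_seed,
                           "q_extend": config.q_extend,
                           "min_delta": config.min_delta},
            "n_clone_regions": {int(c): int(len(r))
                                for c, r in clone_regions.items()},
            "n_genetic_regions": int(len(genetic)),
            "n_genetic_mask": int(len(genetic_mask)),
            "n_master_regions": int(len(master)),
        }

        if config.write_outputs:
            stage = "write"
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for clone, track in counts.items():
                write_count_track(track, out / f"clone{clone}_counts.tsv")
                profile = profile_counts(track, config.rt)
                write_rt_profile(profile, out, prefix=f"clone{clone}")
                write_bed(clone_regions[clone],
                          out / f"clone{clone}_regions.bed")
            write_bed(genetic, out / "genetic_regions.bed")
            write_bed(master, out / "master_regions.bed")
            truth_bed = truth.as_regions_for_clone(0)
            truth_bed["max_abs_delta"] = config.sim.as_effect
            write_bed(truth_bed, out / "truth_as_regions.bed")
            config.to_yaml(out / "config.yaml")
            (out / "run_log.json").write_text(json.dumps(log, indent=2))
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return PipelineResult(truth=truth, clone_tests=clone_tests,
                          clone_regions=clone_regions,
                          genetic_regions=genetic, genetic_mask=genetic_mask,
                          master=master, log=log)
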