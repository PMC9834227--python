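"""Run configuration: a YAML file with one block per pipeline stage.

Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults), relative paths are resolved against the config file's
directory, and defaults are filled in so a dumped config reloads to the
same object.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

_STAGES = ("simulate", "genotype", "annotate", "mispriming", "qc", "evaluate", "lineage")

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "outdir": "dropgeno_out",
    "kit": None,  # 3p | 5p; defaults to the simulate block's kit_end
    "stages": list(_STAGES),
    "inputs": {
        "bam": None,
        "vcf": None,
        "gtf": None,
        "fasta": None,
        "counts": None,
        "cell_metadata": None,
        "mane_ids": None,
    },
    "simulate": {
        "n_cells": 300,
        "n_genes": 6,
        "kit_end": "three_prime",
        "read_length": None,
        "transcript_length_range": [800, 2500],
        "capture_decay": 0.0,
        "mispriming_rate": 0.05,
        "error_rate": 0.001,
        "mosaic_fraction": 0.05,
        "mutant_cell_types": None,
        "nb_mean_range": [0.5, 5.0],
        "nb_dispersion": 2.0,
        "umi_duplicate_rate": 0.2,
        "internal_polyA": [],  # list of [gene, tx_coord, run_length]
        "variants": [[0, 50, "somatic_candidate"]],  # [gene, tx_coord, role]
    },
    "genotype": {
        "min_mapping_quality": 30,
        "min_base_quality": 20,
        "umi_consensus": "majority",
        "call_policy": "alt_dominant",
    },
    "mispriming": {"min_run": 6, "window": 10, "min_frac": 0.8},
    "qc": {"max_pct_mito": 5.0},
    "evaluate": {
        "detect_threshold": 0.05,
        "near_threshold": 100,
        "far_threshold": 1000,
        "expr_thresholds": [0.1, 5.0],
    },
    "lineage": {"min_alt_cells_per_layer": 2, "germ_map": None},
}

_PATH_KEYS = {"bam", "vcf", "gtf", "fasta", "counts", "cell_metadata", "mane_ids", "germ_map"}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int
    outdir: Path
    kit: Optional[str]
    stages: list[str]
    inputs: dict[str, Optional[str]]
    simulate: dict[str, Any]
    genotype: dict[str, Any]
    mispriming: dict[str, Any]
    qc: dict[str, Any]
    evaluate: dict[str, Any]
    lineage: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        d = {
            "seed": self.seed,
            "outdir": str(self.outdir),
            "kit": self.kit,
            "stages": list(self.stages),
            "inputs": dict(self.inputs),
            "simulate": copy.deepcopy(self.simulate),
            "genotype": dict(self.genotype),
            "mispriming": dict(self.mispriming),
            "qc": dict(self.qc),
            "evaluate": copy.deepcopy(self.evaluate),
            "lineage": dict(self.lineage),
        }
        return d

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _merge(defaults: dict, given: dict, crumb: str) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key '{crumb}{key}'")
        if isinstance(defaults[key], dict) and key != "inputs":
            if not isinstance(value, dict):
                raise ConfigError(f"'{crumb}{key}' must be a mapping")
            out[key] = _merge(defaults[key], value, f"{crumb}{key}.")
        elif key == "inputs":
            if not isinstance(value, dict):
                raise ConfigError(f"'{crumb}{key}' must be a mapping")
            for ik in value:
                if ik not in defaults["inputs"]:
                    raise ConfigError(f"unknown configuration key '{crumb}inputs.{ik}'")
            out["inputs"] = {**defaults["inputs"], **value}
        else:
            out[key] = value
    return out


def _check_ranges(cfg: dict) -> None:
    sim = cfg["simulate"]
    for key in ("mispriming_rate", "error_rate", "mosaic_fraction"):
        if not 0.0 <= float(sim[key]) <= 1.0:
            raise ConfigError(f"'simulate.{key}' must lie in [0, 1], got {sim[key]}")
    for key in ("min_mapping_quality", "min_base_quality"):
        if int(cfg["genotype"][key]) < 0:
            raise ConfigError(f"'genotype.{key}' must be >= 0")
    if not 0.0 <= float(cfg["evaluate"]["detect_threshold"]) <= 1.0:
        raise ConfigError("'evaluate.detect_threshold' must lie in [0, 1]")
    for s in cfg["stages"]:
        if s not in _STAGES:
            raise ConfigError(f"unknown stage '{s}' (choose from {', '.join(_STAGES)})")
    if cfg["kit"] is not None and cfg["kit"] not in ("3p", "5p"):
        raise ConfigError("'kit' must be 3p or 5p")


def validate_config(path: str | Path) -> RunConfig:
    """Load, default-fill and validate a YAML run configuration.

    Missing required input paths are only an error for stages that need
    them and only when the simulate stage will not produce them.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = _merge(_DEFAULTS, raw, "")
    _check_ranges(cfg)

    base = path.parent.resolve()

    def resolve(p: Optional[str]) -> Optional[str]:
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    cfg["inputs"] = {k: resolve(v) for k, v in cfg["inputs"].items()}
    cfg["lineage"]["germ_map"] = resolve(cfg["lineage"]["germ_map"])
    outdir = Path(resolve(cfg["outdir"]))

    simulating = "simulate" in cfg["stages"]
    needed = {
        "genotype": ("bam", "vcf", "cell_metadata"),
        "annotate": ("gtf", "vcf"),
        "mispriming": ("fasta", "gtf", "vcf"),
        "qc": ("counts",),
    }
    for stage, keys in needed.items():
        if stage in cfg["stages"] and not simulating:
            for k in keys:
                if cfg["inputs"][k] is None:
                    raise ConfigError(f"stage '{stage}' requires inputs.{k}")
                if not Path(cfg["inputs"][k]).exists():
                    raise ConfigError(f"inputs.{k} does not exist: {cfg['inputs'][k]}")
    if cfg["lineage"]["germ_map"] is not None and not Path(cfg["lineage"]["germ_map"]).exists():
        raise ConfigError(f"lineage.germ_map does not exist: {cfg['lineage']['germ_map']}")

    kit = cfg["kit"]
    if kit is None:
        kit = "3p" if cfg["simulate"]["kit_end"] == "three_prime" else "5p"

    return RunConfig(
        seed=int(cfg["seed"]),
        outdir=outdir,
        kit=kit,
        stages=list(cfg["stages"]),
        inputs=cfg["inputs"],
        simulate=cfg["simulate"],
        genotype=cfg["genotype"],
        mispriming=cfg["mispriming"],
        qc=cfg["qc"],
        evaluate=cfg["evaluate"],
        lineage=cfg["lineage"],
    )


def sim_config_from_block(block: dict[str, Any], seed: int):
    """Translate the YAML simulate block into a SimConfig."""
    from .simulate import PolyASpec, SimConfig, VariantPlacement

    return SimConfig(
        n_cells=int(block["n_cells"]),
        n_genes=int(block["n_genes"]),
        kit_end=block["kit_end"],
        read_length=block["read_length"],
        transcript_length_range=tuple(block["transcript_length_range"]),
        capture_decay=float(block["capture_decay"]),
        mispriming_rate=float(block["mispriming_rate"]),
        error_rate=float(block["error_rate"]),
        mosaic_fraction=float(block["mosaic_fraction"]),
        mutant_cell_types=(
            tuple(block["mutant_cell_types"]) if block["mutant_cell_types"] else None
        ),
        nb_mean_range=tuple(block["nb_mean_range"]),
        nb_dispersion=float(block["nb_dispersion"]),
        umi_duplicate_rate=float(block["umi_duplicate_rate"]),
        internal_polyA=tuple(PolyASpec(*spec) for spec in block["internal_polyA"]),
        variants=tuple(VariantPlacement(*v) for v in block["variants"]),
        seed=seed,
    )
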