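"""Run configuration: defaults, validation, and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

__all__ = ["RunConfig", "validate_config", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    """All pipeline thresholds, with the analysis defaults.

    Thresholds: TPM expression filter 1; NMD rule fold change 1.2 /
    alpha 0.05 / 2-of-3 conditions; dependence split 1.5 (up) and 1.2
    (neutral); canonical-region RPKM filter 5; meta-exon window 100 nt with
    a 10-read gene minimum; 50-nt junction rule (strict "more than").
    """

    # inputs
    gtf: Optional[str] = None
    counts: Optional[str] = None
    de_tables: list[str] = field(default_factory=list)
    reads: Optional[str] = None
    out_dir: str = "nmdtools_out"
    seed: int = 0

    # thresholds
    tpm_threshold: float = 1.0
    nmd_fc_threshold: float = 1.2
    nmd_alpha: float = 0.05
    nmd_min_supporting: int = 2
    nmd_n_conditions: int = 3
    dependence_up_fc: float = 1.5
    dependence_neutral_fc: float = 1.2
    min_rpkm: float = 5.0
    meta_window: int = 100
    meta_min_gene_reads: int = 10
    ptc_min_distance_nt: int = 50
    ptc_min_downstream_junctions: int = 2
    ptc_strict_greater: bool = True


def validate_config(raw: dict[str, Any] | RunConfig) -> RunConfig:
    """Fill defaults and check all threshold constraints; unknown keys warn.

    Errors are collected and reported together.
    """
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            warnings.warn(f"unknown config keys ignored: {sorted(unknown)}")
        cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})

    errors: list[str] = []
    if cfg.nmd_fc_threshold <= 1:
        errors.append("nmd_fc_threshold must exceed 1")
    if not 0 < cfg.nmd_alpha < 1:
        errors.append("nmd_alpha must lie in (0, 1)")
    if cfg.nmd_min_supporting > cfg.nmd_n_conditions:
        errors.append("nmd_min_supporting exceeds nmd_n_conditions")
    if not cfg.dependence_up_fc > cfg.dependence_neutral_fc > 1:
        errors.append("require dependence_up_fc > dependence_neutral_fc > 1")
    if cfg.tpm_threshold < 0:
        errors.append("tpm_threshold must be >= 0")
    if cfg.min_rpkm < 0:
        errors.append("min_rpkm must be >= 0")
    if cfg.meta_window < 1:
        errors.append("meta_window must be >= 1")
    if cfg.ptc_min_distance_nt < 0:
        errors.append("ptc_min_distance_nt must be >= 0")
    if cfg.ptc_min_downstream_junctions < 1:
        errors.append("ptc_min_downstream_junctions must be >= 1")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return cfg


def load_config(path: Optional[str]) -> RunConfig:
    if path is None:
        return validate_config({})
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(cfg: RunConfig, out_path: str, extra: Optional[dict] = None) -> dict:
    """Record resolved config plus input checksums for reproducibility."""
    from . import __version__

    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "inputs": {},
    }
    for name in ("gtf", "counts", "reads"):
        path = getattr(cfg, name)
        if path and os.path.exists(path):
            manifest["inputs"][name] = _checksum(path)
    for path in cfg.de_tables:
        if os.path.exists(path):
            manifest["inputs"][path] = _checksum(path)
    if extra:
        manifest.update(extra)
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
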