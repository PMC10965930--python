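"""Pipeline configuration: YAML parsing, validation, defaults.

``validate_config`` parses a YAML document, checks every field against the
domain invariants, injects defaults, and either returns a complete
:class:`PipelineConfig` or raises :class:`ConfigError` listing every
violation with its path.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from .phantom import AcquisitionParams, CohortSpec, GROUPS
from .recon import ReconConfig
from .roi import STRUCTURES


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(self.errors))


@dataclass
class PipelineConfig:
    """End-to-end demo/pipeline settings (phantom -> recon -> ROI -> stats)."""

    grid: int = 48
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    n_per_group: dict = dc_field(default_factory=lambda: {"HC": 3, "MDD": 3, "SCZ": 3})
    snr: float = 50.0
    acquisition: AcquisitionParams = dc_field(default_factory=AcquisitionParams)
    recon: ReconConfig = dc_field(
        default_factory=lambda: ReconConfig(vsharp_radii_mm=(1, 3, 5, 7),
                                            lsqr_max_iter=15, pad_vox=6))
    cohort: CohortSpec = dc_field(default_factory=CohortSpec)
    posthoc_gate: float = 0.05
    seed: int = 0
    log_level: str = "INFO"


def _check(errors, condition, path, reason):
    if not condition:
        errors.append(f"{path}: {reason}")
    return condition


def validate_config(raw_text: str | None) -> PipelineConfig:
    """Parse + validate YAML text; empty input yields the full default config."""
    data = yaml.safe_load(raw_text) if raw_text else None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(["top level: expected a mapping"])

    errors: list[str] = []
    known = {"grid", "voxel_size_mm", "n_per_group", "snr", "acquisition",
             "recon", "cohort", "posthoc_gate", "seed", "log_level"}
    for key in data:
        _check(errors, key in known, key, f"unknown key (known: {sorted(known)})")

    cfg = PipelineConfig()

    if "grid" in data:
        _check(errors, isinstance(data["grid"], int) and data["grid"] >= 48,
               "grid", "must be an integer >= 48 (the 10-structure scene needs the room)")
    if "voxel_size_mm" in data:
        v = data["voxel_size_mm"]
        if _check(errors, isinstance(v, (list, tuple)) and len(v) == 3
                  and all(isinstance(x, (int, float)) and x > 0 for x in v),
                  "voxel_size_mm", "must be 3 positive numbers"):
            cfg.voxel_size_mm = tuple(float(x) for x in v)
    if "n_per_group" in data:
        npg = data["n_per_group"]
        ok = isinstance(npg, dict) and set(npg) <= set(GROUPS) \
            and all(isinstance(n, int) and n >= 2 for n in npg.values())
        _check(errors, ok, "n_per_group",
               f"must map groups {GROUPS} to integers >= 2")
    if "snr" in data:
        snr = data["snr"]
        _check(errors, isinstance(snr, (int, float)) and snr > 0,
               "snr", "must be a positive number (or omit for the default)")
    if "posthoc_gate" in data:
        g = data["posthoc_gate"]
        _check(errors, isinstance(g, (int, float)) and 0 < g <= 1,
               "posthoc_gate", "must lie in (0, 1]")
    if "seed" in data:
        _check(errors, isinstance(data["seed"], int), "seed", "must be an integer")
    if "log_level" in data:
        _check(errors, str(data["log_level"]).upper() in
               ("DEBUG", "INFO", "WARNING", "ERROR"),
               "log_level", "must be one of DEBUG/INFO/WARNING/ERROR")

    acq_kwargs = dict(data.get("acquisition") or {})
    recon_kwargs = dict(data.get("recon") or {})
    cohort_kwargs = dict(data.get("cohort") or {})

    # cohort-level overrides: group sizes, slopes, per-region moment tables
    cohort_fields = {}
    if "n_per_group" in cohort_kwargs:
        cohort_fields["n_per_group"] = cohort_kwargs.pop("n_per_group")
    if "seed" in cohort_kwargs:
        cohort_fields["seed"] = cohort_kwargs.pop("seed")
    if "slopes" in cohort_kwargs:
        slopes = {}
        for item in cohort_kwargs.pop("slopes") or []:
            region = item.get("region")
            group = item.get("group")
            if not _check(errors, region in STRUCTURES, "cohort.slopes.region",
                          f"unknown region {region!r}; valid names: {list(STRUCTURES)}"):
                continue
            if not _check(errors, group in GROUPS, "cohort.slopes.group",
                          f"unknown group {group!r}; valid: {GROUPS}"):
                continue
            slopes[(group, region)] = float(item.get("slope", 0.0))
        cohort_fields["slopes"] = slopes
    for moment_key in ("susceptibility", "volume"):
        if moment_key in cohort_kwargs:
            spec_table = cohort_kwargs.pop(moment_key) or {}
            for region in spec_table:
                _check(errors, region in STRUCTURES, f"cohort.{moment_key}.{region}",
                       f"unknown region; valid names: {list(STRUCTURES)}")
            if not errors:
                base = {r: dict(v) for r, v in
                        getattr(CohortSpec(), moment_key).items()}
                for region, per_group in spec_table.items():
                    for group, ms in per_group.items():
                        base[region][group] = tuple(ms)
                cohort_fields[moment_key] = base
    for key in cohort_kwargs:
        _check(errors, False, f"cohort.{key}", "unknown key")

    if errors:
        raise ConfigError(errors)

    try:
        cfg.acquisition = AcquisitionParams(**acq_kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"acquisition: {exc}")
    try:
        cfg.recon = ReconConfig(**{**{"vsharp_radii_mm": (1, 3, 5, 7),
                                      "lsqr_max_iter": 15, "pad_vox": 6},
                                   **recon_kwargs})
    except (TypeError, ValueError) as exc:
        errors.append(f"recon: {exc}")
    try:
        cfg.cohort = CohortSpec(**cohort_fields)
    except (TypeError, ValueError) as exc:
        errors.append(f"cohort: {exc}")
    if errors:
        raise ConfigError(errors)

    if "grid" in data:
        cfg.grid = int(data["grid"])
    if "n_per_group" in data:
        cfg.n_per_group = dict(data["n_per_group"])
    if "snr" in data:
        cfg.snr = float(data["snr"])
    if "posthoc_gate" in data:
        cfg.posthoc_gate = float(data["posthoc_gate"])
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "log_level" in data:
        cfg.log_level = str(data["log_level"]).upper()
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Echo the effective configuration (defaults injected) as plain data."""
    return {
        "grid": cfg.grid,
        "voxel_size_mm": list(cfg.voxel_size_mm),
        "n_per_group": dict(cfg.n_per_group),
        "snr": None if np.isinf(cfg.snr) else cfg.snr,
        "acquisition": {
            "te_first_ms": cfg.acquisition.te_first_ms,
            "echo_spacing_ms": cfg.acquisition.echo_spacing_ms,
            "n_echoes": cfg.acquisition.n_echoes,
            "b0_tesla": cfg.acquisition.b0_tesla,
            "flip_deg": cfg.acquisition.flip_deg,
        },
        "recon": {
            "vsharp_radii_mm": list(cfg.recon.vsharp_radii_mm),
            "deconv_threshold": cfg.recon.deconv_threshold,
            "lsqr_max_iter": cfg.recon.lsqr_max_iter,
            "lsqr_tol": cfg.recon.lsqr_tol,
            "streak_kernel_threshold": cfg.recon.streak_kernel_threshold,
            "pad_vox": cfg.recon.pad_vox,
        },
        "posthoc_gate": cfg.posthoc_gate,
        "seed": cfg.seed,
        "log_level": cfg.log_level,
    }
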