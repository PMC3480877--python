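"""Pipeline configuration: thresholds, seed, paths.

Defaults are the published analysis constants: homology acceptance at
E <= 1e-4 and identity >= 60%, paralogue floor 50%, 5% rank tolerance,
blocks of >= 2 contiguous loci, LOD grouping thresholds 4.0 (female) /
3.0 (male), 1000 permutations, chromosome-wide and FDR alpha 0.05.
``flank_bp`` (2 Mbp) controls 'proximal' candidate-gene calls and is a
package choice, logged on every use.

The on-disk format is flat ``key = value`` plain text; CLI flags override
file values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

log = logging.getLogger("synqtl")


@dataclass
class PipelineConfig:
    evalue_max: float = 1e-4
    identity_min: float = 60.0
    paralog_floor_pct: float = 50.0
    tolerance_frac: float = 0.05
    tolerance_mode: str = "relative"  # or 'absolute'
    min_block: int = 2
    max_gap: int = 0
    merge_gap: float = 0.0
    lod_female: float = 4.0
    lod_male: float = 3.0
    n_perm: int = 1000
    alpha_chrom: float = 0.05
    alpha_fdr: float = 0.05
    flank_bp: float = 2_000_000.0
    batch_size: int = 20
    seed: int = 0
    verbosity: int = 0
    paths: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if not (0 <= self.identity_min <= 100):
            raise ValueError("identity_min outside [0, 100]")
        if not (0 <= self.paralog_floor_pct <= 100):
            raise ValueError("paralog_floor_pct outside [0, 100]")
        if not (0 <= self.tolerance_frac <= 1):
            raise ValueError("tolerance_frac outside [0, 1]")
        if self.tolerance_mode not in ("relative", "absolute"):
            raise ValueError("tolerance_mode must be relative or absolute")
        if self.min_block < 1:
            raise ValueError("min_block must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.lod_female <= 0 or self.lod_male <= 0:
            raise ValueError("LOD thresholds must be positive")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        for a in (self.alpha_chrom, self.alpha_fdr):
            if not (0 < a < 1):
                raise ValueError("alpha outside (0, 1)")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}


def _coerce(name: str, raw: str) -> Any:
    default = getattr(PipelineConfig(), name)
    if isinstance(default, bool):
        return raw.strip().lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw.strip()


def read_config(path: str | Path, overrides: Optional[dict] = None) -> PipelineConfig:
    """Parse a flat key=value config file; ``overrides`` (e.g. from CLI
    flags) win over file values."""
    values: dict[str, Any] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = stripped.partition("=")
        key = key.strip()
        if key.startswith("path."):
            values.setdefault("paths", {})[key[5:]] = raw.strip()
            continue
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _coerce(key, raw)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig(**values)
    log.info("config loaded from %s (%d keys)", path, len(values))
    return cfg


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = []
    for f in dataclasses.fields(cfg):
        if f.name == "paths":
            for k, v in cfg.paths.items():
                lines.append(f"path.{k} = {v}")
            continue
        lines.append(f"{f.name} = {getattr(cfg, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n")
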