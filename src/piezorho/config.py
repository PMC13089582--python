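"""Pipeline configuration: a YAML key-value file validated into a dataclass.

Every output table written by the pipeline carries a ``#``-prefixed metadata
header (package version, config hash, seed) so runs are diffable and
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .property_partition import P_GRID


@dataclass
class PipelineConfig:
    """Validated top-level configuration for :func:`piezorho.pipeline.run_pipeline`."""

    seed: int = 0
    output_dir: str = "piezorho_out"
    verbosity: int = 1

    # evolution track
    alignment: str | None = None
    tree: str | None = None
    fg_clades: list = field(default_factory=list)
    scale: str | None = None  # path; None = packaged synthetic K0 scale
    model_kind: str = "branch"  # branch | site | both
    P_grid: list = field(default_factory=lambda: list(P_GRID))
    posterior_threshold: float = 0.95
    min_decrease: float = 0.0
    optimize_branch_lengths: bool = False
    freq_method: str = "F3X4"
    restarts: int = 3
    lineages: list = field(default_factory=list)  # dicts: name/parent/child

    # structure track
    thermo: dict = field(default_factory=dict)  # low/high condition inputs
    constants: dict = field(default_factory=dict)

    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__ if f != "raw"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known}, raw=dict(raw))
        if cfg.model_kind not in ("branch", "site", "both"):
            raise ValueError("model_kind must be branch, site or both")
        if not 0 < cfg.posterior_threshold < 1:
            raise ValueError("posterior_threshold must lie in (0, 1)")
        bad = set(cfg.P_grid) - set(P_GRID)
        if bad:
            raise ValueError(f"P grid values outside {P_GRID}: {sorted(bad)}")
        base = base_dir or Path(".")
        for attr in ("alignment", "tree", "scale"):
            value = getattr(cfg, attr)
            if value is not None:
                p = Path(value)
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FileNotFoundError(f"config {attr}: {p} does not exist")
                setattr(cfg, attr, str(p))
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def metadata_header(self) -> str:
        from . import __version__

        return (f"# piezorho {__version__}\n"
                f"# config_hash {self.config_hash()}\n"
                f"# seed {self.seed}\n")


def write_table(frame, path, config: PipelineConfig | None = None) -> None:
    """Write a delimited table with the metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.metadata_header())
        frame.to_csv(fh, sep="\t", index=False)
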