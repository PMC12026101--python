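"""Run configuration: one serializable object holding every threshold,
scoring parameter and the top-level seed.

All randomness in a run flows from ``seed``, expanded per stage/consumer by
a fixed labeling scheme (see :func:`itlsig.utils.derive_seed`), so any stage
can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigurationError


@dataclass
class RunConfig:
    # mode: "synthetic" generates all inputs; "files" reads them from disk
    mode: str = "synthetic"
    seed: int = 0
    out_dir: str = "itl_run"

    # synthetic mode: overrides forwarded to SimConfig, plus ITL planting
    sim: dict[str, Any] = field(default_factory=dict)
    plant_itl_in_mes: bool = True
    deg_n_boundary: int = 5

    # files mode
    counts_path: str | None = None
    counts_format: str = "mtx"  # "mtx" (triplet dir) or "dense" (TSV)
    signatures_gmt: str | None = None
    deg_paths: list[str] = field(default_factory=list)

    # QC and normalization
    min_features: int = 500
    min_counts: int = 500
    max_pct_mito: float = 20.0
    scale: float = 10_000.0

    # scoring
    nbins: int = 30
    ctrl: int = 100
    alpha: float = 0.75
    n_perm: int = 1000

    # derivation and detection
    padj_max: float = 0.05
    lfc_min: float = 0.0
    min_frac: float = 0.01

    # geometry / extras
    x_sign: str = "neftel"
    compute_pca: bool = False
    n_pcs: int = 20
    write_matrices: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.counts_path:
            raise ConfigurationError("files mode requires counts_path")
        if self.counts_format not in ("mtx", "dense"):
            raise ConfigurationError(f"unknown counts format {self.counts_format!r}")
        if self.deg_paths and len(self.deg_paths) < 2:
            raise ConfigurationError("need at least two DEG tables to intersect")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load from YAML; keyword overrides (CLI flags) beat file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)
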