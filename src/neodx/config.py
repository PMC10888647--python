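"""Pipeline configuration (YAML-serializable)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]

_STAGES = ("univariate", "pca", "network", "enrichment", "opls", "logistic")


@dataclass
class PipelineConfig:
    """Everything :func:`neodx.pipeline.run_pipeline` needs.

    Either ``table_path`` (a CSV/TSV concentration table) or ``scenario``
    (a synthetic scenario name, generated with ``seed``) supplies the
    input.  ``reference_group`` is the negative class; every other group
    is compared against it.  ``network_pair``/``opls_n_ortho`` control
    the rewiring and OPLS stages; ``gmt_path`` defaults to the packaged
    synthetic pathway library.
    """

    out_dir: str = "neodx_out"
    table_path: str | None = None
    scenario: str = "hie_timecourse"
    reference_group: str | None = None
    network_pair: tuple[str, str] | None = None
    gmt_path: str | None = None
    alpha_univariate: float = 0.05
    alpha_enrichment: float = 0.1
    opls_n_ortho: dict[str, int] = field(default_factory=dict)
    default_n_ortho: int = 2
    seed: int = 0
    stages: tuple[str, ...] = _STAGES

    def __post_init__(self) -> None:
        for name, a in (("alpha_univariate", self.alpha_univariate),
                        ("alpha_enrichment", self.alpha_enrichment)):
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ValueError("seed must be a nonnegative integer")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.table_path is None and not self.scenario:
            raise ValueError("either table_path or scenario is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "network_pair" in raw and raw["network_pair"] is not None:
            raw["network_pair"] = tuple(raw["network_pair"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        if self.network_pair is not None:
            d["network_pair"] = list(self.network_pair)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
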