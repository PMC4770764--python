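"""Pipeline configuration and plain-text summary reporting."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import yaml

from mirisk.diffexpr import DifferentialSummary, round_half_away
from mirisk.errors import ConfigError


def format_count(k: int, n: int) -> str:
    """Render a count as 'k/n (p%)' with one-decimal percentage."""
    pct = round_half_away(100.0 * k / n, 1)
    return f"{k}/{n} ({pct}%)"


@dataclass
class PipelineConfig:
    """Resolved settings for an end-to-end run; round-trips through YAML."""

    alpha: float = 0.05
    r_threshold: float = 0.6
    keep_fraction: float = 0.2
    min_tools: int = 6
    maxstat_bounds: tuple[float, float] = (0.1, 0.9)
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if not (0 < self.r_threshold <= 1):
            raise ConfigError("r_threshold must lie in (0, 1]")
        if not (0 < self.keep_fraction <= 1):
            raise ConfigError("keep_fraction must lie in (0, 1]")
        if self.min_tools < 0:
            raise ConfigError("min_tools must be non-negative")
        lo, hi = self.maxstat_bounds
        if not (0 < lo < hi < 1):
            raise ConfigError("maxstat_bounds must satisfy 0 < lo < hi < 1")
        self.maxstat_bounds = (float(lo), float(hi))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["maxstat_bounds"] = list(self.maxstat_bounds)
        with open(str(path), "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(str(path)) as fh:
            d = yaml.safe_load(fh) or {}
        if "maxstat_bounds" in d:
            d["maxstat_bounds"] = tuple(d["maxstat_bounds"])
        return cls(**d)


def summary_report(sections: dict[str, object]) -> str:
    """Deterministic plain-text report from named artifacts.

    Differential summaries render as 'k/n (p%)' count lines; everything else
    is stringified, dicts as sorted key: value lines.
    """
    lines: list[str] = []
    for name in sections:
        lines.append(f"== {name} ==")
        value = sections[name]
        if isinstance(value, DifferentialSummary):
            lines.append(
                f"down-regulated: {format_count(value.n_down, value.n_total)}"
            )
            lines.append(f"up-regulated: {format_count(value.n_up, value.n_total)}")
            lines.append(
                f"total significant: {format_count(value.n_signif, value.n_total)}"
            )
        elif isinstance(value, dict):
            for k in sorted(value):
                lines.append(f"{k}: {value[k]}")
        else:
            lines.append(str(value))
        lines.append("")
    return "\n".join(lines)


def write_manifest(outdir, entries: dict[str, str]) -> None:
    """Write a manifest of run artifacts; paths are stored relative to the
    run directory so reruns in different directories are byte-identical."""
    import os

    rel = {k: os.path.relpath(v, str(outdir)) for k, v in entries.items()}
    with open(os.path.join(str(outdir), "manifest.json"), "w") as fh:
        json.dump(rel, fh, indent=1, sort_keys=True)
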