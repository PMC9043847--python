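"""Run configuration: analysis thresholds, optionally loaded from YAML."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["Thresholds", "load_thresholds"]


@dataclass(frozen=True)
class Thresholds:
    """Analysis cutoffs, with the study's defaults.

    maf: rare-variant reference allele-frequency cutoff.
    hwe_alpha: exact Hardy-Weinberg screen significance level.
    p_sig: overall association significance ("flexible" cutoff).
    p_strong: strong-association cutoff (red tier).
    ne_blue: normalized testis expression required for the blue tier.
    ne_expansive: minimum NE for expansive trio candidates.
    or_blue: carrier odds ratio required for the blue tier when estimable.
    """

    maf: float = 0.01
    hwe_alpha: float = 0.05
    p_sig: float = 0.05
    p_strong: float = 1e-4
    ne_blue: float = 16.0
    ne_expansive: float = 1.0
    or_blue: float = 6.0


def load_thresholds(path: Path) -> Thresholds:
    """Load thresholds from a YAML mapping; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(Thresholds)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return Thresholds(**data)
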