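"""TOML run configuration with strict unknown-key rejection.

Silent misconfiguration (a typo'd key falling back to a default) is the main
user hazard in rule-based designers, so every key is validated against the
schema and the fully resolved configuration is echoed into output headers.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .spacer_design import DesignConfig


class ConfigError(ValueError):
    pass


@dataclass
class ArrayConfig:
    repeat_name: str = "Francisella"
    # canonical FnCas12a direct repeat (5-bp 3'-terminal processing hairpin);
    # replace with the repeat of the Cas12a ortholog actually used
    repeat_sequence: str = "AATTTCTACTGTTGTAGAT"
    energy_window: float = 2.0
    max_structures: int = 20
    strict: bool = False
    attempt_cap: int = 50
    trailing_repeat: bool = False


@dataclass
class CloningConfig:
    gibson_arm_5: str = "ATTTCTACTGTTGTAGAT"
    gibson_arm_3: str = "GTCGACCTGCAGGCATGC"
    vector_overhang_5: str = "AATG"
    vector_overhang_3: str = "GCTT"


@dataclass
class ScreenConfig:
    flank_5: str = "ATTTCTACTGTTGTAGAT"
    flank_3: str = "GTCGACCTGCAGGCATGC"
    max_flank_mismatch: int = 1
    pseudocount: float = 0.5
    log2fc_cutoff: float = 0.5
    fdr_cutoff: float = 0.05


@dataclass
class RunConfig:
    design: DesignConfig = field(default_factory=DesignConfig)
    array: ArrayConfig = field(default_factory=ArrayConfig)
    cloning: CloningConfig = field(default_factory=CloningConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    def header_lines(self, version: str) -> list[str]:
        """Resolved configuration as TSV comment lines for output headers."""
        lines = [f"# crisprikit {version}"]
        for section in fields(self):
            d = asdict(getattr(self, section.name))
            d.pop("pam", None)  # nested dataclass, printed separately
            kv = " ".join(f"{k}={v}" for k, v in d.items())
            lines.append(f"# {section.name}: {kv}")
        return lines


_SECTIONS = {
    "design": DesignConfig,
    "array": ArrayConfig,
    "cloning": CloningConfig,
    "screen": ScreenConfig,
}


def load_config(path: str | Path | None) -> RunConfig:
    """Parse a TOML config; unknown sections or keys raise ConfigError."""
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    for section, payload in data.items():
        if section not in _SECTIONS:
            raise ConfigError(f"unknown config section {section!r}")
        cls = _SECTIONS[section]
        known = {f.name for f in fields(cls)} - {"pam"}
        for key in payload:
            if key not in known:
                raise ConfigError(f"unknown key {key!r} in section [{section}]")
        current = getattr(cfg, section)
        for key, value in payload.items():
            setattr(current, key, tuple(value) if isinstance(value, list) else value)
        if section == "design":
            cfg.design.__post_init__()
    return cfg
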