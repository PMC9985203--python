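"""Run configuration: documented defaults, YAML loading, strict validation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(Exception):
    """Unknown or ill-typed configuration key."""


@dataclass
class PreprocessConfig:
    min_rel_intensity: float = 0.05  # peaks below 5% of base peak are dropped
    precursor_ppm: float = 15.0


@dataclass
class MatchThresholds:
    gnps: float = 0.85
    hmdb: float = 0.70
    massbank: float = 0.70


@dataclass
class MatchSection:
    ppm: float = 15.0
    threshold: MatchThresholds = field(default_factory=MatchThresholds)
    postfilter: float = 0.50
    mz_score_mode: str = "dice"


@dataclass
class FingerprintSection:
    radius: int = 2
    n_bits: int = 2048


@dataclass
class SelectSection:
    identity_threshold: float = 0.99
    similarity_threshold: float = 0.85
    top_n: int = 25
    fingerprint: FingerprintSection = field(default_factory=FingerprintSection)
    mcss_timeout_s: int = 5


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    match: MatchSection = field(default_factory=MatchSection)
    select: SelectSection = field(default_factory=SelectSection)
    seed: int = 42

    def match_config(self):
        from ms2derep.spectral_match import MatchConfig

        return MatchConfig(
            fragment_ppm=self.match.ppm,
            precursor_ppm=self.preprocess.precursor_ppm,
            similarity_thresholds={
                "GNPS": self.match.threshold.gnps,
                "HMDB": self.match.threshold.hmdb,
                "MassBank": self.match.threshold.massbank,
            },
            postfilter=self.match.postfilter,
            mz_score_mode=self.match.mz_score_mode,
            min_rel_intensity=self.preprocess.min_rel_intensity,
        )

    def fingerprint_config(self):
        from ms2derep.candidate_selection import FingerprintConfig

        return FingerprintConfig(
            radius=self.select.fingerprint.radius, n_bits=self.select.fingerprint.n_bits
        )

    def dump(self, path: str | Path) -> Path:
        """Serialize the effective configuration into the results directory."""
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")
        return path


def _build(cls, data: dict, prefix: str = ""):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown config key(s): {', '.join(sorted(prefix + k for k in unknown))}"
        )
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        nested = {
            "PreprocessConfig": PreprocessConfig,
            "MatchSection": MatchSection,
            "MatchThresholds": MatchThresholds,
            "SelectSection": SelectSection,
            "FingerprintSection": FingerprintSection,
        }.get(ftype)
        if nested is not None:
            if not isinstance(value, dict):
                raise ConfigError(f"config section {prefix + name!r} must be a mapping")
            kwargs[name] = _build(nested, value, prefix=f"{prefix}{name}.")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config, rejecting unknown keys; None gives the defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return _build(RunConfig, data)
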