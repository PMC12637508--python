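"""Run configuration: one flat, validated document for every stage.

Defaults follow the published pipeline constants where they exist (30-nt
search window, 19-nt read prefix, 10-TPM target expression floor, top 10%
target fraction, 21 resampling iterations); the rest are documented
artifact defaults.  Unknown keys are rejected so typos fail loudly, and the
effective configuration can be echoed next to every output for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .pairing_score import ScoreParams


class ConfigError(ValueError):
    """Unknown key or type mismatch in a configuration document."""


@dataclass(frozen=True)
class RunConfig:
    # 3'-pairing score
    match_point: float = 1.0
    end_bonus: float = 0.5
    terminal_wobble_bonus: float = 0.5
    interruption_point: float = 1.0
    offset_free: int = 3
    offset_point: float = 0.5
    window: int = 30
    three_prime_start: int = 9
    end_bonus_mode: str = "per_position"
    # trigger search
    min_tpm: float = 1.0
    energy_backend: str = "builtin"  # or "external" (RNAduplex)
    energy_tiebreak: bool = True
    # small-RNA quantification
    prefix_len: int = 19
    de_alpha: float = 0.05
    de_min_log2fc: float = 0.0
    # target repression
    target_min_tpm: float = 10.0
    top_fraction: float = 0.10
    iterations: int = 21
    # randomness
    seed: int = 0

    def score_params(self) -> ScoreParams:
        return ScoreParams(
            match_point=self.match_point,
            end_bonus=self.end_bonus,
            terminal_wobble_bonus=self.terminal_wobble_bonus,
            interruption_point=self.interruption_point,
            offset_free=self.offset_free,
            offset_point=self.offset_point,
            window=self.window,
            three_prime_start=self.three_prime_start,
            end_bonus_mode=self.end_bonus_mode,
        )

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Merge defaults <- file <- overrides, rejecting unknown keys."""
    values: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as handle:
            doc = yaml.safe_load(handle) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        values.update(doc)
    values.update(overrides or {})
    known = {f.name: f.type for f in fields(RunConfig)}
    unknown = set(values) - set(known)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    defaults = RunConfig()
    coerced = {}
    for key, val in values.items():
        default = getattr(defaults, key)
        try:
            if isinstance(default, bool):
                if not isinstance(val, bool):
                    raise TypeError("expected boolean")
                coerced[key] = val
            elif isinstance(default, int):
                if isinstance(val, float) and not float(val).is_integer():
                    raise TypeError("expected integer")
                coerced[key] = int(val)
            elif isinstance(default, float):
                coerced[key] = float(val)
            else:
                coerced[key] = type(default)(val)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"configuration key {key!r}: {exc}") from exc
    return RunConfig(**coerced)


def echo_config(config: RunConfig, path: str | Path) -> None:
    """Write the effective configuration (for reproducibility) as YAML."""
    doc = asdict(config)
    doc["_config_hash"] = config.config_hash()
    with open(path, "w", encoding="utf-8") as out:
        yaml.safe_dump(doc, out, sort_keys=True)


def digest_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
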