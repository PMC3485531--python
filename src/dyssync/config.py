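"""Run configuration shared by the CLI commands.

A config is a flat JSON file mirrorable by CLI flags; flags win over file
values.  All enumerations are validated on construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

from .errors import ValidationError

_SDI_DIVISORS = ("n_minus_1", "n")
_T_TESTS = ("student", "welch")
_CUTOFF_RULES = ("youden",)
_DIRECTIONS = ("higher_is_positive", "lower_is_positive")


@dataclass(frozen=True)
class RunConfig:
    n_samples: int = 201
    sdi_divisor: str = "n_minus_1"
    t_test: str = "student"
    cutoff_rule: str = "youden"
    directions: Mapping[str, str] = field(default_factory=dict)
    allow_partial: bool = False
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ValidationError(f"n_samples must be >= 8, got {self.n_samples}")
        if self.sdi_divisor not in _SDI_DIVISORS:
            raise ValidationError(f"sdi_divisor must be one of {_SDI_DIVISORS}")
        if self.t_test not in _T_TESTS:
            raise ValidationError(f"t_test must be one of {_T_TESTS}")
        if self.cutoff_rule not in _CUTOFF_RULES:
            raise ValidationError(f"cutoff_rule must be one of {_CUTOFF_RULES}")
        for metric, d in self.directions.items():
            if d not in _DIRECTIONS:
                raise ValidationError(
                    f"direction for {metric!r} must be one of {_DIRECTIONS}"
                )

    @classmethod
    def load(cls, path: str | Path | None, **overrides) -> "RunConfig":
        """Build from an optional JSON file; keyword overrides (CLI flags)
        take precedence.  ``None`` overrides are ignored."""
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                doc = json.load(fh)
            known = {f.name for f in fields(cls)}
            unknown = set(doc) - known
            if unknown:
                raise ValidationError(
                    f"{path}: unknown config key(s): {', '.join(sorted(unknown))}"
                )
            values.update(doc)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "sdi_divisor": self.sdi_divisor,
            "t_test": self.t_test,
            "cutoff_rule": self.cutoff_rule,
            "directions": dict(self.directions),
            "allow_partial": self.allow_partial,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }
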