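"""Run manifests: enough metadata to bit-reproduce any output file."""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .model_core import SimulationConfig

#: Analysis conventions that affect numbers and therefore travel with outputs.
_DEFAULT_CONVENTIONS = {
    "snr": "rms",
    "p_value": "one_sided_upper",
    "phase_to_signal": "sin",
    "integration": "forward_euler",
}


@dataclass
class RunManifest:
    """Snapshot of configuration, seed and conventions for one output set.

    Two runs with equal manifests (ignoring ``timestamp``) produce
    byte-identical outputs.
    """

    config: dict[str, Any]
    master_seed: int
    conventions: dict[str, Any] = field(default_factory=dict)
    extra: dict[str, Any] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        config: SimulationConfig,
        master_seed: int,
        filter_band: tuple[float, float] | None,
        edge_trim_s: float,
        **extra: Any,
    ) -> "RunManifest":
        from . import __version__

        conventions = dict(_DEFAULT_CONVENTIONS)
        conventions["frequency_mode"] = config.frequency_mode
        conventions["frequency_distribution"] = config.frequency_distribution
        conventions["filter_band_hz"] = list(filter_band) if filter_band else "none"
        conventions["edge_trim_s"] = edge_trim_s
        return cls(
            config=dataclasses.asdict(config),
            master_seed=int(master_seed),
            conventions=conventions,
            extra=dict(extra),
            version=__version__,
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def same_conventions(self, other: "RunManifest") -> bool:
        """True when two manifests describe compatible (mixable) runs."""
        return (
            self.config == other.config
            and self.master_seed == other.master_seed
            and self.conventions == other.conventions
            and self.version == other.version
        )
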