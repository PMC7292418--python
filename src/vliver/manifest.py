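"""Run manifests: enough provenance to reproduce any output bit-for-bit."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .config import VExperimentConfig


@dataclass
class RunManifest:
    config_hash: str
    resolved_config: dict
    trial_seeds: list
    software_version: str
    outputs: list = field(default_factory=list)
    created_utc: str = ""

    @classmethod
    def for_run(cls, cfg: VExperimentConfig, seeds: list[int], outputs: list[str]) -> "RunManifest":
        from . import __version__

        return cls(
            config_hash=cfg.config_hash(),
            resolved_config=cfg.to_dict(),
            trial_seeds=list(seeds),
            software_version=__version__,
            outputs=list(outputs),
            created_utc=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True, default=str))
        return path
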