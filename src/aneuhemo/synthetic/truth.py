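"""Ground-truth sidecar attached to every synthetic generator output."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class SyntheticTruth:
    """Records generator identity, parameters, seed, and planted targets."""

    generator: str
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    targets: dict[str, Any] = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        payload = {
            "generator": self.generator,
            "parameters": _jsonable(self.parameters),
            "seed": self.seed,
            "targets": _jsonable(self.targets),
        }
        return json.dumps(payload, indent=2, sort_keys=True, **kwargs)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
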