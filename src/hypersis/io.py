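"""Result serialization and run configuration."""

from __future__ import annotations

import json
from pathlib import Path

__all__ = ["write_results", "load_config"]


def write_results(obj, path: str | Path) -> Path:
    """Write a result object (FixedPointSet, SweepResult, PhaseDiagram,
    BistabilityCurve, SimTrajectory — anything with ``to_frame``) as CSV
    with deterministic column order and full float precision."""
    if not hasattr(obj, "to_frame"):
        raise TypeError(f"cannot serialize {type(obj).__name__}: no to_frame()")
    path = Path(path)
    obj.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
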