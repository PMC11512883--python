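"""Report writers and the run manifest.

Every command writes delimited tables and/or JSON summaries into an output
directory together with a :class:`RunManifest` recording the command, inputs,
seed, tool version and the files produced -- enough to reproduce the run.
The manifest is written even when the run fails partway.

Display formatting follows HTA reporting practice: euro amounts to 0
decimals, QALYs to 2, fractions to 4, with half-away-from-zero rounding for
comparisons against printed values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

__all__ = ["RunManifest", "round_half_away", "fmt_eur", "fmt_qaly", "fmt_fraction", "write_json"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed model tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def fmt_eur(x: float) -> str:
    return f"{round_half_away(x, 0):,.0f}"


def fmt_qaly(x: float) -> str:
    return f"{round_half_away(x, 2):.2f}"


def fmt_fraction(x: float) -> str:
    return f"{round_half_away(x, 4):.4f}"


def write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


@dataclass
class RunManifest:
    """Provenance record of one CLI run."""

    command: str
    config_path: Optional[str] = None
    life_table_path: Optional[str] = None
    seed: Optional[int] = None
    flags: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    status: str = "running"
    error: Optional[str] = None

    def record(self, path: Path) -> str:
        self.outputs.append(str(path))
        return str(path)

    def write(self, out_dir: Path) -> Path:
        from . import __version__

        payload = {
            "command": self.command,
            "config": self.config_path,
            "life_table": self.life_table_path,
            "seed": self.seed,
            "flags": self.flags,
            "tool_version": __version__,
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            "outputs": self.outputs,
            "status": self.status,
            "error": self.error,
        }
        path = out_dir / f"manifest_{self.command.replace(' ', '_')}.json"
        write_json(payload, path)
        return path
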