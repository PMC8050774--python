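"""Structured JSON-lines run log.

Every filtering, normalization, and aggregation decision in the pipeline is
recorded as one event so that reported counts can be audited after the fact.
Events carry no wall-clock timestamps: identical inputs must produce
byte-identical logs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any


class RunLog:
    """Append-only collector of structured log events."""

    def __init__(self) -> None:
        self.events: list[dict[str, Any]] = []

    def log(self, event: str, **fields: Any) -> None:
        rec = {"event": event}
        rec.update(fields)
        self.events.append(rec)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.events:
                fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.events)


def ensure_log(log: RunLog | None) -> RunLog:
    """Return *log* or a fresh throwaway collector."""
    return log if log is not None else RunLog()
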