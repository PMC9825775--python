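"""Structured run event log.

One line per event — scan start/end, job start/end/skip — with a monotonic
timestamp.  The log is what makes the scheduling contracts observable: the
pass count, the at-most-one-active-scan rule, and the overlap of batch i+1
extraction with batch i execution can all be read off the event sequence.
"""

from __future__ import annotations

import json
import threading
import time
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional


@dataclass(frozen=True)
class Event:
    kind: str
    t: float
    data: Dict[str, Any] = field(default_factory=dict)


class EventLog:
    """Thread-safe append-only event list with an optional JSON-lines sink."""

    def __init__(self, path: Optional[str] = None):
        self._events: List[Event] = []
        self._lock = threading.Lock()
        self._fh = open(path, "w") if path else None

    def emit(self, kind: str, **data: Any) -> Event:
        event = Event(kind=kind, t=time.monotonic(), data=data)
        with self._lock:
            self._events.append(event)
            if self._fh is not None:
                json.dump({"kind": kind, "t": event.t, **data}, self._fh)
                self._fh.write("\n")
                self._fh.flush()
        return event

    def events(self, kind: Optional[str] = None) -> List[Event]:
        with self._lock:
            if kind is None:
                return list(self._events)
            return [e for e in self._events if e.kind == kind]

    def count(self, kind: str) -> int:
        return len(self.events(kind))

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None
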