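"""Lock-based coordination of concurrent proofreaders.

Each segment (body) has a unique ID, so collaboration is coordinated by a
table of per-body exclusive locks: a client asks to lock a body before
manipulating it, and a body already locked by someone else yields a denial
rather than an exception. Mutating store operations call :meth:`Librarian.guard`
first and must leave state untouched when it raises.

Locks are held until released; there is no lease expiry. Grants are
re-entrant for the holder. The table is in-process and deliberately free of
authentication — callers are trusted to present a stable user string.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .errors import LockError, OwnershipError


@dataclass(frozen=True)
class LockResult:
    granted: bool
    holder: Optional[str] = None


class Librarian:
    """Per-body exclusive lock table with deny-on-conflict semantics."""

    def __init__(self) -> None:
        self._table: Dict[int, Tuple[str, float]] = {}

    def acquire(self, body: int, user: str) -> LockResult:
        """Grant iff unlocked or already held by ``user`` (re-entrant)."""
        held = self._table.get(body)
        if held is not None and held[0] != user:
            return LockResult(False, held[0])
        if held is None:
            self._table[body] = (user, time.time())
        return LockResult(True, user)

    def release(self, body: int, user: str) -> None:
        held = self._table.get(body)
        if held is None or held[0] != user:
            raise OwnershipError(
                f"user {user!r} does not hold the lock on body {body}"
                + (f" (held by {held[0]!r})" if held else " (unlocked)")
            )
        del self._table[body]

    def holder(self, body: int) -> Optional[str]:
        held = self._table.get(body)
        return held[0] if held else None

    def guard(self, body: int, user: str) -> None:
        """Raise :class:`LockError` unless ``user`` holds the lock on ``body``."""
        held = self._table.get(body)
        if held is None or held[0] != user:
            raise LockError(
                f"body {body} is not locked by {user!r}; refusing mutation"
            )

    def status(self) -> Dict[int, Dict[str, object]]:
        """JSON-ready dump of the lock table."""
        return {
            body: {"holder": holder, "acquired_at": ts}
            for body, (holder, ts) in sorted(self._table.items())
        }

    def to_json_dict(self) -> Dict[str, Dict[str, object]]:
        return {str(b): v for b, v in self.status().items()}

    @classmethod
    def from_json_dict(cls, d) -> "Librarian":
        lib = cls()
        for body, rec in d.items():
            lib._table[int(body)] = (rec["holder"], float(rec["acquired_at"]))
        return lib
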