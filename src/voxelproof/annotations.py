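"""Workflow metadata: statuses, bookmarks, to-dos, synapses, body tables.

Proofreading a large connectome is organized through annotations rather than
through the voxel data itself: each body carries a name and one of seven
predefined statuses; owner-private bookmarks tag interesting locations;
shared to-do marks form the team's checklist; synapses are point elements
(pre- or post-synaptic) joined by directed pre→post links.

Association between a point annotation and a body is position-based and
resolved against the current label volume at query time, so marks follow
voxels through merges and splits automatically. Body-keyed records (name,
status) are rewritten explicitly when an ID is retired by a merge; the store
fires :meth:`AnnotationStore.sync_after_relabel` through its sync hook.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .errors import BodyNotFoundError, ValidationError
from .geometry import BoundingBox, Coordinate

BODY_STATUSES = (
    "not examined",
    "traced",
    "traced in ROI",
    "partially traced",
    "orphan",
    "hard to trace",
    "finalized",
)

DEFAULT_STATUS = BODY_STATUSES[0]

TODO_STATUSES = ("to-do", "done")
TODO_ACTIONS = ("none", "to merge", "to split")
SYNAPSE_KINDS = ("pre", "post")


@dataclass
class BodyAnnotation:
    body: int
    name: str = ""
    status: str = DEFAULT_STATUS
    comment_log: List[str] = field(default_factory=list)


@dataclass(frozen=True)
class Bookmark:
    """Owner-private 3D point with a type and comment (e.g. "false merge")."""

    position: Coordinate
    type: str = ""
    comment: str = ""
    owner: str = ""


@dataclass(frozen=True)
class TodoMark:
    """Shared checklist point; action is meaningful only while status is to-do."""

    position: Coordinate
    status: str = "to-do"
    action: str = "none"

    def __post_init__(self) -> None:
        if self.status not in TODO_STATUSES:
            raise ValidationError(f"todo status must be one of {TODO_STATUSES}")
        if self.action not in TODO_ACTIONS:
            raise ValidationError(f"todo action must be one of {TODO_ACTIONS}")


@dataclass(frozen=True)
class SynapseElement:
    position: Coordinate
    kind: str
    confidence: float = 1.0
    verified: bool = False

    def __post_init__(self) -> None:
        if self.kind not in SYNAPSE_KINDS:
            raise ValidationError(f"synapse kind must be one of {SYNAPSE_KINDS}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError("confidence must lie in [0, 1]")


class AnnotationStore:
    """All annotation kinds plus query, re-association and sequencer table.

    ``label_store`` (a :class:`~voxelproof.store.VersionedLabelStore`) is
    optional; without it, body-scoped queries and the sequencer's voxel
    counts are unavailable.
    """

    def __init__(self, label_store=None) -> None:
        self.label_store = label_store
        self.body_annotations: Dict[int, BodyAnnotation] = {}
        self.bookmarks: Dict[Tuple[Coordinate, str], Bookmark] = {}
        self.todos: Dict[Coordinate, TodoMark] = {}
        self.synapses: Dict[Coordinate, SynapseElement] = {}
        self.links: Set[Tuple[Coordinate, Coordinate]] = set()
        if label_store is not None:
            label_store.add_sync_hook(self.sync_after_relabel)

    # -- body records -----------------------------------------------------

    def _record(self, body: int) -> BodyAnnotation:
        if self.label_store is not None and body not in self.label_store.bodies():
            raise BodyNotFoundError(body)
        return self.body_annotations.setdefault(body, BodyAnnotation(body))

    def set_body_status(self, body: int, status: str) -> None:
        if status not in BODY_STATUSES:
            raise ValidationError(
                f"status {status!r} is not one of the {len(BODY_STATUSES)} admissible statuses"
            )
        self._record(body).status = status

    def set_body_name(self, body: int, name: str) -> None:
        self._record(body).name = name

    def get_body_status(self, body: int) -> str:
        rec = self.body_annotations.get(body)
        return rec.status if rec else DEFAULT_STATUS

    def get_body_name(self, body: int) -> str:
        rec = self.body_annotations.get(body)
        return rec.name if rec else ""

    # -- bookmarks & todos ------------------------------------------------

    def add_bookmark(self, position: Coordinate, type: str, comment: str, owner: str) -> None:
        self.bookmarks[(position, owner)] = Bookmark(position, type, comment, owner)

    def move_bookmark(self, src: Coordinate, dst: Coordinate, owner: str) -> None:
        bm = self.bookmarks.pop((src, owner), None)
        if bm is None:
            raise ValidationError(f"no bookmark of {owner!r} at {tuple(src)}")
        self.bookmarks[(dst, owner)] = replace(bm, position=dst)

    def delete_bookmark(self, position: Coordinate, owner: str) -> None:
        if self.bookmarks.pop((position, owner), None) is None:
            raise ValidationError(f"no bookmark of {owner!r} at {tuple(position)}")

    def add_todo(self, position: Coordinate, action: str = "none") -> None:
        self.todos[position] = TodoMark(position, "to-do", action)

    def set_todo_status(self, position: Coordinate, status: str) -> None:
        mark = self.todos.get(position)
        if mark is None:
            raise ValidationError(f"no todo at {tuple(position)}")
        self.todos[position] = replace(mark, status=status)

    def move_todo(self, src: Coordinate, dst: Coordinate) -> None:
        mark = self.todos.pop(src, None)
        if mark is None:
            raise ValidationError(f"no todo at {tuple(src)}")
        self.todos[dst] = replace(mark, position=dst)

    def delete_todo(self, position: Coordinate) -> None:
        if self.todos.pop(position, None) is None:
            raise ValidationError(f"no todo at {tuple(position)}")

    def edit_point_annotation(self, kind: str, verb: str, payload: Mapping) -> None:
        """Generic dispatcher used by the CLI; methods above are the API."""
        p = dict(payload)

        def coord(key="position"):
            x, y, z = p[key]
            return Coordinate(int(x), int(y), int(z))

        if kind == "bookmark":
            if verb == "add":
                self.add_bookmark(coord(), p.get("type", ""), p.get("comment", ""), p["owner"])
            elif verb == "move":
                self.move_bookmark(coord("src"), coord("dst"), p["owner"])
            elif verb == "delete":
                self.delete_bookmark(coord(), p["owner"])
            else:
                raise ValidationError(f"unknown bookmark verb {verb!r}")
        elif kind == "todo":
            if verb == "add":
                self.add_todo(coord(), p.get("action", "none"))
            elif verb == "move":
                self.move_todo(coord("src"), coord("dst"))
            elif verb == "delete":
                self.delete_todo(coord())
            elif verb == "set-status":
                self.set_todo_status(coord(), p["status"])
            else:
                raise ValidationError(f"unknown todo verb {verb!r}")
        else:
            raise ValidationError(f"unknown annotation kind {kind!r}")

    # -- synapses ---------------------------------------------------------

    def add_synapse(
        self, position: Coordinate, kind: str, confidence: float = 1.0, verified: bool = False
    ) -> None:
        """Upsert an element; at most one element per exact coordinate.

        Replacing an element with one of a different kind drops its incident
        links (their endpoint kind contract would otherwise break).
        """
        old = self.synapses.get(position)
        if old is not None and old.kind != kind:
            self.links = {
                (a, b) for a, b in self.links if a != position and b != position
            }
        self.synapses[position] = SynapseElement(position, kind, confidence, verified)

    def link_synapses(self, pre: Coordinate, post: Coordinate) -> None:
        a, b = self.synapses.get(pre), self.synapses.get(post)
        if a is None or b is None:
            raise ValidationError("both link endpoints must exist")
        if a.kind != "pre" or b.kind != "post":
            raise ValidationError("links are directed pre→post; endpoint kinds mismatch")
        self.links.add((pre, post))

    def unlink_synapses(self, pre: Coordinate, post: Coordinate) -> None:
        self.links.discard((pre, post))

    def move_synapse(self, src: Coordinate, dst: Coordinate) -> None:
        """Move an element; incident link endpoints follow it.

        An element already at ``dst`` is replaced, and its links removed.
        """
        elem = self.synapses.get(src)
        if elem is None:
            raise ValidationError(f"no synapse element at {tuple(src)}")
        if dst != src and dst in self.synapses:
            self.links = {(a, b) for a, b in self.links if a != dst and b != dst}
        del self.synapses[src]
        self.synapses[dst] = replace(elem, position=dst)
        self.links = {
            (dst if a == src else a, dst if b == src else b) for a, b in self.links
        }

    def delete_synapse(self, position: Coordinate) -> None:
        if self.synapses.pop(position, None) is None:
            raise ValidationError(f"no synapse element at {tuple(position)}")
        self.links = {(a, b) for a, b in self.links if a != position and b != position}

    # -- queries ----------------------------------------------------------

    def _body_of(self, position: Coordinate) -> int:
        if self.label_store is None:
            return 0
        return self.label_store.label_at(position)

    def query_annotations(
        self,
        *,
        region: Optional[BoundingBox] = None,
        body: Optional[int] = None,
        user: str = "",
        include_all: bool = False,
    ) -> Dict[str, list]:
        """Records in a region or on a body; bookmarks filtered to ``user``."""

        def wanted(pos: Coordinate) -> bool:
            if region is not None and not region.contains(pos):
                return False
            if body is not None and self._body_of(pos) != body:
                return False
            return True

        return {
            "bookmarks": [
                bm
                for bm in self.bookmarks.values()
                if wanted(bm.position) and (include_all or bm.owner == user)
            ],
            "todos": [t for t in self.todos.values() if wanted(t.position)],
            "synapses": [s for s in self.synapses.values() if wanted(s.position)],
        }

    # -- re-association ---------------------------------------------------

    def sync_after_relabel(self, retired_to_target: Mapping[int, int]) -> int:
        """Rewrite body-keyed records after IDs are retired by a merge.

        Conflict policy: the target's record wins; a retired body's name is
        appended to the target's comment log. Position-keyed marks need no
        rewrite (they resolve at query time). Returns records updated.
        """
        mapping = {int(k): int(v) for k, v in retired_to_target.items()}
        for src in mapping:
            seen = {src}
            cur = mapping[src]
            while cur in mapping:
                cur = mapping[cur]
                if cur in seen:
                    raise ValidationError("relabel mapping contains a cycle")
                seen.add(cur)
        updated = 0
        for retired, target in mapping.items():
            rec = self.body_annotations.pop(retired, None)
            if rec is None:
                continue
            final = target
            while final in mapping:
                final = mapping[final]
            tgt = self.body_annotations.setdefault(final, BodyAnnotation(final))
            if rec.name:
                tgt.comment_log.append(f"absorbed body {retired} named {rec.name!r}")
                if not tgt.name:
                    tgt.name = rec.name
            updated += 1
        return updated

    # -- sequencer --------------------------------------------------------

    def sequencer_query(
        self,
        filter_regex: Optional[str] = None,
        sort_key: str = "synapse_count",
        descending: bool = False,
    ) -> pd.DataFrame:
        """Filterable, sortable table of annotated bodies.

        Columns: body, name, status, synapse_count, voxel_count. The regex
        is matched anywhere in the name (full scan); the sort is stable.
        """
        if sort_key not in ("synapse_count", "voxel_count", "name", "status"):
            raise ValidationError(f"unknown sort key {sort_key!r}")
        if filter_regex is not None:
            try:
                pattern = re.compile(filter_regex)
            except re.error as exc:
                raise ValidationError(f"invalid regex: {exc}") from exc
        else:
            pattern = None

        syn_count: Dict[int, int] = {}
        for s in self.synapses.values():
            b = self._body_of(s.position)
            syn_count[b] = syn_count.get(b, 0) + 1

        rows = []
        for body, rec in sorted(self.body_annotations.items()):
            if pattern is not None and not pattern.search(rec.name):
                continue
            if self.label_store is not None:
                try:
                    vc = self.label_store.get_body_sparse(body).voxel_count
                except BodyNotFoundError:
                    vc = 0
            else:
                vc = 0
            rows.append(
                {
                    "body": body,
                    "name": rec.name,
                    "status": rec.status,
                    "synapse_count": syn_count.get(body, 0),
                    "voxel_count": vc,
                }
            )
        df = pd.DataFrame(rows, columns=["body", "name", "status", "synapse_count", "voxel_count"])
        return df.sort_values(sort_key, ascending=not descending, kind="stable").reset_index(
            drop=True
        )

    # -- persistence (JSON-lines per kind) --------------------------------

    def save(self, path) -> None:
        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)

        def dump(name: str, records: List[dict]) -> None:
            (root / f"{name}.jsonl").write_text(
                "".join(json.dumps(r) + "\n" for r in records)
            )

        dump(
            "body_annotations",
            [
                {"body": r.body, "name": r.name, "status": r.status, "comment_log": r.comment_log}
                for r in self.body_annotations.values()
            ],
        )
        dump(
            "bookmarks",
            [
                {"position": list(b.position), "type": b.type, "comment": b.comment, "owner": b.owner}
                for b in self.bookmarks.values()
            ],
        )
        dump(
            "todos",
            [
                {"position": list(t.position), "status": t.status, "action": t.action}
                for t in self.todos.values()
            ],
        )
        dump(
            "synapses",
            [
                {
                    "position": list(s.position),
                    "kind": s.kind,
                    "confidence": s.confidence,
                    "verified": s.verified,
                }
                for s in self.synapses.values()
            ],
        )
        dump("links", [{"pre": list(a), "post": list(b)} for a, b in sorted(self.links)])

    def load(self, path) -> None:
        root = Path(path)

        def rows(name: str):
            fp = root / f"{name}.jsonl"
            if not fp.exists():
                return []
            return [json.loads(line) for line in fp.read_text().splitlines() if line.strip()]

        for r in rows("body_annotations"):
            self.body_annotations[r["body"]] = BodyAnnotation(
                r["body"], r["name"], r["status"], list(r.get("comment_log", []))
            )
        for r in rows("bookmarks"):
            self.add_bookmark(Coordinate(*r["position"]), r["type"], r["comment"], r["owner"])
        for r in rows("todos"):
            self.todos[Coordinate(*r["position"])] = TodoMark(
                Coordinate(*r["position"]), r["status"], r["action"]
            )
        for r in rows("synapses"):
            self.add_synapse(
                Coordinate(*r["position"]), r["kind"], r["confidence"], r["verified"]
            )
        for r in rows("links"):
            self.links.add((Coordinate(*r["pre"]), Coordinate(*r["post"])))
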