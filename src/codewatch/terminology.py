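"""Hierarchical clinical coding dictionaries (CTV3-style trees, SNOMED-style codes).

UK primary care activity is recorded against codes from a hierarchical
dictionary: short (5-character, case-sensitive) CTV3-style codes arranged in a
parent--child forest in which broad "parent" concepts refine into specific
"child" codes, plus long numeric SNOMED-CT-style concept identifiers for newer
activities.  This module parses such dictionaries from delimited text, validates
the tree structure, and supports the three grouping mechanisms used when rolling
related activities together:

* **prefix groups** -- every code whose string starts with given leading
  characters (CTV3 code strings encode the hierarchy by prefix only
  approximately, so this is a string operation, deliberately distinct from tree
  position);
* **subtree groups** -- a root concept together with all of its descendants;
* **explicit groups** -- a hand-curated code list.

Keyword search over code descriptions (case-insensitive substring match) is the
companion mechanism for data-driven code discovery.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ClinicalCode",
    "CodeHierarchy",
    "CodeGroup",
    "GroupDefinition",
    "build_group",
    "load_terminology",
    "write_terminology",
    "DEFAULT_DIALECT",
]

#: Default column mapping for terminology files: comma-delimited with columns
#: ``code``, ``description``, ``parent`` (blank parent = top-level concept).
DEFAULT_DIALECT: Mapping[str, str] = {
    "code": "code",
    "description": "description",
    "parent": "parent",
}

_SNOMED_RE = re.compile(r"^\d{6,}$")


def infer_terminology(code_id: str) -> str:
    """Classify a code string as ``"CTV3"`` or ``"SNOMED"``.

    Long all-digit identifiers (6+ digits) are treated as SNOMED-CT concept
    ids; everything else as CTV3-style.
    """
    return "SNOMED" if _SNOMED_RE.match(code_id) else "CTV3"


@dataclass(frozen=True)
class ClinicalCode:
    """A single concept in a clinical coding dictionary.

    Parameters
    ----------
    code_id :
        The code string.  CTV3-style codes are 5 characters and case-sensitive
        (``XaF8d`` and ``Xaf8d`` are distinct concepts); SNOMED-style codes are
        longer numeric strings.
    description :
        Free-text description of the concept.
    parent_id :
        The parent concept's code, or ``None`` for a top-level concept.
    terminology :
        ``"CTV3"`` or ``"SNOMED"``; inferred from the code string if omitted.
    """

    code_id: str
    description: str = ""
    parent_id: str | None = None
    terminology: str = ""

    def __post_init__(self) -> None:
        if not self.code_id:
            raise ValueError("code_id must be non-empty")
        if not self.terminology:
            object.__setattr__(self, "terminology", infer_terminology(self.code_id))
        elif self.terminology not in ("CTV3", "SNOMED"):
            raise ValueError(f"unknown terminology {self.terminology!r}")


class CodeHierarchy:
    """A validated forest of clinical codes.

    The constructor checks the structural invariants once, so every query
    method can assume a well-formed acyclic forest:

    * code ids are unique and non-empty;
    * every ``parent_id`` refers to an existing code;
    * following parent links always reaches a top-level concept (no cycles).

    Multiple top-level concepts are permitted (a forest, not a single-rooted
    tree), matching real coding dictionaries.
    """

    def __init__(self, codes: Iterable[ClinicalCode]):
        self._codes: dict[str, ClinicalCode] = {}
        for c in codes:
            if c.code_id in self._codes:
                raise ValueError(f"duplicate code_id {c.code_id!r}")
            self._codes[c.code_id] = c

        self._children: dict[str, set[str]] = {}
        for c in self._codes.values():
            if c.parent_id is not None:
                if c.parent_id not in self._codes:
                    raise ValueError(
                        f"code {c.code_id!r} refers to unknown parent {c.parent_id!r}"
                    )
                self._children.setdefault(c.parent_id, set()).add(c.code_id)

        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # Walk parent chains with path tracking; each code is resolved once.
        state: dict[str, int] = {}  # 0 = on current path, 1 = done
        for start in self._codes:
            path: list[str] = []
            node: str | None = start
            while node is not None and node not in state:
                state[node] = 0
                path.append(node)
                node = self._codes[node].parent_id
            if node is not None and state[node] == 0:
                i = path.index(node) if node in path else 0
                cycle = path[i:] + [node]
                raise ValueError("cycle in parent links: " + " -> ".join(cycle))
            for p in path:
                state[p] = 1

    # -- basic container protocol ------------------------------------------

    def __contains__(self, code_id: str) -> bool:
        return code_id in self._codes

    def __len__(self) -> int:
        return len(self._codes)

    def __iter__(self):
        return iter(self._codes.values())

    def get(self, code_id: str) -> ClinicalCode:
        try:
            return self._codes[code_id]
        except KeyError:
            raise KeyError(f"unknown code_id {code_id!r}") from None

    @property
    def code_ids(self) -> set[str]:
        return set(self._codes)

    @property
    def children_index(self) -> dict[str, set[str]]:
        """Mapping parent code id -> set of direct child ids (inverse of parent_id)."""
        return {k: set(v) for k, v in self._children.items()}

    def roots(self) -> set[str]:
        """Top-level concepts (codes with no parent)."""
        return {c.code_id for c in self._codes.values() if c.parent_id is None}

    # -- queries ------------------------------------------------------------

    def descendants(self, code_id: str) -> set[str]:
        """All codes strictly below ``code_id`` in the tree.

        Excludes ``code_id`` itself; the empty set for a leaf.
        """
        if code_id not in self._codes:
            raise KeyError(f"unknown code_id {code_id!r}")
        out: set[str] = set()
        stack = list(self._children.get(code_id, ()))
        while stack:
            node = stack.pop()
            if node not in out:
                out.add(node)
                stack.extend(self._children.get(node, ()))
        return out

    def subtree(self, code_id: str) -> set[str]:
        """``code_id`` together with all of its descendants."""
        return {code_id} | self.descendants(code_id)

    def codes_with_prefix(self, prefix: str) -> set[str]:
        """Codes whose id starts with ``prefix`` (case-sensitive string match)."""
        if not prefix:
            raise ValueError("prefix must be non-empty")
        return {cid for cid in self._codes if cid.startswith(prefix)}

    def keyword_search(self, terms: Sequence[str]) -> set[str]:
        """Codes whose description contains any term (case-insensitive substring).

        The result is the union over terms; at least one term is required.
        """
        if not terms:
            raise ValueError("at least one search term is required")
        lowered = [t.lower() for t in terms]
        return {
            c.code_id
            for c in self._codes.values()
            if any(t in c.description.lower() for t in lowered)
        }

    def to_frame(self) -> pd.DataFrame:
        """The code/description/parent relation as a DataFrame, sorted by code."""
        rows = [
            (c.code_id, c.description, c.parent_id if c.parent_id is not None else "")
            for c in self._codes.values()
        ]
        df = pd.DataFrame(rows, columns=["code", "description", "parent"])
        return df.sort_values("code", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class GroupDefinition:
    """How a :class:`CodeGroup`'s membership is defined.

    Exactly one of ``prefix``, ``members`` or ``root`` must be given.
    """

    name: str
    prefix: str | None = None
    members: tuple[str, ...] | None = None
    root: str | None = None
    topic: str | None = None

    def __post_init__(self) -> None:
        given = sum(x is not None for x in (self.prefix, self.members, self.root))
        if given != 1:
            raise ValueError(
                "exactly one of prefix, members or root must be specified"
            )
        if self.members is not None:
            object.__setattr__(self, "members", tuple(self.members))

    @property
    def kind(self) -> str:
        if self.prefix is not None:
            return "prefix"
        if self.members is not None:
            return "explicit"
        return "subtree"


@dataclass(frozen=True)
class CodeGroup:
    """A named, fully resolved set of codes (no lazy membership)."""

    name: str
    member_codes: frozenset[str]
    definition: GroupDefinition
    topic: str | None = None

    def __post_init__(self) -> None:
        if not self.member_codes:
            raise ValueError(f"group {self.name!r} resolved to no codes")
        object.__setattr__(self, "member_codes", frozenset(self.member_codes))


def build_group(h: CodeHierarchy, definition: GroupDefinition) -> CodeGroup:
    """Resolve a group definition against a hierarchy.

    Prefix groups take every code starting with the prefix; subtree groups take
    the root plus all descendants; explicit groups validate each listed member.
    """
    if definition.prefix is not None:
        members = h.codes_with_prefix(definition.prefix)
    elif definition.root is not None:
        if definition.root not in h:
            raise KeyError(
                f"group {definition.name!r}: subtree root {definition.root!r} not in hierarchy"
            )
        members = h.subtree(definition.root)
    else:
        assert definition.members is not None
        missing = [m for m in definition.members if m not in h]
        if missing:
            raise KeyError(
                f"group {definition.name!r}: member codes not in hierarchy: {missing}"
            )
        members = set(definition.members)
    return CodeGroup(
        name=definition.name,
        member_codes=frozenset(members),
        definition=definition,
        topic=definition.topic,
    )


def load_terminology(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    delimiter: str = ",",
) -> CodeHierarchy:
    """Read a coding dictionary from delimited text.

    Parameters
    ----------
    path :
        A CSV file with one row per code.
    dialect :
        Maps the logical names ``code``, ``description``, ``parent`` to the
        file's column names; defaults to :data:`DEFAULT_DIALECT`.
    delimiter :
        Field delimiter (default comma).

    The loaded hierarchy is independent of row order.  Duplicate codes, orphan
    parents and cycles raise ``ValueError`` naming the offending codes.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [v for v in d.values() if v not in df.columns]
    if missing:
        raise ValueError(f"terminology file missing columns: {missing}")
    codes = [
        ClinicalCode(
            code_id=row[d["code"]],
            description=row[d["description"]],
            parent_id=row[d["parent"]] or None,
        )
        for row in df.to_dict("records")
    ]
    return CodeHierarchy(codes)


def write_terminology(
    h: CodeHierarchy,
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    delimiter: str = ",",
) -> None:
    """Write a hierarchy back to delimited text (round-trips with load)."""
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = h.to_frame().rename(
        columns={"code": d["code"], "description": d["description"], "parent": d["parent"]}
    )
    df.to_csv(path, sep=delimiter, index=False)
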