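"""Named gene sets and the GMT file format.

A :class:`GeneSet` is a named collection of unique gene identifiers.
Identifiers are matched by exact string equality after whitespace trimming;
no symbol aliasing is attempted (aliasing would require external databases).

GMT is the tab-delimited gene-set format used throughout enrichment
software: one set per line, ``name<TAB>description<TAB>member1<TAB>...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers.

    Parameters
    ----------
    name:
        Label for the set (e.g. a signature or DE-list name).
    members:
        Gene identifiers; whitespace-trimmed, duplicates rejected.
    description:
        Free-text description carried into the GMT second column.
    """

    name: str
    members: frozenset[str]
    description: str = ""

    def __init__(self, name: str, members: Iterable[str], description: str = ""):
        cleaned = [str(m).strip() for m in members]
        cleaned = [m for m in cleaned if m]
        if len(cleaned) != len(set(cleaned)):
            seen: set[str] = set()
            dups = sorted({m for m in cleaned if m in seen or seen.add(m)})
            raise ValueError(f"duplicate gene identifiers in set {name!r}: {dups[:10]}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(cleaned))
        object.__setattr__(self, "description", description)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def intersection(self, other: "GeneSet") -> frozenset[str]:
        return self.members & other.members

    def issubset(self, other: "GeneSet") -> bool:
        return self.members <= other.members


def count_overlap(query: GeneSet, reference: GeneSet) -> int:
    """Size of the intersection between two gene sets.

    Exact identifier equality (case-sensitive, whitespace already trimmed
    at construction).
    """
    return len(query.members & reference.members)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read all gene sets from a GMT file."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line (need name, description): {line!r}")
            name, desc, *members = parts
            sets.append(GeneSet(name, members, description=desc))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets to a GMT file (members sorted for reproducibility)."""
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")
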