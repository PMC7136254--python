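"""Reading and writing gene-set collections in GMT format.

A GMT file has one set per line: set name, description, then tab-separated
member symbols. Collections are plain ``dict[str, list[str]]`` mappings from
set name to an ordered, duplicate-free member list.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [members...]}``.

    Duplicate members within a set are dropped (first occurrence kept) with a
    warning; duplicate set names are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name, _desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(m for m in members if m))
            if len(unique) < sum(1 for m in members if m):
                logger.warning(
                    "set %r: dropped %d duplicate member(s)",
                    name, sum(1 for m in members if m) - len(unique),
                )
            sets[name] = unique
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "") -> None:
    """Write a collection to GMT. Set names must be unique (mapping keys are);
    members are written in iteration order."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in sets.items():
            members = list(members)
            if len(set(members)) != len(members):
                raise ValueError(f"set {name!r} has duplicate members")
            if not members:
                raise ValueError(f"set {name!r} is empty")
            fh.write("\t".join([name, description, *members]) + "\n")
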