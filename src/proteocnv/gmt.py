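"""Reading and writing GMT gene-set files (term <TAB> description <TAB> genes...)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

__all__ = ["read_gmt", "write_gmt"]


def read_gmt(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a GMT file into an ordered mapping term -> member genes.

    Lines with fewer than two fields are rejected; comment lines (#) and
    blank lines are skipped. Duplicate member genes within a term are
    collapsed, preserving order.
    """
    terms: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs term and description fields")
            term = fields[0]
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            terms[term] = members
    return terms


def write_gmt(terms: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write terms to GMT. An empty mapping yields an empty, valid file."""
    with open(path, "w") as fh:
        for term, members in terms.items():
            desc = descriptions.get(term, "na") if descriptions else "na"
            fh.write("\t".join([term, desc, *members]) + "\n")
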