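"""Pathway gene sets and the GMT format.

GMT is the field's plain-text gene-set carrier: one set per line, tab
separated — set identifier, free-text description, then member symbols.
Used here to supply the KEGG endometrial-cancer pathway (hsa05213) whose
member mRNAs define the disease-relevant triplets.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError


@dataclass(frozen=True)
class GeneSet:
    """A named pathway with its member gene symbols.

    Symbols are uppercased on construction so that membership tests are
    case-insensitive (KEGG and expression-profile symbol casing differ).
    Duplicates are dropped preserving first occurrence.
    """

    set_id: str
    description: str
    members: tuple

    def __post_init__(self):
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(str(m).upper(), None)
        object.__setattr__(self, "members", tuple(seen))
        if not self.members:
            raise ValidationError(f"gene set {self.set_id!r} has no members")

    def __contains__(self, symbol) -> bool:
        return str(symbol).upper() in self.members


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file into a list of :class:`GeneSet`.

    Empty or whitespace-only lines are ignored; a line with fewer than
    three tab-separated fields is a validation error naming the line.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields "
                    f"(id, description, members), got {len(fields)}")
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return sets


def write_gmt(genesets: list[GeneSet], path) -> None:
    """Serialize gene sets, one per line, in the given order."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.set_id, gs.description, *gs.members]) + "\n")


def select_gene_set(genesets: list[GeneSet], set_id: str,
                    union: bool = False) -> GeneSet:
    """Pick one set by id, or with ``union=True`` merge all sets into one."""
    if union:
        members = tuple(m for gs in genesets for m in gs.members)
        return GeneSet("union", "union of all sets", members)
    for gs in genesets:
        if gs.set_id == set_id:
            return gs
    raise ValidationError(
        f"gene set {set_id!r} not found; available: "
        f"{[gs.set_id for gs in genesets]}")
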