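"""Pathway definitions with signed activator/repressor gene roles.

A pathway is a named gene set in which every member gene carries a discrete
signed weight, the activator/repressor role (ARR): +1 for an activator,
-1 for a repressor, with half-weights for weak roles and 0 for a neutral
member.  The file format is a tab-separated dialect of GMT with roles
attached to each gene::

    pathway_id<TAB>kind<TAB>GENE_A:+1<TAB>GENE_B:-0.5

``kind`` distinguishes signaling from metabolic pathways.  A plain GMT
reader is provided for interoperability; there every gene defaults to an
activator role of +1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ARR_VALUES",
    "ARR_TERNARY",
    "GeneRole",
    "PathwayDefinition",
    "read_pathway_db",
    "write_pathway_db",
    "read_gmt",
]

#: Five-level activator/repressor alphabet: repressor, weak repressor,
#: neutral, weak activator, activator.
ARR_VALUES: tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0)

#: Restricted three-level alphabet for users who do not distinguish weak roles.
ARR_TERNARY: tuple[float, ...] = (-1.0, 0.0, 1.0)

PATHWAY_KINDS = ("signaling", "metabolic")

# canonical textual form of each ARR level used on disk
_ARR_TOKENS = {-1.0: "-1", -0.5: "-0.5", 0.0: "0", 0.5: "+0.5", 1.0: "+1"}


@dataclass(frozen=True)
class GeneRole:
    """A member gene and its signed role weight within one pathway."""

    gene_symbol: str
    arr: float

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if self.arr not in ARR_VALUES:
            raise ValueError(
                f"ARR value {self.arr!r} for gene {self.gene_symbol!r} is not in "
                f"the discrete set {ARR_VALUES}"
            )


@dataclass
class PathwayDefinition:
    """A named gene set with signed member roles.

    ``name`` defaults to ``pathway_id``; the on-disk format stores the id
    only, so a divergent display name does not survive a write/read cycle.
    """

    pathway_id: str
    kind: str
    members: list[GeneRole]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValueError("pathway_id must be non-empty")
        if self.kind not in PATHWAY_KINDS:
            raise ValueError(f"kind must be one of {PATHWAY_KINDS}, got {self.kind!r}")
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")
        symbols = [m.gene_symbol for m in self.members]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(
                f"pathway {self.pathway_id!r} has duplicate gene symbols: {dupes}"
            )
        if not self.name:
            self.name = self.pathway_id

    @property
    def genes(self) -> list[str]:
        return [m.gene_symbol for m in self.members]

    def arr_map(self) -> dict[str, float]:
        return {m.gene_symbol: m.arr for m in self.members}


def _parse_arr(token: str, allowed: Sequence[float], lineno: int) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"line {lineno}: cannot parse ARR value {token!r}") from None
    if value not in allowed:
        raise ValueError(
            f"line {lineno}: ARR value {token!r} not in the discrete set {tuple(allowed)}"
        )
    return value


def read_pathway_db(
    path: str | Path,
    allowed_arr: Sequence[float] = ARR_VALUES,
) -> list[PathwayDefinition]:
    """Read a role-annotated pathway database.

    Parameters
    ----------
    path
        Tab-separated file, one pathway per line:
        ``pathway_id<TAB>kind<TAB>gene:arr<TAB>gene:arr...``.
    allowed_arr
        The discrete ARR alphabet to accept; pass :data:`ARR_TERNARY` to
        restrict to {-1, 0, +1}.

    Returns the pathways in file order.  Raises ``ValueError`` naming the
    line number for malformed lines, out-of-alphabet ARR values, or a
    duplicated pathway id.
    """
    db: list[PathwayDefinition] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: expected pathway_id, kind and at least one "
                    f"gene:arr field, got {len(fields)} fields"
                )
            pathway_id, kind = fields[0], fields[1]
            if pathway_id in seen:
                raise ValueError(f"line {lineno}: duplicate pathway_id {pathway_id!r}")
            members = []
            for tok in fields[2:]:
                gene, sep, arr_tok = tok.rpartition(":")
                if not sep or not gene:
                    raise ValueError(
                        f"line {lineno}: malformed gene:arr field {tok!r}"
                    )
                members.append(
                    GeneRole(gene.upper(), _parse_arr(arr_tok, allowed_arr, lineno))
                )
            try:
                db.append(PathwayDefinition(pathway_id, kind, members))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            seen.add(pathway_id)
    return db


def write_pathway_db(db: Iterable[PathwayDefinition], path: str | Path) -> None:
    """Write a pathway database; inverse of :func:`read_pathway_db`."""
    buf = io.StringIO()
    for pw in db:
        fields = [pw.pathway_id, pw.kind]
        fields.extend(f"{m.gene_symbol}:{_ARR_TOKENS[m.arr]}" for m in pw.members)
        buf.write("\t".join(fields) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_gmt(path: str | Path, kind: str = "signaling") -> list[PathwayDefinition]:
    """Read a plain GMT file (``name<TAB>description<TAB>gene...``).

    Every gene receives an activator role of +1; ``kind`` applies to all
    pathways in the file.
    """
    db: list[PathwayDefinition] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: GMT line needs name, description and genes"
                )
            pathway_id = fields[0]
            if pathway_id in seen:
                raise ValueError(f"line {lineno}: duplicate pathway_id {pathway_id!r}")
            members = [GeneRole(g.upper(), 1.0) for g in fields[2:] if g]
            db.append(PathwayDefinition(pathway_id, kind, members))
            seen.add(pathway_id)
    return db
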