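"""Role-annotated pathway gene sets and the pathway cloud.

A *pathway cloud* is an ordered collection of signalling/metabolic pathways
scored jointly.  Every member gene carries a discrete activator/repressor
role (ARR) weight describing its part in pathway excitation:

* ``+1``  -- activator,
* ``-1``  -- repressor,
* ``+0.5`` / ``-0.5`` -- predominantly activator / repressor,
* ``0``   -- can act as either.

Role assignment comes from pathway databases and the literature; it is an
input to this package, never a computation.

The native on-disk dialect is a 3-column TSV ``(pathway_id, gene, arr)``
with an optional ``# name:`` header line per pathway, because plain GMT
cannot carry per-gene roles.  A GMT importer is provided for convenience;
it assigns ``arr = 1`` to every member and is therefore lossy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

__all__ = [
    "VALID_ARR",
    "PathwayFormatError",
    "GeneRole",
    "RoleAnnotatedPathway",
    "PathwayCloud",
    "read_pathway_file",
    "write_pathway_file",
    "read_gmt",
]

#: The admissible ARR weights.  Any other value is rejected at load time.
VALID_ARR = (-1.0, -0.5, 0.0, 0.5, 1.0)


class PathwayFormatError(ValueError):
    """Raised for malformed pathway files; the message names the line."""


@dataclass(frozen=True)
class GeneRole:
    """A member gene together with its ARR weight.

    Gene symbols are case-insensitive and normalized to uppercase
    (HGNC convention).
    """

    gene: str
    arr: float

    def __post_init__(self) -> None:
        symbol = self.gene.strip().upper()
        if not symbol:
            raise ValueError("gene symbol must be non-empty")
        object.__setattr__(self, "gene", symbol)
        arr = float(self.arr)
        if arr not in VALID_ARR:
            raise ValueError(
                f"invalid ARR {self.arr!r} for gene {symbol}: "
                f"must be one of {VALID_ARR}"
            )
        object.__setattr__(self, "arr", arr)


@dataclass(frozen=True)
class RoleAnnotatedPathway:
    """A named gene set whose members carry ARR weights."""

    pathway_id: str
    name: str
    members: tuple[GeneRole, ...]

    def __post_init__(self) -> None:
        if not self.pathway_id.strip():
            raise ValueError("pathway_id must be non-empty")
        members = tuple(self.members)
        if not members:
            raise ValueError(f"pathway {self.pathway_id}: members must be non-empty")
        genes = [m.gene for m in members]
        if len(set(genes)) != len(genes):
            dup = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(
                f"pathway {self.pathway_id}: duplicate gene(s) {', '.join(dup)}"
            )
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_genes(self) -> tuple[str, ...]:
        return tuple(m.gene for m in self.members)

    @property
    def arr_by_gene(self) -> Mapping[str, float]:
        return {m.gene: m.arr for m in self.members}

    def activators(self) -> tuple[str, ...]:
        """Genes with positive ARR."""
        return tuple(m.gene for m in self.members if m.arr > 0)

    def repressors(self) -> tuple[str, ...]:
        """Genes with negative ARR."""
        return tuple(m.gene for m in self.members if m.arr < 0)


@dataclass(frozen=True)
class PathwayCloud:
    """Ordered, deterministic collection of role-annotated pathways."""

    pathways: tuple[RoleAnnotatedPathway, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        pathways = tuple(self.pathways)
        ids = [p.pathway_id for p in pathways]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway_id(s): {', '.join(dup)}")
        object.__setattr__(self, "pathways", pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[RoleAnnotatedPathway]:
        return iter(self.pathways)

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(p.pathway_id for p in self.pathways)

    def get(self, pathway_id: str) -> RoleAnnotatedPathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def all_genes(self) -> frozenset[str]:
        """Union of member genes across all pathways."""
        return frozenset(g for p in self.pathways for g in p.member_genes)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_NAME_PREFIX = "# name:"


def read_pathway_file(path: str | Path) -> PathwayCloud:
    """Read a pathway cloud from the native 3-column TSV dialect.

    Data rows are ``pathway_id<TAB>gene<TAB>arr``.  An optional
    ``# name: pathway_id<TAB>display name`` line gives a pathway its
    human-readable name; other ``#`` lines and blank lines are ignored.
    Pathway order is first-appearance order (deterministic).

    Raises
    ------
    PathwayFormatError
        On malformed ARR values, duplicate (pathway, gene) pairs, wrong
        column counts (with the offending line number) or an empty file.
    """
    path = Path(path)
    names: dict[str, str] = {}
    rows: dict[str, list[GeneRole]] = {}
    seen: set[tuple[str, str]] = set()
    with path.open("r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_NAME_PREFIX):
                payload = line[len(_NAME_PREFIX):].strip()
                pid, _, display = payload.partition("\t")
                if not pid:
                    raise PathwayFormatError(
                        f"{path}:{lineno}: malformed '# name:' header"
                    )
                names[pid.strip()] = display.strip() or pid.strip()
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise PathwayFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"found {len(fields)}"
                )
            pid, gene, arr_text = (f.strip() for f in fields)
            try:
                arr = float(arr_text)
            except ValueError:
                raise PathwayFormatError(
                    f"{path}:{lineno}: invalid ARR {arr_text!r}"
                ) from None
            try:
                role = GeneRole(gene=gene, arr=arr)
            except ValueError as exc:
                raise PathwayFormatError(f"{path}:{lineno}: {exc}") from None
            key = (pid, role.gene)
            if key in seen:
                raise PathwayFormatError(
                    f"{path}:{lineno}: duplicate gene {role.gene!r} "
                    f"in pathway {pid!r}"
                )
            seen.add(key)
            rows.setdefault(pid, []).append(role)
    if not rows:
        raise PathwayFormatError(f"{path}: no pathway rows found")
    pathways = tuple(
        RoleAnnotatedPathway(
            pathway_id=pid, name=names.get(pid, pid), members=tuple(members)
        )
        for pid, members in rows.items()
    )
    return PathwayCloud(pathways=pathways, provenance=f"read from {path}")


def write_pathway_file(cloud: PathwayCloud, path: str | Path) -> None:
    """Write a cloud in the native TSV dialect.

    Round-trip property: ``read_pathway_file`` on the result reproduces the
    cloud's pathways exactly.  Refuses to write an empty cloud.
    """
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty pathway cloud")
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for pathway in cloud:
            handle.write(f"{_NAME_PREFIX} {pathway.pathway_id}\t{pathway.name}\n")
            for member in pathway.members:
                handle.write(
                    f"{pathway.pathway_id}\t{member.gene}\t{member.arr:g}\n"
                )


def read_gmt(path: str | Path) -> PathwayCloud:
    """Import a plain GMT file (set name, description, genes...).

    GMT carries no per-gene roles, so every member is loaded with
    ``arr = 1`` (all-activator).  This import is lossy by construction and
    the provenance string says so.
    """
    path = Path(path)
    pathways: list[RoleAnnotatedPathway] = []
    with path.open("r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PathwayFormatError(
                    f"{path}:{lineno}: GMT rows need set name, description "
                    f"and at least one gene"
                )
            name, _description, *genes = fields
            members = tuple(
                GeneRole(gene=g, arr=1.0) for g in dict.fromkeys(
                    g.strip().upper() for g in genes if g.strip()
                )
            )
            if not members:
                raise PathwayFormatError(f"{path}:{lineno}: set {name!r} has no genes")
            pathways.append(
                RoleAnnotatedPathway(pathway_id=name, name=name, members=members)
            )
    if not pathways:
        raise PathwayFormatError(f"{path}: no gene sets found")
    return PathwayCloud(
        pathways=tuple(pathways),
        provenance=f"GMT import from {path} (roles lost: all ARR set to 1)",
    )
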