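"""Identifier cross-mapping between datasource systems.

Omics tables and pathway nodes rarely use the same identifier scheme (a
table may carry Entrez Gene ids while pathway nodes are annotated with
Ensembl accessions).  This module links the two through a mapping store of
equivalence sets over (system code, identifier) pairs, in the BridgeDb
spirit: cross-references form an equivalence web, so transitive closure is
computed at load time with union-find.

System codes are the short BridgeDb-style datasource codes ("L" Entrez
Gene, "En" Ensembl, "Ce" ChEBI, ...).  Identifiers are case-sensitive.

Mapping tables are flat TSVs of pairwise links::

    source_code<TAB>source_id<TAB>target_code<TAB>target_id

with '#' comment lines ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SYSTEM_CODES",
    "register_system_code",
    "database_to_code",
    "MappingStore",
    "MappingError",
    "UnknownSystemCodeError",
    "load_mapping_table",
    "map_identifier",
    "is_known",
]


class MappingError(Exception):
    """Base class for identifier-mapping errors."""


class MappingFormatError(MappingError):
    """Mapping table file malformed (missing header/columns)."""


class UnknownSystemCodeError(MappingError):
    """A system code is not registered in the code table."""


# ---------------------------------------------------------------------------
# System code table (BridgeDb-style), user-extensible via register_system_code

SYSTEM_CODES: dict[str, str] = {
    "L": "Entrez Gene",
    "En": "Ensembl",
    "H": "HGNC",
    "S": "Uniprot-TrEMBL",
    "X": "Affy",
    "Ag": "Agilent",
    "I": "RGD",
    "M": "MGI",
    "Om": "OMIM",
    "Pd": "PDB",
    "R": "RefSeq",
    "U": "UniGene",
    "Wg": "Wikigenes",
    "Ca": "CAS",
    "Ce": "ChEBI",
    "Ch": "HMDB",
    "Ck": "KEGG Compound",
    "Cpc": "PubChem-compound",
    "Wd": "Wikidata",
    "T": "GeneOntology",
    "Wp": "WikiPathways",
}

_DATABASE_TO_CODE = {name: code for code, name in SYSTEM_CODES.items()}


def register_system_code(code: str, database_name: str) -> None:
    """Register an additional datasource code (configuration extension point)."""
    if not code:
        raise UnknownSystemCodeError("system code must be non-empty")
    SYSTEM_CODES[code] = database_name
    _DATABASE_TO_CODE[database_name] = code


def database_to_code(database: str) -> str:
    """Map a full datasource name back to its code; unknown names pass through
    unchanged (so unregistered codes round-trip through GPML)."""
    return _DATABASE_TO_CODE.get(database, database)


def _check_code(code: str) -> None:
    if code not in SYSTEM_CODES:
        raise UnknownSystemCodeError(
            f"system code {code!r} is not registered; known codes: "
            + ", ".join(sorted(SYSTEM_CODES))
        )


# ---------------------------------------------------------------------------
# Mapping store

Key = tuple[str, str]  # (system_code, identifier)


@dataclass
class MappingStore:
    """Equivalence sets of (system_code, identifier) pairs.

    ``sets`` maps a set index to its member keys; ``index`` maps each key to
    its set.  Built by :func:`load_mapping_table`; symmetric and transitive
    by construction.
    """

    species: str = ""
    sets: list[frozenset[Key]] = field(default_factory=list)
    index: dict[Key, int] = field(default_factory=dict)

    def members(self, key: Key) -> frozenset[Key]:
        i = self.index.get(key)
        return self.sets[i] if i is not None else frozenset()

    def __len__(self) -> int:
        return len(self.index)


class _UnionFind:
    def __init__(self):
        self.parent: dict[Key, Key] = {}

    def find(self, k: Key) -> Key:
        self.parent.setdefault(k, k)
        root = k
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[k] != root:  # path compression
            self.parent[k], k = root, self.parent[k]
        return root

    def union(self, a: Key, b: Key) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


_HEADER = ("source_code", "source_id", "target_code", "target_id")


def load_mapping_table(path, species: str = "") -> MappingStore:
    """Load a pairwise-link TSV into a transitively closed MappingStore.

    Duplicate rows collapse; '#' comment lines and blank lines are ignored.
    Raises MappingFormatError when the header is absent or lacks columns.
    """
    uf = _UnionFind()
    with open(path, "r", encoding="utf-8") as fh:
        header = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header is None:
                header = tuple(line.split("\t"))
                if tuple(header[:4]) != _HEADER:
                    raise MappingFormatError(
                        f"mapping table must start with header {'	'.join(_HEADER)!r}; "
                        f"got {line!r}"
                    )
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise MappingFormatError(f"mapping row has {len(parts)} columns: {line!r}")
            sc, sid, tc, tid = parts[:4]
            uf.union((sc, sid), (tc, tid))
        if header is None:
            raise MappingFormatError("mapping table is empty (no header line)")

    groups: dict[Key, set[Key]] = {}
    for key in uf.parent:
        groups.setdefault(uf.find(key), set()).add(key)

    store = MappingStore(species=species)
    for root in sorted(groups):  # deterministic set order
        idx = len(store.sets)
        members = frozenset(groups[root])
        store.sets.append(members)
        for key in members:
            store.index[key] = idx
    return store


def map_identifier(store: MappingStore, identifier: str, source_code: str, target_code: str) -> set[str]:
    """Map an identifier from one system to another.

    Returns the possibly-empty set of equivalent identifiers in the target
    system.  Identity mapping (source == target) returns {identifier} whether
    or not the id occurs in the store.
    """
    _check_code(source_code)
    _check_code(target_code)
    if source_code == target_code:
        return {identifier}
    return {
        ident
        for (code, ident) in store.members((source_code, identifier))
        if code == target_code
    }


def is_known(store: MappingStore, identifier: str, code: str) -> bool:
    """True iff (code, identifier) occurs in any equivalence set."""
    _check_code(code)
    return (code, identifier) in store.index
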