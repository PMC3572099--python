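"""Core domain types.

Conventions shared by every stage:

* Protein identifiers are normalized UniProt-style accessions (uppercase,
  isoform suffix stripped), see :func:`normalize_accession`.
* All residue coordinates are 1-based and inclusive.
* Interactions are undirected pairs; an optional orientation (source, target,
  posterior) is attached by the edge-direction stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "PHOSPHO_RESIDUES",
    "KINASE_GROUPS",
    "MalformedIdentifierError",
    "normalize_accession",
    "PTMSite",
    "DomainAnnotation",
    "DisorderSegment",
    "ProteinRecord",
    "Interaction",
    "AnnotatedNetwork",
]

PHOSPHO_RESIDUES = frozenset("STY")
KINASE_GROUPS = ("AGC", "CAMK", "CK1", "CMGC", "STE", "TK", "TKL", "atypical", "other")

_ISOFORM_SUFFIX = re.compile(r"-\d+$")


class MalformedIdentifierError(ValueError):
    pass


def normalize_accession(raw_id: str) -> str:
    """Normalize a protein identifier: strip whitespace, uppercase, drop a
    trailing isoform suffix (``P62258-2`` -> ``P62258``).  Idempotent.
    """
    if raw_id is None:
        raise MalformedIdentifierError("identifier is None")
    s = str(raw_id).strip()
    if not s:
        raise MalformedIdentifierError("empty protein identifier")
    return _ISOFORM_SUFFIX.sub("", s.upper())


@dataclass(frozen=True, order=True)
class PTMSite:
    """One modified residue: 1-based position, one-letter residue code and a
    modification label (``phosphorylation``, ``acetylation``, ...)."""

    protein_id: str
    position: int
    residue: str
    modification: str

    def validate(self) -> Optional[str]:
        """Return a rejection reason, or None if the site is consistent.

        Phosphorylation must sit on S/T/Y and acetylation on K; the analysis
        pivots on residue identity so mismatched rows are rejected upstream.
        """
        if self.position < 1:
            return "position < 1"
        if self.modification == "phosphorylation" and self.residue not in PHOSPHO_RESIDUES:
            return f"phosphorylation on residue {self.residue!r}"
        if self.modification == "acetylation" and self.residue != "K":
            return f"acetylation on residue {self.residue!r}"
        return None

    @property
    def is_phospho(self) -> bool:
        return self.modification == "phosphorylation"

    @property
    def is_acetyl(self) -> bool:
        return self.modification == "acetylation"


@dataclass(frozen=True, order=True)
class DomainAnnotation:
    protein_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain span [{self.start}, {self.end}]")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, order=True)
class DisorderSegment:
    protein_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid disorder span [{self.start}, {self.end}]")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def merge_segments(segments: Iterable[DisorderSegment]) -> list[DisorderSegment]:
    """Merge overlapping/adjacent disorder segments of one protein."""
    segs = sorted(segments, key=lambda s: (s.start, s.end))
    merged: list[DisorderSegment] = []
    for s in segs:
        if merged and s.start <= merged[-1].end + 1:
            prev = merged[-1]
            if s.end > prev.end:
                merged[-1] = DisorderSegment(prev.protein_id, prev.start, s.end)
        else:
            merged.append(s)
    return merged


@dataclass
class ProteinRecord:
    """One protein with every annotation the pipeline consumes."""

    protein_id: str
    length: int = 0
    domains: list[DomainAnnotation] = field(default_factory=list)
    disorder: list[DisorderSegment] = field(default_factory=list)
    ptms: list[PTMSite] = field(default_factory=list)
    go_terms: set[str] = field(default_factory=set)
    localization: set[str] = field(default_factory=set)
    has_nls: bool = False
    kinase_group: Optional[str] = None

    @property
    def is_kinase(self) -> bool:
        return self.kinase_group is not None

    def phospho_sites(self, residue: Optional[str] = None) -> list[PTMSite]:
        return [s for s in self.ptms if s.is_phospho and (residue is None or s.residue == residue)]

    def acetyl_sites(self) -> list[PTMSite]:
        return [s for s in self.ptms if s.is_acetyl]

    def disorder_fraction(self) -> float:
        if self.length <= 0:
            return 0.0
        return sum(s.length for s in self.disorder) / self.length

    def effective_length(self) -> int:
        """Known length, else the maximal annotated coordinate."""
        if self.length > 0:
            return self.length
        coords = [d.end for d in self.domains] + [s.end for s in self.disorder]
        coords += [p.position for p in self.ptms]
        return max(coords, default=0)


@dataclass(frozen=True)
class Interaction:
    """An undirected interaction between two proteins.

    ``source``/``target``/``posterior`` are set by the orientation stage;
    until then the edge is undirected and ``source`` is None.
    """

    a: str
    b: str
    provenance: str = ""
    source: Optional[str] = None
    posterior: Optional[float] = None

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError(f"self-interaction {self.a!r}")
        if self.source is not None and self.source not in (self.a, self.b):
            raise ValueError("orientation source must be one of the endpoints")

    @property
    def key(self) -> frozenset:
        return frozenset((self.a, self.b))

    @property
    def directed_pair(self) -> Optional[tuple[str, str]]:
        if self.source is None:
            return None
        return (self.source, self.b if self.source == self.a else self.a)

    def oriented(self, source: str, posterior: float) -> "Interaction":
        return replace(self, source=source, posterior=posterior)


class AnnotatedNetwork:
    """Node set of :class:`ProteinRecord` plus undirected interactions.

    Edges are stored keyed by the unordered pair, so duplicates collapse.
    """

    def __init__(
        self,
        proteins: Optional[dict[str, ProteinRecord]] = None,
        edges: Optional[Iterable[Interaction]] = None,
        isoform_ids: Optional[Iterable[str]] = None,
    ):
        self.proteins: dict[str, ProteinRecord] = dict(proteins or {})
        self._edges: dict[frozenset, Interaction] = {}
        self.isoform_ids: list[str] = list(isoform_ids or [])
        for e in edges or []:
            self.add_edge(e)

    # -- construction -------------------------------------------------
    def add_protein(self, record: ProteinRecord) -> None:
        self.proteins[record.protein_id] = record

    def ensure_protein(self, protein_id: str) -> ProteinRecord:
        if protein_id not in self.proteins:
            self.proteins[protein_id] = ProteinRecord(protein_id=protein_id)
        return self.proteins[protein_id]

    def add_edge(self, edge: Interaction) -> None:
        self.ensure_protein(edge.a)
        self.ensure_protein(edge.b)
        self._edges[edge.key] = edge

    # -- access --------------------------------------------------------
    @property
    def edges(self) -> list[Interaction]:
        return list(self._edges.values())

    def edge_between(self, a: str, b: str) -> Optional[Interaction]:
        return self._edges.get(frozenset((a, b)))

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._edges

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for key in self._edges:
            if node in key:
                out |= key - {node}
        return out

    @property
    def n_nodes(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def summary(self) -> dict:
        clients = set()
        for iso in self.isoform_ids:
            clients |= self.neighbors(iso)
        clients -= set(self.isoform_ids)
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_isoforms": len(self.isoform_ids),
            "n_clients": len(clients),
        }

    def client_set(self) -> set[str]:
        s = self.summary()  # noqa: F841 - keeps counts consistent
        clients = set()
        for iso in self.isoform_ids:
            clients |= self.neighbors(iso)
        return clients - set(self.isoform_ids)
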