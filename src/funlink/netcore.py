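"""Core data model: evidence networks, annotation and ortholog maps, file I/O.

The whole toolkit works on undirected weighted gene graphs.  An
:class:`EvidenceNetwork` holds one source's raw-scored associations; an
:class:`IntegratedNetwork` holds the union graph with a confidence in [0, 1)
per edge plus the set of sources that contributed it.  Gene identifiers are
opaque case-sensitive strings; every edge is stored once under its
lexicographically sorted id pair, which makes iteration order deterministic
everywhere downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Iterator, Set, Tuple, Union

logger = logging.getLogger(__name__)

#: gene -> non-empty set of function-term (GO BP) identifiers.  Genes with no
#: annotation are absent from the map: presence means "annotated".
AnnotationMap = Dict[str, Set[str]]

EdgeKey = Tuple[str, str]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def edge_key(u: str, v: str) -> EdgeKey:
    """Canonical unordered edge key: lexicographically sorted id pair."""
    return (u, v) if u <= v else (v, u)


def _check_gene_id(gid: str) -> str:
    if not gid or any(c.isspace() for c in gid):
        raise ValueError(f"invalid gene id: {gid!r}")
    return gid


@dataclass
class EvidenceNetwork:
    """One source's undirected gene graph with raw scores.

    Invariants: no self-edges, one edge per unordered pair (duplicates keep
    the maximum raw score), canonical key ordering.
    """

    source_id: str
    _edges: Dict[EdgeKey, float] = field(default_factory=dict)

    def add_edge(self, u: str, v: str, score: float) -> bool:
        """Add an edge, collapsing duplicates by max score.

        Returns False (and adds nothing) for a self-edge.
        """
        _check_gene_id(u)
        _check_gene_id(v)
        if u == v:
            return False
        key = edge_key(u, v)
        prev = self._edges.get(key)
        self._edges[key] = float(score) if prev is None else max(prev, float(score))
        return True

    def edges(self) -> Iterator[Tuple[str, str, float]]:
        """Yield (u, v, score) in canonical (sorted-key) order."""
        for (u, v) in sorted(self._edges):
            yield u, v, self._edges[(u, v)]

    def score(self, u: str, v: str) -> float:
        return self._edges[edge_key(u, v)]

    def has_edge(self, u: str, v: str) -> bool:
        return edge_key(u, v) in self._edges

    def nodes(self) -> Set[str]:
        return {g for key in self._edges for g in key}

    def scores(self) -> Iterator[float]:
        return iter(self._edges.values())

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceNetwork):
            return NotImplemented
        return self.source_id == other.source_id and self._edges == other._edges


@dataclass
class IntegratedNetwork:
    """Union graph with a noisy-OR confidence r in [0, 1) and per-edge provenance."""

    _edges: Dict[EdgeKey, Tuple[float, FrozenSet[str]]] = field(default_factory=dict)

    def add_edge(self, u: str, v: str, confidence: float, sources: Iterable[str]) -> None:
        if u == v:
            raise ValueError(f"self-edge {u!r}")
        src = frozenset(sources)
        if not src:
            raise ValueError(f"edge ({u}, {v}) has empty provenance")
        if not 0.0 <= confidence <= 1.0:
            raise ValueError(f"confidence {confidence} outside [0, 1]")
        self._edges[edge_key(u, v)] = (float(confidence), src)

    def edges(self) -> Iterator[Tuple[str, str, float, FrozenSet[str]]]:
        for (u, v) in sorted(self._edges):
            r, src = self._edges[(u, v)]
            yield u, v, r, src

    def confidence(self, u: str, v: str) -> float:
        return self._edges[edge_key(u, v)][0]

    def has_edge(self, u: str, v: str) -> bool:
        return edge_key(u, v) in self._edges

    def provenance(self, u: str, v: str) -> FrozenSet[str]:
        return self._edges[edge_key(u, v)][1]

    def nodes(self) -> Set[str]:
        return {g for key in self._edges for g in key}

    def neighbors(self, gene: str) -> Set[str]:
        out = set()
        for (u, v) in self._edges:
            if u == gene:
                out.add(v)
            elif v == gene:
                out.add(u)
        return out

    def adjacency(self) -> Dict[str, Dict[str, float]]:
        """gene -> {neighbor -> confidence}; built once for scoring loops."""
        adj: Dict[str, Dict[str, float]] = {}
        for (u, v), (r, _src) in self._edges.items():
            adj.setdefault(u, {})[v] = r
            adj.setdefault(v, {})[u] = r
        return adj

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntegratedNetwork):
            return NotImplemented
        return self._edges == other._edges


@dataclass
class OrthologMap:
    """Many-to-many ortholog pairs from one donor organism to the target genome."""

    donor_organism: str
    pairs: Set[Tuple[str, str]] = field(default_factory=set)

    def add_pair(self, donor_gene: str, target_gene: str) -> None:
        _check_gene_id(donor_gene)
        _check_gene_id(target_gene)
        self.pairs.add((donor_gene, target_gene))

    def donor_to_targets(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for d, t in self.pairs:
            out.setdefault(d, set()).add(t)
        return out

    def target_to_donors(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for d, t in self.pairs:
            out.setdefault(t, set()).add(d)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Readers / writers.  All files are UTF-8 TSV without quoting; '#'-prefixed
# lines are comments.
# ---------------------------------------------------------------------------


def _data_lines(path: Union[str, Path]) -> Iterator[Tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_edge_list(path: Union[str, Path], source_id: str) -> EvidenceNetwork:
    """Read a `gene1<TAB>gene2<TAB>score[<TAB>sources]` edge list.

    A header line is tolerated (detected by a non-numeric third field on the
    first data line).  Self-edges are dropped with a logged count; duplicate
    pairs keep the maximum score.
    """
    net = EvidenceNetwork(source_id=source_id)
    n_self = 0
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        if first:
            first = False
            if not _is_number(fields[2]):
                continue  # header line
        try:
            score = float(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric score {fields[2]!r}") from None
        if fields[0] == fields[1]:
            n_self += 1
            continue
        net.add_edge(fields[0], fields[1], score)
    if n_self:
        logger.info("%s: dropped %d self-edge line(s)", path, n_self)
    return net


def write_edge_list(
    net: Union[EvidenceNetwork, IntegratedNetwork],
    path: Union[str, Path],
    header_comments: Iterable[str] = (),
) -> None:
    """Write a network as TSV in canonical edge order, scores at full precision.

    Integrated networks gain a fourth column with comma-joined source ids.
    ``read_edge_list(write_edge_list(n))`` reproduces ``n`` exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        if isinstance(net, IntegratedNetwork):
            fh.write("gene1\tgene2\tconfidence\tsources\n")
            for u, v, r, src in net.edges():
                fh.write(f"{u}\t{v}\t{r!r}\t{','.join(sorted(src))}\n")
        else:
            fh.write("gene1\tgene2\tscore\n")
            for u, v, s in net.edges():
                fh.write(f"{u}\t{v}\t{s!r}\n")


def read_integrated_network(path: Union[str, Path]) -> IntegratedNetwork:
    """Read an integrated edge list (4th column: comma-joined source ids)."""
    net = IntegratedNetwork()
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
        if first:
            first = False
            if not _is_number(fields[2]):
                continue
        try:
            r = float(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric confidence {fields[2]!r}") from None
        net.add_edge(fields[0], fields[1], r, fields[3].split(","))
    return net


def read_annotations(path: Union[str, Path], dialect: str = "tsv2col") -> AnnotationMap:
    """Read gene -> GO BP term sets.

    ``tsv2col``: lines ``gene<TAB>term``.  ``gaf``: GAF 2.x; object id from
    column 2, GO id from column 5, and only rows whose aspect (column 9) is
    "P" (Biological Process) are kept.
    """
    ann: AnnotationMap = {}
    if dialect == "tsv2col":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected gene<TAB>term")
            ann.setdefault(fields[0], set()).add(fields[1])
    elif dialect == "gaf":
        for lineno, line in _data_lines(path):
            if line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise ParseError(
                    f"{path}:{lineno}: GAF row has {len(fields)} columns, expected >=15"
                )
            if fields[8] != "P":
                continue
            ann.setdefault(fields[1], set()).add(fields[4])
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return ann


def write_annotations(ann: AnnotationMap, path: Union[str, Path]) -> None:
    """Write a 2-column annotation TSV in sorted order."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_ortholog_map(path: Union[str, Path], donor: str) -> OrthologMap:
    """Read a ``donor_gene<TAB>target_gene`` map; duplicate rows collapse."""
    omap = OrthologMap(donor_organism=donor)
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected donor<TAB>target")
        omap.add_pair(fields[0], fields[1])
    return omap


def read_gene_list(path: Union[str, Path]) -> Set[str]:
    """Read one gene id per line (reference lists, DE-gene lists)."""
    return {line.strip() for _lineno, line in _data_lines(path) if line.strip()}
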