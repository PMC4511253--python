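"""Score normalization and noisy-OR integration.

Raw scores from heterogeneous sources live on incomparable scales, so each
source is calibrated against a shared criterion: Gene Ontology Biological
Process annotation.  A source's score range (taken over its edges whose both
endpoints are annotated) is cut into ``n`` equal-width bins; the confidence of
a bin is the smoothed fraction of its annotated edges whose endpoints share a
GO BP term,

    p(k, b) = sum S_f(u, v) / (|E_kb| + 1),

where S_f(u, v) is 1 iff u and v share any term.  The +1 smoothing keeps
every confidence strictly below 1.  Scores below the fitted minimum fall in
bin 0 with confidence 0 (they are outside the calibratable range).  Sources
are then combined edge-wise with a noisy-OR,

    r(u, v) = 1 - prod_{k in D_uv} (1 - p(k, bin_k(S_k(u, v)))),

treating each source as an independent chance that the association is real:
edges seen by several sources gain confidence, and a single source can never
push r to 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .netcore import AnnotationMap, EvidenceNetwork, IntegratedNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinSpec:
    """Equal-width binning of one source's score range into n bins.

    Bin 1 starts at ``s_min``; bin ``n_bins`` ends at ``s_max``; anything
    below ``s_min`` maps to bin 0.
    """

    source_id: str
    s_min: float
    s_max: float
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.s_min > self.s_max:
            raise ValueError(f"s_min {self.s_min} > s_max {self.s_max}")
        if self.n_bins < 1:
            raise ValueError(f"n_bins {self.n_bins} < 1")


@dataclass
class ConfidenceTable:
    """Per source: its BinSpec and confidences p[0..n] (p[0] is always 0)."""

    specs: Dict[str, BinSpec] = field(default_factory=dict)
    p: Dict[str, List[float]] = field(default_factory=dict)
    #: per source and bin: (n_annotated_edges, n_sharing) used for reporting
    counts: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)

    def add_source(
        self,
        spec: BinSpec,
        confidences: Sequence[float],
        counts: Sequence[Tuple[int, int]] = (),
    ) -> None:
        if len(confidences) != spec.n_bins + 1:
            raise ValueError("need one confidence per bin 0..n")
        if confidences[0] != 0.0:
            raise ValueError("bin 0 confidence must be 0")
        if not all(0.0 <= c < 1.0 for c in confidences):
            raise ValueError("confidences must lie in [0, 1)")
        self.specs[spec.source_id] = spec
        self.p[spec.source_id] = list(confidences)
        self.counts[spec.source_id] = list(counts) if counts else [(0, 0)] * (spec.n_bins + 1)

    def confidence_of(self, source_id: str, score: float) -> float:
        spec = self.specs[source_id]
        return self.p[source_id][bin_index(score, spec)]

    def sources(self) -> List[str]:
        return sorted(self.specs)


def make_bin_spec(net: EvidenceNetwork, n_bins: int = 10) -> BinSpec:
    """Fit a BinSpec to the observed score extremes of a network."""
    scores = list(net.scores())
    if not scores:
        raise ValueError(f"source {net.source_id!r} has no edges")
    return BinSpec(source_id=net.source_id, s_min=min(scores), s_max=max(scores), n_bins=n_bins)


def bin_index(S: float, spec: BinSpec) -> int:
    """Map a raw score to its bin: 0 below s_min, else
    min(n, floor((S - s_min) / (s_max - s_min) * n) + 1).

    A degenerate spec (s_min == s_max) maps every S >= s_min to bin 1.
    """
    if S < spec.s_min:
        return 0
    if spec.s_max == spec.s_min:
        return 1
    if S >= spec.s_max:  # top bin; also guards overflow on tiny ranges
        return spec.n_bins
    frac = (S - spec.s_min) / (spec.s_max - spec.s_min)
    return min(spec.n_bins, math.floor(frac * spec.n_bins) + 1)


def shares_function(u: str, v: str, ann: AnnotationMap) -> int:
    """1 iff u and v share at least one annotation term; unannotated genes
    share nothing."""
    return int(bool(ann.get(u, set()) & ann.get(v, set())))


def bin_confidence(bin_edges: Sequence[Tuple[str, str]], ann: AnnotationMap) -> float:
    """Smoothed sharing fraction of one bin: sum S_f / (|E| + 1); empty -> 0.

    Callers pass only edges whose both endpoints are annotated.
    """
    n_share = sum(shares_function(u, v, ann) for u, v in bin_edges)
    return n_share / (len(bin_edges) + 1)


def confidence_table(
    nets: Sequence[EvidenceNetwork],
    ann: AnnotationMap,
    n_bins: int = 10,
) -> ConfidenceTable:
    """Calibrate every source against shared GO BP annotation.

    Per source, the bin range is fitted on the edges whose both endpoints
    are annotated (the only edges whose sharing status is observable), the
    annotated edges are partitioned by bin, and each bin's confidence is its
    smoothed sharing fraction.  Bins receiving no annotated edge get 0.  A
    source with no annotated edge at all is an error: its confidence cannot
    be estimated.
    """
    table = ConfidenceTable()
    for net in nets:
        if len(net) == 0:
            raise ValueError(f"source {net.source_id!r} is empty")
        annotated = [(u, v, s) for u, v, s in net.edges() if u in ann and v in ann]
        if not annotated:
            raise ValueError(
                f"source {net.source_id!r}: no edge has both endpoints annotated; "
                "confidence unestimable"
            )
        ann_scores = [s for _u, _v, s in annotated]
        spec = BinSpec(
            source_id=net.source_id,
            s_min=min(ann_scores),
            s_max=max(ann_scores),
            n_bins=n_bins,
        )
        bins: List[List[Tuple[str, str]]] = [[] for _ in range(n_bins + 1)]
        for u, v, s in annotated:
            bins[bin_index(s, spec)].append((u, v))
        confidences = [0.0]
        counts = [(0, 0)]
        for b in range(1, n_bins + 1):
            n_share = sum(shares_function(u, v, ann) for u, v in bins[b])
            confidences.append(n_share / (len(bins[b]) + 1))
            counts.append((len(bins[b]), n_share))
        table.add_source(spec, confidences, counts)
        logger.info(
            "confidence_table[%s]: %d/%d annotated edges, range [%g, %g]",
            net.source_id,
            len(annotated),
            len(net),
            spec.s_min,
            spec.s_max,
        )
    return table


def write_confidence_table(table: ConfidenceTable, path, header_comments=()) -> None:
    """Write the calibration as TSV: one row per (source, bin 1..n)."""
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("source\tbin\ts_lo\ts_hi\tn_edges\tn_sharing\tp\n")
        for sid in table.sources():
            spec = table.specs[sid]
            width = (spec.s_max - spec.s_min) / spec.n_bins
            for b in range(1, spec.n_bins + 1):
                lo = spec.s_min + (b - 1) * width
                hi = spec.s_max if b == spec.n_bins else spec.s_min + b * width
                n_edges, n_share = table.counts[sid][b]
                fh.write(
                    f"{sid}\t{b}\t{lo!r}\t{hi!r}\t{n_edges}\t{n_share}\t"
                    f"{table.p[sid][b]!r}\n"
                )


def read_confidence_table(path) -> ConfidenceTable:
    """Read a TSV written by :func:`write_confidence_table`."""
    rows: Dict[str, Dict[int, Tuple[float, float, int, int, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("source\t"):
                continue
            sid, b, lo, hi, n_edges, n_share, p = line.split("\t")
            rows.setdefault(sid, {})[int(b)] = (
                float(lo),
                float(hi),
                int(n_edges),
                int(n_share),
                float(p),
            )
    table = ConfidenceTable()
    for sid, bins in rows.items():
        n_bins = max(bins)
        spec = BinSpec(
            source_id=sid, s_min=bins[1][0], s_max=bins[n_bins][1], n_bins=n_bins
        )
        confidences = [0.0] + [bins[b][4] for b in range(1, n_bins + 1)]
        counts = [(0, 0)] + [(bins[b][2], bins[b][3]) for b in range(1, n_bins + 1)]
        table.add_source(spec, confidences, counts)
    return table


def integrate(nets: Sequence[EvidenceNetwork], table: ConfidenceTable) -> IntegratedNetwork:
    """Noisy-OR combination of all sources into one confidence-weighted graph.

    The node/edge union is taken over all sources; each edge's confidence is
    r = 1 - prod over contributing sources of (1 - p(source, bin(score))).
    Unannotated-endpoint edges still receive their bin's calibrated
    confidence; scores below a source's fitted minimum contribute factor 1
    (confidence 0).  Provenance records the contributing source ids.
    """
    for net in nets:
        if net.source_id not in table.specs:
            raise KeyError(f"confidence table lacks source {net.source_id!r}")
    acc: Dict[Tuple[str, str], Tuple[float, List[str]]] = {}
    for net in nets:
        for u, v, s in net.edges():
            p = table.confidence_of(net.source_id, s)
            prod, sources = acc.get((u, v), (1.0, []))
            acc[(u, v)] = (prod * (1.0 - p), sources + [net.source_id])
    out = IntegratedNetwork()
    for (u, v), (prod, sources) in acc.items():
        out.add_edge(u, v, 1.0 - prod, sources)
    logger.info("integrate: %d edges over %d nodes", len(out), len(out.nodes()))
    return out
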