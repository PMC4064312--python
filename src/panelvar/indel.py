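"""Indel detection by de novo local assembly.

Reads overlapping a targeted exon window are decomposed into k-mers and
assembled into a de Bruijn graph anchored at the window's flanking
reference k-mers.  Anchored source-to-sink paths are enumerated as candidate
haplotypes, aligned globally to the reference window with affine gap
penalties, and gaps in the alignment are emitted as left-normalised,
VCF-anchored indel calls supported by exact read-consistency counting.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from Bio import Align

__all__ = [
    "DeBruijnGraph", "HaplotypeCandidate", "IndelCall", "build_graph",
    "prune_graph", "enumerate_haplotypes", "align_haplotype", "call_indels",
    "left_normalize",
]

DEFAULT_K = 21
RETRY_K = 31
DEFAULT_MIN_SUPPORT = 2
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -2.0, -5.0, -1.0


@dataclass
class DeBruijnGraph:
    """k-mer graph with read-support counts and reference anchors."""

    k: int
    graph: nx.DiGraph  # nodes: k-mer strings; node/edge attr "support"
    source: str  # leftmost reference k-mer
    sink: str  # rightmost reference k-mer

    @property
    def anchored(self) -> bool:
        g = self.graph
        if self.source not in g or self.sink not in g:
            return False
        if self.source == self.sink:
            return True
        return nx.has_path(g, self.source, self.sink)

    @property
    def cyclic(self) -> bool:
        return not nx.is_directed_acyclic_graph(self.graph)


@dataclass
class HaplotypeCandidate:
    sequence: str
    support: int  # minimum edge support along the path
    alignment: object = field(default=None, repr=False)


@dataclass
class IndelCall:
    contig: str
    pos: int  # 1-based position of the anchor base
    ref: str
    alt: str
    supporting_fraction: float = 0.0

    def __post_init__(self) -> None:
        if (len(self.ref) > 1) == (len(self.alt) > 1):
            raise ValueError("exactly one of ref/alt must be longer (anchored indel)")

    @property
    def length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield seq[i: i + k]


def build_graph(reads, reference_window: str, k: int = DEFAULT_K) -> DeBruijnGraph:
    """Assemble read k-mers into a directed graph anchored at the window flanks.

    Node and edge support counts are k-mer occurrence counts over the reads;
    reference k-mers are present as nodes (support may be 0) so the flanking
    anchors always exist.
    """
    if k < 11 or k > 63 or k % 2 == 0:
        raise ValueError("k must be odd and within [11, 63]")
    if len(reference_window) < k:
        raise ValueError("reference window shorter than k")
    g = nx.DiGraph()
    for km in _kmers(reference_window, k):
        if km not in g:
            g.add_node(km, support=0, reference=True)
        else:
            g.nodes[km]["reference"] = True
    prev = None
    for km in _kmers(reference_window, k):
        if prev is not None and not g.has_edge(prev, km):
            g.add_edge(prev, km, support=0)
        prev = km
    for seq in reads:
        seq = seq if isinstance(seq, str) else str(seq)
        if len(seq) <= k:
            continue
        prev = None
        for km in _kmers(seq, k):
            if not set(km) <= set("ACGT"):
                prev = None
                continue
            if km in g:
                g.nodes[km]["support"] += 1
            else:
                g.add_node(km, support=1, reference=False)
            if prev is not None:
                if g.has_edge(prev, km):
                    g[prev][km]["support"] += 1
                else:
                    g.add_edge(prev, km, support=1)
            prev = km
    return DeBruijnGraph(k=k, graph=g,
                         source=reference_window[:k],
                         sink=reference_window[-k:])


def prune_graph(dbg: DeBruijnGraph, min_support: int = DEFAULT_MIN_SUPPORT,
                relative: float = 0.0) -> DeBruijnGraph:
    """Drop nodes/edges below the support threshold; anchors are never pruned.

    Reference-derived nodes and edges (support possibly 0) are retained so
    the reference haplotype always remains representable.  With
    ``relative`` > 0, a branch edge is additionally dropped when its support
    is below ``relative`` times the best sibling edge at the same node:
    coincident sequencing errors can push spurious k-mers past any absolute
    threshold at high depth, but they stay far below the local coverage.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    g = dbg.graph.copy()
    keep_nodes = {
        n for n, d in g.nodes(data=True)
        if d.get("reference") or d["support"] >= min_support
    }
    keep_nodes |= {dbg.source, dbg.sink}
    g.remove_nodes_from(set(g.nodes) - keep_nodes)

    def prunable(u, v):
        return not (g.nodes[u].get("reference") and g.nodes[v].get("reference"))

    drop_edges = {
        (u, v) for u, v, d in g.edges(data=True)
        if d["support"] < min_support and prunable(u, v)
    }
    if relative > 0:
        for n in g.nodes:
            for edges in (g.out_edges(n, data=True), g.in_edges(n, data=True)):
                edges = list(edges)
                if len(edges) < 2:
                    continue
                best = max(d["support"] for _, _, d in edges)
                drop_edges |= {
                    (u, v) for u, v, d in edges
                    if d["support"] < relative * best and prunable(u, v)
                }
    g.remove_edges_from(drop_edges)
    g.remove_nodes_from([n for n in list(g.nodes)
                         if g.degree(n) == 0 and not g.nodes[n].get("reference")])
    return DeBruijnGraph(k=dbg.k, graph=g, source=dbg.source, sink=dbg.sink)


def enumerate_haplotypes(dbg: DeBruijnGraph, max_paths: int = 8,
                         path_cap: int = 2000) -> list[HaplotypeCandidate]:
    """Anchored source-to-sink paths as haplotypes, ranked by support.

    Paths never revisit a node, so repeat-induced cycles terminate; path
    support is the minimum edge support along the path (reference-only edges
    contribute their own, possibly zero, support).  At most ``max_paths``
    haplotypes are returned, best-supported first.
    """
    if not dbg.anchored:
        return []
    g, k = dbg.graph, dbg.k
    if dbg.source == dbg.sink:
        return [HaplotypeCandidate(dbg.source, g.nodes[dbg.source]["support"])]
    paths = []
    for path in nx.all_simple_paths(g, dbg.source, dbg.sink):
        paths.append(path)
        if len(paths) >= path_cap:
            break
    out = []
    for path in paths:
        seq = path[0] + "".join(n[-1] for n in path[1:])
        support = min(g[u][v]["support"] for u, v in zip(path, path[1:]))
        out.append(HaplotypeCandidate(seq, support))
    out.sort(key=lambda h: (-h.support, h.sequence))
    return out[:max_paths]


def _aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def align_haplotype(haplotype: str, reference_window: str,
                    gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND,
                    match: float = MATCH, mismatch: float = MISMATCH):
    """Optimal global affine-gap alignment of a haplotype to the reference.

    A gap of length L scores ``gap_open + (L-1)*gap_extend``.  Returns a
    Biopython alignment object (``.score``, ``.aligned`` coordinate blocks).
    """
    if not haplotype or not reference_window:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    return next(iter(aligner.align(reference_window, haplotype)))


def left_normalize(window: str, offset: int, ref_allele: str, alt_allele: str):
    """Shift an anchored indel to its leftmost equivalent representation.

    ``offset`` is the 0-based window position of the anchor base.  Standard
    VCF left-alignment: while the bases preceding the event allow it, the
    indel slides left (homopolymers and tandem repeats report the leftmost
    site).  Idempotent.
    """
    ref, alt = ref_allele, alt_allele
    longer, shorter = (ref, alt) if len(ref) > len(alt) else (alt, ref)
    if len(shorter) != 1 or longer[0] != shorter[0]:
        raise ValueError("expected anchored indel alleles")
    inserted = longer[1:]
    while offset > 0 and inserted and inserted[-1] == window[offset]:
        inserted = window[offset] + inserted[:-1]
        offset -= 1
    anchor = window[offset]
    longer = anchor + inserted
    shorter = anchor
    if len(ref_allele) > len(alt_allele):
        return offset, longer, shorter
    return offset, shorter, longer


def _indels_from_alignment(alignment, window: str, contig: str,
                           window_start_1based: int) -> list[IndelCall]:
    """Extract gaps from aligned blocks as anchored, left-normalised calls."""
    ref_blocks, hap_blocks = alignment.aligned
    hap = alignment[1].replace("-", "")
    calls = []
    for i in range(len(ref_blocks) - 1):
        r_end, r_next = ref_blocks[i][1], ref_blocks[i + 1][0]
        h_end, h_next = hap_blocks[i][1], hap_blocks[i + 1][0]
        if r_next > r_end and h_next == h_end:  # deletion in haplotype
            off = r_end - 1
            if off < 0:
                continue
            ref_a = window[off: r_next]
            alt_a = window[off]
        elif h_next > h_end and r_next == r_end:  # insertion in haplotype
            off = r_end - 1
            if off < 0:
                continue
            ref_a = window[off]
            alt_a = window[off] + hap[h_end:h_next]
        else:
            continue
        off, ref_a, alt_a = left_normalize(window, off, ref_a, alt_a)
        calls.append(IndelCall(contig, window_start_1based + off, ref_a, alt_a))
    return calls


def _read_consistency(reads, window: str, haplotype: str,
                      event_start: int | None = None,
                      event_end: int | None = None) -> float:
    """Fraction of event-informative reads consistent with the alt haplotype.

    A read votes for a haplotype when it is an exact substring of that
    haplotype only; reads consistent with both (or neither, e.g. carrying
    errors) are uninformative.  Reference-only reads count only when their
    match overlaps the event interval ``[event_start, event_end)`` (0-based
    window coordinates): a ref read far from the indel says nothing about
    it, and counting it would dilute long deletions' supporting fraction.
    """
    alt_only = ref_only = 0
    for seq in reads:
        seq = seq if isinstance(seq, str) else str(seq)
        in_alt = seq in haplotype
        in_ref = seq in window
        if in_alt and not in_ref:
            alt_only += 1
        elif in_ref and not in_alt:
            if event_start is None:
                ref_only += 1
            else:
                q = window.find(seq)
                if q < event_end and q + len(seq) > event_start:
                    ref_only += 1
    total = alt_only + ref_only
    return alt_only / total if total else 0.0


def call_indels(
    reads,
    reference_window: str,
    contig: str = "chr1",
    window_start_1based: int = 1,
    k: int = DEFAULT_K,
    retry_k: int | None = RETRY_K,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_fraction: float = 0.10,
    relative_prune: float = 0.05,
    max_paths: int = 8,
    log: list | None = None,
) -> list[IndelCall]:
    """Assemble one exon window and emit supported indel calls.

    Builds the k-mer graph, prunes singleton-error k-mers, enumerates
    anchored haplotypes, aligns each to the reference window and extracts
    gaps; candidates are re-scored by exact read-consistency counting and
    kept at supporting fraction >= ``min_fraction``.  If the graph is
    unanchored or cyclic at the default k, assembly retries once at a
    larger k; an unanchored graph yields no calls (with a logged warning).
    """
    reads = [r if isinstance(r, str) else str(r) for r in reads]
    dbg = prune_graph(build_graph(reads, reference_window, k), min_support,
                      relative=relative_prune)
    if (not dbg.anchored or dbg.cyclic) and retry_k and retry_k != k:
        if len(reference_window) >= retry_k:
            dbg = prune_graph(build_graph(reads, reference_window, retry_k),
                              min_support, relative=relative_prune)
    if not dbg.anchored:
        if log is not None:
            log.append(f"{contig}:{window_start_1based}: assembly unanchored; no indel calls")
        return []
    calls: dict[tuple, IndelCall] = {}
    for hap in enumerate_haplotypes(dbg, max_paths=max_paths):
        if hap.sequence == reference_window:
            continue
        aln = align_haplotype(hap.sequence, reference_window)
        for call in _indels_from_alignment(aln, reference_window, contig,
                                           window_start_1based):
            off = call.pos - window_start_1based
            frac = _read_consistency(reads, reference_window, hap.sequence,
                                     event_start=off,
                                     event_end=off + len(call.ref))
            key = (call.pos, call.ref, call.alt)
            if frac >= min_fraction and (key not in calls
                                         or frac > calls[key].supporting_fraction):
                call.supporting_fraction = frac
                calls[key] = call
    return sorted(calls.values(), key=lambda c: (c.contig, c.pos, c.alt))
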