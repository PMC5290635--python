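"""Chromothripsis and double-minute candidate detection.

Chromothripsis — one catastrophic shattering and reassembly of a chromosome —
leaves a characteristic joint footprint in exome-derived copy-number segments
and structural-variant junctions: copy states oscillating between few levels,
many clustered intra-chromosomal breakpoints with high read support, and
either high-level amplification (>= ~20 copies, the double-minute route) or
extensive deletion. The detector operationalises this as explicit gates:

* amplifying event: ``n_switches >= switch_min`` and
  ``n_intra_supported >= break_min`` and ``max_cn >= amp_min``;
* deleting event: ``n_switches >= switch_min`` and
  ``n_intra_supported + supported incident inter links >= break_min`` and
  ``frac_deleted >= del_frac_min``.

Positive chromosomes joined by at least one supported inter-chromosomal
breakpoint are merged into a single multi-chromosome call. A shift in the
lesser-allele frequency away from 0.5 is reported as supporting evidence but
never gates a call. High-copy segments stitched together by supported
breakpoints form double-minute *candidates* (sequencing alone cannot separate
double minutes from homogeneously staining regions; that requires FISH).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import Breakpoint, CNSegment

__all__ = [
    "ChromothripsisParams",
    "ChromFeatures",
    "ChromothripsisCall",
    "DmComponent",
    "chromosome_features",
    "call_chromothripsis",
    "dm_candidates",
]


@dataclass(frozen=True)
class ChromothripsisParams:
    """Detector thresholds.

    ``amp_min`` (>= 20 copies) and ``support_min`` (> 100 supporting reads)
    are anchored to the printed evidence levels; the oscillation and break
    counts and the deleted fraction are this package's operationalisation and
    are all configurable.
    """

    support_min: int = 100
    amp_min: float = 20.0
    switch_min: int = 10
    break_min: int = 10
    del_frac_min: float = 0.3
    merge_tol: int = 10_000

    def to_jsonable(self) -> dict:
        return {
            "support_min": self.support_min,
            "amp_min": self.amp_min,
            "switch_min": self.switch_min,
            "break_min": self.break_min,
            "del_frac_min": self.del_frac_min,
            "merge_tol": self.merge_tol,
        }


@dataclass(frozen=True)
class ChromFeatures:
    """Per-chromosome summary of copy-number oscillation and break support."""

    chrom: str
    n_segments: int
    n_switches: int
    n_states: int
    max_cn: float
    frac_deleted: float
    n_intra_supported: int
    laf_shift: float | None

    def to_jsonable(self) -> dict:
        return {
            "chrom": self.chrom,
            "n_segments": self.n_segments,
            "n_switches": self.n_switches,
            "n_states": self.n_states,
            "max_cn": self.max_cn,
            "frac_deleted": self.frac_deleted,
            "n_intra_supported": self.n_intra_supported,
            "laf_shift": self.laf_shift,
        }


@dataclass
class DmComponent:
    """A connected set of high-copy segments linked by supported breakpoints —
    a double-minute candidate (FISH is required for confirmation)."""

    segments: list[CNSegment]
    linking_breakpoints: list[Breakpoint]
    chroms: frozenset[str]

    def to_jsonable(self) -> dict:
        return {
            "chroms": sorted(self.chroms),
            "segments": [
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "total_cn": s.total_cn,
                }
                for s in self.segments
            ],
            "n_linking_breakpoints": len(self.linking_breakpoints),
        }


@dataclass
class ChromothripsisCall:
    """One chromothripsis event, possibly spanning several linked chromosomes."""

    sample_id: str
    chroms: frozenset[str]
    event_type: str  # amplifying | deleting
    features: dict[str, ChromFeatures]
    n_inter_links: int
    dm_candidates: list[DmComponent] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "chroms": sorted(self.chroms),
            "event_type": self.event_type,
            "features": {c: f.to_jsonable() for c, f in sorted(self.features.items())},
            "n_inter_links": self.n_inter_links,
            "dm_candidates": [d.to_jsonable() for d in self.dm_candidates],
        }


def _sorted_chrom_segments(
    segments: Iterable[CNSegment], chrom: str
) -> list[CNSegment]:
    return sorted((s for s in segments if s.chrom == chrom), key=lambda s: s.start)


def chromosome_features(
    segments: Iterable[CNSegment],
    breakpoints: Iterable[Breakpoint],
    chrom: str,
    support_min: int = 100,
) -> ChromFeatures:
    """Summarise one chromosome's copy-number oscillation and breakpoint load.

    Copy states are rounded to the nearest integer before switch/state
    counting, absorbing segmentation noise; ``frac_deleted`` is the fraction
    of segmented length at rounded CN <= 1; ``laf_shift`` is the
    length-weighted mean |0.5 - laf| where lesser-allele frequencies are
    available.
    """
    segs = _sorted_chrom_segments(segments, chrom)
    states = [round(s.total_cn) for s in segs]
    n_switches = sum(1 for a, b in zip(states, states[1:]) if a != b)
    total_len = sum(s.length for s in segs)
    del_len = sum(s.length for s, st in zip(segs, states) if st <= 1)
    laf_segs = [s for s in segs if s.laf is not None]
    laf_len = sum(s.length for s in laf_segs)
    laf_shift = (
        sum(abs(0.5 - s.laf) * s.length for s in laf_segs) / laf_len
        if laf_len > 0
        else None
    )
    n_intra = sum(
        1
        for b in breakpoints
        if b.kind == "intra" and b.chrom_a == chrom and b.support >= support_min
    )
    return ChromFeatures(
        chrom=chrom,
        n_segments=len(segs),
        n_switches=n_switches,
        n_states=len(set(states)),
        max_cn=max((s.total_cn for s in segs), default=0.0),
        frac_deleted=del_len / total_len if total_len > 0 else 0.0,
        n_intra_supported=n_intra,
        laf_shift=laf_shift,
    )


def call_chromothripsis(
    segments: Sequence[CNSegment],
    breakpoints: Sequence[Breakpoint],
    params: ChromothripsisParams = ChromothripsisParams(),
) -> list[ChromothripsisCall]:
    """Call chromothripsis events for one sample.

    Per-chromosome gates (see module docstring) mark chromosomes positive as
    amplifying or deleting; positive chromosomes connected by at least one
    supported inter-chromosomal breakpoint are merged into one call. An event
    is typed ``amplifying`` when any member chromosome passes the amplifying
    gate, otherwise ``deleting``. Calls carry double-minute candidates whose
    segments lie on the event chromosomes.
    """
    if not segments:
        return []
    sample_ids = {s.sample_id for s in segments} | {b.sample_id for b in breakpoints}
    if len(sample_ids) > 1:
        raise ValueError(f"call_chromothripsis is per-sample; got {sorted(sample_ids)}")
    sample_id = sample_ids.pop()

    chroms = sorted({s.chrom for s in segments})
    supported_inter = [
        b for b in breakpoints if b.kind == "inter" and b.support >= params.support_min
    ]
    inter_incidence = {c: 0 for c in chroms}
    for b in supported_inter:
        for c in (b.chrom_a, b.chrom_b):
            if c in inter_incidence:
                inter_incidence[c] += 1

    features: dict[str, ChromFeatures] = {}
    amplifying: set[str] = set()
    deleting: set[str] = set()
    for c in chroms:
        f = chromosome_features(segments, breakpoints, c, params.support_min)
        features[c] = f
        if (
            f.n_switches >= params.switch_min
            and f.n_intra_supported >= params.break_min
            and f.max_cn >= params.amp_min
        ):
            amplifying.add(c)
        elif (
            f.n_switches >= params.switch_min
            and f.n_intra_supported + inter_incidence[c] >= params.break_min
            and f.frac_deleted >= params.del_frac_min
        ):
            deleting.add(c)
    positive = amplifying | deleting
    if not positive:
        return []

    g = nx.Graph()
    g.add_nodes_from(positive)
    link_counts: dict[frozenset[str], int] = {}
    for b in supported_inter:
        if b.chrom_a in positive and b.chrom_b in positive:
            g.add_edge(b.chrom_a, b.chrom_b)
            key = frozenset((b.chrom_a, b.chrom_b))
            link_counts[key] = link_counts.get(key, 0) + 1

    dms = dm_candidates(
        segments, breakpoints, params.amp_min, params.support_min, params.merge_tol
    )

    calls = []
    for comp in sorted(nx.connected_components(g), key=lambda s: sorted(s)[0]):
        comp = frozenset(comp)
        n_links = sum(
            n for key, n in link_counts.items() if key <= comp and len(key) > 1
        )
        calls.append(
            ChromothripsisCall(
                sample_id=sample_id,
                chroms=comp,
                event_type="amplifying" if comp & amplifying else "deleting",
                features={c: features[c] for c in comp},
                n_inter_links=n_links,
                dm_candidates=[d for d in dms if d.chroms & comp],
            )
        )
    return calls


def dm_candidates(
    segments: Sequence[CNSegment],
    breakpoints: Sequence[Breakpoint],
    amp_min: float = 20.0,
    support_min: int = 100,
    merge_tol: int = 10_000,
) -> list[DmComponent]:
    """Extract double-minute candidate components from the breakpoint graph.

    Nodes are segments with rounded CN >= ``amp_min``; edges are supported
    breakpoints with both ends inside (or within ``merge_tol`` of) node
    segments. Connected components with at least one edge are returned; an
    isolated high-copy segment is not a candidate.
    """
    nodes = sorted(
        (s for s in segments if round(s.total_cn) >= amp_min),
        key=lambda s: (s.chrom, s.start, s.end),
    )
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))

    def _hits(chrom: str, pos: int) -> list[int]:
        return [
            i
            for i, s in enumerate(nodes)
            if s.chrom == chrom and s.start - merge_tol <= pos <= s.end + merge_tol
        ]

    edge_bps: dict[tuple[int, int], list[Breakpoint]] = {}
    for b in breakpoints:
        if b.support < support_min:
            continue
        for i in _hits(b.chrom_a, b.pos_a):
            for j in _hits(b.chrom_b, b.pos_b):
                if i == j:
                    continue
                e = (min(i, j), max(i, j))
                g.add_edge(*e)
                edge_bps.setdefault(e, []).append(b)

    components = []
    for comp in nx.connected_components(g):
        if g.subgraph(comp).number_of_edges() == 0:
            continue
        idx = sorted(comp)
        segs = [nodes[i] for i in idx]
        bps = sorted(
            {
                id(b): b
                for e, blist in edge_bps.items()
                if e[0] in comp and e[1] in comp
                for b in blist
            }.values(),
            key=lambda b: (b.chrom_a, b.pos_a, b.chrom_b, b.pos_b),
        )
        components.append(
            DmComponent(
                segments=segs,
                linking_breakpoints=list(bps),
                chroms=frozenset(s.chrom for s in segs),
            )
        )
    components.sort(key=lambda d: (sorted(d.chroms)[0], d.segments[0].start))
    return components
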