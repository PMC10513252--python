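"""Post-processing of raw detector output: interval IoU, 1D non-max
suppression, clustering of domain calls into LTR-RT internal regions, and
flank extension for handoff to an external LTR-boundary tool.

Thresholding is two-stage, mirroring the detection pipeline: a permissive
raw presence filter (default 0.1) keeps candidates before NMS, and a
stricter reporting threshold (default 0.8, the precision x recall optimum
of the full-scale detector) selects the final calls.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

from .labels import DomainAnnotation
from .seqio import SequenceRecord, write_fasta

RAW_THRESHOLD = 0.1
REPORT_THRESHOLD = 0.8
NMS_IOU = 0.1
CLUSTER_MIN_DOMAINS = 3
CLUSTER_MAX_GAP = 3_000
FLANK = 8_000


@dataclasses.dataclass(frozen=True)
class Interval:
    """0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class InternalRegion:
    """A cluster of nearby domain calls approximating an LTR-RT internal
    part; spans the first member's start to the last member's end."""

    interval: Interval
    members: tuple[DomainAnnotation, ...]
    source_id: str


def interval_iou(a: Interval, b: Interval) -> float:
    """Intersection over union of two segments; union is total covered
    length (so disjoint segments give 0)."""
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    union = a.length + b.length - inter
    return inter / union


def _dom_interval(d: DomainAnnotation) -> Interval:
    return Interval(d.start, d.end)


def non_max_suppression(
    domains: Sequence[DomainAnnotation], iou_threshold: float = NMS_IOU
) -> list[DomainAnnotation]:
    """Greedy 1D NMS: repeatedly keep the highest-probability remaining call
    and discard the rest whose IoU with it exceeds ``iou_threshold``.

    Calls on different source sequences never suppress each other.  Ties in
    probability break toward the smaller start (then the longer call), so
    the output is deterministic.  Output sorted by (source, start).
    """
    kept: list[DomainAnnotation] = []
    by_source: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_source.setdefault(d.source_id, []).append(d)
    for source in sorted(by_source):
        pool = sorted(by_source[source], key=lambda d: (-d.presence_prob, d.start, -d.length))
        while pool:
            best = pool.pop(0)
            kept.append(best)
            bi = _dom_interval(best)
            pool = [d for d in pool if interval_iou(bi, _dom_interval(d)) <= iou_threshold]
    kept.sort(key=lambda d: (d.source_id, d.start))
    return kept


def filter_by_probability(
    domains: Sequence[DomainAnnotation], threshold: float
) -> list[DomainAnnotation]:
    return [d for d in domains if d.presence_prob > threshold]


def cluster_domains(
    domains: Sequence[DomainAnnotation],
    min_domains: int = CLUSTER_MIN_DOMAINS,
    max_gap: int = CLUSTER_MAX_GAP,
) -> list[InternalRegion]:
    """Single linear scan over start-sorted calls: a new cluster opens when
    the gap to the previous call (next.start - prev.end, the spacer length)
    exceeds ``max_gap``; clusters smaller than ``min_domains`` are dropped.

    All calls must come from one source sequence.
    """
    if not domains:
        return []
    sources = {d.source_id for d in domains}
    if len(sources) > 1:
        raise ValueError(f"cluster_domains expects one source sequence, got {sorted(sources)}")
    source = sources.pop()
    ordered = sorted(domains, key=lambda d: (d.start, d.end))
    clusters: list[list[DomainAnnotation]] = [[ordered[0]]]
    cur_end = ordered[0].end  # running max end handles nested/overlapping calls
    for d in ordered[1:]:
        if d.start - cur_end > max_gap:
            clusters.append([d])
            cur_end = d.end
        else:
            clusters[-1].append(d)
            cur_end = max(cur_end, d.end)
    out = []
    for members in clusters:
        if len(members) < min_domains:
            continue
        out.append(
            InternalRegion(
                interval=Interval(members[0].start, max(m.end for m in members)),
                members=tuple(members),
                source_id=source,
            )
        )
    return out


def extend_regions(
    regions: Sequence[InternalRegion], seq_len: int, flank: int = FLANK
) -> list[Interval]:
    """Grow each region by ``flank`` bp on both sides, clipped to
    ``[0, seq_len)`` — the segments handed to an LTR-boundary tool so the
    terminal repeats fall inside them."""
    out = []
    for r in regions:
        if r.interval.end > seq_len:
            raise ValueError(f"region {r.interval} exceeds sequence length {seq_len}")
        out.append(Interval(max(0, r.interval.start - flank), min(seq_len, r.interval.end + flank)))
    return out


def write_regions_fasta(
    intervals: Sequence[Interval], record: SequenceRecord, path: str | Path
) -> None:
    """Write extracted intervals as FASTA; record ids encode the source and
    1-based inclusive coordinates (``<id>:<start>-<end>``)."""
    recs = [
        SequenceRecord(
            id=f"{record.id}:{iv.start + 1}-{iv.end}",
            sequence=record.sequence[iv.start : iv.end],
        )
        for iv in intervals
    ]
    write_fasta(recs, path)


def write_regions_gff(regions: Sequence[InternalRegion], path: str | Path) -> None:
    """Write internal regions as GFF3 rows (type ``internal_region``) with
    the member count in the attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in sorted(regions, key=lambda r: (r.source_id, r.interval.start)):
            fh.write(
                f"{r.source_id}\tretrodetect\tinternal_region\t{r.interval.start + 1}\t"
                f"{r.interval.end}\t.\t+\t.\tn_domains={len(r.members)}\n"
            )
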