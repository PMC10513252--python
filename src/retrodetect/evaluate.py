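"""Evaluation: nucleotide-basis confusion counts and derived metrics,
precision-recall sweeps over the presence threshold, parity data for
domain start positions, COCO-style mAP@0.5 per class, inter-domain distance
statistics, and track plots of predictions against truth.

Nucleotide-basis means every count is measured in base pairs of overlap
between the union of predicted intervals and the union of true intervals —
detection quality is scored independently of classification.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from . import schema as S
from .labels import DomainAnnotation
from .postprocess import Interval, interval_iou, non_max_suppression
from .simulate import COPIA, GYPSY

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Nucleotide-basis confusion counts
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN in nucleotides over one evaluated length."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def accuracy(self) -> float | None:
        d = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / d if d else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    out: list[Interval] = []
    for iv in ivs:
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = Interval(out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def _covered(intervals: Sequence[Interval]) -> int:
    return sum(iv.length for iv in intervals)


def _intersection_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Total overlap between two *merged* interval lists (linear sweep)."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if hi > lo:
            total += hi - lo
        if a[i].end < b[j].end:
            i += 1
        else:
            j += 1
    return total


def nucleotide_confusion(
    pred: Sequence[Interval], truth: Sequence[Interval], total_len: int
) -> ConfusionCounts:
    """Confusion counts in nucleotides.  Overlapping intervals within either
    list are unioned first, so a double-covered base counts once."""
    for iv in list(pred) + list(truth):
        if iv.start < 0 or iv.end > total_len:
            raise ValueError(f"interval {iv} outside [0, {total_len})")
    p = merge_intervals(pred)
    t = merge_intervals(truth)
    tp = _intersection_length(p, t)
    fp = _covered(p) - tp
    fn = _covered(t) - tp
    tn = total_len - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def domains_to_intervals(domains: Iterable[DomainAnnotation]) -> list[Interval]:
    return [Interval(d.start, d.end) for d in domains]


def nucleotide_confusion_by_source(
    pred_domains: Sequence[DomainAnnotation],
    true_domains: Sequence[DomainAnnotation],
    total_len: int,
) -> ConfusionCounts:
    """Confusion counts over domains from several source sequences: overlap
    is measured per source and summed; ``total_len`` is the summed length of
    all evaluated sequence (the basis of the TN term)."""
    sources = {d.source_id for d in pred_domains} | {d.source_id for d in true_domains}
    tp = fp = fn = 0
    for s in sources:
        p = merge_intervals(Interval(d.start, d.end) for d in pred_domains if d.source_id == s)
        t = merge_intervals(Interval(d.start, d.end) for d in true_domains if d.source_id == s)
        i = _intersection_length(p, t)
        tp += i
        fp += _covered(p) - i
        fn += _covered(t) - i
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=max(total_len - tp - fp - fn, 0))


# ---------------------------------------------------------------------------
# Precision-recall sweep over the presence threshold
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float | None  # None where undefined (no predictions kept)
    recall: float | None


@dataclasses.dataclass(frozen=True)
class PRCurve:
    points: tuple[PRPoint, ...]
    best_threshold: float  # argmax of precision x recall over defined points


def pr_curve(
    raw_domains: Sequence[DomainAnnotation],
    truth: Sequence[Interval],
    total_len: int,
    thresholds: Sequence[float],
    nms_iou: float = 0.1,
    cluster: Callable[[Sequence[DomainAnnotation]], Sequence[Interval]] | None = None,
) -> PRCurve:
    """Sweep the presence threshold: filter raw calls, apply NMS, optionally
    map the surviving calls to intervals through ``cluster`` (e.g. internal
    regions), and score nucleotide precision/recall against ``truth``.

    Undefined precision (nothing kept) is recorded as missing, not 0.  The
    returned ``best_threshold`` maximizes precision x recall; ties break
    toward the lower threshold.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    points = []
    best_thr, best_prod = thresholds[0] if thresholds else 0.0, -1.0
    for thr in thresholds:
        kept = non_max_suppression(
            [d for d in raw_domains if d.presence_prob > thr], iou_threshold=nms_iou
        )
        intervals = list(cluster(kept)) if cluster is not None else domains_to_intervals(kept)
        cc = nucleotide_confusion(intervals, truth, total_len)
        points.append(PRPoint(threshold=thr, precision=cc.precision, recall=cc.recall))
        if cc.precision is not None and cc.recall is not None:
            prod = cc.precision * cc.recall
            if prod > best_prod:
                best_prod, best_thr = prod, thr
    return PRCurve(points=tuple(points), best_threshold=best_thr)


# ---------------------------------------------------------------------------
# Parity (predicted vs true start positions)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ParityData:
    """Matched (true start, predicted start) pairs plus the unmatched calls:
    false-positive starts go on the vertical axis of a parity plot,
    false-negative starts on the horizontal axis.  ``r_squared`` is the
    coefficient of determination over matched pairs only."""

    pairs: tuple[tuple[int, int], ...]
    fp_starts: tuple[int, ...]
    fn_starts: tuple[int, ...]
    r_squared: float | None


def parity(
    pred_domains: Sequence[DomainAnnotation], true_domains: Sequence[DomainAnnotation]
) -> ParityData:
    """Greedy one-to-one matching of predictions to overlapping truths.

    Predictions are visited in descending probability; each takes the
    still-unmatched overlapping truth whose start is nearest.  R^2 is
    1 - SS_res/SS_tot of predicted vs true starts over the matched pairs
    (1.0 when every pair is exact; None with fewer than 2 pairs or zero
    variance in the true starts with any residual).
    """
    order = sorted(range(len(pred_domains)),
                   key=lambda i: (-pred_domains[i].presence_prob, pred_domains[i].start))
    unmatched_truth = set(range(len(true_domains)))
    pairs: list[tuple[int, int]] = []
    fp: list[int] = []
    for i in order:
        p = pred_domains[i]
        best_j, best_dist = None, None
        for j in unmatched_truth:
            t = true_domains[j]
            if t.source_id != p.source_id:
                continue
            if min(p.end, t.end) - max(p.start, t.start) <= 0:
                continue
            dist = abs(p.start - t.start)
            if best_dist is None or dist < best_dist:
                best_j, best_dist = j, dist
        if best_j is None:
            fp.append(p.start)
        else:
            unmatched_truth.remove(best_j)
            pairs.append((true_domains[best_j].start, p.start))
    fn = [true_domains[j].start for j in sorted(unmatched_truth)]

    r2: float | None = None
    if pairs:
        t = np.array([a for a, _ in pairs], dtype=float)
        y = np.array([b for _, b in pairs], dtype=float)
        ss_res = float(((y - t) ** 2).sum())
        ss_tot = float(((t - t.mean()) ** 2).sum())
        if ss_tot > 0:
            r2 = 1.0 - ss_res / ss_tot
        elif ss_res == 0:
            r2 = 1.0
    return ParityData(
        pairs=tuple(pairs), fp_starts=tuple(fp), fn_starts=tuple(fn), r_squared=r2
    )


# ---------------------------------------------------------------------------
# COCO-style average precision at a single IoU threshold
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class APResult:
    per_class: Mapping[str, float]
    mean_ap: float
    class_contribution: Mapping[str, float]  # fraction of truth instances


def _average_precision(matched: Sequence[bool], n_truth: int) -> float:
    """101-point interpolated AP from a score-ordered match flag sequence."""
    if n_truth == 0:
        return 0.0
    tp = np.cumsum(np.asarray(matched, dtype=float))
    fp = np.cumsum(1.0 - np.asarray(matched, dtype=float))
    recall = tp / n_truth
    precision = tp / (tp + fp)
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recall >= r
        ap += precision[mask].max() if mask.any() else 0.0
    return ap / 101.0


def coco_map(
    pred_domains: Sequence[DomainAnnotation],
    true_domains: Sequence[DomainAnnotation],
    class_of: str | Callable[[DomainAnnotation], str] = "type",
    iou_threshold: float = 0.5,
) -> APResult:
    """Per-class interpolated AP with greedy IoU matching, averaged over the
    classes that have at least one truth instance.

    ``class_of`` selects the label: ``"type"`` (six domain types),
    ``"lineage"`` (thirteen lineages), or any callable.  Within a class,
    predictions are taken in descending probability; each matches the
    unmatched same-class truth of highest IoU if that IoU >= the threshold.
    """
    if class_of == "type":
        key: Callable[[DomainAnnotation], str] = lambda d: d.domain_type
        known = set(S.DOMAIN_TYPES)
    elif class_of == "lineage":
        key = lambda d: d.lineage
        known = set(S.LINEAGES)
    elif callable(class_of):
        key, known = class_of, None
    else:
        raise ValueError("class_of must be 'type', 'lineage', or a callable")

    if known is not None:
        for d in list(pred_domains) + list(true_domains):
            if key(d) not in known:
                raise ValueError(f"unknown class label {key(d)!r}")

    truth_by_class: dict[str, list[DomainAnnotation]] = {}
    for d in true_domains:
        truth_by_class.setdefault(key(d), []).append(d)
    pred_by_class: dict[str, list[DomainAnnotation]] = {}
    for d in pred_domains:
        pred_by_class.setdefault(key(d), []).append(d)

    per_class: dict[str, float] = {}
    for cls, truths in truth_by_class.items():
        preds = sorted(pred_by_class.get(cls, []),
                       key=lambda d: (-d.presence_prob, d.start))
        taken = [False] * len(truths)
        flags: list[bool] = []
        for p in preds:
            pi = Interval(p.start, p.end)
            best_j, best_iou = None, iou_threshold
            for j, t in enumerate(truths):
                if taken[j] or t.source_id != p.source_id:
                    continue
                iou = interval_iou(pi, Interval(t.start, t.end))
                if iou >= best_iou:
                    best_j, best_iou = j, iou
            if best_j is None:
                flags.append(False)
            else:
                taken[best_j] = True
                flags.append(True)
        per_class[cls] = _average_precision(flags, len(truths))

    n_total = len(true_domains)
    contribution = {c: len(v) / n_total for c, v in truth_by_class.items()} if n_total else {}
    mean_ap = float(np.mean(list(per_class.values()))) if per_class else 0.0
    return APResult(per_class=per_class, mean_ap=mean_ap, class_contribution=contribution)


def detection_f1(
    pred_domains: Sequence[DomainAnnotation],
    true_domains: Sequence[DomainAnnotation],
    iou_threshold: float = 0.5,
) -> ConfusionCounts:
    """Domain-level (not nucleotide-level) counts: predictions are matched
    greedily in descending probability to unmatched truths at interval
    IoU >= ``iou_threshold``, ignoring classification.  TN is 0 (undefined
    at domain level)."""
    taken = [False] * len(true_domains)
    tp = fp = 0
    for p in sorted(pred_domains, key=lambda d: (-d.presence_prob, d.start)):
        pi = Interval(p.start, p.end)
        best_j, best_iou = None, iou_threshold
        for j, t in enumerate(true_domains):
            if taken[j] or t.source_id != p.source_id:
                continue
            iou = interval_iou(pi, Interval(t.start, t.end))
            if iou >= best_iou:
                best_j, best_iou = j, iou
        if best_j is None:
            fp += 1
        else:
            taken[best_j] = True
            tp += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=taken.count(False), tn=0)


# ---------------------------------------------------------------------------
# Inter-domain distances
# ---------------------------------------------------------------------------

#: Canonical consecutive-pair labels per superfamily.  NEXT is the distance
#: from the named domain to whatever domain follows it (additional domains,
#: e.g. ENV, may precede the 3' LTR); PRE-LTR-3' is the distance from the
#: last domain to the 3' LTR.
PAIR_LABELS = {
    COPIA: ("5'-LTR-GAG", "GAG-AP", "AP-INT", "INT-RT", "RT-RH", "RH-NEXT", "PRE-LTR-3'"),
    GYPSY: ("5'-LTR-GAG", "GAG-AP", "AP-RT", "RT-RH", "RH-INT", "INT-NEXT", "PRE-LTR-3'"),
}

_CORE_ORDER = {COPIA: ("GAG", "AP", "INT", "RT", "RH"),
               GYPSY: ("GAG", "AP", "RT", "RH", "INT")}


@dataclasses.dataclass(frozen=True)
class DistanceTable:
    """Per pair-label distance samples (bp) and their means, keyed by
    superfamily then pair label."""

    distances: Mapping[str, Mapping[str, tuple[int, ...]]]
    n_skipped: int

    def means(self) -> dict[str, dict[str, float]]:
        return {
            sf: {lbl: float(np.mean(v)) for lbl, v in pairs.items() if v}
            for sf, pairs in self.distances.items()
        }


def domain_distances(
    elements: Sequence[
        tuple[str, Sequence[DomainAnnotation], tuple[Interval, Interval] | None]
    ],
) -> DistanceTable:
    """Distances between consecutive domains of each element.

    Each element is (superfamily, start-sorted domains, optional (5' LTR,
    3' LTR) intervals).  Distance is downstream.start - upstream.end (the
    spacer length).  Elements whose core domains are out of canonical order
    are skipped with a warning and counted in ``n_skipped``.
    """
    dist: dict[str, dict[str, list[int]]] = {
        sf: {lbl: [] for lbl in labels} for sf, labels in PAIR_LABELS.items()
    }
    skipped = 0
    for superfamily, domains, ltrs in elements:
        if superfamily not in PAIR_LABELS:
            raise ValueError(f"unknown superfamily {superfamily!r}")
        domains = sorted(domains, key=lambda d: d.start)
        order = _CORE_ORDER[superfamily]
        core = [d for d in domains if d.domain_type in order]
        core_types = [d.domain_type for d in core]
        if core_types != [t for t in order if t in core_types]:
            logger.warning("element domains out of canonical %s order: %s",
                           superfamily, core_types)
            skipped += 1
            continue
        table = dist[superfamily]
        by_type = {d.domain_type: d for d in core}
        # consecutive canonical pairs present in this element
        present = [t for t in order if t in by_type]
        for up, down in zip(present, present[1:]):
            if order.index(down) == order.index(up) + 1:
                table[f"{up}-{down}"].append(by_type[down].start - by_type[up].end)
        # NEXT: from the last core-order domain type to whatever follows it
        last_core = order[-1]
        if last_core in by_type:
            after = [d for d in domains if d.start >= by_type[last_core].end
                     and d is not by_type[last_core]]
            if after:
                table[f"{last_core}-NEXT"].append(after[0].start - by_type[last_core].end)
        if ltrs is not None and domains:
            ltr5, ltr3 = ltrs
            if "GAG" in by_type:
                table["5'-LTR-GAG"].append(by_type["GAG"].start - ltr5.end)
            table["PRE-LTR-3'"].append(ltr3.start - domains[-1].end)
    return DistanceTable(
        distances={sf: {k: tuple(v) for k, v in pairs.items()} for sf, pairs in dist.items()},
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Track visualization
# ---------------------------------------------------------------------------

#: Distinct color per domain type (GAG red, AP black, ENV green, RT blue,
#: RH light blue, INT orange).
TYPE_COLORS = {
    "GAG": "#d62728",
    "AP": "#000000",
    "INT": "#ff7f0e",
    "RT": "#1f77b4",
    "RH": "#17becf",
    "ENV": "#2ca02c",
}


def plot_tracks(
    pred_domains: Sequence[DomainAnnotation],
    true_domains: Sequence[DomainAnnotation],
    window_len: int,
    path: str | Path | None = None,
):
    """Two horizontal tracks — predictions above, truth below — with each
    domain drawn as a colored segment at its coordinates.  Returns the
    matplotlib figure; writes an image when ``path`` is given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.lines import Line2D

    fig, ax = plt.subplots(figsize=(10, 2.2))
    for track_y, domains in ((1.0, pred_domains), (0.0, true_domains)):
        for d in domains:
            ax.hlines(track_y, d.start, d.end, colors=TYPE_COLORS[d.domain_type], linewidth=6)
    ax.set_xlim(0, window_len)
    ax.set_ylim(-0.5, 1.5)
    ax.set_yticks([0.0, 1.0])
    ax.set_yticklabels(["truth", "predicted"])
    ax.set_xlabel("position (bp)")
    handles = [Line2D([0], [0], color=c, lw=4, label=t) for t, c in TYPE_COLORS.items()]
    ax.legend(handles=handles, ncol=6, fontsize=7, loc="upper center",
              bbox_to_anchor=(0.5, 1.35), frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def metrics_report(cc: ConfusionCounts) -> dict:
    return {
        "tp": cc.tp, "fp": cc.fp, "fn": cc.fn, "tn": cc.tn,
        "precision": cc.precision, "recall": cc.recall,
        "accuracy": cc.accuracy, "f1": cc.f1,
    }


def write_metrics_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
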