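"""End-to-end wiring: generate -> train -> predict -> cluster -> evaluate ->
distances, shared by the CLI and by scripted use.

A trained model is persisted as a bundle of three text-adjacent files:
``<stem>.npz`` (weights), ``<stem>.json`` (architecture) and
``<stem>.maxlen.json`` (the per-type maximum domain lengths the labels were
normalized with — required to decode predictions back to base pairs).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import schema as S
from .labels import DomainAnnotation, MaxLengthTable, decode_grid, encode_labels
from .network import Detector, LossWeights, ModelConfig, TrainConfig, train
from .postprocess import (CLUSTER_MAX_GAP, CLUSTER_MIN_DOMAINS, FLANK, NMS_IOU,
                          RAW_THRESHOLD, REPORT_THRESHOLD, InternalRegion,
                          cluster_domains, filter_by_probability,
                          non_max_suppression)
from .seqio import (SequenceRecord, one_hot_encode, read_fasta, slice_windows)
from .simulate import COPIA, GYPSY, GeneratorConfig


@dataclasses.dataclass(frozen=True)
class PostprocessConfig:
    raw_threshold: float = RAW_THRESHOLD
    report_threshold: float = REPORT_THRESHOLD
    nms_iou: float = NMS_IOU
    min_domains: int = CLUSTER_MIN_DOMAINS
    max_gap: int = CLUSTER_MAX_GAP
    flank: int = FLANK


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """One object holding every knob of the pipeline; defaults are the
    full-scale study conditions.  Serializable to a YAML file; CLI flags
    override file values."""

    generator: GeneratorConfig = GeneratorConfig()
    model: ModelConfig = ModelConfig()
    train: TrainConfig = TrainConfig()
    post: PostprocessConfig = PostprocessConfig()
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "generator": dataclasses.asdict(self.generator),
            "model": self.model.to_dict(),
            "train": {
                **{k: v for k, v in dataclasses.asdict(self.train).items() if k != "weights"},
                "split": list(self.train.split),
                "lambda_obj": self.train.weights.lambda_obj,
                "lambda_nonobj": self.train.weights.lambda_nonobj,
            },
            "post": dataclasses.asdict(self.post),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        tr = dict(d.get("train", {}))
        weights = LossWeights(
            lambda_obj=tr.pop("lambda_obj", 1.0),
            lambda_nonobj=tr.pop("lambda_nonobj", 0.06),
        )
        if "split" in tr:
            tr["split"] = tuple(tr["split"])
        return cls(
            generator=GeneratorConfig(**d.get("generator", {})),
            model=ModelConfig.from_dict(d["model"]) if "model" in d else ModelConfig(),
            train=TrainConfig(weights=weights, **tr),
            post=PostprocessConfig(**d.get("post", {})),
            seed=int(d.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# Model bundle persistence
# ---------------------------------------------------------------------------

def save_bundle(model: Detector, max_lengths: MaxLengthTable, stem: str | Path) -> None:
    stem = Path(stem)
    model.save(stem)
    Path(str(stem) + ".maxlen.json").write_text(
        json.dumps(dict(max_lengths), indent=2) + "\n"
    )


def load_bundle(stem: str | Path) -> tuple[Detector, dict[str, int]]:
    stem = Path(stem)
    if not stem.with_suffix(".npz").exists():
        raise FileNotFoundError(f"no model checkpoint at {stem}.npz")
    model = Detector.load(stem)
    max_lengths = {
        k: int(v) for k, v in json.loads(Path(str(stem) + ".maxlen.json").read_text()).items()
    }
    return model, max_lengths


# ---------------------------------------------------------------------------
# Inference over arbitrary FASTA
# ---------------------------------------------------------------------------

def predict_sequences(
    model: Detector,
    records: Sequence[SequenceRecord],
    max_lengths: MaxLengthTable,
    raw_threshold: float = RAW_THRESHOLD,
    nms_iou: float = NMS_IOU,
    report_threshold: float | None = REPORT_THRESHOLD,
    stride: int | None = None,
    batch_size: int = 8,
    scan_reverse: bool = False,
) -> list[DomainAnnotation]:
    """Scan sequences with the detector and return absolute-coordinate calls.

    Each sequence is sliced into model-sized windows (terminal partial
    windows are zero-padded; calls starting inside padding are dropped),
    decoded at the permissive ``raw_threshold``, de-duplicated with NMS in
    absolute coordinates (this also removes duplicates from overlapping
    windows), then filtered at ``report_threshold`` (None skips the final
    filter).  With ``scan_reverse`` the reverse complement is scanned too
    and hits are reported in forward coordinates.
    """
    W = model.config.window_len
    calls: list[DomainAnnotation] = []
    for rec in records:
        strands = [(rec, False)]
        if scan_reverse:
            from .seqio import reverse_complement
            strands.append(
                (SequenceRecord(id=rec.id, sequence=reverse_complement(rec.sequence)), True)
            )
        rec_calls: list[DomainAnnotation] = []
        for strand_rec, is_rev in strands:
            windows = slice_windows(strand_rec, W, stride)
            feats = np.stack([one_hot_encode(w, pad_to=W) for w in windows])
            grids = model.predict(feats, batch_size=batch_size)
            for w, grid in zip(windows, grids):
                for d in decode_grid(
                    grid, raw_threshold, max_lengths, source_id=rec.id,
                    window_offset=w.offset, cell_size=model.config.cell_size,
                    valid_len=w.length,
                ):
                    if is_rev:
                        # map back to forward coordinates
                        fwd_start = rec.length - d.end
                        if fwd_start < 0:
                            continue
                        d = dataclasses.replace(d, start=fwd_start)
                    if d.end > rec.length:
                        # decoded length (class-maximum scaled) may overrun
                        # the sequence end; clip to the record
                        if rec.length - d.start < 1:
                            continue
                        d = dataclasses.replace(d, length=rec.length - d.start)
                    rec_calls.append(d)
        rec_calls = non_max_suppression(rec_calls, iou_threshold=nms_iou)
        if report_threshold is not None:
            rec_calls = filter_by_probability(rec_calls, report_threshold)
        calls.extend(rec_calls)
    calls.sort(key=lambda d: (d.source_id, d.start))
    return calls


# ---------------------------------------------------------------------------
# Cluster-derived elements and superfamily inference
# ---------------------------------------------------------------------------

def infer_superfamily(members: Sequence[DomainAnnotation]) -> str | None:
    """Superfamily from the INT position relative to RT: INT before RT is
    Ty1/copia, INT after RT is Ty3/gypsy; None when either is absent."""
    ints = [d.start for d in members if d.domain_type == "INT"]
    rts = [d.start for d in members if d.domain_type == "RT"]
    if not ints or not rts:
        return None
    return COPIA if ints[0] < rts[0] else GYPSY


def regions_to_elements(regions: Sequence[InternalRegion]):
    """Turn clustered regions into (superfamily, domains, None) tuples for
    distance analysis, dropping regions whose superfamily is undecidable."""
    out = []
    for r in regions:
        sf = infer_superfamily(r.members)
        if sf is not None:
            out.append((sf, list(r.members), None))
    return out


def cluster_predictions(
    domains: Sequence[DomainAnnotation],
    min_domains: int = CLUSTER_MIN_DOMAINS,
    max_gap: int = CLUSTER_MAX_GAP,
) -> list[InternalRegion]:
    """Cluster calls per source sequence and concatenate the results."""
    by_source: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_source.setdefault(d.source_id, []).append(d)
    regions: list[InternalRegion] = []
    for source in sorted(by_source):
        regions.extend(cluster_domains(by_source[source], min_domains, max_gap))
    return regions


# ---------------------------------------------------------------------------
# Desk-scale end-to-end experiment
# ---------------------------------------------------------------------------

def run_desk_experiment(
    seed: int = 0,
    n_windows: int = 200,
    n_elements: int = 60,
    epochs: int = 20,
    thresholds: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 2)),
) -> dict:
    """Train and evaluate the detector on the 10x-reduced synthetic task:
    5 kb windows, desk-scale generator and training presets.

    The reporting threshold is chosen on the validation split as the argmax
    of nucleotide precision x recall (the same rule the full-scale pipeline
    uses); detection quality is then measured on the untouched test split as
    domain-level precision/recall/F1 with IoU >= 0.5 matching, ignoring
    classification.  Returns a dict with the training history, the selected
    threshold and the test-split metrics.
    """
    from .evaluate import detection_f1, nucleotide_confusion_by_source
    from .network.train import desk_scale_train_config
    from .simulate import (build_max_length_table, desk_scale_config,
                           generate_dataset, generate_fixture_library)

    library, background = generate_fixture_library(n_elements, seed)
    max_lengths = build_max_length_table(library)
    gen = desk_scale_config(seed=seed)
    feats, grids, windows = generate_dataset(library, background, n_windows, gen)

    model = Detector(
        ModelConfig(window_len=gen.window_len), seed=seed
    )
    model, history = train(model, feats, grids, desk_scale_train_config(seed=seed, epochs=epochs))

    def decode_split(idx, threshold):
        calls = []
        preds = model.predict(feats[idx], batch_size=16)
        for i, grid in zip(idx, preds):
            win_calls = decode_grid(
                np.asarray(grid, dtype=np.float64), RAW_THRESHOLD, max_lengths,
                source_id=windows[i].source_id, cell_size=S.DEFAULT_CELL_SIZE,
            )
            calls.extend(non_max_suppression(win_calls))
        return filter_by_probability(calls, threshold)

    # threshold selection on the validation split (nucleotide P x R)
    val_truth = [d for i in history.val_idx for d in windows[i].truth]
    val_total = len(history.val_idx) * gen.window_len
    best_thr, best_prod = thresholds[0], -1.0
    val_raw = decode_split(history.val_idx, 0.0)
    for thr in thresholds:
        cc = nucleotide_confusion_by_source(
            filter_by_probability(val_raw, thr), val_truth, val_total
        )
        if cc.precision is None or cc.recall is None:
            continue
        if cc.precision * cc.recall > best_prod:
            best_prod, best_thr = cc.precision * cc.recall, thr

    test_truth = [d for i in history.test_idx for d in windows[i].truth]
    test_calls = decode_split(history.test_idx, best_thr)
    cc = detection_f1(test_calls, test_truth, iou_threshold=0.5)
    return {
        "history": history,
        "best_threshold": float(best_thr),
        "test_counts": cc,
        "test_f1": cc.f1,
        "test_precision": cc.precision,
        "test_recall": cc.recall,
        "n_test_windows": int(history.test_idx.size),
        "model": model,
        "max_lengths": max_lengths,
    }


def write_run_log(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    import hashlib

    cfg_yaml = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    log = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "numpy_version": np.__version__,
    }
    if extra:
        log.update(extra)
    Path(path).write_text(json.dumps(log, indent=2, default=str) + "\n")
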