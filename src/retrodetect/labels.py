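"""Grid-label codec: domain annotations <-> per-cell 22-coordinate labels.

Each window is tiled into ``cell_size``-bp cells (100 bp by default).  A cell
whose span contains the *start* of a domain carries that domain's full label:
presence 1, the fractional start offset within the cell, the length
normalized by the per-type maximum over the reference library, and one-hot
type / lineage vectors.  Cells covered only by a domain's interior stay
zero — the label marks where domains begin, and the length coordinate
carries the extent.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import schema as S

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DomainAnnotation:
    """One ground-truth or predicted protein-coding domain.

    ``start`` is 0-based; whether it is absolute (genome/sequence) or
    window-relative is documented per call site.  ``presence_prob`` is 1 for
    ground truth.
    """

    source_id: str
    start: int
    length: int
    domain_type: str
    lineage: str
    presence_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("domain length must be positive")
        if self.start < 0:
            raise ValueError("domain start must be >= 0")

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length

    def shifted(self, delta: int) -> "DomainAnnotation":
        return dataclasses.replace(self, start=self.start + delta)


class UnknownClassError(ValueError):
    """A domain type or lineage name is not in the schema vocabulary."""


MaxLengthTable = Mapping[str, int]
"""Per-domain-type maximum length (bp) over the reference library; the
normalizer for the length coordinate."""


def validate_max_lengths(max_lengths: MaxLengthTable) -> None:
    missing = [t for t in S.DOMAIN_TYPES if t not in max_lengths]
    if missing:
        raise ValueError(f"max-length table lacks domain types: {missing}")
    bad = [t for t in S.DOMAIN_TYPES if max_lengths[t] <= 0]
    if bad:
        raise ValueError(f"max-length table has non-positive entries: {bad}")


def encode_labels(
    annotations: Iterable[DomainAnnotation],
    window_len: int,
    max_lengths: MaxLengthTable,
    cell_size: int = S.DEFAULT_CELL_SIZE,
) -> np.ndarray:
    """Encode window-relative annotations into a ``C x 22`` label grid.

    For an annotation starting at ``s``: cell index ``s // cell_size`` gets
    presence 1, relative start ``(s % cell_size) / cell_size``, normalized
    length ``min(length / max_lengths[type], 1)``, and the one-hot class
    vectors.  If two annotations start in the same cell (the label format
    admits one domain per cell) the longer one is kept and a warning logged.
    """
    if window_len % cell_size != 0:
        raise ValueError(f"window_len {window_len} not divisible by cell_size {cell_size}")
    validate_max_lengths(max_lengths)
    n_cells = window_len // cell_size
    grid = np.zeros((n_cells, S.N_COORDS), dtype=np.float64)
    occupant: dict[int, DomainAnnotation] = {}
    for ann in annotations:
        if ann.domain_type not in S.DOMAIN_TYPE_INDEX:
            raise UnknownClassError(f"unknown domain type {ann.domain_type!r}")
        if ann.lineage not in S.LINEAGE_INDEX:
            raise UnknownClassError(f"unknown lineage {ann.lineage!r}")
        if not 0 <= ann.start < window_len:
            raise ValueError(f"annotation start {ann.start} outside window of {window_len} bp")
        cell = ann.start // cell_size
        prev = occupant.get(cell)
        if prev is not None:
            logger.warning(
                "two domains start in cell %d (%s and %s); keeping the longer",
                cell, prev.domain_type, ann.domain_type,
            )
            if ann.length <= prev.length:
                continue
        occupant[cell] = ann
        row = np.zeros(S.N_COORDS, dtype=np.float64)
        row[S.IDX_PRESENCE] = 1.0
        row[S.IDX_START] = (ann.start % cell_size) / cell_size
        row[S.IDX_LENGTH] = min(ann.length / max_lengths[ann.domain_type], 1.0)
        row[3 + S.DOMAIN_TYPE_INDEX[ann.domain_type]] = 1.0
        row[3 + S.N_TYPES + S.LINEAGE_INDEX[ann.lineage]] = 1.0
        grid[cell] = row
    return grid


def _round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (unlike numpy's banker's round)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def decode_grid(
    grid: np.ndarray,
    presence_threshold: float,
    max_lengths: MaxLengthTable,
    source_id: str = "",
    window_offset: int = 0,
    cell_size: int = S.DEFAULT_CELL_SIZE,
    valid_len: int | None = None,
) -> list[DomainAnnotation]:
    """Decode a ``C x 22`` prediction grid into domain calls.

    Cells with presence ``p > presence_threshold`` emit a domain with
    absolute start ``window_offset + cell*cell_size + round(x*cell_size)``,
    length ``round(w * max_lengths[argmax type])``, argmax type and lineage,
    and presence probability ``p``.  ``valid_len`` (the unpadded window
    length) discards calls that start inside encoder padding.
    """
    if not 0.0 <= presence_threshold <= 1.0:
        raise ValueError("presence_threshold must lie in [0, 1]")
    validate_max_lengths(max_lengths)
    grid = np.asarray(grid)
    if grid.ndim != 2 or grid.shape[1] != S.N_COORDS:
        raise ValueError(f"expected a C x {S.N_COORDS} grid, got shape {grid.shape}")
    out: list[DomainAnnotation] = []
    hot = np.nonzero(grid[:, S.IDX_PRESENCE] > presence_threshold)[0]
    for cell in hot:
        row = grid[cell]
        rel_start = cell * cell_size + _round_half_away(float(row[S.IDX_START]) * cell_size)
        if valid_len is not None and rel_start >= valid_len:
            continue  # call starts inside padding
        t_idx = int(np.argmax(row[S.TYPE_SLICE]))
        l_idx = int(np.argmax(row[S.LINEAGE_SLICE]))
        dtype = S.DOMAIN_TYPES[t_idx]
        length = _round_half_away(float(row[S.IDX_LENGTH]) * max_lengths[dtype])
        if length <= 0:
            length = 1
        out.append(
            DomainAnnotation(
                source_id=source_id,
                start=window_offset + rel_start,
                length=length,
                domain_type=dtype,
                lineage=S.LINEAGES[l_idx],
                presence_prob=float(row[S.IDX_PRESENCE]),
            )
        )
    return out


def grid_is_valid(grid: np.ndarray) -> bool:
    """Check the ground-truth grid invariants: p in {0,1}; empty cells all
    zero; occupied cells have unit type and lineage one-hot segments,
    x in [0,1) and w in (0,1]."""
    grid = np.asarray(grid)
    p = grid[:, S.IDX_PRESENCE]
    if not np.all(np.isin(p, (0.0, 1.0))):
        return False
    empty = p == 0
    if not np.all(grid[empty] == 0):
        return False
    occ = grid[~empty]
    if occ.size == 0:
        return True
    return bool(
        np.all(occ[:, S.TYPE_SLICE].sum(axis=1) == 1)
        and np.all(occ[:, S.LINEAGE_SLICE].sum(axis=1) == 1)
        and np.all((occ[:, S.IDX_START] >= 0) & (occ[:, S.IDX_START] < 1))
        and np.all((occ[:, S.IDX_LENGTH] > 0) & (occ[:, S.IDX_LENGTH] <= 1))
    )
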