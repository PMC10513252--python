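"""Synthetic training/evaluation data: plant annotated LTR-RT elements into
TE-free background windows, and build a self-contained fixture library that
stands in for a curated TE database so nothing needs downloading.

A generated window is a fixed-length DNA string assembled left to right:
a gap of background, an element copied verbatim, a gap, the next element, …
Gap lengths are drawn uniformly from ``[gap_min, gap_max]``; placement stops
when the next element would not fit.  Each planted element contributes its
domain annotations, shifted by the insertion offset, to the window's ground
truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from . import schema as S
from .labels import DomainAnnotation, MaxLengthTable, encode_labels
from .seqio import SequenceRecord, write_fasta

COPIA = "Ty1/copia"
GYPSY = "Ty3/gypsy"

#: Canonical internal-domain order (5' to 3') per superfamily; the position
#: of INT relative to RT distinguishes the two.
DOMAIN_ORDER = {
    COPIA: ("GAG", "AP", "INT", "RT", "RH"),
    GYPSY: ("GAG", "AP", "RT", "RH", "INT"),
}

#: Lineages belonging to each superfamily (subset of the 13-lineage schema).
SUPERFAMILY_LINEAGES = {
    COPIA: ("ALE-RETROFIT", "ANGELA", "BIANCA", "IKEROS", "ORYCO-IVANA", "SIRE", "TORK-TAR"),
    GYPSY: ("ATHILA", "CRM", "DEL-TEKAY", "GALADRIEL", "REINA", "TAT"),
}


@dataclasses.dataclass(frozen=True)
class TELibraryEntry:
    """One reference LTR-RT element with domain annotations relative to the
    element's own sequence."""

    id: str
    sequence: str
    domains: tuple[DomainAnnotation, ...]
    superfamily: str

    def __post_init__(self) -> None:
        for d in self.domains:
            if d.end > len(self.sequence):
                raise ValueError(f"domain {d.domain_type} exceeds element {self.id}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class SyntheticWindow:
    """A generated window, its ground-truth (window-relative) domains and
    the recorded element insertions (library id, start, end)."""

    sequence: str
    truth: tuple[DomainAnnotation, ...]
    inserted_elements: tuple[tuple[str, int, int], ...]
    source_id: str = "synthetic"


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Window-generator settings.

    Defaults are the study conditions: 50 kb windows with inter-element gaps
    drawn uniformly from [3,000, 4,000] bp and a 0.1 fraction of windows
    built from background only.
    """

    window_len: int = S.DEFAULT_WINDOW_LEN
    gap_min: int = 3_000
    gap_max: int = 4_000
    negative_only_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gap_min <= self.gap_max < self.window_len):
            raise ValueError("need 0 < gap_min <= gap_max < window_len")
        if not 0.0 <= self.negative_only_fraction <= 1.0:
            raise ValueError("negative_only_fraction must lie in [0, 1]")


def desk_scale_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A 10x-reduced configuration for CPU-scale experiments: 5 kb windows
    and gaps scaled by the same factor to [300, 400] bp."""
    kw = dict(window_len=5_000, gap_min=300, gap_max=400, seed=seed)
    kw.update(overrides)
    return GeneratorConfig(**kw)


def build_max_length_table(library: Sequence[TELibraryEntry]) -> dict[str, int]:
    """Per-type maximum domain length over the library (the length
    normalizer for label encoding)."""
    if not library:
        raise ValueError("library is empty")
    table: dict[str, int] = {}
    for entry in library:
        for d in entry.domains:
            if d.length > table.get(d.domain_type, 0):
                table[d.domain_type] = d.length
    missing = [t for t in S.DOMAIN_TYPES if t not in table]
    if missing:
        raise ValueError(f"library lacks domain types: {missing}")
    return table


def _background(pool: Sequence[SequenceRecord], n: int, rng: np.random.Generator) -> str:
    """Concatenate random pool sequences (random starting record, cycled) to
    at least n bp and crop."""
    if not pool:
        raise ValueError("background pool is empty")
    total = sum(r.length for r in pool)
    if total == 0:
        raise ValueError("background pool has no sequence")
    parts: list[str] = []
    got = 0
    i = int(rng.integers(len(pool)))
    while got < n:
        parts.append(pool[i].sequence)
        got += pool[i].length
        i = (i + 1) % len(pool)
    return "".join(parts)[:n]


class _ElementSupply:
    """Without-replacement supply over the library: elements are dealt in a
    shuffled order until exhausted, then the library is reshuffled.  peek()
    lets the placer leave an element that does not fit for the next window."""

    def __init__(self, library: Sequence[TELibraryEntry], rng: np.random.Generator):
        if not library:
            raise ValueError("library is empty")
        self._library = library
        self._rng = rng
        self._order: list[int] = []

    def peek(self) -> TELibraryEntry:
        if not self._order:
            self._order = list(self._rng.permutation(len(self._library)))
        return self._library[self._order[-1]]

    def pop(self) -> TELibraryEntry:
        entry = self.peek()
        self._order.pop()
        return entry


def generate_synthetic_window(
    library: Sequence[TELibraryEntry],
    background_pool: Sequence[SequenceRecord],
    config: GeneratorConfig,
    rng: np.random.Generator,
    supply: "_ElementSupply | None" = None,
    window_id: str = "synthetic",
    negative_only: bool | None = None,
) -> SyntheticWindow:
    """Generate one window.

    ``supply``, when given, is the shared without-replacement element supply
    used by :func:`generate_dataset`; otherwise elements are drawn from
    ``library`` uniformly at random.  ``negative_only`` forces/suppresses a
    background-only window; by default it is drawn with probability
    ``config.negative_only_fraction``.
    """
    W = config.window_len
    seq = list(_background(background_pool, W, rng))
    if negative_only is None:
        negative_only = bool(rng.random() < config.negative_only_fraction)

    own_supply = supply is None
    truth: list[DomainAnnotation] = []
    inserted: list[tuple[str, int, int]] = []
    if not negative_only:
        if own_supply:
            supply = _ElementSupply(library, rng)
        pos = int(rng.integers(config.gap_min, config.gap_max + 1))
        while True:
            entry = supply.peek()
            if entry.length > W:
                raise ValueError(f"element {entry.id} ({entry.length} bp) exceeds the window")
            if pos + entry.length > W:
                break  # leave the element for the next window
            supply.pop()
            seq[pos : pos + entry.length] = entry.sequence
            inserted.append((entry.id, pos, pos + entry.length))
            truth.extend(dataclasses.replace(d, source_id=window_id).shifted(pos) for d in entry.domains)
            pos += entry.length + int(rng.integers(config.gap_min, config.gap_max + 1))
    return SyntheticWindow(
        sequence="".join(seq),
        truth=tuple(truth),
        inserted_elements=tuple(inserted),
        source_id=window_id,
    )


def generate_dataset(
    library: Sequence[TELibraryEntry],
    background_pool: Sequence[SequenceRecord],
    n_windows: int,
    config: GeneratorConfig,
    max_lengths: MaxLengthTable | None = None,
    cell_size: int = S.DEFAULT_CELL_SIZE,
) -> tuple[np.ndarray, np.ndarray, list[SyntheticWindow]]:
    """Generate aligned (features, labels, windows).

    Features are the one-hot matrices stacked as ``n x 4 x window_len``;
    labels the encoded grids stacked as ``n x C x 22``.  Exactly
    ``round(negative_only_fraction * n_windows)`` windows are background
    only (their positions chosen by the seeded rng).  Elements are consumed
    without replacement until the library is exhausted, then reshuffled.
    """
    from .seqio import one_hot_encode  # local import avoids cycle at module load

    if n_windows <= 0:
        raise ValueError("n_windows must be positive")
    if max_lengths is None:
        max_lengths = build_max_length_table(library)
    rng = np.random.default_rng(config.seed)

    n_neg = round(config.negative_only_fraction * n_windows)
    neg_mask = np.zeros(n_windows, dtype=bool)
    neg_mask[rng.permutation(n_windows)[:n_neg]] = True

    supply = _ElementSupply(library, rng)
    feats = np.empty((n_windows, 4, config.window_len), dtype=np.float32)
    grids = np.empty((n_windows, config.window_len // cell_size, S.N_COORDS), dtype=np.float64)
    windows: list[SyntheticWindow] = []
    for i in range(n_windows):
        win = generate_synthetic_window(
            library,
            background_pool,
            config,
            rng,
            supply=supply,
            window_id=f"w{i:05d}",
            negative_only=bool(neg_mask[i]),
        )
        windows.append(win)
        feats[i] = one_hot_encode(win.sequence)
        grids[i] = encode_labels(win.truth, config.window_len, max_lengths, cell_size)
    return feats, grids, windows


# ---------------------------------------------------------------------------
# Fixture library (synthetic stand-in for a curated TE database)
# ---------------------------------------------------------------------------

#: Per-type maximum (profile) domain length in bp for the fixture library.
FIXTURE_DOMAIN_LEN = {"GAG": 400, "AP": 220, "INT": 300, "RT": 350, "RH": 180, "ENV": 250}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(n: int, rng: np.random.Generator, p: Sequence[float] | None = None) -> str:
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    arr[hit] = _BASES[rng.integers(0, 4, size=hit.size)]
    return arr.tobytes().decode("ascii")


def generate_fixture_library(
    n_elements: int,
    rng: np.random.Generator | int,
    mutation_rate: float = 0.10,
    lineage_divergence: float = 0.15,
    include_env_prob: float = 0.25,
    n_background: int = 40,
    background_len: int = 2_000,
) -> tuple[list[TELibraryEntry], list[SequenceRecord]]:
    """Build a seeded synthetic TE library plus a TE-free background pool.

    Each domain type has one conserved GC-balanced profile sequence; each
    lineage derives type profiles by a fixed ``lineage_divergence`` fraction
    of substitutions; each element instance takes a random-length prefix
    (60–100% of the profile) further mutated at ``mutation_rate`` per
    position.  Domains are joined by 50–150 bp random linkers in the
    canonical superfamily order (copia: GAG-AP-INT-RT-RH; gypsy:
    GAG-AP-RT-RH-INT), with ENV optionally appended.  The background pool is
    drawn from an AT-rich composition so it is distinguishable from the
    elements.  This is a synthetic stand-in for a curated TE library, built
    so that the detection task is learnable; it makes no biological claim
    about real sequences.
    """
    if n_elements <= 0:
        raise ValueError("n_elements must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    type_profiles = {t: _random_dna(n, rng) for t, n in FIXTURE_DOMAIN_LEN.items()}
    lineage_profiles: dict[str, dict[str, str]] = {}
    lineage_super: dict[str, str] = {}
    for sf, lineages in SUPERFAMILY_LINEAGES.items():
        for lin in lineages:
            lineage_profiles[lin] = {
                t: _mutate(p, lineage_divergence, rng) for t, p in type_profiles.items()
            }
            lineage_super[lin] = sf

    all_lineages = list(lineage_profiles)
    # ENV is drawn per element; force it on the first so every domain type
    # is represented even in tiny libraries
    env_flags = [bool(rng.random() < include_env_prob) for _ in range(n_elements)]
    if not any(env_flags):
        env_flags[0] = True
    library: list[TELibraryEntry] = []
    for i in range(n_elements):
        lin = all_lineages[int(rng.integers(len(all_lineages)))]
        sf = lineage_super[lin]
        order = list(DOMAIN_ORDER[sf])
        if env_flags[i]:
            order.append("ENV")
        parts: list[str] = []
        domains: list[DomainAnnotation] = []
        pos = 0
        for t in order:
            linker = _random_dna(int(rng.integers(50, 151)), rng)
            parts.append(linker)
            pos += len(linker)
            profile = lineage_profiles[lin][t]
            dlen = int(rng.integers(int(0.6 * len(profile)), len(profile) + 1))
            dom_seq = _mutate(profile[:dlen], mutation_rate, rng)
            parts.append(dom_seq)
            domains.append(
                DomainAnnotation(
                    source_id=f"te{i:04d}", start=pos, length=dlen,
                    domain_type=t, lineage=lin,
                )
            )
            pos += dlen
        tail = _random_dna(int(rng.integers(50, 151)), rng)
        parts.append(tail)
        library.append(
            TELibraryEntry(
                id=f"te{i:04d}",
                sequence="".join(parts),
                domains=tuple(domains),
                superfamily=sf,
            )
        )

    at_rich = [0.35, 0.15, 0.15, 0.35]  # A, C, G, T
    background = [
        SequenceRecord(id=f"bg{j:03d}", sequence=_random_dna(background_len, rng, at_rich))
        for j in range(n_background)
    ]
    return library, background


# ---------------------------------------------------------------------------
# Library / dataset text interchange
# ---------------------------------------------------------------------------

def write_library(library: Sequence[TELibraryEntry], fasta_path: str | Path, table_path: str | Path) -> None:
    """Write a library as FASTA plus a side-car tab file (element id, domain
    start/end 1-based inclusive, type, lineage, superfamily)."""
    write_fasta([SequenceRecord(id=e.id, sequence=e.sequence) for e in library], fasta_path)
    with open(table_path, "w") as fh:
        fh.write("element_id\tstart\tend\tdomain_type\tlineage\tsuperfamily\n")
        for e in library:
            for d in e.domains:
                fh.write(f"{e.id}\t{d.start + 1}\t{d.end}\t{d.domain_type}\t{d.lineage}\t{e.superfamily}\n")


def read_library(fasta_path: str | Path, table_path: str | Path) -> list[TELibraryEntry]:
    """Read a library written by :func:`write_library`."""
    from .seqio import read_fasta

    seqs = {r.id: r.sequence for r in read_fasta(fasta_path)}
    domains: dict[str, list[DomainAnnotation]] = {}
    superfamily: dict[str, str] = {}
    with open(table_path) as fh:
        header = fh.readline()
        if not header.startswith("element_id"):
            raise ValueError(f"unexpected library-table header in {table_path}")
        for line in fh:
            if not line.strip():
                continue
            eid, s1, e1, t, lin, sf = line.rstrip("\n").split("\t")
            domains.setdefault(eid, []).append(
                DomainAnnotation(source_id=eid, start=int(s1) - 1,
                                 length=int(e1) - int(s1) + 1, domain_type=t, lineage=lin)
            )
            superfamily[eid] = sf
    return [
        TELibraryEntry(id=eid, sequence=seq, domains=tuple(domains.get(eid, ())),
                       superfamily=superfamily.get(eid, COPIA))
        for eid, seq in seqs.items()
    ]
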