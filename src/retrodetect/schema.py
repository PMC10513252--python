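"""Label-schema constants shared by every module.

The detector tiles an input window into fixed-size grid cells (100 bp by
default) and predicts, per cell, a 22-coordinate vector:

====  =======================================================
idx   meaning
====  =======================================================
0     presence probability p of a domain starting in the cell
1     relative start x of the domain within the cell, in [0, 1)
2     normalized length w = length / max length of that domain
      type across the reference library, in (0, 1]
3-8   one-hot over the six domain types
9-21  one-hot over the thirteen LTR-RT lineages
====  =======================================================
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

#: Internal protein-coding domain types of LTR retrotransposons, in label
#: order: capsid/nucleocapsid (GAG), aspartic proteinase (AP), integrase
#: (INT), reverse transcriptase (RT), ribonuclease H (RH) and the envelope
#: remnant (ENV).
DOMAIN_TYPES: tuple[str, ...] = ("GAG", "AP", "INT", "RT", "RH", "ENV")

#: Plant LTR-RT lineages, in label order.
LINEAGES: tuple[str, ...] = (
    "ALE-RETROFIT",
    "ANGELA",
    "ATHILA",
    "BIANCA",
    "CRM",
    "DEL-TEKAY",
    "GALADRIEL",
    "IKEROS",
    "ORYCO-IVANA",
    "REINA",
    "SIRE",
    "TAT",
    "TORK-TAR",
)

DOMAIN_TYPE_INDEX: dict[str, int] = {t: i for i, t in enumerate(DOMAIN_TYPES)}
LINEAGE_INDEX: dict[str, int] = {l: i for i, l in enumerate(LINEAGES)}

N_TYPES = len(DOMAIN_TYPES)        # 6
N_LINEAGES = len(LINEAGES)         # 13
N_COORDS = 3 + N_TYPES + N_LINEAGES  # 22

# Slices into the per-cell coordinate vector.
IDX_PRESENCE = 0
IDX_START = 1
IDX_LENGTH = 2
TYPE_SLICE = slice(3, 3 + N_TYPES)
LINEAGE_SLICE = slice(3 + N_TYPES, N_COORDS)

DEFAULT_CELL_SIZE = 100       # bp per grid cell
DEFAULT_WINDOW_LEN = 50_000   # bp per input window


@dataclasses.dataclass(frozen=True)
class LabelSchema:
    """Grid-label layout: cell size plus the class vocabularies.

    Serializable to a plain-text JSON file so that a trained model, its
    predictions and downstream evaluation always agree on the layout.
    """

    cell_size: int = DEFAULT_CELL_SIZE
    domain_types: tuple[str, ...] = DOMAIN_TYPES
    lineages: tuple[str, ...] = LINEAGES

    @property
    def n_coords(self) -> int:
        return 3 + len(self.domain_types) + len(self.lineages)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cell_size": self.cell_size,
                    "domain_types": list(self.domain_types),
                    "lineages": list(self.lineages),
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelSchema":
        d = json.loads(Path(path).read_text())
        return cls(
            cell_size=int(d["cell_size"]),
            domain_types=tuple(d["domain_types"]),
            lineages=tuple(d["lineages"]),
        )
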