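"""Reporter-library design: tiles, oligos, and barcode assignment.

Each TSS is assayed with two 144-bp tiles: one directly surrounding the TSS
(-114/+30 relative to the TSS on its own strand) and one slightly upstream
(-228/-84).  Every oligo is 200 bp: 144 bp of regulatory sequence, an 11-bp
barcode, and 45 bp of cloning adapter.  TSS tiles carry 13 barcodes, random
negative-control sequences 3, and positive-control tiles 60.

All genomic intervals are 0-based half-open (BED convention).  The tile
windows are interpreted so each tile has exactly 144 bases and tile1 contains
the TSS base itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

TILE_LENGTH = 144
BARCODE_LENGTH = 11
ADAPTER_LENGTH = 45
OLIGO_LENGTH = TILE_LENGTH + BARCODE_LENGTH + ADAPTER_LENGTH  # 200

#: barcode multiplicity per element class
DEFAULT_BARCODES_PER_CLASS = {"TSS": 13, "negative": 3, "positive": 60}

_BASES = np.array(list("ACGT"))


class DesignError(ValueError):
    """Raised on invalid tile coordinates or oligo components."""


@dataclass(frozen=True)
class TssRecord:
    chromosome: str
    position: int  # 0-based coordinate of the TSS base
    strand: str
    species: str = "human"
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise DesignError(f"TSS position must be >= 0, got {self.position}")
        if self.strand not in ("+", "-"):
            raise DesignError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class Tile:
    chromosome: str
    start: int  # 0-based, half-open
    end: int
    label: str  # "tile1" (TSS-overlapping) or "tile2" (upstream)
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class Oligo:
    regulatory_sequence: str
    barcode: str
    adapter_sequence: str

    @property
    def full_sequence(self) -> str:
        return self.regulatory_sequence + self.barcode + self.adapter_sequence


def design_tiles(tss: TssRecord) -> tuple[Tile, Tile]:
    """Return the TSS-overlapping tile (tile1) and the upstream tile (tile2).

    Plus strand: tile1 = [pos-114, pos+30), tile2 = [pos-228, pos-84).
    Minus strand: mirrored around the TSS so "upstream" lies rightward in
    genome coordinates: tile1 = [pos-29, pos+115), tile2 = [pos+85, pos+229).
    """
    pos = tss.position
    if tss.strand == "+":
        tile1 = Tile(tss.chromosome, pos - 114, pos + 30, "tile1", "+")
        tile2 = Tile(tss.chromosome, pos - 228, pos - 84, "tile2", "+")
    else:
        tile1 = Tile(tss.chromosome, pos - 29, pos + 115, "tile1", "-")
        tile2 = Tile(tss.chromosome, pos + 85, pos + 229, "tile2", "-")
    for tile in (tile1, tile2):
        if tile.start < 0:
            raise DesignError(
                f"tile {tile.label} for TSS at {pos} extends below coordinate 0"
            )
        assert tile.length == TILE_LENGTH
    return tile1, tile2


def assemble_oligo(tile_sequence: str, barcode: str, adapter: str) -> Oligo:
    """Assemble a 200-bp oligo from its 144/11/45-bp components."""
    expected = {
        "regulatory sequence": (tile_sequence, TILE_LENGTH),
        "barcode": (barcode, BARCODE_LENGTH),
        "adapter": (adapter, ADAPTER_LENGTH),
    }
    for name, (seq, want) in expected.items():
        if len(seq) != want:
            raise DesignError(f"{name} must be {want} bp, got {len(seq)} bp")
    oligo = Oligo(tile_sequence, barcode, adapter)
    assert len(oligo.full_sequence) == OLIGO_LENGTH
    return oligo


def generate_barcodes(n: int, rng: np.random.Generator, length: int = BARCODE_LENGTH) -> list[str]:
    """Generate ``n`` distinct random barcodes of the given length."""
    barcodes: dict[str, None] = {}
    while len(barcodes) < n:
        draw = rng.integers(0, 4, size=(n - len(barcodes), length))
        for row in draw:
            barcodes["".join(_BASES[row])] = None
    return list(barcodes)[:n]


def assign_barcodes(
    catalog: Iterable[tuple[str, str]],
    barcodes_per_class: Mapping[str, int] | None = None,
    barcode_pool: list[str] | None = None,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Assign distinct barcodes to every element of the catalog.

    Parameters
    ----------
    catalog
        Iterable of ``(element_id, element_class)`` with class in
        {"TSS", "negative", "positive"}.
    barcodes_per_class
        Multiplicity per class; defaults to 13/3/60.
    barcode_pool
        Optional explicit pool of unique barcodes; generated randomly when
        omitted (``seed`` controls the generator).

    Returns
    -------
    dict mapping element_id to its list of barcodes.  No barcode is reused
    across the whole library.
    """
    multiplicity = dict(barcodes_per_class or DEFAULT_BARCODES_PER_CLASS)
    elements = list(catalog)
    needed = 0
    for _, cls in elements:
        if cls not in multiplicity:
            raise DesignError(f"no barcode multiplicity configured for class {cls!r}")
        needed += multiplicity[cls]
    if barcode_pool is None:
        rng = np.random.default_rng(seed)
        barcode_pool = generate_barcodes(needed, rng)
    if len(set(barcode_pool)) != len(barcode_pool):
        raise DesignError("barcode pool contains duplicates")
    if len(barcode_pool) < needed:
        raise DesignError(
            f"barcode pool exhausted: need {needed}, have {len(barcode_pool)}"
        )
    out: dict[str, list[str]] = {}
    cursor = 0
    for element_id, cls in elements:
        k = multiplicity[cls]
        out[element_id] = barcode_pool[cursor : cursor + k]
        cursor += k
    return out
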