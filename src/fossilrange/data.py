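"""Stratigraphic age tables and presence/absence geography tables.

The geography reader accepts the classic Lagrange/BioGeoBEARS text dialect::

    2 3 (SA AF AU)
    T1 100
    T2 011

(header = ntaxa nareas, optional parenthesised area names; one presence
string per taxon), as well as a plain CSV with taxa as rows and areas as
columns.  Ranges are stored as bitmasks over the ordered area list.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "AgeTable",
    "GeographyTable",
    "parse_ages",
    "parse_geography",
    "write_geography",
]


class DataError(ValueError):
    pass


@dataclass
class AgeTable:
    """Per-taxon first (FAD) and last (LAD) appearance data, in Ma."""

    fad: dict[str, float]
    lad: dict[str, float]

    def __post_init__(self):
        for taxon, f in self.fad.items():
            l = self.lad.get(taxon)
            if l is None:
                raise DataError(f"taxon {taxon} missing LAD")
            if not (f >= l >= 0):
                raise DataError(
                    f"taxon {taxon}: FAD >= LAD >= 0 violated ({f}, {l})"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.fad)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.fad

    def subset(self, taxa: Iterable[str]) -> "AgeTable":
        taxa = list(taxa)
        return AgeTable({t: self.fad[t] for t in taxa},
                        {t: self.lad[t] for t in taxa})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon": self.taxa,
             "FAD": [self.fad[t] for t in self.taxa],
             "LAD": [self.lad[t] for t in self.taxa]}
        )

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False)


def parse_ages(text_or_path) -> AgeTable:
    """Read a CSV with columns taxon, FAD, LAD into an :class:`AgeTable`.

    An empty LAD cell is interpreted as a point occurrence (LAD = FAD).
    """
    buf = io.StringIO(text_or_path) if "\n" in str(text_or_path) or "," in str(
        text_or_path) else text_or_path
    df = pd.read_csv(buf)
    cols = {c.lower(): c for c in df.columns}
    for need in ("taxon", "fad", "lad"):
        if need not in cols:
            raise DataError(f"age table missing column '{need}'")
    fad, lad = {}, {}
    for _, row in df.iterrows():
        t = str(row[cols["taxon"]])
        f = float(row[cols["fad"]])
        l = row[cols["lad"]]
        l = f if pd.isna(l) else float(l)
        if l > f:
            raise DataError(f"taxon {t}: LAD {l} > FAD {f}")
        fad[t], lad[t] = f, l
    return AgeTable(fad, lad)


@dataclass
class GeographyTable:
    """Ordered area list plus a presence bitmask per taxon.

    Bit ``i`` of a mask corresponds to ``areas[i]``.  Every taxon must be
    present in at least one area (no null tip ranges).
    """

    areas: list[str]
    ranges: dict[str, int]

    def __post_init__(self):
        n = len(self.areas)
        if len(set(self.areas)) != n:
            raise DataError("duplicate area names")
        for taxon, mask in self.ranges.items():
            if mask == 0:
                raise DataError(f"taxon {taxon} has an empty range")
            if mask >> n:
                raise DataError(f"taxon {taxon} range exceeds area list")

    @property
    def nareas(self) -> int:
        return len(self.areas)

    @property
    def taxa(self) -> list[str]:
        return list(self.ranges)

    def mask(self, taxon: str) -> int:
        return self.ranges[taxon]

    def areas_of(self, taxon: str) -> list[str]:
        m = self.ranges[taxon]
        return [a for i, a in enumerate(self.areas) if m >> i & 1]

    def subset(self, taxa: Iterable[str]) -> "GeographyTable":
        return GeographyTable(list(self.areas),
                              {t: self.ranges[t] for t in taxa})

    def bits(self, taxon: str) -> str:
        return format(self.ranges[taxon], f"0{self.nareas}b")[::-1]


def parse_geography(text: str) -> GeographyTable:
    """Parse the Lagrange-style dialect (see module docstring)."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DataError("empty geography file")
    header = lines[0]
    areas: list[str]
    if "(" in header:
        head, _, names = header.partition("(")
        names = names.rstrip(")").strip()
        areas = names.split()
    else:
        head, areas = header, []
    parts = head.split()
    if len(parts) < 2:
        raise DataError(f"bad geography header: {header!r}")
    ntaxa, nareas = int(parts[0]), int(parts[1])
    if not areas:
        areas = [f"A{i}" for i in range(nareas)]
    if len(areas) != nareas:
        raise DataError("header area-name count does not match nareas")
    body = lines[1:]
    if len(body) != ntaxa:
        raise DataError(f"expected {ntaxa} taxon rows, found {len(body)}")
    ranges: dict[str, int] = {}
    for ln in body:
        try:
            taxon, bits = ln.split(maxsplit=1)
        except ValueError:
            raise DataError(f"bad geography row: {ln!r}") from None
        bits = bits.replace(" ", "")
        if len(bits) != nareas:
            raise DataError(
                f"taxon {taxon}: presence string length {len(bits)} != "
                f"nareas {nareas}"
            )
        if set(bits) - {"0", "1"}:
            raise DataError(
                f"taxon {taxon}: presence string may contain only 0/1 "
                f"(ambiguity codes unsupported)"
            )
        mask = sum(1 << i for i, b in enumerate(bits) if b == "1")
        if mask == 0:
            raise DataError(f"taxon {taxon}: empty range")
        if taxon in ranges:
            raise DataError(f"duplicate taxon {taxon}")
        ranges[taxon] = mask
    return GeographyTable(areas, ranges)


def write_geography(geo: GeographyTable) -> str:
    lines = [f"{len(geo.taxa)} {geo.nareas} ({' '.join(geo.areas)})"]
    for t in geo.taxa:
        lines.append(f"{t} {geo.bits(t)}")
    return "\n".join(lines) + "\n"


def geography_from_frame(df: pd.DataFrame) -> GeographyTable:
    """Build a GeographyTable from a 0/1 DataFrame (taxa x areas)."""
    areas = [str(c) for c in df.columns]
    ranges = {}
    for taxon, row in df.iterrows():
        ranges[str(taxon)] = sum(1 << i for i, v in enumerate(row) if int(v))
    return GeographyTable(areas, ranges)
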