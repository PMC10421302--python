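"""Digital molecular ID cards: per-marker genotype codebooks and fixed-length
numeric fingerprints.

Each marker's distinct genotype patterns (sorted allele-size tuples) are
assigned two-digit codes "01".."99" in ascending lexicographic order of the
pattern; "00" is reserved for missing/undetectable typing. A sample's ID is
the concatenation of its per-marker codes in a fixed marker order, so a
12-marker panel yields a 24-digit ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .popgen import GenotypeTable

__all__ = [
    "Codebook",
    "CodebookCapacityError",
    "EncodingError",
    "build_codebook",
    "encode_ids",
    "decode_id",
    "check_uniqueness",
]

MISSING_CODE = "00"


class CodebookCapacityError(ValueError):
    """More than 99 distinct genotype patterns at one marker."""


class EncodingError(KeyError):
    """A sample's pattern is absent from the codebook."""


@dataclass
class Codebook:
    marker_order: list[str]
    codes: dict[str, dict[tuple[int, ...], str]]

    def patterns(self, marker: str) -> dict[str, tuple[int, ...]]:
        """Inverse map code -> pattern for one marker."""
        return {c: p for p, c in self.codes[marker].items()}

    def to_json_obj(self) -> dict:
        return {
            "marker_order": self.marker_order,
            "codes": {
                m: {"/".join(map(str, p)): c for p, c in table.items()}
                for m, table in self.codes.items()
            },
        }

    @classmethod
    def from_json_obj(cls, obj: Mapping) -> "Codebook":
        codes = {
            m: {
                tuple(int(x) for x in p.split("/")): c for p, c in table.items()
            }
            for m, table in obj["codes"].items()
        }
        return cls(marker_order=list(obj["marker_order"]), codes=codes)


def build_codebook(
    table: GenotypeTable, marker_order: list[str] | None = None
) -> Codebook:
    """Assign codes "01", "02", ... to each marker's patterns in ascending
    lexicographic order of the sorted allele-size tuple (deterministic)."""
    marker_order = list(marker_order) if marker_order is not None else list(table.markers)
    for m in marker_order:
        if m not in table.markers:
            raise KeyError(f"marker {m!r} not present in the genotype table")
    codes: dict[str, dict[tuple[int, ...], str]] = {}
    for m in marker_order:
        patterns = sorted({table.cell(s, m) for s in table.samples if table.cell(s, m)})
        if len(patterns) > 99:
            raise CodebookCapacityError(
                f"marker {m!r} has {len(patterns)} patterns; two digits allow 99"
            )
        codes[m] = {p: f"{i:02d}" for i, p in enumerate(patterns, start=1)}
    return Codebook(marker_order=marker_order, codes=codes)


def encode_ids(table: GenotypeTable, codebook: Codebook) -> dict[str, str]:
    """Encode every sample as a 2*len(marker_order)-digit ID string."""
    ids: dict[str, str] = {}
    for s in table.samples:
        parts = []
        for m in codebook.marker_order:
            cell = table.cell(s, m)
            if not cell:
                parts.append(MISSING_CODE)
                continue
            code = codebook.codes[m].get(cell)
            if code is None:
                raise EncodingError(
                    f"pattern {cell} of sample {s!r} at marker {m!r} "
                    "is absent from the codebook"
                )
            parts.append(code)
        ids[s] = "".join(parts)
    return ids


def decode_id(id_string: str, codebook: Codebook) -> dict[str, tuple[int, ...] | None]:
    """Recover per-marker genotype patterns from an ID (None where missing)."""
    if len(id_string) != 2 * len(codebook.marker_order):
        raise ValueError(
            f"ID length {len(id_string)} != 2 x {len(codebook.marker_order)} markers"
        )
    out: dict[str, tuple[int, ...] | None] = {}
    for i, m in enumerate(codebook.marker_order):
        code = id_string[2 * i : 2 * i + 2]
        if code == MISSING_CODE:
            out[m] = None
        else:
            inverse = codebook.patterns(m)
            if code not in inverse:
                raise ValueError(f"unknown code {code!r} for marker {m!r}")
            out[m] = inverse[code]
    return out


def check_uniqueness(ids: Mapping[str, str]) -> list[list[str]]:
    """Groups of samples sharing an identical ID (empty iff all unique)."""
    groups: dict[str, list[str]] = {}
    for sample, id_string in ids.items():
        groups.setdefault(id_string, []).append(sample)
    return [sorted(g) for _id, g in sorted(groups.items()) if len(g) > 1]
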