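"""Per-marker diversity statistics from SSR genotype tables.

A genotype table holds, per sample and marker, the multiset of observed
allele fragment sizes (bp); samples may be diploid or triploid. Statistics
follow the standard definitions:

* Na — number of distinct observed alleles,
* Ne — effective number of alleles, 1 / sum(p_i^2),
* Ho — observed heterozygosity, the fraction of typed samples carrying at
  least two distinct alleles,
* He — Nei's gene diversity (expected heterozygosity), 1 - sum(p_i^2);
  an unbiased small-sample corrected variant (2n/(2n-1)) is available,
* PIC — polymorphism information content (Botstein et al.),
  1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2; values > 0.5 mark a highly
  informative marker.

Allele frequencies count each typed sample's alleles with the multiplicity
recorded in its cell (a triploid cell contributes three copies).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenotypeTable",
    "MarkerStats",
    "PanelSummary",
    "NoDataError",
    "allele_frequencies",
    "marker_stats",
    "stats_from_frequencies",
    "panel_summary",
    "load_marker_stats_table",
]

MISSING_TOKENS = {"", "00", "0", "NA", "."}


class NoDataError(ValueError):
    """A marker has no typed samples at all."""


@dataclass
class GenotypeTable:
    """samples x markers table of allele-size multisets; ploidy-aware."""

    samples: list[str]
    markers: list[str]
    cells: dict[tuple[str, str], tuple[int, ...]]
    ploidy: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.samples:
            self.ploidy.setdefault(s, 2)
        for (s, m), alleles in list(self.cells.items()):
            alleles = tuple(sorted(int(a) for a in alleles))
            if any(a <= 0 for a in alleles):
                raise ValueError(f"non-positive allele size in cell ({s}, {m})")
            if len(alleles) > self.ploidy[s]:
                raise ValueError(
                    f"cell ({s}, {m}) has {len(alleles)} alleles but sample "
                    f"ploidy is {self.ploidy[s]}"
                )
            self.cells[(s, m)] = alleles

    def cell(self, sample: str, marker: str) -> tuple[int, ...]:
        return self.cells.get((sample, marker), ())

    def typed_samples(self, marker: str) -> list[str]:
        return [s for s in self.samples if self.cell(s, marker)]

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "GenotypeTable":
        """Read a delimited table: rows = samples, columns = markers,
        cell = '/'-joined allele sizes ('245/251'); empty or '00' = missing.
        An optional 'ploidy' column sets per-sample ploidy (default 2)."""
        with open(path, "rt") as fh:
            lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
        header = lines[0].split("\t")
        markers = [c for c in header[1:] if c.lower() != "ploidy"]
        ploidy_col = next((i for i, c in enumerate(header) if c.lower() == "ploidy"), None)
        samples: list[str] = []
        cells: dict[tuple[str, str], tuple[int, ...]] = {}
        ploidy: dict[str, int] = {}
        for line in lines[1:]:
            fields = line.split("\t")
            sample = fields[0]
            samples.append(sample)
            if ploidy_col is not None:
                ploidy[sample] = int(fields[ploidy_col])
            mi = 0
            for i, value in enumerate(fields[1:], start=1):
                if ploidy_col is not None and i == ploidy_col:
                    continue
                marker = markers[mi]
                mi += 1
                value = value.strip()
                if value in MISSING_TOKENS:
                    continue
                alleles = tuple(int(a) for a in value.split("/") if a not in MISSING_TOKENS)
                if alleles:
                    cells[(sample, marker)] = alleles
        table = cls(samples=samples, markers=markers, cells=cells, ploidy=ploidy)
        return table

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "wt") as fh:
            fh.write("sample\tploidy\t" + "\t".join(self.markers) + "\n")
            for s in self.samples:
                row = [s, str(self.ploidy[s])]
                for m in self.markers:
                    cell = self.cell(s, m)
                    row.append("/".join(str(a) for a in cell) if cell else "00")
                fh.write("\t".join(row) + "\n")


def allele_frequencies(
    table: GenotypeTable, marker: str, diploid_only: bool = False
) -> dict[int, float]:
    """Allele frequencies at a marker over typed samples (copy counting)."""
    counts: dict[int, int] = {}
    total = 0
    for s in table.samples:
        if diploid_only and table.ploidy[s] != 2:
            continue
        for a in table.cell(s, marker):
            counts[a] = counts.get(a, 0) + 1
            total += 1
    if total == 0:
        raise NoDataError(f"marker {marker!r} has no typed samples")
    return {a: c / total for a, c in sorted(counts.items())}


@dataclass
class MarkerStats:
    """One marker's diversity summary (a row of a panel-characteristics table)."""

    marker_id: str
    na: int
    ne: float
    ho: float
    he: float
    pic: float
    n_typed: int = 0
    allele_freqs: dict[int, float] | None = None


def _pic(freqs: Sequence[float]) -> float:
    s2 = sum(p * p for p in freqs)
    cross = 0.0
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            cross += 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    return 1.0 - s2 - cross


def stats_from_frequencies(freqs: Mapping[int, float] | Sequence[float]) -> tuple[int, float, float, float]:
    """(Na, Ne, He, PIC) from an allele-frequency vector."""
    p = list(freqs.values()) if isinstance(freqs, Mapping) else list(freqs)
    if not p or not math.isclose(sum(p), 1.0, abs_tol=1e-6):
        raise ValueError("allele frequencies must sum to 1")
    s2 = sum(x * x for x in p)
    return len(p), 1.0 / s2, 1.0 - s2, _pic(p)


def marker_stats(
    table: GenotypeTable,
    marker: str,
    unbiased_he: bool = False,
    diploid_only: bool = False,
) -> MarkerStats:
    """Compute Na, Ne, Ho, He and PIC for one marker."""
    freqs = allele_frequencies(table, marker, diploid_only=diploid_only)
    na, ne, he, pic = stats_from_frequencies(freqs)
    typed = [
        s
        for s in table.typed_samples(marker)
        if not (diploid_only and table.ploidy[s] != 2)
    ]
    n_copies = sum(len(table.cell(s, marker)) for s in typed)
    if unbiased_he and n_copies > 1:
        he = he * n_copies / (n_copies - 1)
    het = sum(1 for s in typed if len(set(table.cell(s, marker))) >= 2)
    ho = het / len(typed)
    return MarkerStats(
        marker_id=marker,
        na=na,
        ne=ne,
        ho=ho,
        he=he,
        pic=pic,
        n_typed=len(typed),
        allele_freqs=freqs,
    )


@dataclass
class PanelSummary:
    """Across-marker totals, unweighted means and ranges of the statistics."""

    n_markers: int
    total_alleles: int
    mean: dict[str, float]
    min: dict[str, tuple[str, float]]
    max: dict[str, tuple[str, float]]

    def format_table(self) -> str:
        lines = ["stat\tmean\tmin(marker)\tmax(marker)"]
        for k in ("na", "ne", "ho", "he", "pic"):
            lines.append(
                f"{k}\t{self.mean[k]:.4g}\t{self.min[k][1]:.4g} ({self.min[k][0]})\t"
                f"{self.max[k][1]:.4g} ({self.max[k][0]})"
            )
        lines.append(f"total alleles\t{self.total_alleles}")
        return "\n".join(lines)


def panel_summary(stats: Iterable[MarkerStats]) -> PanelSummary:
    stats = list(stats)
    if not stats:
        raise ValueError("panel_summary needs at least one marker")
    mean: dict[str, float] = {}
    lo: dict[str, tuple[str, float]] = {}
    hi: dict[str, tuple[str, float]] = {}
    for key in ("na", "ne", "ho", "he", "pic"):
        values = [(getattr(st, key), st.marker_id) for st in stats]
        mean[key] = sum(v for v, _ in values) / len(values)
        vmin = min(values)
        vmax = max(values)
        lo[key] = (vmin[1], vmin[0])
        hi[key] = (vmax[1], vmax[0])
    return PanelSummary(
        n_markers=len(stats),
        total_alleles=sum(st.na for st in stats),
        mean=mean,
        min=lo,
        max=hi,
    )


def load_marker_stats_table(path: str | os.PathLike) -> list[MarkerStats]:
    """Read a published panel-characteristics TSV (marker, Na, Ne, Ho, He, PIC)."""
    stats: list[MarkerStats] = []
    with open(path, "rt") as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = [c.strip().lower() for c in line.split("\t")]
                continue
            row = dict(zip(header, line.split("\t")))
            stats.append(
                MarkerStats(
                    marker_id=row["marker"],
                    na=int(row["na"]),
                    ne=float(row["ne"]),
                    ho=float(row["ho"]),
                    he=float(row["he"]),
                    pic=float(row["pic"]),
                )
            )
    return stats
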