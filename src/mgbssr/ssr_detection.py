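"""Perfect microsatellite (SSR) detection with 3-6 nt motifs.

A reported locus is a maximal perfect tandem run of a *primitive* motif
(one that is not itself a repetition of a shorter motif): the run cannot be
extended by one full motif copy on either side, and partial trailing copies
are not part of the core. Runs containing N are split at the N. When maximal
runs overlap (a long run always contains shorter runs of its cyclic
rotations), the leftmost-then-longest run wins, so reported loci never
overlap and each repeat tract is reported exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .sequence_io import GenomeSequence, reverse_complement

__all__ = [
    "SSRLocus",
    "SSRSummary",
    "detect_ssrs",
    "summarize_ssrs",
    "is_primitive",
    "canonical_motif",
    "DEFAULT_MOTIF_LENGTHS",
    "DEFAULT_MIN_REPEATS",
]

DEFAULT_MOTIF_LENGTHS: tuple[int, ...] = (3, 4, 5, 6)
DEFAULT_MIN_REPEATS = 4


@dataclass(frozen=True, order=True)
class SSRLocus:
    """One perfect SSR occurrence on the forward strand, 0-based half-open."""

    genome_label: str
    seq_id: str
    start: int
    end: int
    motif: str
    repeat_count: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.repeat_count:
            raise ValueError(
                f"interval length {self.end - self.start} != "
                f"len(motif) x repeat_count = {len(self.motif) * self.repeat_count}"
            )

    @property
    def core_seq(self) -> str:
        return self.motif * self.repeat_count

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def canonical(self) -> str:
        return canonical_motif(self.motif)


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter motif."""
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical key of a motif's cyclic-rotation + reverse-complement class.

    Loci are *reported* with the motif as spelled in the genome; this key is
    only for optional deduplication/grouping across strands and phases.
    """
    rc = reverse_complement(motif)
    variants = [motif[i:] + motif[:i] for i in range(len(motif))]
    variants += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(variants)


def _min_repeats_map(
    min_repeats: int | Mapping[int, int], motif_lengths: Iterable[int]
) -> dict[int, int]:
    if isinstance(min_repeats, Mapping):
        table = {int(k): int(v) for k, v in min_repeats.items()}
    else:
        table = {k: int(min_repeats) for k in motif_lengths}
    for k in motif_lengths:
        if k not in table:
            raise ValueError(f"no min_repeats threshold for motif length {k}")
        if table[k] < 2:
            raise ValueError("min_repeats must be >= 2")
    return table


def _segments(seq: str) -> Iterator[tuple[int, str]]:
    """Yield (offset, subsequence) for maximal N-free stretches."""
    start = None
    for i, ch in enumerate(seq):
        if ch == "N":
            if start is not None:
                yield start, seq[start:i]
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, seq[start:]


def _candidate_runs(
    seq: str, motif_lengths: Iterable[int], min_repeats: Mapping[int, int]
) -> list[tuple[int, int, str, int]]:
    """All left-maximal whole-unit runs of primitive motifs above threshold.

    Returns (start, end, motif, count) tuples; may contain overlapping runs
    (rotations of one tract) — selection happens afterwards.
    """
    out: list[tuple[int, int, str, int]] = []
    for off, seg in _segments(seq):
        n = len(seg)
        for k in sorted(motif_lengths):
            thr = min_repeats[k]
            limit = n - 2 * k
            i = 0
            while i <= limit:
                motif = seg[i : i + k]
                if seg[i + k : i + 2 * k] == motif:
                    # left-maximality: preceding k characters are not the motif
                    if i >= k and seg[i - k : i] == motif:
                        i += 1
                        continue
                    j = i + 2 * k
                    while seg[j : j + k] == motif:
                        j += k
                    count = (j - i) // k
                    if count >= thr and is_primitive(motif):
                        out.append((off + i, off + j, motif, count))
                i += 1
    return out


def select_nonoverlapping(
    runs: list[tuple[int, int, str, int]]
) -> list[tuple[int, int, str, int]]:
    """Greedy leftmost-then-longest selection; ties broken by shorter motif."""
    runs = sorted(runs, key=lambda r: (r[0], r[0] - r[1], len(r[2]), r[2]))
    chosen: list[tuple[int, int, str, int]] = []
    last_end = -1
    for r in runs:
        if r[0] >= last_end:
            chosen.append(r)
            last_end = r[1]
    return chosen


def detect_ssrs(
    genome: GenomeSequence,
    motif_lengths: Iterable[int] = DEFAULT_MOTIF_LENGTHS,
    min_repeats: int | Mapping[int, int] = DEFAULT_MIN_REPEATS,
) -> list[SSRLocus]:
    """Find all perfect SSRs in a genome (forward strand, sorted by position).

    Parameters
    ----------
    genome : GenomeSequence
    motif_lengths : iterable of int
        Motif sizes to search, each in 1..6 (defaults to 3-6).
    min_repeats : int or mapping {motif length: int}
        Minimum number of whole motif copies (>= 2); default 4.
    """
    lengths = sorted(set(int(k) for k in motif_lengths))
    for k in lengths:
        if not 1 <= k <= 6:
            raise ValueError(f"motif length {k} outside supported range 1..6")
    table = _min_repeats_map(min_repeats, lengths)
    loci: list[SSRLocus] = []
    for seq_id, seq in genome.records.items():
        runs = _candidate_runs(seq, lengths, table)
        for start, end, motif, count in select_nonoverlapping(runs):
            loci.append(
                SSRLocus(
                    genome_label=genome.genome_label,
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    motif=motif,
                    repeat_count=count,
                )
            )
    loci.sort(key=lambda l: (l.seq_id, l.start))
    return loci


@dataclass
class SSRSummary:
    """Per-genome SSR counts and percentages by motif length."""

    genome_label: str
    counts: dict[int, int]
    total: int

    @property
    def percentages(self) -> dict[int, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * c / self.total for k, c in self.counts.items()}

    def format_table(self) -> str:
        lines = [f"Genome: {self.genome_label}"]
        lines.append("motif_len\tcount\tpercent")
        pct = self.percentages
        for k in sorted(self.counts):
            lines.append(f"{k}\t{self.counts[k]}\t{pct[k]:.2f}%")
        lines.append(f"total\t{self.total}\t100.00%" if self.total else "total\t0\t0%")
        return "\n".join(lines)


def summarize_ssrs(loci: list[SSRLocus], genome: GenomeSequence) -> SSRSummary:
    """Tabulate loci by motif length (counts and percentages of the total)."""
    for loc in loci:
        if loc.genome_label != genome.genome_label:
            raise ValueError(
                f"locus from genome {loc.genome_label!r} does not belong to "
                f"{genome.genome_label!r}"
            )
    lengths = sorted({len(l.motif) for l in loci}) or list(DEFAULT_MOTIF_LENGTHS)
    counts = {k: 0 for k in lengths}
    for loc in loci:
        counts[len(loc.motif)] += 1
    return SSRSummary(genome_label=genome.genome_label, counts=counts, total=len(loci))
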