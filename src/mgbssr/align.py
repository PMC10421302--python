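"""Seed-and-extend local search of a query against a genome.

The screen's contract is "find the orthologous flank block", not BLAST
specifically: exact k-mer seeds are clustered by diagonal, and each candidate
window is refined with a banded gapped alignment (edlib, infix mode) from
which identity is read off the alignment path. Minus-strand hits are found by
searching the reverse complement of the query and are reported in forward
coordinates of the target with strand '-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .sequence_io import GenomeSequence, reverse_complement

__all__ = ["GenomeHit", "search_genome", "alignment_identity", "SeedIndex"]

DEFAULT_SEED_LEN = 15
_WINDOW_PAD = 40


class ParameterError(ValueError):
    pass


@dataclass
class GenomeHit:
    """One local hit of a query in a target genome.

    ``flank_identity`` is matches / aligned columns of this hit's alignment;
    for screen hits it covers flank columns only (the SSR core is excised
    before alignment). ``target_repeat_count`` is filled by the screen.
    """

    target_genome: str
    seq_id: str
    start: int
    end: int
    strand: str
    flank_identity: float
    query_coverage: float = 1.0
    target_repeat_count: int = 0

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


class SeedIndex:
    """Exact k-mer position index over a genome, built lazily and cached
    on the genome object itself."""

    def __init__(self, genome: GenomeSequence, k: int):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for seq_id, seq in genome.records.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((seq_id, i))

    @classmethod
    def for_genome(cls, genome: GenomeSequence, k: int) -> "SeedIndex":
        cache = genome.__dict__.setdefault("_seed_indexes", {})
        idx = cache.get(k)
        if idx is None:
            idx = cls(genome, k)
            cache[k] = idx
        return idx


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, aligned columns) from an edlib extended cigar."""
    matches = 0
    columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches, columns


def alignment_identity(query: str, target_window: str) -> tuple[float, tuple[int, int]] | None:
    """Best infix alignment of query in window: (identity, window-local interval)."""
    res = edlib.align(query, target_window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    matches, columns = _cigar_stats(res["cigar"])
    if columns == 0:
        return None
    s, e = res["locations"][0]
    return matches / columns, (s, e + 1)


def _cluster_seeds(
    matches: list[tuple[str, int, int]], qlen: int, band: int = 25
) -> list[tuple[str, int, int]]:
    """Group seed matches (seq_id, tpos, qpos) into candidate target windows."""
    windows: list[tuple[str, int, int]] = []
    matches.sort(key=lambda m: (m[0], m[1] - m[2]))
    cur: list[tuple[str, int, int]] = []
    for m in matches:
        if cur and (m[0] != cur[-1][0] or (m[1] - m[2]) - (cur[-1][1] - cur[-1][2]) > band):
            windows.append(_window_of(cur, qlen))
            cur = []
        cur.append(m)
    if cur:
        windows.append(_window_of(cur, qlen))
    return windows


def _window_of(cluster: list[tuple[str, int, int]], qlen: int) -> tuple[str, int, int]:
    seq_id = cluster[0][0]
    starts = [t - q for _, t, q in cluster]
    lo = min(starts) - _WINDOW_PAD
    hi = max(starts) + qlen + _WINDOW_PAD
    return seq_id, lo, hi


def search_genome(
    query: str,
    target: GenomeSequence,
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
    seed_len: int = DEFAULT_SEED_LEN,
    seed_step: int | None = None,
    both_strands: bool = True,
) -> list[GenomeHit]:
    """All local hits of ``query`` in ``target`` at >= min_identity.

    Hits are sorted by descending identity, ties by (seq_id, start). The
    infix alignment consumes the whole query, so query coverage is 1 by
    construction; heavily diverged ends depress identity instead.
    """
    query = query.upper()
    if len(query) < seed_len:
        raise ParameterError(
            f"query length {len(query)} is shorter than the seed length {seed_len}"
        )
    if seed_step is None:
        seed_step = 1 if len(query) < 60 else max(1, seed_len // 3)
    idx = SeedIndex.for_genome(target, seed_len)
    hits: list[GenomeHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        q = query if strand == "+" else reverse_complement(query)
        qpositions = list(range(0, len(q) - seed_len + 1, seed_step))
        if qpositions[-1] != len(q) - seed_len:
            qpositions.append(len(q) - seed_len)
        matches: list[tuple[str, int, int]] = []
        for qp in qpositions:
            for seq_id, tp in idx.index.get(q[qp : qp + seed_len], ()):
                matches.append((seq_id, tp, qp))
        for seq_id, lo, hi in _cluster_seeds(matches, len(q)):
            seq = target.records[seq_id]
            lo = max(0, lo)
            hi = min(len(seq), hi)
            res = alignment_identity(q, seq[lo:hi])
            if res is None:
                continue
            identity, (ws, we) = res
            if identity < min_identity:
                continue
            hits.append(
                GenomeHit(
                    target_genome=target.genome_label,
                    seq_id=seq_id,
                    start=lo + ws,
                    end=lo + we,
                    strand=strand,
                    flank_identity=identity,
                )
            )
    hits = _dedupe(hits)
    hits.sort(key=lambda h: (-h.flank_identity, h.seq_id, h.start))
    return hits


def _dedupe(hits: list[GenomeHit]) -> list[GenomeHit]:
    """Merge hits whose target intervals overlap >50% on the same seq/strand."""
    kept: list[GenomeHit] = []
    for h in sorted(hits, key=lambda h: -h.flank_identity):
        dup = False
        for k in kept:
            if h.seq_id != k.seq_id or h.strand != k.strand:
                continue
            ov = min(h.end, k.end) - max(h.start, k.start)
            if ov > 0.5 * min(h.end - h.start, k.end - k.start):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept
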