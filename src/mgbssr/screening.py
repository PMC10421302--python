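"""Cross-genome polymorphic SSR screen.

Anchor-genome SSRs are extracted with their flanking sequence and pushed
through a five-stage funnel:

(a) self-uniqueness — the flanked sequence must occur exactly once in the
    anchor genome (repetitive context is useless primer territory);
(b) cross-genome matching — the flanks must be found, unambiguously and at
    >= ``min_identity`` over flank columns (the SSR core is excised before
    alignment, so repeat-count variation cannot depress identity), in every
    other genome, on either strand;
(c) repeat-count comparison — loci whose repeat count is identical in all
    genomes are monomorphic and dropped;
(d) flank-mutation filter — substitutions/indels within the primer-design
    window immediately adjacent to the core disqualify a locus;
(e) full polymorphism — loci whose counts differ between only two genomes
    are dropped; retained loci have pairwise-distinct counts in all genomes.

With exactly two genomes, stage (e) degenerates to a no-op: any two
differing counts are already pairwise distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import GenomeHit, alignment_identity, search_genome
from .sequence_io import GenomeSequence, reverse_complement, subsequence
from .ssr_detection import (
    SSRLocus,
    _candidate_runs,
    select_nonoverlapping,
)

__all__ = [
    "FlankedSSR",
    "PolymorphicLocus",
    "ScreenParams",
    "ScreenResult",
    "extract_flanked",
    "screen_polymorphic",
    "STATUSES",
]

STATUSES = (
    "retained",
    "dropped_nonunique",
    "dropped_low_identity",
    "dropped_monomorphic",
    "dropped_two_way_only",
    "dropped_flank_mutation",
)


@dataclass
class FlankedSSR:
    """An SSR locus with up/downstream flanks attached (truncated at contig ends)."""

    locus: SSRLocus
    left_flank: str
    right_flank: str
    truncated: bool = False

    @property
    def full_seq(self) -> str:
        return self.left_flank + self.locus.core_seq + self.right_flank


@dataclass
class PolymorphicLocus:
    """Screen output record for one anchor locus."""

    anchor: FlankedSSR
    hits: dict[str, GenomeHit] = field(default_factory=dict)
    repeat_counts: dict[str, int] = field(default_factory=dict)
    status: str = "retained"

    @property
    def marker_id(self) -> str:
        loc = self.anchor.locus
        return f"{loc.seq_id}:{loc.start + 1}"


@dataclass
class ScreenParams:
    """Knobs of the polymorphic screen; defaults follow the method's protocol."""

    flank_len: int = 300
    min_identity: float = 0.90
    min_coverage: float = 0.90
    seed_len: int = 15
    #: a secondary hit challenges uniqueness only if within this identity margin
    cohit_margin: float = 0.05
    #: primer-design window adjacent to the core that must align edit-free
    primer_window: int = 50
    max_window_edits: int = 0
    #: largest tolerated distance between the paired flank hits in a target
    max_core_gap: int = 400
    motif_lengths: tuple[int, ...] = (3, 4, 5, 6)
    min_repeats: int = 4


def extract_flanked(
    loci: list[SSRLocus], genome: GenomeSequence, flank_len: int = 300
) -> list[FlankedSSR]:
    """Attach up to ``flank_len`` bp of flanking genome sequence to each locus."""
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    out = []
    for loc in loci:
        if loc.seq_id not in genome or loc.end > len(genome[loc.seq_id]):
            raise KeyError(f"locus {loc} not within genome {genome.genome_label!r}")
        lstart = max(0, loc.start - flank_len)
        rend = min(len(genome[loc.seq_id]), loc.end + flank_len)
        left = subsequence(genome, loc.seq_id, lstart, loc.start)
        right = subsequence(genome, loc.seq_id, loc.end, rend)
        out.append(
            FlankedSSR(
                locus=loc,
                left_flank=left,
                right_flank=right,
                truncated=(len(left) < flank_len or len(right) < flank_len),
            )
        )
    return out


def _count_motif_repeats(window: str, motif: str, min_count: int = 2) -> int:
    """Largest whole-unit run of any cyclic rotation of ``motif`` in ``window``."""
    k = len(motif)
    rotations = {motif[i:] + motif[:i] for i in range(k)}
    runs = _candidate_runs(window, [k], {k: min_count})
    best = 0
    for start, end, m, count in runs:
        if m in rotations:
            best = max(best, count)
    return best


def _is_ambiguous(hits: list[GenomeHit], margin: float) -> bool:
    """Near-co-optimal secondary hits signal repetitive context."""
    return len(hits) > 1 and hits[1].flank_identity >= hits[0].flank_identity - margin


@dataclass
class _FlankMatch:
    hit: GenomeHit
    window_clean: bool


def _match_in_target(
    fl: FlankedSSR, target: GenomeSequence, params: ScreenParams
) -> _FlankMatch | str:
    """Locate the orthologous flank block in one target genome.

    Returns a :class:`_FlankMatch`, or ``"absent"`` (no qualifying placement)
    or ``"ambiguous"`` (several near-equal placements).
    """
    kw = dict(
        min_identity=params.min_identity,
        min_coverage=params.min_coverage,
        seed_len=params.seed_len,
    )
    lhits = search_genome(fl.left_flank, target, **kw)
    rhits = search_genome(fl.right_flank, target, **kw)
    pairs: list[tuple[float, GenomeHit, GenomeHit]] = []
    for lh in lhits:
        for rh in rhits:
            if lh.seq_id != rh.seq_id or lh.strand != rh.strand:
                continue
            gap = (rh.start - lh.end) if lh.strand == "+" else (lh.start - rh.end)
            if not (0 <= gap <= params.max_core_gap):
                continue
            # combined identity weighted by flank lengths
            wl, wr = len(fl.left_flank), len(fl.right_flank)
            ident = (lh.flank_identity * wl + rh.flank_identity * wr) / (wl + wr)
            pairs.append((ident, lh, rh))
    if not pairs:
        return "absent"
    pairs.sort(key=lambda p: (-p[0], p[1].seq_id, p[1].start))
    if len(pairs) > 1 and pairs[1][0] >= pairs[0][0] - params.cohit_margin:
        # distinct placements only (not the same pair re-ranked)
        best, second = pairs[0], pairs[1]
        if (second[1].start, second[2].start) != (best[1].start, best[2].start):
            return "ambiguous"
    ident, lh, rh = pairs[0]
    seq = target.records[lh.seq_id]
    motif = fl.locus.motif
    k = len(motif)
    if lh.strand == "+":
        core_lo, core_hi = lh.end, rh.start
        window = seq[max(0, core_lo - k) : core_hi + k]
        count = _count_motif_repeats(window, motif)
        left_tpl = seq[max(0, core_lo - params.primer_window) : core_lo]
        right_tpl = seq[core_hi : core_hi + params.primer_window]
        clean = _windows_clean(fl, left_tpl, right_tpl, params)
    else:
        core_lo, core_hi = rh.end, lh.start
        window = reverse_complement(seq[max(0, core_lo - k) : core_hi + k])
        count = _count_motif_repeats(window, motif)
        left_tpl = reverse_complement(seq[core_hi : core_hi + params.primer_window])
        right_tpl = reverse_complement(seq[max(0, core_lo - params.primer_window) : core_lo])
        clean = _windows_clean(fl, left_tpl, right_tpl, params)
    hit = GenomeHit(
        target_genome=target.genome_label,
        seq_id=lh.seq_id,
        start=min(lh.start, rh.start),
        end=max(lh.end, rh.end),
        strand=lh.strand,
        flank_identity=ident,
        target_repeat_count=count,
    )
    return _FlankMatch(hit=hit, window_clean=clean)


def _windows_clean(
    fl: FlankedSSR, target_left: str, target_right: str, params: ScreenParams
) -> bool:
    """Primer windows adjacent to the core must match the anchor edit-free."""
    w = params.primer_window
    anchor_left = fl.left_flank[-w:] if w else ""
    anchor_right = fl.right_flank[:w] if w else ""
    import edlib

    for anc, tpl in ((anchor_left, target_left), (anchor_right, target_right)):
        if not anc:
            continue
        if len(tpl) < len(anc):
            return False
        d = edlib.align(anc, tpl, mode="HW")["editDistance"]
        if d < 0 or d > params.max_window_edits:
            return False
    return True


@dataclass
class ScreenResult:
    loci: list[PolymorphicLocus]
    funnel: dict[str, int]

    @property
    def retained(self) -> list[PolymorphicLocus]:
        return [l for l in self.loci if l.status == "retained"]

    def to_rows(self) -> list[dict]:
        rows = []
        for pl in self.loci:
            row = {
                "marker_id": pl.marker_id,
                "seq_id": pl.anchor.locus.seq_id,
                "start": pl.anchor.locus.start + 1,
                "end": pl.anchor.locus.end,
                "motif": pl.anchor.locus.motif,
                "status": pl.status,
            }
            for g, c in pl.repeat_counts.items():
                row[f"repeats_{g}"] = c
            for g, h in pl.hits.items():
                row[f"identity_{g}"] = round(h.flank_identity, 4)
            rows.append(row)
        return rows


def screen_polymorphic(
    genomes: list[GenomeSequence],
    params: ScreenParams | None = None,
    anchor: str | None = None,
    loci: list[SSRLocus] | None = None,
) -> ScreenResult:
    """Run the full screen; the first genome is the anchor unless named.

    ``loci`` may supply pre-detected anchor SSRs; otherwise detection runs
    with the parameters in ``params``.
    """
    if len(genomes) < 2:
        raise ValueError("the screen needs at least 2 genomes")
    params = params or ScreenParams()
    labels = [g.genome_label for g in genomes]
    if anchor is None:
        anchor = labels[0]
    if anchor not in labels:
        raise ValueError(f"anchor genome {anchor!r} not among {labels}")
    anchor_g = genomes[labels.index(anchor)]
    others = [g for g in genomes if g.genome_label != anchor]

    from .ssr_detection import detect_ssrs

    if loci is None:
        loci = detect_ssrs(anchor_g, params.motif_lengths, params.min_repeats)
    flanked = extract_flanked(loci, anchor_g, params.flank_len)

    funnel: dict[str, int] = {"detected": len(flanked)}
    results: list[PolymorphicLocus] = []

    # stage (a): self-uniqueness in the anchor genome — the flank block must
    # place exactly once (identity is flank-only, the core is excised, so a
    # duplicated flank block scores ~1 no matter how long the core is)
    unique: list[PolymorphicLocus] = []
    for fl in flanked:
        pl = PolymorphicLocus(anchor=fl)
        pl.repeat_counts[anchor] = fl.locus.repeat_count
        m = _match_in_target(fl, anchor_g, params)
        if isinstance(m, str):  # "ambiguous" or (defensively) "absent"
            pl.status = "dropped_nonunique"
            results.append(pl)
        else:
            unique.append(pl)
    funnel["self_unique"] = len(unique)

    # stages (b)-(e)
    matched: list[PolymorphicLocus] = []
    for pl in unique:
        verdict = None
        clean = True
        for tg in others:
            m = _match_in_target(pl.anchor, tg, params)
            if m == "absent":
                verdict = "dropped_low_identity"
                break
            if m == "ambiguous":
                verdict = "dropped_nonunique"
                break
            pl.hits[tg.genome_label] = m.hit
            pl.repeat_counts[tg.genome_label] = m.hit.target_repeat_count
            clean = clean and m.window_clean
        if verdict:
            pl.status = verdict
            results.append(pl)
            continue
        counts = [pl.repeat_counts[l] for l in labels]
        if len(set(counts)) == 1:
            pl.status = "dropped_monomorphic"
        elif not clean:
            pl.status = "dropped_flank_mutation"
        elif len(set(counts)) < len(counts):
            pl.status = "dropped_two_way_only"
        else:
            pl.status = "retained"
        results.append(pl)
        if pl.status in ("retained", "dropped_monomorphic", "dropped_two_way_only",
                        "dropped_flank_mutation"):
            matched.append(pl)
    funnel["cross_matched"] = len(matched)
    funnel["polymorphic"] = sum(
        1 for pl in matched if pl.status not in ("dropped_monomorphic",)
    )
    funnel["clean_flanks"] = sum(
        1
        for pl in matched
        if pl.status not in ("dropped_monomorphic", "dropped_flank_mutation")
    )
    funnel["retained"] = sum(1 for pl in results if pl.status == "retained")
    for s in STATUSES:
        funnel[s] = sum(1 for pl in results if pl.status == s)

    results.sort(key=lambda pl: (pl.anchor.locus.seq_id, pl.anchor.locus.start))
    return ScreenResult(loci=results, funnel=funnel)
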