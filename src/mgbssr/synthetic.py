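"""Synthetic ground-truth fixtures: related genomes with planted SSR loci of
controlled polymorphism classes, and genotype tables drawn from known allele
frequencies.

The genome generator plants one block per locus — left flank, motif run,
right flank — separated by random *repeat-suppressed* spacer sequence
(rejection-sampled so no chance 3-6-mer run reaches the detection
threshold), which makes the planted truth table the only truth: every other
module's precision/recall can be asserted exactly. Six locus classes map
one-to-one onto the screen's funnel outcomes:

* ``three_way_polymorphic`` — identical flanks, pairwise-distinct repeat
  counts in every genome: the screen must retain these;
* ``two_way_only`` — counts differ between only two genomes;
* ``monomorphic`` — the same count everywhere;
* ``nonunique_decoy`` — the flank block is duplicated elsewhere in the
  anchor genome (core omitted in the copy);
* ``low_identity_flank`` — one non-anchor genome's flanks carry ~15%
  substitutions, below the screen's 90% identity floor;
* ``flank_mutation`` — a few substitutions inside the primer-design window
  right next to the core (flanks still >90% identical overall).

What the generator does *not* emulate: indel divergence between genomes,
compound/interrupted repeats, assembly gaps and sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popgen import GenotypeTable
from .sequence_io import GenomeSequence
from .ssr_detection import _candidate_runs

__all__ = ["PlantSpec", "PlantedLocus", "generate_genomes", "generate_genotypes"]

CLASSES = (
    "three_way_polymorphic",
    "two_way_only",
    "monomorphic",
    "nonunique_decoy",
    "low_identity_flank",
    "flank_mutation",
)

_BASES = np.array(list("ACGT"))


@dataclass
class PlantSpec:
    """Conditions the genome generator plants; defaults follow the screen's
    study design (300 bp flanks, 3-4 nt motifs, detection threshold 4)."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in CLASSES}
    )
    motif_lengths: tuple[int, ...] = (3, 4)
    repeat_count_range: tuple[int, int] = (4, 12)
    flank_len: int = 300
    genome_length: int = 100_000
    low_identity_divergence: float = 0.15
    n_window_mutations: int = 2
    primer_window: int = 50
    min_repeats: int = 4
    seed: int = 0


@dataclass
class PlantedLocus:
    """Truth-table row for one planted locus."""

    locus_id: str
    cls: str
    motif: str
    repeat_counts: dict[str, int]
    anchor_interval: tuple[int, int]  # core interval in the anchor genome
    expected_status: str
    per_genome_interval: dict[str, tuple[int, int]] = field(default_factory=dict)


_EXPECTED_STATUS = {
    "three_way_polymorphic": "retained",
    "two_way_only": "dropped_two_way_only",
    "monomorphic": "dropped_monomorphic",
    "nonunique_decoy": "dropped_nonunique",
    "low_identity_flank": "dropped_low_identity",
    "flank_mutation": "dropped_flank_mutation",
}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _has_run(seq: str, lengths, threshold: int) -> bool:
    table = {k: threshold for k in lengths}
    return bool(_candidate_runs(seq, lengths, table))


def _repeat_free(rng: np.random.Generator, length: int, lengths, threshold: int) -> str:
    """Random sequence with no run of ``threshold - 1`` or more motif copies
    (one copy of slack guards runs that straddle junctions with neighbors)."""
    guard = max(2, threshold - 1)
    for _ in range(200):
        s = _random_seq(rng, length)
        if not _has_run(s, lengths, guard):
            return s
    raise RuntimeError("could not sample a repeat-free spacer; length too large?")


def _primitive_random_motif(rng: np.random.Generator, k: int) -> str:
    from .ssr_detection import is_primitive

    while True:
        m = _random_seq(rng, k)
        if is_primitive(m) and len(set(m)) >= 2:
            return m


def _mutate(
    rng: np.random.Generator, seq: str, positions: np.ndarray
) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _distinct_counts(rng: np.random.Generator, n: int, lo: int, hi: int) -> list[int]:
    return list(rng.choice(np.arange(lo, hi + 1), size=n, replace=False))


def generate_genomes(
    spec: PlantSpec, n_genomes: int = 3
) -> tuple[list[GenomeSequence], list[PlantedLocus]]:
    """Build ``n_genomes`` related genomes plus the planted truth table.

    Deterministic for a given (spec.seed, n_genomes); the assembled genomes
    are verified so that running the detector recovers exactly the planted
    cores (a failed verification re-rolls the randomness, still seeded).
    """
    if n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    for cls in spec.n_per_class:
        if cls not in CLASSES:
            raise ValueError(f"unknown locus class {cls!r}")
    for attempt in range(20):
        rng = np.random.default_rng([spec.seed % (2**31), attempt, n_genomes])
        try:
            return _generate_once(spec, n_genomes, rng)
        except _VerificationFailure:
            continue
    raise RuntimeError("genome generation failed verification 20 times")


class _VerificationFailure(Exception):
    pass


def _plan_counts(
    spec: PlantSpec, cls: str, rng: np.random.Generator, labels: list[str]
) -> dict[str, int]:
    lo, hi = spec.repeat_count_range
    n = len(labels)
    if cls == "monomorphic":
        c = int(rng.integers(lo, hi + 1))
        return {g: c for g in labels}
    if cls == "two_way_only":
        if n == 2:  # degenerates: any difference is already fully polymorphic
            counts = _distinct_counts(rng, 2, lo, hi)
            return dict(zip(labels, counts))
        a, b = _distinct_counts(rng, 2, lo, hi)
        counts = {g: int(a) for g in labels}
        odd = labels[int(rng.integers(0, n))]
        counts[odd] = int(b)
        return counts
    counts = _distinct_counts(rng, n, lo, hi)
    return {g: int(c) for g, c in zip(labels, counts)}


def _generate_once(
    spec: PlantSpec, n_genomes: int, rng: np.random.Generator
) -> tuple[list[GenomeSequence], list[PlantedLocus]]:
    labels = [f"G{i + 1}" for i in range(n_genomes)]
    anchor = labels[0]
    motif_lengths = list(spec.motif_lengths)
    # suppress chance repeats over the detector's full default motif range,
    # not just the planted lengths, so downstream screens see planted truth only
    lengths = sorted(set(motif_lengths) | {3, 4, 5, 6})
    thr = spec.min_repeats

    loci_plan: list[dict] = []
    i = 0
    for cls in CLASSES:
        for _ in range(spec.n_per_class.get(cls, 0)):
            k = int(rng.choice(motif_lengths))
            motif = _primitive_random_motif(rng, k)
            counts = _plan_counts(spec, cls, rng, labels)
            left = _repeat_free(rng, spec.flank_len, lengths, thr)
            right = _repeat_free(rng, spec.flank_len, lengths, thr)
            # flanks must not extend the core, not even by one base: a flank
            # character matching the adjacent motif character would shift the
            # maximal run into a cyclic rotation starting inside the flank
            if left[-1] == motif[-1]:
                repl = next(b for b in "ACGT" if b != motif[-1] and b != left[-2])
                left = left[:-1] + repl
            if right[0] == motif[0]:
                repl = next(b for b in "ACGT" if b != motif[0] and b != right[1])
                right = repl + right[1:]
            plan = {
                "locus_id": f"L{i + 1:03d}",
                "cls": cls,
                "motif": motif,
                "counts": counts,
                "left": {g: left for g in labels},
                "right": {g: right for g in labels},
            }
            if cls == "low_identity_flank" and n_genomes >= 2:
                victim = labels[1 + int(rng.integers(0, n_genomes - 1))]
                n_mut = max(1, int(round(spec.low_identity_divergence * spec.flank_len)))
                for side in ("left", "right"):
                    pos = rng.choice(spec.flank_len, size=n_mut, replace=False)
                    plan[side][victim] = _mutate(rng, plan[side][victim], pos)
            if cls == "flank_mutation" and n_genomes >= 2:
                victim = labels[1 + int(rng.integers(0, n_genomes - 1))]
                w = spec.primer_window
                # substitutions inside the primer window next to the core,
                # away from the extreme edges so flank matching stays intact
                pos = spec.flank_len - w + rng.choice(
                    np.arange(5, w - 5), size=spec.n_window_mutations, replace=False
                )
                plan["left"][victim] = _mutate(rng, plan["left"][victim], pos)
            loci_plan.append(plan)
            i += 1

    rng.shuffle(loci_plan)

    n_loci = len(loci_plan)
    n_decoys = sum(1 for p in loci_plan if p["cls"] == "nonunique_decoy")
    block_len = sum(
        2 * spec.flank_len + len(p["motif"]) * max(p["counts"].values())
        for p in loci_plan
    ) + n_decoys * 2 * spec.flank_len
    n_spacers = n_loci + n_decoys + 1
    spare = spec.genome_length - block_len
    if n_loci and spare < n_spacers * 2 * spec.flank_len:
        raise ValueError(
            f"genome_length {spec.genome_length} too small for {n_loci} loci "
            f"with >= {2 * spec.flank_len} bp spacing"
        )
    mean_spacer = spare // n_spacers if n_spacers else 0

    spacer_lens = {
        g: [
            int(rng.integers(int(0.8 * mean_spacer), int(1.2 * mean_spacer) + 1))
            for _ in range(n_spacers)
        ]
        for g in labels
    }

    truth: list[PlantedLocus] = []
    parts: dict[str, list[str]] = {g: [] for g in labels}
    pos: dict[str, int] = {g: 0 for g in labels}
    intervals: dict[str, dict[str, tuple[int, int]]] = {g: {} for g in labels}

    def emit(g: str, s: str) -> None:
        parts[g].append(s)
        pos[g] += len(s)

    decoy_queue: list[dict] = []
    for si, plan in enumerate(loci_plan):
        for g in labels:
            emit(g, _repeat_free(rng, spacer_lens[g][si], lengths, thr))
        for g in labels:
            emit(g, plan["left"][g])
            core = plan["motif"] * plan["counts"][g]
            intervals[g][plan["locus_id"]] = (pos[g], pos[g] + len(core))
            emit(g, core)
            emit(g, plan["right"][g])
        if plan["cls"] == "nonunique_decoy":
            decoy_queue.append(plan)
        truth.append(
            PlantedLocus(
                locus_id=plan["locus_id"],
                cls=plan["cls"],
                motif=plan["motif"],
                repeat_counts=dict(plan["counts"]),
                anchor_interval=intervals[anchor][plan["locus_id"]],
                expected_status=_EXPECTED_STATUS[plan["cls"]]
                if not (n_genomes == 2 and plan["cls"] == "two_way_only")
                else "retained",
                per_genome_interval={},
            )
        )

    # decoy copies (flanks only, no core) go at the anchor's tail
    for di, plan in enumerate(decoy_queue):
        si = n_loci + di
        for g in labels:
            emit(g, _repeat_free(rng, spacer_lens[g][si], lengths, thr))
        emit(anchor, plan["left"][anchor] + plan["right"][anchor])
    for g in labels:
        emit(g, _repeat_free(rng, spacer_lens[g][-1], lengths, thr))

    genomes = [
        GenomeSequence(genome_label=g, records={"chr1": "".join(parts[g])})
        for g in labels
    ]
    for t in truth:
        t.per_genome_interval = {g: intervals[g][t.locus_id] for g in labels}

    _verify(genomes, truth, spec)
    return genomes, truth


def _verify(
    genomes: list[GenomeSequence], truth: list[PlantedLocus], spec: PlantSpec
) -> None:
    """The detector must recover exactly the planted cores in every genome."""
    from .ssr_detection import detect_ssrs

    det_lengths = sorted(set(spec.motif_lengths) | {3, 4, 5, 6})
    for g in genomes:
        found = {
            (l.start, l.end)
            for l in detect_ssrs(g, det_lengths, spec.min_repeats)
        }
        planted = {t.per_genome_interval[g.genome_label] for t in truth}
        if found != planted:
            raise _VerificationFailure(
                f"{g.genome_label}: {len(found)} detected vs {len(planted)} planted"
            )


def truth_to_tsv(truth: list[PlantedLocus], path) -> None:
    labels = sorted(truth[0].repeat_counts) if truth else []
    with open(path, "wt") as fh:
        cols = ["locus_id", "class", "motif", "anchor_start", "anchor_end",
                "expected_status"] + [f"repeats_{g}" for g in labels]
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            row = [t.locus_id, t.cls, t.motif, str(t.anchor_interval[0] + 1),
                   str(t.anchor_interval[1]), t.expected_status]
            row += [str(t.repeat_counts[g]) for g in labels]
            fh.write("\t".join(row) + "\n")


def generate_genotypes(
    freqs: dict[str, dict[int, float]],
    n_samples: int | None = None,
    ploidy_plan: dict[int, int] | list[int] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeTable, dict[str, dict[int, float]]]:
    """Hardy-Weinberg sampling of a genotype table from known frequencies.

    ``ploidy_plan`` is either a per-sample list of ploidies or a mapping
    {ploidy: n_samples} (e.g. ``{2: 26, 3: 4}``, the mixed diploid/triploid
    panel design); by default all samples are diploid.
    """
    rng = np.random.default_rng(seed)
    for m, f in freqs.items():
        total = sum(f.values())
        if not np.isclose(total, 1.0, atol=1e-8) or any(p < 0 for p in f.values()):
            raise ValueError(f"frequencies for marker {m!r} are not a distribution")
    if ploidy_plan is None:
        ploidies = [2] * (n_samples or 0)
    elif isinstance(ploidy_plan, dict):
        ploidies = [p for p, n in sorted(ploidy_plan.items()) for _ in range(n)]
    else:
        ploidies = list(ploidy_plan)
    if n_samples is not None and len(ploidies) != n_samples:
        raise ValueError("ploidy plan does not cover n_samples")
    samples = [f"S{i + 1:03d}" for i in range(len(ploidies))]
    markers = list(freqs)
    cells: dict[tuple[str, str], tuple[int, ...]] = {}
    for m in markers:
        alleles = np.array(sorted(freqs[m]))
        p = np.array([freqs[m][a] for a in alleles], dtype=float)
        p = p / p.sum()
        for s, ploidy in zip(samples, ploidies):
            if missing_rate and rng.random() < missing_rate:
                continue
            drawn = rng.choice(alleles, size=ploidy, replace=True, p=p)
            cells[(s, m)] = tuple(sorted(int(a) for a in drawn))
    table = GenotypeTable(
        samples=samples,
        markers=markers,
        cells=cells,
        ploidy=dict(zip(samples, ploidies)),
    )
    return table, freqs
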