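"""Primer-pair evaluation against the screen's six design criteria,
plus fluorescent multiplex panel assembly.

Primer *design* is left to dedicated thermodynamic engines; this module
scores externally supplied pairs so the criteria work regardless of which
designer produced them:

1. both primers lie wholly within the locus flanks (conserved regions);
2. expected amplicon length within [50, 300] bp;
3. melting temperatures within ``tm_tolerance`` of each other
   (nearest-neighbor, SantaLucia 1998 parameters, 50 mM Na+, 250 nM primer);
4. no inter-primer complementarity: longest perfect duplex run < 8 nt and
   no 3'-anchored run >= 5 nt;
5. genome specificity: exactly one amplifiable site per genome (both
   primers in convergent orientation within the maximum product size);
6. the forward primer carries the 18 nt M13(-21) universal tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .align import search_genome
from .screening import FlankedSSR, PolymorphicLocus
from .sequence_io import GenomeSequence, reverse_complement

__all__ = [
    "M13_TAIL",
    "DYES",
    "PrimerPair",
    "CriterionReport",
    "EvaluationThresholds",
    "melting_temperature",
    "complementarity_runs",
    "evaluate_primer_pair",
    "assign_panels",
    "PanelPackingError",
]

#: M13(-21) universal sequencing primer, the standard 18 nt fluorescent tail
M13_TAIL = "TGTAAAACGACGGCCAGT"
DYES = ("FAM", "HEX", "ROX", "TAMRA")
#: common alternative spellings seen in panel tables
DYE_ALIASES = {"TAME": "TAMRA", "6-FAM": "FAM"}


@dataclass
class PrimerPair:
    marker_id: str
    forward_seq: str
    reverse_seq: str
    expected_amplicon_len: int
    dye: str | None = None
    core_unit: str | None = None

    def __post_init__(self) -> None:
        self.forward_seq = self.forward_seq.upper()
        self.reverse_seq = self.reverse_seq.upper()
        if self.dye in DYE_ALIASES:
            self.dye = DYE_ALIASES[self.dye]

    @property
    def tm_forward(self) -> float:
        return melting_temperature(self.forward_seq)

    @property
    def tm_reverse(self) -> float:
        return melting_temperature(self.reverse_seq)

    @property
    def m13_tagged_forward(self) -> str:
        return M13_TAIL + self.forward_seq


def melting_temperature(seq: str, na_mM: float = 50.0, primer_nM: float = 250.0) -> float:
    """Nearest-neighbor Tm (degC), SantaLucia 1998 unified parameters."""
    return float(
        _mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, Na=na_mM, dnac1=primer_nM, dnac2=0,
                  saltcorr=5)
    )


def complementarity_runs(forward: str, reverse: str) -> tuple[int, int]:
    """(longest duplex run, longest 3'-anchored run) between two primers.

    A duplex run is a stretch where the primers are perfectly Watson-Crick
    complementary in antiparallel orientation. A run is 3'-anchored if it
    includes the 3'-terminal base of either primer.
    """
    f = forward.upper()
    rc_r = reverse_complement(reverse.upper())
    nf, nr = len(f), len(rc_r)
    # M[i][j]: length of the common substring starting at f[i], rc_r[j]
    M = [[0] * (nr + 1) for _ in range(nf + 1)]
    for i in range(nf - 1, -1, -1):
        row = M[i]
        nxt = M[i + 1]
        fi = f[i]
        for j in range(nr - 1, -1, -1):
            if fi == rc_r[j]:
                row[j] = nxt[j + 1] + 1
    longest = 0
    anchored = 0
    for i in range(nf):
        for j in range(nr):
            run = M[i][j]
            if run == 0:
                continue
            longest = max(longest, run)
            if i + run == nf:  # reaches the 3' end of the forward primer
                anchored = max(anchored, run)
            if j == 0:  # rc_r[0] corresponds to the reverse primer's 3' base
                anchored = max(anchored, run)
    return longest, anchored


@dataclass
class EvaluationThresholds:
    amplicon_min: int = 50
    amplicon_max: int = 300
    tm_tolerance: float = 5.0
    dimer_run: int = 8
    dimer_run_3p: int = 5
    max_product: int = 2000
    primer_min_identity: float = 0.90


@dataclass
class CriterionReport:
    """Pass/fail per criterion for one primer pair at one locus."""

    marker_id: str
    in_flanks: bool
    amplicon_in_range: bool
    tm_compatible: bool
    no_dimer: bool
    specific: bool
    m13_tagged: bool
    details: dict = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return (
            self.in_flanks
            and self.amplicon_in_range
            and self.tm_compatible
            and self.no_dimer
            and self.specific
            and self.m13_tagged
        )


def _flanked_of(locus) -> FlankedSSR:
    if isinstance(locus, PolymorphicLocus):
        return locus.anchor
    if isinstance(locus, FlankedSSR):
        return locus
    raise TypeError("locus must be a FlankedSSR or PolymorphicLocus")


def count_amplifiable_sites(
    pair: PrimerPair, genome: GenomeSequence, thresholds: EvaluationThresholds
) -> int:
    """Number of convergent forward/reverse annealing site pairs in a genome."""
    kw = dict(min_identity=thresholds.primer_min_identity, seed_len=15, seed_step=1)
    fhits = search_genome(pair.forward_seq, genome, **kw)
    rhits = search_genome(pair.reverse_seq, genome, **kw)
    n = 0
    for fh in fhits:
        for rh in rhits:
            if fh.seq_id != rh.seq_id:
                continue
            if fh.strand == "+" and rh.strand == "-" and rh.end > fh.start:
                if rh.end - fh.start <= thresholds.max_product:
                    n += 1
            elif fh.strand == "-" and rh.strand == "+" and fh.end > rh.start:
                if fh.end - rh.start <= thresholds.max_product:
                    n += 1
    return n


def evaluate_primer_pair(
    pair: PrimerPair,
    locus,
    genomes: list[GenomeSequence] | None = None,
    thresholds: EvaluationThresholds | None = None,
    m13_tagged_forward: str | None = None,
) -> CriterionReport:
    """Score one primer pair against the six criteria.

    ``genomes`` may be omitted, in which case the specificity criterion is
    vacuously true (recorded in ``details``). ``m13_tagged_forward`` is the
    tailed oligo as ordered; when omitted the pair's own tagged sequence is
    used (criterion 6 then checks the tail constant itself).
    """
    th = thresholds or EvaluationThresholds()
    fl = _flanked_of(locus)
    if not pair.forward_seq or not pair.reverse_seq:
        raise ValueError("primer sequences must be non-empty")
    for s in (pair.forward_seq, pair.reverse_seq):
        if not set(s) <= set("ACGT"):
            raise ValueError(f"primer {s!r} contains non-ACGT characters")

    # (1) both primers wholly within the flanks
    fwd_pos = fl.left_flank.find(pair.forward_seq)
    rev_site = reverse_complement(pair.reverse_seq)
    rev_pos = fl.right_flank.find(rev_site)
    in_flanks = fwd_pos >= 0 and rev_pos >= 0

    # (2) amplicon size window
    amplicon_ok = th.amplicon_min <= pair.expected_amplicon_len <= th.amplicon_max

    # (3) annealing-temperature compatibility
    dtm = abs(pair.tm_forward - pair.tm_reverse)
    tm_ok = dtm <= th.tm_tolerance

    # (4) inter-primer complementarity
    run, run3p = complementarity_runs(pair.forward_seq, pair.reverse_seq)
    no_dimer = run < th.dimer_run and run3p < th.dimer_run_3p

    # (5) one amplifiable site per genome
    if genomes:
        sites = {g.genome_label: count_amplifiable_sites(pair, g, th) for g in genomes}
        specific = all(n == 1 for n in sites.values())
    else:
        sites = {}
        specific = True

    # (6) M13 tail present on the tagged forward oligo
    tagged = m13_tagged_forward or pair.m13_tagged_forward
    m13_ok = tagged == M13_TAIL + pair.forward_seq

    return CriterionReport(
        marker_id=pair.marker_id,
        in_flanks=in_flanks,
        amplicon_in_range=amplicon_ok,
        tm_compatible=tm_ok,
        no_dimer=no_dimer,
        specific=specific,
        m13_tagged=m13_ok,
        details={
            "forward_pos_in_left_flank": fwd_pos,
            "reverse_site_pos_in_right_flank": rev_pos,
            "delta_tm": dtm,
            "dimer_run": run,
            "dimer_run_3p": run3p,
            "sites_per_genome": sites,
        },
    )


class PanelPackingError(ValueError):
    def __init__(self, conflicts: list[str]):
        self.conflicts = conflicts
        super().__init__(
            "cannot assign all primer pairs to dye panels:\n" + "\n".join(conflicts)
        )


def assign_panels(
    pairs: list[PrimerPair],
    dyes: tuple[str, ...] = DYES,
    per_panel: int = 3,
    min_separation: int = 20,
) -> dict[str, list[PrimerPair]]:
    """Greedy dye assignment so same-dye amplicons are size-separable.

    Pairs are taken in descending expected amplicon length (deterministic;
    ties by marker id) and placed on the least-loaded dye whose current
    members are all >= ``min_separation`` bp away (ties broken by dye list
    order). Spreading tight size clusters across dyes first keeps panels
    packable that first-fit would jam.
    """
    if len(pairs) > len(dyes) * per_panel:
        raise PanelPackingError(
            [f"{len(pairs)} pairs exceed capacity {len(dyes)} dyes x {per_panel}"]
        )
    assignment: dict[str, list[PrimerPair]] = {d: [] for d in dyes}
    conflicts: list[str] = []
    for pair in sorted(pairs, key=lambda p: (-p.expected_amplicon_len, p.marker_id)):
        feasible = [
            dye
            for dye in dyes
            if len(assignment[dye]) < per_panel
            and all(
                abs(pair.expected_amplicon_len - m.expected_amplicon_len)
                >= min_separation
                for m in assignment[dye]
            )
        ]
        if feasible:
            dye = min(feasible, key=lambda d: (len(assignment[d]), dyes.index(d)))
            assignment[dye].append(pair)
            pair.dye = dye
        else:
            near = [
                f"{m.marker_id}({m.expected_amplicon_len}bp)"
                for d in dyes
                for m in assignment[d]
                if abs(pair.expected_amplicon_len - m.expected_amplicon_len)
                < min_separation
            ]
            conflicts.append(
                f"{pair.marker_id}({pair.expected_amplicon_len}bp) conflicts with "
                + ", ".join(near)
            )
    if conflicts:
        raise PanelPackingError(conflicts)
    return assignment
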