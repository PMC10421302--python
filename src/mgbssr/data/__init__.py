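"""Packaged reference tables for the published 12-marker jujube LSSR panel."""

from importlib import resources

from ..popgen import MarkerStats, load_marker_stats_table
from ..primers import PrimerPair

__all__ = ["jujube_panel_stats", "jujube_panel_primers", "JUJUBE_MARKER_ORDER"]

#: the panel's fixed marker order used for ID cards (LSSR-15 is the published
#: list's alternative name for LSSR-25)
JUJUBE_MARKER_ORDER = [
    "LSSR-4", "LSSR-6", "LSSR-8", "LSSR-10", "LSSR-25", "LSSR-17",
    "LSSR-22", "LSSR-23", "LSSR-26", "LSSR-27", "LSSR-28", "LSSR-29",
]


def _path(name: str):
    return resources.files(__package__) / name


def jujube_panel_stats() -> list[MarkerStats]:
    """The published per-marker diversity statistics (12 rows)."""
    with resources.as_file(_path("jujube_lssr_panel_stats.tsv")) as p:
        return load_marker_stats_table(p)


def jujube_panel_primers() -> list[PrimerPair]:
    """The published primer pairs with expected sizes, core units and dyes."""
    pairs: list[PrimerPair] = []
    with _path("jujube_lssr_panel_primers.tsv").open() as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            pairs.append(
                PrimerPair(
                    marker_id=row["marker"],
                    forward_seq=row["forward"],
                    reverse_seq=row["reverse"],
                    expected_amplicon_len=int(row["expected_len"]),
                    core_unit=row["core_unit"],
                    dye=row["dye"],
                )
            )
    return pairs
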