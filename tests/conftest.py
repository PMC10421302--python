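import pytest

from mgbssr.popgen import GenotypeTable
from mgbssr.synthetic import PlantSpec, generate_genomes


@pytest.fixture(scope="session")
def small_trio():
    """A small synthetic trio (3 loci per class) with its truth table."""
    spec = PlantSpec(
        n_per_class={c: 3 for c in (
            "three_way_polymorphic", "two_way_only", "monomorphic",
            "nonunique_decoy", "low_identity_flank", "flank_mutation",
        )},
        genome_length=40_000,
        seed=11,
    )
    return generate_genomes(spec, 3)


@pytest.fixture()
def toy_table():
    """Hand-built genotype table: 3 diploids + 1 triploid, 2 markers."""
    return GenotypeTable(
        samples=["a", "b", "c", "t"],
        markers=["M1", "M2"],
        cells={
            ("a", "M1"): (100, 100),
            ("b", "M1"): (100, 120),
            ("c", "M1"): (120, 120),
            ("t", "M1"): (100, 100, 120),
            ("a", "M2"): (200, 204),
            ("b", "M2"): (200, 200),
            # c missing at M2
            ("t", "M2"): (200, 204, 208),
        },
        ploidy={"a": 2, "b": 2, "c": 2, "t": 3},
    )
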