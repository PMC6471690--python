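import pytest

from editorf import PlantedOrfSpec, make_genome


@pytest.fixture
def toy_fasta(tmp_path):
    """Single-record FASTA with one hand-checkable ORF."""
    p = tmp_path / "toy.fasta"
    p.write_text(">toy\nATGAAATAA\n")
    return p


@pytest.fixture
def planted_genome():
    """A genome with four planted ORFs covering all start/stop type combos."""
    specs = [
        PlantedOrfSpec("fwd", "main", "main", 110),
        PlantedOrfSpec("fwd", "edited", "main", 120),
        PlantedOrfSpec("rev", "main", "edited", 115),
        PlantedOrfSpec("rev", "edited", "edited", 125),
    ]
    genome, truth = make_genome(specs, background_length=4000, seed=11)
    return genome, truth
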