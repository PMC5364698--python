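import numpy as np
import pytest

from concordmeta.study_io import DEProfile, GeneUniverse


@pytest.fixture
def toy_universe() -> GeneUniverse:
    return GeneUniverse(genes=tuple(f"G{i}" for i in range(1, 9)))


@pytest.fixture
def eight_gene_profile() -> DEProfile:
    """The worked signature-extraction example: 8 genes, mixed significance."""
    return DEProfile.from_entries(
        "toy",
        {
            "G1": (2.0, 0.01),   # A
            "G2": (-1.5, 0.04),  # B
            "G3": (1.4, 0.20),   # C (excluded by p)
            "G4": (1.0, 0.01),   # D
            "G5": (-0.5, 0.03),  # E
            "G6": (0.2, 0.01),   # F
            "G7": (3.0, 0.06),   # G (excluded by p)
            "G8": (-2.5, 0.001), # H
        },
    )


def random_profile(
    study_id: str, genes: list[str], rng: np.random.Generator
) -> DEProfile:
    return DEProfile.from_entries(
        study_id,
        {
            g: (float(rng.normal()), float(rng.uniform()))
            for g in genes
        },
    )
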