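from __future__ import annotations

import numpy as np
import pytest

from mutclust.genome import ReferenceGenome

BASES = "ACGT"


@pytest.fixture(scope="session")
def genome_dict() -> dict[str, str]:
    """Small deterministic reference with an N-containing contig."""
    rng = np.random.default_rng(7)
    chr1 = "".join(rng.choice(list(BASES), size=400))
    chr2 = "".join(rng.choice(list(BASES), size=300))
    chrn = "ACGT" + "N" * 8 + "".join(rng.choice(list(BASES), size=28))
    return {"chr1": chr1, "chr2": chr2, "chrN": chrn}


@pytest.fixture(scope="session")
def ref(genome_dict) -> ReferenceGenome:
    return ReferenceGenome(genome_dict)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
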