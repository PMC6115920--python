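"""Shared fixtures: planted-motif sequences and a compact synthetic blueprint."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from nlrscan.core_io import SequenceRecord
from nlrscan.synth import GenomeBlueprint

PLANTED_MOTIF = "GMGGLGKTT"


@pytest.fixture(scope="session")
def planted_motif_seqs() -> list[SequenceRecord]:
    """50 random length-100 proteins, each with one planted P-loop 9-mer."""
    rng = np.random.default_rng(42)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    seqs = []
    for i in range(50):
        res = list(rng.choice(aa, size=100))
        pos = rng.integers(0, 100 - len(PLANTED_MOTIF))
        res[pos:pos + len(PLANTED_MOTIF)] = list(PLANTED_MOTIF)
        seqs.append(SequenceRecord(id=f"s{i:02d}", residues="".join(res)))
    return seqs


@pytest.fixture()
def small_blueprint() -> GenomeBlueprint:
    """One gene of every subgroup code, two planted clusters, 4 chromosomes."""
    counts = {code: 1 for code in GenomeBlueprint().subgroup_counts}
    counts["TNNL"] = 1
    return GenomeBlueprint(
        n_chromosomes=4,
        subgroup_counts=counts,
        planted_clusters=[(1, 3), (2, 2)],
        n_unplaced=1,
        proteome_size=1000,
        seed=7,
    )
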