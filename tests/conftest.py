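import numpy as np
import pandas as pd
import pytest

from mnsbs import THREE_PRIME
from mnsbs.simulate import simulate_genome, simulate_molecule_table


@pytest.fixture(scope="session")
def small_genome():
    """40 genes on 2 contigs, 10% same-strand overlapping pairs."""
    return simulate_genome(40, seed=2, overlap_fraction=0.1)


@pytest.fixture(scope="session")
def clean_genome():
    """30 genes, no overlapping pairs — for boundary-extension fixtures."""
    return simulate_genome(30, seed=12, overlap_fraction=0.0)


@pytest.fixture(scope="session")
def molecule_table():
    return simulate_molecule_table(
        n_cells=8, n_genes=40, molecules_per_cell=500, seed=5
    )


@pytest.fixture()
def gtf_file(tmp_path, small_genome):
    _, gtf, _ = small_genome
    path = tmp_path / "annotation.gtf"
    path.write_text("\n".join(gtf) + "\n")
    return path


@pytest.fixture()
def clean_gtf_file(tmp_path, clean_genome):
    _, gtf, _ = clean_genome
    path = tmp_path / "annotation_clean.gtf"
    path.write_text("\n".join(gtf) + "\n")
    return path


def random_phred_read(rng, rid="r", min_len=0, max_len=60):
    from mnsbs.chemistry import PhredRead

    n = int(rng.integers(min_len, max_len + 1))
    bases = "".join(rng.choice(list("ACGT"), size=n)) if n else ""
    quals = rng.integers(0, 41, size=n).tolist()
    return PhredRead(rid, bases, quals)
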