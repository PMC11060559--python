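import numpy as np
import pandas as pd
import pytest

from mosvirome import ContigRecord, CountMatrix, HostGroup


@pytest.fixture
def rng():
    return np.random.default_rng(20240430)


@pytest.fixture
def small_counts():
    """4 taxa x 3 libraries with a dominant row and sparse low counts."""
    return CountMatrix(pd.DataFrame(
        {"L1": [2000, 15, 0, 3], "L2": [80, 200, 12, 0], "L3": [150, 40, 9, 110]},
        index=["vA", "vB", "vC", "vD"]))


def make_contig(cid="c1", species="Testvirus 1", pid=95.0, aln=200,
                host=HostGroup.ARTHROPODA, cov=None, length=2000):
    return ContigRecord(
        contig_id=cid, best_hit_species=species, best_hit_accession=f"ACC_{cid}",
        pid_aa=pid, aln_len_aa=aln, evalue=1e-20, contig_len_nt=length,
        host_group=host, nonviral_cov_pct=cov)


@pytest.fixture
def contig_factory():
    return make_contig


def random_count_matrix(rng, n_taxa=50, n_libs=12, skew=True):
    """Sparse skewed integer matrix resembling post-collapse VTU counts."""
    if skew:
        base = rng.lognormal(3.0, 2.0, size=(n_taxa, n_libs))
        arr = np.floor(base).astype(np.int64)
        arr[rng.random((n_taxa, n_libs)) < 0.3] = 0
    else:
        arr = rng.integers(0, 50, size=(n_taxa, n_libs))
    return CountMatrix(pd.DataFrame(
        arr, index=[f"v{i:03d}" for i in range(n_taxa)],
        columns=[f"L{j:02d}" for j in range(n_libs)]))
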