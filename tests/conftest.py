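import numpy as np
import pytest

from radnet import io_demux, simdata, tag_network
from radnet.io_demux import GenotypeMatrix


@pytest.fixture(scope="session")
def small_read_panel(tmp_path_factory):
    """A small but complete simulated read panel (24 lines, 60 loci)."""
    cfg = simdata.SimConfig(
        n_lines=24, n_loci_allelic=60, n_homeolog_families=12, seed=101
    )
    out = simdata.simulate_read_panel(cfg, tmp_path_factory.mktemp("panel"))
    return cfg, out


@pytest.fixture(scope="session")
def small_tag_table(small_read_panel):
    _cfg, out = small_read_panel
    res = io_demux.demultiplex(out["fastq_r1"], out["fastq_r2"], out["barcodes"])
    tags = tag_network.collapse_reads(io_demux.trim_stream(iter(res.assigned)))
    return out, tag_network.filter_singletons(tags)


def random_genotype_matrix(rng, n_lines=None, n_markers=None):
    n_lines = n_lines or int(rng.integers(1, 12))
    n_markers = n_markers or int(rng.integers(1, 20))
    calls = rng.choice(
        np.array([0, 1, 2, -1], dtype=np.int8), size=(n_lines, n_markers)
    )
    return GenotypeMatrix(
        [f"L{i}" for i in range(n_lines)],
        [f"m{j}" for j in range(n_markers)],
        calls,
        [("A", "C")] * n_markers,
    )


def make_tag(r1, r2, counts=None):
    return tag_network.Tag(r1, r2, dict(counts or {"L1": 1, "L2": 1}))
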