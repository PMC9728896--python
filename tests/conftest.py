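import numpy as np
import pytest

from popscan.genotype_io import GenotypeMatrix, PopulationMap
from popscan.simulate import SimConfig, simulate_wf


def make_gm(
    dosages,
    pos=None,
    chrom=None,
    qual=None,
    alts=None,
    samples=None,
    chrom_lengths=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (sites x samples) dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    if chrom is None:
        chrom = ["chr1"] * n_sites
    if qual is None:
        qual = np.full(n_sites, 60.0)
    if alts is None:
        alts = [("T",)] * n_sites
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if chrom_lengths is None:
        chrom_lengths = {c: int(max(np.asarray(pos)[np.asarray(chrom, dtype=object) == c], default=1))
                         for c in dict.fromkeys(chrom)} if n_sites else {}
    return GenotypeMatrix(
        samples=list(samples),
        chrom=np.array(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=["A"] * n_sites,
        alts=list(alts),
        qual=np.asarray(qual, dtype=float),
        dosages=dosages,
        chrom_lengths=dict(chrom_lengths),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small two-deme simulated dataset shared across tests."""
    cfg = SimConfig(
        seq_length=60_000,
        n_chrom=2,
        mu=8e-6,
        rec=5e-7,
        demes=[("wild", 30), ("dom", 30)],
        migration={"wild": {"dom": 0.01}, "dom": {"wild": 0.01}},
        sample_sizes={"wild": 12, "dom": 12},
        seed=1234,
    )
    gm, truth = simulate_wf(cfg)
    pm = PopulationMap({s: s.rsplit("_", 1)[0] for s in gm.samples})
    return gm, pm, truth
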