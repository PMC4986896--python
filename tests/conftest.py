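import pyfaidx
import pytest

from clipsplice.simulate import GenomeConfig, SimulatedGenome, make_genome, write_genome


@pytest.fixture(scope="session")
def small_sim() -> SimulatedGenome:
    return make_genome(GenomeConfig(n_genes=20), seed=7)


@pytest.fixture(scope="session")
def small_sim_files(small_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("genome")
    fa, gtf = d / "genome.fa", d / "annotation.gtf"
    write_genome(small_sim, str(fa), str(gtf))
    return {"fasta": fa, "gtf": gtf}


@pytest.fixture(scope="session")
def small_fasta(small_sim_files):
    return pyfaidx.Fasta(str(small_sim_files["fasta"]))
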