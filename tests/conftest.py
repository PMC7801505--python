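import pytest

from circpipe import simulate as sim

CHROM_LENGTHS = {"chr1": 2_000_000, "chr2": 1_000_000}


@pytest.fixture(scope="session")
def annotation():
    return sim.gen_annotation(1, n_genes=60, chrom_lengths=CHROM_LENGTHS)


@pytest.fixture(scope="session")
def truth(annotation):
    return sim.gen_truth(2, annotation, n_circs=40)


@pytest.fixture(scope="session")
def chains(truth):
    return sim.gen_chain_for_truth(3, truth, CHROM_LENGTHS)


@pytest.fixture(scope="session")
def circ_db(truth, chains):
    return sim.gen_circ_db(truth, chains)


@pytest.fixture(scope="session")
def design():
    return sim.encephalon_design()


@pytest.fixture(scope="session")
def mirna():
    from circpipe.sponge import MirnaRecord

    return MirnaRecord("miR-7", "UGGAAGACUAGUGAUUUUGUUGU", orthology_confident=True)
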