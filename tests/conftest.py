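import pytest

import gwaff
from gwaff import simulate as sim


@pytest.fixture(scope="session")
def mini_world():
    """A small but complete simulated experiment: 300 kb genome, rare
    cutter, 2 populations x 2 sampling replicates, one barcode per sample.
    Shared by tests that need realistic reads with known truth."""
    genome = gwaff.generate_genome(300_000, 0.5, seed=42)
    cfg = sim.SimConfig()
    fragments = gwaff.select_fragments(gwaff.digest(genome, gwaff.PSTI),
                                       cfg.min_fragment, cfg.max_fragment)
    weights = sim.assign_fragment_weights(fragments, cfg, seed=43)
    pops = sim.make_populations(genome, n_pops=2, seed=44)
    barcodes = sim.make_barcode_set(4, (4, 8), seed=45)
    samples = [("pop0", 1), ("pop0", 2), ("pop1", 1), ("pop1", 2)]
    reads = {}
    for i, (pop_name, rep) in enumerate(samples):
        pop = pops[0] if pop_name == "pop0" else pops[1]
        reads[(pop_name, rep)] = gwaff.generate_reads(
            pop, fragments, weights, barcodes.sequences[i], 8000, cfg,
            seed=100 + i)
    return {"genome": genome, "cfg": cfg, "fragments": fragments,
            "weights": weights, "populations": pops, "barcodes": barcodes,
            "samples": samples, "reads": reads}


@pytest.fixture(scope="session")
def mini_processed(mini_world):
    """mini_world taken through demultiplex + preprocess, per sample."""
    from gwaff.preprocess import demultiplex, preprocess_reads
    from gwaff.reads import Reads
    lane = Reads.concat(list(mini_world["reads"].values()))
    demux = demultiplex(lane, mini_world["barcodes"])
    out = {}
    for i, key in enumerate(mini_world["samples"]):
        barcode = mini_world["barcodes"].sequences[i]
        out[key] = preprocess_reads(demux.by_barcode[barcode])
    return out


@pytest.fixture(scope="session")
def mini_loci(mini_processed):
    from gwaff.assemble import assemble_loci
    from gwaff.reads import Reads
    return assemble_loci(Reads.concat(list(mini_processed.values())))
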