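import pytest
from hypothesis import settings

from umiasm.reads import Fragment
from umiasm.simulate import SimConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_fragment(chrom="chr1", blocks=((0, 100),), junctions=None,
                  strand="+", umi=None, cell_id=None, key=None,
                  mate1_strand="+", duplicate_flag=False):
    """Hand-built fragment; junctions default to the gaps between blocks."""
    blocks = tuple(tuple(b) for b in blocks)
    if junctions is None:
        junctions = tuple((a[1], b[0]) for a, b in zip(blocks, blocks[1:]))
    read_type = "umi" if umi else "internal"
    if key is None:
        key = (chrom, blocks, junctions, strand, umi)
    return Fragment(chrom=chrom, read_type=read_type, umi=umi, blocks=blocks,
                    junctions=tuple(junctions), strand=strand, dedup_key=key,
                    mate1_strand=mate1_strand, cell_id=cell_id,
                    duplicate_flag=duplicate_flag)


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """Noiseless 50-locus single-cell dataset with known ground truth."""
    out = tmp_path_factory.mktemp("clean")
    return simulate_dataset(SimConfig.clean(seed=7, n_loci=50), out)


@pytest.fixture(scope="session")
def ir_dataset(tmp_path_factory):
    """Same base reads as ``clean_dataset`` plus injected IR contamination."""
    out = tmp_path_factory.mktemp("ir")
    return simulate_dataset(SimConfig.with_intron_retention(seed=7, n_loci=50),
                            out)


@pytest.fixture(scope="session")
def multicell_dataset(tmp_path_factory):
    """Five cells with per-cell transcript dropout, for meta-assembly."""
    out = tmp_path_factory.mktemp("cells")
    cfg = SimConfig(seed=5, n_loci=20, n_cells=5, expressed_fraction=0.7)
    return simulate_dataset(cfg, out)


def intron_chains(transcripts):
    return {(t.chrom, t.strand, t.introns) for t in transcripts
            if len(t.exons) > 1}
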