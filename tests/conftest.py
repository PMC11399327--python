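import pytest

from ricat.annotation_model import TranscriptModel
from ricat.sim_reads import make_synthetic_annotation, simulate_dataset


@pytest.fixture(scope="session")
def small_annotation():
    """Tiny handcrafted two-gene annotation used across unit tests.

    GENE1 (+): A = exons (100,200)+(300,400)+(500,600); B skips the middle
    exon; C has an alternative TSS 400 bp downstream.
    GENE2 (-): single transcript, two exons.
    """
    a = TranscriptModel("A", "GENE1", "chr1", "+", ((100, 200), (300, 400), (500, 600)))
    b = TranscriptModel("B", "GENE1", "chr1", "+", ((100, 200), (500, 600)))
    c = TranscriptModel("C", "GENE1", "chr1", "+", ((500, 600),))
    d = TranscriptModel("D", "GENE2", "chr1", "-", ((2000, 2100), (2300, 2400)))
    return [a, b, c, d]


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The default 69-isoform + 92-species simulation (seed 7, noise-free),
    shared session-wide; alignment-only (FASTQ emitted by the tests that
    need it)."""
    outdir = tmp_path_factory.mktemp("default_sim")
    return simulate_dataset(outdir, seed=7, emit_fastq=False)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small, fast simulation: 12 isoforms over 2 genes + 8 species, 3 cells."""
    outdir = tmp_path_factory.mktemp("small_sim")
    return simulate_dataset(
        outdir,
        n_isoforms=12,
        n_genes=2,
        n_single=8,
        n_cells=3,
        multi_abundance=8.0,
        seed=11,
        emit_fastq=True,
    )


@pytest.fixture(scope="session")
def random_annotations():
    """A batch of random synthetic annotations for oracle comparisons."""
    out = []
    for seed in range(5):
        transcripts, _ = make_synthetic_annotation(
            n_isoforms=10, n_genes=2, n_single=3, seed=seed
        )
        out.append(transcripts)
    return out
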