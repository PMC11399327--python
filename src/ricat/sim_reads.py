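"""Synthetic-data generator: annotation, molecules, reads and alignments.

Produces everything the pipeline consumes, with ground truth:

* a multi-isoform annotation whose isoforms differ by alternative first
  exon (TSS), last exon (TES) and internal-exon composition, modelled on
  multi-isoform spike-in standards (69 isoforms over ~7 genes by default);
* a ladder of single-isoform species spanning >4 orders of magnitude of
  expected abundance (92 species, 23 x 2-fold levels by default);
* per-cell molecules carrying cell barcode + UMI (Poisson capture);
* paired 5'-end ("TSS") and 3'-end ("TES") library FASTQ reads in either
  dialect, the TES reads reverse-complemented as sequenced;
* spliced SAM alignments with CB/UB/GX tags, bypassing an external aligner.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64),
so every output is byte-deterministic per seed across platforms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ricat.annotation_model import TranscriptModel, write_gtf
from ricat.read_structure import Dialect, LOW_THROUGHPUT, reverse_complement

__all__ = [
    "SpikeTruth",
    "MoleculeRecord",
    "make_synthetic_annotation",
    "make_abundance_ladder",
    "cell_barcodes",
    "simulate_molecules",
    "synthetic_genome",
    "emit_reads",
    "emit_alignments",
    "simulate_dataset",
]

DEFAULT_N_ISOFORMS = 69
DEFAULT_N_GENES = 7
DEFAULT_N_SINGLE = 92
DEFAULT_CELLS = 6

MULTI_ABUNDANCE = 20.0  # expected molecules/cell for each multi-isoform transcript
LADDER_LEVELS = 23
LADDER_SPECIES_PER_LEVEL = 4
LADDER_BASE = 2.0 ** -12  # lowest expected molecules/cell; top = base * 2^22

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SpikeTruth:
    species_id: str
    transcript_id: str
    expected_abundance: float  # molecules per cell


@dataclass(frozen=True)
class MoleculeRecord:
    molecule_id: str
    cb: str
    umi: str
    transcript_id: str
    cell_id: str


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def cell_barcodes(n_cells: int, cb_len: int) -> list[str]:
    """Fixed per-cell barcode list: deterministic, independent of the
    simulation seed, pairwise distinct."""
    rng = np.random.default_rng(20240101)
    out: list[str] = []
    seen = set()
    while len(out) < n_cells:
        bc = _random_seq(rng, cb_len)
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _gene_scaffold(rng: np.random.Generator, n_exons: int, origin: int) -> list[tuple[int, int]]:
    exons = []
    pos = origin
    for _ in range(n_exons):
        length = int(rng.integers(150, 351))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(300, 601))
    return exons


def _isoform_combos(n_exons: int):
    """Deterministic enumeration of (first-exon, last-exon, middle-subset)
    choices in transcript orientation; every pair of combos differs in at
    least one end or one junction."""
    middles = list(range(2, n_exons - 2))
    subsets = []
    for r in range(len(middles), -1, -1):
        subsets.extend(itertools.combinations(middles, r))
    for first, last, subset in itertools.product((0, 1), (n_exons - 1, n_exons - 2), subsets):
        yield first, last, subset


def make_synthetic_annotation(
    n_isoforms: int = DEFAULT_N_ISOFORMS,
    n_genes: int = DEFAULT_N_GENES,
    n_single: int = DEFAULT_N_SINGLE,
    seed: int = 0,
    chrom: str = "chrS",
    gene_gap: int = 10_000,
) -> tuple[list[TranscriptModel], list[SpikeTruth]]:
    """Build the synthetic annotation: *n_isoforms* transcripts spread over
    *n_genes* multi-isoform genes plus *n_single* single-isoform ladder
    species, all on one contig.  Isoforms of a gene share an exon scaffold
    and differ by first exon, last exon and internal-exon subset, so every
    isoform carries at least one distinguishing feature.

    Returns (transcripts, abundance ladder truth for the single-isoform
    species).
    """
    if n_genes < 1 or n_isoforms < n_genes:
        raise ValueError("need n_isoforms >= n_genes >= 1")
    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptModel] = []
    cursor = gene_gap

    per_gene = [n_isoforms // n_genes] * n_genes
    for i in range(n_isoforms % n_genes):
        per_gene[i] += 1

    n_exons = 8
    max_combos = sum(1 for _ in _isoform_combos(n_exons))
    if max(per_gene) > max_combos:
        raise ValueError(f"cannot place {max(per_gene)} isoforms on one gene scaffold")

    for g, k in enumerate(per_gene, start=1):
        gene_id = f"SIM{g}"
        strand = "+" if g % 2 == 1 else "-"
        scaffold = _gene_scaffold(rng, n_exons, cursor)
        cursor = scaffold[-1][1] + gene_gap
        # transcript-orientation index -> genomic exon index
        order = list(range(n_exons)) if strand == "+" else list(range(n_exons - 1, -1, -1))
        for j, (first, last, subset) in enumerate(itertools.islice(_isoform_combos(n_exons), k), start=1):
            tx_indices = [first] + sorted(subset) + [last]
            genomic = sorted(order[i] for i in tx_indices)
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.i{j:02d}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(scaffold[i] for i in genomic),
                )
            )

    ladder = make_abundance_ladder(n_single)
    for sp in ladder:
        strand = "+"
        length = int(rng.integers(500, 1501))
        transcripts.append(
            TranscriptModel(
                transcript_id=sp.transcript_id,
                gene_id=sp.species_id,
                chrom=chrom,
                strand=strand,
                exons=((cursor, cursor + length),),
            )
        )
        cursor += length + gene_gap
    return transcripts, ladder


def make_abundance_ladder(
    n_species: int = DEFAULT_N_SINGLE,
    levels: int = LADDER_LEVELS,
    per_level: int = LADDER_SPECIES_PER_LEVEL,
    base: float = LADDER_BASE,
    fold: float = 2.0,
) -> list[SpikeTruth]:
    """Expected-abundance ladder: species at ``base * fold**level``
    molecules/cell, spread evenly over *levels* levels (*per_level* species
    per level at full capacity; >=4 orders of magnitude with the
    defaults)."""
    if n_species > levels * per_level:
        raise ValueError("n_species exceeds ladder capacity")
    out = []
    for i in range(n_species):
        level = (i * levels) // n_species if n_species < levels * per_level else i // per_level
        sid = f"ERCCS{i + 1:03d}"
        out.append(SpikeTruth(sid, f"{sid}.t1", base * fold**level))
    return out


def simulate_molecules(
    truth: Sequence[SpikeTruth],
    n_cells: int = DEFAULT_CELLS,
    depth_scale: float = 1.0,
    seed: int = 0,
    cb_len: int = LOW_THROUGHPUT.cb_len,
    umi_len: int = LOW_THROUGHPUT.umi_len,
) -> list[MoleculeRecord]:
    """Per cell and species, draw Poisson(expected_abundance * depth_scale)
    molecules, each with the cell's barcode and a uniform random UMI."""
    if depth_scale < 0:
        raise ValueError("depth_scale must be non-negative")
    rng = np.random.default_rng(seed)
    barcodes = cell_barcodes(n_cells, cb_len)
    out: list[MoleculeRecord] = []
    mol_no = 0
    for cell_idx, cb in enumerate(barcodes):
        cell_id = f"cell{cell_idx + 1}"
        for sp in truth:
            n = int(rng.poisson(sp.expected_abundance * depth_scale))
            if n == 0:
                continue
            umis = rng.choice(_BASES, size=(n, umi_len))
            for row in umis:
                mol_no += 1
                out.append(
                    MoleculeRecord(
                        molecule_id=f"mol{mol_no:07d}",
                        cb=cb,
                        umi=row.tobytes().decode(),
                        transcript_id=sp.transcript_id,
                        cell_id=cell_id,
                    )
                )
    return out


def synthetic_genome(transcripts: Sequence[TranscriptModel], seed: int = 0, margin: int = 1000) -> dict[str, str]:
    """Deterministic random genome long enough to hold every transcript."""
    rng = np.random.default_rng(seed + 773)
    lengths: dict[str, int] = {}
    for t in transcripts:
        lengths[t.chrom] = max(lengths.get(t.chrom, 0), t.span[1] + margin)
    return {chrom: _random_seq(rng, n) for chrom, n in sorted(lengths.items())}


def _transcript_sequence(t: TranscriptModel, genome: dict[str, str]) -> str:
    seq = "".join(genome[t.chrom][s:e] for s, e in t.exons)
    return seq if t.strand == "+" else reverse_complement(seq)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    subs = rng.choice(_BASES, size=len(hits))
    for i, b in zip(hits, subs):
        if arr[i] == b:  # force a change
            b = _BASES[(np.nonzero(_BASES == b)[0][0] + 1) % 4]
        arr[i] = b
    return arr.tobytes().decode()


def emit_reads(
    molecules: Sequence[MoleculeRecord],
    transcripts: Sequence[TranscriptModel],
    tss_fastq,
    tes_fastq,
    truth_tsv,
    dialect: Dialect = LOW_THROUGHPUT,
    noise_rate: float = 0.0,
    seed: int = 0,
    cdna_len: int = 80,
    genome: dict[str, str] | None = None,
) -> int:
    """Emit one 5'-end and one 3'-end library read per molecule, plus a
    ground-truth TSV (read_id, cb, umi, transcript_id, end_class).

    5'-end reads: anchor+CB+UMI+tag+TSO+cDNA(first *cdna_len* nt of the
    transcript).  3'-end reads carry anchor+CB+UMI+tag+cDNA(last
    *cdna_len* nt)+polyA and are written reverse-complemented, matching the
    sequencing orientation of the 3'-end library.  Returns the number of
    reads written per library.
    """
    rng = np.random.default_rng(seed)
    by_id = {t.transcript_id: t for t in transcripts}
    if genome is None:
        genome = synthetic_genome(transcripts, seed=0)
    tx_seq = {tid: _transcript_sequence(by_id[tid], genome) for tid in {m.transcript_id for m in molecules}}

    tag = dialect.tag
    polya = "A" * 12
    n = 0
    with open(tss_fastq, "w") as ftss, open(tes_fastq, "w") as ftes, open(truth_tsv, "w") as ftru:
        ftru.write("read_id\tcb\tumi\ttranscript_id\tend_class\n")
        for m in molecules:
            seq = tx_seq[m.transcript_id]
            head = dialect.anchor + m.cb + m.umi + tag
            cdna5 = seq[:cdna_len]
            cdna3 = seq[-cdna_len:]
            tss_read = _mutate(head + dialect.tso + cdna5, noise_rate, rng)
            tes_read = _mutate(reverse_complement(head + cdna3 + polya), noise_rate, rng)
            rid5, rid3 = f"{m.molecule_id}.T", f"{m.molecule_id}.E"
            ftss.write(f"@{rid5}\n{tss_read}\n+\n{'I' * len(tss_read)}\n")
            ftes.write(f"@{rid3}\n{tes_read}\n+\n{'I' * len(tes_read)}\n")
            ftru.write(f"{rid5}\t{m.cb}\t{m.umi}\t{m.transcript_id}\tTSS\n")
            ftru.write(f"{rid3}\t{m.cb}\t{m.umi}\t{m.transcript_id}\tTES\n")
            n += 1
    return n


def _map_to_blocks(t: TranscriptModel, tstart: int, tend: int) -> tuple[tuple[int, int], ...]:
    """Map a transcript-coordinate interval [tstart, tend) to genomic blocks."""
    exons = t.exons if t.strand == "+" else tuple(reversed(t.exons))
    blocks = []
    offset = 0
    for s, e in exons:
        elen = e - s
        lo, hi = max(tstart - offset, 0), min(tend - offset, elen)
        if lo < hi:
            if t.strand == "+":
                blocks.append((s + lo, s + hi))
            else:
                blocks.append((e - hi, e - lo))
        offset += elen
    return tuple(sorted(blocks))


def _blocks_to_cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def emit_alignments(
    molecules: Sequence[MoleculeRecord],
    transcripts: Sequence[TranscriptModel],
    tss_sam,
    tes_sam,
    coverage: str = "full",
    frag_len: int = 100,
) -> int:
    """Write spliced SAM alignments for every molecule, bypassing an
    external aligner.  Each record carries CB/UB/GX tags from truth plus an
    ``XE`` end-class tag.

    ``coverage="full"`` emits two overlapping half-molecule fragments per
    molecule (5'-anchored and 3'-anchored) that jointly cover the whole
    transcript — the concatemer-read regime where every feature of the
    molecule is observed.  ``coverage="ends"`` emits *frag_len*-limited end
    fragments only.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    lengths: dict[str, int] = {}
    for t in transcripts:
        lengths[t.chrom] = max(lengths.get(t.chrom, 0), t.span[1] + 1000)
    header_lines = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{c}\tLN:{n}" for c, n in sorted(lengths.items())
    ]

    # precompute per-transcript fragment windows and their blocks/cigars
    frag_cache: dict[str, list[tuple[str, int, str]]] = {}
    for tid in {m.transcript_id for m in molecules}:
        t = by_id[tid]
        L = t.length
        if coverage == "full":
            half = L // 2 + 25
            windows = [(0, min(half, L), "TSS"), (max(0, L - half), L, "TES")]
        elif coverage == "ends":
            windows = [(0, min(frag_len, L), "TSS"), (max(0, L - frag_len), L, "TES")]
        else:
            raise ValueError(f"unknown coverage mode {coverage!r}")
        entries = []
        flag = 16 if t.strand == "-" else 0
        for tstart, tend, end_class in windows:
            blocks = _map_to_blocks(t, tstart, tend)
            cigar = _blocks_to_cigar(blocks)
            fields = (
                f"{flag}\t{t.chrom}\t{blocks[0][0] + 1}\t255\t{cigar}\t*\t0\t0\t*\t*"
                f"\tCB:Z:{{cb}}\tUB:Z:{{umi}}\tGX:Z:{t.gene_id}\tXE:Z:{end_class}"
            )
            entries.append((end_class, fields))
        frag_cache[tid] = entries

    n = 0
    with open(tss_sam, "w") as ftss, open(tes_sam, "w") as ftes:
        for fh in (ftss, ftes):
            fh.write("\n".join(header_lines) + "\n")
        for m in molecules:
            for end_class, fields in frag_cache[m.transcript_id]:
                suffix = "T" if end_class == "TSS" else "E"
                line = f"{m.molecule_id}.{suffix}\t" + fields.format(cb=m.cb, umi=m.umi)
                (ftss if end_class == "TSS" else ftes).write(line + "\n")
                n += 1
    return n


def simulate_dataset(
    outdir,
    n_isoforms: int = DEFAULT_N_ISOFORMS,
    n_genes: int = DEFAULT_N_GENES,
    n_single: int = DEFAULT_N_SINGLE,
    n_cells: int = DEFAULT_CELLS,
    depth_scale: float = 1.0,
    multi_abundance: float = MULTI_ABUNDANCE,
    seed: int = 7,
    dialect: Dialect = LOW_THROUGHPUT,
    noise_rate: float = 0.0,
    emit_fastq: bool = True,
    coverage: str = "full",
) -> dict:
    """One-call fixture: annotation + molecules + reads + alignments + truth
    tables written under *outdir*.  Returns a manifest of paths and the
    in-memory objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, ladder = make_synthetic_annotation(
        n_isoforms=n_isoforms, n_genes=n_genes, n_single=n_single, seed=seed
    )
    write_gtf(transcripts, outdir / "annotation.gtf")

    truth = list(ladder) + [
        SpikeTruth(t.gene_id, t.transcript_id, multi_abundance)
        for t in transcripts
        if t.gene_id.startswith("SIM")
    ]
    molecules = simulate_molecules(
        truth,
        n_cells=n_cells,
        depth_scale=depth_scale,
        seed=seed,
        cb_len=dialect.cb_len,
        umi_len=dialect.umi_len,
    )
    with open(outdir / "molecules.tsv", "w") as fh:
        fh.write("molecule_id\tcb\tumi\ttranscript_id\tcell_id\n")
        for m in molecules:
            fh.write(f"{m.molecule_id}\t{m.cb}\t{m.umi}\t{m.transcript_id}\t{m.cell_id}\n")
    with open(outdir / "ladder.tsv", "w") as fh:
        fh.write("species_id\ttranscript_id\texpected_abundance\n")
        for sp in ladder:
            fh.write(f"{sp.species_id}\t{sp.transcript_id}\t{sp.expected_abundance!r}\n")

    manifest = {
        "annotation": outdir / "annotation.gtf",
        "molecules": outdir / "molecules.tsv",
        "ladder": outdir / "ladder.tsv",
        "tss_sam": outdir / "tss.sam",
        "tes_sam": outdir / "tes.sam",
        "transcripts": transcripts,
        "ladder_truth": ladder,
        "molecule_records": molecules,
    }
    emit_alignments(molecules, transcripts, manifest["tss_sam"], manifest["tes_sam"], coverage=coverage)
    if emit_fastq:
        manifest["tss_fastq"] = outdir / "tss.fastq"
        manifest["tes_fastq"] = outdir / "tes.fastq"
        manifest["read_truth"] = outdir / "read_truth.tsv"
        emit_reads(
            molecules,
            transcripts,
            manifest["tss_fastq"],
            manifest["tes_fastq"],
            manifest["read_truth"],
            dialect=dialect,
            noise_rate=noise_rate,
            seed=seed + 1,
        )
    return manifest
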