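"""Raw-read structure parsing: anchor search, CB/UMI extraction, trimming.

Both libraries carry the same anchored construct at the read 5' end:

    anchor + CB + UMI + tag [+ TSO + cDNA  (5'-end library)]
                            [+ cDNA + polyA (3'-end library)]

3'-end-library ("TES") reads are sequenced in the opposite orientation and
are reverse-complemented before the construct is parsed.  CB/UMI offsets
are 1-based within the anchored construct, mirroring common aligner
barcode parameters (low-throughput dialect: CB start 11 len 6, UMI start
17 len 12).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, TextIO

__all__ = [
    "Dialect",
    "TaggedRead",
    "RejectReason",
    "LOW_THROUGHPUT",
    "TENX",
    "DIALECTS",
    "parse_read",
    "reverse_complement",
    "tag_fastq",
    "TagSummary",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MIN_CDNA_LEN = 30
POLYT_MIN_RUN = 8  # minimum consecutive T accepted as the tenx polyT tag


class RejectReason:
    NO_ANCHOR = "no_anchor"
    BAD_TAG = "bad_tag"
    BAD_TSO = "bad_tso"
    SHORT_CDNA = "short_cdna"


@dataclass(frozen=True)
class Dialect:
    """Read-structure dialect: anchor/tag/TSO sequences and CB/UMI layout.

    ``cb_start``/``umi_start`` are 1-based positions within the anchored
    construct (position 1 = first base of the anchor).  A ``tag`` of all T
    is matched as a homopolymer run of >= POLYT_MIN_RUN rather than a fixed
    string.
    """

    name: str
    anchor: str
    tag: str
    tso: str
    cb_start: int
    cb_len: int
    umi_start: int
    umi_len: int

    @property
    def tag_is_polyt(self) -> bool:
        return set(self.tag) == {"T"}


LOW_THROUGHPUT = Dialect(
    name="low_throughput",
    anchor="AACGCAGAGT",
    tag="AGTTAACGCT",
    tso="GCAGGGTTGGG",
    cb_start=11,
    cb_len=6,
    umi_start=17,
    umi_len=12,
)

# 10x-style dialect: pattern read1-anchor + CB + UMI + polyT tag, TSO GAGTACATGGG.
# CB 16 nt / UMI 12 nt defaults; the source protocol states the pattern only.
TENX = Dialect(
    name="tenx",
    anchor="CTTCCGATCT",
    tag="TTTTTTTTTT",
    tso="GAGTACATGGG",
    cb_start=11,
    cb_len=16,
    umi_start=27,
    umi_len=12,
)

DIALECTS = {d.name: d for d in (LOW_THROUGHPUT, TENX)}


@dataclass(frozen=True)
class TaggedRead:
    read_id: str
    cb: str
    umi: str
    end_class: str  # "TSS" | "TES"
    cdna: str
    dialect: str


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (case-preserving)."""
    bad = set(seq) - set("ACGTNacgtn")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _hamming_leq(a: str, b: str, max_mm: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mm:
                return False
    return True


def _find_subseq(seq: str, pattern: str, max_mm: int, start: int = 0) -> int:
    """Leftmost position of *pattern* in *seq* with <= max_mm mismatches, or -1."""
    if max_mm == 0:
        return seq.find(pattern, start)
    n, m = len(seq), len(pattern)
    for i in range(start, n - m + 1):
        if _hamming_leq(seq[i : i + m], pattern, max_mm):
            return i
    return -1


def _run_length(seq: str, pos: int, base: str) -> int:
    i = pos
    while i < len(seq) and seq[i] == base:
        i += 1
    return i - pos


def parse_read(
    seq: str,
    dialect: Dialect,
    end_class: str,
    read_id: str = "",
    max_mismatches: int = 0,
    min_cdna_len: int = MIN_CDNA_LEN,
) -> TaggedRead | str:
    """Parse one read against the dialect's construct.

    Returns a :class:`TaggedRead` on success or a reject-reason string
    (one of :class:`RejectReason`) on failure.  TES-class reads are
    reverse-complemented before parsing; the cDNA of a TSS read is the
    sequence following the TSO, that of a TES read the sequence between the
    tag and the trailing polyA.
    """
    if end_class not in ("TSS", "TES"):
        raise ValueError(f"end_class must be TSS or TES, got {end_class!r}")
    oriented = reverse_complement(seq) if end_class == "TES" else seq

    p = _find_subseq(oriented, dialect.anchor, max_mismatches)
    if p < 0:
        return RejectReason.NO_ANCHOR
    cb_off = p + dialect.cb_start - 1
    umi_off = p + dialect.umi_start - 1
    cb = oriented[cb_off : cb_off + dialect.cb_len]
    umi = oriented[umi_off : umi_off + dialect.umi_len]
    if len(cb) < dialect.cb_len or len(umi) < dialect.umi_len:
        return RejectReason.BAD_TAG
    tag_off = umi_off + dialect.umi_len

    if dialect.tag_is_polyt:
        run = _run_length(oriented, tag_off, "T")
        if run < POLYT_MIN_RUN:
            return RejectReason.BAD_TAG
        after_tag = tag_off + run
    else:
        tag_obs = oriented[tag_off : tag_off + len(dialect.tag)]
        if len(tag_obs) < len(dialect.tag) or not _hamming_leq(tag_obs, dialect.tag, max_mismatches):
            return RejectReason.BAD_TAG
        after_tag = tag_off + len(dialect.tag)

    if end_class == "TSS":
        tso_obs = oriented[after_tag : after_tag + len(dialect.tso)]
        if len(tso_obs) < len(dialect.tso) or not _hamming_leq(tso_obs, dialect.tso, max_mismatches):
            return RejectReason.BAD_TSO
        cdna = oriented[after_tag + len(dialect.tso) :]
    else:
        cdna = oriented[after_tag:]
        # strip the trailing polyA tail (>=5 A keeps short A-rich 3' ends intact)
        tail = 0
        while tail < len(cdna) and cdna[-1 - tail] == "A":
            tail += 1
        if tail >= 5:
            cdna = cdna[: len(cdna) - tail]

    if len(cdna) < min_cdna_len:
        return RejectReason.SHORT_CDNA
    return TaggedRead(
        read_id=read_id, cb=cb, umi=umi, end_class=end_class, cdna=cdna, dialect=dialect.name
    )


@dataclass
class TagSummary:
    n_input: int = 0
    n_parsed: int = 0
    rejects: dict = None

    def __post_init__(self):
        if self.rejects is None:
            self.rejects = {}

    @property
    def n_rejected(self) -> int:
        return sum(self.rejects.values())


def _open_text(path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(fh: TextIO) -> Iterator[tuple[str, str, str]]:
    while True:
        header = fh.readline()
        if not header:
            return
        seq = fh.readline().rstrip("\n")
        fh.readline()  # +
        qual = fh.readline().rstrip("\n")
        if not header.startswith("@"):
            raise ValueError(f"malformed FASTQ record header: {header!r}")
        yield header[1:].split()[0].rstrip("\n"), seq, qual


def tag_fastq(
    fastq_in,
    fastq_out,
    sidecar_out,
    dialect: Dialect,
    end_class: str,
    max_mismatches: int = 0,
    min_cdna_len: int = MIN_CDNA_LEN,
) -> TagSummary:
    """Parse a FASTQ file, writing a cDNA-only FASTQ with ``CB``, ``UMI``
    and end-class encoded in the read headers, plus a TSV sidecar with one
    row per input read (parsed or rejected-with-reason).  Order-preserving.
    """
    summary = TagSummary()
    with _open_text(fastq_in) as fin, open(fastq_out, "w") as fout, open(sidecar_out, "w") as side:
        side.write("read_id\tcb\tumi\tend_class\treject_reason\n")
        for read_id, seq, qual in _iter_fastq(fin):
            summary.n_input += 1
            result = parse_read(
                seq.upper(), dialect, end_class, read_id=read_id,
                max_mismatches=max_mismatches, min_cdna_len=min_cdna_len,
            )
            if isinstance(result, TaggedRead):
                summary.n_parsed += 1
                header = f"{read_id}|CB:{result.cb}|UMI:{result.umi}|END:{end_class}"
                cq = "I" * len(result.cdna)
                fout.write(f"@{header}\n{result.cdna}\n+\n{cq}\n")
                side.write(f"{read_id}\t{result.cb}\t{result.umi}\t{end_class}\t.\n")
            else:
                summary.rejects[result] = summary.rejects.get(result, 0) + 1
                side.write(f"{read_id}\t.\t.\t{end_class}\t{result}\n")
    return summary
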