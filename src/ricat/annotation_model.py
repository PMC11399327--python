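"""Annotation model: GTF I/O, per-gene feature index, promoter windows.

Internal coordinates are 0-based half-open throughout; GTF files are
converted at the I/O boundary (GTF is 1-based inclusive).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "TranscriptModel",
    "FeatureIndex",
    "PromoterWindow",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "build_feature_index",
    "promoter_window",
    "indistinguishable_groups",
]

DEFAULT_TOLERANCE_BP = 50

# promoter: upstream 2000 bp / downstream 200 bp of the TSS, strand-aware
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 200


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"GTF line {lineno}: {message}")


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated isoform: gene, strand, ordered exon chain, TSS, TES.

    ``exons`` are 0-based half-open genomic intervals, sorted and disjoint.
    ``tss``/``tes`` are the strand-aware 5'/3' termini: on ``+`` the TSS is
    the start of the first exon and the TES the end of the last; on ``-``
    the roles are mirrored.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = tuple(tuple(e) for e in self.exons)
        for s, e in exons:
            if not (0 <= s < e):
                raise ValueError(f"{self.transcript_id}: bad exon interval ({s},{e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if e0 > s1:
                raise ValueError(f"{self.transcript_id}: exons unsorted or overlapping")
        object.__setattr__(self, "exons", exons)

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def tes(self) -> int:
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (end of one exon, start of the next), 0-based half-open."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def feature_key(self) -> tuple:
        """Exact feature triple used to decide indistinguishability."""
        return (self.tss, self.tes, self.junctions)


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    transcript_id: str
    chrom: str
    interval: tuple[int, int]
    strand: str


@dataclass
class _GeneIndex:
    """Per-gene end/junction lookups; positions kept sorted for bisect."""

    gene_id: str
    chrom: str
    strand: str
    transcript_ids: list[str] = field(default_factory=list)
    tss_positions: list[int] = field(default_factory=list)  # sorted
    tes_positions: list[int] = field(default_factory=list)  # sorted
    tss_to_tx: dict[int, set[str]] = field(default_factory=dict)
    tes_to_tx: dict[int, set[str]] = field(default_factory=dict)
    junction_to_tx: dict[tuple[int, int], set[str]] = field(default_factory=dict)
    tx_junctions: dict[str, frozenset[tuple[int, int]]] = field(default_factory=dict)


class FeatureIndex:
    """Index over annotated TSS/TES positions and splice junctions per gene.

    Answers, for an observed end position or junction, which transcripts of
    a gene carry a compatible feature.  End matching uses ``tolerance_bp``:
    an observed end matches an annotated end iff |obs - ann| <= tolerance.
    Two annotated ends closer than twice the tolerance are kept distinct; a
    query may match both.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel], tolerance_bp: int = DEFAULT_TOLERANCE_BP):
        if tolerance_bp < 0:
            raise ValueError("tolerance_bp must be non-negative")
        self.tolerance_bp = int(tolerance_bp)
        self._genes: dict[str, _GeneIndex] = {}
        self._transcripts: dict[str, TranscriptModel] = {}
        for t in transcripts:
            self._transcripts[t.transcript_id] = t
            gi = self._genes.get(t.gene_id)
            if gi is None:
                gi = self._genes[t.gene_id] = _GeneIndex(t.gene_id, t.chrom, t.strand)
            gi.transcript_ids.append(t.transcript_id)
            gi.tss_to_tx.setdefault(t.tss, set()).add(t.transcript_id)
            gi.tes_to_tx.setdefault(t.tes, set()).add(t.transcript_id)
            gi.tx_junctions[t.transcript_id] = frozenset(t.junctions)
            for j in t.junctions:
                gi.junction_to_tx.setdefault(j, set()).add(t.transcript_id)
        for gi in self._genes.values():
            gi.tss_positions = sorted(gi.tss_to_tx)
            gi.tes_positions = sorted(gi.tes_to_tx)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    @property
    def genes(self) -> list[str]:
        return list(self._genes)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    def gene_transcripts(self, gene_id: str) -> list[str]:
        return list(self._genes[gene_id].transcript_ids)

    def _match_end(self, positions: list[int], pos_to_tx: dict[int, set[str]], pos: int) -> set[str]:
        lo = bisect.bisect_left(positions, pos - self.tolerance_bp)
        hi = bisect.bisect_right(positions, pos + self.tolerance_bp)
        out: set[str] = set()
        for p in positions[lo:hi]:
            out |= pos_to_tx[p]
        return out

    def match_tss(self, gene_id: str, pos: int) -> set[str]:
        """Transcripts of *gene_id* whose annotated TSS is within tolerance of *pos*."""
        gi = self._genes.get(gene_id)
        if gi is None:
            return set()
        return self._match_end(gi.tss_positions, gi.tss_to_tx, pos)

    def match_tes(self, gene_id: str, pos: int) -> set[str]:
        gi = self._genes.get(gene_id)
        if gi is None:
            return set()
        return self._match_end(gi.tes_positions, gi.tes_to_tx, pos)

    def match_junction(self, gene_id: str, junction: tuple[int, int]) -> set[str]:
        """Transcripts carrying exactly this intron (donor, acceptor) pair."""
        gi = self._genes.get(gene_id)
        if gi is None:
            return set()
        return set(gi.junction_to_tx.get(tuple(junction), set()))

    def transcript_junctions(self, transcript_id: str) -> frozenset[tuple[int, int]]:
        t = self._transcripts[transcript_id]
        return self._genes[t.gene_id].tx_junctions[transcript_id]


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(lineno, f"malformed attribute {chunk!r}")
        key, val = parts
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into :class:`TranscriptModel` objects.

    Coordinates are converted from GTF 1-based inclusive to 0-based
    half-open.  Only ``exon`` features are used; each must carry ``gene_id``
    and ``transcript_id`` attributes.  Transcript order follows first
    appearance in the file.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start < 1 or end < start:
                raise GtfParseError(lineno, f"invalid interval [{start},{end}]")
            if strand not in ("+", "-"):
                raise GtfParseError(lineno, f"invalid strand {strand!r}")
            attrs = _parse_attributes(attr, lineno)
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(lineno, "exon lacks gene_id/transcript_id attribute")
            tx = attrs["transcript_id"]
            if tx not in meta:
                meta[tx] = (attrs["gene_id"], chrom, strand)
                order.append(tx)
            exons.setdefault(tx, []).append((start - 1, end))  # to 0-based half-open
    out = []
    for tx in order:
        gene, chrom, strand = meta[tx]
        out.append(
            TranscriptModel(
                transcript_id=tx,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(exons[tx])),
            )
        )
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path, source: str = "ricat") -> None:
    """Write transcripts as GTF exon records (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for i, (s, e) in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def build_feature_index(
    transcripts: Iterable[TranscriptModel], tolerance_bp: int = DEFAULT_TOLERANCE_BP
) -> FeatureIndex:
    """Build the per-gene TSS/TES/junction lookup used for isoform matching."""
    return FeatureIndex(transcripts, tolerance_bp=tolerance_bp)


def promoter_window(
    t: TranscriptModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    contig_length: int | None = None,
) -> PromoterWindow:
    """Strand-aware promoter interval around the TSS: upstream 2000 bp and
    downstream 200 bp by default, clamped at 0 (and at the contig end when
    its length is known)."""
    if t.strand == "+":
        lo, hi = t.tss - upstream, t.tss + downstream
    else:
        lo, hi = t.tss - downstream, t.tss + upstream
    lo = max(0, lo)
    if contig_length is not None:
        hi = min(hi, contig_length)
    return PromoterWindow(
        gene_id=t.gene_id,
        transcript_id=t.transcript_id,
        chrom=t.chrom,
        interval=(lo, hi),
        strand=t.strand,
    )


def indistinguishable_groups(transcripts: Iterable[TranscriptModel]) -> list[frozenset[str]]:
    """Group transcripts of each gene that share the exact (TSS, TES,
    junction-set) feature triple and therefore cannot be told apart by the
    assignment algorithm.  Every transcript appears in exactly one group;
    distinguishable transcripts form singleton groups."""
    by_key: dict[tuple, set[str]] = {}
    for t in transcripts:
        by_key.setdefault((t.gene_id, t.feature_key()), set()).add(t.transcript_id)
    return [frozenset(v) for v in by_key.values()]
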