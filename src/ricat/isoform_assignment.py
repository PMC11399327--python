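"""Core isoform-assignment algorithm.

Merges 5'- and 3'-end library alignments, collapses reads sharing
(cell barcode, gene, UMI) into molecule groups, matches each group's
observed features (end positions, splice junctions, contiguous coverage
across annotated introns) against the annotation, assigns UMIs directly
when a single isoform is compatible, and rescues ambiguous UMIs by an
empirical-abundance arg-max ("maximal probability") pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from scipy import sparse
from scipy.io import mmwrite

from ricat.annotation_model import FeatureIndex, build_feature_index, read_gtf

__all__ = [
    "AlignedFragment",
    "UmiGroup",
    "Assignment",
    "MatchEvidence",
    "IsoformCountMatrix",
    "AssignConfig",
    "group_umis",
    "match_features",
    "assign_direct",
    "assign_probabilistic",
    "build_matrix",
    "run_pipeline",
    "read_tagged_sam",
    "write_matrix",
]

END_TSS = "TSS"
END_TES = "TES"
END_INTERNAL = "internal"  # extra fragments carrying junction evidence only

METHOD_DIRECT = "direct"
METHOD_PROBABILISTIC = "probabilistic"
METHOD_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AlignedFragment:
    """An aligned read with barcode/UMI/gene tags and its aligned blocks."""

    read_id: str
    cb: str
    umi: str
    end_class: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    gene_id: str | None = None

    def __post_init__(self):
        blocks = tuple(tuple(b) for b in self.blocks)
        for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
            if e0 > s1:
                raise ValueError(f"{self.read_id}: blocks unsorted or overlapping")
        object.__setattr__(self, "blocks", blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        return tuple((e0, s1) for (_, e0), (s1, _) in zip(self.blocks, self.blocks[1:]))

    def five_prime(self, gene_strand: str) -> int:
        return self.start if gene_strand == "+" else self.end

    def three_prime(self, gene_strand: str) -> int:
        return self.end if gene_strand == "+" else self.start


@dataclass
class UmiGroup:
    """All fragments sharing one (cell barcode, gene, UMI) key — one molecule."""

    key: tuple[str, str, str]  # (cb, gene_id, umi)
    fragments: list[AlignedFragment]

    @property
    def cb(self) -> str:
        return self.key[0]

    @property
    def gene_id(self) -> str:
        return self.key[1]

    @property
    def umi(self) -> str:
        return self.key[2]

    @property
    def end_classes_present(self) -> frozenset[str]:
        return frozenset(f.end_class for f in self.fragments)


@dataclass(frozen=True)
class MatchEvidence:
    tss_matched: bool
    tes_matched: bool
    junctions_matched: int


@dataclass
class Assignment:
    key: tuple[str, str, str]
    transcript_id: str | None
    compat: frozenset[str]
    method: str
    evidence: MatchEvidence | None = None
    reason: str | None = None


@dataclass
class IsoformCountMatrix:
    """Sparse isoform x cell UMI-count matrix with assignment provenance."""

    transcript_ids: list[str]
    barcodes: list[str]
    counts: sparse.csr_matrix
    direct_counts: sparse.csr_matrix
    probabilistic_counts: sparse.csr_matrix
    summary: dict = field(default_factory=dict)

    def total(self, transcript_id: str) -> int:
        i = self.transcript_ids.index(transcript_id)
        return int(self.counts[i].sum())

    def totals_by_transcript(self) -> dict[str, int]:
        sums = np.asarray(self.counts.sum(axis=1)).ravel()
        return {t: int(s) for t, s in zip(self.transcript_ids, sums)}


@dataclass
class AssignConfig:
    tolerance_bp: int = 50
    require_both_ends: bool = False
    pseudocount: float = 1.0
    pool_across_cells: bool = True
    em_iterations: int = 0  # optional iterative refinement of the rescue pass
    cb_tag: str = "CB"
    umi_tag: str = "UB"
    gene_tag: str = "GX"
    end_tag: str = "XE"


def group_umis(fragments: Iterable[AlignedFragment]) -> tuple[list[UmiGroup], dict]:
    """Collapse fragments by (cb, gene_id, umi).

    Fragments without a gene assignment (or tagged to multiple genes,
    encoded as a ';'-separated gene_id) are dropped and counted.  Group
    order is deterministic: sorted by key.
    """
    dropped = {"no_gene": 0, "multi_gene": 0}
    groups: dict[tuple[str, str, str], list[AlignedFragment]] = {}
    for f in fragments:
        if f.gene_id is None or f.gene_id in ("", "-", "."):
            dropped["no_gene"] += 1
            continue
        if ";" in f.gene_id:
            dropped["multi_gene"] += 1
            continue
        groups.setdefault((f.cb, f.gene_id, f.umi), []).append(f)
    out = [UmiGroup(key=k, fragments=groups[k]) for k in sorted(groups)]
    return out, dropped


def _block_spans_junction(blocks: Sequence[tuple[int, int]], junction: tuple[int, int]) -> bool:
    js, je = junction
    return any(s < js and e > je for s, e in blocks)


def match_features(
    group: UmiGroup, index: FeatureIndex
) -> tuple[frozenset[str], MatchEvidence | str]:
    """Compute the isoform compatibility set for one UMI group.

    Starting from all isoforms of the group's gene, intersect with
    (a) isoforms whose annotated TSS lies within tolerance of the 5'
    terminus of any TSS-class fragment, (b) likewise for TES, (c) isoforms
    carrying every junction observed in split alignments, and remove
    isoforms spliced where a fragment block aligns contiguously across the
    annotated intron.  Fragments on the wrong strand are ignored.
    """
    gene_id = group.gene_id
    if gene_id not in index:
        return frozenset(), "gene_not_in_annotation"
    gene_strand = index.transcript(index.gene_transcripts(gene_id)[0]).strand
    frags = [f for f in group.fragments if f.strand == gene_strand]
    if not frags:
        return frozenset(), "strand_mismatch"

    compat: set[str] = set(index.gene_transcripts(gene_id))

    tss_frags = [f for f in frags if f.end_class == END_TSS]
    tes_frags = [f for f in frags if f.end_class == END_TES]

    tss_matched = False
    if tss_frags:
        hits: set[str] = set()
        for f in tss_frags:
            hits |= index.match_tss(gene_id, f.five_prime(gene_strand))
        compat &= hits
        tss_matched = bool(hits)
    tes_matched = False
    if tes_frags:
        hits = set()
        for f in tes_frags:
            hits |= index.match_tes(gene_id, f.three_prime(gene_strand))
        compat &= hits
        tes_matched = bool(hits)

    observed_junctions: set[tuple[int, int]] = set()
    all_blocks: list[tuple[int, int]] = []
    for f in frags:
        observed_junctions.update(f.junctions)
        all_blocks.extend(f.blocks)
    for j in observed_junctions:
        compat &= index.match_junction(gene_id, j)

    # contiguous alignment across an annotated intron excludes isoforms spliced there
    if compat and all_blocks:
        compat = {
            t
            for t in compat
            if not any(
                _block_spans_junction(all_blocks, j) for j in index.transcript_junctions(t)
            )
        }

    evidence = MatchEvidence(
        tss_matched=tss_matched,
        tes_matched=tes_matched,
        junctions_matched=len(observed_junctions),
    )
    return frozenset(compat), evidence


def assign_direct(key, compat: frozenset[str], evidence=None) -> Assignment:
    """Direct assignment: unique compatibility → direct; several → ambiguous
    (deferred to the probabilistic pass); none → unassigned."""
    if len(compat) == 1:
        return Assignment(key, next(iter(compat)), compat, METHOD_DIRECT, evidence)
    if len(compat) > 1:
        return Assignment(key, None, compat, METHOD_UNASSIGNED, evidence, reason="ambiguous")
    return Assignment(key, None, compat, METHOD_UNASSIGNED, evidence, reason="no_compatible")


def assign_probabilistic(
    ambiguous: list[Assignment],
    direct_assignments: list[Assignment],
    config: AssignConfig | None = None,
) -> list[Assignment]:
    """Rescue ambiguous UMIs by maximal estimated probability.

    Each ambiguous UMI is assigned to the isoform of its compatibility set
    with the highest empirical abundance among directly assigned UMIs of
    the same gene (pooled across cells by default, per cell behind
    ``pool_across_cells=False``), plus a pseudocount; ties break to the
    lexicographically smallest transcript_id.  ``em_iterations > 0``
    iterates the abundance estimate including rescued UMIs.
    """
    config = config or AssignConfig()

    def count_key(a: Assignment):
        gene = a.key[1]
        return gene if config.pool_across_cells else (a.key[0], gene)

    counts: dict = {}
    for a in direct_assignments:
        if a.method == METHOD_DIRECT:
            counts.setdefault(count_key(a), {})
            counts[count_key(a)][a.transcript_id] = (
                counts[count_key(a)].get(a.transcript_id, 0) + 1
            )

    def resolve(a: Assignment, tally: dict) -> str:
        gene_counts = tally.get(count_key(a), {})
        best = min(
            a.compat,
            key=lambda t: (-(gene_counts.get(t, 0) + config.pseudocount), t),
        )
        return best

    out = []
    for a in ambiguous:
        tx = resolve(a, counts)
        out.append(Assignment(a.key, tx, a.compat, METHOD_PROBABILISTIC, a.evidence))

    for _ in range(config.em_iterations):
        tally = {k: dict(v) for k, v in counts.items()}
        for a in out:
            tally.setdefault(count_key(a), {})
            tally[count_key(a)][a.transcript_id] = tally[count_key(a)].get(a.transcript_id, 0) + 1
        new_out = []
        changed = False
        for a in out:
            tx = resolve(a, tally)
            if tx != a.transcript_id:
                changed = True
            new_out.append(Assignment(a.key, tx, a.compat, METHOD_PROBABILISTIC, a.evidence))
        out = new_out
        if not changed:
            break
    return out


def build_matrix(
    assignments: Iterable[Assignment],
    transcript_ids: Sequence[str] | None = None,
    barcodes: Sequence[str] | None = None,
) -> IsoformCountMatrix:
    """Count assigned UMIs per (transcript, cell); unassigned UMIs are
    excluded from the matrix but tallied in ``summary``."""
    assignments = list(assignments)
    assigned = [a for a in assignments if a.transcript_id is not None]
    summary = {
        "n_groups": len(assignments),
        "n_assigned": len(assigned),
        "n_direct": sum(1 for a in assigned if a.method == METHOD_DIRECT),
        "n_probabilistic": sum(1 for a in assigned if a.method == METHOD_PROBABILISTIC),
        "n_unassigned": sum(1 for a in assignments if a.transcript_id is None),
        "unassigned_reasons": {},
    }
    for a in assignments:
        if a.transcript_id is None and a.reason:
            summary["unassigned_reasons"][a.reason] = (
                summary["unassigned_reasons"].get(a.reason, 0) + 1
            )

    if transcript_ids is None:
        transcript_ids = sorted({a.transcript_id for a in assigned})
    if barcodes is None:
        barcodes = sorted({a.key[0] for a in assigned})
    t_idx = {t: i for i, t in enumerate(transcript_ids)}
    b_idx = {b: i for i, b in enumerate(barcodes)}

    shape = (len(transcript_ids), len(barcodes))
    mats = {}
    for label, subset in (
        ("all", assigned),
        (METHOD_DIRECT, [a for a in assigned if a.method == METHOD_DIRECT]),
        (METHOD_PROBABILISTIC, [a for a in assigned if a.method == METHOD_PROBABILISTIC]),
    ):
        rows = [t_idx[a.transcript_id] for a in subset]
        cols = [b_idx[a.key[0]] for a in subset]
        mats[label] = sparse.coo_matrix(
            (np.ones(len(subset), dtype=np.int64), (rows, cols)), shape=shape
        ).tocsr()

    return IsoformCountMatrix(
        transcript_ids=list(transcript_ids),
        barcodes=list(barcodes),
        counts=mats["all"],
        direct_counts=mats[METHOD_DIRECT],
        probabilistic_counts=mats[METHOD_PROBABILISTIC],
        summary=summary,
    )


def read_tagged_sam(path, end_class_default: str, config: AssignConfig | None = None) -> list[AlignedFragment]:
    """Read aligned fragments from a SAM/BAM file with CB/UB/GX-style tags.

    ``end_class_default`` labels records lacking the optional end-class tag
    (``XE``); files produced by the simulator carry it per record.  Raises
    on the first record missing the CB/UMI tags.
    """
    config = config or AssignConfig()
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            tags = dict(rec.get_tags())
            if config.cb_tag not in tags or config.umi_tag not in tags:
                raise ValueError(
                    f"{path}: record {rec.query_name!r} lacks {config.cb_tag}/{config.umi_tag} tags"
                )
            gene = tags.get(config.gene_tag)
            end_class = tags.get(config.end_tag, end_class_default)
            blocks = rec.get_blocks()
            if not blocks:
                continue
            out.append(
                AlignedFragment(
                    read_id=rec.query_name,
                    cb=tags[config.cb_tag],
                    umi=tags[config.umi_tag],
                    end_class=end_class,
                    chrom=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    blocks=tuple(blocks),
                    gene_id=gene,
                )
            )
    return out


def assign_groups(
    groups: list[UmiGroup], index: FeatureIndex, config: AssignConfig | None = None
) -> list[Assignment]:
    """Run the direct + probabilistic assignment passes over UMI groups."""
    config = config or AssignConfig()
    direct: list[Assignment] = []
    ambiguous: list[Assignment] = []
    for g in groups:
        if config.require_both_ends and not {END_TSS, END_TES} <= set(g.end_classes_present):
            direct.append(
                Assignment(g.key, None, frozenset(), METHOD_UNASSIGNED, reason="missing_end")
            )
            continue
        compat, evidence = match_features(g, index)
        if isinstance(evidence, str):
            direct.append(
                Assignment(g.key, None, frozenset(), METHOD_UNASSIGNED, reason=evidence)
            )
            continue
        a = assign_direct(g.key, compat, evidence)
        if a.reason == "ambiguous":
            ambiguous.append(a)
        else:
            direct.append(a)
    rescued = assign_probabilistic(ambiguous, direct, config)
    return direct + rescued


def run_pipeline(
    tss_alignments,
    tes_alignments,
    annotation,
    config: AssignConfig | None = None,
    return_assignments: bool = False,
):
    """End-to-end assignment: merge both libraries' alignments, group by
    (cb, gene, umi), match features, assign directly then probabilistically,
    and build the isoform x cell matrix.  Deterministic given inputs and
    config, regardless of record order.

    *annotation* may be a GTF path or a pre-built list of TranscriptModel.
    """
    config = config or AssignConfig()
    if isinstance(annotation, (str, Path)):
        transcripts = read_gtf(annotation)
    else:
        transcripts = list(annotation)
    index = build_feature_index(transcripts, tolerance_bp=config.tolerance_bp)

    fragments: list[AlignedFragment] = []
    if tss_alignments is not None:
        fragments.extend(read_tagged_sam(tss_alignments, END_TSS, config))
    if tes_alignments is not None:
        fragments.extend(read_tagged_sam(tes_alignments, END_TES, config))

    groups, dropped = group_umis(fragments)
    assignments = assign_groups(groups, index, config)
    matrix = build_matrix(
        assignments,
        transcript_ids=[t.transcript_id for t in transcripts],
        barcodes=sorted({g.cb for g in groups}),
    )
    matrix.summary["n_fragments"] = len(fragments)
    matrix.summary["dropped_fragments"] = dropped
    if return_assignments:
        return matrix, assignments
    return matrix


def write_matrix(matrix: IsoformCountMatrix, outdir, gene_ids: dict | None = None) -> None:
    """Write MTX + features.tsv + barcodes.tsv + report.json into *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), matrix.counts.tocoo())
    with open(outdir / "features.tsv", "w") as fh:
        for t in matrix.transcript_ids:
            gene = gene_ids.get(t, ".") if gene_ids else "."
            fh.write(f"{t}\t{gene}\n")
    with open(outdir / "barcodes.tsv", "w") as fh:
        for b in matrix.barcodes:
            fh.write(b + "\n")
    with open(outdir / "report.json", "w") as fh:
        json.dump(matrix.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
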