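"""Downstream statistics on isoform matrices and accessibility peaks.

Covers: pairwise alternative-splicing event classification between
isoforms (AP/APA/SE/RI/MXE/A3SS/A5SS), Wilcoxon rank-sum differential
tables for isoform expression (|log2FC| > 0.25, BH-adjusted p < 0.05) and
peak accessibility (|log2FC| > 0.1, raw p < 0.0005), isoform-switch dIF
flags, peak-to-promoter annotation, and the fraction of splicing sites
whose +/-100 bp window overlaps a differentially accessible region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from ricat.annotation_model import TranscriptModel, promoter_window

__all__ = [
    "ASEvent",
    "Peak",
    "classify_as_events",
    "differential_isoforms",
    "differential_peaks",
    "isoform_switches",
    "annotate_peaks_to_promoters",
    "splice_site_dar_overlap",
    "splice_site_windows",
]

# event types
AP = "AP"
APA = "APA"
SE = "SE"
RI = "RI"
MXE = "MXE"
A3SS = "A3SS"
A5SS = "A5SS"

EXPR_LOG2FC_CUTOFF = 0.25
EXPR_ADJ_P_CUTOFF = 0.05
PEAK_LOG2FC_CUTOFF = 0.1
PEAK_P_CUTOFF = 0.0005
SWITCH_DIF_CUTOFF = 0.1
SWITCH_ALPHA = 0.05
SPLICE_WINDOW_BP = 100


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    event_type: str
    site: tuple[int, int]  # genomic interval of the differential region
    isoform_pair: tuple[str, str]
    chrom: str = "."


@dataclass(frozen=True)
class Peak:
    chrom: str
    interval: tuple[int, int]
    peak_id: str = ""


def _donor_acceptor(junction: tuple[int, int], strand: str) -> tuple[int, int]:
    """(donor, acceptor) genomic positions of an intron, strand-aware: the
    donor is the 5' splice site, the acceptor the 3' splice site."""
    s, e = junction
    return (s, e) if strand == "+" else (e, s)


def classify_as_events(
    a: TranscriptModel, b: TranscriptModel, tolerance_bp: int = 0
) -> list[ASEvent]:
    """Classify the alternative-splicing differences between two isoforms of
    the same gene.  Multiple events may co-occur; each is reported with the
    genomic interval of its differential region:

    * AP  — TSS differ beyond tolerance (site: interval between the TSSs)
    * APA — TES differ (likewise)
    * SE  — internal exon of one absent from the other, flanking junctions
      shared (site: the skipped exon)
    * RI  — one isoform's exon spans the other's intron with shared outer
      boundaries (site: the retained intron)
    * MXE — two mutually exclusive internal exons with shared outer flanks
      (site: hull of the two exons)
    * A3SS / A5SS — junctions sharing the donor (resp. acceptor) but not the
      acceptor (resp. donor); strand-aware (site: between the two
      alternative splice sites)
    """
    if a.gene_id != b.gene_id:
        raise ValueError(f"different genes: {a.gene_id} vs {b.gene_id}")
    if a.strand != b.strand:
        raise ValueError("isoforms on different strands")
    strand = a.strand
    events: list[ASEvent] = []
    pair = (a.transcript_id, b.transcript_id)

    def ev(event_type: str, lo: int, hi: int) -> ASEvent:
        return ASEvent(a.gene_id, event_type, (min(lo, hi), max(lo, hi)), pair, a.chrom)

    if abs(a.tss - b.tss) > tolerance_bp:
        events.append(ev(AP, a.tss, b.tss))
    if abs(a.tes - b.tes) > tolerance_bp:
        events.append(ev(APA, a.tes, b.tes))

    ja, jb = set(a.junctions), set(b.junctions)
    exa, exb = set(a.exons), set(b.exons)

    def skipped_exons(x: TranscriptModel, jx: set, jy: set, exy: set) -> list[tuple[int, int]]:
        out = []
        for i in range(1, len(x.exons) - 1):
            exon = x.exons[i]
            up = (x.exons[i - 1][1], exon[0])
            down = (exon[1], x.exons[i + 1][0])
            merged = (up[0], down[1])
            if exon not in exy and up in jx and down in jx and merged in jy:
                out.append(exon)
        return out

    se_a = skipped_exons(a, ja, jb, exb)  # exons present in a, skipped in b
    se_b = skipped_exons(b, jb, ja, exa)
    for exon in se_a + se_b:
        events.append(ev(SE, *exon))

    # RI: an exon of x equals the fusion of two exons of y across a y-intron
    def retained(x: TranscriptModel, y: TranscriptModel) -> list[tuple[int, int]]:
        out = []
        yex = set(y.exons)
        for js, je in y.junctions:
            for s, e in x.exons:
                if (s, js) in yex and (je, e) in yex and s < js and je < e:
                    out.append((js, je))
        return out

    for intron in retained(a, b) + retained(b, a):
        events.append(ev(RI, *intron))

    # MXE: internal exon of a and internal exon of b, mutually exclusive,
    # with shared flanking junction endpoints
    for i in range(1, len(a.exons) - 1):
        e1 = a.exons[i]
        if e1 in exb:
            continue
        f1, f2 = a.exons[i - 1][1], a.exons[i + 1][0]
        for j in range(1, len(b.exons) - 1):
            e2 = b.exons[j]
            if e2 in exa or not (e1[1] <= e2[0] or e2[1] <= e1[0]):
                continue
            g1, g2 = b.exons[j - 1][1], b.exons[j + 1][0]
            if f1 == g1 and f2 == g2:
                events.append(ev(MXE, min(e1[0], e2[0]), max(e1[1], e2[1])))

    # A3SS / A5SS over junction pairs sharing exactly one splice site; the
    # exons flanking the alternative site must overlap (otherwise the
    # difference is an SE/MXE-type exon change, not a shifted splice site)
    def _overlap(x: tuple[int, int], y: tuple[int, int]) -> bool:
        return x[0] < y[1] and y[0] < x[1]

    start_a = {e[0]: e for e in a.exons}
    start_b = {e[0]: e for e in b.exons}
    end_a = {e[1]: e for e in a.exons}
    end_b = {e[1]: e for e in b.exons}
    for s1, e1 in ja - jb:
        for s2, e2 in jb - ja:
            if s1 == s2 and e1 != e2 and _overlap(start_a[e1], start_b[e2]):
                # shared genomic-left splice site: donor on +, acceptor on -
                events.append(ev(A3SS if strand == "+" else A5SS, e1, e2))
            elif e1 == e2 and s1 != s2 and _overlap(end_a[s1], end_b[s2]):
                events.append(ev(A5SS if strand == "+" else A3SS, s1, s2))
    return events


def _normalize_cp10k_log1p(counts: np.ndarray) -> np.ndarray:
    """Counts-per-10k per cell followed by log1p (columns are cells)."""
    counts = np.asarray(counts, dtype=float)
    libsize = counts.sum(axis=0)
    libsize[libsize == 0] = 1.0
    return np.log1p(counts / libsize * 1e4)


def _wilcoxon_table(
    counts: np.ndarray,
    feature_ids: Sequence[str],
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    normalize: bool = True,
) -> pd.DataFrame:
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each group needs >= 3 cells")
    data = _normalize_cp10k_log1p(counts) if normalize else np.asarray(counts, dtype=float)
    xa, xb = data[:, mask_a], data[:, mask_b]
    pvals = np.ones(len(feature_ids))
    for i in range(len(feature_ids)):
        va, vb = xa[i], xb[i]
        if np.ptp(np.concatenate([va, vb])) == 0:
            continue
        pvals[i] = mannwhitneyu(va, vb, alternative="two-sided").pvalue
    mean_a = np.expm1(xa).mean(axis=1)
    mean_b = np.expm1(xb).mean(axis=1)
    log2fc = np.log2(mean_a + 1) - np.log2(mean_b + 1)
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "adjusted_p": adj,
            "mean_group_a": mean_a,
            "mean_group_b": mean_b,
        }
    )


def _group_masks(barcodes: Sequence[str], groups: Mapping[str, str]) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    labels = sorted({groups[b] for b in barcodes if b in groups})
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    ga, gb = labels
    mask_a = np.array([groups.get(b) == ga for b in barcodes])
    mask_b = np.array([groups.get(b) == gb for b in barcodes])
    return mask_a, mask_b, (ga, gb)


def differential_isoforms(matrix, groups: Mapping[str, str]) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per isoform between two cell groups on
    cp10k/log1p-normalized counts, BH adjustment; significant iff
    |log2FC| > 0.25 and adjusted p < 0.05."""
    mask_a, mask_b, _ = _group_masks(matrix.barcodes, groups)
    table = _wilcoxon_table(
        matrix.counts.toarray(), matrix.transcript_ids, mask_a, mask_b
    )
    table["significant"] = (
        (table["log2_fold_change"].abs() > EXPR_LOG2FC_CUTOFF)
        & (table["adjusted_p"] < EXPR_ADJ_P_CUTOFF)
    )
    return table


def isoform_switches(
    matrix, groups: Mapping[str, str], gene_of: Mapping[str, str]
) -> pd.DataFrame:
    """Isoform-switch variant: adds the change in within-gene isoform
    fraction (dIF) between groups; flagged iff |dIF| > 0.1 and adjusted
    p < 0.05 (alpha)."""
    table = differential_isoforms(matrix, groups)
    mask_a, mask_b, _ = _group_masks(matrix.barcodes, groups)
    counts = matrix.counts.toarray().astype(float)
    sums_a = counts[:, mask_a].sum(axis=1)
    sums_b = counts[:, mask_b].sum(axis=1)
    genes = np.array([gene_of[t] for t in matrix.transcript_ids])
    dif = np.zeros(len(genes))
    for g in np.unique(genes):
        sel = genes == g
        tot_a, tot_b = sums_a[sel].sum(), sums_b[sel].sum()
        fa = sums_a[sel] / tot_a if tot_a > 0 else np.zeros(sel.sum())
        fb = sums_b[sel] / tot_b if tot_b > 0 else np.zeros(sel.sum())
        dif[sel] = fa - fb
    table["gene_id"] = genes
    table["dIF"] = dif
    table["switch"] = (np.abs(dif) > SWITCH_DIF_CUTOFF) & (
        table["adjusted_p"] < SWITCH_ALPHA
    )
    return table


def differential_peaks(
    peaks: Sequence[Peak], counts: np.ndarray, barcodes: Sequence[str], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Differential accessibility: same rank-sum machinery, thresholds
    |log2FC| > 0.1 and raw p < 0.0005 (unadjusted)."""
    mask_a, mask_b, _ = _group_masks(barcodes, groups)
    ids = [p.peak_id or f"{p.chrom}:{p.interval[0]}-{p.interval[1]}" for p in peaks]
    table = _wilcoxon_table(np.asarray(counts), ids, mask_a, mask_b)
    table["significant"] = (
        (table["log2_fold_change"].abs() > PEAK_LOG2FC_CUTOFF)
        & (table["p_value"] < PEAK_P_CUTOFF)
    )
    return table


def annotate_peaks_to_promoters(
    peaks: Sequence[Peak], transcripts: Sequence[TranscriptModel]
) -> pd.DataFrame:
    """Assign each peak to "promoter" of a gene when it overlaps any
    transcript's promoter window (TSS -2000/+200 strand-aware), otherwise
    to the nearest gene with a signed distance (negative = peak upstream of
    the gene span); nearest ties break to the smaller gene_id."""
    windows = [(promoter_window(t), t) for t in transcripts]
    spans: dict[tuple[str, str], tuple[int, int]] = {}
    for t in transcripts:
        key = (t.chrom, t.gene_id)
        s, e = t.span
        if key in spans:
            spans[key] = (min(spans[key][0], s), max(spans[key][1], e))
        else:
            spans[key] = (s, e)

    rows = []
    for p in peaks:
        ps, pe = p.interval
        hit = None
        for w, t in windows:
            if w.chrom == p.chrom and ps < w.interval[1] and w.interval[0] < pe:
                if hit is None or t.gene_id < hit:
                    hit = t.gene_id
        if hit is not None:
            rows.append((p.peak_id, p.chrom, ps, pe, hit, "promoter", 0))
            continue
        best = None
        for (chrom, gene), (gs, ge) in sorted(spans.items(), key=lambda kv: kv[0][1]):
            if chrom != p.chrom:
                continue
            if pe <= gs:
                dist = -(gs - pe)  # peak upstream of gene span start
            elif ps >= ge:
                dist = ps - ge
            else:
                dist = 0
            if best is None or abs(dist) < abs(best[1]):
                best = (gene, dist)
        if best is None:
            rows.append((p.peak_id, p.chrom, ps, pe, None, "unplaced", np.nan))
        else:
            rows.append((p.peak_id, p.chrom, ps, pe, best[0], "distal", best[1]))
    return pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "gene_id", "region", "distance"]
    )


def splice_site_windows(
    events: Sequence[ASEvent], window_bp: int = SPLICE_WINDOW_BP
) -> list[tuple[str, int, int, str]]:
    """BED-style (chrom, start, end, event_type) windows of +/- *window_bp*
    around each event's differential site, clamped at 0."""
    return [
        (e.chrom, max(0, e.site[0] - window_bp), e.site[1] + window_bp, e.event_type)
        for e in events
    ]


def splice_site_dar_overlap(
    events: Sequence[ASEvent],
    dars: Sequence[Peak],
    window_bp: int = SPLICE_WINDOW_BP,
) -> tuple[float, list[bool]]:
    """Fraction of splicing events whose site, extended by *window_bp* on
    each side, overlaps at least one differentially accessible region."""
    if not events:
        raise ValueError("no events")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in dars:
        by_chrom.setdefault(d.chrom, []).append(d.interval)
    flags = []
    for e in events:
        lo, hi = max(0, e.site[0] - window_bp), e.site[1] + window_bp
        flags.append(
            any(lo < de and ds < hi for ds, de in by_chrom.get(e.chrom, ()))
        )
    return sum(flags) / len(flags), flags
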