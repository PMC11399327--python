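"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written as naive enumeration over
definitions, independent of the indexed/incremental implementations it
checks.
"""

from __future__ import annotations


def brute_force_end_match(transcripts, gene_id, pos, which, tolerance):
    """All transcripts of *gene_id* whose annotated end lies within
    tolerance of *pos*, by linear scan."""
    out = set()
    for t in transcripts:
        if t.gene_id != gene_id:
            continue
        end = t.tss if which == "tss" else t.tes
        if abs(end - pos) <= tolerance:
            out.add(t.transcript_id)
    return out


def brute_force_junction_match(transcripts, gene_id, junction):
    out = set()
    for t in transcripts:
        if t.gene_id == gene_id and tuple(junction) in t.junctions:
            out.add(t.transcript_id)
    return out


def brute_force_compatibility(transcripts, group, tolerance):
    """Per-isoform compatibility test over every transcript of the group's
    gene: TSS/TES end windows, junction containment, and exclusion of
    isoforms spliced where a block aligns contiguously across the intron."""
    gene_txs = [t for t in transcripts if t.gene_id == group.gene_id]
    if not gene_txs:
        return set()
    strand = gene_txs[0].strand
    frags = [f for f in group.fragments if f.strand == strand]
    if not frags:
        return set()
    compatible = set()
    for t in gene_txs:
        ok = True
        tss_frags = [f for f in frags if f.end_class == "TSS"]
        if tss_frags and not any(
            abs((f.blocks[0][0] if strand == "+" else f.blocks[-1][1]) - t.tss) <= tolerance
            for f in tss_frags
        ):
            ok = False
        tes_frags = [f for f in frags if f.end_class == "TES"]
        if ok and tes_frags and not any(
            abs((f.blocks[-1][1] if strand == "+" else f.blocks[0][0]) - t.tes) <= tolerance
            for f in tes_frags
        ):
            ok = False
        if ok:
            for f in frags:
                for j in zip([b[1] for b in f.blocks[:-1]], [b[0] for b in f.blocks[1:]]):
                    if j not in t.junctions:
                        ok = False
        if ok:
            for js, je in t.junctions:
                for f in frags:
                    for bs, be in f.blocks:
                        if bs < js and be > je:
                            ok = False
        if ok:
            compatible.add(t.transcript_id)
    return compatible


def brute_force_nearest_gene(peaks_interval, chrom, gene_spans):
    """(gene, signed distance) by scanning every gene span; ties to the
    smaller gene_id."""
    ps, pe = peaks_interval
    best = None
    for (gchrom, gene), (gs, ge) in sorted(gene_spans.items(), key=lambda kv: kv[0][1]):
        if gchrom != chrom:
            continue
        if pe <= gs:
            dist = -(gs - pe)
        elif ps >= ge:
            dist = ps - ge
        else:
            dist = 0
        if best is None or abs(dist) < abs(best[1]):
            best = (gene, dist)
    return best


def brute_force_as_events(a, b, tolerance=0):
    """Event-type set between two isoforms, re-derived from the raw exon
    sets with plain nested loops."""
    types = set()
    if abs(a.tss - b.tss) > tolerance:
        types.add("AP")
    if abs(a.tes - b.tes) > tolerance:
        types.add("APA")

    for x, y in ((a, b), (b, a)):
        xe, ye = list(x.exons), set(y.exons)
        xj, yj = set(x.junctions), set(y.junctions)
        # SE: internal exon of x missing in y, flanks shared, merged junction in y
        for i in range(1, len(xe) - 1):
            if xe[i] in ye:
                continue
            up = (xe[i - 1][1], xe[i][0])
            down = (xe[i][1], xe[i + 1][0])
            if up in xj and down in xj and (up[0], down[1]) in yj:
                types.add("SE")
        # RI: exon of x equal to two y-exons fused across the y-intron between them
        for s, e in xe:
            for js, je in y.junctions:
                if s < js < je < e and (s, js) in ye and (je, e) in ye:
                    types.add("RI")
        # A3SS/A5SS: junction pairs sharing one splice site whose exons at
        # the alternative site overlap
        for s1, e1 in xj - yj:
            for s2, e2 in yj - xj:
                plus = x.strand == "+"
                if s1 == s2 and e1 != e2:
                    ex1 = [e for e in x.exons if e[0] == e1][0]
                    ex2 = [e for e in y.exons if e[0] == e2][0]
                    if ex1[0] < ex2[1] and ex2[0] < ex1[1]:
                        types.add("A3SS" if plus else "A5SS")
                if e1 == e2 and s1 != s2:
                    ex1 = [e for e in x.exons if e[1] == s1][0]
                    ex2 = [e for e in y.exons if e[1] == s2][0]
                    if ex1[0] < ex2[1] and ex2[0] < ex1[1]:
                        types.add("A5SS" if plus else "A3SS")
    # MXE: mutually exclusive internal exons with identical outer flanks
    for i in range(1, len(a.exons) - 1):
        for j in range(1, len(b.exons) - 1):
            e1, e2 = a.exons[i], b.exons[j]
            if e1 in set(b.exons) or e2 in set(a.exons):
                continue
            if not (e1[1] <= e2[0] or e2[1] <= e1[0]):
                continue
            if (
                a.exons[i - 1][1] == b.exons[j - 1][1]
                and a.exons[i + 1][0] == b.exons[j + 1][0]
            ):
                types.add("MXE")
    return types
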