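"""Spike-in style evaluation of pipeline output against ground truth:
detection sensitivity, per-UMI full-length feature accuracy, and
expected-vs-observed / replicate correlations on the log scale."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr

from ricat.annotation_model import TranscriptModel
from ricat.isoform_assignment import Assignment, IsoformCountMatrix
from ricat.sim_reads import MoleculeRecord, SpikeTruth

__all__ = [
    "EvalReport",
    "sensitivity",
    "feature_accuracy",
    "truth_keys_from_molecules",
    "abundance_correlation",
    "replicate_correlation",
    "evaluate",
]


@dataclass
class EvalReport:
    n_truth_isoforms: int
    n_detected: int
    sensitivity: float
    feature_accuracy: float | None = None
    pearson_expected_observed: float | None = None
    pearson_replicates: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _detected_units(
    truth_isoforms: set[str],
    totals: Mapping[str, int],
    min_umis: int,
    groups: Sequence[frozenset[str]] | None,
) -> tuple[int, int]:
    """(detected units, truth units), counting indistinguishable groups once."""
    if groups is None:
        groups = [frozenset([t]) for t in truth_isoforms]
    units = [g for g in groups if g & truth_isoforms]
    n_det = sum(
        1 for g in units if sum(totals.get(t, 0) for t in g) >= min_umis
    )
    return n_det, len(units)


def sensitivity(
    truth_isoforms: Iterable[str],
    matrix: IsoformCountMatrix,
    min_umis: int = 1,
    indist_groups: Sequence[frozenset[str]] | None = None,
) -> float:
    """Fraction of truth isoforms (those with >= 1 simulated molecule) whose
    total UMI count reaches *min_umis*; isoforms within an indistinguishable
    group are pooled and counted once."""
    truth = set(truth_isoforms)
    if not truth:
        raise ValueError("empty truth set")
    totals = matrix.totals_by_transcript()
    n_det, n_truth = _detected_units(truth, totals, min_umis, indist_groups)
    return n_det / n_truth


def feature_accuracy(
    assignments: Iterable[Assignment],
    truth_by_key: Mapping[tuple[str, str, str], str],
    indist_groups: Sequence[frozenset[str]] | None = None,
) -> float:
    """Fraction of assigned UMIs whose transcript equals the generating
    transcript.  *truth_by_key* maps (cb, gene_id, umi) to the generating
    transcript_id.  An assignment inside the generating transcript's
    indistinguishable group counts as correct."""
    group_of: dict[str, frozenset[str]] = {}
    for g in indist_groups or []:
        for t in g:
            group_of[t] = g
    n_assigned = 0
    n_correct = 0
    for a in assignments:
        if a.transcript_id is None:
            continue
        n_assigned += 1
        true_tx = truth_by_key.get(a.key)
        if true_tx is None:
            continue
        if a.transcript_id == true_tx or a.transcript_id in group_of.get(true_tx, ()):
            n_correct += 1
    if n_assigned == 0:
        raise ValueError("no assigned UMIs")
    return n_correct / n_assigned


def truth_keys_from_molecules(
    molecules: Iterable[MoleculeRecord], transcripts: Iterable[TranscriptModel]
) -> dict[tuple[str, str, str], str]:
    """Ground-truth (cb, gene, umi) -> transcript map for feature_accuracy."""
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    return {(m.cb, gene_of[m.transcript_id], m.umi): m.transcript_id for m in molecules}


def _log_transform(x: np.ndarray, base: float = 2.0, offset: float = 1.0) -> np.ndarray:
    return np.log(np.asarray(x, dtype=float) + offset) / np.log(base)


def abundance_correlation(
    expected: Sequence[SpikeTruth],
    matrix: IsoformCountMatrix,
    log_base: float = 2.0,
    offset: float = 1.0,
) -> float:
    """Pearson r between log-transformed expected abundances and observed
    per-species UMI totals (zeros included)."""
    if len(expected) < 3:
        raise ValueError("need >= 3 species")
    totals = matrix.totals_by_transcript()
    exp = np.array([sp.expected_abundance for sp in expected], dtype=float)
    obs = np.array([totals.get(sp.transcript_id, 0) for sp in expected], dtype=float)
    x = _log_transform(exp, log_base, offset)
    y = _log_transform(obs, log_base, offset)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(pearsonr(x, y).statistic)


def replicate_correlation(
    matrix_a: IsoformCountMatrix,
    matrix_b: IsoformCountMatrix,
    species: Sequence[str] | None = None,
    log_base: float = 2.0,
    offset: float = 1.0,
) -> float:
    """Pearson r of log-transformed per-species totals between two
    independent runs over their shared species universe."""
    ta, tb = matrix_a.totals_by_transcript(), matrix_b.totals_by_transcript()
    if species is None:
        species = sorted(set(ta) & set(tb))
    if not species:
        raise ValueError("empty species overlap")
    if len(species) < 3:
        raise ValueError("need >= 3 shared species")
    x = _log_transform([ta.get(s, 0) for s in species], log_base, offset)
    y = _log_transform([tb.get(s, 0) for s in species], log_base, offset)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(pearsonr(x, y).statistic)


def evaluate(
    matrix: IsoformCountMatrix,
    truth_isoforms: Iterable[str],
    assignments: Iterable[Assignment] | None = None,
    truth_by_key: Mapping | None = None,
    expected: Sequence[SpikeTruth] | None = None,
    matrix_replicate: IsoformCountMatrix | None = None,
    min_umis: int = 1,
    indist_groups: Sequence[frozenset[str]] | None = None,
) -> EvalReport:
    """Bundle the panel metrics into one report."""
    truth = set(truth_isoforms)
    totals = matrix.totals_by_transcript()
    n_det, n_truth = _detected_units(truth, totals, min_umis, indist_groups)
    report = EvalReport(
        n_truth_isoforms=n_truth,
        n_detected=n_det,
        sensitivity=n_det / n_truth,
    )
    if assignments is not None and truth_by_key is not None:
        report.feature_accuracy = feature_accuracy(assignments, truth_by_key, indist_groups)
    if expected is not None:
        report.pearson_expected_observed = abundance_correlation(expected, matrix)
    if matrix_replicate is not None:
        report.pearson_replicates = replicate_correlation(matrix, matrix_replicate)
    return report
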