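"""Evaluation helpers for simulated runs with known ground truth."""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .nhmm import PeakCall
from .simulator import SimResult


def expression_recovery(beta_gene: np.ndarray, abundances: np.ndarray) -> float:
    """Spearman rank correlation of fitted gene coefficients vs true abundances."""
    return float(spearmanr(beta_gene, abundances).statistic)


def summit_accuracy(peaks: list[PeakCall], result: SimResult) -> float:
    """Fraction of peaks whose summit sits exactly on a planted crosslink site."""
    if not peaks:
        return 0.0
    gene_index = {g.gene_id: i for i, g in enumerate(result.genes)}
    hits = 0
    for pk in peaks:
        gi = gene_index[pk.gene_id]
        sites = result.truth.crosslink_sites[gi] + result.genes[gi].start
        if np.any(sites == pk.summit):
            hits += 1
    return hits / len(peaks)


def _overlap_fraction(a: list[PeakCall], b: list[PeakCall]) -> float:
    if not a:
        return 0.0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for pk in b:
        by_chrom.setdefault(pk.chrom, []).append((pk.start, pk.end))
    hits = 0
    for pk in a:
        for s, e in by_chrom.get(pk.chrom, ()):
            if s < pk.end and e > pk.start:
                hits += 1
                break
    return hits / len(a)


def peak_overlap(a: list[PeakCall], b: list[PeakCall]) -> float:
    """Mean reciprocal fraction of peaks overlapping (>= 1 bp) across two runs."""
    return 0.5 * (_overlap_fraction(a, b) + _overlap_fraction(b, a))


def conversion_fraction(result: SimResult) -> float:
    """Observed conversion rate among crosslink-site-covering CLIP reads."""
    labels = np.concatenate(list(result.truth.conversion_labels.values()))
    return float(labels.mean())


def conversion_label_count(result: SimResult) -> int:
    return int(sum(v.size for v in result.truth.conversion_labels.values()))
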