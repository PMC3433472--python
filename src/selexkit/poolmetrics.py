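"""Per-round pool statistics for a SELEX selection.

Complexity C = U/T (unique over total reads) and % Enrichment E = 1 - C
are the round-level progress metrics; a four-parameter logistic fit over
(round, E) locates the round of 50% enrichment.  The module also provides
the read-weighted variable-region length distribution, the recurrence
(rounds-present) and cluster-size histograms used to separate true-selected
from non-selected sequences, and the true-selected filter itself
(present in >= 2 rounds and cluster size >= 3 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import EmptyPoolError, FitError, InputError
from .seqio import RoundPool, SequenceRecord

DEFAULT_MIN_ROUNDS = 2
DEFAULT_MIN_CLUSTER = 3


@dataclass
class LengthStats:
    """Read-weighted variable-region length distribution of a pool."""

    frequencies: dict[int, float]  # nt length -> fraction of reads
    mean: float
    sem: float
    mode: int
    min: int
    max: int
    n_reads: int


@dataclass
class RoundSummary:
    """Counts-level summary of one selection round."""

    round_label: int
    unique_reads: int
    total_reads: int
    complexity: float
    enrichment: float
    length: LengthStats | None = None


@dataclass
class EnrichmentCurveFit:
    """4-parameter logistic fit of % Enrichment against round number."""

    bottom: float
    top: float
    midpoint_round: float
    slope: float
    residual_ss: float
    extrapolated: bool

    def predict(self, x):
        return logistic4(np.asarray(x, dtype=float), self.bottom, self.top,
                         self.midpoint_round, self.slope)


def logistic4(x, bottom, top, x0, k):
    return bottom + (top - bottom) / (1.0 + np.exp(-k * (x - x0)))


# ---------------------------------------------------------------------------
# Enrichment / complexity
# ---------------------------------------------------------------------------

def pool_enrichment_stats(pool: RoundPool) -> RoundSummary:
    """Complexity and enrichment of one round pool."""
    total = pool.total_reads
    if total == 0:
        raise EmptyPoolError(f"round {pool.round_label} has no reads")
    unique = pool.unique_reads
    c = unique / total
    return RoundSummary(
        round_label=pool.round_label,
        unique_reads=unique,
        total_reads=total,
        complexity=c,
        enrichment=1.0 - c,
        length=length_distribution(pool.counts),
    )


def fit_enrichment_midpoint(points: Sequence[tuple[float, float]]) -> EnrichmentCurveFit:
    """Fit a sigmoid to (round, enrichment) points; midpoint = 50% crossing.

    The fitted form is E(x) = bottom + (top-bottom)/(1+exp(-k(x-x0))) with
    0 <= bottom, top <= 1; x0 is the round at which the curve crosses the
    half-way level (top+bottom)/2.
    """
    if len(points) < 4:
        raise InputError("at least 4 (round, enrichment) points are required")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(y) < 1e-12:
        raise FitError("enrichment is constant across rounds; sigmoid fit is degenerate")
    p0 = (max(y.min(), 0.0), min(y.max(), 1.0), float(np.median(x)), 1.0)
    bounds = ([0.0, 0.0, x.min() - 10 * np.ptp(x) - 1, 1e-6],
              [1.0, 1.0, x.max() + 10 * np.ptp(x) + 1, 100.0])
    try:
        popt, _ = optimize.curve_fit(logistic4, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    bottom, top, x0, k = (float(v) for v in popt)
    resid = float(np.sum((logistic4(x, *popt) - y) ** 2))
    return EnrichmentCurveFit(
        bottom=bottom, top=top, midpoint_round=x0, slope=k, residual_ss=resid,
        extrapolated=not (x.min() <= x0 <= x.max()),
    )


# ---------------------------------------------------------------------------
# Length distribution
# ---------------------------------------------------------------------------

def length_distribution(counts: Mapping[str, int]) -> LengthStats:
    """Read-weighted length distribution over {sequence: read count}."""
    if not counts:
        raise EmptyPoolError("empty sequence set")
    length_counts: dict[int, int] = {}
    for seq, c in counts.items():
        length_counts[len(seq)] = length_counts.get(len(seq), 0) + c
    n = sum(length_counts.values())
    lengths = np.array(sorted(length_counts), dtype=float)
    weights = np.array([length_counts[int(l)] for l in lengths], dtype=float)
    mean = float(np.average(lengths, weights=weights))
    if n > 1:
        var = float(np.sum(weights * (lengths - mean) ** 2) / (n - 1))
        sem = math.sqrt(var / n)
    else:
        sem = 0.0
    mode = int(max(sorted(length_counts), key=lambda l: length_counts[l]))
    return LengthStats(
        frequencies={l: c / n for l, c in sorted(length_counts.items())},
        mean=mean, sem=sem, mode=mode,
        min=int(lengths.min()), max=int(lengths.max()), n_reads=n,
    )


def length_ttest(counts_a: Mapping[str, int], counts_b: Mapping[str, int]) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance) on read-weighted lengths.

    Returns (t statistic, two-tailed p).  Computed from count-weighted
    moments, equivalent to expanding every read into its length.
    """
    stats_a = length_distribution(counts_a)
    stats_b = length_distribution(counts_b)
    na, nb = stats_a.n_reads, stats_b.n_reads
    if na < 2 or nb < 2:
        raise InputError("each pool needs at least 2 reads for a t-test")
    var_a = stats_a.sem ** 2 * na
    var_b = stats_b.sem ** 2 * nb
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    if sp2 == 0:
        raise FitError("zero pooled variance; t statistic undefined")
    t = (stats_a.mean - stats_b.mean) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Recurrence and cluster-size histograms; true-selected filter
# ---------------------------------------------------------------------------

def cluster_size(record: SequenceRecord, rounds: Iterable[int] | None = None) -> int:
    """A sequence's cluster size: its maximum per-round duplicate count.

    ``rounds`` restricts which rounds are considered (default: all rounds
    the record was seen in).  Per-round counts stay available on the record,
    so the alternative total-reads convention is recomputable by callers.
    """
    counts = record.reads_per_round
    if rounds is not None:
        rounds = set(rounds)
        counts = {r: c for r, c in counts.items() if r in rounds}
    return max(counts.values(), default=0)


def rounds_present(record: SequenceRecord, rounds: Iterable[int] | None = None) -> int:
    counts = record.reads_per_round
    if rounds is not None:
        rounds = set(rounds)
        counts = {r: c for r, c in counts.items() if r in rounds}
    return sum(1 for c in counts.values() if c > 0)


def recurrence_histogram(
    records: Sequence[SequenceRecord], rounds: Iterable[int] | None = None
) -> dict[int, int]:
    """Histogram of (#rounds a unique sequence was seen in) -> #sequences."""
    hist: dict[int, int] = {}
    for rec in records:
        k = rounds_present(rec, rounds)
        if k > 0:
            hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def cluster_size_histogram(
    records: Sequence[SequenceRecord], rounds: Iterable[int] | None = None
) -> dict[int, int]:
    """Histogram of cluster size (max per-round count) -> #unique sequences."""
    hist: dict[int, int] = {}
    for rec in records:
        c = cluster_size(rec, rounds)
        if c > 0:
            hist[c] = hist.get(c, 0) + 1
    return dict(sorted(hist.items()))


def split_by_round0(
    records: Sequence[SequenceRecord], round0_label: int = 0
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition the database into round-0 members and selection-round members.

    A sequence may belong to both groups if it was seen in round 0 and in a
    later round (the published selection observed no such overlap).
    """
    in_round0 = [r for r in records if r.reads_in(round0_label) > 0]
    in_selection = [
        r for r in records
        if any(c > 0 for rnd, c in r.reads_per_round.items() if rnd != round0_label)
    ]
    return in_round0, in_selection


def filter_true_selected(
    records: Sequence[SequenceRecord],
    min_rounds: int = DEFAULT_MIN_ROUNDS,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    selection_rounds: Iterable[int] | None = None,
    round0_label: int = 0,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition into (true-selected, discarded) sequences.

    A sequence is true-selected when, over the selection rounds (round 0
    excluded by default), it appears in >= min_rounds rounds AND its cluster
    size is >= min_cluster.  Returns disjoint (kept, discarded) lists whose
    union is the input.
    """
    if min_rounds < 1 or min_cluster < 1:
        raise InputError("thresholds must be >= 1")
    if selection_rounds is None:
        all_rounds = {r for rec in records for r in rec.reads_per_round}
        selection_rounds = sorted(all_rounds - {round0_label})
    selection_rounds = list(selection_rounds)
    kept, discarded = [], []
    for rec in records:
        if (rounds_present(rec, selection_rounds) >= min_rounds
                and cluster_size(rec, selection_rounds) >= min_cluster):
            kept.append(rec)
        else:
            discarded.append(rec)
    return kept, discarded


def summaries_to_frame(summaries: Sequence[RoundSummary]):
    """One row per round: counts, complexity, enrichment, length stats."""
    import pandas as pd

    rows = []
    for s in summaries:
        row = {
            "round": s.round_label,
            "unique_reads": s.unique_reads,
            "total_reads": s.total_reads,
            "complexity": s.complexity,
            "enrichment": s.enrichment,
        }
        if s.length is not None:
            row.update(
                length_mean=s.length.mean, length_sem=s.length.sem,
                length_mode=s.length.mode, length_min=s.length.min,
                length_max=s.length.max,
            )
        rows.append(row)
    return pd.DataFrame(rows)
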