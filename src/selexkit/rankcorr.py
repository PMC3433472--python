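"""Per-sequence enrichment scoring, candidate selection, and correlation
with experimental internalization.

Read counts are first normalized within each round (a_r = max(c_r, 1)/T_r;
a read number of 1 is substituted for zeros so ratios stay finite).  Over
a window of rounds three scores are computed per sequence:

* fold enrichment  FE = a_late / a_early (last vs first sequenced round
  of the window),
* rate enrichment  RE = (a_late - a_early) / (round_late - round_early),
  reported on a reads-per-million scale,
* rising           rho = Pearson correlation of abundance with round
  number across the window's sequenced rounds (0 by convention when the
  abundance is constant).

One representative per family and window is nominated by the lexicographic
rule (FE, then RE, then total reads, then smallest id); the union over
windows, plus highly-read orphans, forms the candidate set.  Candidate
metrics are correlated with measured fold internalization by Spearman's
rank correlation (exact permutation p for small n, t approximation
otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distfam import Family
from .errors import EmptyPoolError, InputError
from .seqio import SequenceRecord

DEFAULT_WINDOWS = ((1, 3), (1, 8), (3, 8), (6, 8))
DEFAULT_ORPHAN_MIN_READS = 100
RPM_SCALE = 1e6


@dataclass
class EnrichmentProfile:
    """Normalized per-round abundances and window scores for one sequence."""

    sequence_id: int
    abundance: dict[int, float]          # round -> a_r (zero-substituted)
    reads: dict[int, int]                # round -> raw count
    total_reads: int
    fold_enrichment: dict[tuple[int, int], float] = field(default_factory=dict)
    rate_enrichment: dict[tuple[int, int], float] = field(default_factory=dict)
    rising: dict[tuple[int, int], float | None] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    """Spearman correlation between two variables."""

    r: float
    p: float
    n: int
    variables: tuple[str, str] = ("", "")
    normality_p: tuple[float, float] | None = None


@dataclass
class CandidateSet:
    """Representatives from both family kinds, plus orphans."""

    edit_representatives: list[int]
    tree_representatives: list[int]
    orphans: list[int]
    venn: tuple[int, int, int]  # (edit-only, both, tree-only)

    @property
    def all_ids(self) -> list[int]:
        return sorted(set(self.edit_representatives)
                      | set(self.tree_representatives) | set(self.orphans))


# ---------------------------------------------------------------------------
# Normalization and window scores
# ---------------------------------------------------------------------------

def round_totals(records: Sequence[SequenceRecord]) -> dict[int, int]:
    totals: dict[int, int] = {}
    for rec in records:
        for r, c in rec.reads_per_round.items():
            totals[r] = totals.get(r, 0) + c
    return totals


def normalize_read_counts(
    records: Sequence[SequenceRecord],
    rounds: Sequence[int],
    totals: Mapping[int, int] | None = None,
    global_total: bool = False,
) -> dict[int, EnrichmentProfile]:
    """Per-round normalized abundances with the read-number-1 substitution.

    ``totals`` should normally be the per-round totals of the *full*
    database (pass them when scoring a filtered subset).  With
    ``global_total`` the denominator is the grand total over all rounds
    instead of each round's own total.
    """
    if totals is None:
        totals = round_totals(records)
    for r in rounds:
        if totals.get(r, 0) <= 0:
            raise EmptyPoolError(f"round {r} has no reads")
    denom = sum(totals[r] for r in rounds) if global_total else None
    profiles = {}
    for rec in records:
        ab = {
            r: max(rec.reads_in(r), 1) / (denom if global_total else totals[r])
            for r in rounds
        }
        profiles[rec.id] = EnrichmentProfile(
            sequence_id=rec.id, abundance=ab,
            reads={r: rec.reads_in(r) for r in rounds},
            total_reads=rec.total_reads,
        )
    return profiles


def window_rounds(window: tuple[int, int], rounds: Sequence[int]) -> list[int]:
    """Sequenced rounds falling inside [window_start, window_end]."""
    lo, hi = window
    return [r for r in sorted(rounds) if lo <= r <= hi]


def fold_enrichment(profile: EnrichmentProfile, round_early: int, round_late: int) -> float:
    """FE = a_late / a_early on normalized abundances."""
    if round_early >= round_late:
        raise InputError("round_early must precede round_late")
    for r in (round_early, round_late):
        if r not in profile.abundance:
            raise InputError(f"round {r} was not sequenced for this profile")
    return profile.abundance[round_late] / profile.abundance[round_early]


def rate_enrichment(profile: EnrichmentProfile, round_early: int, round_late: int) -> float:
    """RE = d(abundance)/d(round) on a reads-per-million scale."""
    if round_early == round_late:
        raise InputError("zero-width window")
    for r in (round_early, round_late):
        if r not in profile.abundance:
            raise InputError(f"round {r} was not sequenced for this profile")
    da = profile.abundance[round_late] - profile.abundance[round_early]
    return RPM_SCALE * da / (round_late - round_early)


def rising_score(profile: EnrichmentProfile, rounds_in_window: Sequence[int]) -> float | None:
    """Pearson correlation of (round, abundance); None when < 3 rounds,
    0 by convention when the abundance does not vary."""
    rs = [r for r in rounds_in_window if r in profile.abundance]
    if len(rs) < 3:
        return None
    x = np.array(rs, dtype=float)
    y = np.array([profile.abundance[r] for r in rs])
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def score_windows(
    profiles: Mapping[int, EnrichmentProfile],
    windows: Sequence[tuple[int, int]],
    rounds: Sequence[int],
) -> None:
    """Fill FE/RE/rising for every profile and window (in place).

    A window is scored over its sequenced rounds; windows with fewer than
    two sequenced rounds are left unscored.
    """
    for window in windows:
        wr = window_rounds(window, rounds)
        if len(wr) < 2:
            continue
        early, late = wr[0], wr[-1]
        for prof in profiles.values():
            prof.fold_enrichment[window] = fold_enrichment(prof, early, late)
            prof.rate_enrichment[window] = rate_enrichment(prof, early, late)
            prof.rising[window] = rising_score(prof, wr)


# ---------------------------------------------------------------------------
# Representative selection
# ---------------------------------------------------------------------------

def _nomination_key(prof: EnrichmentProfile, window: tuple[int, int]):
    return (
        prof.fold_enrichment.get(window, -math.inf),
        prof.rate_enrichment.get(window, -math.inf),
        prof.total_reads,
        -prof.sequence_id,  # smaller id wins on full tie
    )


def select_family_representatives(
    families: Sequence[Family],
    profiles: Mapping[int, EnrichmentProfile],
    windows: Sequence[tuple[int, int]],
) -> list[int]:
    """Union over windows of each family's best member (FE, RE, reads, id)."""
    reps: set[int] = set()
    for fam in families:
        scored = [w for w in windows
                  if any(w in profiles[m].fold_enrichment for m in fam.members)]
        best_overall: int | None = None
        for window in scored:
            best = max(fam.members, key=lambda m: _nomination_key(profiles[m], window))
            reps.add(best)
            if best_overall is None:
                best_overall = best
        if fam.representative_id is None and best_overall is not None:
            fam.representative_id = best_overall
    return sorted(reps)


def find_orphans(
    records: Sequence[SequenceRecord],
    orphan_min_reads: int = DEFAULT_ORPHAN_MIN_READS,
) -> list[int]:
    """Highly represented sequences belonging to no family of either kind."""
    return sorted(
        r.id for r in records
        if r.sequence_family is None and r.structure_family is None
        and r.total_reads >= orphan_min_reads
    )


def compare_candidate_sets(edit_reps: Iterable[int], tree_reps: Iterable[int]
                           ) -> tuple[int, int, int]:
    """(edit-only, both, tree-only) counts; they sum to |union|."""
    e, t = set(edit_reps), set(tree_reps)
    return (len(e - t), len(e & t), len(t - e))


def select_representatives(
    records: Sequence[SequenceRecord],
    sequence_families: Sequence[Family],
    structure_families: Sequence[Family],
    profiles: Mapping[int, EnrichmentProfile],
    windows: Sequence[tuple[int, int]] = DEFAULT_WINDOWS,
    orphan_min_reads: int = DEFAULT_ORPHAN_MIN_READS,
) -> CandidateSet:
    """Assemble the candidate aptamer set from both family analyses."""
    edit_reps = select_family_representatives(sequence_families, profiles, windows)
    tree_reps = select_family_representatives(structure_families, profiles, windows)
    orphans = find_orphans(records, orphan_min_reads)
    for rec in records:
        rec.representative = rec.id in set(edit_reps) | set(tree_reps) | set(orphans)
    return CandidateSet(
        edit_representatives=edit_reps,
        tree_representatives=tree_reps,
        orphans=orphans,
        venn=compare_candidate_sets(edit_reps, tree_reps),
    )


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

EXACT_PERMUTATION_MAX_N = 9


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc) / denom


def spearman_correlation(
    x: Sequence[float], y: Sequence[float],
    variables: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Spearman's rank correlation with a two-tailed p-value.

    r is the Pearson correlation of mid-ranks (average ranks for ties).
    For n <= 9 the p-value is exact, from the permutation distribution of
    the rank correlation; for larger n the usual t approximation with
    n - 2 degrees of freedom is used.  Normality of each input (Shapiro-
    Wilk p) is reported as an annotation only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise InputError("at least 3 pairs are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("constant variable: correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = _pearson(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        count = 0
        total = 0
        target = abs(r) - 1e-12
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_pearson(rx, np.asarray(perm))) >= target:
                count += 1
        p = count / total
    else:
        t = r * math.sqrt((n - 2) / max(1.0 - r * r, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    norm = None
    if n >= 3:
        norm = (float(stats.shapiro(x).pvalue), float(stats.shapiro(y).pvalue))
    return CorrelationResult(r=r, p=p, n=n, variables=variables, normality_p=norm)


def correlate_internalization(
    profiles: Mapping[int, EnrichmentProfile],
    internalization: Mapping[int, float],
    windows: Sequence[tuple[int, int]] = DEFAULT_WINDOWS,
    rounds: Sequence[int] = (),
) -> pd.DataFrame:
    """Correlation grid: fold internalization vs. each enrichment metric per
    window, and vs. (normalized) read number per round and in total.

    Candidates without measurements are excluded (n is reported per cell).
    Rows: metric, window/round, r, p, n, significant (p < 0.05).
    """
    ids = sorted(set(profiles) & set(internalization))
    if len(ids) < 3:
        raise InputError("need at least 3 candidates with measurements")
    internal = np.array([internalization[i] for i in ids], dtype=float)
    rows = []

    def corr_row(metric: str, label: str, values: list[float | None]) -> None:
        pairs = [(v, m) for v, m in zip(values, internal) if v is not None]
        if len(pairs) < 3:
            return
        v = np.array([p[0] for p in pairs])
        m = np.array([p[1] for p in pairs])
        if np.ptp(v) == 0:
            return
        res = spearman_correlation(m, v, ("fold_internalization", metric))
        rows.append({
            "metric": metric, "window": label, "r": res.r, "p": res.p,
            "n": res.n, "significant": res.p < 0.05,
        })

    for window in windows:
        label = f"{window[0]}-{window[1]}"
        corr_row("fold_enrichment", label,
                 [profiles[i].fold_enrichment.get(window) for i in ids])
        corr_row("rising", label,
                 [profiles[i].rising.get(window) for i in ids])
        corr_row("rate_enrichment", label,
                 [profiles[i].rate_enrichment.get(window) for i in ids])
    for r in rounds:
        corr_row("read_number", str(r),
                 [profiles[i].abundance.get(r) for i in ids])
    if rounds:
        corr_row("read_number", "total",
                 [float(profiles[i].total_reads) for i in ids])
    return pd.DataFrame(rows, columns=["metric", "window", "r", "p", "n", "significant"])


def profiles_to_frame(
    profiles: Mapping[int, EnrichmentProfile],
    windows: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    rows = []
    for i in sorted(profiles):
        prof = profiles[i]
        row: dict = {"id": i, "total_reads": prof.total_reads}
        for r in sorted(prof.abundance):
            row[f"abundance_{r}"] = prof.abundance[r]
        for w in windows:
            label = f"{w[0]}-{w[1]}"
            row[f"FE_{label}"] = prof.fold_enrichment.get(w)
            row[f"RE_{label}"] = prof.rate_enrichment.get(w)
            row[f"rising_{label}"] = prof.rising.get(w)
        rows.append(row)
    return pd.DataFrame(rows)
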