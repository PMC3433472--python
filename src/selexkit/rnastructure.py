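"""Secondary-structure prediction and ensemble statistics.

Every unique aptamer sequence is assigned a single most-stable secondary
structure (its MFE structure) together with four ensemble statistics:

* ``mfe_energy``      G_mfe, energy of the best structure (kcal/mol)
* ``ensemble_fe``     G_ens = -RT ln Z over all structures (kcal/mol)
* ``ensemble_probability``  P_mfe = exp(-G_mfe/RT)/Z, the Boltzmann weight
  of the MFE structure within the ensemble
* ``ensemble_diversity``    D = sum_{i<j} 2 p_ij (1-p_ij), the expected
  base-pair distance between two independent draws from the ensemble

The builtin engine uses a deliberately simple additive pair-energy model
(default GC/CG -3.0, AU/UA -2.0, optional GU/UG -1.0 kcal/mol; no dangles
or loop penalties) so that every quantity is exactly checkable against
exhaustive structure enumeration at small lengths.  Structural constraints
mirror the usual folding conventions: no pseudoknots, a minimum hairpin
loop of 3 nt, and (by default) no lonely pairs — every helix must be at
least two stacked pairs long.  The no-lonely-pair rule is enforced exactly
by a three-nonterminal grammar:

    F  — structures of a segment needing no outside help (every outermost
         helix starts with a stack),
    S  — (i,j) paired and stacked inward on (i+1,j-1),
    N  — (i,j) paired, interior without the mutual pair (i+1,j-1); legal
         only when stacked outward, i.e. reachable only through S.

Partition functions run the same grammar in sum-product form; an outside
pass yields exact base-pair probabilities.  An adapter to an external
nearest-neighbor engine (ViennaRNA's RNAfold console output) is provided
for realism; all downstream family analyses consume dot-brackets and are
engine-agnostic.
"""

from __future__ import annotations

import math
import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, ParseError

GAS_CONSTANT = 0.0019872  # kcal / (mol K)

DEFAULT_PAIR_ENERGIES = {
    "GC": -3.0, "CG": -3.0,
    "AU": -2.0, "UA": -2.0,
    "GU": -1.0, "UG": -1.0,
}

_WOBBLE = {"GU", "UG"}


@dataclass
class FoldConfig:
    """Parameters of the builtin folding model.

    ``temperature_c`` defaults to 30 (the folding temperature used for the
    selection's structure predictions); GU wobble pairs and lonely pairs
    are disabled by default, matching the external engine's --noGU/--noLP
    switches in spirit.
    """

    temperature_c: float = 30.0
    allow_gu: bool = False
    allow_lonely_pairs: bool = False
    min_hairpin_loop: int = 3
    pair_energies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_ENERGIES))

    def __post_init__(self) -> None:
        if self.min_hairpin_loop < 0:
            raise InputError("min_hairpin_loop must be >= 0")
        for pair, e in self.pair_energies.items():
            if not math.isfinite(e):
                raise InputError(f"non-finite energy for pair {pair}")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * (self.temperature_c + 273.15)

    def legal_pairs(self) -> dict[str, float]:
        return {p: e for p, e in self.pair_energies.items()
                if self.allow_gu or p not in _WOBBLE}


@dataclass
class StructureRecord:
    """A predicted structure with its ensemble statistics."""

    dot_bracket: str
    mfe_energy: float = math.nan
    ensemble_fe: float = math.nan
    ensemble_probability: float = math.nan
    ensemble_diversity: float = math.nan
    engine: str = "builtin"

    def __post_init__(self) -> None:
        validate_dot_bracket(self.dot_bracket)

    @classmethod
    def from_dot_bracket(cls, dot_bracket: str) -> "StructureRecord":
        return cls(dot_bracket=dot_bracket)

    @property
    def n_pairs(self) -> int:
        return self.dot_bracket.count("(")


def validate_dot_bracket(dot: str) -> None:
    depth = 0
    for ch in dot:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise InputError(f"unbalanced dot-bracket: {dot!r}")
        elif ch != ".":
            raise InputError(f"invalid character {ch!r} in dot-bracket")
    if depth != 0:
        raise InputError(f"unbalanced dot-bracket: {dot!r}")


def pairs_from_dot_bracket(dot: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(dot):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    return sorted(pairs)


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise InputError("sequence must be non-empty")
    bad = set(seq) - set("ACGU")
    if bad:
        raise InputError(f"invalid RNA base(s): {sorted(bad)}")
    return seq


def _pair_energy_matrix(seq: str, config: FoldConfig) -> np.ndarray:
    """e[i,j] = pair energy, +inf where (i,j) cannot pair."""
    n = len(seq)
    legal = config.legal_pairs()
    e = np.full((n, n), math.inf)
    for i in range(n):
        for j in range(i + config.min_hairpin_loop + 1, n):
            energy = legal.get(seq[i] + seq[j])
            if energy is not None:
                e[i, j] = energy
    return e


# ---------------------------------------------------------------------------
# MFE dynamic program (min-plus) with traceback
# ---------------------------------------------------------------------------

def fold_mfe(sequence: str, config: FoldConfig | None = None) -> tuple[str, float]:
    """Minimum-free-energy structure and energy under the builtin model.

    Traceback is deterministic: pairing position i is preferred over
    leaving it unpaired, and among equal-energy partners the smallest j
    wins; inside a pair, continuing the stack is preferred.
    """
    config = config or FoldConfig()
    seq = _check_sequence(sequence)
    n = len(seq)
    e = _pair_energy_matrix(seq, config)
    INF = math.inf
    Sm = np.full((n, n), INF)
    Nm = np.full((n, n), INF)
    Fxm = np.zeros((n, n))
    Fm = np.zeros((n, n))

    def fF(i: int, j: int) -> float:
        return Fm[i, j] if i <= j else 0.0

    def fFx(i: int, j: int) -> float:
        return Fxm[i, j] if i <= j else 0.0

    nolp = not config.allow_lonely_pairs
    for L in range(1, n + 1):
        for i in range(0, n - L + 1):
            j = i + L - 1
            if e[i, j] < INF:
                if nolp:
                    inner = min(Sm[i + 1, j - 1], Nm[i + 1, j - 1]) if i + 1 <= j - 1 else INF
                    Sm[i, j] = e[i, j] + inner
                    Nm[i, j] = e[i, j] + fFx(i + 1, j - 1)
                else:
                    Sm[i, j] = e[i, j] + fF(i + 1, j - 1)
            best_x = fF(i + 1, j)
            for k in range(i + 1, j):
                if Sm[i, k] < INF:
                    best_x = min(best_x, Sm[i, k] + fF(k + 1, j))
            Fxm[i, j] = best_x
            Fm[i, j] = min(best_x, Sm[i, j]) if Sm[i, j] < INF else best_x

    pairs: list[tuple[int, int]] = []

    def tb_F(i: int, j: int) -> None:
        if i > j:
            return
        target = Fm[i, j]
        for k in range(i + 1, j + 1):
            if Sm[i, k] < INF and Sm[i, k] + fF(k + 1, j) == target:
                tb_S(i, k)
                tb_F(k + 1, j)
                return
        tb_F(i + 1, j)

    def tb_Fx(i: int, j: int) -> None:
        if i > j:
            return
        target = Fxm[i, j]
        for k in range(i + 1, j):
            if Sm[i, k] < INF and Sm[i, k] + fF(k + 1, j) == target:
                tb_S(i, k)
                tb_F(k + 1, j)
                return
        tb_F(i + 1, j)

    def tb_S(i: int, j: int) -> None:
        pairs.append((i, j))
        if not nolp:
            tb_F(i + 1, j - 1)
            return
        if i + 1 <= j - 1 and Sm[i + 1, j - 1] < INF \
                and Sm[i, j] == e[i, j] + Sm[i + 1, j - 1]:
            tb_S(i + 1, j - 1)
        else:
            tb_N(i + 1, j - 1)

    def tb_N(i: int, j: int) -> None:
        pairs.append((i, j))
        tb_Fx(i + 1, j - 1)

    tb_F(0, n - 1)
    dot = ["."] * n
    for i, j in pairs:
        dot[i], dot[j] = "(", ")"
    return "".join(dot), float(Fm[0, n - 1]) if n else 0.0


# ---------------------------------------------------------------------------
# Partition function (sum-product) with outside pass
# ---------------------------------------------------------------------------

def _inside(seq: str, config: FoldConfig):
    n = len(seq)
    e = _pair_energy_matrix(seq, config)
    rt = config.rt
    w = np.exp(-e / rt)  # e = +inf where unpairable -> weight 0
    S = np.zeros((n, n))
    N = np.zeros((n, n))
    Fx = np.zeros((n, n))
    F = np.zeros((n, n))

    def fF(i, j):
        return F[i, j] if i <= j else 1.0

    def fFx(i, j):
        return Fx[i, j] if i <= j else 1.0

    nolp = not config.allow_lonely_pairs
    for L in range(1, n + 1):
        for i in range(0, n - L + 1):
            j = i + L - 1
            if w[i, j] > 0.0:
                if nolp:
                    inner = (S[i + 1, j - 1] + N[i + 1, j - 1]) if i + 1 <= j - 1 else 0.0
                    S[i, j] = w[i, j] * inner
                    N[i, j] = w[i, j] * fFx(i + 1, j - 1)
                else:
                    S[i, j] = w[i, j] * fF(i + 1, j - 1)
            acc = fF(i + 1, j)
            for k in range(i + 1, j):
                if S[i, k] > 0.0:
                    acc += S[i, k] * fF(k + 1, j)
            Fx[i, j] = acc
            F[i, j] = acc + S[i, j]
    return w, S, N, Fx, F


def pair_probabilities(sequence: str, config: FoldConfig | None = None) -> np.ndarray:
    """Exact base-pair probability matrix p[i,j] (upper triangular)."""
    config = config or FoldConfig()
    seq = _check_sequence(sequence)
    n = len(seq)
    w, S, N, Fx, F = _inside(seq, config)
    Z = F[0, n - 1] if n else 1.0
    hF = np.zeros((n, n))
    hFx = np.zeros((n, n))
    hS = np.zeros((n, n))
    hN = np.zeros((n, n))
    hF[0, n - 1] = 1.0

    def fF(i, j):
        return F[i, j] if i <= j else 1.0

    nolp = not config.allow_lonely_pairs
    for L in range(n, 0, -1):
        for i in range(0, n - L + 1):
            j = i + L - 1
            oF, oFx = hF[i, j], hFx[i, j]
            if oF > 0.0:
                if i + 1 <= j:
                    hF[i + 1, j] += oF
                for k in range(i + 1, j + 1):
                    if S[i, k] > 0.0:
                        hS[i, k] += oF * fF(k + 1, j)
                        if k + 1 <= j:
                            hF[k + 1, j] += oF * S[i, k]
            if oFx > 0.0:
                if i + 1 <= j:
                    hF[i + 1, j] += oFx
                for k in range(i + 1, j):
                    if S[i, k] > 0.0:
                        hS[i, k] += oFx * fF(k + 1, j)
                        if k + 1 <= j:
                            hF[k + 1, j] += oFx * S[i, k]
            # the F/Fx contexts above may have added to this very cell's
            # hS (a pair spanning the whole free segment): read S/N outside
            # values only now
            oS, oN = hS[i, j], hN[i, j]
            if oS > 0.0 and w[i, j] > 0.0:
                if nolp:
                    if i + 1 <= j - 1:
                        hS[i + 1, j - 1] += w[i, j] * oS
                        hN[i + 1, j - 1] += w[i, j] * oS
                else:
                    if i + 1 <= j - 1:
                        hF[i + 1, j - 1] += w[i, j] * oS
            if oN > 0.0 and w[i, j] > 0.0 and i + 1 <= j - 1:
                hFx[i + 1, j - 1] += w[i, j] * oN

    p = np.zeros((n, n))
    if Z > 0.0:
        for i in range(n):
            for j in range(i + 1, n):
                p[i, j] = (S[i, j] * hS[i, j] + N[i, j] * hN[i, j]) / Z
    return p


def ensemble_statistics(
    sequence: str, config: FoldConfig | None = None,
    mfe_energy: float | None = None,
) -> tuple[float, float, float]:
    """(ensemble free energy, MFE-structure probability, ensemble diversity)."""
    config = config or FoldConfig()
    seq = _check_sequence(sequence)
    n = len(seq)
    _, _, _, _, F = _inside(seq, config)
    Z = F[0, n - 1] if n else 1.0
    rt = config.rt
    g_ens = -rt * math.log(Z)
    if mfe_energy is None:
        mfe_energy = fold_mfe(seq, config)[1]
    p_mfe = math.exp(-mfe_energy / rt) / Z
    p = pair_probabilities(seq, config)
    diversity = float(np.sum(2.0 * p * (1.0 - p)))
    return g_ens, p_mfe, diversity


def fold_sequence(sequence: str, config: FoldConfig | None = None) -> StructureRecord:
    """Full builtin prediction: MFE structure plus ensemble statistics."""
    config = config or FoldConfig()
    dot, g_mfe = fold_mfe(sequence, config)
    g_ens, p_mfe, diversity = ensemble_statistics(sequence, config, mfe_energy=g_mfe)
    return StructureRecord(
        dot_bracket=dot, mfe_energy=g_mfe, ensemble_fe=g_ens,
        ensemble_probability=p_mfe, ensemble_diversity=diversity, engine="builtin",
    )


# ---------------------------------------------------------------------------
# External engine adapter (ViennaRNA RNAfold console output)
# ---------------------------------------------------------------------------

_MFE_RE = re.compile(r"^([.()]+)\s+\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")
_ENS_RE = re.compile(r"\[\s*(-?\d+(?:\.\d+)?)\s*\]")
_FREQ_RE = re.compile(r"frequency of mfe structure in ensemble\s+([0-9.eE+-]+)")
_DIV_RE = re.compile(r"ensemble diversity\s+([0-9.eE+-]+)")


def parse_external_fold_output(text: str) -> StructureRecord:
    """Parse the console report of the external partition-function folder.

    Expects the standard layout: a dot-bracket line with '(energy)', an
    ensemble free-energy line with '[energy]', and a final line carrying
    the MFE-structure frequency and the ensemble diversity.
    """
    dot = energy = None
    for line in text.splitlines():
        m = _MFE_RE.match(line.strip())
        if m:
            dot, energy = m.group(1), float(m.group(2))
            break
    if dot is None:
        raise ParseError("missing field: mfe_structure")
    m = _ENS_RE.search(text)
    if not m:
        raise ParseError("missing field: ensemble_fe")
    ens = float(m.group(1))
    m = _FREQ_RE.search(text)
    if not m:
        raise ParseError("missing field: ensemble_probability")
    freq = float(m.group(1))
    m = _DIV_RE.search(text)
    if not m:
        raise ParseError("missing field: ensemble_diversity")
    div = float(m.group(1))
    return StructureRecord(
        dot_bracket=dot, mfe_energy=energy, ensemble_fe=ens,
        ensemble_probability=freq, ensemble_diversity=div, engine="external",
    )


def build_external_command(config: FoldConfig, executable: str = "RNAfold") -> list[str]:
    cmd = [executable, "-p", "--noPS", "-d2", "-T", str(config.temperature_c)]
    if not config.allow_gu:
        cmd.append("--noGU")
    if not config.allow_lonely_pairs:
        cmd.append("--noLP")
    return cmd


def fold_external(
    sequence: str, config: FoldConfig | None = None,
    command: Sequence[str] | None = None,
) -> StructureRecord:
    """Fold one sequence with the external engine and parse its report."""
    config = config or FoldConfig()
    seq = _check_sequence(sequence)
    cmd = list(command) if command is not None else build_external_command(config)
    with tempfile.TemporaryDirectory() as tmp:
        proc = subprocess.run(
            cmd, input=seq + "\n", capture_output=True, text=True, cwd=tmp, check=True,
        )
    return parse_external_fold_output(proc.stdout)


# ---------------------------------------------------------------------------
# Pool-level structure summaries
# ---------------------------------------------------------------------------

_STAT_FIELDS = ("mfe_energy", "ensemble_fe", "ensemble_probability", "ensemble_diversity")


def pool_structure_summary(
    records: Sequence, weighting: str = "unique", round_label: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Mean +/- SEM of the four structure statistics over a record set.

    ``unique`` weighting averages over unique sequences; ``reads`` weights
    each unique sequence by its read number (in ``round_label`` if given,
    else its total), reproducing the statistics of the total-read pool.
    """
    if weighting not in ("unique", "reads"):
        raise InputError(f"unknown weighting: {weighting}")
    values: dict[str, list[float]] = {f: [] for f in _STAT_FIELDS}
    weights: list[float] = []
    for rec in records:
        st = rec.structure
        if st is None or math.isnan(st.mfe_energy):
            raise InputError(f"record {rec.id} has no folded structure")
        for f in _STAT_FIELDS:
            values[f].append(getattr(st, f))
        if weighting == "reads":
            wt = rec.reads_in(round_label) if round_label is not None else rec.total_reads
        else:
            wt = 1.0
        weights.append(float(wt))
    w = np.asarray(weights)
    if w.sum() <= 0:
        raise InputError("no reads in the requested round")
    out = {}
    n = w.sum()
    for f in _STAT_FIELDS:
        x = np.asarray(values[f])
        mean = float(np.average(x, weights=w))
        if n > 1:
            var = float(np.sum(w * (x - mean) ** 2) / (n - 1))
            sem = math.sqrt(var / n)
        else:
            sem = 0.0
        out[f] = (mean, sem)
    return out
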