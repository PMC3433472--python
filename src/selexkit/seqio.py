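"""Read handling for SELEX round sequencing data.

This module takes per-round Illumina reads (FASTQ/FASTA, optionally
gzipped), demultiplexes them by 5' barcode, extracts the randomized
variable region lying between the library's constant flanks, collapses
duplicates into per-round pools of unique sequences, and assembles the
non-redundant cross-round sequence database (one row per unique variable
region, with per-round read counts).

The default constant regions are those of the Sel2 library: the 5'
constant is the tail of the Sel2 5' primer and the 3' constant is the
reverse complement of the Sel2 3' primer, giving full-length RNAs of
15 + variable + 16 nt.
"""

from __future__ import annotations

import gzip
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, InputError, ParseError

# Sel2 library constant regions (DNA sense strand).
FLANK5_DNA = "GGGAGGACGATGCGG"
FLANK3_DNA = "CAGACGACTCGCCCGA"
CONSTANT5_RNA = "GGGAGGACGAUGCGG"
CONSTANT3_RNA = "CAGACGACUCGCCCGA"

DEFAULT_LENGTH_RANGE = (18, 22)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Rejection reason codes (rejection is a value, not an error).
NO_FLANK5 = "no_flank5"
NO_FLANK3 = "no_flank3"
BAD_LENGTH = "bad_length"
AMBIGUOUS_BASE = "ambiguous_base"
NO_BARCODE = "no_barcode"
LOW_QUALITY = "low_quality"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """One sequencing read assigned (or assignable) to a selection round."""

    sequence: str
    quality: Sequence[int] | None = None
    round_label: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("read sequence must be non-empty")


@dataclass
class Rejection:
    """A read that failed a filter, with the reason code."""

    sequence: str
    reason: str


@dataclass
class ExtractionResult:
    """Outcome of variable-region extraction: a region or a reason code."""

    variable_region: str | None
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.variable_region is not None


@dataclass
class RoundPool:
    """Unique variable-region sequences of one round with duplicate counts.

    ``counts`` is ordered by read count descending, then lexicographically,
    so iteration order is deterministic.
    """

    round_label: int
    counts: dict[str, int]

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def unique_reads(self) -> int:
        return len(self.counts)


@dataclass
class SequenceRecord:
    """One unique variable-region sequence across all sequenced rounds.

    Mirrors one row of the non-redundant database (the Database S1 row
    layout): identity, per-round cluster sizes, derived full-length RNA,
    predicted structure and family labels.
    """

    id: int
    variable_region_dna: str
    reads_per_round: dict[int, int]
    variable_region_rna: str = ""
    full_rna: str = ""
    structure: object | None = None  # StructureRecord, filled by rnastructure
    sequence_family: str | None = None
    structure_family: str | None = None
    representative: bool = False

    def __post_init__(self) -> None:
        if not self.variable_region_rna:
            self.variable_region_rna = self.variable_region_dna.replace("T", "U")
        if not self.full_rna:
            self.full_rna = CONSTANT5_RNA + self.variable_region_rna + CONSTANT3_RNA
        self.reads_per_round = {r: c for r, c in self.reads_per_round.items() if c > 0}

    @property
    def length(self) -> int:
        return len(self.variable_region_dna)

    @property
    def total_reads(self) -> int:
        return sum(self.reads_per_round.values())

    @property
    def rounds_present(self) -> int:
        return len(self.reads_per_round)

    def reads_in(self, round_label: int) -> int:
        return self.reads_per_round.get(round_label, 0)


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _guess_format(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    raise InputError(f"cannot infer sequence format from file name: {path}")


def read_sequence_file(path: str | Path, round_label: int | None = None) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ or FASTA file (gzip transparent)."""
    fmt = _guess_format(path)
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            qual = rec.letter_annotations.get("phred_quality") if fmt == "fastq" else None
            yield ReadRecord(str(rec.seq).upper(), qual, round_label)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def demultiplex_reads(
    reads: Iterable[ReadRecord],
    barcode_map: Mapping[str, int],
) -> tuple[dict[int, list[ReadRecord]], list[Rejection]]:
    """Assign reads to rounds by their 5' barcode.

    The barcode is expected as an exact prefix of the read; if absent the
    reverse complement of the read is tried (reads may be sequenced from
    either strand), and the read is re-oriented on success.  Returns the
    per-round read lists (barcode stripped) and the reject bin; counts are
    conserved: assigned + rejected == input.
    """
    if not barcode_map:
        raise ConfigurationError("barcode map is empty")
    lengths = {len(b) for b in barcode_map}
    if len(lengths) != 1:
        raise ConfigurationError("barcodes must all have the same length")
    if len(set(barcode_map.values())) != len(barcode_map):
        # two barcodes to one round is fine; same barcode twice cannot occur in a dict,
        # but a case-folded collision can:
        pass
    upper = {b.upper(): r for b, r in barcode_map.items()}
    if len(upper) != len(barcode_map):
        raise ConfigurationError("duplicate barcode in map")
    blen = lengths.pop()

    assigned: dict[int, list[ReadRecord]] = defaultdict(list)
    rejected: list[Rejection] = []
    for read in reads:
        for seq in (read.sequence, reverse_complement(read.sequence)):
            rnd = upper.get(seq[:blen])
            if rnd is not None:
                assigned[rnd].append(ReadRecord(seq[blen:], None, rnd))
                break
        else:
            rejected.append(Rejection(read.sequence, NO_BARCODE))
    return dict(assigned), rejected


# ---------------------------------------------------------------------------
# Variable-region extraction
# ---------------------------------------------------------------------------

def _find_approx(haystack: str, needle: str, start: int, max_mismatch: int) -> int:
    """Leftmost position >= start where needle matches with <= max_mismatch
    Hamming mismatches (no indels); -1 if none."""
    n, m = len(haystack), len(needle)
    if max_mismatch == 0:
        return haystack.find(needle, start)
    for i in range(start, n - m + 1):
        mism = 0
        for a, b in zip(haystack[i : i + m], needle):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return -1


def _extract_oriented(
    seq: str, flank5: str, flank3: str, max_mismatch: int,
    length_range: tuple[int, int],
) -> ExtractionResult:
    p5 = _find_approx(seq, flank5, 0, max_mismatch)
    if p5 < 0:
        return ExtractionResult(None, NO_FLANK5)
    p3 = _find_approx(seq, flank3, p5 + len(flank5), max_mismatch)
    if p3 < 0:
        return ExtractionResult(None, NO_FLANK3)
    region = seq[p5 + len(flank5) : p3]
    if "N" in region:
        return ExtractionResult(None, AMBIGUOUS_BASE)
    lo, hi = length_range
    if not lo <= len(region) <= hi:
        return ExtractionResult(None, BAD_LENGTH)
    return ExtractionResult(region)


_REASON_RANK = {NO_FLANK5: 0, NO_FLANK3: 1, AMBIGUOUS_BASE: 2, BAD_LENGTH: 2}


def extract_variable_region(
    read: ReadRecord | str,
    flank5: str = FLANK5_DNA,
    flank3: str = FLANK3_DNA,
    max_mismatch: int = 0,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    min_mean_quality: float | None = None,
) -> ExtractionResult:
    """Extract the variable region strictly between the two constant flanks.

    Both read orientations are attempted (as given first); the rejection
    reason reported is that of the orientation that progressed furthest.
    """
    if not flank5 or not flank3:
        raise InputError("flanks must be non-empty")
    seq = read.sequence if isinstance(read, ReadRecord) else str(read).upper()
    if min_mean_quality is not None and isinstance(read, ReadRecord) and read.quality:
        if sum(read.quality) / len(read.quality) < min_mean_quality:
            return ExtractionResult(None, LOW_QUALITY)
    fwd = _extract_oriented(seq, flank5, flank3, max_mismatch, length_range)
    if fwd.ok:
        return fwd
    rev = _extract_oriented(reverse_complement(seq), flank5, flank3, max_mismatch, length_range)
    if rev.ok:
        return rev
    worst = max(fwd, rev, key=lambda r: _REASON_RANK[r.reason])
    return worst


# ---------------------------------------------------------------------------
# Collapsing and database construction
# ---------------------------------------------------------------------------

def dna_to_full_rna(
    variable_region_dna: str,
    constant5: str = CONSTANT5_RNA,
    constant3: str = CONSTANT3_RNA,
) -> str:
    """T->U convert a variable region and flank it with the RNA constants."""
    if not variable_region_dna:
        raise InputError("variable region is empty")
    if set(variable_region_dna) - set("ACGT"):
        bad = sorted(set(variable_region_dna) - set("ACGT"))
        raise InputError(f"non-ACGT character(s) in variable region: {bad}")
    return constant5 + variable_region_dna.replace("T", "U") + constant3


def collapse_to_unique(variable_regions: Iterable[str], round_label: int) -> RoundPool:
    """Collapse extracted variable regions of one round into unique sequences."""
    counter = Counter(variable_regions)
    ordered = dict(sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])))
    return RoundPool(round_label, ordered)


def merge_pools(pools: Sequence[RoundPool]) -> list[RoundPool]:
    """Sum counts of pools sharing a round label (e.g. round 0 sequenced twice)."""
    by_round: dict[int, Counter] = defaultdict(Counter)
    for pool in pools:
        by_round[pool.round_label].update(pool.counts)
    return [
        RoundPool(r, dict(sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))))
        for r, c in sorted(by_round.items())
    ]


def build_database(
    pools: Sequence[RoundPool],
    constant5: str = CONSTANT5_RNA,
    constant3: str = CONSTANT3_RNA,
) -> list[SequenceRecord]:
    """Build the non-redundant database of unique sequences across rounds.

    Records are numbered 1..N in descending total-read order (ties broken
    lexicographically), the ordering used by the published database.
    """
    if not pools:
        raise InputError("at least one round pool is required")
    merged = merge_pools(pools)
    per_seq: dict[str, dict[int, int]] = defaultdict(dict)
    for pool in merged:
        for seq, count in pool.counts.items():
            per_seq[seq][pool.round_label] = count
    ordered = sorted(per_seq.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    return [
        SequenceRecord(
            id=i,
            variable_region_dna=seq,
            reads_per_round=counts,
            variable_region_rna=seq.replace("T", "U"),
            full_rna=constant5 + seq.replace("T", "U") + constant3,
        )
        for i, (seq, counts) in enumerate(ordered, start=1)
    ]


def database_rounds(records: Sequence[SequenceRecord]) -> list[int]:
    """Sorted list of round labels observed anywhere in the database."""
    rounds: set[int] = set()
    for rec in records:
        rounds.update(rec.reads_per_round)
    return sorted(rounds)


# ---------------------------------------------------------------------------
# Database CSV serialization (Database S1 column layout)
# ---------------------------------------------------------------------------

_FIXED_HEAD = ["#", "Representatives", "HTS read variable region", "Length"]
_FIXED_TAIL = ["Total", "Rounds", "RNA", "Structure", "Sequence Family", "Structure Family"]


def database_to_frame(
    records: Sequence[SequenceRecord], rounds: Sequence[int] | None = None
) -> pd.DataFrame:
    if rounds is None:
        rounds = database_rounds(records)
    rows = []
    for rec in records:
        row = {
            "#": rec.id,
            "Representatives": "X" if rec.representative else "",
            "HTS read variable region": rec.variable_region_dna,
            "Length": rec.length,
        }
        for r in rounds:
            row[str(r)] = rec.reads_in(r)
        row.update(
            {
                "Total": rec.total_reads,
                "Rounds": rec.rounds_present,
                "RNA": rec.full_rna,
                "Structure": rec.structure.dot_bracket if rec.structure is not None else "",
                "Sequence Family": rec.sequence_family or "",
                "Structure Family": rec.structure_family or "",
            }
        )
        rows.append(row)
    columns = _FIXED_HEAD + [str(r) for r in rounds] + _FIXED_TAIL
    return pd.DataFrame(rows, columns=columns)


def write_database(
    records: Sequence[SequenceRecord],
    path: str | Path,
    rounds: Sequence[int] | None = None,
) -> None:
    database_to_frame(records, rounds).to_csv(path, index=False)


def _family_columns(columns: list[str]) -> tuple[str, str]:
    """Locate the sequence/structure family columns.

    Our own files use explicit 'Sequence Family'/'Structure Family' headers;
    the published file repeats 'Sequence'/'Structure' after the 'RNA' and
    dot-bracket columns (pandas renames the repeat 'Structure.1')."""
    if "Sequence Family" in columns and "Structure Family" in columns:
        return "Sequence Family", "Structure Family"
    if "Sequence" in columns and "Structure.1" in columns:
        return "Sequence", "Structure.1"
    raise ParseError("missing column: Sequence Family / Structure Family")


def read_database(path: str | Path) -> list[SequenceRecord]:
    """Read a database CSV in the Database S1 column layout."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(frame.columns)
    for required in ("#", "HTS read variable region", "Total", "Rounds", "RNA", "Structure"):
        if required not in cols:
            raise ParseError(f"missing column: {required}")
    round_cols = [c for c in cols if re.fullmatch(r"\d+", c)]
    if not round_cols:
        raise ParseError("missing column: per-round read counts")
    seq_col, struct_col = _family_columns(cols)
    rep_col = "Representatives" if "Representatives" in cols else None

    from .rnastructure import StructureRecord  # local import to avoid a cycle

    records = []
    for _, row in frame.iterrows():
        try:
            counts = {int(c): int(row[c] or 0) for c in round_cols}
        except ValueError as exc:
            raise ParseError(f"non-integer read count in round columns: {exc}") from exc
        dot = row["Structure"].strip()
        structure = StructureRecord.from_dot_bracket(dot) if dot else None
        rna = row["RNA"].strip()
        var_rna = row["HTS read variable region"].strip().replace("T", "U")
        rec = SequenceRecord(
            id=int(row["#"]),
            variable_region_dna=row["HTS read variable region"].strip().upper(),
            reads_per_round=counts,
            variable_region_rna=var_rna,
            full_rna=rna,
            structure=structure,
            sequence_family=row[seq_col].strip() or None,
            structure_family=row[struct_col].strip() or None,
            representative=bool(rep_col and row[rep_col].strip()),
        )
        records.append(rec)
    return records


def write_round_fasta(pool: RoundPool, records_by_seq: Mapping[str, SequenceRecord],
                      path: str | Path) -> None:
    """Write the unique sequences of one round as FASTA, 'seq{ID}-{count}' headers."""
    with open(path, "w") as handle:
        for seq, count in pool.counts.items():
            rec = records_by_seq[seq]
            handle.write(f">seq{rec.id}-{count}\n{seq}\n")
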