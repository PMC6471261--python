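"""Read-cleaning cascade: raw reads → clean tags.

Rules are applied in a fixed order and every read is accounted to exactly
one outcome, so rejection counts plus the clean count always equal the raw
count for each library:

1. low_quality  — more than one base with Q <= 20
2. contains_n   — any unknown nucleotide (N)
3. no_3_adapter — leading 8-mer of the 3' adapter not found
4. has_5_adapter — leading 8-mer of the 5' adapter present in the insert
5. no_insert    — empty insert between adapters
6. polya        — insert is polyA (>= 80% A or a terminal run of >= 10 A)
7. too_short    — insert shorter than 18 nt
8. too_long     — insert longer than 30 nt (the library purifies 18–30 nt)
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .sequence_io import RawRead

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30
LOW_QUALITY_Q = 20  # inclusive
ADAPTER_SEED = 8

#: rejection reasons in cascade order, plus the surviving class
REASONS = (
    "low_quality", "contains_n", "no_3_adapter", "has_5_adapter",
    "no_insert", "polya", "too_short", "too_long",
)


@dataclass
class CleanTag:
    """A unique adapter-trimmed insert with per-library counts."""

    seq: str
    count_per_library: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "N" in self.seq:
            raise ValueError("clean tag may not contain N")
        if len(self.seq) < MIN_TAG_LEN:
            raise ValueError(f"clean tag shorter than {MIN_TAG_LEN} nt")

    @property
    def total(self) -> int:
        return sum(self.count_per_library.values())


@dataclass
class FilterReport:
    """Per-library accounting of the cleaning cascade."""

    removed: dict[str, Counter] = field(default_factory=dict)
    clean: Counter = field(default_factory=Counter)
    raw: Counter = field(default_factory=Counter)

    def add(self, library: str, reason: str | None) -> None:
        self.raw[library] += 1
        if reason is None:
            self.clean[library] += 1
        else:
            self.removed.setdefault(library, Counter())[reason] += 1

    def balanced(self) -> bool:
        """Conservation: removed + clean == raw, per library, exactly."""
        for lib, n_raw in self.raw.items():
            n_rm = sum(self.removed.get(lib, Counter()).values())
            if n_rm + self.clean[lib] != n_raw:
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for lib in sorted(self.raw):
            row = {r: self.removed.get(lib, Counter()).get(r, 0) for r in REASONS}
            row["clean"] = self.clean[lib]
            row["raw"] = self.raw[lib]
            rows[lib] = row
        return pd.DataFrame.from_dict(rows, orient="index")


def is_polya(insert: str) -> bool:
    """PolyA contamination: >= 80% A overall, or a 3'-terminal run of >= 10 A."""
    if not insert:
        return False
    if insert.count("A") / len(insert) >= 0.8:
        return True
    run = len(insert) - len(insert.rstrip("A"))
    return run >= 10


def clean_read(read: RawRead, adapter3: str, adapter5: str) -> tuple[str | None, str | None]:
    """Apply the cleaning cascade to one read.

    Returns (insert, None) for a surviving read or (None, reason) with the
    first rule that rejected it.  Adapter location is an exact-match search
    for the first occurrence of the adapter's leading 8-mer.
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    if sum(1 for q in read.qual if q <= LOW_QUALITY_Q) > 1:
        return None, "low_quality"
    if "N" in read.seq:
        return None, "contains_n"
    seed3 = adapter3[:ADAPTER_SEED]
    pos3 = read.seq.find(seed3)
    if pos3 < 0:
        return None, "no_3_adapter"
    insert = read.seq[:pos3]
    seed5 = adapter5[:ADAPTER_SEED]
    if seed5 in insert:
        return None, "has_5_adapter"
    if not insert:
        return None, "no_insert"
    if is_polya(insert):
        return None, "polya"
    if len(insert) < MIN_TAG_LEN:
        return None, "too_short"
    if len(insert) > MAX_TAG_LEN:
        return None, "too_long"
    return insert, None


def collapse_tags(
    reads_per_library: Mapping[str, Iterable[RawRead]],
    adapter3: str,
    adapter5: str,
) -> tuple[list[CleanTag], FilterReport]:
    """Clean every library and collapse identical inserts to unique tags.

    Tags are returned sorted by descending total count, then sequence, so
    output order is independent of input read order.
    """
    report = FilterReport()
    counts: dict[str, Counter] = {}
    for lib, reads in reads_per_library.items():
        for read in reads:
            insert, reason = clean_read(read, adapter3, adapter5)
            report.add(lib, reason)
            if insert is not None:
                counts.setdefault(insert, Counter())[lib] += 1
    tags = [CleanTag(seq, dict(c)) for seq, c in counts.items()]
    tags.sort(key=lambda t: (-t.total, t.seq))
    return tags, report


def total_clean_tags(tags: list[CleanTag], libraries: list[str]) -> dict[str, int]:
    """Per-library total clean-tag count — the TPM denominator."""
    totals = {lib: 0 for lib in libraries}
    for t in tags:
        for lib, c in t.count_per_library.items():
            totals[lib] = totals.get(lib, 0) + c
    return totals


def write_clean_tags_fasta(path, tags: list[CleanTag]) -> None:
    """clean_tags.fa with headers 'tagN|libA:3;libB:1'."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags, 1):
            cstr = ";".join(f"{lib}:{n}" for lib, n in sorted(t.count_per_library.items()))
            fh.write(f">tag{i}|{cstr}\n{t.seq}\n")


def read_clean_tags_fasta(path) -> list[CleanTag]:
    tags = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                header = line[1:]
            elif line:
                _, cstr = header.split("|", 1)
                counts = {}
                for part in cstr.split(";"):
                    lib, n = part.rsplit(":", 1)
                    counts[lib] = int(n)
                tags.append(CleanTag(line, counts))
    return tags
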