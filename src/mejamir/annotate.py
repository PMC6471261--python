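"""Classification of clean tags.

Each unique tag receives exactly one category, assigned in the removal
order used by small-RNA pipelines: other non-coding RNA first (rRNA, tRNA,
snRNA, snoRNA, scRNA), then repeat-like tags (too many transcriptome
loci), then — for tags mapping exactly to the transcriptome — a hairpin
screen separating novel miRNA candidates from mRNA degradation fragments,
with the mature-miRNA reference search taking precedence over the
fragment verdict.  Tags matching nothing are 'unannotated'.

The hairpin screen is a simplified precursor test: a transcriptome window
around the mapped tag must fold (see :mod:`mejamir.fold`) into a stem in
which the tag lies entirely on one arm, pairs at >= 14 of its bases with
the opposite arm, leaves <= 4 of its bases unpaired, and reaches a folding
score <= −18.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .fold import MIN_FOLD_LEN, MAX_FOLD_LEN, fold_window
from .preprocess import CleanTag
from .sequence_io import ValidationError

CATEGORIES = (
    "known_mirna", "other_ncrna", "mrna_fragment",
    "novel_candidate", "repeat", "unannotated",
)

MAX_KNOWN_MISMATCH = 2   # mature-reference search tolerance
MAX_END_OFFSET = 2       # nt of slack at each end vs the mature reference
MAX_LOCI = 10            # > this many transcriptome loci => repeat-like
MIN_PAIRED = 14          # tag bases paired with the opposite arm
MAX_BULGED = 4           # tag bases in bulges/loops
MAX_FOLD_SCORE = -18.0   # folding score threshold (surrogate energy)
WINDOW_FLANK_LONG = 150
WINDOW_FLANK_SHORT = 20


@dataclass
class ReferenceSet:
    """Fixture reference sequences standing in for the public databases."""

    mature_mirnas: dict[str, str]   # id -> mature sequence
    mature_families: dict[str, str]  # id -> family label (e.g. MIR169)
    other_ncrna: dict[str, str]
    transcriptome: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mature_mirnas or not self.transcriptome:
            raise ValidationError("reference set must be non-empty")
        for mid, seq in self.mature_mirnas.items():
            if not 18 <= len(seq) <= 26:
                raise ValidationError(
                    f"mature reference {mid}: length {len(seq)} outside [18, 26]"
                )


@dataclass
class TagAnnotation:
    tag_id: str
    seq: str
    category: str
    hit: Optional[tuple[str, str, int]] = None  # (reference id, strand, 0-based start)
    family: Optional[str] = None
    mirna_id: Optional[str] = None  # mature-reference id (known) or generated id (novel)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "known_mirna" and not self.family:
            raise ValueError("known_mirna annotation requires a family")
        if self.category in ("known_mirna", "novel_candidate") and not self.mirna_id:
            raise ValueError(f"{self.category} annotation requires a miRNA id")


@dataclass
class HairpinCandidate:
    contig: str
    window_start: int       # 0-based, on the contig
    window_end: int         # half-open
    arm: str                # '5p' or '3p' — which arm holds the mature tag
    paired_bases: int
    star_seq: str
    fold_score: float


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def match_known(tag_seq: str, refs: ReferenceSet) -> Optional[tuple[str, str, int]]:
    """Best mature-reference hit: <= 2 mismatches, no indels, ends within
    ±2 nt.  Returns (mirna id, family, mismatches) or None.  Equal-score
    ties go to the alphabetically first reference id."""
    best: Optional[tuple[int, str]] = None
    for mid in sorted(refs.mature_mirnas):
        mseq = refs.mature_mirnas[mid]
        # offset of tag 5' end relative to mature 5' end
        for off in range(-MAX_END_OFFSET, MAX_END_OFFSET + 1):
            end_off = (off + len(tag_seq)) - len(mseq)
            if abs(end_off) > MAX_END_OFFSET:
                continue
            # overlap region in tag coordinates
            t0 = max(0, -off)
            t1 = len(tag_seq) - max(0, end_off)
            if t1 - t0 <= 0:
                continue
            mm = _mismatches(tag_seq[t0:t1], mseq[t0 + off: t1 + off])
            if mm <= MAX_KNOWN_MISMATCH and (best is None or mm < best[0]):
                best = (mm, mid)
    if best is None:
        return None
    mid = best[1]
    return mid, refs.mature_families.get(mid, mid.split("-")[0]), best[0]


def _find_loci(tag_seq: str, transcriptome: dict[str, str]) -> list[tuple[str, int]]:
    loci = []
    for cid in sorted(transcriptome):
        seq = transcriptome[cid]
        start = seq.find(tag_seq)
        while start >= 0:
            loci.append((cid, start))
            if len(loci) > MAX_LOCI:
                return loci
            start = seq.find(tag_seq, start + 1)
    return loci


def screen_novel(
    tag_seq: str, contig_id: str, contig_seq: str, start: int
) -> HairpinCandidate | str:
    """Hairpin screen around an exactly-mapped tag.

    Excises the two windows [start−20, end+150) and [start−150, end+20)
    (clipped to the contig), folds each, and tests the better (lower
    score) window against the arm/pairing/bulge/score rules.  Returns a
    HairpinCandidate or a rejection reason string.
    """
    end = start + len(tag_seq)
    windows = []
    for left, right in (
        (start - WINDOW_FLANK_SHORT, end + WINDOW_FLANK_LONG),
        (start - WINDOW_FLANK_LONG, end + WINDOW_FLANK_SHORT),
    ):
        w0, w1 = max(0, left), min(len(contig_seq), right)
        if w1 - w0 < MIN_FOLD_LEN or w1 - w0 > MAX_FOLD_LEN:
            continue
        windows.append((w0, w1))
    if not windows:
        return "no-window"

    best = None
    for w0, w1 in windows:
        pairs, score = fold_window(contig_seq[w0:w1])
        if best is None or score < best[2]:
            best = (w0, w1, score, pairs)
    w0, w1, score, pairs = best

    t0, t1 = start - w0, end - w0  # tag in window coordinates
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    tag_partners = [partner.get(k) for k in range(t0, t1)]
    paired = [p for p in tag_partners if p is not None]
    if len(paired) < MIN_PAIRED:
        return "no-hairpin"
    if len(tag_seq) - len(paired) > MAX_BULGED:
        return "bulge-rule"
    # arm rule: every partner strictly on one side of the tag
    if all(p >= t1 for p in paired):
        arm = "5p"
    elif all(p < t0 for p in paired):
        arm = "3p"
    else:
        return "arm-rule"
    if score > MAX_FOLD_SCORE:
        return "weak-fold"
    s0, s1 = min(paired), max(paired) + 1
    return HairpinCandidate(
        contig=contig_id,
        window_start=w0,
        window_end=w1,
        arm=arm,
        paired_bases=len(paired),
        star_seq=contig_seq[w0 + s0: w0 + s1],
        fold_score=score,
    )


def classify_tags(
    tags: list[CleanTag], refs: ReferenceSet
) -> tuple[list[TagAnnotation], dict[str, HairpinCandidate]]:
    """Assign every tag exactly one category (see module docstring for the
    order).  Returns the annotations plus accepted hairpin candidates
    keyed by tag id."""
    annotations: list[TagAnnotation] = []
    hairpins: dict[str, HairpinCandidate] = {}
    novel_serial = 0
    for i, tag in enumerate(tags, 1):
        tag_id = f"tag{i}"
        ann = None

        for nid in sorted(refs.other_ncrna):
            pos = refs.other_ncrna[nid].find(tag.seq)
            if pos >= 0:
                ann = TagAnnotation(tag_id, tag.seq, "other_ncrna", (nid, "+", pos))
                break
        if ann is None:
            loci = _find_loci(tag.seq, refs.transcriptome)
            known = match_known(tag.seq, refs)
            if len(loci) > MAX_LOCI:
                ann = TagAnnotation(tag_id, tag.seq, "repeat")
            elif loci:
                cid, start = loci[0]
                if known is not None:
                    mid, family, _ = known
                    ann = TagAnnotation(tag_id, tag.seq, "known_mirna", (mid, "+", 0),
                                        family, mid)
                else:
                    result = screen_novel(tag.seq, cid, refs.transcriptome[cid], start)
                    if isinstance(result, HairpinCandidate):
                        novel_serial += 1
                        nid = f"novel-m{novel_serial:04d}-{result.arm}"
                        ann = TagAnnotation(tag_id, tag.seq, "novel_candidate",
                                            (cid, "+", start), nid, nid)
                        hairpins[tag_id] = result
                    else:
                        ann = TagAnnotation(tag_id, tag.seq, "mrna_fragment", (cid, "+", start))
            elif known is not None:
                mid, family, _ = known
                ann = TagAnnotation(tag_id, tag.seq, "known_mirna", (mid, "+", 0),
                                    family, mid)
            else:
                ann = TagAnnotation(tag_id, tag.seq, "unannotated")
        annotations.append(ann)
    return annotations, hairpins
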