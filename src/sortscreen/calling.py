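"""Part-level read annotation, GFF3 emission and genotype calling.

Each oriented read is annotated against the part reference set. Candidate
part placements are located with a fast semi-global edit-distance scan
(edlib); candidates surviving an identity prefilter are rescored with an
affine-gap local alignment (match +2, mismatch -3, gap open -4, gap extend
-2) restricted to the located window, which yields per-hit identity, part
coverage and score. Accepted hits are resolved per grammar slot and reduced
to a (promoter, signal peptide, CDS) genotype call; a read whose promoter,
signal peptide and 3' fusion module are present but whose CDS is missing is
the "false-high" class: a truncated construct that can still display.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd
from Bio import Align

from .parts import Part, PartRegistry, SLOT_ORDER

#: grammar slots that must be present, in order, for a full call
CALL_SLOTS = ("promoter", "sp_flag", "cds", "fusion_4a")

#: slots annotated on reads (barcode roles are handled by the demultiplexer)
ANNOTATED_ROLES = SLOT_ORDER

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -4, -2

#: edlib prefilter slack below min_identity: a hit acceptable after local
#: trimming can exceed the naive (1 - min_identity) distance bound by a
#: little, but true hits at nanopore error rates sit far below it
PREFILTER_MARGIN = 0.05

#: adjacent parts share a 4-nt fusion junction; allow alignment fuzz on top
ORDER_OVERLAP_SLACK = 20

#: a promoter hit flush with the 5' barcode junction may be PCR-clipped;
#: within this many nt of the read start, coverage >= 0.5 is accepted
FLUSH_5P_LIMIT = 40
CLIPPED_PROMOTER_MIN_COVERAGE = 0.5

FULL = "full"
CALL_STATUSES = (FULL, "truncated_no_cds", "partial", "ambiguous", "uncallable")


@dataclass(frozen=True)
class PartHit:
    """One accepted part placement on a read (0-based half-open coords)."""

    part_id: str
    role: str
    start: int
    stop: int
    strand: str
    identity: float
    coverage: float
    score: float
    clipped_5p: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0) or not (0.0 <= self.coverage <= 1.0 + 1e-9):
            raise ValueError("identity and coverage must lie in [0, 1]")
        if self.start < 0 or self.stop <= self.start:
            raise ValueError("hit coordinates must be ordered and non-negative")

    def overlaps(self, other: "PartHit") -> bool:
        span = min(self.stop, other.stop) - max(self.start, other.start)
        return span > 0.5 * min(self.stop - self.start, other.stop - other.start)


@dataclass(frozen=True)
class GenotypeCall:
    read_id: str
    call_status: str
    promoter_id: str | None = None
    sp_id: str | None = None
    cds_id: str | None = None
    n_hits: int = 0

    @property
    def genotype_key(self) -> tuple[str, str, str] | None:
        if self.promoter_id and self.sp_id and self.cds_id:
            return (self.promoter_id, self.sp_id, self.cds_id)
        return None


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = MATCH
    al.mismatch_score = MISMATCH
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    return al


_ALIGNER = _aligner()


def _rescore_window(
    read: str, part: Part, win_start: int, win_stop: int
) -> tuple[float, float, float, int, int]:
    """Affine-gap local alignment of the part against a read window.

    Returns (score, identity, coverage, read_start, read_stop).
    """
    window = read[win_start:win_stop]
    aln = _ALIGNER.align(window, part.sequence)[0]
    if len(aln.aligned[0]) == 0:  # degenerate: nothing aligned
        return 0.0, 0.0, 0.0, win_start, win_start + 1
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    q_blocks = aln.aligned[1]
    coverage = (q_blocks[-1][1] - q_blocks[0][0]) / len(part) if len(q_blocks) else 0.0
    t_blocks = aln.aligned[0]
    start = win_start + int(t_blocks[0][0])
    stop = win_start + int(t_blocks[-1][1])
    return float(aln.score), identity, coverage, start, stop


def annotate_read(
    read: str,
    registry: PartRegistry,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> list[PartHit]:
    """Annotate one oriented (+ strand) read against every registry part.

    Hits failing ``min_identity`` or ``min_coverage`` are dropped (promoters
    flush with the 5' end are allowed down to coverage 0.5, since the PCR
    primer can clip them); overlapping hits of the same slot keep the higher
    score, then the longer alignment. Hits are returned sorted by read start.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    if not (0.0 < min_identity <= 1.0) or not (0.0 < min_coverage <= 1.0):
        raise ValueError("thresholds must lie in (0, 1]")

    candidates: list[PartHit] = []
    for part in registry:
        if part.role not in ANNOTATED_ROLES:
            continue
        hit = _locate_and_score(read, part, min_identity, min_coverage)
        if hit is not None:
            candidates.append(hit)

    # PCR-clipped promoter rescue only when no promoter was found outright
    if not any(h.role == "promoter" for h in candidates):
        for part in registry.by_role("promoter"):
            hit = _rescue_clipped_promoter(read, part, min_identity)
            if hit is not None:
                candidates.append(hit)

    return _resolve_slot_overlaps(candidates)


_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _cigar_affine(cigar: str) -> tuple[int, int, int, float]:
    """(matches, mismatches, gap columns, affine score) of an edlib path."""
    matches = mismatches = gap_cols = 0
    score = 0.0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            matches += n
            score += MATCH * n
        elif op == "X":
            mismatches += n
            score += MISMATCH * n
        else:  # I or D: one gap run
            gap_cols += n
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
    return matches, mismatches, gap_cols, score


def _locate_and_score(
    read: str, part: Part, min_identity: float, min_coverage: float
) -> PartHit | None:
    """Two-stage scoring: a semi-global edlib alignment places the full part
    on the read; if its column identity already clears ``min_identity`` the
    hit is accepted outright (coverage 1.0 by construction). Borderline
    candidates are rescored by local affine alignment, which may trim to a
    cleaner sub-region — higher identity at reduced coverage."""
    max_dist = int(len(part) * (1.0 - min_identity + PREFILTER_MARGIN))
    res = edlib.align(part.sequence, read, mode="HW", task="path", k=max_dist)
    if res["editDistance"] == -1:
        return None
    loc_start, loc_stop = res["locations"][0]
    if res["editDistance"] == 0:
        return PartHit(part.part_id, part.role, loc_start, loc_stop + 1, "+",
                       1.0, 1.0, float(MATCH * len(part)))
    matches, mismatches, gap_cols, score = _cigar_affine(res["cigar"])
    identity = matches / (matches + mismatches + gap_cols)
    if identity >= min_identity:  # full part placed: coverage is 1 by construction
        return PartHit(part.part_id, part.role, loc_start, loc_stop + 1, "+",
                       identity, 1.0, score)
    pad = 30
    score, identity, coverage, start, stop = _rescore_window(
        read, part, max(0, loc_start - pad), min(len(read), loc_stop + 1 + pad)
    )
    if identity >= min_identity and coverage >= min_coverage:
        return PartHit(part.part_id, part.role, start, stop, "+", identity, coverage, score)
    return None


def _rescue_clipped_promoter(read: str, part: Part, min_identity: float) -> PartHit | None:
    """Accept a 5'-clipped promoter: its 3' portion aligned flush with the
    read start at reduced coverage. Prefiltered on the promoter's 3' half,
    without slack — random near-misses would otherwise dominate runtime."""
    half = part.sequence[len(part) // 2 :]
    head = read[: len(part) + FLUSH_5P_LIMIT]
    max_dist = int(len(half) * (1.0 - min_identity))
    res = edlib.align(half, head, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] == -1:
        return None
    score, identity, coverage, start, stop = _rescore_window(read, part, 0, len(head))
    if start <= FLUSH_5P_LIMIT and identity >= min_identity and coverage >= CLIPPED_PROMOTER_MIN_COVERAGE:
        return PartHit(part.part_id, part.role, start, stop, "+", identity, coverage,
                       score, clipped_5p=True)
    return None


def _resolve_slot_overlaps(candidates: Sequence[PartHit]) -> list[PartHit]:
    """Within each grammar slot, keep the best hit among overlapping ones
    (higher score, then longer alignment); cross-slot hits are untouched."""
    kept: list[PartHit] = []
    for role in ANNOTATED_ROLES:
        role_hits = sorted(
            (h for h in candidates if h.role == role),
            key=lambda h: (-h.score, -(h.stop - h.start), h.start),
        )
        accepted: list[PartHit] = []
        for hit in role_hits:
            if not any(hit.overlaps(a) for a in accepted):
                accepted.append(hit)
        kept.extend(accepted)
    return sorted(kept, key=lambda h: (h.start, h.stop))


def call_genotype(hits: Sequence[PartHit], read_id: str = "") -> GenotypeCall:
    """Reduce one read's part hits to a genotype call.

    full: exactly one accepted hit in each of promoter, sp, cds, 4a, in
    left-to-right grammar order. truncated_no_cds: promoter + sp + 4a present
    and ordered but the CDS missing (the false-high class). Two accepted hits
    in one slot, or slot order violated, give ambiguous; fewer slots partial;
    no hits uncallable.
    """
    n_hits = len(hits)
    if n_hits == 0:
        return GenotypeCall(read_id, "uncallable")
    by_slot: dict[str, list[PartHit]] = {slot: [] for slot in CALL_SLOTS}
    for hit in hits:
        if hit.role in by_slot:
            by_slot[hit.role].append(hit)

    if any(len(v) > 1 for v in by_slot.values()):
        return GenotypeCall(read_id, "ambiguous", n_hits=n_hits)

    present = [slot for slot in CALL_SLOTS if by_slot[slot]]
    ordered_hits = [by_slot[slot][0] for slot in present]
    for left, right in zip(ordered_hits, ordered_hits[1:]):
        if right.start < left.start or right.start < left.stop - ORDER_OVERLAP_SLACK:
            return GenotypeCall(read_id, "ambiguous", n_hits=n_hits)

    slot_ids = {slot: by_slot[slot][0].part_id for slot in present}
    if len(present) == len(CALL_SLOTS):
        return GenotypeCall(read_id, FULL, slot_ids["promoter"], slot_ids["sp_flag"],
                            slot_ids["cds"], n_hits)
    if set(present) == {"promoter", "sp_flag", "fusion_4a"}:
        return GenotypeCall(read_id, "truncated_no_cds", slot_ids["promoter"],
                            slot_ids["sp_flag"], None, n_hits)
    return GenotypeCall(
        read_id, "partial",
        slot_ids.get("promoter"), slot_ids.get("sp_flag"), slot_ids.get("cds"), n_hits,
    )


def call_reads(
    oriented: Mapping[str, str],
    registry: PartRegistry,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> tuple[dict[str, list[PartHit]], list[GenotypeCall]]:
    """Annotate and call every oriented read; returns hits per read and calls."""
    hits_by_read: dict[str, list[PartHit]] = {}
    calls: list[GenotypeCall] = []
    for read_id, seq in oriented.items():
        hits = annotate_read(seq, registry, min_identity, min_coverage)
        hits_by_read[read_id] = hits
        calls.append(call_genotype(hits, read_id))
    return hits_by_read, calls


# ---------------------------------------------------------------------------
# GFF3 emission (1-based inclusive coordinates) and its round-trip reader

GFF_HEADER = "##gff-version 3"


def emit_gff(hits_by_read: Mapping[str, Sequence[PartHit]], out: str | Path) -> None:
    """Write one GFF3 feature per part hit; seqid is the read id."""
    with open(out, "w") as fh:
        fh.write(GFF_HEADER + "\n")
        for read_id in hits_by_read:
            for h in hits_by_read[read_id]:
                attrs = (
                    f"ID={read_id}:{h.part_id};part_id={h.part_id};role={h.role};"
                    f"identity={h.identity:.6f};coverage={h.coverage:.6f};"
                    f"clipped_5p={int(h.clipped_5p)}"
                )
                fh.write(
                    "\t".join(
                        [read_id, "sortscreen", "genetic_part",
                         str(h.start + 1), str(h.stop), f"{h.score:.1f}",
                         h.strand, ".", attrs]
                    )
                    + "\n"
                )


def read_gff(path: str | Path) -> dict[str, list[PartHit]]:
    """Parse a GFF3 written by :func:`emit_gff` back into PartHit lists."""
    hits: dict[str, list[PartHit]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            seqid, _, _, start, stop, score, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
            hits.setdefault(seqid, []).append(
                PartHit(
                    part_id=fields["part_id"],
                    role=fields["role"],
                    start=int(start) - 1,
                    stop=int(stop),
                    strand=strand,
                    identity=float(fields["identity"]),
                    coverage=float(fields["coverage"]),
                    score=float(score),
                    clipped_5p=bool(int(fields.get("clipped_5p", "0"))),
                )
            )
    return hits


def calls_to_frame(calls: Iterable[GenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "status": c.call_status,
                "promoter": c.promoter_id or "",
                "sp": c.sp_id or "",
                "cds": c.cds_id or "",
                "n_hits": c.n_hits,
            }
            for c in calls
        ]
    )
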