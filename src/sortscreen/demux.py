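"""Dual-barcode demultiplexing, full-amplicon length filtering and orientation.

A read enters the analysis only if it carries exactly one forward (ORF
library) barcode and one reverse (gate) barcode — the full-amplicon rule — and
is at least ``min_len`` (default 2000 nt, inclusive). Orientation is then
unified with the cellulose-binding-module (CBM) sequence as the 3' marker:
the strand placing the marker nearer the 3' end is kept, reads without a
marker hit are dropped, and reads with two disjoint marker hits are flagged
as chimeric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .simulate import ReadRecord, revcomp

DEFAULT_MAX_DIST = 4
DEFAULT_WINDOW = 150
DEFAULT_MIN_LEN = 2000

ASSIGNED = "assigned"
STATUSES = (ASSIGNED, "no_fwd", "no_rev", "ambiguous", "too_short", "no_marker", "chimeric")


@dataclass(frozen=True)
class BarcodeHit:
    """Best infix match of one barcode near one read end (0-based half-open)."""

    barcode_id: str
    end: str  # head | tail
    edit_distance: int
    start: int
    stop: int


@dataclass
class PoolAssignment:
    """Demultiplexing outcome for one read."""

    read_id: str
    status: str
    orf_pool: str | None = None
    gate_pool: str | None = None
    fwd_dist: int | None = None
    rev_dist: int | None = None
    length: int = 0
    strand: str | None = None


def match_barcode(
    read: str,
    barcode: str,
    end: str = "head",
    max_dist: int = DEFAULT_MAX_DIST,
    window: int = DEFAULT_WINDOW,
    barcode_id: str = "",
) -> BarcodeHit | None:
    """Best infix alignment of ``barcode`` within the head or tail window.

    Returns None when the best edit distance exceeds ``max_dist``. Among
    equally distant placements the smallest start coordinate wins. A window
    larger than the read is clipped, not an error.
    """
    if end not in ("head", "tail"):
        raise ValueError(f"end must be 'head' or 'tail', got {end!r}")
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    window = min(max(window, len(barcode)), len(read))
    if window == 0 or not read:
        return None
    offset = 0 if end == "head" else len(read) - window
    segment = read[offset : offset + window]
    res = edlib.align(barcode, segment, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] == -1:
        return None
    start, stop = min(res["locations"])  # smallest start among best placements
    return BarcodeHit(
        barcode_id=barcode_id,
        end=end,
        edit_distance=res["editDistance"],
        start=offset + start,
        stop=offset + stop + 1,  # edlib reports inclusive end
    )


def _best_unique(hits: Sequence[BarcodeHit]) -> tuple[BarcodeHit | None, bool]:
    """Best hit by (distance, start); ambiguous when two distinct barcodes
    both match within range — such reads are excluded, never arbitrated."""
    if not hits:
        return None, False
    best = min(hits, key=lambda h: (h.edit_distance, h.start))
    ambiguous = len({h.barcode_id for h in hits}) > 1
    return best, ambiguous


def demultiplex(
    reads: Iterable[ReadRecord],
    barcodes: pd.DataFrame,
    max_dist: int = DEFAULT_MAX_DIST,
    window: int = DEFAULT_WINDOW,
) -> list[PoolAssignment]:
    """Assign each read to an (ORF library, gate) pool by dual barcodes.

    Both read orientations are tested: on the forward orientation the forward
    barcode must sit in the head window and the reverse barcode in the tail
    window (the manifest gives both as forward-strand sequences of the
    amplicon). A read matching two or more forward (or
    reverse) barcodes equally well is ``ambiguous``; missing either barcode
    gives ``no_fwd``/``no_rev``.
    """
    fwd = barcodes[barcodes["role"] == "fwd"]
    rev = barcodes[barcodes["role"] == "rev"]
    if fwd.empty or rev.empty:
        raise ValueError("barcode manifest must contain forward and reverse barcodes")
    dup = barcodes["barcode_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate barcode ids: {barcodes.loc[dup, 'barcode_id'].tolist()}")
    # manifest convention: both barcodes are given as they appear on the
    # forward strand of the amplicon (fwd at the 5' head, rev at the 3' tail)
    fwd_list = [(r["barcode_id"], r["sequence"]) for _, r in fwd.iterrows()]
    rev_list = [(r["barcode_id"], r["sequence"]) for _, r in rev.iterrows()]
    pool_of = barcodes.set_index("barcode_id")["pool"]

    return [
        _assign_one(read, fwd_list, rev_list, pool_of, max_dist, window) for read in reads
    ]


def _scan(read_seq: str, fwd_list, rev_list, max_dist: int, window: int):
    """Forward-orientation scan: fwd barcodes at head, revcomp of rev at tail."""
    fwd_hits = [
        h
        for bc_id, seq in fwd_list
        if (h := match_barcode(read_seq, seq, "head", max_dist, window, bc_id))
    ]
    rev_hits = [
        h
        for bc_id, seq in rev_list
        if (h := match_barcode(read_seq, seq, "tail", max_dist, window, bc_id))
    ]
    return fwd_hits, rev_hits


def _assign_one(
    read: ReadRecord, fwd_list, rev_list, pool_of: pd.Series, max_dist: int, window: int
) -> PoolAssignment:
    candidates = []
    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        fwd_hits, rev_hits = _scan(seq, fwd_list, rev_list, max_dist, window)
        best_f, amb_f = _best_unique(fwd_hits)
        best_r, amb_r = _best_unique(rev_hits)
        candidates.append((strand, best_f, amb_f, best_r, amb_r))

    # prefer the orientation with both barcodes and the lower total distance
    def rank(c):
        _, bf, _, br, _ = c
        n = (bf is not None) + (br is not None)
        total = (bf.edit_distance if bf else 0) + (br.edit_distance if br else 0)
        return (-n, total)

    strand, best_f, amb_f, best_r, amb_r = min(candidates, key=rank)
    if best_f is None:
        return PoolAssignment(read.read_id, "no_fwd", length=len(read.sequence))
    if best_r is None:
        return PoolAssignment(read.read_id, "no_rev", length=len(read.sequence))
    if amb_f or amb_r:
        return PoolAssignment(read.read_id, "ambiguous", length=len(read.sequence))
    return PoolAssignment(
        read_id=read.read_id,
        status=ASSIGNED,
        orf_pool=str(pool_of[best_f.barcode_id]),
        gate_pool=str(pool_of[best_r.barcode_id]),
        fwd_dist=best_f.edit_distance,
        rev_dist=best_r.edit_distance,
        length=len(read.sequence),
        strand=strand,
    )


def length_filter(
    assignments: Sequence[PoolAssignment],
    reads: Mapping[str, ReadRecord] | Sequence[ReadRecord],
    min_len: int = DEFAULT_MIN_LEN,
) -> list[PoolAssignment]:
    """Demote assigned reads shorter than ``min_len`` to ``too_short``.

    The threshold is inclusive: a read of exactly ``min_len`` nt is kept,
    matching an "at least 2 kb" rule.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    if not isinstance(reads, Mapping):
        reads = {r.read_id: r for r in reads}
    out = []
    for a in assignments:
        if a.status == ASSIGNED and len(reads[a.read_id].sequence) < min_len:
            out.append(
                PoolAssignment(a.read_id, "too_short", a.orf_pool, a.gate_pool,
                               a.fwd_dist, a.rev_dist, a.length, a.strand)
            )
        else:
            out.append(a)
    return out


def _marker_hits(seq: str, marker: str, max_dist: int) -> list[tuple[int, int, int]]:
    """All disjoint infix hits of the marker in seq as (distance, start, stop)."""
    hits = []
    masked = seq
    for _ in range(4):  # more than 2 hits never changes the verdict
        res = edlib.align(marker, masked, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] == -1:
            break
        start, stop = min(res["locations"])
        hits.append((res["editDistance"], start, stop + 1))
        masked = masked[: start] + "N" * (stop + 1 - start) + masked[stop + 1 :]
    return hits


def orient_reads(
    reads: Iterable[ReadRecord],
    assignments: Sequence[PoolAssignment],
    marker: str,
    min_identity: float = 0.8,
) -> tuple[dict[str, str], list[PoolAssignment]]:
    """Unify read orientation using the marker (CBM) as the 3' anchor.

    For each assigned read the marker is aligned to both strands; the strand
    placing it nearer the 3' end is kept. Reads with no marker at
    >= ``min_identity`` become ``no_marker``; two disjoint marker hits on the
    chosen strand flag the read ``chimeric``. Returns the oriented sequences
    (read_id -> + strand sequence) and updated assignments.
    """
    if len(marker) < 30:
        raise ValueError("marker must be at least 30 nt")
    max_dist = int(round(len(marker) * (1.0 - min_identity)))
    read_map = {r.read_id: r for r in reads}
    oriented: dict[str, str] = {}
    out: list[PoolAssignment] = []
    for a in assignments:
        if a.status != ASSIGNED:
            out.append(a)
            continue
        seq = read_map[a.read_id].sequence
        fwd_hits = _marker_hits(seq, marker, max_dist)
        rc = revcomp(seq)
        rev_hits = _marker_hits(rc, marker, max_dist)
        if not fwd_hits and not rev_hits:
            out.append(PoolAssignment(a.read_id, "no_marker", a.orf_pool, a.gate_pool,
                                      a.fwd_dist, a.rev_dist, a.length, a.strand))
            continue

        def dist_to_3p(hits, length):
            return min(length - stop for _, _, stop in hits) if hits else float("inf")

        # keep the strand placing the (best) marker closer to the 3' end;
        # ties resolve toward the + strand for determinism
        if dist_to_3p(fwd_hits, len(seq)) <= dist_to_3p(rev_hits, len(rc)):
            chosen_seq, chosen_hits, strand = seq, fwd_hits, "+"
        else:
            chosen_seq, chosen_hits, strand = rc, rev_hits, "-"
        if len(chosen_hits) >= 2:
            out.append(PoolAssignment(a.read_id, "chimeric", a.orf_pool, a.gate_pool,
                                      a.fwd_dist, a.rev_dist, a.length, a.strand))
            continue
        oriented[a.read_id] = chosen_seq
        out.append(PoolAssignment(a.read_id, ASSIGNED, a.orf_pool, a.gate_pool,
                                  a.fwd_dist, a.rev_dist, a.length, strand))
    return oriented, out


def assignments_to_frame(assignments: Iterable[PoolAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "status": a.status,
                "orf_pool": a.orf_pool or "",
                "gate_pool": a.gate_pool or "",
                "fwd_dist": a.fwd_dist if a.fwd_dist is not None else -1,
                "rev_dist": a.rev_dist if a.rev_dist is not None else -1,
                "length": a.length,
                "strand": a.strand or "",
            }
            for a in assignments
        ]
    )
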