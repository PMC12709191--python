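"""Event-type and translocation-class assignment for split reads.

Decision order for the event type of a split read:

1. a telomeric clip (irregular TG-rich units on either strand) is a
   telomere addition, unless a substantial non-telomeric remainder of
   the clip places in subtelomeric repeat context, in which case the
   read is a repeat-templated translocation (class C) and flagged;
2. a clip with exactly one placement, on the break chromosome,
   telomere-proximal to the URA3 marker, and outside repeat
   annotations, is a deletion;
3. any other placed clip is a translocation (including every ambiguous
   or multi-mapping case);
4. otherwise the read is unclassified.

Translocation classes are evaluated in the fixed order C -> B -> A so
that a clip satisfying several rules receives a single, stable class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from gcrmap._util import revcomp, seq_to_array
from gcrmap.errors import DataError
from gcrmap.genome_model import AnnotationSet, Genome, RepairRegion, REPEAT_KINDS
from gcrmap.splitread import (
    AnchoredRead,
    Breakpoint,
    ClipTooShortError,
    KmerIndex,
    TargetHit,
    breakpoint_coordinate,
    realign_clip,
)

ATAT_MOTIF = "ATATATAT"


class TelomericMatch(enum.Enum):
    G_STRAND = "match_G_strand"
    C_STRAND = "match_C_strand"
    NO_MATCH = "no_match"

    def __bool__(self) -> bool:
        return self is not TelomericMatch.NO_MATCH


def longest_telomeric_prefix(seq: str, strand: str = "G") -> int:
    """Length of the longest prefix consistent with the irregular telomeric
    repeat: runs of G of length <= 3 separated by single Ts (G strand), or
    runs of C of length <= 3 separated by single As (C strand)."""
    if strand == "G":
        multi, single = "G", "T"
    elif strand == "C":
        multi, single = "C", "A"
    else:
        raise ValueError(f"strand must be 'G' or 'C', not {strand!r}")
    n = 0
    run_multi = run_single = 0
    for ch in seq:
        if ch == multi:
            run_multi += 1
            run_single = 0
            if run_multi > 3:
                break
        elif ch == single:
            run_single += 1
            run_multi = 0
            if run_single > 1:
                break
        else:
            break
        n += 1
    return n


def is_telomeric(
    seq: str,
    min_len: int = 8,
    min_fraction: float = 0.9,
    window: int = 30,
) -> TelomericMatch:
    """Classify a sequence as G-strand telomeric, C-strand telomeric, or
    neither.

    The longest telomeric prefix must span at least ``min_fraction`` of
    ``min(len(seq), window)`` and be at least ``min_len``.  Both strands
    are evaluated; the longer match wins.
    """
    if not seq:
        raise DataError("is_telomeric requires a non-empty sequence")
    w = min(len(seq), window)
    need = max(min_len, min_fraction * w)
    g = longest_telomeric_prefix(seq, "G")
    c = longest_telomeric_prefix(seq, "C")
    best = max(g, c)
    if best < need:
        return TelomericMatch.NO_MATCH
    return TelomericMatch.G_STRAND if g >= c else TelomericMatch.C_STRAND


# ---------------------------------------------------------------------------
# Microhomology


@dataclass(frozen=True)
class MicrohomologyReport:
    """Best ungapped local alignment window between two junction flanks."""

    span: int
    identity: float
    score: int
    offset_a: int
    offset_b: int

    def is_present(self, min_span: int = 8, min_identity: float = 0.8) -> bool:
        return self.span >= min_span and self.identity >= min_identity


def microhomology(flank_a: str, flank_b: str, window: int = 8) -> MicrohomologyReport:
    """Best-scoring ungapped window between two flanks (match +1,
    mismatch -1), exhaustively scanned over every diagonal.

    Ties on score prefer the longer window, then the smallest offsets, so
    the result is deterministic.  ``window`` is the minimum span
    considered when judging presence (see :meth:`MicrohomologyReport.is_present`).
    """
    if not flank_a or not flank_b:
        return MicrohomologyReport(0, 0.0, 0, 0, 0)
    a = seq_to_array(flank_a)
    b = seq_to_array(flank_b)
    la, lb = len(a), len(b)
    best = (-(10**9), 0, 0, 0)  # score, span, -offset_a, -offset_b (maximised)
    best_off = (0, 0)
    for d in range(-(lb - 1), la):
        ia = max(0, d)
        ib = ia - d
        ln = min(la - ia, lb - ib)
        if ln <= 0:
            continue
        vals = np.where(a[ia : ia + ln] == b[ib : ib + ln], 1, -1)
        c = np.concatenate(([0], np.cumsum(vals)))
        for s in range(ln):
            for e in range(s + 1, ln + 1):
                score = int(c[e] - c[s])
                span = e - s
                cand = (score, span, -(ia + s), -(ib + s))
                if cand > best:
                    best = cand
                    best_off = (ia + s, ib + s)
    score, span = best[0], best[1]
    if span == 0:
        return MicrohomologyReport(0, 0.0, 0, 0, 0)
    matches = (span + score) // 2
    return MicrohomologyReport(
        span=span,
        identity=matches / span,
        score=score,
        offset_a=best_off[0],
        offset_b=best_off[1],
    )


# ---------------------------------------------------------------------------
# Events


@dataclass
class GCREvent:
    """A classified rearrangement breakpoint with read support."""

    breakpoint: Breakpoint
    event_type: str  # {telomere_addition, deletion, translocation, unclassified}
    translocation_class: str = "not_applicable"  # {A, B, C, other, not_applicable}
    target_hits: list[TargetHit] = field(default_factory=list)
    support: int = 1
    microhomology: MicrohomologyReport | None = None
    flags: tuple[str, ...] = ()
    clip_seq: str = ""  # junction-first representative clip
    read_ids: list[str] = field(default_factory=list)

    @property
    def best_hit(self) -> TargetHit | None:
        return self.target_hits[0] if self.target_hits else None

    @property
    def target_key(self) -> tuple[str, int, str] | None:
        h = self.best_hit
        if h is None:
            return None
        return (h.chrom, h.junction_coord(), h.strand)


@dataclass
class ClassifyParams:
    """Tunable thresholds for event classification."""

    tel_min_len: int = 8
    tel_min_fraction: float = 0.9
    tel_window: int = 30
    min_remainder: int = 20  # clip tail needed to refine a telomeric call
    max_mismatch: int | None = None  # None -> len//25
    atat_min_lead: int = 6  # leading alternating-A/T bases accepted as motif
    yprime_edge_tolerance: int = 5
    mh_flank: int = 30
    mh_min_span: int = 12
    mh_min_identity: float = 0.8
    class_c_min_tract: int = 8


def _telomeric_prefix_both(seq: str) -> int:
    return max(
        longest_telomeric_prefix(seq, "G"), longest_telomeric_prefix(seq, "C")
    )


def _hits_in_context(
    hits: list[TargetHit], annotations: AnnotationSet, kinds: frozenset[str]
) -> bool:
    return any(
        annotations.overlapping(h.chrom, h.start, h.end, kinds) for h in hits
    )


def target_flank(hit: TargetHit, genome: Genome, width: int) -> str:
    """Genomic sequence adjacent to the junction on the far side of a hit,
    oriented for direct comparison with the retained repair-region flank."""
    seq = genome[hit.chrom]
    if hit.strand == "-":
        return seq[hit.end : hit.end + width]
    lo = max(0, hit.start - width)
    return revcomp(seq[lo : hit.start])


def _safe_realign(
    seq: str, genome: Genome, index: KmerIndex, max_mismatch: int | None
) -> list[TargetHit]:
    try:
        return realign_clip(seq, genome, max_mismatch=max_mismatch, index=index)
    except ClipTooShortError:
        return []


def translocation_class(
    clip: str,
    hits: list[TargetHit],
    breakpoint: Breakpoint,
    genome: Genome,
    annotations: AnnotationSet,
    region: RepairRegion,
    index: KmerIndex,
    params: ClassifyParams | None = None,
) -> tuple[str, MicrohomologyReport | None]:
    """Assign a translocation class; ``clip`` is junction-first.

    Precedence is C, then B, then A; anything else is "other".
    """
    params = params or ClassifyParams()

    # Class C: telomeric tract at the junction followed by sequence placing
    # in Y'/ITS (subtelomeric repeat) context.
    tract = _telomeric_prefix_both(clip)
    if tract >= params.class_c_min_tract and tract < len(clip):
        rem = clip[tract:]
        rem_hits = _safe_realign(rem, genome, index, params.max_mismatch)
        ctx = frozenset({"Yprime_element", "ITS", "telomere"})
        if _hits_in_context(rem_hits, annotations, ctx) or (
            tract >= params.class_c_min_tract
            and _hits_in_context(hits, annotations, ctx)
        ):
            if rem_hits or hits:
                return "C", None

    # Class B: the clip begins with the characteristic ATATATAT motif and
    # its continuation places at a Y' element start.  Junction
    # canonicalisation may absorb the motif's first base(s) into the
    # anchor, so a leading alternating-A/T run stands in for the motif.
    if len(clip) >= params.atat_min_lead:
        lead = 0
        while (
            lead < len(clip)
            and lead < len(ATAT_MOTIF)
            and clip[lead] in "AT"
            and (lead == 0 or clip[lead] != clip[lead - 1])
        ):
            lead += 1
        if lead >= params.atat_min_lead:
            rem = clip[lead:]
            rem_hits = _safe_realign(rem, genome, index, params.max_mismatch)
            tol = params.yprime_edge_tolerance
            for h in rem_hits:
                for yp in annotations.by_kind("Yprime_element", h.chrom):
                    near_edge = (
                        abs(h.junction_coord() - yp.end) <= tol
                        or abs(h.junction_coord() - yp.start) <= tol
                    )
                    overlaps = h.start < yp.end and yp.start < h.end
                    if overlaps and near_edge:
                        return "B", None

    # Class A: best placement strictly internal to an X or Y' element with
    # microhomology between the breakpoint flank and the target flank.
    if hits:
        best_mm = min(h.mismatches for h in hits)
        best_hits = [h for h in hits if h.mismatches == best_mm]
        flank_a = _retained_flank(breakpoint, genome, region, params.mh_flank)
        for h in best_hits:
            internal = any(
                f.start < h.start and h.end < f.end
                for f in annotations.overlapping(
                    h.chrom, h.start, h.end, {"X_element", "Yprime_element"}
                )
            )
            if not internal:
                continue
            mh = microhomology(flank_a, target_flank(h, genome, params.mh_flank))
            if mh.is_present(params.mh_min_span, params.mh_min_identity):
                return "A", mh
    return "other", None


def _retained_flank(
    breakpoint: Breakpoint, genome: Genome, region: RepairRegion, width: int
) -> str:
    """First ``width`` retained reference bases at the junction, reading
    away from the junction into the repair region."""
    seq = genome[breakpoint.chrom]
    b = breakpoint.retained_boundary
    if region.orientation == "left":
        return seq[b : b + width]
    lo = max(0, b - width)
    return revcomp(seq[lo:b])


def classify_event(
    read: AnchoredRead,
    hits: list[TargetHit] | None,
    annotations: AnnotationSet,
    region: RepairRegion,
    genome: Genome,
    index: KmerIndex | None = None,
    params: ClassifyParams | None = None,
) -> GCREvent:
    """Classify one split read into a support-1 :class:`GCREvent`.

    ``hits`` are the placements of the junction-first clip; pass None to
    let this function realign the clip itself.
    """
    params = params or ClassifyParams()
    if index is None:
        index = KmerIndex(genome)
    clip = read.clip_junction_first
    if not clip:
        raise DataError(f"read {read.read_id} has no clip to classify")
    bp = breakpoint_coordinate(read, region)
    if hits is None:
        hits = _safe_realign(clip, genome, index, params.max_mismatch)
    flags: list[str] = list(bp.flags)

    tel = is_telomeric(
        clip, params.tel_min_len, params.tel_min_fraction, params.tel_window
    )
    if tel:
        tract = _telomeric_prefix_both(clip)
        rem = clip[tract:]
        refine = (
            len(rem) >= params.min_remainder
            and not is_telomeric(
                rem, params.tel_min_len, params.tel_min_fraction, params.tel_window
            )
        )
        if refine:
            rem_hits = _safe_realign(rem, genome, index, params.max_mismatch)
            ctx = frozenset({"Yprime_element", "ITS", "telomere"})
            if _hits_in_context(rem_hits, annotations, ctx):
                flags.append("tg_then_subtelomeric")
                tclass, mh = translocation_class(
                    clip, hits, bp, genome, annotations, region, index, params
                )
                return GCREvent(
                    breakpoint=bp,
                    event_type="translocation",
                    translocation_class=tclass,
                    target_hits=rem_hits,
                    microhomology=mh,
                    flags=tuple(flags),
                    clip_seq=clip,
                    read_ids=[read.read_id],
                )
        if hits and _hits_in_context(
            hits, annotations, frozenset({"ITS", "telomere"})
        ):
            # telomeric clip that also places at interstitial telomeric
            # repeats: keep the telomere-addition call but mark it
            flags.append("tg_places_at_its")
        return GCREvent(
            breakpoint=bp,
            event_type="telomere_addition",
            target_hits=hits or [],
            flags=tuple(flags),
            clip_seq=clip,
            read_ids=[read.read_id],
        )

    if hits:
        best = hits[0]
        if best.n_equivalent == 1:
            in_repeat = bool(
                annotations.overlapping(best.chrom, best.start, best.end, REPEAT_KINDS)
            )
            ura3 = annotations.by_kind("URA3_marker", region.chrom)
            if ura3 and best.chrom == region.chrom and not in_repeat:
                anchor = (
                    ura3[0].start
                    if region.orientation == "left"
                    else ura3[0].end
                )
                tel_proximal = region.is_telomere_proximal(
                    best.junction_coord(), anchor
                )
                if tel_proximal:
                    return GCREvent(
                        breakpoint=bp,
                        event_type="deletion",
                        target_hits=hits,
                        flags=tuple(flags),
                        clip_seq=clip,
                        read_ids=[read.read_id],
                    )
        tclass, mh = translocation_class(
            clip, hits, bp, genome, annotations, region, index, params
        )
        return GCREvent(
            breakpoint=bp,
            event_type="translocation",
            translocation_class=tclass,
            target_hits=hits,
            microhomology=mh,
            flags=tuple(flags),
            clip_seq=clip,
            read_ids=[read.read_id],
        )

    return GCREvent(
        breakpoint=bp,
        event_type="unclassified",
        flags=tuple(flags),
        clip_seq=clip,
        read_ids=[read.read_id],
    )


def classify_reads(
    reads: list[AnchoredRead],
    annotations: AnnotationSet,
    region: RepairRegion,
    genome: Genome,
    params: ClassifyParams | None = None,
) -> list[GCREvent]:
    """Classify every split read, sharing one k-mer index."""
    index = KmerIndex(genome)
    return [
        classify_event(r, None, annotations, region, genome, index, params)
        for r in reads
    ]
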