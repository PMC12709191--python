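"""Split-read detection, breakpoint calling, and clip placement.

A split read anchors in the repair region and carries a soft-clipped
tail derived from the rearrangement partner.  This module extracts
anchored reads from SAM alignments (or aligns raw reads against the
repair region with a built-in seed-and-extend aligner suitable for toy
genomes), calls the breakpoint coordinate, and places clipped tails on
the genome with a 12-mer seeded Hamming search.

Clip strings are stored in reference (+) orientation, as in SAM.  The
``junction-first`` orientation (reading outward from the junction) is
derived where classification needs it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from gcrmap._util import revcomp, seq_to_array
from gcrmap.errors import DataError
from gcrmap.genome_model import Genome, RepairRegion

DEFAULT_SEED_SIZE = 12
DEFAULT_MIN_CLIP = 10


@dataclass
class AnchoredRead:
    """A read with an aligned anchor and (optionally) one clipped tail."""

    read_id: str
    chrom: str
    anchor_start: int
    anchor_end: int
    strand: str
    clip_seq: str = ""
    clip_side: str = "none"  # {left, right, none}
    mapq: int = 60

    @property
    def has_clip(self) -> bool:
        return bool(self.clip_seq)

    @property
    def clip_junction_first(self) -> str:
        """The clip read outward from the junction, 5'->3'.

        For a left clip the junction sits at the clip's right end, so the
        junction-first view is the reverse complement.
        """
        if self.clip_side == "left":
            return revcomp(self.clip_seq)
        return self.clip_seq


@dataclass(frozen=True)
class TargetHit:
    """One genomic placement of a clipped tail."""

    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    n_equivalent: int = 1

    def junction_coord(self) -> int:
        """Reference coordinate of the junction boundary, assuming the
        placed query was in junction-first orientation."""
        return self.start if self.strand == "+" else self.end

    def with_equivalents(self, n: int) -> "TargetHit":
        return TargetHit(
            self.chrom, self.start, self.end, self.strand, self.mismatches, n
        )


@dataclass(frozen=True)
class Breakpoint:
    """Reference position at which a split read diverges from the genome.

    ``coordinate`` is the 0-based position of the first divergent
    nucleotide (reported 1-based in output tables); ``side`` is the clip
    side.  ``retained_boundary`` gives the first retained reference base
    on the repair-region side of the junction, which is invariant across
    reads of the same junction.
    """

    chrom: str
    coordinate: int
    side: str
    flags: tuple[str, ...] = ()

    @property
    def retained_boundary(self) -> int:
        return self.coordinate + 1 if self.side == "left" else self.coordinate

    @property
    def coordinate_1based(self) -> int:
        return self.coordinate + 1


class ClipTooShortError(DataError):
    """Raised when a clip is shorter than the realignment seed size;
    callers should skip placement-based classification for such reads."""


class KmerIndex:
    """Exact k-mer index over the + strand of a genome."""

    def __init__(self, genome: Genome, k: int = DEFAULT_SEED_SIZE):
        self.genome = genome
        self.k = k
        self.arrays = {c: seq_to_array(genome[c]) for c in genome}
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in genome:
            seq = genome[chrom]
            for i in range(len(seq) - k + 1):
                index[seq[i : i + k]].append((chrom, i))
        self._index = dict(index)

    def positions(self, kmer: str) -> Sequence[tuple[str, int]]:
        return self._index.get(kmer, ())


def default_max_mismatch(clip_length: int) -> int:
    """Tolerant-local-alignment stand-in: one mismatch per 25 nt."""
    return clip_length // 25


def realign_clip(
    clip_seq: str,
    genome: Genome,
    max_mismatch: int | None = None,
    index: KmerIndex | None = None,
) -> list[TargetHit]:
    """Place a clipped tail on both strands of the genome.

    Seed-and-extend over a k-mer index: every k-mer of the query is
    looked up, candidate diagonals are verified by full-length Hamming
    comparison, and all placements with at most ``max_mismatch``
    mismatches are returned.  ``n_equivalent`` on each hit counts the
    placements achieving the best (minimum) mismatch count.

    With seeds taken at every query offset, any placement with
    ``m <= len(clip)//(k+1) - 1`` mismatches contains a clean k-mer, so
    for the default ``max_mismatch = len//25`` and k = 12 the result is
    identical to a brute-force sliding-window Hamming search.
    """
    if index is None:
        index = KmerIndex(genome)
    k = index.k
    L = len(clip_seq)
    if L < k:
        raise ClipTooShortError(
            f"clip of length {L} is shorter than the seed size {k}; "
            "skip placement-based classification for this read"
        )
    if max_mismatch is None:
        max_mismatch = default_max_mismatch(L)

    hits: list[TargetHit] = []
    seen: set[tuple[str, int, str]] = set()
    for strand, query in (("+", clip_seq), ("-", revcomp(clip_seq))):
        qarr = seq_to_array(query)
        candidates: set[tuple[str, int]] = set()
        for off in range(L - k + 1):
            for chrom, pos in index.positions(query[off : off + k]):
                candidates.add((chrom, pos - off))
        for chrom, start in candidates:
            if start < 0 or start + L > len(index.arrays[chrom]):
                continue
            key = (chrom, start, strand)
            if key in seen:
                continue
            mism = int((index.arrays[chrom][start : start + L] != qarr).sum())
            if mism <= max_mismatch:
                seen.add(key)
                hits.append(TargetHit(chrom, start, start + L, strand, mism))
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    n_eq = sum(1 for h in hits if h.mismatches == best)
    hits = [h.with_equivalents(n_eq) for h in hits]
    hits.sort(key=lambda h: (h.mismatches, h.chrom, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# SAM parsing


def parse_alignments(
    path: str | Path, genome: Genome, region: RepairRegion
) -> list[AnchoredRead]:
    """Extract anchored reads overlapping the repair region from a SAM file.

    Soft-clipped tails become ``clip_seq`` (the longer clip when both
    ends are clipped); hard-clipped records are skipped with a warning;
    secondary and supplementary alignments are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"alignment file not found: {path}")
    reads: list[AnchoredRead] = []
    warnings: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for lineno, rec in enumerate(af, start=1):
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                chrom = rec.reference_name
                if chrom not in genome:
                    raise DataError(f"unknown reference {chrom!r}")
                if any(op == 5 for op, _ in rec.cigartuples or ()):
                    warnings.append(
                        f"read {rec.query_name}: hard-clipped record skipped"
                    )
                    continue
                start, end = rec.reference_start, rec.reference_end
                if chrom != region.chrom or end <= region.start or start >= region.end:
                    continue
                cig = rec.cigartuples or []
                left = cig[0][1] if cig and cig[0][0] == 4 else 0
                right = cig[-1][1] if cig and cig[-1][0] == 4 else 0
                seq = rec.query_sequence or ""
                clip_seq, clip_side = "", "none"
                if left or right:
                    # one junction per read in this assay: analyse the longer
                    # clip and ignore the other
                    if left >= right:
                        clip_seq, clip_side = seq[:left], "left"
                    else:
                        clip_seq, clip_side = seq[len(seq) - right :], "right"
                reads.append(
                    AnchoredRead(
                        read_id=rec.query_name,
                        chrom=chrom,
                        anchor_start=start,
                        anchor_end=end,
                        strand="-" if rec.is_reverse else "+",
                        clip_seq=clip_seq,
                        clip_side=clip_side,
                        mapq=rec.mapping_quality,
                    )
                )
            except DataError:
                raise
            except Exception as exc:
                raise DataError(f"{path}: unparseable record #{lineno}: {exc}") from exc
    parse_alignments.last_warnings = warnings  # type: ignore[attr-defined]
    return reads


def detect_split_reads(
    reads: Iterable[AnchoredRead],
    region: RepairRegion,
    min_clip: int = DEFAULT_MIN_CLIP,
    min_mapq: int = 0,
) -> list[AnchoredRead]:
    """Keep reads whose anchor lies in the repair region and whose clip is
    long enough and on the side pointing away from the retained
    (centromeric) segment."""
    if min_clip < 1:
        raise DataError("min_clip must be >= 1")
    out = []
    for r in reads:
        if not r.has_clip or len(r.clip_seq) < min_clip:
            continue
        if r.mapq < min_mapq:
            continue
        if r.clip_side != region.telomere_side:
            continue
        bp = breakpoint_coordinate(r, region)
        if not region.contains(r.chrom, bp.retained_boundary) and not region.contains(
            r.chrom, bp.coordinate
        ):
            continue
        out.append(r)
    return out


def breakpoint_coordinate(read: AnchoredRead, region: RepairRegion) -> Breakpoint:
    """The reference coordinate at which the read diverges from the genome:
    the position adjacent to the last reference-matching base, on the
    clipped side of the anchor."""
    if not read.has_clip:
        raise DataError(f"read {read.read_id} has no clip")
    flags: list[str] = []
    if read.clip_side == "left":
        coord = read.anchor_start - 1
    else:
        coord = read.anchor_end
    if read.clip_side != region.telomere_side:
        flags.append("clip_on_centromeric_side")
    boundary = coord + 1 if read.clip_side == "left" else coord
    if boundary <= region.start or boundary >= region.end:
        flags.append("at_region_edge")
    return Breakpoint(read.chrom, coord, read.clip_side, tuple(flags))


# ---------------------------------------------------------------------------
# Built-in read aligner for toy genomes


class RegionAligner:
    """Seed-and-extend aligner of raw reads against the repair region.

    Stands in for an external local aligner on toy genomes.  Anchors are
    grown by maximal exact extension; a mismatch is absorbed only when
    followed by ``error_lookahead`` further matches, so isolated
    sequencing errors extend the anchor while divergent (clipped) tails
    stop it at the junction.
    """

    def __init__(
        self,
        genome: Genome,
        region: RepairRegion,
        k: int = DEFAULT_SEED_SIZE,
        seed_stride: int = 4,
        min_anchor: int = 14,
        error_lookahead: int = 8,
        edge_slack: int = 5,
        margin: int = 200,
    ):
        self.genome = genome
        self.region = region
        self.k = k
        self.seed_stride = seed_stride
        self.min_anchor = min_anchor
        self.error_lookahead = error_lookahead
        self.edge_slack = edge_slack
        self.chrom_arr = seq_to_array(genome[region.chrom])
        index: dict[str, list[int]] = defaultdict(list)
        seq = genome[region.chrom]
        lo = max(0, region.start - margin)
        hi = min(len(seq), region.end + margin)
        for i in range(lo, hi - k + 1):
            index[seq[i : i + k]].append(i)
        self._index = dict(index)

    def _extend(self, match: np.ndarray, lo: int, hi: int) -> tuple[int, int]:
        """Grow [lo, hi) over the match mask, absorbing a mismatch only
        when the next ``error_lookahead`` positions all match."""
        la = self.error_lookahead
        n = len(match)
        while True:
            if lo > 0 and match[lo - 1]:
                lo -= 1
            elif lo > la and match[lo - 1 - la : lo - 1].all():
                lo -= 1 + la
            else:
                break
        while True:
            if hi < n and match[hi]:
                hi += 1
            elif hi + la < n and match[hi + 1 : hi + 1 + la].all():
                hi += 1 + la
            else:
                break
        return lo, hi

    def _evaluate(self, qarr: np.ndarray, g0: int) -> tuple[int, int] | None:
        """Best anchor interval (read offsets) for a fixed diagonal."""
        L = len(qarr)
        n = len(self.chrom_arr)
        lo_clip = max(0, -g0)
        hi_clip = min(L, n - g0)
        if hi_clip - lo_clip < self.k:
            return None
        match = np.zeros(L, dtype=bool)
        match[lo_clip:hi_clip] = (
            self.chrom_arr[g0 + lo_clip : g0 + hi_clip] == qarr[lo_clip:hi_clip]
        )
        # longest exact run as the anchor seed
        best_len = best_start = 0
        run = 0
        for j in range(L):
            if match[j]:
                run += 1
                if run > best_len:
                    best_len, best_start = run, j - run + 1
            else:
                run = 0
        if best_len < self.k:
            return None
        lo, hi = self._extend(match, best_start, best_start + best_len)
        # The junction-side edge must be deterministic across reads of one
        # junction: mismatch absorption may creep variably into repeat-like
        # clipped tails, so the edge on the (longer-)clipped side is refined
        # to the pure maximal exact run around the seed instead.
        left_res, right_res = lo, L - hi
        if left_res >= right_res and left_res > 0:
            lo = best_start
            while lo > 0 and match[lo - 1]:
                lo -= 1
        elif right_res > 0:
            hi = best_start + best_len
            while hi < L and match[hi]:
                hi += 1
        return lo, hi

    def align(self, read_id: str, seq: str) -> AnchoredRead | None:
        """Align one read; returns None when no adequate anchor exists."""
        best: tuple[int, int, int, str] | None = None  # (anchor_len, g0, lo, strand)
        best_interval: tuple[int, int] | None = None
        ambiguous = False
        for strand, q in (("+", seq), ("-", revcomp(seq))):
            L = len(q)
            votes: dict[int, int] = defaultdict(int)
            for off in range(0, L - self.k + 1, self.seed_stride):
                for pos in self._index.get(q[off : off + self.k], ()):
                    votes[pos - off] += 1
            if not votes:
                continue
            qarr = seq_to_array(q)
            top = sorted(votes, key=votes.get, reverse=True)[:4]
            for g0 in top:
                res = self._evaluate(qarr, g0)
                if res is None:
                    continue
                lo, hi = res
                alen = hi - lo
                if best is None or alen > best[0]:
                    best = (alen, g0, lo, strand)
                    best_interval = (lo, hi)
                    ambiguous = False
                elif alen == best[0] and (g0, strand) != (best[1], best[3]):
                    ambiguous = True
        if best is None or best[0] < self.min_anchor:
            return None
        alen, g0, lo, strand = best
        lo, hi = best_interval  # type: ignore[misc]
        q = seq if strand == "+" else revcomp(seq)
        left_len, right_len = lo, len(q) - hi
        # A genuine junction read's anchor reaches the read's far end (bar a
        # few error bases); anchors floating mid-read are coincidental
        # matches of repeat-like tails and are rejected outright.
        if min(left_len, right_len) > self.edge_slack:
            return None
        if left_len >= right_len and left_len > 0:
            clip_seq, clip_side = q[:lo], "left"
        elif right_len > 0:
            clip_seq, clip_side = q[hi:], "right"
        else:
            clip_seq, clip_side = "", "none"
        return AnchoredRead(
            read_id=read_id,
            chrom=self.region.chrom,
            anchor_start=g0 + lo,
            anchor_end=g0 + hi,
            strand=strand,
            clip_seq=clip_seq,
            clip_side=clip_side,
            mapq=0 if ambiguous else 60,
        )


class FullPlacementChecker:
    """Detects reads that place contiguously somewhere in the genome.

    A read with a clipped tail in the repair region but a full-length
    placement elsewhere is an ordinary read from a repeat-sharing locus,
    not a junction read; an external aligner would have mapped it away
    from the region.  Any placement within the mismatch budget contains a
    clean stretch of >= len/(budget+1) nt, far longer than the seed, so
    seeds at stride 8 surface every qualifying placement.
    """

    def __init__(
        self,
        genome: Genome,
        k: int = DEFAULT_SEED_SIZE,
        stride: int = 8,
        max_mismatch: int = 2,
    ):
        self.index = KmerIndex(genome, k)
        self.stride = stride
        self.max_mismatch = max_mismatch

    def has_full_placement(self, seq: str) -> bool:
        k = self.index.k
        L = len(seq)
        if L < k:
            return False
        # a genuine non-junction read places with ~0 mismatches (sequencing
        # errors only); a tight budget avoids absorbing short-clip junction
        # reads whose telomeric tails resemble telomere-like reference
        budget = self.max_mismatch
        for strand_seq in (seq, revcomp(seq)):
            qarr = seq_to_array(strand_seq)
            tried: set[tuple[str, int]] = set()
            offsets = list(range(0, L - k + 1, self.stride))
            if offsets[-1] != L - k:
                offsets.append(L - k)
            for off in offsets:
                for chrom, pos in self.index.positions(strand_seq[off : off + k]):
                    start = pos - off
                    arr = self.index.arrays[chrom]
                    if start < 0 or start + L > len(arr) or (chrom, start) in tried:
                        continue
                    tried.add((chrom, start))
                    if int((arr[start : start + L] != qarr).sum()) <= budget:
                        return True
        return False


def align_reads(
    reads: Iterable[tuple[str, str]],
    genome: Genome,
    region: RepairRegion,
    filter_full_placements: bool = True,
    **kwargs,
) -> list[AnchoredRead]:
    """Align (read_id, sequence) pairs to the repair region.

    Clipped reads that also place full-length anywhere in the genome are
    discarded (see :class:`FullPlacementChecker`).
    """
    aligner = RegionAligner(genome, region, **kwargs)
    checker = FullPlacementChecker(genome) if filter_full_placements else None
    out = []
    for read_id, seq in reads:
        a = aligner.align(read_id, seq)
        if a is None:
            continue
        if (
            checker is not None
            and a.has_clip
            and len(a.clip_seq) >= 4
            and checker.has_full_placement(seq)
        ):
            continue
        out.append(a)
    return out


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Minimal FASTQ reader returning (read_id, sequence) pairs."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTQ file not found: {path}")
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise DataError(f"malformed FASTQ record in {path}")
            out.append((header[1:].split()[0], seq.upper()))
    return out


def write_sam(
    reads: Iterable[AnchoredRead], genome: Genome, path: str | Path
) -> None:
    """Serialise anchored reads as plain-text SAM (sequence fields hold the
    reference-orientation read: anchor plus clip)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in genome:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{genome.length(chrom)}\n")
        for r in reads:
            anchor = genome[r.chrom][r.anchor_start : r.anchor_end]
            alen = r.anchor_end - r.anchor_start
            if r.clip_side == "left":
                cigar = f"{len(r.clip_seq)}S{alen}M"
                seq = r.clip_seq + anchor
            elif r.clip_side == "right":
                cigar = f"{alen}M{len(r.clip_seq)}S"
                seq = anchor + r.clip_seq
            else:
                cigar = f"{alen}M"
                seq = anchor
            flag = 16 if r.strand == "-" else 0
            fh.write(
                f"{r.read_id}\t{flag}\t{r.chrom}\t{r.anchor_start + 1}\t"
                f"{r.mapq}\t{cigar}\t*\t0\t0\t{seq}\t{'I' * len(seq)}\n"
            )


# ---------------------------------------------------------------------------
# Intermediate split-read table

SPLITREAD_COLUMNS = [
    "read_id",
    "chrom",
    "anchor_start",
    "anchor_end",
    "strand",
    "clip_side",
    "clip_seq",
    "mapq",
    "breakpoint_1based",
]


def write_splitread_table(
    reads: Iterable[AnchoredRead],
    region: RepairRegion,
    path: str | Path,
    header_comment: str = "",
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(SPLITREAD_COLUMNS) + "\n")
        for r in reads:
            bp = breakpoint_coordinate(r, region) if r.has_clip else None
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        r.chrom,
                        str(r.anchor_start),
                        str(r.anchor_end),
                        r.strand,
                        r.clip_side,
                        r.clip_seq,
                        str(r.mapq),
                        str(bp.coordinate_1based) if bp else "",
                    ]
                )
                + "\n"
            )


def read_splitread_table(path: str | Path) -> list[AnchoredRead]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"split-read table not found: {path}")
    reads = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            reads.append(
                AnchoredRead(
                    read_id=row["read_id"],
                    chrom=row["chrom"],
                    anchor_start=int(row["anchor_start"]),
                    anchor_end=int(row["anchor_end"]),
                    strand=row["strand"],
                    clip_seq=row.get("clip_seq", ""),
                    clip_side=row.get("clip_side", "none"),
                    mapq=int(row.get("mapq", 60)),
                )
            )
    return reads
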