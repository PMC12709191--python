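"""Filtering, read-support modelling, and frequency quantification.

The published quantity is read-weighted: the frequency of split reads
at a location and/or of a given type is the number of split reads
meeting those criteria divided by the total number of split reads
mapping to the repair region.  An event-weighted table (each collapsed
event counted once) is also produced.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from gcrmap.classify import GCREvent
from gcrmap.errors import DataError
from gcrmap.genome_model import AnnotationSet, Feature, RepairRegion

EVENT_TYPE_COLUMNS = ["telomere_addition", "deletion", "translocation", "unclassified"]

SINGLETON_THRESHOLD = 200


@dataclass
class PlateCounts:
    """Colony counts from the inducible-cleavage plating assay."""

    galr_colonies: int
    cells_plated_gal: int
    galr_assayed: int
    foar_colonies: int

    def __post_init__(self):
        for name in ("galr_colonies", "cells_plated_gal", "galr_assayed", "foar_colonies"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.foar_colonies > self.galr_assayed:
            raise DataError("foar_colonies cannot exceed galr_assayed")


def gcr_frequency(counts: PlateCounts) -> float:
    """Overall rearrangement frequency: the frequency of galactose-resistant
    colonies times the fraction of those that survive 5-FOA selection."""
    if counts.galr_assayed == 0:
        raise DataError("galr_assayed is zero; frequency undefined")
    if counts.cells_plated_gal == 0:
        raise DataError("cells_plated_gal is zero; frequency undefined")
    return (counts.galr_colonies / counts.cells_plated_gal) * (
        counts.foar_colonies / counts.galr_assayed
    )


def load_plate_counts(path: str | Path) -> PlateCounts:
    """Read plate counts from a 4-field key-value text file."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"plate-count file not found: {path}")
    values: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.replace("=", "\t").partition("\t")
            values[key.strip()] = int(val.strip())
    try:
        return PlateCounts(**values)
    except TypeError as exc:
        raise DataError(f"plate-count file {path} malformed: {exc}") from None


# ---------------------------------------------------------------------------
# Event collapsing and the singleton filter


def collapse_events(
    read_events: list[GCREvent], merge_distance: int = 2
) -> list[GCREvent]:
    """Collapse per-read calls into events keyed by (breakpoint,
    event_type, target), merging breakpoints within ``merge_distance``
    of one another to absorb alignment jitter near junctions."""
    def group_key(ev: GCREvent):
        tk = ev.target_key or ("", -1, "")
        return (ev.event_type, ev.translocation_class, tk[0], tk[2])

    buckets: dict[tuple, list[GCREvent]] = {}
    for ev in read_events:
        buckets.setdefault(group_key(ev), []).append(ev)

    collapsed: list[GCREvent] = []
    for _, evs in sorted(buckets.items()):
        evs.sort(
            key=lambda e: (
                e.breakpoint.retained_boundary,
                (e.target_key or ("", -1, ""))[1],
            )
        )
        current: list[GCREvent] = []
        for ev in evs:
            if current:
                prev = current[-1]
                close = (
                    abs(
                        ev.breakpoint.retained_boundary
                        - prev.breakpoint.retained_boundary
                    )
                    <= merge_distance
                )
                tprev = (prev.target_key or ("", -1, ""))[1]
                tcur = (ev.target_key or ("", -1, ""))[1]
                close = close and abs(tcur - tprev) <= merge_distance
                if close:
                    current.append(ev)
                    continue
            if current:
                collapsed.append(_merge(current))
            current = [ev]
        if current:
            collapsed.append(_merge(current))
    collapsed.sort(
        key=lambda e: (e.breakpoint.retained_boundary, e.event_type)
    )
    return collapsed


def _merge(group: list[GCREvent]) -> GCREvent:
    # modal boundary (by read support) wins; the longest clip within the
    # modal sub-group is kept as the representative junction sequence
    votes: dict[int, int] = {}
    for e in group:
        b = e.breakpoint.retained_boundary
        votes[b] = votes.get(b, 0) + e.support
    modal = max(votes, key=lambda b: (votes[b], -b))
    modal_group = [e for e in group if e.breakpoint.retained_boundary == modal]
    rep = max(modal_group, key=lambda e: (len(e.clip_seq), e.breakpoint.retained_boundary))
    flags = tuple(sorted({f for e in group for f in e.flags}))
    read_ids = [rid for e in group for rid in e.read_ids]
    return GCREvent(
        breakpoint=rep.breakpoint,
        event_type=rep.event_type,
        translocation_class=rep.translocation_class,
        target_hits=rep.target_hits,
        support=sum(e.support for e in group),
        microhomology=rep.microhomology,
        flags=flags,
        clip_seq=rep.clip_seq,
        read_ids=read_ids,
    )


@dataclass
class FilterLog:
    total_split_reads: int
    threshold: int
    applied: bool
    n_removed: int
    removed_support: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def singleton_filter(
    events: list[GCREvent],
    total_split_reads: int,
    threshold: int = SINGLETON_THRESHOLD,
) -> tuple[list[GCREvent], list[GCREvent], FilterLog]:
    """Remove single-read events only when the experiment yielded more
    than ``threshold`` split reads (strictly greater); below that, single
    reads are retained to avoid discarding true events."""
    apply_filter = total_split_reads > threshold
    if apply_filter:
        retained = [e for e in events if e.support > 1]
        removed = [e for e in events if e.support == 1]
    else:
        retained, removed = list(events), []
    log = FilterLog(
        total_split_reads=total_split_reads,
        threshold=threshold,
        applied=apply_filter,
        n_removed=len(removed),
        removed_support=sum(e.support for e in removed),
    )
    return retained, removed, log


@dataclass
class PoissonSummary:
    lam: float
    pmf: list[float]
    expected_singletons: float

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "pmf": self.pmf,
            "expected_singletons": self.expected_singletons,
        }


def poisson_read_model(
    total_split_reads: int, n_events: int = 30, k_max: int | None = None
) -> PoissonSummary:
    """Poisson prediction of reads per rearrangement event: with
    lambda = total/n, the expected number of events seen exactly once is
    n * lambda * exp(-lambda); used as a diagnostic alongside the
    singleton filter.  ``k_max`` defaults to a range wide enough for the
    pmf to account for all but ~1e-9 of the mass."""
    if n_events < 1:
        raise DataError("n_events must be >= 1")
    lam = total_split_reads / n_events
    if k_max is None:
        k_max = max(50, int(math.ceil(lam + 12 * math.sqrt(lam) + 10)))
    pmf = [float(p) for p in stats.poisson.pmf(np.arange(k_max + 1), lam)]
    expected_singletons = n_events * lam * math.exp(-lam)
    return PoissonSummary(lam=lam, pmf=pmf, expected_singletons=expected_singletons)


# ---------------------------------------------------------------------------
# Frequency tables


def _event_location(ev: GCREvent) -> int:
    # events are mapped by their repair-region coordinate
    return ev.breakpoint.retained_boundary


def _type_counts(
    events: list[GCREvent], lo: int, hi: int, weight: str
) -> dict[str, float]:
    out = {t: 0.0 for t in EVENT_TYPE_COLUMNS}
    for ev in events:
        pos = _event_location(ev)
        if lo <= pos < hi:
            out[ev.event_type] += ev.support if weight == "read" else 1
    return out


def event_frequencies(
    events: list[GCREvent],
    total_split_reads: int,
    region: RepairRegion,
    annotations: AnnotationSet,
    bin_sizes: tuple[int, ...] = (1000, 100),
    weighting: str = "read",
) -> dict[str, pd.DataFrame]:
    """Frequency tables at feature and fixed-bin resolution.

    Each cell is 100 x (split reads meeting the criteria) / (total split
    reads in the repair region); with ``weighting="event"`` each
    collapsed event counts once and the denominator is the event count.
    """
    if weighting not in {"read", "event"}:
        raise DataError("weighting must be 'read' or 'event'")
    denom = total_split_reads if weighting == "read" else max(len(events), 1)
    if denom == 0:
        denom = 1
    tables: dict[str, pd.DataFrame] = {}

    rows = []
    for f in sorted(annotations):
        if f.chrom != region.chrom or not f.overlaps(region.start, region.end):
            continue
        counts = _type_counts(events, f.start, f.end, weighting)
        rows.append(
            {
                "kind": f.kind,
                "label": f.label,
                "start_1based": f.start + 1,
                "end_1based": f.end,
                **{t: 100.0 * c / denom for t, c in counts.items()},
                "total": 100.0 * sum(counts.values()) / denom,
            }
        )
    tables["feature"] = pd.DataFrame(
        rows,
        columns=["kind", "label", "start_1based", "end_1based"]
        + EVENT_TYPE_COLUMNS
        + ["total"],
    )

    for size in bin_sizes:
        if size > region.length:
            raise DataError(
                f"bin size {size} exceeds repair region length {region.length}"
            )
        rows = []
        for lo in range(region.start, region.end, size):
            hi = min(lo + size, region.end)
            counts = _type_counts(events, lo, hi, weighting)
            rows.append(
                {
                    "start_1based": lo + 1,
                    "end_1based": hi,
                    **{t: 100.0 * c / denom for t, c in counts.items()},
                    "total": 100.0 * sum(counts.values()) / denom,
                }
            )
        tables[f"bin_{size}"] = pd.DataFrame(
            rows, columns=["start_1based", "end_1based"] + EVENT_TYPE_COLUMNS + ["total"]
        )
    return tables


def per_nucleotide_map(
    events: list[GCREvent],
    total_split_reads: int,
    feature: Feature,
    region: RepairRegion,
) -> pd.DataFrame:
    """Per-base event-type fractions across a feature.

    Rows are emitted in 3'->5' orientation of the TG-rich strand with
    the centromere to the right: for a left-arm region that is simply
    ascending reference coordinate.
    """
    if not feature.overlaps(region.start, region.end, region.chrom):
        raise DataError("feature does not overlap the repair region")
    denom = total_split_reads or 1
    rows = []
    positions = range(feature.start, feature.end)
    if region.orientation == "right":
        positions = reversed(positions)
    for pos in positions:
        counts = {t: 0.0 for t in EVENT_TYPE_COLUMNS}
        for ev in events:
            if _event_location(ev) == pos:
                counts[ev.event_type] += ev.support
        rows.append(
            {
                "position_1based": pos + 1,
                **{t: 100.0 * c / denom for t, c in counts.items()},
                "total": 100.0 * sum(counts.values()) / denom,
            }
        )
    return pd.DataFrame(
        rows, columns=["position_1based"] + EVENT_TYPE_COLUMNS + ["total"]
    )


def write_bedgraph(
    nt_map: pd.DataFrame,
    chrom: str,
    path: str | Path,
    column: str = "total",
) -> None:
    """Write a per-nucleotide table as a bedGraph-style 4-column track."""
    with open(path, "w") as fh:
        for _, row in nt_map.iterrows():
            start = int(row["position_1based"]) - 1
            fh.write(f"{chrom}\t{start}\t{start + 1}\t{row[column]:.6g}\n")


FUNCTIONAL_THRESHOLD_PERCENT = 6.6


def sirta_call(feature_fraction_dnta: float) -> str:
    """Call a hotspot functional when its telomere-addition fraction of
    total split reads meets the 6.6% threshold (inclusive)."""
    return (
        "functional"
        if feature_fraction_dnta >= FUNCTIONAL_THRESHOLD_PERCENT
        else "non_functional"
    )


# ---------------------------------------------------------------------------
# Pool report


@dataclass
class PoolReport:
    """Quantified summary of one pool."""

    total_split_reads: int
    events: list[GCREvent]
    removed: list[GCREvent]
    frequencies: dict[str, pd.DataFrame]
    event_weighted: dict[str, pd.DataFrame]
    filter_log: FilterLog
    poisson: PoissonSummary
    sirta_calls: dict[str, str] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "total_split_reads": self.total_split_reads,
            "n_events_retained": len(self.events),
            "n_events_removed": len(self.removed),
            "filter_log": self.filter_log.to_dict(),
            "poisson": self.poisson.to_dict(),
            "sirta_calls": self.sirta_calls,
        }


def build_report(
    read_events: list[GCREvent],
    region: RepairRegion,
    annotations: AnnotationSet,
    bin_sizes: tuple[int, ...] = (1000, 100),
    merge_distance: int = 2,
    singleton_threshold: int = SINGLETON_THRESHOLD,
    n_clones: int = 30,
) -> PoolReport:
    """Collapse, filter, and quantify per-read calls into a pool report."""
    total = sum(e.support for e in read_events)
    collapsed = collapse_events(read_events, merge_distance)
    retained, removed, log = singleton_filter(collapsed, total, singleton_threshold)
    freqs = event_frequencies(retained, total, region, annotations, bin_sizes, "read")
    event_weighted = event_frequencies(
        retained, total, region, annotations, bin_sizes, "event"
    )
    poisson = poisson_read_model(total, n_clones)
    calls: dict[str, str] = {}
    feat = freqs["feature"]
    for _, row in feat[feat["kind"] == "SiRTA"].iterrows():
        calls[row["label"] or f"{row['start_1based']}-{row['end_1based']}"] = sirta_call(
            row["telomere_addition"]
        )
    return PoolReport(
        total_split_reads=total,
        events=retained,
        removed=removed,
        frequencies=freqs,
        event_weighted=event_weighted,
        filter_log=log,
        poisson=poisson,
        sirta_calls=calls,
    )


# ---------------------------------------------------------------------------
# Event table serialisation

EVENT_COLUMNS = [
    "chrom",
    "breakpoint_1based",
    "clip_side",
    "event_type",
    "translocation_class",
    "target_chrom",
    "target_coord_1based",
    "target_strand",
    "n_equivalent",
    "support",
    "mh_span",
    "mh_identity",
    "flags",
    "clip_seq",
]


def write_event_table(
    events: list[GCREvent], path: str | Path, header_comment: str = ""
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for ev in events:
            hit = ev.best_hit
            fh.write(
                "\t".join(
                    [
                        ev.breakpoint.chrom,
                        str(ev.breakpoint.coordinate_1based),
                        ev.breakpoint.side,
                        ev.event_type,
                        ev.translocation_class,
                        hit.chrom if hit else "",
                        str(hit.junction_coord() + 1) if hit else "",
                        hit.strand if hit else "",
                        str(hit.n_equivalent) if hit else "",
                        str(ev.support),
                        str(ev.microhomology.span) if ev.microhomology else "",
                        f"{ev.microhomology.identity:.3f}" if ev.microhomology else "",
                        ",".join(ev.flags),
                        ev.clip_seq,
                    ]
                )
                + "\n"
            )


def read_event_table(path: str | Path) -> list[GCREvent]:
    """Re-load a classified-event table (possibly hand-edited)."""
    from gcrmap.splitread import Breakpoint, TargetHit

    path = Path(path)
    if not path.exists():
        raise DataError(f"event table not found: {path}")
    events: list[GCREvent] = []
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
            bp = Breakpoint(
                chrom=row["chrom"],
                coordinate=int(row["breakpoint_1based"]) - 1,
                side=row.get("clip_side", "left"),
            )
            hits = []
            if row.get("target_chrom"):
                coord = int(row["target_coord_1based"]) - 1
                strand = row.get("target_strand", "+")
                # reconstruct a 1 nt hit whose junction_coord round-trips
                if strand == "+":
                    start, end = coord, coord + 1
                else:
                    start, end = max(coord - 1, 0), coord
                hits = [
                    TargetHit(
                        chrom=row["target_chrom"],
                        start=start,
                        end=end,
                        strand=strand,
                        mismatches=0,
                        n_equivalent=int(row.get("n_equivalent") or 1),
                    )
                ]
            events.append(
                GCREvent(
                    breakpoint=bp,
                    event_type=row["event_type"],
                    translocation_class=row.get("translocation_class", "not_applicable"),
                    target_hits=hits,
                    support=int(row.get("support") or 1),
                    flags=tuple(f for f in row.get("flags", "").split(",") if f),
                    clip_seq=row.get("clip_seq", ""),
                )
            )
    return events
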