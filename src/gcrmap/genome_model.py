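"""Reference sequences, feature annotations, and repair-region geometry.

Coordinate conventions are fixed package-wide here: 0-based, half-open
intervals internally; user-facing tables convert to 1-based inclusive
at the reporting layer and nowhere else.  Every downstream module
receives coordinates through these types; no other module re-derives
region boundaries.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from gcrmap._util import DNA_ALPHABET
from gcrmap.errors import ConfigurationError, DataError

FEATURE_KINDS = frozenset(
    {
        "HO_cut_site",
        "URA3_marker",
        "SiRTA",
        "SiRTA_stim",
        "SiRTA_core",
        "X_element",
        "Yprime_element",
        "ITS",
        "essential_gene",
        "telomere",
    }
)

#: Annotation kinds treated as repetitive when judging placement uniqueness.
REPEAT_KINDS = frozenset({"X_element", "Yprime_element", "ITS", "telomere"})


class Genome:
    """Named uppercase DNA sequences over the alphabet A, C, G, T, N."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise DataError("genome has no sequences")
        clean: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise DataError(f"sequence {name!r} is empty")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise DataError(
                    f"sequence {name!r} contains characters outside "
                    f"A/C/G/T/N: {sorted(bad)}"
                )
            clean[name] = seq
        self.sequences = clean

    def __getitem__(self, chrom: str) -> str:
        try:
            return self.sequences[chrom]
        except KeyError:
            raise DataError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def names(self) -> list[str]:
        return list(self.sequences)

    def write(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True, order=True)
class Feature:
    """A typed genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    kind: str
    strand: str = "+"
    label: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise DataError(
                f"unknown feature kind {self.kind!r}; valid kinds: "
                f"{', '.join(sorted(FEATURE_KINDS))}"
            )
        if not (0 <= self.start < self.end):
            raise DataError(
                f"invalid interval [{self.start}, {self.end}) for "
                f"{self.kind} on {self.chrom}"
            )
        if self.strand not in {"+", "-"}:
            raise DataError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int, chrom: str | None = None) -> bool:
        if chrom is not None and chrom != self.chrom:
            return False
        return self.start < end and start < self.end

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class AnnotationSet:
    """A validated collection of :class:`Feature` objects."""

    def __init__(self, features: Iterable[Feature] = ()):
        self.features: list[Feature] = list(features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationSet) and self.features == other.features

    def add(self, feature: Feature) -> None:
        self.features.append(feature)

    def by_kind(self, kind: str, chrom: str | None = None) -> list[Feature]:
        return [
            f
            for f in self.features
            if f.kind == kind and (chrom is None or f.chrom == chrom)
        ]

    def one(self, kind: str, chrom: str | None = None) -> Feature:
        hits = self.by_kind(kind, chrom)
        where = f" on {chrom}" if chrom else ""
        if not hits:
            raise ConfigurationError(f"no {kind} feature{where}")
        if len(hits) > 1:
            raise ConfigurationError(f"expected one {kind} feature{where}, found {len(hits)}")
        return hits[0]

    def overlapping(
        self, chrom: str, start: int, end: int, kinds: Iterable[str] | None = None
    ) -> list[Feature]:
        kindset = frozenset(kinds) if kinds is not None else None
        return [
            f
            for f in self.features
            if f.overlaps(start, end, chrom)
            and (kindset is None or f.kind in kindset)
        ]

    def at(self, chrom: str, pos: int, kinds: Iterable[str] | None = None) -> list[Feature]:
        return self.overlapping(chrom, pos, pos + 1, kinds)

    def write(self, path: str | Path) -> None:
        """Write a 6-column BED-like table (kind in column 4)."""
        with open(path, "w") as fh:
            for f in self.features:
                fh.write(
                    f"{f.chrom}\t{f.start}\t{f.end}\t{f.kind}\t{f.strand}\t{f.label}\n"
                )


@dataclass(frozen=True)
class RepairRegion:
    """The assay interval from the cut-site integration point to the most
    distal essential gene.

    ``orientation`` records which end is telomere-proximal: ``"left"``
    means the telomere lies at low coordinates (the default; mirrors a
    left chromosome arm), ``"right"`` the opposite.
    """

    chrom: str
    start: int
    end: int
    orientation: str = "left"

    def __post_init__(self):
        if self.start >= self.end:
            raise ConfigurationError(
                f"repair region start {self.start} >= end {self.end}"
            )
        if self.orientation not in {"left", "right"}:
            raise ConfigurationError(f"invalid orientation {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    @property
    def telomere_side(self) -> str:
        """Clip side (in reference orientation) that points away from the
        retained, centromere-containing segment."""
        return "left" if self.orientation == "left" else "right"

    def is_telomere_proximal(self, pos: int, anchor: int) -> bool:
        """True if ``pos`` lies telomere-proximal to ``anchor``."""
        if self.orientation == "left":
            return pos < anchor
        return pos > anchor


def load_reference(path: str | Path) -> Genome:
    """Load a (multi-)FASTA reference into a :class:`Genome`.

    Sequences are uppercased; characters outside A/C/G/T/N are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"reference file not found: {path}")
    sequences: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in sequences:
                raise DataError(f"duplicate FASTA record {rec.id!r}")
            sequences[rec.id] = str(rec.seq).upper()
    except DataError:
        raise
    except Exception as exc:  # malformed FASTA
        raise DataError(f"could not parse FASTA {path}: {exc}") from exc
    if not sequences:
        raise DataError(f"no FASTA records found in {path}")
    for name, seq in sequences.items():
        if not seq:
            raise DataError(f"FASTA record {name!r} has an empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise DataError(
                f"FASTA record {name!r} contains invalid characters: {sorted(bad)}"
            )
    return Genome(sequences)


def load_annotations(path: str | Path, genome: Genome) -> AnnotationSet:
    """Load a 4-6 column tab-separated BED-like annotation file.

    Columns: chrom, start, end, kind[, strand, label].  Coordinates are
    validated against ``genome`` bounds; unknown kinds are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation file not found: {path}")
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise DataError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns"
                )
            chrom, start_s, end_s, kind = cols[:4]
            strand = cols[4] if len(cols) > 4 and cols[4] else "+"
            label = cols[5] if len(cols) > 5 else ""
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from None
            if chrom not in genome:
                raise DataError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= genome.length(chrom)):
                raise DataError(
                    f"{path}:{lineno}: interval [{start}, {end}) out of bounds "
                    f"for {chrom} (length {genome.length(chrom)})"
                )
            try:
                features.append(
                    Feature(chrom, start, end, kind, strand, label)
                )
            except DataError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from None
    return AnnotationSet(features)


def repair_region_span(
    annotations: AnnotationSet, chrom: str, orientation: str = "left"
) -> RepairRegion:
    """Derive the repair region for ``chrom`` from its annotations.

    The region runs from the telomere-proximal boundary of the (single)
    HO_cut_site feature to the far boundary of the most distal
    essential_gene feature.
    """
    hocs = annotations.one("HO_cut_site", chrom)
    genes = annotations.by_kind("essential_gene", chrom)
    if not genes:
        raise ConfigurationError(f"no essential_gene feature on {chrom}")
    if orientation == "left":
        # Most distal essential gene = lowest coordinates above the cut site.
        distal = min(genes, key=lambda f: f.start)
        return RepairRegion(chrom, hocs.start, distal.end, "left")
    distal = max(genes, key=lambda f: f.end)
    return RepairRegion(chrom, distal.start, hocs.end, "right")


def region_fraction(feature: Feature, region: RepairRegion) -> float:
    """Percent of the repair region's base pairs covered by ``feature``."""
    if feature.chrom != region.chrom:
        raise DataError(
            f"feature on {feature.chrom} does not overlap region on {region.chrom}"
        )
    overlap = min(feature.end, region.end) - max(feature.start, region.start)
    if overlap <= 0:
        raise DataError(
            f"feature [{feature.start}, {feature.end}) does not overlap "
            f"region [{region.start}, {region.end})"
        )
    return 100.0 * overlap / region.length


def to_report_interval(start: int, end: int) -> tuple[int, int]:
    """Convert an internal half-open interval to 1-based inclusive."""
    return start + 1, end


def feature_to_row(feature: Feature) -> dict:
    row = dataclasses.asdict(feature)
    row["start_1based"], row["end_1based"] = to_report_interval(
        feature.start, feature.end
    )
    return row
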