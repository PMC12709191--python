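"""Seeded simulator of pooled rearranged clones over a toy genome.

The toy genome mirrors the repeat architecture the analysis assumes: a
"repair" chromosome carrying (telomere -> centromere) a terminal
telomeric tract, unique sequence, a URA3 marker, an HO cut site, a
bipartite TG-rich hotspot (Core + Stim, CA-rich on the top strand of a
left arm), and a distal essential gene; plus donor chromosomes whose
subtelomeres carry Y' elements (mutated copies of one master), ITS
tracts of 80-150 nt, an ATATATAT motif adjacent to a configurable
fraction of Y' copies, and an X element.

Each simulated pool holds 30 clones (by default), one rearrangement
per clone, and reads are drawn uniformly at equal per-clone depth with
substitution-only errors.  All outputs are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from gcrmap._util import mutate, random_dna, revcomp
from gcrmap.errors import ConfigurationError, DataError
from gcrmap.genome_model import (
    AnnotationSet,
    Feature,
    Genome,
    repair_region_span,
)

EVENT_TYPES = (
    "telomere_addition",
    "deletion",
    "translocation_A",
    "translocation_B",
    "translocation_C",
    "hocs_indel",
)

ATAT_MOTIF = "ATATATAT"

#: canonical 24-nt HO endonuclease recognition cassette used in the toy genome
HOCS_SEQ = "TTTCAGCTTTCCGCAACAGTATAA"

#: (event_type, translocation_class) expected from the pipeline per truth type
PIPELINE_LABELS = {
    "telomere_addition": ("telomere_addition", "not_applicable"),
    "deletion": ("deletion", "not_applicable"),
    "translocation_A": ("translocation", "A"),
    "translocation_B": ("translocation", "B"),
    "translocation_C": ("translocation", "C"),
    "hocs_indel": ("unclassified", "not_applicable"),
}


@dataclass
class ToyGenomeConfig:
    n_chromosomes: int = 4  # one repair chromosome + donors
    chrom_length: int = 16000
    repair_chrom: str = "chrR"
    n_yprime: int = 4  # total Y' copies across donors
    yprime_identity: float = 0.96
    yprime_length: int = 900
    its_lengths: tuple[int, int] = (80, 150)
    atat_motif_fraction: float = 0.5
    telomere_length: int = 250
    x_element_length: int = 500
    ura3_length: int = 700
    sirta_offset: int = 2500  # distance from HOcs end to the hotspot
    sirta_span: int = 300
    core_length: int = 100
    stim_length: int = 52
    essential_gene_length: int = 1200
    microhomology_length: int = 25
    microhomology_mismatches: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0.9 <= self.yprime_identity <= 1.0):
            raise ConfigurationError("yprime_identity must be in [0.9, 1.0]")
        if not (0.0 <= self.atat_motif_fraction <= 1.0):
            raise ConfigurationError("atat_motif_fraction must be in [0, 1]")
        if self.n_chromosomes < 2:
            raise ConfigurationError("need at least one donor chromosome")
        lo, hi = self.its_lengths
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid its_lengths range")


@dataclass(frozen=True)
class EventSpec:
    """Ground truth for one clone's rearrangement."""

    clone_id: str
    event_type: str
    breakpoint: int  # first retained base on the repair chromosome
    target: tuple[str, int, str] | None = None  # (chrom, coord, strand)
    tract: str = ""  # synthesized G-strand TG tract for telomere additions

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise DataError(f"unknown event type {self.event_type!r}")
        needs_target = self.event_type in {
            "deletion",
            "translocation_A",
            "translocation_B",
            "translocation_C",
        }
        if needs_target and self.target is None:
            raise DataError(f"{self.event_type} requires a target")
        if not needs_target and self.target is not None:
            raise DataError(f"{self.event_type} must not carry a target")


@dataclass
class PoolTruth:
    """Simulator ground truth for one pool of clones."""

    events: list[EventSpec]
    config: ToyGenomeConfig
    seed: int

    def __post_init__(self):
        ids = [e.clone_id for e in self.events]
        if len(set(ids)) != len(ids):
            raise DataError("clone_ids must be unique")

    def mixture(self) -> dict[str, float]:
        n = len(self.events)
        out: dict[str, float] = {}
        for e in self.events:
            out[e.event_type] = out.get(e.event_type, 0.0) + 1.0 / n
        return out

    def write(self, path: str | Path, genome: Genome | None = None) -> None:
        """Tab-separated truth table; with a genome, adds the
        alignment-canonical breakpoint (see :func:`canonical_breakpoint`)."""
        with open(path, "w") as fh:
            cols = [
                "clone_id",
                "event_type",
                "breakpoint",
                "canonical_breakpoint",
                "target_chrom",
                "target_coord",
                "target_strand",
                "tract_len",
            ]
            fh.write("\t".join(cols) + "\n")
            for e in self.events:
                canon = (
                    canonical_breakpoint(genome, e, self.config)
                    if genome is not None
                    else ""
                )
                tchrom, tcoord, tstrand = e.target or ("", "", "")
                fh.write(
                    "\t".join(
                        [
                            e.clone_id,
                            e.event_type,
                            str(e.breakpoint),
                            str(canon),
                            str(tchrom),
                            str(tcoord),
                            str(tstrand),
                            str(len(e.tract)),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# TG tract synthesis


def make_tg_tract(length: int, seed: int | np.random.Generator) -> str:
    """Synthesize an irregular telomeric G-strand tract of exactly
    ``length`` nt: an optional leading run of up to three Gs, then
    repeated T·G^k units with k drawn uniformly from {1, 2, 3}."""
    if length < 1:
        raise DataError("tract length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = ["G" * int(rng.integers(0, 4))]
    total = len(parts[0])
    while total < length:
        unit = "T" + "G" * int(rng.integers(1, 4))
        parts.append(unit)
        total += len(unit)
    return "".join(parts)[:length]


def _ca_tract(rng: np.random.Generator, length: int) -> str:
    """Top-strand (C-rich) telomeric tract for left-arm telomeres/ITSs."""
    return revcomp(make_tg_tract(length, rng))


# ---------------------------------------------------------------------------
# Toy genome construction


@dataclass
class _Layout:
    """Derived coordinates of the toy repair chromosome."""

    ura3: tuple[int, int]
    hocs: tuple[int, int]
    sirta: tuple[int, int]
    core: tuple[int, int]
    stim: tuple[int, int]
    essential: tuple[int, int]


def _repair_layout(cfg: ToyGenomeConfig) -> _Layout:
    L = cfg.chrom_length
    tel = cfg.telomere_length
    ura3_start = tel + 800
    ura3 = (ura3_start, ura3_start + cfg.ura3_length)
    hocs = (ura3[1] + 150, ura3[1] + 150 + len(HOCS_SEQ))
    sirta_start = hocs[1] + cfg.sirta_offset
    sirta = (sirta_start, sirta_start + cfg.sirta_span)
    core = (sirta_start + 40, sirta_start + 40 + cfg.core_length)
    stim_start = sirta[1] - cfg.stim_length - 20
    stim = (stim_start, stim_start + cfg.stim_length)
    essential = (L - cfg.essential_gene_length - 800, L - 800)
    if sirta[1] + 500 > essential[0]:
        raise ConfigurationError(
            "chrom_length too small to fit marker, cut site, hotspot, and "
            "essential gene"
        )
    return _Layout(ura3, hocs, sirta, core, stim, essential)


def class_a_breakpoint_offsets(cfg: ToyGenomeConfig) -> list[int]:
    """Fixed offsets into the SiRTA core used for microhomology-mediated
    (class A) junctions; shared by the builder and the event sampler."""
    return [10, 10 + cfg.microhomology_length + 10]


def build_toy_genome(config: ToyGenomeConfig) -> tuple[Genome, AnnotationSet]:
    """Deterministically build the toy genome and its annotations."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lay = _repair_layout(cfg)
    L = cfg.chrom_length

    # --- repair chromosome (left arm: telomere at coordinate 0)
    seq = list(random_dna(rng, L))

    def paste(start: int, s: str) -> None:
        seq[start : start + len(s)] = list(s)

    paste(0, _ca_tract(rng, cfg.telomere_length))
    paste(lay.hocs[0], HOCS_SEQ)
    # hotspot: CA-rich on the top strand (TG-rich on the resected strand);
    # Core sits telomere-proximal to Stim
    paste(lay.core[0], _ca_tract(rng, cfg.core_length))
    paste(lay.stim[0], _ca_tract(rng, cfg.stim_length))

    features = [
        Feature(cfg.repair_chrom, 0, cfg.telomere_length, "telomere", "+", "tel_left"),
        Feature(cfg.repair_chrom, *lay.ura3, "URA3_marker", "+", "URA3"),
        Feature(cfg.repair_chrom, *lay.hocs, "HO_cut_site", "+", "HOcs"),
        Feature(cfg.repair_chrom, *lay.sirta, "SiRTA", "+", "hotspot"),
        Feature(cfg.repair_chrom, *lay.core, "SiRTA_core", "+", "core"),
        Feature(cfg.repair_chrom, *lay.stim, "SiRTA_stim", "+", "stim"),
        Feature(cfg.repair_chrom, *lay.essential, "essential_gene", "+", "ESS1"),
    ]

    # --- donors: telomere, [Y' (motif?) ITS]*, X element, unique filler
    n_donors = cfg.n_chromosomes - 1
    per_donor = [cfg.n_yprime // n_donors] * n_donors
    for i in range(cfg.n_yprime % n_donors):
        per_donor[i] += 1
    yprime_master = random_dna(rng, cfg.yprime_length)
    x_master = random_dna(rng, cfg.x_element_length)
    n_subs = round((1.0 - cfg.yprime_identity) * cfg.yprime_length)
    # deterministic motif assignment honouring the configured fraction
    n_motif = round(cfg.atat_motif_fraction * cfg.n_yprime)
    motif_flags = [i < n_motif for i in range(cfg.n_yprime)]
    rng.shuffle(motif_flags)

    sequences = {cfg.repair_chrom: "".join(seq)}
    yp_index = 0
    for d in range(n_donors):
        name = f"chrD{d + 1}"
        parts: list[str] = [_ca_tract(rng, cfg.telomere_length)]
        pos = cfg.telomere_length
        for _ in range(per_donor[d]):
            yp = mutate(yprime_master, rng, n_subs)
            features.append(
                Feature(name, pos, pos + len(yp), "Yprime_element", "+", f"Yp{yp_index}")
            )
            parts.append(yp)
            pos += len(yp)
            if motif_flags[yp_index]:
                parts.append(ATAT_MOTIF)
                pos += len(ATAT_MOTIF)
            its_len = int(rng.integers(cfg.its_lengths[0], cfg.its_lengths[1] + 1))
            features.append(Feature(name, pos, pos + its_len, "ITS", "+", "ITS"))
            parts.append(_ca_tract(rng, its_len))
            pos += its_len
            yp_index += 1
        xe = mutate(x_master, rng, max(1, n_subs // 2))
        features.append(Feature(name, pos, pos + len(xe), "X_element", "+", f"X{d}"))
        parts.append(xe)
        pos += len(xe)
        if pos >= L:
            raise ConfigurationError(
                f"donor {name} layout exceeds chrom_length {L}"
            )
        parts.append(random_dna(rng, L - pos))
        sequences[name] = "".join(parts)

    genome = Genome(sequences)
    annotations = AnnotationSet(sorted(features))

    # plant microhomology for class A junctions: copy the retained flank at
    # fixed core offsets into the interior of an X and a Y' element
    sites = class_a_sites(cfg, annotations)
    for bp, (tchrom, tcoord, _) in sites:
        flank = sequences[cfg.repair_chrom][bp : bp + cfg.microhomology_length]
        patched = mutate(flank, rng, cfg.microhomology_mismatches)
        donor = list(sequences[tchrom])
        donor[tcoord : tcoord + len(patched)] = list(patched)
        sequences[tchrom] = "".join(donor)
    genome = Genome(sequences)
    return genome, annotations


def class_a_sites(
    cfg: ToyGenomeConfig, annotations: AnnotationSet
) -> list[tuple[int, tuple[str, int, str]]]:
    """Deterministic (breakpoint, target) pairs for class A junctions:
    breakpoints at fixed core offsets, targets strictly internal to the
    first Y' element and the first X element."""
    core = annotations.one("SiRTA_core", None)
    yprimes = annotations.by_kind("Yprime_element")
    xs = annotations.by_kind("X_element")
    if not yprimes or not xs:
        raise ConfigurationError("class A sites require Y' and X elements")
    offsets = class_a_breakpoint_offsets(cfg)
    targets = [
        (yprimes[0].chrom, yprimes[0].start + yprimes[0].length // 2, "-"),
        (xs[0].chrom, xs[0].start + xs[0].length // 2, "-"),
    ]
    return [
        (core.start + off, tgt) for off, tgt in zip(offsets, targets)
    ]


# ---------------------------------------------------------------------------
# Event sampling


DEFAULT_SPATIAL = {"core": 0.55, "hocs_adjacent": 0.2, "uniform": 0.25}


def _motif_yprimes(genome: Genome, annotations: AnnotationSet) -> list[Feature]:
    out = []
    for yp in annotations.by_kind("Yprime_element"):
        if genome[yp.chrom][yp.end : yp.end + len(ATAT_MOTIF)] == ATAT_MOTIF:
            out.append(yp)
    return out


def _its_after_yprime(annotations: AnnotationSet) -> list[Feature]:
    """ITS tracts whose telomere side abuts a Y' element (optionally via
    the ATATATAT motif)."""
    out = []
    for its in annotations.by_kind("ITS"):
        for yp in annotations.by_kind("Yprime_element", its.chrom):
            gap = its.start - yp.end
            if 0 <= gap <= len(ATAT_MOTIF):
                out.append(its)
                break
    return out


def sample_pool_events(
    mixture: dict[str, float],
    n_clones: int,
    genome: Genome,
    annotations: AnnotationSet,
    seed: int,
    config: ToyGenomeConfig | None = None,
    spatial: dict[str, float] | None = None,
) -> PoolTruth:
    """Assign one rearrangement to each clone in a pool.

    Breakpoints follow a mixture of spatial components (concentrated at
    the hotspot core, adjacent to the cut site, and uniform background);
    targets are drawn per event-type rules.
    """
    if n_clones < 1:
        raise DataError("n_clones must be >= 1")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise DataError(f"mixture probabilities sum to {total}, expected 1")
    unknown = set(mixture) - set(EVENT_TYPES)
    if unknown:
        raise DataError(f"unknown event types in mixture: {sorted(unknown)}")
    config = config or ToyGenomeConfig()
    spatial = spatial or DEFAULT_SPATIAL

    rng = np.random.default_rng(seed)
    region = repair_region_span(annotations, config.repair_chrom)
    hocs = annotations.one("HO_cut_site", config.repair_chrom)
    core = annotations.one("SiRTA_core", config.repair_chrom)
    ura3 = annotations.one("URA3_marker", config.repair_chrom)
    tel = annotations.by_kind("telomere", config.repair_chrom)
    unique_lo = (max(f.end for f in tel) if tel else 0) + 50
    essential = min(
        annotations.by_kind("essential_gene", config.repair_chrom),
        key=lambda f: f.start,
    )

    def draw_breakpoint() -> int:
        keys = list(spatial)
        probs = np.array([spatial[k] for k in keys], dtype=float)
        probs /= probs.sum()
        comp = keys[rng.choice(len(keys), p=probs)]
        if comp == "core":
            return int(rng.integers(core.start, core.end))
        if comp == "hocs_adjacent":
            return int(rng.integers(hocs.end + 1, hocs.end + 101))
        return int(rng.integers(hocs.end + 1, essential.start))

    types = list(mixture)
    probs = np.array([mixture[t] for t in types], dtype=float)
    probs /= probs.sum()
    a_sites = None
    motif_yps = _motif_yprimes(genome, annotations)
    its_sites = _its_after_yprime(annotations)

    events: list[EventSpec] = []
    for i in range(n_clones):
        etype = types[rng.choice(len(types), p=probs)]
        clone_id = f"clone{i:02d}"
        if etype == "telomere_addition":
            # full-length telomeric tracts exceed the read length, so every
            # junction yields the same split-read window as other events
            tract = make_tg_tract(int(rng.integers(150, 301)), rng)
            events.append(EventSpec(clone_id, etype, draw_breakpoint(), tract=tract))
        elif etype == "deletion":
            t = int(rng.integers(unique_lo, ura3.start - 50))
            events.append(
                EventSpec(clone_id, etype, draw_breakpoint(), target=(region.chrom, t, "-"))
            )
        elif etype == "translocation_A":
            if a_sites is None:
                a_sites = class_a_sites(config, annotations)
            bp, tgt = a_sites[int(rng.integers(len(a_sites)))]
            events.append(EventSpec(clone_id, etype, bp, target=tgt))
        elif etype == "translocation_B":
            if not motif_yps:
                raise ConfigurationError(
                    "translocation_B requires motif-bearing Y' elements "
                    "(atat_motif_fraction > 0)"
                )
            yp = motif_yps[int(rng.integers(len(motif_yps)))]
            events.append(
                EventSpec(
                    clone_id, etype, draw_breakpoint(), target=(yp.chrom, yp.end, "-")
                )
            )
        elif etype == "translocation_C":
            if not its_sites:
                raise ConfigurationError("translocation_C requires ITS tracts")
            its = its_sites[int(rng.integers(len(its_sites)))]
            t = its.start + int(rng.integers(12, 25))
            events.append(
                EventSpec(clone_id, etype, draw_breakpoint(), target=(its.chrom, t, "-"))
            )
        elif etype == "hocs_indel":
            events.append(EventSpec(clone_id, etype, hocs.start))
    return PoolTruth(events=events, config=config, seed=seed)


# ---------------------------------------------------------------------------
# Clone synthesis


def _novel_piece(genome: Genome, event: EventSpec, cfg: ToyGenomeConfig) -> str:
    """Top-strand sequence joined telomere-proximal to the breakpoint."""
    if event.event_type == "telomere_addition":
        return revcomp(event.tract)
    chrom, coord, _ = event.target  # type: ignore[misc]
    if event.event_type == "translocation_B":
        coord += len(ATAT_MOTIF)  # the motif is part of the acquired sequence
    return genome[chrom][:coord]


def synthesize_clone_sequence(
    genome: Genome,
    event: EventSpec,
    config: ToyGenomeConfig | None = None,
) -> str:
    """Construct the rearranged repair chromosome for one clone.

    The product joins the retained centromeric segment (from the
    breakpoint to the chromosome end) to the event's novel sequence:
    a telomeric tract, unique sequence telomere-proximal to the URA3
    marker (deletion), or a donor subtelomere through to its terminus
    (non-reciprocal translocation).  The product never contains the
    URA3 marker or the HO cut site.
    """
    cfg = config or ToyGenomeConfig()
    chrom = genome[cfg.repair_chrom]
    b = event.breakpoint
    if event.event_type == "hocs_indel":
        hocs_at = chrom.find(HOCS_SEQ)
        if hocs_at < 0:
            raise DataError("repair chromosome lacks the HO cut site sequence")
        return chrom[: hocs_at + 8] + chrom[hocs_at + 11 :]
    if not (0 < b < len(chrom)):
        raise DataError(f"breakpoint {b} outside repair chromosome")
    if event.target is not None:
        tchrom, tcoord, _ = event.target
        if tchrom == cfg.repair_chrom and tcoord >= b:
            raise DataError(
                "target lies inside the retained segment; the product would "
                "retain the URA3 marker"
            )
    return _novel_piece(genome, event, cfg) + chrom[b:]


def canonical_breakpoint(
    genome: Genome, event: EventSpec, config: ToyGenomeConfig | None = None
) -> int:
    """Alignment-canonical boundary of the junction.

    When the novel sequence ends with bases identical to the reference
    just telomere-proximal to the breakpoint, any aligner extends the
    anchor through them; the canonical boundary is the breakpoint moved
    maximally toward the telomere.  Junctions in repeat-like context
    (e.g. telomeric tracts added inside a telomere-like hotspot) shift
    accordingly, by construction.
    """
    cfg = config or ToyGenomeConfig()
    if event.event_type == "hocs_indel":
        return event.breakpoint
    chrom = genome[cfg.repair_chrom]
    novel = _novel_piece(genome, event, cfg)
    b = event.breakpoint
    e = 0
    while e < len(novel) and b - 1 - e >= 0 and novel[-1 - e] == chrom[b - 1 - e]:
        e += 1
    return b - e


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    clones: list[str],
    depth: float,
    read_len: int = 150,
    error_rate: float = 0.001,
    seed: int = 0,
    clone_weights: list[float] | None = None,
) -> list[tuple[str, str]]:
    """Draw uniformly positioned single-end reads from each clone.

    Returns (read_id, sequence) pairs; read ids encode the source clone
    index, the start offset within the clone, and the strand, so tests
    can recover per-read truth.  Errors are substitutions only.
    """
    if depth <= 0:
        raise DataError("depth must be > 0")
    if not (0 <= error_rate < 0.05):
        raise DataError("error_rate must be in [0, 0.05)")
    rng = np.random.default_rng(seed)
    weights = clone_weights or [1.0] * len(clones)
    if len(weights) != len(clones):
        raise DataError("clone_weights length must match clones")
    reads: list[tuple[str, str]] = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for ci, clone in enumerate(clones):
        if read_len > len(clone):
            raise DataError(
                f"read_len {read_len} exceeds clone {ci} length {len(clone)}"
            )
        n_reads = int(round(depth * weights[ci] * len(clone) / read_len))
        starts = rng.integers(0, len(clone) - read_len + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for ri, (s, neg) in enumerate(zip(starts, strands)):
            seq = clone[s : s + read_len]
            if neg:
                seq = revcomp(seq)
            if error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                errs = np.nonzero(rng.random(read_len) < error_rate)[0]
                for p in errs:
                    choices = bases[bases != arr[p]]
                    arr[p] = choices[rng.integers(len(choices))]
                seq = arr.tobytes().decode()
            strand = "-" if neg else "+"
            reads.append((f"c{ci:02d}_{ri:05d}_{s}{strand}", seq))
    return reads


def write_fastq(reads: list[tuple[str, str]], path: str | Path, qual: str = "I") -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual * len(seq)}\n")


def write_truth_sam(
    truth: PoolTruth,
    genome: Genome,
    clones: list[str],
    reads: list[tuple[str, str]],
    path: str | Path,
) -> None:
    """Emit per-read truth alignments against the reference.

    Junction-spanning reads get a soft-clipped CIGAR at the canonical
    breakpoint; reads entirely within the retained segment map fully;
    reads entirely within the novel piece are left unmapped.
    """
    cfg = truth.config
    chrom = cfg.repair_chrom
    novel_lens = []
    canon = []
    for ev, clone in zip(truth.events, clones):
        novel_lens.append(len(clone) - (genome.length(chrom) - ev.breakpoint))
        canon.append(canonical_breakpoint(genome, ev, cfg))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in genome:
            fh.write(f"@SQ\tSN:{c}\tLN:{genome.length(c)}\n")
        for read_id, seq in reads:
            ci = int(read_id[1:3])
            start = int(read_id.split("_")[2][:-1])
            neg = read_id.endswith("-")
            ev = truth.events[ci]
            nl = novel_lens[ci]
            b = ev.breakpoint
            read_len = len(seq)
            # clone coordinate of the canonical junction
            junction = nl - (b - canon[ci])
            flag = 16 if neg else 0
            fwd = revcomp(seq) if neg else seq
            if start >= junction:
                pos = canon[ci] + (start - junction)
                fh.write(
                    f"{read_id}\t{flag}\t{chrom}\t{pos + 1}\t60\t{read_len}M"
                    f"\t*\t0\t0\t{fwd}\t{'I' * read_len}\n"
                )
            elif start + read_len > junction:
                clip = junction - start
                fh.write(
                    f"{read_id}\t{flag}\t{chrom}\t{canon[ci] + 1}\t60\t"
                    f"{clip}S{read_len - clip}M\t*\t0\t0\t{fwd}\t{'I' * read_len}\n"
                )
            else:
                fh.write(
                    f"{read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{fwd}\t{'I' * read_len}\n"
                )


def simulate_pool(
    genome: Genome,
    annotations: AnnotationSet,
    truth: PoolTruth,
    depth: float = 30.0,
    read_len: int = 150,
    error_rate: float = 0.001,
    seed: int = 0,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Synthesize every clone in a pool and simulate its reads."""
    clones = [
        synthesize_clone_sequence(genome, ev, truth.config) for ev in truth.events
    ]
    reads = simulate_reads(clones, depth, read_len, error_rate, seed)
    return clones, reads
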