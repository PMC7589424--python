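"""Synthetic amplicon-splicing data with known ground truth.

This module emulates a targeted long-amplicon RNA-seq experiment on a
large multi-exon gene: a mixture of transcript isoforms (exon skipping,
pseudoexon insertion, alternative splice sites at configurable
frequencies) is sampled either as spliced long-read alignments (SAM) or
directly as a junction-count table, together with the generative truth
(junction counts, per-exon inclusion, per-event usage). The default
geometry mirrors a dystrophin-like gene: 79 exons on the minus strand,
~11.3 kb of exonic sequence amplified as a single fragment, reads of
mean length 374 bp, and a mean junction depth of 1638x.

Sequencing error is deliberately not simulated: downstream junction
extraction operates on alignment geometry alone, so base-level noise
would be invisible to it anyway.
"""

from __future__ import annotations

import itertools
import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .gene_model import GeneModel, Exon, locate, parse_exon_relative_label
from .junction_quant import JunctionTable, mark_annotated

logger = logging.getLogger(__name__)

__all__ = [
    "EventSpec",
    "Isoform",
    "ConditionProfile",
    "GroundTruth",
    "synthetic_dmd_model",
    "build_isoforms",
    "simulate_junction_counts",
    "simulate_alignments",
    "reads_to_fastq",
    "StudyScenario",
    "study_emulation_preset",
]


# ----------------------------------------------------------------------
# Event and profile specifications


@dataclass(frozen=True)
class EventSpec:
    """One alternative-splicing event injected into the isoform mixture.

    ``kind`` is one of ``exon_skip``, ``multi_exon_skip``,
    ``pseudoexon_insert``, ``alt5ss``, ``alt3ss``. For pseudoexons,
    ``pe_start``/``pe_end`` are the genomic (low, high) boundaries of the
    inserted block, strictly inside ``intron``. For alternative splice
    sites, ``site`` is the genomic position of the novel donor/acceptor
    (the boundary-adjacent intronic base replacing the annotated one).
    ``frequency`` is the fraction of transcripts carrying the event.
    Events sharing a ``group`` are mutually exclusive; ungrouped events
    combine independently.
    """

    kind: str
    frequency: float
    name: str
    exons: tuple[int, ...] = ()
    intron: Optional[int] = None
    pe_start: Optional[int] = None
    pe_end: Optional[int] = None
    site: Optional[int] = None
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in (
            "exon_skip",
            "multi_exon_skip",
            "pseudoexon_insert",
            "alt5ss",
            "alt3ss",
        ):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency must be in [0,1], got {self.frequency}")

    def validate(self, model: GeneModel) -> None:
        if self.kind in ("exon_skip", "multi_exon_skip"):
            if not self.exons:
                raise ValueError(f"{self.name}: skip event needs exon indices")
            lo, hi = min(self.exons), max(self.exons)
            if set(self.exons) != set(range(lo, hi + 1)):
                raise ValueError(f"{self.name}: skipped exons must be contiguous")
            if lo < 2 or hi > model.n_exons - 1:
                raise ValueError(f"{self.name}: only internal exons can be skipped")
        elif self.kind == "pseudoexon_insert":
            if self.intron is None or self.pe_start is None or self.pe_end is None:
                raise ValueError(f"{self.name}: pseudoexon needs intron and boundaries")
            if self.pe_start > self.pe_end:
                raise ValueError(f"{self.name}: pe_start > pe_end")
            for pos in (self.pe_start, self.pe_end):
                where, idx = locate(model, pos)
                if (where, idx) != ("intron", self.intron):
                    raise ValueError(
                        f"{self.name}: pseudoexon boundary {pos} not inside intron {self.intron}"
                    )
        else:  # alt ss
            if self.intron is None or self.site is None:
                raise ValueError(f"{self.name}: alt splice site needs intron and site")
            where, idx = locate(model, self.site)
            if (where, idx) != ("intron", self.intron):
                raise ValueError(
                    f"{self.name}: site {self.site} not inside intron {self.intron}"
                )

    def claims(self) -> frozenset:
        """Resource tokens used to detect incompatible co-occurring events."""
        if self.kind in ("exon_skip", "multi_exon_skip"):
            lo, hi = min(self.exons), max(self.exons)
            toks = {("exon", e) for e in self.exons}
            toks |= {("intron", lo - 1), ("intron", hi)}
            return frozenset(toks)
        return frozenset({("intron", self.intron)})


@dataclass(frozen=True)
class ConditionProfile:
    """Sequencing design for one condition (replicates share the event mix)."""

    condition: str
    events: tuple[EventSpec, ...]
    n_replicates: int = 2
    depth: int = 1638
    read_len_mean: float = 374.0
    read_len_sd: float = 40.0
    read_len_min: int = 100
    read_len_max: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{self.condition}_rep{r}" for r in range(1, self.n_replicates + 1)]


@dataclass
class Isoform:
    """An ordered chain of genomic blocks (transcript order) with a weight."""

    blocks: tuple[tuple[int, int], ...]
    weight: float
    events: tuple[str, ...] = ()
    contains: frozenset[int] = frozenset()  # annotated exon indices retained

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.blocks)

    def junctions(self, strand: str) -> list[tuple[int, int]]:
        """(donor, acceptor) site pairs between consecutive blocks."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((s1 - 1, e2 + 1))
        return out


@dataclass
class GroundTruth:
    """Generative truth emitted alongside simulated data."""

    junction_counts: pd.DataFrame  # index (donor, acceptor), columns = samples
    exon_psi: pd.Series  # true inclusion per annotated exon (isoform weights)
    event_usage: dict[str, float]  # event name -> generative frequency

    def write(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        jc = self.junction_counts.reset_index()
        jc.to_csv(directory / "truth_junction_counts.tsv", sep="\t", index=False)
        self.exon_psi.rename("true_psi").rename_axis("exon").reset_index().to_csv(
            directory / "truth_exon_psi.tsv", sep="\t", index=False
        )
        pd.Series(self.event_usage, name="frequency").rename_axis("event").reset_index().to_csv(
            directory / "truth_event_usage.tsv", sep="\t", index=False
        )


# ----------------------------------------------------------------------
# Deterministic dystrophin-like gene geometry

_EXON71_LEN = 39
_EXON78_LEN = 32


def synthetic_dmd_model(gene_id: str = "Dp427m-like", chrom: str = "chrX") -> GeneModel:
    """A deterministic 79-exon minus-strand gene model.

    Exon sizes follow a fixed pseudo-irregular table summing to ~11.3 kb,
    with the two short exons (71: 39 nt, 78: 32 nt) of the dystrophin
    muscle isoform preserved. Intron sizes vary; intron 1 is large (deep
    pseudoexon territory) and intron 77 is 4000 nt so that deep-intronic
    alternative donors at offsets +1619 and -94 are both valid
    nearest-boundary labels.
    """
    n = 79
    exon_lens = [118 + ((i * 53) % 61) for i in range(1, n + 1)]
    exon_lens[0] = 250  # first exon (primer anchor)
    exon_lens[70] = _EXON71_LEN
    exon_lens[77] = _EXON78_LEN
    exon_lens[78] = 420  # last exon includes the 3' primer region
    intron_lens = [300 + ((i * 97) % 1700) for i in range(1, n)]
    intron_lens[0] = 25000
    intron_lens[33] = 8000
    intron_lens[62] = 6000
    intron_lens[76] = 4000
    # minus strand: exon 1 sits at the genomic top, walk downwards
    top = 1_000_000
    exons = []
    cur_end = top
    for i in range(n):
        start = cur_end - exon_lens[i] + 1
        exons.append(Exon(i + 1, start, cur_end))
        if i < n - 1:
            cur_end = start - 1 - intron_lens[i]
    return GeneModel(gene_id, chrom, "-", tuple(exons))


# ----------------------------------------------------------------------
# Isoform construction


def build_isoforms(model: GeneModel, events: Sequence[EventSpec]) -> list[Isoform]:
    """Enumerate the isoform mixture implied by a set of events.

    Ungrouped events combine independently (product distribution over
    present/absent); events sharing a ``group`` are mutually exclusive
    alternatives whose frequencies must sum to <= 1. Active events from
    different groups that modify the same exon or intron boundary are
    inconsistent and raise ``ValueError``.
    """
    for ev in events:
        ev.validate(model)
    names = [ev.name for ev in events]
    if len(set(names)) != len(names):
        raise ValueError("event names must be unique")

    groups: dict[str, list[EventSpec]] = {}
    for i, ev in enumerate(events):
        groups.setdefault(ev.group or f"__solo_{i}", []).append(ev)
    choice_sets = []
    for key, evs in groups.items():
        total = sum(e.frequency for e in evs)
        if total > 1.0 + 1e-12:
            raise ValueError(f"frequencies in group {key!r} sum to {total} > 1")
        choice_sets.append([(None, 1.0 - total)] + [(e, e.frequency) for e in evs])

    isoforms: list[Isoform] = []
    for combo in itertools.product(*choice_sets):
        active = [ev for ev, _ in combo if ev is not None]
        weight = float(np.prod([w for _, w in combo])) if combo else 1.0
        if weight == 0.0:
            continue
        seen: dict = {}
        for ev in active:
            for tok in ev.claims():
                if tok in seen:
                    raise ValueError(
                        f"inconsistent events {seen[tok]!r} and {ev.name!r} both modify {tok}"
                    )
                seen[tok] = ev.name
        isoforms.append(_assemble(model, active, weight))
    total_w = sum(iso.weight for iso in isoforms)
    if abs(total_w - 1.0) > 1e-9:  # pragma: no cover - arithmetic guard
        raise AssertionError(f"isoform weights sum to {total_w}")
    return isoforms


def _assemble(model: GeneModel, active: Sequence[EventSpec], weight: float) -> Isoform:
    bounds = {e.index: [e.start, e.end] for e in model.exons}
    removed: set[int] = set()
    inserts: dict[int, tuple[int, int]] = {}  # intron index -> PE block
    for ev in active:
        if ev.kind in ("exon_skip", "multi_exon_skip"):
            removed |= set(ev.exons)
        elif ev.kind == "pseudoexon_insert":
            inserts[ev.intron] = (ev.pe_start, ev.pe_end)
        elif ev.kind == "alt5ss":
            # donor of exon `intron` moves to `site`: exon extends/retracts
            if model.strand == "+":
                bounds[ev.intron][1] = ev.site - 1
            else:
                bounds[ev.intron][0] = ev.site + 1
        elif ev.kind == "alt3ss":
            if model.strand == "+":
                bounds[ev.intron + 1][0] = ev.site + 1
            else:
                bounds[ev.intron + 1][1] = ev.site - 1
    blocks: list[tuple[int, int]] = []
    for i in range(1, model.n_exons + 1):
        if i not in removed:
            blocks.append(tuple(bounds[i]))
        if i in inserts:
            blocks.append(inserts[i])
    contains = frozenset(i for i in range(1, model.n_exons + 1) if i not in removed)
    return Isoform(
        blocks=tuple(blocks),
        weight=weight,
        events=tuple(ev.name for ev in active),
        contains=contains,
    )


def _true_exon_psi(model: GeneModel, isoforms: Sequence[Isoform]) -> pd.Series:
    vals = {
        e.index: sum(iso.weight for iso in isoforms if e.index in iso.contains)
        for e in model.exons
    }
    return pd.Series(vals, name="true_psi")


def _event_usage(isoforms: Sequence[Isoform]) -> dict[str, float]:
    usage: dict[str, float] = {}
    for iso in isoforms:
        for name in iso.events:
            usage[name] = usage.get(name, 0.0) + iso.weight
    return usage


# ----------------------------------------------------------------------
# Fast path: multinomial junction counts


def _assign_junction_loci(
    model: GeneModel, isoforms: Sequence[Isoform]
) -> list[dict[int, list[tuple[int, int]]]]:
    """Per isoform: annotated-intron locus -> junctions attributed there.

    Each isoform junction is attributed to the first annotated intron
    (transcript order) that its removed span covers; both junctions of a
    pseudoexon therefore share their host intron's locus, so their
    counts stay equal within a draw, as they are on one transcript.
    """
    spans = [model.intron_span(i) for i in range(1, model.n_introns + 1)]
    out = []
    for iso in isoforms:
        per_locus: dict[int, list[tuple[int, int]]] = {}
        for d, a in iso.junctions(model.strand):
            lo, hi = (d, a) if d <= a else (a, d)
            locus = None
            for idx, (ilo, ihi) in enumerate(spans, start=1):
                if lo <= ihi and hi >= ilo:
                    locus = idx
                    break
            if locus is None:  # pragma: no cover - events always span an intron
                continue
            per_locus.setdefault(locus, []).append((d, a))
        out.append(per_locus)
    return out


def simulate_junction_counts(
    model: GeneModel,
    isoforms: Sequence[Isoform],
    profile: ConditionProfile,
    rng: Optional[np.random.Generator] = None,
) -> tuple[JunctionTable, GroundTruth]:
    """Draw per-replicate junction counts directly (no read simulation).

    At every annotated intron locus, ``depth`` junction-crossing reads
    are distributed multinomially over the isoform mixture; each
    isoform's draw is credited to the junction(s) it splices at that
    locus (isoforms whose junction over that locus was already credited
    at an upstream locus contribute nothing there, mimicking a read
    counted once per junction).
    """
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    weights = np.array([iso.weight for iso in isoforms])
    loci = _assign_junction_loci(model, isoforms)
    samples = profile.sample_ids
    counts: dict[tuple[int, int], np.ndarray] = {}
    for rep in range(profile.n_replicates):
        for locus in range(1, model.n_introns + 1):
            draw = rng.multinomial(profile.depth, weights)
            for iso_idx, c in enumerate(draw):
                if c == 0:
                    continue
                for junc in loci[iso_idx].get(locus, ()):
                    arr = counts.setdefault(junc, np.zeros(len(samples), dtype=np.int64))
                    arr[rep] += c
    index = pd.MultiIndex.from_tuples(sorted(counts), names=["donor", "acceptor"])
    df = pd.DataFrame(
        [counts[j] for j in index] if len(index) else np.empty((0, len(samples)), dtype=np.int64),
        index=index,
        columns=samples,
    )
    table = JunctionTable(chrom=model.chrom, counts=df, annotated=mark_annotated(df.index, model))
    truth = GroundTruth(
        junction_counts=df.copy(),
        exon_psi=_true_exon_psi(model, isoforms),
        event_usage=_event_usage(isoforms),
    )
    return table, truth


# ----------------------------------------------------------------------
# Read-level path: spliced SAM alignments


def _draw_read_lengths(
    rng: np.random.Generator, profile: ConditionProfile, n: int
) -> np.ndarray:
    """Truncated-normal read lengths (rejection sampling, vectorized)."""
    out = np.full(n, profile.read_len_mean)
    mask = np.ones(n, dtype=bool)
    for _ in range(100):
        k = int(mask.sum())
        if not k:
            break
        out[mask] = rng.normal(profile.read_len_mean, profile.read_len_sd, size=k)
        mask = (out < profile.read_len_min) | (out > profile.read_len_max)
    out = np.clip(out, profile.read_len_min, profile.read_len_max)
    return np.rint(out).astype(np.int64)


def _read_segments(
    blocks: Sequence[tuple[int, int]],
    cum: np.ndarray,
    start0: int,
    length: int,
    minus: bool,
) -> list[tuple[int, int]]:
    """Genomic segments (transcript order) covered by transcript
    interval [start0, start0+length), truncated at the isoform end.

    ``cum`` holds cumulative block offsets (cum[k] = transcript offset of
    block k's first base). Within a block, transcript offsets run 5'->3',
    i.e. from the low genomic end on the plus strand and from the high
    end on the minus strand.
    """
    segs = []
    end = min(start0 + length, int(cum[-1]))
    b = bisect_right(cum, start0) - 1
    pos = start0
    while pos < end:
        s, e = blocks[b]
        inblock = pos - int(cum[b])
        take = min(int(cum[b + 1]) - pos, end - pos)
        if minus:
            segs.append((e - inblock - take + 1, e - inblock))
        else:
            segs.append((s + inblock, s + inblock + take - 1))
        pos += take
        b += 1
    return segs


@dataclass
class SimulatedAlignments:
    paths: dict[str, Path]
    truth: GroundTruth
    n_reads: dict[str, int]


def simulate_alignments(
    model: GeneModel,
    isoforms: Sequence[Isoform],
    profile: ConditionProfile,
    out_dir: Union[str, Path],
    anchor: int = 8,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedAlignments:
    """Emit coordinate-sorted spliced SAM alignments per replicate.

    Reads are drawn from the isoform mixture by weight; the fragment
    start is uniform over the transcript and the read length follows a
    truncated normal (default mean 374, sd 40, range [100, 600]),
    truncated at the transcript end. Exon blocks become match
    operations, introns become skip operations. The returned ground
    truth counts every junction spanned with >= ``anchor`` aligned bases
    on both sides — exactly what junction extraction recovers from the
    emitted records. Deterministic given the profile seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    weights = np.array([iso.weight for iso in isoforms])
    strand_minus = model.strand == "-"
    lo, hi = model.span
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": model.chrom, "LN": hi + 1000}],
    }
    full_len = sum(e.length for e in model.exons)
    usable = max(1.0, profile.read_len_mean - 2 * anchor + 1)
    n_reads = max(1, int(round(profile.depth * full_len / usable)))

    samples = profile.sample_ids
    counts: dict[tuple[int, int], np.ndarray] = {}
    paths: dict[str, Path] = {}
    truncated = 0
    iso_blocks = [iso.blocks for iso in isoforms]
    iso_cum = [
        np.concatenate(([0], np.cumsum([e - s + 1 for s, e in iso.blocks])))
        for iso in isoforms
    ]
    tlens = np.array([iso.length for iso in isoforms], dtype=np.int64)
    for rep, sample in enumerate(samples):
        iso_idx = rng.choice(len(isoforms), size=n_reads, p=weights)
        starts = np.floor(rng.random(n_reads) * tlens[iso_idx]).astype(np.int64)
        lengths = _draw_read_lengths(rng, profile, n_reads)
        truncated += int((starts + lengths > tlens[iso_idx]).sum())
        records = []
        for i in range(n_reads):
            k = iso_idx[i]
            segs = _read_segments(
                iso_blocks[k], iso_cum[k], int(starts[i]), int(lengths[i]), strand_minus
            )
            # junction truth with the anchor rule
            for k in range(len(segs) - 1):
                left = segs[k][1] - segs[k][0] + 1
                right = segs[k + 1][1] - segs[k + 1][0] + 1
                if left < anchor or right < anchor:
                    continue
                (s1, e1), (s2, e2) = segs[k], segs[k + 1]
                junc = (s1 - 1, e2 + 1) if strand_minus else (e1 + 1, s2 - 1)
                arr = counts.setdefault(junc, np.zeros(len(samples), dtype=np.int64))
                arr[rep] += 1
            gsegs = sorted(segs)  # reference order for the CIGAR
            cig = []
            for k, (s, e) in enumerate(gsegs):
                if k:
                    gap = s - gsegs[k - 1][1] - 1
                    cig.append((3, gap))  # N
                cig.append((0, e - s + 1))  # M
            records.append((gsegs[0][0] - 1, f"{sample}_read{i}", cig))
        records.sort(key=lambda r: (r[0], r[1]))
        path = out_dir / f"{sample}.sam"
        paths[sample] = path
        with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
            for ref_start, name, cig in records:
                a = pysam.AlignedSegment(sam.header)
                a.query_name = name
                a.flag = 16 if strand_minus else 0
                a.reference_id = 0
                a.reference_start = ref_start
                a.mapping_quality = 60
                a.cigartuples = cig
                sam.write(a)
    if truncated:
        logger.warning("%d reads truncated at transcript 3' end", truncated)
    index = pd.MultiIndex.from_tuples(sorted(counts), names=["donor", "acceptor"])
    df = pd.DataFrame(
        [counts[j] for j in index] if len(index) else np.empty((0, len(samples)), dtype=np.int64),
        index=index,
        columns=samples,
    )
    truth = GroundTruth(
        junction_counts=df,
        exon_psi=_true_exon_psi(model, isoforms),
        event_usage=_event_usage(isoforms),
    )
    return SimulatedAlignments(paths=paths, truth=truth, n_reads={s: n_reads for s in samples})


def reads_to_fastq(
    sam_path: Union[str, Path],
    fastq_path: Union[str, Path],
    fasta: Optional[Union[str, Path]] = None,
) -> int:
    """Convert simulated alignments to FASTQ (optional integration aid).

    With a genome FASTA the read sequences are reconstructed from the
    aligned reference blocks; otherwise N-filled placeholders of the
    aligned length are written. Returns the number of reads written.
    """
    genome = None
    if fasta is not None:
        from pyfaidx import Fasta

        genome = Fasta(str(fasta))
    n = 0
    with pysam.AlignmentFile(str(sam_path), "r") as sam, open(fastq_path, "w") as out:
        for read in sam:
            if read.is_unmapped:
                continue
            if genome is not None:
                seq = "".join(
                    str(genome[read.reference_name][s:e]) for s, e in read.get_blocks()
                )
            else:
                seq = "N" * read.query_alignment_length
            out.write(f"@{read.query_name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


# ----------------------------------------------------------------------
# Study-emulation preset


@dataclass
class StudyScenario:
    """A packaged knockdown-screen scenario with a shared gene model."""

    model: GeneModel
    profiles: dict[str, ConditionProfile]
    control: str = "si-ctrl"
    metadata: dict = field(default_factory=dict)

    @property
    def treated(self) -> list[str]:
        return [c for c in self.profiles if c != self.control]

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for cond, prof in self.profiles.items():
            for r, sample in enumerate(prof.sample_ids, start=1):
                rows.append({"sample": sample, "condition": cond, "replicate": r})
        return pd.DataFrame(rows)


def _baseline_events(model: GeneModel) -> dict[str, EventSpec]:
    """Baseline (control) event mix: a quiescent splicing landscape with
    all events below 5%, mildly elevated skipping of the two short exons
    and of the intron-1 pseudoexon, and trace-level deep-intronic events.

    These frequencies are emulation parameters chosen to resemble a
    well-regulated muscle transcript; they are not measurements.
    """
    pe = lambda intron, off_lo, off_hi: (  # genomic block from donor offsets, minus strand
        model.exon(intron).start - off_hi,
        model.exon(intron).start - off_lo,
    )
    pe1_lo, pe1_hi = pe(1, 9001, 9120)
    pe34_lo, pe34_hi = pe(34, 3001, 3080)
    pe63_lo, pe63_hi = pe(63, 2501, 2590)
    specs = [
        EventSpec("exon_skip", 0.005, "exon9_skip", exons=(9,)),
        EventSpec("exon_skip", 0.005, "exon37_skip", exons=(37,), group="ex37_38"),
        EventSpec("exon_skip", 0.005, "exon38_skip", exons=(38,), group="ex37_38"),
        EventSpec("exon_skip", 0.005, "exon41_skip", exons=(41,)),
        EventSpec("exon_skip", 0.03, "exon71_skip", exons=(71,)),
        EventSpec("exon_skip", 0.005, "exon74_skip", exons=(74,)),
        EventSpec("exon_skip", 0.04, "exon78_skip", exons=(78,), group="ex78_region"),
        EventSpec(
            "pseudoexon_insert", 0.04, "PE1a", intron=1, pe_start=pe1_lo, pe_end=pe1_hi
        ),
        EventSpec(
            "pseudoexon_insert", 0.001, "34x", intron=34, pe_start=pe34_lo, pe_end=pe34_hi
        ),
        EventSpec(
            "pseudoexon_insert", 0.001, "63x", intron=63, pe_start=pe63_lo, pe_end=pe63_hi
        ),
        EventSpec(
            "alt5ss",
            0.001,
            "E77+1619",
            intron=77,
            site=parse_exon_relative_label(model, "E77+1619"),
            group="ex78_region",
        ),
        EventSpec(
            "alt5ss",
            0.002,
            "E78-94",
            intron=77,
            site=parse_exon_relative_label(model, "E78-94"),
            group="ex78_region",
        ),
    ]
    return {s.name: s for s in specs}


def study_emulation_preset(
    knockdowns: Optional[Mapping[str, Mapping[str, float]]] = None,
    *,
    depth: int = 1638,
    n_control: int = 4,
    n_treated: int = 2,
    seed: int = 0,
) -> StudyScenario:
    """The packaged knockdown-screen scenario.

    Parameters
    ----------
    knockdowns
        Mapping ``condition name -> {event name: frequency shift}``; each
        shift is added to the control frequency of that event (the
        resulting frequency must stay in [0, 1]). E.g. a strong splicing
        activator's knockdown is emulated as
        ``{"si-QKI": {"exon71_skip": +0.40}}``.
    depth
        Expected junction-crossing reads per junction position (default
        1638, the design depth of the emulated experiment).
    n_control, n_treated
        Replicates per condition (default 4 control vs 2 treated).
    seed
        Base seed; each condition gets a distinct derived seed.
    """
    model = synthetic_dmd_model()
    base = _baseline_events(model)
    profiles: dict[str, ConditionProfile] = {}

    def make_profile(name: str, events: dict[str, EventSpec], n_reps: int, idx: int):
        return ConditionProfile(
            condition=name,
            events=tuple(events.values()),
            n_replicates=n_reps,
            depth=depth,
            seed=(seed * 1009 + idx) % (2**31 - 1),
        )

    profiles["si-ctrl"] = make_profile("si-ctrl", base, n_control, 0)
    for idx, (cond, shifts) in enumerate(sorted((knockdowns or {}).items()), start=1):
        events = dict(base)
        for ev_name, shift in shifts.items():
            if ev_name not in events:
                raise KeyError(f"unknown event {ev_name!r} in knockdown {cond!r}")
            new_f = events[ev_name].frequency + shift
            if not 0.0 <= new_f <= 1.0:
                raise ValueError(f"{cond}/{ev_name}: shifted frequency {new_f} outside [0,1]")
            events[ev_name] = replace(events[ev_name], frequency=new_f)
        profiles[cond] = make_profile(cond, events, n_treated, idx)
    return StudyScenario(
        model=model,
        profiles=profiles,
        control="si-ctrl",
        metadata={
            "note": "event frequencies are emulation parameters, not measurements",
            "depth": depth,
            "seed": seed,
        },
    )
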