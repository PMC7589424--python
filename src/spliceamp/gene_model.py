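"""Gene models for junction-centric splicing analysis.

A :class:`GeneModel` holds the ordered exon structure of a single
(multi-exon) transcript and is the coordinate authority for everything
else in the package: canonical junction enumeration, exon/intron lookup,
and the exon-relative naming of intronic positions (``E77+1619`` style,
as used for deep-intronic alternative splice sites and pseudoexon
boundaries).

Conventions
-----------
* All internal coordinates are 1-based, inclusive, genomic (SAM/GFF3
  convention). BED12 input is converted on read.
* Exons are stored in *transcript* order (exon 1 = 5' end of the mRNA),
  so genomic coordinates decrease along the list for a minus-strand gene.
* A *donor* site is the first intronic base 3' of an exon in transcript
  orientation; an *acceptor* site is the last intronic base 5' of an
  exon. Junctions are keyed by ``(donor_pos, acceptor_pos)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

__all__ = [
    "Exon",
    "GenomicSite",
    "GeneModel",
    "load_gene_model",
    "write_bed12",
    "canonical_junctions",
    "name_intronic_position",
    "parse_exon_relative_label",
    "locate",
]


@dataclass(frozen=True)
class Exon:
    """One exon in transcript order. ``start <= end`` always (genomic)."""

    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"exon index must be >= 1, got {self.index}")
        if self.start > self.end:
            raise ValueError(f"exon {self.index}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomicSite:
    """A splice site: the boundary-adjacent intronic base, with its role."""

    chrom: str
    pos: int
    role: Literal["donor", "acceptor"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    exons: tuple[Exon, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if len(self.exons) < 2:
            raise ValueError("a junction-based model needs at least 2 exons")
        for i, ex in enumerate(self.exons, start=1):
            if ex.index != i:
                raise ValueError(f"exon indices must be 1..n in order, got {ex.index} at {i}")
        # transcript order: genomic coordinates strictly monotone along strand
        sign = 1 if self.strand == "+" else -1
        prev = self.exons[0]
        for ex in self.exons[1:]:
            if sign > 0 and ex.start <= prev.end:
                raise ValueError(f"exons {prev.index}/{ex.index} overlap or unsorted for '+' strand")
            if sign < 0 and ex.end >= prev.start:
                raise ValueError(f"exons {prev.index}/{ex.index} overlap or unsorted for '-' strand")
            prev = ex

    # ------------------------------------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min, max) of the gene, inclusive."""
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return lo, hi

    def exon(self, index: int) -> Exon:
        return self.exons[index - 1]

    # -- splice-site coordinates ---------------------------------------
    def donor_site(self, exon_index: int) -> GenomicSite:
        """First intronic base 3' of exon ``exon_index`` (transcript sense)."""
        if not 1 <= exon_index < self.n_exons:
            raise ValueError(f"exon {exon_index} has no donor (n={self.n_exons})")
        ex = self.exon(exon_index)
        pos = ex.end + 1 if self.strand == "+" else ex.start - 1
        return GenomicSite(self.chrom, pos, "donor")

    def acceptor_site(self, exon_index: int) -> GenomicSite:
        """Last intronic base 5' of exon ``exon_index`` (transcript sense)."""
        if not 1 < exon_index <= self.n_exons:
            raise ValueError(f"exon {exon_index} has no acceptor")
        ex = self.exon(exon_index)
        pos = ex.start - 1 if self.strand == "+" else ex.end + 1
        return GenomicSite(self.chrom, pos, "acceptor")

    def intron_span(self, intron_index: int) -> tuple[int, int]:
        """Genomic (lo, hi) of intron ``i`` (between exons i and i+1), inclusive."""
        if not 1 <= intron_index <= self.n_introns:
            raise ValueError(f"no intron {intron_index}")
        a, b = self.exon(intron_index), self.exon(intron_index + 1)
        if self.strand == "+":
            return a.end + 1, b.start - 1
        return b.end + 1, a.start - 1

    def tpos(self, pos: int) -> int:
        """Monotone transcript-orientation key (increases 5'->3')."""
        return pos if self.strand == "+" else -pos

    def summary_frame(self):
        """Exon table (index, start, end, length) as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "exon": [e.index for e in self.exons],
                "start": [e.start for e in self.exons],
                "end": [e.end for e in self.exons],
                "length": [e.length for e in self.exons],
            }
        )

    def write_summary(self, path: Union[str, Path]) -> None:
        self.summary_frame().to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# Loading


def _exons_from_genomic_intervals(
    intervals: Iterable[tuple[int, int]], strand: str
) -> tuple[Exon, ...]:
    ivs = sorted(intervals)  # ascending genomic
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping exons: ({s1},{e1}) and ({s2},{e2})")
    if strand == "-":
        ivs = ivs[::-1]
    return tuple(Exon(i, s, e) for i, (s, e) in enumerate(ivs, start=1))


def _load_bed12(path: Path, transcript_id: Optional[str]) -> GeneModel:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 fields, got {len(f)}: {line[:80]}")
            records.append(f)
    if transcript_id is not None:
        records = [f for f in records if f[3] == transcript_id]
        if not records:
            raise ValueError(f"transcript {transcript_id!r} not found in {path}")
    if not records:
        raise ValueError(f"no BED records in {path}")
    f = records[0]
    chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand {strand!r} in BED12 record {name}")
    n_blocks = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(f"blockCount mismatch in BED12 record {name}")
    # half-open 0-based -> 1-based inclusive
    intervals = [
        (chrom_start + st + 1, chrom_start + st + sz) for st, sz in zip(starts, sizes)
    ]
    return GeneModel(name, chrom, strand, _exons_from_genomic_intervals(intervals, strand))


def _load_gff3(path: Path, transcript_id: Optional[str]) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    by_parent: dict[str, list] = {}
    for ex in db.features_of_type("exon"):
        for parent in ex.attributes.get("Parent", ["<orphan>"]):
            by_parent.setdefault(parent, []).append(ex)
    if not by_parent:
        raise ValueError(f"no exon features in {path}")
    if transcript_id is not None:
        if transcript_id not in by_parent:
            raise ValueError(f"transcript {transcript_id!r} not found in {path}")
        parent = transcript_id
    else:
        parent = next(iter(by_parent))
    exons = by_parent[parent]
    chrom = exons[0].seqid
    strand = exons[0].strand
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand {strand!r} for transcript {parent}")
    if any(e.seqid != chrom for e in exons):
        raise ValueError(f"transcript {parent} spans multiple sequences")
    intervals = [(e.start, e.end) for e in exons]  # gffutils is 1-based inclusive
    return GeneModel(parent, chrom, strand, _exons_from_genomic_intervals(intervals, strand))


def load_gene_model(
    path: Union[str, Path],
    format: Optional[str] = None,
    transcript_id: Optional[str] = None,
) -> GeneModel:
    """Load a single-transcript gene model from BED12 or GFF3.

    Parameters
    ----------
    path
        Annotation file.
    format
        ``"bed12"`` or ``"gff3"``; inferred from the file extension when
        omitted.
    transcript_id
        Selects one transcript when the file holds several; by default
        the first one is used.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "bed12" if suffix in (".bed", ".bed12") else "gff3"
    format = format.lower()
    if format == "bed12":
        return _load_bed12(path, transcript_id)
    if format in ("gff3", "gff"):
        return _load_gff3(path, transcript_id)
    raise ValueError(f"unsupported gene-model format {format!r}")


def write_bed12(model: GeneModel, path: Union[str, Path]) -> None:
    """Serialize a model as one BED12 line (round-trips through
    :func:`load_gene_model`)."""
    ivs = sorted((e.start, e.end) for e in model.exons)
    chrom_start = ivs[0][0] - 1  # 0-based half-open
    chrom_end = ivs[-1][1]
    sizes = ",".join(str(e - s + 1) for s, e in ivs)
    starts = ",".join(str(s - 1 - chrom_start) for s, _ in ivs)
    fields = [
        model.chrom,
        str(chrom_start),
        str(chrom_end),
        model.gene_id,
        "0",
        model.strand,
        str(chrom_start),
        str(chrom_end),
        "0",
        str(len(ivs)),
        sizes,
        starts,
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")


# ----------------------------------------------------------------------
# Coordinate operations


def canonical_junctions(model: GeneModel) -> list[tuple[GenomicSite, GenomicSite]]:
    """The n-1 annotated junctions joining consecutive exons."""
    return [
        (model.donor_site(i), model.acceptor_site(i + 1))
        for i in range(1, model.n_exons)
    ]


def locate(model: GeneModel, pos: int) -> tuple[str, Optional[int]]:
    """Classify a genomic position as ``("exon", i)``, ``("intron", i)``
    or ``("outside", None)`` relative to the model."""
    lo, hi = model.span
    if pos < lo or pos > hi:
        return ("outside", None)
    for ex in model.exons:
        if ex.start <= pos <= ex.end:
            return ("exon", ex.index)
    for i in range(1, model.n_introns + 1):
        ilo, ihi = model.intron_span(i)
        if ilo <= pos <= ihi:
            return ("intron", i)
    return ("outside", None)  # pragma: no cover - span guarantees a hit


def name_intronic_position(model: GeneModel, site: Union[GenomicSite, int]) -> str:
    """Exon-relative label of an intronic position.

    A site k intronic bases 3' (transcript sense) of exon i's donor
    boundary is ``E<i>+<k>``; one k bases 5' of exon i+1's acceptor
    boundary is ``E<i+1>-<k>``. The nearer boundary wins; ties go to the
    downstream (``+``) form.
    """
    pos = site.pos if isinstance(site, GenomicSite) else int(site)
    where, idx = locate(model, pos)
    if where != "intron":
        raise ValueError(f"position {pos} is not intronic (found: {where} {idx})")
    up_exon = model.exon(idx)  # exon 5' of the intron (transcript sense)
    down_exon = model.exon(idx + 1)
    if model.strand == "+":
        k_down = pos - up_exon.end  # offset past donor boundary
        k_up = down_exon.start - pos  # offset before acceptor boundary
    else:
        k_down = up_exon.start - pos
        k_up = pos - down_exon.end
    if k_down <= k_up:
        return f"E{idx}+{k_down}"
    return f"E{idx + 1}-{k_up}"


_LABEL_RE = re.compile(r"^E(\d+)([+-])(\d+)$")


def parse_exon_relative_label(model: GeneModel, label: str) -> int:
    """Inverse of :func:`name_intronic_position`: label -> genomic position."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"malformed exon-relative label {label!r}")
    i, sign, k = int(m.group(1)), m.group(2), int(m.group(3))
    if k < 1:
        raise ValueError(f"offset must be >= 1 in {label!r}")
    ex = model.exon(i)
    if sign == "+":
        return ex.end + k if model.strand == "+" else ex.start - k
    return ex.start - k if model.strand == "+" else ex.end + k
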