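"""Splice-junction extraction and intron-centric usage metrics.

Junctions are read off the skip (``N``) operations of spliced
alignments and counted per sample into a :class:`JunctionTable`. Usage
is quantified with the intron-centric indices psi5 and psi3 — the
fraction of junction reads at a shared donor (psi5) or shared acceptor
(psi3) carried by each junction — from which event-level usage (SJ_ES
for exon skipping, SJ_PI for pseudoexon insertion, SJ_Altss for
alternative splice sites) and per-exon percent-spliced-in (PSI) are
derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .gene_model import GeneModel, canonical_junctions, locate, name_intronic_position

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionTable",
    "mark_annotated",
    "extract_junctions",
    "filter_junctions",
    "compute_psi",
    "SpliceEvent",
    "classify_junction",
    "detect_events",
    "compute_sj_usage",
    "compute_exon_psi",
    "event_usage_table",
    "annotate_dinucleotides",
]

# reference-consuming CIGAR ops that count toward an aligned anchor
_ALIGNED_OPS = {0, 7, 8}  # M, =, X
_REF_OPS = {0, 2, 7, 8}  # M, D, =, X
_SKIP_OP = 3  # N


def mark_annotated(index: pd.MultiIndex, model: GeneModel) -> pd.Series:
    """Boolean series: is each (donor, acceptor) a canonical junction?"""
    canon = {(d.pos, a.pos) for d, a in canonical_junctions(model)}
    return pd.Series([t in canon for t in index], index=index, name="annotated")


@dataclass
class JunctionTable:
    """Per-sample read counts keyed by (donor, acceptor) site positions.

    ``counts`` is indexed by a (donor, acceptor) MultiIndex with one
    integer column per sample; ``annotated`` flags canonical junctions.
    """

    chrom: str
    counts: pd.DataFrame
    annotated: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("junction counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def junctions(self) -> list[tuple[int, int]]:
        return list(self.counts.index)

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.reset_index()
        df.insert(0, "chrom", self.chrom)
        df.insert(3, "annotated", self.annotated.values)
        return df

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "JunctionTable":
        df = pd.read_csv(path, sep="\t")
        chrom = str(df.pop("chrom").iloc[0])
        annotated = df.pop("annotated").astype(bool)
        counts = df.set_index(["donor", "acceptor"])
        annotated.index = counts.index
        return cls(chrom=chrom, counts=counts, annotated=annotated)


# ----------------------------------------------------------------------
# Extraction


def _junctions_of_read(read: pysam.AlignedSegment, min_anchor: int) -> list[tuple[int, int]]:
    """Genomic (intron_lo, intron_hi) spans of anchored skips in one read."""
    out = []
    ref = read.reference_start  # 0-based
    # split the cigar into aligned stretches separated by skips
    blocks: list[int] = [0]  # aligned length per inter-skip block
    introns: list[tuple[int, int]] = []
    for op, length in read.cigartuples or ():
        if op == _SKIP_OP:
            introns.append((ref + 1, ref + length))  # 1-based inclusive
            ref += length
            blocks.append(0)
            continue
        if op in _REF_OPS:
            ref += length
        if op in _ALIGNED_OPS:
            blocks[-1] += length
    for i, (lo, hi) in enumerate(introns):
        if blocks[i] >= min_anchor and blocks[i + 1] >= min_anchor:
            out.append((lo, hi))
    return out


def extract_junctions(
    alignments: Union[str, Path, Mapping[str, Union[str, Path]]],
    model: GeneModel,
    min_anchor: int = 8,
) -> JunctionTable:
    """Count splice junctions per sample from spliced SAM/BAM alignments.

    Each skip operation in a primary alignment contributes one count to
    its junction, provided the read aligns at least ``min_anchor`` bases
    on both sides of the gap; a read spanning k junctions contributes to
    all k. Junction keys are (donor, acceptor) site positions in
    transcript orientation (the first and last base of the removed
    region, ordered by strand).

    ``alignments`` is a single path (sample named after the file stem)
    or a mapping of sample id to path.
    """
    if not isinstance(alignments, Mapping):
        alignments = {Path(alignments).stem: alignments}
    minus = model.strand == "-"
    per_sample: dict[str, dict[tuple[int, int], int]] = {}
    for sample, path in alignments.items():
        tally = {"used": 0, "skipped": 0}
        counts: dict[tuple[int, int], int] = {}
        mode = "rb" if str(path).endswith(".bam") else "r"
        with pysam.AlignmentFile(str(path), mode) as sam:
            for read in sam:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    tally["skipped"] += 1
                    continue
                if read.reference_name != model.chrom:
                    raise ValueError(
                        f"{sample}: read on {read.reference_name!r}, model is on {model.chrom!r}"
                    )
                tally["used"] += 1
                for lo, hi in _junctions_of_read(read, min_anchor):
                    key = (hi, lo) if minus else (lo, hi)
                    counts[key] = counts.get(key, 0) + 1
        logger.info(
            "extract_junctions[%s]: %d reads used, %d skipped, %d junctions",
            sample,
            tally["used"],
            tally["skipped"],
            len(counts),
        )
        per_sample[sample] = counts
    keys = sorted({k for c in per_sample.values() for k in c})
    index = pd.MultiIndex.from_tuples(keys, names=["donor", "acceptor"]) if keys else (
        pd.MultiIndex.from_arrays([[], []], names=["donor", "acceptor"])
    )
    df = pd.DataFrame(
        {s: [c.get(k, 0) for k in keys] for s, c in per_sample.items()},
        index=index,
        dtype=np.int64,
    )
    return JunctionTable(chrom=model.chrom, counts=df, annotated=mark_annotated(df.index, model))


def filter_junctions(
    table: JunctionTable,
    treated_samples: Sequence[str],
    min_reads: int = 5,
) -> JunctionTable:
    """Keep novel junctions covered by >= ``min_reads`` in at least one
    treated replicate; annotated junctions are always retained."""
    missing = [s for s in treated_samples if s not in table.samples]
    if missing:
        raise ValueError(f"treated samples not in table: {missing}")
    treated = table.counts[list(treated_samples)]
    keep = table.annotated | (treated >= min_reads).any(axis=1)
    dropped = int((~keep).sum())
    logger.info(
        "filter_junctions: kept %d, dropped %d (min_reads=%d over %d treated samples)",
        int(keep.sum()),
        dropped,
        min_reads,
        len(treated_samples),
    )
    return JunctionTable(
        chrom=table.chrom,
        counts=table.counts[keep],
        annotated=table.annotated[keep],
    )


# ----------------------------------------------------------------------
# Intron-centric usage


def compute_psi(table: JunctionTable) -> pd.DataFrame:
    """psi5/psi3 per junction per sample (tidy frame).

    psi5(j) = count(j) / sum of counts over junctions sharing j's donor;
    psi3(j) likewise over the shared acceptor. Zero denominators yield
    NaN (undefined), never 0/0 = 0.
    """
    long = (
        table.counts.stack()
        .rename("count")
        .rename_axis(["donor", "acceptor", "sample"])
        .reset_index()
    )
    donor_tot = long.groupby(["donor", "sample"])["count"].transform("sum")
    acc_tot = long.groupby(["acceptor", "sample"])["count"].transform("sum")
    long["psi5"] = np.where(donor_tot > 0, long["count"] / donor_tot, np.nan)
    long["psi3"] = np.where(acc_tot > 0, long["count"] / acc_tot, np.nan)
    return long


# ----------------------------------------------------------------------
# Event classification


@dataclass(frozen=True)
class SpliceEvent:
    """A classified alternative-splicing event.

    ``kind``: single_ES, multi_ES, PI, alt5ss or alt3ss. ``junctions``
    holds the defining (donor, acceptor) keys — one for skips and
    alternative sites, two (upstream, downstream) for pseudoexons.
    ``shared`` records, for alternative splice sites, which end is the
    annotated one (that side's psi index is the event usage).
    """

    kind: str
    label: str
    junctions: tuple[tuple[int, int], ...]
    exons: tuple[int, ...] = ()
    intron: Optional[int] = None
    shared: Optional[str] = None  # 'donor' | 'acceptor' (alt ss only)


def _pi_label(intron: int) -> str:
    # field convention for this gene: the intron-1 pseudoexon is PE1a
    return "PE1a" if intron == 1 else f"{intron}x"


def classify_junction(
    junction: tuple[int, int], model: GeneModel
) -> Optional[dict]:
    """Geometry of one junction against the model (internal helper).

    Returns None for canonical junctions, a dict with a ``status`` of
    ``es`` / ``novel_acceptor`` / ``novel_donor`` / ``unresolved``
    otherwise.
    """
    donor, acceptor = junction
    donor_exon = {model.donor_site(i).pos: i for i in range(1, model.n_exons)}
    acceptor_exon = {model.acceptor_site(i).pos: i for i in range(2, model.n_exons + 1)}
    di = donor_exon.get(donor)
    ai = acceptor_exon.get(acceptor)
    if di is not None and ai is not None:
        if ai == di + 1:
            return None  # canonical
        if ai > di + 1:
            return {"status": "es", "donor_exon": di, "acceptor_exon": ai}
        return {"status": "unresolved"}
    if di is not None:
        return {"status": "novel_acceptor", "donor_exon": di, "site": acceptor}
    if ai is not None:
        return {"status": "novel_donor", "acceptor_exon": ai, "site": donor}
    return {"status": "unresolved"}


def _exonic_label(model: GeneModel, exon_index: int, pos: int) -> str:
    ex = model.exon(exon_index)
    offset = (pos - ex.start + 1) if model.strand == "+" else (ex.end - pos + 1)
    return f"E{exon_index}.{offset}"


def detect_events(table: JunctionTable, model: GeneModel) -> list[SpliceEvent]:
    """Classify every non-canonical junction in the table into events.

    Exon skips come from junctions joining two annotated sites that
    bridge one or more exons. Within each intron, a lone pair of novel
    junctions enclosing an internal block is a pseudoexon insertion;
    unpaired novel ends are alternative splice sites, named by their
    exon-relative intronic position (or ``E<i>.<k>`` for exonic sites).
    Junctions matching no pattern are logged and excluded.
    """
    events: list[SpliceEvent] = []
    # PI candidates per intron: A = annotated donor -> novel acceptor,
    # B = novel donor -> annotated acceptor
    cand_a: dict[int, list[tuple[tuple[int, int], dict]]] = {}
    cand_b: dict[int, list[tuple[tuple[int, int], dict]]] = {}
    loose: list[tuple[tuple[int, int], dict, str]] = []
    for junction in table.junctions:
        info = classify_junction(junction, model)
        if info is None:
            continue
        status = info["status"]
        if status == "unresolved":
            logger.warning("unresolved junction %s excluded from event tables", junction)
            continue
        if status == "es":
            skipped = tuple(range(info["donor_exon"] + 1, info["acceptor_exon"]))
            kind = "single_ES" if len(skipped) == 1 else "multi_ES"
            label = (
                f"exon{skipped[0]}_skip"
                if len(skipped) == 1
                else f"exon{skipped[0]}-{skipped[-1]}_skip"
            )
            events.append(SpliceEvent(kind, label, (junction,), exons=skipped))
            continue
        where, idx = locate(model, info["site"])
        if status == "novel_acceptor":
            if where == "intron" and idx == info["donor_exon"]:
                cand_a.setdefault(idx, []).append((junction, info))
            else:
                loose.append((junction, info, where if where == "exon" else "intron"))
        else:  # novel_donor
            if where == "intron" and idx == info["acceptor_exon"] - 1:
                cand_b.setdefault(idx, []).append((junction, info))
            else:
                loose.append((junction, info, where if where == "exon" else "intron"))

    paired_a: set[tuple[int, int]] = set()
    paired_b: set[tuple[int, int]] = set()
    for intron in sorted(set(cand_a) & set(cand_b)):
        if len(cand_a[intron]) == 1 and len(cand_b[intron]) == 1:
            (ja, _ia), (jb, _ib) = cand_a[intron][0], cand_b[intron][0]
            novel_acc, novel_don = ja[1], jb[0]
            # the enclosed block must be non-empty in transcript orientation
            gap = (novel_don - novel_acc) if model.strand == "+" else (novel_acc - novel_don)
            if gap >= 2:
                events.append(
                    SpliceEvent("PI", _pi_label(intron), (ja, jb), intron=intron)
                )
                paired_a.add(ja)
                paired_b.add(jb)

    # everything not absorbed into a PI is an alternative splice site
    for intron, cands in cand_a.items():
        for junction, info in cands:
            if junction not in paired_a:
                loose.append((junction, info, "intron"))
    for intron, cands in cand_b.items():
        for junction, info in cands:
            if junction not in paired_b:
                loose.append((junction, info, "intron"))
    for junction, info, where in loose:
        site = info["site"]
        if info["status"] == "novel_acceptor":
            kind, shared = "alt3ss", "donor"
        else:
            kind, shared = "alt5ss", "acceptor"
        if where == "exon":
            _, exon_idx = locate(model, site)
            label = _exonic_label(model, exon_idx, site)
        else:
            label = name_intronic_position(model, site)
        events.append(
            SpliceEvent(
                kind,
                label,
                (junction,),
                intron=locate(model, site)[1] if where == "intron" else None,
                shared=shared,
            )
        )
    return events


# ----------------------------------------------------------------------
# Event-level usage and exon PSI


def _psi_lookup(psi: pd.DataFrame) -> pd.DataFrame:
    return psi.set_index(["donor", "acceptor", "sample"])


def compute_sj_usage(
    event: SpliceEvent, psi: pd.DataFrame, samples: Optional[Sequence[str]] = None
) -> pd.Series:
    """Per-sample event usage (SJ value) from the psi5/psi3 table.

    Exon skipping: mean of psi5 and psi3 of the skipping junction.
    Alternative splice site: the psi index at the annotated shared site.
    Pseudoexon: mean of psi5 of the upstream novel junction and psi3 of
    the downstream one. Undefined components are dropped from the mean;
    an event with no defined component is NaN for that sample.
    """
    lut = _psi_lookup(psi)
    if samples is None:
        samples = sorted(psi["sample"].unique())
    out = {}
    for sample in samples:
        vals: list[float] = []
        if event.kind in ("single_ES", "multi_ES"):
            j = event.junctions[0]
            row = lut.loc[(j[0], j[1], sample)] if (j[0], j[1], sample) in lut.index else None
            if row is not None:
                vals = [row["psi5"], row["psi3"]]
        elif event.kind in ("alt5ss", "alt3ss"):
            j = event.junctions[0]
            if (j[0], j[1], sample) in lut.index:
                row = lut.loc[(j[0], j[1], sample)]
                vals = [row["psi5"] if event.shared == "donor" else row["psi3"]]
        elif event.kind == "PI":
            ja, jb = event.junctions
            if (ja[0], ja[1], sample) in lut.index:
                vals.append(lut.loc[(ja[0], ja[1], sample)]["psi5"])
            if (jb[0], jb[1], sample) in lut.index:
                vals.append(lut.loc[(jb[0], jb[1], sample)]["psi3"])
        vals = [v for v in vals if not pd.isna(v)]
        out[sample] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, name=event.label)


def compute_exon_psi(
    exon_index: int, table: JunctionTable, model: GeneModel
) -> pd.DataFrame:
    """Percent-spliced-in of one exon per sample.

    PSI = (c_up + c_down) / (c_up + c_down + 2 * c_skip) for an internal
    exon, where c_up/c_down count the annotated junctions into and out
    of the exon and c_skip counts every junction bridging clear over it.
    Terminal exons use their single flank (denominator c_flank +
    c_skip). A zero denominator yields NaN with a flag.
    """
    ex = model.exon(exon_index)
    flanks: list[tuple[int, int]] = []
    if exon_index > 1:
        flanks.append(
            (model.donor_site(exon_index - 1).pos, model.acceptor_site(exon_index).pos)
        )
    if exon_index < model.n_exons:
        flanks.append(
            (model.donor_site(exon_index).pos, model.acceptor_site(exon_index + 1).pos)
        )
    t = model.tpos
    exon_t5 = t(ex.start if model.strand == "+" else ex.end)
    exon_t3 = t(ex.end if model.strand == "+" else ex.start)
    rows = []
    for sample in table.samples:
        col = table.counts[sample]
        c_inc = [int(col.get(f, 0)) for f in flanks]
        c_skip = 0
        for (d, a), n in col.items():
            if t(d) < exon_t5 and t(a) > exon_t3:
                c_skip += int(n)
        inc = sum(c_inc)
        denom = inc + len(flanks) * c_skip
        psi = inc / denom if denom > 0 else np.nan
        rows.append(
            {
                "exon": exon_index,
                "sample": sample,
                "psi": psi,
                "c_up": c_inc[0] if exon_index > 1 else np.nan,
                "c_down": c_inc[-1] if exon_index < model.n_exons else np.nan,
                "c_skip": c_skip,
                "defined": denom > 0,
            }
        )
    return pd.DataFrame(rows)


def event_usage_table(
    table: JunctionTable, model: GeneModel, events: Optional[Sequence[SpliceEvent]] = None
) -> pd.DataFrame:
    """Tidy per-event, per-sample usage: SJ value plus, for single-exon
    skips, the skipped exon's PSI. The input feed for the differential
    stage."""
    if events is None:
        events = detect_events(table, model)
    psi = compute_psi(table)
    frames = []
    for event in events:
        sj = compute_sj_usage(event, psi, samples=table.samples)
        df = sj.rename("sj").rename_axis("sample").reset_index()
        df.insert(0, "event", event.label)
        df.insert(1, "kind", event.kind)
        if event.kind == "single_ES":
            epsi = compute_exon_psi(event.exons[0], table, model)[["sample", "psi"]]
            df = df.merge(epsi, on="sample", how="left")
            df["exon"] = event.exons[0]
        else:
            df["psi"] = np.nan
            df["exon"] = np.nan
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["event", "kind", "sample", "sj", "psi", "exon"])
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# Optional annotation


def annotate_dinucleotides(
    table: JunctionTable, model: GeneModel, fasta: Union[str, Path]
) -> pd.DataFrame:
    """Donor/acceptor dinucleotides (GT..AG on the transcript strand) per
    junction, from a genome FASTA. Annotational only — never a filter."""
    from pyfaidx import Fasta

    genome = Fasta(str(fasta))
    seq = genome[table.chrom]

    def fetch(pos: int, length: int) -> str:
        return str(seq[pos - 1 : pos - 1 + length]).upper()

    comp = str.maketrans("ACGT", "TGCA")
    rows = []
    for d, a in table.junctions:
        if model.strand == "+":
            donor_di = fetch(d, 2)
            acc_di = fetch(a - 1, 2)
        else:
            donor_di = fetch(d - 1, 2).translate(comp)[::-1]
            acc_di = fetch(a, 2).translate(comp)[::-1]
        rows.append(
            {
                "donor": d,
                "acceptor": a,
                "donor_dinucleotide": donor_di,
                "acceptor_dinucleotide": acc_di,
                "canonical_gt_ag": donor_di == "GT" and acc_di == "AG",
            }
        )
    return pd.DataFrame(rows)
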