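"""Intron/exon read counting and gene-body coverage integration.

Counting follows exon-intron-split conventions for estimating pre-mRNA
(intronic) and mature-mRNA (exonic) signal from the same library:

* a read overlapping any intronic base of a gene counts as **intron**,
  including junction-spanning reads;
* a read whose aligned blocks fall entirely in exons counts as **exon**,
  and a spliced read crossing several exons of one gene counts once;
* reads not overlapping the gene count nothing for it.

Counts normalize to FPKM (reads per kilobase of feature per million
mapped reads).  Coverage integration averages a bedGraph-style track
over the gene body extended by a flank on both sides (default 10 kb),
which is how ChIP-style speckle-chromatin signal is summarized per gene.

Coordinates are 0-based half-open throughout (BED convention); GTF's
1-based closed intervals are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "ReadAlignment",
    "GeneCounts",
    "CoverageTrack",
    "assign_read",
    "count_gene",
    "count_genes",
    "normalize_counts",
    "integrate_gene_body",
    "metagene_matrix",
    "read_gtf",
    "write_gtf",
    "read_bed12",
    "write_bed12",
    "read_bedgraph",
    "write_bedgraph",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of exons on one strand.

    ``exons`` are 0-based half-open, sorted and non-overlapping; introns
    are the gaps between consecutive exons, and the gene span runs from
    the first exon start to the last exon end.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError("gene needs at least one exon")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"empty exon [{s}, {e})")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError("exons must be sorted and non-overlapping")
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        )

    @property
    def exon_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def intron_len(self) -> int:
        s, e = self.span
        return (e - s) - self.exon_len


@dataclass(frozen=True)
class ReadAlignment:
    """An aligned read as sorted, non-overlapping blocks on one chromosome."""

    chrom: str
    blocks: tuple[Interval, ...]

    def __post_init__(self) -> None:
        blocks = tuple((int(s), int(e)) for s, e in self.blocks)
        if not blocks:
            raise ValueError("read needs at least one block")
        for s, e in blocks:
            if e <= s:
                raise ValueError(f"empty block [{s}, {e})")
        for (_, e0), (s1, _) in zip(blocks, blocks[1:]):
            if s1 < e0:
                raise ValueError("blocks must be sorted and non-overlapping")
        object.__setattr__(self, "blocks", blocks)


@dataclass(frozen=True)
class GeneCounts:
    gene_id: str
    exon_reads: int
    intron_reads: int
    exon_len: int
    intron_len: int
    norm_exon: float | None = None
    norm_intron: float | None = None


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def assign_read(read: ReadAlignment, gene: GeneModel) -> str:
    """Assign a read to ``'exon'``, ``'intron'`` or ``'none'`` for one gene.

    Any aligned base overlapping an intron makes the whole read intronic
    (junction reads count as intron); a read is exonic when it touches an
    exon and no intron.  A read not overlapping the gene span is
    ``'none'``.  Bases outside the gene span are ignored, so a read
    overhanging the gene end still counts by its in-gene overlap.
    """
    if read.chrom != gene.chrom:
        return "none"
    span = gene.span
    if not any(_overlaps(b, span) for b in read.blocks):
        return "none"
    for intron in gene.introns:
        if any(_overlaps(b, intron) for b in read.blocks):
            return "intron"
    if any(any(_overlaps(b, ex) for ex in gene.exons) for b in read.blocks):
        return "exon"
    return "none"


def count_gene(reads: Iterable[ReadAlignment], gene: GeneModel) -> GeneCounts:
    """Tally intron/exon read counts for one gene (one count per read)."""
    n_exon = n_intron = 0
    for read in reads:
        cat = assign_read(read, gene)
        if cat == "exon":
            n_exon += 1
        elif cat == "intron":
            n_intron += 1
    return GeneCounts(gene.gene_id, n_exon, n_intron, gene.exon_len, gene.intron_len)


def count_genes(
    reads: Sequence[ReadAlignment], genes: Sequence[GeneModel], total_reads: int | None = None
) -> list[GeneCounts]:
    """Count every gene independently and FPKM-normalize.

    A read overlapping two genes contributes to each; ``total_reads``
    defaults to the library size ``len(reads)``.
    """
    total = len(reads) if total_reads is None else total_reads
    return [normalize_counts(count_gene(reads, g), total) for g in genes]


def normalize_counts(counts: GeneCounts, total_reads: int) -> GeneCounts:
    """Fill FPKM fields: count / (length/1e3) / (total/1e6)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")

    def fpkm(n: int, length: int) -> float:
        if length == 0:
            return 0.0
        return n / (length / 1e3) / (total_reads / 1e6)

    return replace(
        counts,
        norm_exon=fpkm(counts.exon_reads, counts.exon_len),
        norm_intron=fpkm(counts.intron_reads, counts.intron_len),
    )


# --------------------------------------------------------------------------
# coverage tracks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CoverageTrack:
    """Sorted non-overlapping scored intervals on one chromosome (bedGraph)."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.starts, dtype=np.int64)
        e = np.asarray(self.ends, dtype=np.int64)
        v = np.asarray(self.values, dtype=float)
        if not (s.size == e.size == v.size):
            raise ValueError("starts/ends/values length mismatch")
        if np.any(e <= s):
            raise ValueError("empty coverage interval")
        if s.size > 1 and np.any(s[1:] < e[:-1]):
            raise ValueError("coverage intervals must be sorted, non-overlapping")
        if np.any(v < 0):
            raise ValueError("coverage values must be >= 0")
        object.__setattr__(self, "starts", s)
        object.__setattr__(self, "ends", e)
        object.__setattr__(self, "values", v)

    def _cum_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints and cumulative integral for piecewise-linear lookup."""
        if self.starts.size == 0:
            return np.array([0.0]), np.array([0.0])
        areas = self.values * (self.ends - self.starts)
        cum = np.concatenate([[0.0], np.cumsum(areas)])
        xp = np.empty(2 * self.starts.size, dtype=float)
        fp = np.empty_like(xp)
        xp[0::2], xp[1::2] = self.starts, self.ends
        fp[0::2], fp[1::2] = cum[:-1], cum[1:]
        # drop duplicate abutting coordinates (same cumulative value)
        keep = np.concatenate([[True], np.diff(xp) > 0])
        return xp[keep], fp[keep]

    def integral(self, start: float, end: float) -> float:
        """Integral of coverage over [start, end); gaps contribute 0."""
        if end <= start:
            return 0.0
        xp, fp = self._cum_points()
        lo, hi = np.interp([start, end], xp, fp)
        return float(hi - lo)

    def mean(self, start: int, end: int) -> float:
        """Length-weighted mean over [start, end), missing bases as 0."""
        if end <= start:
            raise ValueError("empty region")
        return self.integral(start, end) / (end - start)

    def binned_means(self, edges: np.ndarray) -> np.ndarray:
        """Mean coverage in each bin defined by monotone ``edges``."""
        xp, fp = self._cum_points()
        cum = np.interp(edges, xp, fp)
        widths = np.diff(edges)
        return np.diff(cum) / widths


def integrate_gene_body(
    track: CoverageTrack,
    gene: GeneModel,
    flank: int = 10_000,
    chrom_length: int | None = None,
) -> float:
    """Mean track signal over the gene body plus ``flank`` bp on each side.

    The region runs from ``flank`` upstream of the TSS to ``flank``
    downstream of the TTS in genomic coordinates (strand only relabels
    which end is which), clipped at chromosome bounds.
    """
    s, e = gene.span
    lo = max(0, s - flank)
    hi = e + flank
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    if hi <= lo:
        return 0.0
    return track.mean(lo, hi)


def metagene_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    bins_flank: int = 50,
    bins_body: int = 200,
    flank: int = 10_000,
) -> np.ndarray:
    """Per-gene binned coverage: flank | length-scaled body | flank.

    Rows of minus-strand genes are reversed so the TSS is always on the
    left and the TTS-proximal flank on the right.
    """
    n_cols = 2 * bins_flank + bins_body
    out = np.zeros((len(genes), n_cols))
    for i, gene in enumerate(genes):
        s, e = gene.span
        edges = np.concatenate(
            [
                np.linspace(s - flank, s, bins_flank + 1)[:-1],
                np.linspace(s, e, bins_body + 1)[:-1],
                np.linspace(e, e + flank, bins_flank + 1),
            ]
        )
        row = track.binned_means(edges)
        if gene.strand == "-":
            row = row[::-1]
        out[i] = row
    return out


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------


def read_gtf(path) -> list[GeneModel]:
    """Load gene models from a GTF file (exon features grouped by gene_id)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes["gene_id"][0]
        rec = by_gene.setdefault(gid, {"chrom": feat.seqid, "strand": feat.strand, "exons": []})
        # GTF is 1-based closed; convert to 0-based half-open
        rec["exons"].append((feat.start - 1, feat.end))
    genes = []
    for gid, rec in by_gene.items():
        exons = sorted(rec["exons"])
        genes.append(GeneModel(gid, rec["chrom"], rec["strand"], tuple(exons)))
    return genes


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.span
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\tchronospeckle\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for xs, xe in g.exons:
                fh.write(
                    f"{g.chrom}\tchronospeckle\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_bed12(path) -> list[ReadAlignment]:
    """Load block-structured reads from a BED12 file."""
    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start = f[0], int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
            reads.append(ReadAlignment(chrom, blocks))
    return reads


def write_bed12(reads: Sequence[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            start = r.blocks[0][0]
            end = r.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            offsets = ",".join(str(s - start) for s, _ in r.blocks)
            fh.write(
                f"{r.chrom}\t{start}\t{end}\tread{i}\t0\t+\t{start}\t{end}\t0\t"
                f"{len(r.blocks)}\t{sizes}\t{offsets}\n"
            )


def read_bedgraph(path) -> dict[str, CoverageTrack]:
    """Load bedGraph coverage, one track per chromosome."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    df = df[~df["chrom"].astype(str).str.startswith(("track", "browser"))]
    tracks = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        tracks[str(chrom)] = CoverageTrack(
            str(chrom),
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["value"].to_numpy(float),
        )
    return tracks


def write_bedgraph(tracks: Mapping[str, CoverageTrack] | CoverageTrack, path) -> None:
    if isinstance(tracks, CoverageTrack):
        tracks = {tracks.chrom: tracks}
    with open(path, "w") as fh:
        for chrom in tracks:
            t = tracks[chrom]
            for s, e, v in zip(t.starts, t.ends, t.values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
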