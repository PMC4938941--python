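"""Genomic context of array probes: region labels, CGI status, CpG density,
distances to assembly gaps, and track-smoothing utilities.

Conventions: probe positions are 1-based single-bp sites; every interval
track (transcripts, CGIs, gaps, peaks, states) is 0-based half-open as in
BED.  Conversions happen at this module's boundary only.

Region labels are mutually exclusive with precedence
Promoter > 5UTR > 3UTR > FirstExon > Exon > Intron, defaulting to Intergenic.
The promoter is the 2 kb window upstream of the TSS, strand-aware.  A probe
both upstream of one gene and inside another is a Promoter: the promoter
window outranks all transcript-internal labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import TrackError

logger = logging.getLogger(__name__)

REGION_LABELS = ("Promoter", "5UTR", "3UTR", "FirstExon", "Exon", "Intron", "Intergenic")
CGI_LABELS = ("CGI", "shore", "shelf", "nonCGI")

PROMOTER_BP = 2000
SHORE_BP = 2000
SHELF_BP = 2000


@dataclass
class Transcript:
    """A transcript model: exon blocks plus an optional CDS for UTR calls.

    Coordinates are 0-based half-open.  ``exons`` are (start, end) pairs in
    genomic order; ``cds`` is (thick_start, thick_end) or None for
    non-coding transcripts (whole transcript treated as exon/intron only).
    """

    chrom: str
    start: int
    end: int
    strand: str
    exons: list
    cds: tuple | None = None
    name: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise TrackError(f"transcript {self.name}: bad strand {self.strand!r}")
        if not self.exons:
            raise TrackError(f"transcript {self.name}: no exons")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise TrackError(f"transcript {self.name}: exon [{s},{e}) outside bounds")
            if prev_end is not None and s < prev_end:
                raise TrackError(f"transcript {self.name}: overlapping/unsorted exons")
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.start <= cs <= ce <= self.end):
                raise TrackError(f"transcript {self.name}: CDS outside bounds")

    @property
    def tss(self) -> int:
        """TSS as a 0-based coordinate (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1


def transcripts_from_bed12(df: pd.DataFrame) -> list[Transcript]:
    """Build transcript models from a 12-column BED frame (blocks = exons,
    thickStart/thickEnd = CDS; thickStart == thickEnd means non-coding)."""
    out = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = [(start + off, start + off + size) for off, size in zip(starts, sizes)]
        thick = (int(row.thick_start), int(row.thick_end))
        cds = None if thick[0] == thick[1] else thick
        out.append(
            Transcript(
                chrom=row.chrom, start=start, end=end, strand=row.strand,
                exons=exons, cds=cds, name=str(row.name),
            )
        )
    return out


def _transcript_labeled_intervals(tx: Transcript):
    """Decompose one transcript into labeled half-open intervals.

    UTR portions of exons get 5UTR/3UTR; the strand-aware first exon's
    non-UTR remainder is FirstExon; other exonic remainders are Exon;
    non-exonic transcript body is Intron; plus the 2 kb promoter window.
    """
    ivs = []
    if tx.strand == "+":
        prom = (max(0, tx.start - PROMOTER_BP), tx.start)
    else:
        prom = (tx.end, tx.end + PROMOTER_BP)
    if prom[0] < prom[1]:
        ivs.append((prom[0], prom[1], "Promoter"))

    if tx.cds is None:
        utr5 = utr3 = None
    else:
        cs, ce = tx.cds
        if tx.strand == "+":
            utr5, utr3 = (tx.start, cs), (ce, tx.end)
        else:
            utr5, utr3 = (ce, tx.end), (tx.start, cs)

    first_exon = tx.exons[0] if tx.strand == "+" else tx.exons[-1]

    def clip(seg, within):
        s = max(seg[0], within[0])
        e = min(seg[1], within[1])
        return (s, e) if s < e else None

    for exon in tx.exons:
        remaining = [exon]
        for utr, label in ((utr5, "5UTR"), (utr3, "3UTR")):
            if utr is None:
                continue
            piece = clip(exon, utr)
            if piece:
                ivs.append((piece[0], piece[1], label))
                new_remaining = []
                for seg in remaining:
                    if seg[1] <= piece[0] or seg[0] >= piece[1]:
                        new_remaining.append(seg)
                        continue
                    if seg[0] < piece[0]:
                        new_remaining.append((seg[0], piece[0]))
                    if piece[1] < seg[1]:
                        new_remaining.append((piece[1], seg[1]))
                remaining = new_remaining
        label = "FirstExon" if exon == first_exon else "Exon"
        for seg in remaining:
            ivs.append((seg[0], seg[1], label))

    # introns: transcript span minus exons
    prev = tx.start
    for s, e in tx.exons:
        if prev < s:
            ivs.append((prev, s, "Intron"))
        prev = e
    if prev < tx.end:
        ivs.append((prev, tx.end, "Intron"))
    return ivs


class RegionIndex:
    """Per-chromosome interval tree of labeled transcript regions."""

    def __init__(self, transcripts):
        self._trees: dict[str, IntervalTree] = {}
        self._rank = {lab: i for i, lab in enumerate(REGION_LABELS)}
        for tx in transcripts:
            tree = self._trees.setdefault(tx.chrom, IntervalTree())
            for s, e, label in _transcript_labeled_intervals(tx):
                tree.addi(s, e, label)

    def label(self, chrom: str, pos: int) -> str:
        """Region label for a 1-based probe position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return "Intergenic"
        hits = tree[pos - 1]
        if not hits:
            return "Intergenic"
        return min((h.data for h in hits), key=self._rank.__getitem__)


def assign_region(probes: pd.DataFrame, transcripts) -> pd.Series:
    """Region label per probe (frame with ``chrom`` and 1-based ``pos``)."""
    index = transcripts if isinstance(transcripts, RegionIndex) else RegionIndex(transcripts)
    labels = [index.label(c, p) for c, p in zip(probes["chrom"], probes["pos"])]
    return pd.Series(pd.Categorical(labels, categories=REGION_LABELS), index=probes.index, name="region")


def _nearest_interval_distance(pos0: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """bp from a 0-based point to the nearest of a set of half-open intervals
    (0 if inside any)."""
    d = np.maximum.reduce([starts - pos0, pos0 - (ends - 1), np.zeros_like(starts)])
    return int(d.min())


def assign_cgi_status(
    probes: pd.DataFrame, cgis: pd.DataFrame, shore_bp: int = SHORE_BP, shelf_bp: int = SHELF_BP
) -> pd.Series:
    """CGI / shore / shelf / nonCGI per probe, by distance to the nearest island.

    Shores are the ``shore_bp`` regions flanking an island, shelves the next
    ``shelf_bp`` beyond each shore.  Using the distance to the *nearest*
    island makes the precedence CGI > shore > shelf automatic when the flanks
    of two islands overlap.
    """
    by_chrom = {
        c: (g["start"].to_numpy(), g["end"].to_numpy()) for c, g in cgis.groupby("chrom")
    }
    out = []
    for chrom, pos in zip(probes["chrom"], probes["pos"]):
        arrs = by_chrom.get(chrom)
        if arrs is None:
            out.append("nonCGI")
            continue
        d = _nearest_interval_distance(pos - 1, arrs[0], arrs[1])
        if d == 0:
            out.append("CGI")
        elif d <= shore_bp:
            out.append("shore")
        elif d <= shore_bp + shelf_bp:
            out.append("shelf")
        else:
            out.append("nonCGI")
    return pd.Series(pd.Categorical(out, categories=CGI_LABELS), index=probes.index, name="cgi_status")


def cpg_density(window_seq: str) -> float:
    """CpG density of a sequence window: count of 'CG' dinucleotides divided
    by the maximum possible, floor(len/2).  Case-insensitive."""
    seq = window_seq.upper()
    if len(seq) < 2:
        return 0.0
    n_cg = sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")
    return n_cg / (len(seq) // 2)


def probe_cpg_density(
    genome: dict[str, str], chrom: str, pos: int, window: int = 2000
) -> tuple[float, bool]:
    """Density in a ``window`` bp window centered on a 1-based probe position.

    Windows truncated at a chromosome end are computed on the truncated
    length and flagged (second return value True).
    """
    seq = genome[chrom]
    half = window // 2
    lo = (pos - 1) - half
    hi = (pos - 1) + half
    truncated = lo < 0 or hi > len(seq)
    lo, hi = max(0, lo), min(len(seq), hi)
    return cpg_density(seq[lo:hi]), truncated


def gap_distances(probes: pd.DataFrame, gaps: pd.DataFrame) -> pd.DataFrame:
    """Distance (bp) from each probe to the nearest centromere and telomere
    edge on its chromosome; 0 if the probe lies inside the gap interval.

    ``gaps`` is a BED-like frame with a ``name`` column holding
    'centromere' or 'telomere'.  A chromosome lacking a centromere record
    yields NaN for that probe (logged once per chromosome).
    """
    cen = {c: (g["start"].to_numpy(), g["end"].to_numpy())
           for c, g in gaps[gaps["name"] == "centromere"].groupby("chrom")}
    tel = {c: (g["start"].to_numpy(), g["end"].to_numpy())
           for c, g in gaps[gaps["name"] == "telomere"].groupby("chrom")}
    warned = set()
    d_cen, d_tel = [], []
    for chrom, pos in zip(probes["chrom"], probes["pos"]):
        pos0 = pos - 1
        if chrom in cen:
            d_cen.append(_nearest_interval_distance(pos0, *cen[chrom]))
        else:
            if chrom not in warned:
                logger.warning("chromosome %s has no centromere record", chrom)
                warned.add(chrom)
            d_cen.append(np.nan)
        if chrom in tel:
            d_tel.append(_nearest_interval_distance(pos0, *tel[chrom]))
        else:
            d_tel.append(np.nan)
    return pd.DataFrame({"dist_centromere": d_cen, "dist_telomere": d_tel}, index=probes.index)


def smooth_track(
    track: pd.DataFrame, chrom_sizes: dict[str, int], bin_size: int = 100_000
) -> pd.DataFrame:
    """Average scored peaks into fixed genomic bins for circular plots.

    Each ``bin_size`` bin receives the mean score of all peaks overlapping it
    (any overlap: a peak spanning two bins contributes its full score to
    both); bins with no peak get NaN.
    """
    rows = []
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / bin_size))
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        sub = track[track["chrom"] == chrom]
        for s, e, score in zip(sub["start"], sub["end"], sub["score"]):
            b0 = int(s) // bin_size
            b1 = (int(e) - 1) // bin_size
            for b in range(b0, min(b1, n_bins - 1) + 1):
                sums[b] += score
                counts[b] += 1
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        for b in range(n_bins):
            rows.append((chrom, b * bin_size, min((b + 1) * bin_size, size), means[b]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def enlarge_sites(
    positions: pd.DataFrame, width: int = 200_000, chrom_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Turn point sites into ``width`` bp intervals centered on each site
    (for visualisation tracks), clipped to chromosome bounds when sizes are
    given."""
    half = width // 2
    start = positions["pos"].to_numpy() - half
    end = positions["pos"].to_numpy() + half
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        limits = positions["chrom"].map(chrom_sizes).to_numpy()
        end = np.minimum(end, limits)
    return pd.DataFrame(
        {"chrom": positions["chrom"].to_numpy(), "start": start.astype(int), "end": end.astype(int)},
        index=positions.index,
    )


def probes_in_track(probes: pd.DataFrame, track: pd.DataFrame) -> pd.Series:
    """Boolean membership: probe position contained in any interval of the
    track (single-bp probe convention, half-open intervals)."""
    trees = {}
    for c, g in track.groupby("chrom"):
        tree = IntervalTree()
        for s, e in zip(g["start"], g["end"]):
            if s < e:
                tree.addi(int(s), int(e))
        trees[c] = tree
    member = [
        bool(trees[c][p - 1]) if c in trees else False
        for c, p in zip(probes["chrom"], probes["pos"])
    ]
    return pd.Series(member, index=probes.index)


def annotate_probes(
    probes: pd.DataFrame,
    transcripts,
    cgis: pd.DataFrame,
    gaps: pd.DataFrame,
    genome: dict[str, str] | None = None,
    window: int = 2000,
) -> pd.DataFrame:
    """Full ProbeContext table: region, cgi_status, cpg_density (when a
    genome sequence is available), and gap distances, indexed like ``probes``."""
    ctx = pd.DataFrame(index=probes.index)
    ctx["region"] = assign_region(probes, transcripts)
    ctx["cgi_status"] = assign_cgi_status(probes, cgis)
    if genome is not None:
        dens = [
            probe_cpg_density(genome, c, p, window)[0]
            for c, p in zip(probes["chrom"], probes["pos"])
        ]
        ctx["cpg_density"] = dens
    dists = gap_distances(probes, gaps)
    ctx["dist_centromere"] = dists["dist_centromere"]
    ctx["dist_telomere"] = dists["dist_telomere"]
    return ctx
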