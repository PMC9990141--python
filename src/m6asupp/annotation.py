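"""Transcript models and exon-architecture annotation of m6A sites.

This module is the coordinate engine of the package.  A
:class:`TranscriptModel` holds the exon/CDS structure of a single transcript
and provides bijective maps between transcript coordinates (0-based offsets
along the spliced mRNA) and genomic coordinates (0-based, half-open).  On
top of that sit the architecture quantities used throughout the analysis of
m6A suppression: exon class (first / internal / last / single-exon),
distances to the flanking splice sites, metagene coordinates (5'UTR, CDS and
3'UTR each scaled to unit length), positions of exon junction complexes
(EJCs, deposited ~24 nt upstream of exon-exon junctions), distance to the
nearest EJC, and EJC density (exons overlapping the CDS per kb of CDS).

Conventions
-----------
* All internal coordinates are 0-based, half-open.  GTF input (1-based,
  closed) is converted on load; BED output stays 0-based half-open.
* Exon lists are ordered 5'->3' in *transcript* orientation: descending
  genomic coordinates on the minus strand.
* "Internal exon" means any exon that is neither first nor last of its
  transcript.  For length statistics, exons shared by several transcripts
  are deduplicated by genomic interval to avoid isoform-weighted bias.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class GtfParseError(ValueError):
    """A GTF record could not be parsed."""


class TranscriptValidationError(ValueError):
    """A transcript's features are internally inconsistent."""


class NoncodingTranscriptError(ValueError):
    """An operation requiring a CDS was applied to a non-coding transcript."""


@dataclass(frozen=True)
class ArchitectureConstants:
    """Fixed architecture parameters (all in nucleotides).

    ejc_offset
        EJCs are deposited ~24 nt upstream of exon-exon junctions.
    last_exon_proximal
        The characteristic m6A density peak near stop codons corresponds to
        enrichment within 150 nt past the start of last exons.
    long_exon_p90_reference / short_exon_p10_reference
        Reference 90th/10th percentiles of human internal-exon lengths
        (246 nt and 60 nt): 90% of internal exons are shorter than 246 nt.
    """

    ejc_offset: int = 24
    last_exon_proximal: int = 150
    long_exon_p90_reference: int = 246
    short_exon_p10_reference: int = 60

    def __post_init__(self) -> None:
        for name in ("ejc_offset", "last_exon_proximal",
                     "long_exon_p90_reference", "short_exon_p10_reference"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a strictly positive integer, got {v!r}")


CONSTANTS = ArchitectureConstants()


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    Parameters
    ----------
    exons
        Genomic intervals (0-based, half-open), ordered 5'->3' in transcript
        orientation.  On the minus strand this means descending genomic
        coordinates.
    cds_start, cds_end
        CDS bounds in *transcript* coordinates (0-based, half-open), or
        ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None
    # transcript-coordinate start of each exon, precomputed for bisection
    _tstarts: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TranscriptValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise TranscriptValidationError(f"{self.transcript_id}: no exons")
        for s, e in self.exons:
            if not 0 <= s < e:
                raise TranscriptValidationError(
                    f"{self.transcript_id}: bad exon interval [{s},{e})")
        gsorted = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(gsorted, gsorted[1:]):
            if s2 < e1:
                raise TranscriptValidationError(
                    f"{self.transcript_id}: overlapping exons [{s1},{e1}) and [{s2},{e2})")
        expected = gsorted if self.strand == "+" else gsorted[::-1]
        if list(self.exons) != expected:
            raise TranscriptValidationError(
                f"{self.transcript_id}: exons not ordered 5'->3' for strand {self.strand}")
        lengths = [e - s for s, e in self.exons]
        tstarts = [0]
        for ln in lengths[:-1]:
            tstarts.append(tstarts[-1] + ln)
        object.__setattr__(self, "_tstarts", tuple(tstarts))
        if (self.cds_start is None) != (self.cds_end is None):
            raise TranscriptValidationError(
                f"{self.transcript_id}: cds_start/cds_end must both be set or both absent")
        if self.cds_start is not None:
            if not 0 <= self.cds_start < self.cds_end <= self.length:
                raise TranscriptValidationError(
                    f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                    f"outside transcript of length {self.length}")

    # ------------------------------------------------------------------
    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return self._tstarts[-1] + (self.exons[-1][1] - self.exons[-1][0])

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def junctions(self) -> tuple[int, ...]:
        """Transcript coordinates of exon-exon junctions (first base of each
        downstream exon)."""
        return self._tstarts[1:]

    # ------------------------------------------------------------------
    def _exon_index(self, pos: int) -> int:
        if not 0 <= pos < self.length:
            raise IndexError(
                f"{self.transcript_id}: position {pos} outside [0,{self.length})")
        return bisect.bisect_right(self._tstarts, pos) - 1

    def map_to_genome(self, pos: int) -> int:
        """Transcript coordinate -> genomic coordinate."""
        i = self._exon_index(pos)
        off = pos - self._tstarts[i]
        s, e = self.exons[i]
        return s + off if self.strand == "+" else e - 1 - off

    def map_to_transcript(self, gpos: int) -> int:
        """Genomic coordinate -> transcript coordinate.

        Raises :class:`IndexError` for intronic / outside positions, which
        have no transcript image.
        """
        for i, (s, e) in enumerate(self.exons):
            if s <= gpos < e:
                off = gpos - s if self.strand == "+" else e - 1 - gpos
                return self._tstarts[i] + off
        raise IndexError(
            f"{self.transcript_id}: genomic position {gpos} not exonic")

    def transcript_interval_to_genomic(self, ts: int, te: int) -> list[tuple[int, int]]:
        """Map a transcript-coordinate interval [ts, te) to a list of genomic
        intervals (0-based half-open, sorted by genomic start)."""
        if not 0 <= ts < te <= self.length:
            raise IndexError(f"{self.transcript_id}: bad interval [{ts},{te})")
        pieces = []
        for i, (s, e) in enumerate(self.exons):
            a = max(ts, self._tstarts[i])
            b = min(te, self._tstarts[i] + (e - s))
            if a >= b:
                continue
            if self.strand == "+":
                pieces.append((s + (a - self._tstarts[i]), s + (b - self._tstarts[i])))
            else:
                pieces.append((e - (b - self._tstarts[i]), e - (a - self._tstarts[i])))
        return sorted(pieces)


@dataclass(frozen=True)
class SiteArchitecture:
    """Exon-architecture annotation of one transcript position."""

    exon_class: str                 # first | internal | last | single_exon
    exon_length: int
    dist_3ss: int | None            # nt to upstream (3') splice site
    dist_5ss: int | None            # nt to downstream (5') splice site
    region_class: str               # 5UTR | CDS | 3UTR | noncoding
    metagene_coord: float | None    # in [0,3); None for noncoding
    last_exon_offset: int | None    # nt past last-exon start
    dist_nearest_ejc: int | None    # None for EJC-free transcripts

    @property
    def last_exon_proximal(self) -> bool | None:
        """True when the site lies within 150 nt past the last-exon start."""
        if self.last_exon_offset is None:
            return None
        return self.last_exon_offset < CONSTANTS.last_exon_proximal


# ----------------------------------------------------------------------
# GTF loading
# ----------------------------------------------------------------------

def load_gtf(path: str) -> dict[str, TranscriptModel]:
    """Parse a GTF file into a dict of transcript_id -> TranscriptModel.

    Exon and (optional) CDS features carrying ``transcript_id`` and
    ``gene_id`` attributes are required.  Coordinates are converted from
    GTF's 1-based closed convention to internal 0-based half-open; CDS
    features are converted into transcript coordinates.  Minus-strand exon
    lists are reversed into 5'->3' transcript order.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises a zoo of error types
        raise GtfParseError(f"cannot parse GTF {path!r}: {exc}") from exc

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise GtfParseError(
                f"{path}: {feat.featuretype} at {feat.seqid}:{feat.start} "
                f"lacks transcript_id/gene_id") from exc
        iv = (feat.start - 1, feat.end)  # 1-based closed -> 0-based half-open
        prev = meta.get(tid)
        if prev is not None and prev[:2] != (feat.seqid, feat.strand):
            raise TranscriptValidationError(
                f"{tid}: features on mixed chrom/strand "
                f"({prev[0]}/{prev[1]} vs {feat.seqid}/{feat.strand})")
        meta[tid] = (feat.seqid, feat.strand, gid)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    models: dict[str, TranscriptModel] = {}
    for tid, ivs in exons.items():
        chrom, strand, gid = meta[tid]
        ordered = sorted(ivs)
        if strand == "-":
            ordered = ordered[::-1]
        t = TranscriptModel(tid, gid, chrom, strand, tuple(ordered))
        if tid in cds:
            tcoords = []
            for s, e in cds[tid]:
                a = t.map_to_transcript(s)
                b = t.map_to_transcript(e - 1)
                tcoords.extend((min(a, b), max(a, b)))
            t = TranscriptModel(tid, gid, chrom, strand, tuple(ordered),
                                cds_start=min(tcoords), cds_end=max(tcoords) + 1)
        models[tid] = t
    return models


# ----------------------------------------------------------------------
# Architecture operations
# ----------------------------------------------------------------------

def ejc_sites(t: TranscriptModel,
              ejc_offset: int = CONSTANTS.ejc_offset) -> list[int]:
    """Transcript coordinates of EJC deposition sites.

    One position per exon-exon junction, ``ejc_offset`` nt upstream of the
    junction, clamped so it never falls before the start of the upstream
    exon (relevant for exons shorter than the offset).  Single-exon
    transcripts carry no EJC.
    """
    out = []
    for i, j in enumerate(t.junctions):
        upstream_exon_start = t._tstarts[i]
        out.append(max(j - ejc_offset, upstream_exon_start))
    return out


def dist_to_nearest_ejc(t: TranscriptModel, pos: int,
                        ejc_offset: int = CONSTANTS.ejc_offset) -> int | None:
    """Distance (nt) from ``pos`` to the nearest EJC site; None if the
    transcript has no junctions."""
    if not 0 <= pos < t.length:
        raise IndexError(f"{t.transcript_id}: position {pos} out of range")
    sites = ejc_sites(t, ejc_offset)
    if not sites:
        return None
    return min(abs(pos - e) for e in sites)


def region_class(t: TranscriptModel, pos: int) -> str:
    if not t.is_coding:
        return "noncoding"
    if pos < t.cds_start:
        return "5UTR"
    if pos < t.cds_end:
        return "CDS"
    return "3UTR"


def metagene_coordinate(t: TranscriptModel, pos: int) -> float:
    """Map a transcript position to the metagene axis [0,3).

    5'UTR -> [0,1), CDS -> [1,2), 3'UTR -> [2,3), linearly within each
    segment; ``pos == cds_start`` maps to exactly 1.0 and ``pos == cds_end``
    (first base after the stop) to exactly 2.0.
    """
    if not t.is_coding:
        raise NoncodingTranscriptError(
            f"{t.transcript_id}: metagene coordinate requires a CDS")
    if not 0 <= pos < t.length:
        raise IndexError(f"{t.transcript_id}: position {pos} out of range")
    cs, ce = t.cds_start, t.cds_end
    if pos < cs:
        return pos / cs
    if pos < ce:
        return 1.0 + (pos - cs) / (ce - cs)
    return 2.0 + (pos - ce) / (t.length - ce)


def classify_site(t: TranscriptModel, pos: int,
                  ejc_offset: int = CONSTANTS.ejc_offset) -> SiteArchitecture:
    """Full architecture annotation of a transcript position."""
    i = t._exon_index(pos)
    n = t.n_exons
    if n == 1:
        exon_class = "single_exon"
    elif i == 0:
        exon_class = "first"
    elif i == n - 1:
        exon_class = "last"
    else:
        exon_class = "internal"
    estart = t._tstarts[i]
    elen = t.exon_lengths[i]
    # splice-site distances exist only where the exon boundary is a junction
    dist_3ss = pos - estart if i > 0 else None
    dist_5ss = estart + elen - 1 - pos if i < n - 1 else None
    last_off = pos - t._tstarts[-1] if i == n - 1 else None
    rc = region_class(t, pos)
    mg = metagene_coordinate(t, pos) if t.is_coding else None
    return SiteArchitecture(
        exon_class=exon_class, exon_length=elen,
        dist_3ss=dist_3ss, dist_5ss=dist_5ss,
        region_class=rc, metagene_coord=mg,
        last_exon_offset=last_off,
        dist_nearest_ejc=dist_to_nearest_ejc(t, pos, ejc_offset),
    )


def ejc_density(t: TranscriptModel) -> float:
    """Exons overlapping the CDS per kb of CDS — a proxy for EJC loading."""
    if not t.is_coding or t.cds_end - t.cds_start <= 0:
        raise NoncodingTranscriptError(
            f"{t.transcript_id}: EJC density requires a CDS")
    cs, ce = t.cds_start, t.cds_end
    n_overlap = 0
    for i, ln in enumerate(t.exon_lengths):
        ts, te = t._tstarts[i], t._tstarts[i] + ln
        if ts < ce and te > cs:
            n_overlap += 1
    return n_overlap / ((ce - cs) / 1000.0)


def internal_exon_length_stats(models: Iterable[TranscriptModel],
                               percentiles: Sequence[float] = (10, 50, 90),
                               ) -> dict[float, float]:
    """Percentiles of internal-exon lengths across an annotation.

    Exons shared by multiple transcripts are counted once (deduplicated by
    genomic interval and strand).
    """
    seen: set[tuple[str, int, int, str]] = set()
    lengths: list[int] = []
    for t in models:
        for s, e in t.exons[1:-1]:
            key = (t.chrom, s, e, t.strand)
            if key not in seen:
                seen.add(key)
                lengths.append(e - s)
    if not lengths:
        raise ValueError("no internal exons in the supplied models")
    vals = np.percentile(np.asarray(lengths, dtype=float), list(percentiles))
    return {p: float(v) for p, v in zip(percentiles, vals)}


# ----------------------------------------------------------------------
# Tabular outputs
# ----------------------------------------------------------------------

def site_architecture_table(models: Mapping[str, TranscriptModel],
                            sites: pd.DataFrame) -> pd.DataFrame:
    """One annotated row per site.

    ``sites`` needs columns ``transcript_id`` and ``pos`` (transcript
    coordinates); all other columns are passed through.
    """
    rows = []
    for rec in sites.itertuples(index=False):
        t = models[rec.transcript_id]
        arch = classify_site(t, int(rec.pos))
        try:
            dens = ejc_density(t)
        except NoncodingTranscriptError:
            dens = None
        rows.append({
            "transcript_id": rec.transcript_id,
            "pos": int(rec.pos),
            "exon_class": arch.exon_class,
            "exon_length": arch.exon_length,
            "dist_3ss": arch.dist_3ss,
            "dist_5ss": arch.dist_5ss,
            "region_class": arch.region_class,
            "metagene_coord": arch.metagene_coord,
            "last_exon_offset": arch.last_exon_offset,
            "dist_nearest_ejc": arch.dist_nearest_ejc,
            "ejc_density": dens,
        })
    return pd.DataFrame(rows)


def ejc_sites_bed(models: Mapping[str, TranscriptModel],
                  ejc_offset: int = CONSTANTS.ejc_offset) -> pd.DataFrame:
    """BED6 table of EJC deposition sites in genomic coordinates."""
    rows = []
    for t in models.values():
        for e in ejc_sites(t, ejc_offset):
            g = t.map_to_genome(e)
            rows.append({"chrom": t.chrom, "start": g, "end": g + 1,
                         "name": t.transcript_id, "score": 0, "strand": t.strand})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
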