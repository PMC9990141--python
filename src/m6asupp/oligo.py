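"""Reporter-library design: DRACH scanning, 102-nt windows, knockout controls.

m6A is installed in a DRACH motif (D = A/G/U, R = A/G, then the methylated
A, then C, then H = A/C/U; 18 concrete 5-mers).  For each candidate site the
assay uses a 102-nt window around the central A (51 nt upstream, the A, 50
nt downstream) as the experimental sequence, paired with a negative control
in which every DRACH central A has been substituted so the control carries
no methylatable motif at all.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

WINDOW_SIZE = 102
UPSTREAM_FLANK = 51   # bases before the central A
DOWNSTREAM_FLANK = 50  # bases after the central A

#: The 18 concrete DRACH 5-mers (RNA alphabet).
DRACH_MOTIFS: frozenset[str] = frozenset(
    "".join(m) for m in product("AGU", "AG", "A", "C", "ACU")
)

_DRACH_RE = re.compile(r"(?=([AGU][AG]AC[ACU]))")
_VALID_RE = re.compile(r"^[ACGU]*$")


class AlphabetError(ValueError):
    """Sequence contains characters outside A/C/G/U(T)."""


class DesignError(ValueError):
    """A reporter window cannot be designed for this site."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; reject other characters."""
    s = seq.upper().replace("T", "U")
    if not _VALID_RE.match(s):
        bad = sorted(set(s) - set("ACGU"))
        raise AlphabetError(f"invalid characters in sequence: {bad}")
    return s


def to_dna(seq: str) -> str:
    """RNA -> DNA alphabet for FASTA output (synthesis convention)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class DrachSite:
    """A candidate methylation site: the central A of a DRACH motif."""

    transcript_id: str
    pos: int                # transcript coordinate of the central A
    motif: str              # the 5-mer, RNA alphabet
    endogenous_status: str = "unknown"   # methylated | unmethylated | unknown

    def __post_init__(self) -> None:
        if self.motif not in DRACH_MOTIFS:
            raise ValueError(f"{self.motif!r} is not a DRACH 5-mer")
        if self.pos < 2:
            raise ValueError("central A cannot sit closer than 2 nt to the 5' end")
        if self.endogenous_status not in ("methylated", "unmethylated", "unknown"):
            raise ValueError(f"bad endogenous_status {self.endogenous_status!r}")


@dataclass(frozen=True)
class OligoPair:
    """An experimental 102-mer and its DRACH-free negative control."""

    site: DrachSite
    experimental_seq: str
    control_seq: str
    site_offset: int        # index of the central A within the window
    n_mutations: int

    @property
    def pair_id(self) -> str:
        return f"{self.site.transcript_id}:{self.site.pos}"


# ----------------------------------------------------------------------

def scan_drach(seq: str) -> list[tuple[int, str]]:
    """All DRACH hits in ``seq``, overlaps included.

    Returns ``(offset_of_central_A, 5-mer)`` pairs in ascending order.
    T is accepted and treated as U.
    """
    s = normalize_rna(seq)
    return [(m.start() + 2, m.group(1)) for m in _DRACH_RE.finditer(s)]


def design_window(seq: str, site_pos: int) -> tuple[str, int]:
    """Extract the 102-nt experimental window around a site.

    The window is ``[site_pos - 51, site_pos + 51)`` (51 upstream + A + 50
    downstream).  Near a transcript end the window is shifted to fit while
    keeping length 102, and the returned ``site_offset`` records where the
    central A landed.
    """
    s = normalize_rna(seq)
    if len(s) < WINDOW_SIZE:
        raise DesignError(
            f"transcript of length {len(s)} shorter than window ({WINDOW_SIZE})")
    if not 0 <= site_pos < len(s):
        raise DesignError(f"site position {site_pos} outside transcript")
    start = min(max(site_pos - UPSTREAM_FLANK, 0), len(s) - WINDOW_SIZE)
    return s[start:start + WINDOW_SIZE], site_pos - start


def knockout_drach(seq: str) -> tuple[str, int]:
    """Mutate a sequence until it carries no DRACH motif.

    Each pass substitutes every DRACH central A with G simultaneously, then
    rescans; an A->G substitution can never create a new DRACH centered at
    the substituted position (the center must be A), and each pass strictly
    decreases the A count, so the loop terminates.  Returns the final
    sequence and the total number of substitutions.
    """
    s = list(normalize_rna(seq))
    n_mut = 0
    while True:
        hits = scan_drach("".join(s))
        if not hits:
            break
        for pos, _ in hits:
            s[pos] = "G"
        n_mut += len(hits)
    return "".join(s), n_mut


def build_library(sites: Iterable[DrachSite],
                  seqs: Mapping[str, str],
                  ) -> tuple[list[OligoPair], pd.DataFrame]:
    """Design one :class:`OligoPair` per resolvable site.

    ``seqs`` maps transcript_id to the transcript sequence (RNA or DNA
    alphabet).  Unresolvable sites (missing transcript, transcript shorter
    than the window, position not a DRACH central A in the sequence) are
    skipped with a logged warning and returned in the rejects table.
    """
    pairs: list[OligoPair] = []
    rejects: list[dict] = []

    def reject(site: DrachSite, reason: str) -> None:
        log.warning("rejecting site %s:%d: %s", site.transcript_id, site.pos, reason)
        rejects.append({"transcript_id": site.transcript_id, "pos": site.pos,
                        "reason": reason})

    for site in sites:
        seq = seqs.get(site.transcript_id)
        if seq is None:
            reject(site, "transcript sequence not found")
            continue
        seq = normalize_rna(seq)
        if seq[max(site.pos - 2, 0):site.pos + 3] != site.motif:
            reject(site, "sequence at pos does not match site motif")
            continue
        try:
            window, offset = design_window(seq, site.pos)
        except DesignError as exc:
            reject(site, str(exc))
            continue
        control, n_mut = knockout_drach(window)
        pairs.append(OligoPair(site, window, control, offset, n_mut))
    return pairs, pd.DataFrame(rejects, columns=["transcript_id", "pos", "reason"])


# ----------------------------------------------------------------------
# Serialization
# ----------------------------------------------------------------------

def library_fasta_records(pairs: Sequence[OligoPair]):
    """Yield Biopython SeqRecords for the library FASTA (DNA alphabet).

    IDs follow ``{transcript}:{pos}:{exp|ctl}``.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    for p in pairs:
        yield SeqRecord(Seq(to_dna(p.experimental_seq)),
                        id=f"{p.pair_id}:exp", description="")
        yield SeqRecord(Seq(to_dna(p.control_seq)),
                        id=f"{p.pair_id}:ctl", description="")


def pair_metadata_table(pairs: Sequence[OligoPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pair_id": p.pair_id,
        "transcript_id": p.site.transcript_id,
        "pos": p.site.pos,
        "motif": p.site.motif,
        "endogenous_status": p.site.endogenous_status,
        "site_offset": p.site_offset,
        "n_mutations": p.n_mutations,
    } for p in pairs])
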