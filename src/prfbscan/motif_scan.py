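"""Premature in-frame stop detection and frameshift-motif characterization.

The autoregulatory programmed ribosomal frameshift in *prfB* is recognizable
from the gene sequence alone: an in-frame stop codon well before the end of
the CDS (position 26 in *E. coli*), preceded by a pyrimidine slippery run
(canonically CTTT, the Leu codon plus the stop's first nucleotide), an
internal Shine-Dalgarno-like purine tract a few nucleotides upstream, and a
C immediately after the stop that weakens termination.  This module finds
the premature stops under the genome's genetic code and describes the
surrounding elements; classification as frameshift / no-frameshift depends
*only* on premature-stop presence -- the elements are descriptive.

Genetic-code awareness matters: under NCBI translation table 4 (Mycoplasma
and relatives) TGA codes tryptophan, so a TGA-only "interruption" is not a
stop at all and such a gene is in-frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data import CodonTable

from .genome_io import GeneRecord

__all__ = [
    "UnscannableSequence",
    "MotifParams",
    "PrematureStop",
    "MotifReport",
    "FrameshiftCall",
    "SDMatch",
    "stop_codons_of_table",
    "register_table",
    "find_premature_stops",
    "score_sd_like",
    "characterize_motif",
    "classify_prfb",
    "report_row",
    "REPORT_COLUMNS",
]


class UnscannableSequence(ValueError):
    """CDS cannot be framed into codons (wrong length / too short)."""


# Stop-codon registry, seeded from the NCBI code tables for the two codes the
# analysis meets by default (11: standard bacterial; 4: TGA->Trp).  Extensible
# via :func:`register_table`.
_STOP_REGISTRY: dict = {
    table_id: frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)
    for table_id in (11, 4)
}


def register_table(table_id: int, stop_codons: Sequence[str]) -> None:
    """Register (or override) the stop-codon set for a translation table."""
    stops = frozenset(c.upper() for c in stop_codons)
    if any(len(c) != 3 or set(c) - set("ACGT") for c in stops):
        raise ValueError("stop codons must be 3-nt DNA strings")
    _STOP_REGISTRY[int(table_id)] = stops


def stop_codons_of_table(table_id: int) -> frozenset:
    """Stop-codon set of an NCBI translation table (registry: 11, 4 by default)."""
    try:
        return _STOP_REGISTRY[table_id]
    except KeyError:
        known = sorted(_STOP_REGISTRY)
        raise ValueError(
            f"unknown translation table {table_id}; known tables: {known}"
        ) from None


@dataclass(frozen=True)
class MotifParams:
    """Tunable motif-characterization parameters.

    upstream/downstream define the extracted window around the premature stop
    start (defaults -15..+4, spanning the SD-like element through the
    conserved +4 C); the SD search is constrained so the SD 3' end sits
    ``min_spacer``..``max_spacer`` nt upstream of the slippery-run start.
    ``anti_sd`` is the 16S rRNA 3' tail 3'-UCCUCC-5' written 5'->3' as DNA.
    """

    upstream: int = 15
    downstream: int = 4
    min_spacer: int = 2
    max_spacer: int = 8
    anti_sd: str = "TCCTCC"
    min_sd_score: int = 4


DEFAULT_PARAMS = MotifParams()


@dataclass(frozen=True)
class PrematureStop:
    codon_index: int  # 1-based codon position in the reading frame
    nt_offset: int  # 0-based offset of the codon start within cds_seq
    identity: str  # TAA / TAG / TGA


@dataclass
class MotifReport:
    stop: PrematureStop
    following_nt: Optional[str]
    slippery: str
    slippery_canonical: bool
    sd_match: Optional[str]
    sd_score: int
    sd_spacer: Optional[int]
    window_seq: str
    window_anchor: int  # offset of the stop start within window_seq


@dataclass
class FrameshiftCall:
    status: str  # frameshift | no_frameshift | gene_absent | unscannable
    stops: list = field(default_factory=list)
    primary_motif: Optional[MotifReport] = None
    notes: list = field(default_factory=list)


_VALID = re.compile(r"^[ACGTN]*$")
# The canonical slippery run is CTT (Leu) plus the stop's first T; poly-T
# variants (TTTT, decoded by tRNA-Phe) are reported but flagged non-canonical.
CANONICAL_SLIPPERY = "CTTT"

# Watson-Crick plus G.T(U) wobble, written as (mRNA base, anti-SD base).
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def find_premature_stops(
    cds_seq: str, table_id: int, codon_start: int = 1
) -> list:
    """All in-frame stop codons before the final codon, 5'->3'.

    The reading frame starts after trimming ``codon_start - 1`` leading
    bases (GenBank semantics).  Codons containing N never match.  Raises
    :class:`UnscannableSequence` when the framed length is shorter than two
    codons or not a multiple of three.
    """
    if not cds_seq:
        raise ValueError("empty sequence")
    seq = cds_seq.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    if codon_start not in (1, 2, 3):
        raise ValueError("codon_start must be 1, 2 or 3")
    trim = codon_start - 1
    framed = seq[trim:]
    if len(framed) < 6 or len(framed) % 3 != 0:
        raise UnscannableSequence(
            f"framed length {len(framed)} is not >= 6 and divisible by 3"
        )
    stops = stop_codons_of_table(table_id)
    n_codons = len(framed) // 3
    found = []
    for i in range(n_codons - 1):  # final codon excluded
        codon = framed[3 * i : 3 * i + 3]
        if codon in stops:
            found.append(
                PrematureStop(codon_index=i + 1, nt_offset=trim + 3 * i, identity=codon)
            )
    return found


@dataclass(frozen=True)
class SDMatch:
    score: int
    start: int  # 0-based offset of the match within the searched window
    seq: str


def _alignment_score(sub: str, anti: str) -> int:
    return sum((a, b) in _PAIRS for a, b in zip(sub, anti))


def score_sd_like(
    upstream_window: str, anti_sd: str = DEFAULT_PARAMS.anti_sd, min_score: int = DEFAULT_PARAMS.min_sd_score
) -> Optional[SDMatch]:
    """Best ungapped pairing of a window substring against the anti-SD tail.

    Scores Watson-Crick pairs plus G.T(U) wobble position-by-position; ties
    are broken toward the 3'-most (stop-proximal) placement.  Returns None
    when the best score falls below ``min_score``.
    """
    if not upstream_window:
        return None
    window = upstream_window.upper()
    anti = anti_sd.upper()
    best: Optional[SDMatch] = None
    if len(window) >= len(anti):
        for s in range(len(window) - len(anti) + 1):
            sub = window[s : s + len(anti)]
            score = _alignment_score(sub, anti)
            if best is None or score > best.score or (score == best.score and s > best.start):
                best = SDMatch(score, s, sub)
    else:
        # short window: slide it along the anti-SD instead
        for s in range(len(anti) - len(window) + 1):
            score = _alignment_score(window, anti[s : s + len(window)])
            if best is None or score > best.score:
                best = SDMatch(score, 0, window)
    if best is None or best.score < min_score:
        return None
    return best


def characterize_motif(
    cds_seq: str, stop: PrematureStop, params: MotifParams = DEFAULT_PARAMS
) -> MotifReport:
    """Describe the frameshift-motif elements around a verified premature stop.

    The slippery run is the 4 nt ending at the stop's first nucleotide
    (canonical form ``CTTT``); the SD-like element is searched upstream of
    the slippery start under the spacer constraint; the extracted window
    spans ``params.upstream`` nt before the stop start through
    ``params.downstream`` nt after it, clipped to sequence bounds.
    """
    seq = cds_seq.upper()
    off = stop.nt_offset
    if seq[off : off + 3] != stop.identity:
        raise ValueError(
            f"premature stop inconsistent with sequence: "
            f"cds[{off}:{off + 3}]={seq[off:off + 3]!r} != {stop.identity!r}"
        )
    following_nt = seq[off + 3] if off + 3 < len(seq) else None

    if off >= 3:
        slippery = seq[off - 3 : off + 1]
    else:
        slippery = "." * (3 - off) + seq[: off + 1]
    canonical = slippery == CANONICAL_SLIPPERY

    sd_match = None
    sd_score = 0
    sd_spacer = None
    slip_start = off - 3
    anti_len = len(params.anti_sd)
    if slip_start > 0:
        best: Optional[tuple] = None  # (score, start)
        lo = max(0, slip_start - params.max_spacer - anti_len)
        hi = slip_start - params.min_spacer - anti_len  # last admissible start
        for s in range(lo, hi + 1):
            if s < 0:
                continue
            score = _alignment_score(seq[s : s + anti_len], params.anti_sd)
            if best is None or score > best[0] or (score == best[0] and s > best[1]):
                best = (score, s)
        if best is not None and best[0] >= params.min_sd_score:
            sd_score, s = best
            sd_match = seq[s : s + anti_len]
            sd_spacer = slip_start - (s + anti_len)

    win_lo = max(0, off - params.upstream)
    win_hi = min(len(seq), off + params.downstream + 1)
    return MotifReport(
        stop=stop,
        following_nt=following_nt,
        slippery=slippery,
        slippery_canonical=canonical,
        sd_match=sd_match,
        sd_score=sd_score,
        sd_spacer=sd_spacer,
        window_seq=seq[win_lo:win_hi],
        window_anchor=off - win_lo,
    )


def classify_prfb(
    gene: Optional[GeneRecord], params: MotifParams = DEFAULT_PARAMS,
    table_override: Optional[int] = None,
) -> FrameshiftCall:
    """Classify a release-factor gene by premature-stop presence.

    Absent gene -> ``gene_absent``; unframeable CDS -> ``unscannable``; one
    or more premature stops -> ``frameshift`` with the motif characterized
    at the first (5'-most) stop; otherwise ``no_frameshift``.
    """
    if gene is None:
        return FrameshiftCall(status="gene_absent")
    table = table_override if table_override is not None else gene.transl_table
    notes = []
    if gene.is_pseudo:
        notes.append("annotated as pseudogene")
    try:
        stops = find_premature_stops(gene.cds_seq, table, gene.codon_start)
    except UnscannableSequence as exc:
        return FrameshiftCall(status="unscannable", notes=notes + [str(exc)])
    except ValueError as exc:
        return FrameshiftCall(status="unscannable", notes=notes + [str(exc)])
    if not stops:
        return FrameshiftCall(status="no_frameshift", notes=notes)
    motif = characterize_motif(gene.cds_seq.upper(), stops[0], params)
    return FrameshiftCall(status="frameshift", stops=stops, primary_motif=motif, notes=notes)


REPORT_COLUMNS = [
    "accession",
    "gene",
    "status",
    "n_premature_stops",
    "stop_codon_index",
    "stop_identity",
    "slippery",
    "slippery_canonical",
    "sd_match",
    "sd_score",
    "sd_spacer",
    "following_nt",
    "window_seq",
    "window_anchor",
]


def report_row(accession: str, gene_name: str, call: FrameshiftCall) -> dict:
    """Flatten a FrameshiftCall into one per-gene TSV report row."""
    row = {c: "" for c in REPORT_COLUMNS}
    row.update(accession=accession, gene=gene_name, status=call.status,
               n_premature_stops=len(call.stops))
    m = call.primary_motif
    if m is not None:
        row.update(
            stop_codon_index=m.stop.codon_index,
            stop_identity=m.stop.identity,
            slippery=m.slippery,
            slippery_canonical=m.slippery_canonical,
            sd_match=m.sd_match or "",
            sd_score=m.sd_score,
            sd_spacer="" if m.sd_spacer is None else m.sd_spacer,
            following_nt=m.following_nt or "",
            window_seq=m.window_seq,
            window_anchor=m.window_anchor,
        )
    return row
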