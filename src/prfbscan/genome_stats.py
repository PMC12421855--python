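"""Per-genome statistics: GC content, terminal stop-codon usage, suppressor tRNA.

Three genome characteristics surround the frameshift-motif census: genomic
GC fraction, the distribution of terminal stop codons over all annotated
CDS (the demand signal for RF2, which terminates at TGA/TAA), and presence
of a TGA-reading suppressor tRNA (anticodon UCA/TCA), the hallmark of
reduced genomes that dropped *prfB* entirely and read UGA as tryptophan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genome_io import GeneRecord, GenomeRecord, TRNARecord
from .motif_scan import FrameshiftCall

__all__ = [
    "StopUsage",
    "GenomeStatsRow",
    "gc_content",
    "terminal_stop_usage",
    "has_tga_suppressor_trna",
    "genome_stats_row",
    "rows_to_dataframe",
    "STATS_COLUMNS",
]

CANONICAL_STOPS = ("TAA", "TAG", "TGA")


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); N and other ambiguity codes are ignored."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    g = s.count("G")
    c = s.count("C")
    denom = s.count("A") + s.count("T") + g + c
    if denom == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return (g + c) / denom


@dataclass
class StopUsage:
    """Terminal stop-codon counts of one genome's CDS inventory.

    ``fractions`` are computed over CDS ending in a canonical stop only;
    CDS ending otherwise (mis-annotations, partial genes) are counted under
    ``other`` and do not dilute the fractions.  ``fractions`` is None when
    no CDS ends in a canonical stop.
    """

    n_cds: int
    counts: dict
    fractions: Optional[dict]


def terminal_stop_usage(cds_list: Iterable[GeneRecord]) -> StopUsage:
    """Classify the last three nucleotides of each CDS."""
    counts = {"TAA": 0, "TAG": 0, "TGA": 0, "other": 0}
    n = 0
    for gene in cds_list:
        n += 1
        seq = gene.cds_seq.upper()
        last3 = seq[-3:] if len(seq) >= 3 else ""
        if last3 in counts:
            counts[last3] += 1
        else:
            counts["other"] += 1
    denom = sum(counts[s] for s in CANONICAL_STOPS)
    fractions = (
        {s: counts[s] / denom for s in CANONICAL_STOPS} if denom > 0 else None
    )
    return StopUsage(n_cds=n, counts=counts, fractions=fractions)


def has_tga_suppressor_trna(trnas: Iterable[TRNARecord]) -> bool:
    """True iff some tRNA's anticodon decodes TGA (anticodon TCA / UCA).

    Matching is sequence-based, not amino-acid-label-based, so an annotated
    tRNA-Trp with a TCA anticodon counts while the standard CCA one does not.
    """
    for t in trnas:
        anticodon = (t.anticodon or "").upper().replace("U", "T")
        if anticodon == "TCA":
            return True
    return False


@dataclass
class GenomeStatsRow:
    accession: str
    gc_fraction: float
    stop_usage: StopUsage
    prfb_status: str
    has_tga_suppressor: bool
    taxonomy: dict = field(default_factory=dict)


def genome_stats_row(genome: GenomeRecord, call: FrameshiftCall) -> GenomeStatsRow:
    """Assemble the per-genome statistics row behind the comparative figures.

    GC uses the annotated/parsed genome-level value when present (the
    analysis consumed database GC), falling back to the concatenated CDS.
    """
    gc_percent = genome.metadata.get("gc_percent")
    if gc_percent is not None:
        gc = float(gc_percent) / 100.0
    else:
        gc = gc_content("".join(g.cds_seq for g in genome.genes))
    return GenomeStatsRow(
        accession=genome.accession,
        gc_fraction=gc,
        stop_usage=terminal_stop_usage(genome.genes),
        prfb_status=call.status,
        has_tga_suppressor=has_tga_suppressor_trna(genome.trnas),
        taxonomy=dict(genome.metadata.get("taxonomy", {})),
    )


STATS_COLUMNS = [
    "accession",
    "phylum",
    "gc_fraction",
    "prfb_status",
    "has_tga_suppressor",
    "n_cds",
    "n_stop_TAA",
    "n_stop_TAG",
    "n_stop_TGA",
    "n_stop_other",
    "frac_TAA",
    "frac_TAG",
    "frac_TGA",
]


def rows_to_dataframe(rows: Sequence[GenomeStatsRow]) -> pd.DataFrame:
    """Per-genome stats table (one row per genome, fixed column order)."""
    out = []
    for r in rows:
        u = r.stop_usage
        rec = {
            "accession": r.accession,
            "phylum": r.taxonomy.get("phylum", "unclassified"),
            "gc_fraction": r.gc_fraction,
            "prfb_status": r.prfb_status,
            "has_tga_suppressor": r.has_tga_suppressor,
            "n_cds": u.n_cds,
            "n_stop_TAA": u.counts["TAA"],
            "n_stop_TAG": u.counts["TAG"],
            "n_stop_TGA": u.counts["TGA"],
            "n_stop_other": u.counts["other"],
            "frac_TAA": u.fractions["TAA"] if u.fractions else float("nan"),
            "frac_TAG": u.fractions["TAG"] if u.fractions else float("nan"),
            "frac_TGA": u.fractions["TGA"] if u.fractions else float("nan"),
        }
        out.append(rec)
    return pd.DataFrame(out, columns=STATS_COLUMNS)
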