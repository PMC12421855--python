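"""Reading annotated bacterial genomes and extracting the gene inventory.

The analysis consumes annotated genomes (GenBank flat files, or a GFF3 +
genomic FASTA pair) and works on three record types: coding sequences
(:class:`GeneRecord`), tRNAs (:class:`TRNARecord`) and the per-genome
container (:class:`GenomeRecord`).  Release-factor genes are selected by
annotation (gene name first, product string second), mirroring how the NCBI
Prokaryotic Genome Annotation Pipeline names them.

Coordinate conventions: external formats keep their native 1-based inclusive
coordinates; slicing internally is 0-based half-open; codon indices elsewhere
in the package are 1-based.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "GeneRecord",
    "TRNARecord",
    "GenomeRecord",
    "GeneSelection",
    "read_genome_annotation",
    "genome_from_seqrecords",
    "select_release_factor_gene",
    "filter_genomes_by_contamination",
    "write_genome_json",
    "read_genome_json",
]


class FormatError(ValueError):
    """An input file does not parse under the declared standard."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneRecord:
    """One annotated CDS (or pseudogene), strand-resolved 5'->3'.

    ``segments`` holds the annotated coordinate parts (1-based inclusive) in
    transcript order; for joined/frameshift-annotated CDS, ``cds_seq`` is the
    contiguous genomic span from the 5' end of the first segment to the 3'
    end of the last, read in the frame of the first segment -- *not* the
    spliced concatenation -- so that a programmed premature stop stays
    visible in frame 0.
    """

    gene_name: str
    product: str
    replicon_id: str
    start: int
    end: int
    strand: str
    segments: list = field(default_factory=list)
    is_pseudo: bool = False
    transl_table: int = 11
    codon_start: int = 1
    cds_seq: str = ""

    def to_dict(self) -> dict:
        return {
            "gene_name": self.gene_name,
            "product": self.product,
            "replicon_id": self.replicon_id,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
            "segments": [list(s) for s in self.segments],
            "is_pseudo": self.is_pseudo,
            "transl_table": self.transl_table,
            "codon_start": self.codon_start,
            "cds_seq": self.cds_seq,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneRecord":
        d = dict(d)
        d["segments"] = [tuple(s) for s in d.get("segments", [])]
        return cls(**d)


@dataclass
class TRNARecord:
    """An annotated tRNA; the anticodon is kept as annotated (DNA or RNA)."""

    amino_acid: str
    anticodon: str
    replicon_id: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"

    def to_dict(self) -> dict:
        return {
            "amino_acid": self.amino_acid,
            "anticodon": self.anticodon,
            "replicon_id": self.replicon_id,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TRNARecord":
        return cls(**d)


@dataclass
class GenomeRecord:
    """All gene/tRNA records of one annotated genome plus its metadata.

    ``metadata`` may carry ``taxonomy`` (rank -> name), ``checkm_contamination``
    (percent) and ``gc_percent``; the parser fills ``gc_percent`` from the
    replicon sequences when it is not annotated.
    """

    accession: str
    sequence_length: dict = field(default_factory=dict)
    genes: list = field(default_factory=list)
    trnas: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "accession": self.accession,
            "sequence_length": dict(self.sequence_length),
            "genes": [g.to_dict() for g in self.genes],
            "trnas": [t.to_dict() for t in self.trnas],
            "metadata": self.metadata,
            "n_skipped": self.n_skipped,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeRecord":
        return cls(
            accession=d["accession"],
            sequence_length=dict(d.get("sequence_length", {})),
            genes=[GeneRecord.from_dict(g) for g in d.get("genes", [])],
            trnas=[TRNARecord.from_dict(t) for t in d.get("trnas", [])],
            metadata=d.get("metadata", {}),
            n_skipped=d.get("n_skipped", 0),
        )


# --------------------------------------------------------------------------
# parsing


_ANTICODON_SEQ = re.compile(r"seq\s*:\s*([ACGTUacgtu]{3})")
_ANTICODON_AA = re.compile(r"aa\s*:\s*(\w+)")


def _trna_from_qualifiers(product: str, anticodon_q: str) -> tuple[str, str]:
    """Extract (amino_acid, anticodon) from tRNA qualifiers.

    Accepts both the structured GenBank form
    ``(pos:1..3,aa:Trp,seq:tca)`` and a bare 3-letter anticodon.
    """
    anticodon = ""
    aa = ""
    if anticodon_q:
        m = _ANTICODON_SEQ.search(anticodon_q)
        if m:
            anticodon = m.group(1).upper()
        elif len(anticodon_q.strip()) == 3:
            anticodon = anticodon_q.strip().upper()
        m = _ANTICODON_AA.search(anticodon_q)
        if m:
            aa = m.group(1)
    if not aa and product.startswith("tRNA-"):
        aa = product.split("-", 1)[1]
    return aa, anticodon


def _metadata_from_source(qualifiers: dict) -> dict:
    """Pull taxonomy / quality metadata out of a ``source`` feature."""
    meta: dict = {}
    for note in qualifiers.get("note", []):
        m = re.match(r"^\s*([A-Za-z_]+)\s*=\s*(.+?)\s*$", note)
        if not m:
            continue
        key, value = m.group(1), m.group(2)
        if key == "checkm_contamination":
            try:
                meta["checkm_contamination"] = float(value)
            except ValueError:
                pass
        elif key in {"phylum", "order", "family", "genus", "species"}:
            meta.setdefault("taxonomy", {})[key] = value
        elif key == "gc_percent":
            try:
                meta["gc_percent"] = float(value)
            except ValueError:
                pass
    if "organism" in qualifiers:
        meta.setdefault("organism", qualifiers["organism"][0])
    return meta


def genome_from_seqrecords(records: Sequence, accession: Optional[str] = None) -> GenomeRecord:
    """Build a :class:`GenomeRecord` from parsed Biopython SeqRecords.

    CDS features become :class:`GeneRecord` (reverse-complemented for the
    minus strand), tRNA features become :class:`TRNARecord`; pseudogenes are
    retained and flagged.  Features whose coordinates fall outside the
    replicon are skipped with a warning and counted in ``n_skipped``.
    """
    records = list(records)
    if not records:
        raise FormatError("no sequence records found")
    genome = GenomeRecord(accession=accession or records[0].id)
    gc_num = 0
    gc_den = 0
    for rec in records:
        seq = str(rec.seq).upper()
        replicon_len = len(seq)
        genome.sequence_length[rec.id] = replicon_len
        gc_num += seq.count("G") + seq.count("C")
        gc_den += sum(seq.count(b) for b in "ACGT")
        for feat in rec.features:
            if feat.type == "source":
                for k, v in _metadata_from_source(feat.qualifiers).items():
                    if k == "taxonomy":
                        genome.metadata.setdefault("taxonomy", {}).update(v)
                    else:
                        genome.metadata.setdefault(k, v)
                continue
            if feat.type not in {"CDS", "tRNA"}:
                continue
            parts = feat.location.parts
            span_start = min(int(p.start) for p in parts)
            span_end = max(int(p.end) for p in parts)
            if span_start < 0 or span_end > replicon_len:
                log.warning(
                    "%s: %s feature %d..%d outside replicon %s (len %d); skipped",
                    genome.accession, feat.type, span_start + 1, span_end, rec.id, replicon_len,
                )
                genome.n_skipped += 1
                continue
            strand = "-" if feat.location.strand == -1 else "+"
            segments = sorted(
                ((int(p.start) + 1, int(p.end)) for p in parts), key=lambda s: s[0]
            )
            if strand == "-":
                segments = segments[::-1]  # transcript (5'->3') order
            q = feat.qualifiers
            if feat.type == "tRNA":
                aa, anticodon = _trna_from_qualifiers(
                    q.get("product", [""])[0], q.get("anticodon", [""])[0]
                )
                genome.trnas.append(
                    TRNARecord(
                        amino_acid=aa,
                        anticodon=anticodon,
                        replicon_id=rec.id,
                        start=span_start + 1,
                        end=span_end,
                        strand=strand,
                    )
                )
                continue
            # contiguous genomic span, strand-resolved (see GeneRecord docstring)
            sub = seq[span_start:span_end]
            if strand == "-":
                sub = _revcomp(sub)
            genome.genes.append(
                GeneRecord(
                    gene_name=q.get("gene", [""])[0],
                    product=q.get("product", [""])[0],
                    replicon_id=rec.id,
                    start=span_start + 1,
                    end=span_end,
                    strand=strand,
                    segments=segments,
                    is_pseudo=("pseudo" in q or "pseudogene" in q),
                    transl_table=int(q.get("transl_table", ["11"])[0]),
                    codon_start=int(q.get("codon_start", ["1"])[0]),
                    cds_seq=sub,
                )
            )
    if gc_den > 0:
        genome.metadata.setdefault("gc_percent", 100.0 * gc_num / gc_den)
    return genome


def _read_genbank(path: Path) -> GenomeRecord:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    return genome_from_seqrecords(records)


def _read_gff3(gff_path: Path, fasta_path: Path) -> GenomeRecord:
    import gffutils

    try:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    except Exception as exc:
        raise FormatError(f"{fasta_path}: not parseable as FASTA: {exc}") from exc
    if not seqs:
        raise FormatError(f"{fasta_path}: no FASTA records found")
    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise FormatError(f"{gff_path}: not parseable as GFF3: {exc}") from exc

    genome = GenomeRecord(accession=next(iter(seqs)))
    gc_num = sum(s.count("G") + s.count("C") for s in seqs.values())
    gc_den = sum(sum(s.count(b) for b in "ACGT") for s in seqs.values())
    for rid, s in seqs.items():
        genome.sequence_length[rid] = len(s)
    if gc_den:
        genome.metadata["gc_percent"] = 100.0 * gc_num / gc_den

    # group multi-row CDS by their original ID attribute
    groups: dict = {}
    order: list = []
    for f in db.features_of_type("CDS"):
        key = f.attributes.get("ID", [f"{f.seqid}:{f.start}:{f.end}:{f.strand}"])[0]
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(f)
    for key in order:
        rows = sorted(groups[key], key=lambda f: f.start)
        first = rows[0]
        rid = first.seqid
        if rid not in seqs:
            log.warning("CDS %s on unknown replicon %s; skipped", key, rid)
            genome.n_skipped += 1
            continue
        span_start = min(f.start for f in rows)  # 1-based inclusive
        span_end = max(f.end for f in rows)
        if span_start < 1 or span_end > len(seqs[rid]):
            log.warning("CDS %s coordinates outside replicon %s; skipped", key, rid)
            genome.n_skipped += 1
            continue
        strand = "-" if first.strand == "-" else "+"
        segments = [(f.start, f.end) for f in rows]
        if strand == "-":
            segments = segments[::-1]
        sub = seqs[rid][span_start - 1 : span_end]
        if strand == "-":
            sub = _revcomp(sub)
        five_prime = rows[-1] if strand == "-" else rows[0]
        phase = five_prime.frame
        codon_start = int(phase) + 1 if phase in {"0", "1", "2"} else 1
        attrs = first.attributes
        pseudo = "pseudo" in attrs or "pseudogene" in attrs or (
            attrs.get("gene_biotype", [""])[0] == "pseudogene"
        )
        genome.genes.append(
            GeneRecord(
                gene_name=attrs.get("gene", attrs.get("Name", [""]))[0],
                product=attrs.get("product", [""])[0],
                replicon_id=rid,
                start=span_start,
                end=span_end,
                strand=strand,
                segments=segments,
                is_pseudo=pseudo,
                transl_table=int(attrs.get("transl_table", ["11"])[0]),
                codon_start=codon_start,
                cds_seq=sub,
            )
        )
    for f in db.features_of_type("tRNA"):
        if f.seqid not in seqs or f.start < 1 or f.end > len(seqs[f.seqid]):
            genome.n_skipped += 1
            continue
        aa, anticodon = _trna_from_qualifiers(
            f.attributes.get("product", [""])[0], f.attributes.get("anticodon", [""])[0]
        )
        genome.trnas.append(
            TRNARecord(
                amino_acid=aa,
                anticodon=anticodon,
                replicon_id=f.seqid,
                start=f.start,
                end=f.end,
                strand="-" if f.strand == "-" else "+",
            )
        )
    return genome


def read_genome_annotation(
    path, format: str = "genbank", fasta: Optional[Path] = None
) -> GenomeRecord:
    """Read one annotated genome.

    Parameters
    ----------
    path
        GenBank flat file, or the GFF3 file when ``format="gff3"``.
    format
        ``"genbank"`` or ``"gff3"`` (the latter requires ``fasta``).
    fasta
        Genomic FASTA accompanying a GFF3 annotation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        return _read_genbank(path)
    if format in {"gff3", "gff3+fasta", "gff"}:
        if fasta is None:
            raise ValueError("gff3 format requires the accompanying genomic FASTA")
        return _read_gff3(path, Path(fasta))
    raise ValueError(f"unknown format {format!r}; expected 'genbank' or 'gff3'")


# --------------------------------------------------------------------------
# gene selection and genome filtering


class GeneSelection(NamedTuple):
    gene: Optional[GeneRecord]
    ambiguous: bool = False


_PRODUCT_PATTERNS = {
    "prfB": re.compile(r"release factor (?:RF)?2\b|release factor 2|\bRF2\b|\bRF-2\b", re.I),
    "prfA": re.compile(r"release factor (?:RF)?1\b|release factor 1|\bRF1\b|\bRF-1\b", re.I),
}


def select_release_factor_gene(genome: GenomeRecord, target: str = "prfB") -> GeneSelection:
    """Select the release-factor gene by annotation precedence.

    Exact (case-insensitive) gene-name match outranks a product-string match
    ("release factor 2"/"RF2" for prfB, "release factor 1"/"RF1" for prfA).
    Returns ``GeneSelection(None)`` when no candidate matches; when several
    candidates tie at the top precedence level, the first by coordinate is
    returned with ``ambiguous=True``.
    """
    if target not in _PRODUCT_PATTERNS:
        raise ValueError(f"target must be 'prfB' or 'prfA', got {target!r}")
    by_name = [g for g in genome.genes if g.gene_name.lower() == target.lower()]
    if by_name:
        candidates = by_name
    else:
        pat = _PRODUCT_PATTERNS[target]
        candidates = [g for g in genome.genes if pat.search(g.product or "")]
    if not candidates:
        return GeneSelection(None, False)
    candidates = sorted(candidates, key=lambda g: (g.replicon_id, g.start))
    return GeneSelection(candidates[0], len(candidates) > 1)


def filter_genomes_by_contamination(
    genomes: Iterable[GenomeRecord], max_contamination: float
) -> list:
    """Retain genomes with CheckM contamination strictly below the threshold.

    Genomes without a contamination score pass with a warning: the gate acts
    on metadata availability, not sequence quality.
    """
    if max_contamination < 0:
        raise ValueError("max_contamination must be non-negative")
    kept = []
    for g in genomes:
        contamination = g.metadata.get("checkm_contamination")
        if contamination is None:
            log.warning("%s: no contamination score in metadata; passing", g.accession)
            kept.append(g)
        elif contamination < max_contamination:
            kept.append(g)
    return kept


# --------------------------------------------------------------------------
# internal JSON dialect


def write_genome_json(genome: GenomeRecord, path) -> None:
    Path(path).write_text(json.dumps(genome.to_dict(), indent=1, sort_keys=True))


def read_genome_json(path) -> GenomeRecord:
    return GenomeRecord.from_dict(json.loads(Path(path).read_text()))
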