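"""Parsing annotated genomes, gene selection, and the contamination gate."""

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from prfbscan.genome_io import (
    FormatError,
    GenomeRecord,
    filter_genomes_by_contamination,
    genome_from_seqrecords,
    read_genome_annotation,
    read_genome_json,
    select_release_factor_gene,
    write_genome_json,
)


def _record(seq, features, accession="TEST0001"):
    return SeqRecord(
        Seq(seq),
        id=accession,
        name=accession,
        description="fixture",
        annotations={"molecule_type": "DNA", "date": "01-JAN-2025"},
        features=features,
    )


def _cds(start0, end0, strand, **quals):
    q = {k: [str(v)] for k, v in quals.items()}
    return SeqFeature(FeatureLocation(start0, end0, strand=strand), type="CDS", qualifiers=q)


@pytest.fixture
def two_gene_genome(tmp_path):
    # +strand ATG AAA TAA at 10..19, -strand gene at 30..39 whose 5'->3'
    # CDS is ATG CCC TAA (reverse complement on the chromosome)
    plus_cds = "ATGAAATAA"
    minus_cds = "ATGCCCTAA"
    minus_genomic = str(Seq(minus_cds).reverse_complement())
    seq = "C" * 10 + plus_cds + "C" * 11 + minus_genomic + "C" * 10
    rec = _record(
        seq,
        [
            _cds(10, 19, 1, gene="yaaA", product="hypothetical protein"),
            _cds(30, 39, -1, gene="yaaB", product="hypothetical protein"),
        ],
    )
    path = tmp_path / "two_gene.gbk"
    SeqIO.write([rec], str(path), "genbank")
    return path, seq, minus_cds


def test_strand_resolution_on_genbank_fixture(two_gene_genome):
    path, genome_seq, minus_cds = two_gene_genome
    genome = read_genome_annotation(path)
    assert len(genome.genes) == 2
    plus, minus = genome.genes
    assert plus.strand == "+" and plus.cds_seq == "ATGAAATAA"
    assert minus.strand == "-"
    assert minus.cds_seq == minus_cds
    # minus cds is the reverse complement of the genomic slice
    assert minus.cds_seq == str(Seq(genome_seq[30:39]).reverse_complement())
    assert genome.sequence_length["TEST0001"] == len(genome_seq)


def test_transl_table_qualifier_honored(tmp_path):
    rec = _record("C" * 5 + "ATGAAATAA" + "C" * 5,
                  [_cds(5, 14, 1, gene="x", transl_table=4)])
    path = tmp_path / "t4.gbk"
    SeqIO.write([rec], str(path), "genbank")
    genome = read_genome_annotation(path)
    assert genome.genes[0].transl_table == 4


def test_default_table_and_pseudo_flag(tmp_path):
    f = _cds(5, 14, 1, gene="x")
    f.qualifiers["pseudo"] = [""]
    rec = _record("C" * 5 + "ATGAAATAA" + "C" * 5, [f])
    path = tmp_path / "pseudo.gbk"
    SeqIO.write([rec], str(path), "genbank")
    gene = read_genome_annotation(path).genes[0]
    assert gene.transl_table == 11
    assert gene.is_pseudo


def test_trna_trp_suppressor_anticodon_parsed(tmp_path):
    trna = SeqFeature(
        FeatureLocation(5, 81, strand=1),
        type="tRNA",
        qualifiers={"product": ["tRNA-Trp"],
                    "anticodon": ["(pos:39..41,aa:Trp,seq:tca)"]},
    )
    rec = _record("C" * 90, [trna])
    path = tmp_path / "trna.gbk"
    SeqIO.write([rec], str(path), "genbank")
    genome = read_genome_annotation(path)
    assert len(genome.trnas) == 1
    assert genome.trnas[0].anticodon == "TCA"
    assert genome.trnas[0].amino_acid == "Trp"


def test_out_of_bounds_cds_skipped_and_counted(tmp_path):
    rec = _record(
        "C" * 5 + "ATGAAATAA" + "C" * 5,
        [_cds(5, 14, 1, gene="ok"), _cds(10, 500, 1, gene="overrun")],
    )
    path = tmp_path / "oob.gbk"
    SeqIO.write([rec], str(path), "genbank")
    genome = read_genome_annotation(path)
    # count conservation: features = kept records + skipped records
    assert len(genome.genes) == 1
    assert genome.n_skipped == 1


def test_unparseable_file_raises_format_error(tmp_path):
    bad = tmp_path / "bad.gbk"
    bad.write_text("this is not a genbank file\n")
    with pytest.raises(FormatError):
        read_genome_annotation(bad)


def test_gff3_fasta_pair(tmp_path):
    minus_cds = "ATGCCCTAA"
    minus_genomic = str(Seq(minus_cds).reverse_complement())
    seq = "C" * 10 + "ATGAAATAA" + "C" * 11 + minus_genomic + "C" * 10
    fasta = tmp_path / "g.fa"
    fasta.write_text(f">chr1\n{seq}\n")
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tCDS\t11\t19\t.\t+\t0\tID=cds1;gene=yaaA;product=hypothetical protein\n"
        "chr1\ttest\tCDS\t31\t39\t.\t-\t0\tID=cds2;gene=prfB;product=peptide chain release factor 2\n"
        "chr1\ttest\ttRNA\t41\t46\t.\t+\t.\tID=t1;product=tRNA-Trp;anticodon=tca\n"
    )
    genome = read_genome_annotation(gff, format="gff3", fasta=fasta)
    assert len(genome.genes) == 2
    prfb = select_release_factor_gene(genome, "prfB").gene
    assert prfb is not None and prfb.cds_seq == minus_cds
    assert genome.trnas[0].anticodon == "TCA"


# -- release-factor selection ------------------------------------------------


def _gene_genome(genes):
    return GenomeRecord(accession="G1", sequence_length={"G1": 10_000}, genes=genes)


def _mini_gene(name, product, start=100):
    from prfbscan.genome_io import GeneRecord

    return GeneRecord(gene_name=name, product=product, replicon_id="G1",
                      start=start, end=start + 8, strand="+",
                      segments=[(start, start + 8)], cds_seq="ATGAAATAA")


def test_selection_by_gene_name():
    g = _gene_genome([_mini_gene("prfB", "peptide chain release factor 2")])
    sel = select_release_factor_gene(g, "prfB")
    assert sel.gene is g.genes[0] and not sel.ambiguous


def test_selection_absent_marker():
    g = _gene_genome([_mini_gene("rpoB", "RNA polymerase")])
    assert select_release_factor_gene(g, "prfB").gene is None


def test_selection_by_product_when_name_missing():
    g = _gene_genome([_mini_gene("", "peptide chain release factor 2")])
    assert select_release_factor_gene(g, "prfB").gene is g.genes[0]
    g2 = _gene_genome([_mini_gene("", "peptide chain release factor 1")])
    assert select_release_factor_gene(g2, "prfB").gene is None
    assert select_release_factor_gene(g2, "prfA").gene is g2.genes[0]


def test_selection_name_outranks_product_and_ambiguity_flag():
    by_product = _mini_gene("", "peptide chain release factor 2", start=50)
    by_name = _mini_gene("prfB", "some other annotation", start=500)
    g = _gene_genome([by_product, by_name])
    sel = select_release_factor_gene(g, "prfB")
    assert sel.gene is by_name and not sel.ambiguous

    dup = _gene_genome([_mini_gene("prfB", "x", start=900),
                        _mini_gene("prfB", "x", start=100)])
    sel = select_release_factor_gene(dup, "prfB")
    assert sel.ambiguous
    assert sel.gene.start == 100  # first by coordinate


# -- contamination gate ------------------------------------------------------


def _meta_genome(acc, contamination):
    meta = {} if contamination is None else {"checkm_contamination": contamination}
    return GenomeRecord(accession=acc, metadata=meta)


def test_contamination_strictly_below_threshold():
    genomes = [_meta_genome("a", 5.0), _meta_genome("b", 10.0), _meta_genome("c", 12.0)]
    kept = filter_genomes_by_contamination(genomes, 10.0)
    assert [g.accession for g in kept] == ["a"]


def test_contamination_threshold_100_keeps_all_and_empty_ok():
    genomes = [_meta_genome("a", 5.0), _meta_genome("b", 99.0)]
    assert len(filter_genomes_by_contamination(genomes, 100.0)) == 2
    assert filter_genomes_by_contamination([], 10.0) == []


def test_contamination_missing_metadata_passes():
    kept = filter_genomes_by_contamination([_meta_genome("a", None)], 10.0)
    assert len(kept) == 1


def test_contamination_negative_threshold_rejected():
    with pytest.raises(ValueError):
        filter_genomes_by_contamination([], -1.0)


# -- internal JSON dialect ---------------------------------------------------


def test_json_round_trip_preserves_inventories(two_gene_genome, tmp_path):
    path, _, _ = two_gene_genome
    genome = read_genome_annotation(path)
    out = tmp_path / "genome.json"
    write_genome_json(genome, out)
    back = read_genome_json(out)
    assert back.to_dict() == genome.to_dict()
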