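"""Synthetic annotated genomes with known ground truth.

The generator emulates the statistical structure the analysis assumes about
RefSeq-style annotated genomes: per-genome GC content, open reading frames
free of internal stops under the genome's genetic code, terminal stop
codons drawn from a per-genome distribution (optionally linked to GC by a
logistic law, reproducing the observed GC -> TGA-usage association),
release-factor genes with or without the planted frameshift motif
(SD-like + spacer + slippery + premature stop + trailing C, stop at codon
26 by default, as in *E. coli*), and translation-table-4 genomes that lack
*prfB* but carry a TGA-suppressor tRNA.

Every genome is emitted in GenBank-writable form so the production parser
is exercised on the real format, alongside a truth manifest recording what
is actually on disk (elements are re-read after mutation), which makes
parameter-recovery tests honest.

GC is controlled at the codon-sampling level: bases are drawn from
GC-weighted probabilities that are numerically calibrated so that rejecting
stop codons does not bias the realized GC, and stop codons are
rejection-resampled rather than masked, keeping every reading frame valid.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genome_io import GenomeRecord, genome_from_seqrecords
from .motif_scan import stop_codons_of_table

__all__ = [
    "GenerationError",
    "MotifTemplate",
    "GenomeSpec",
    "SyntheticTruth",
    "GenomeResult",
    "CohortParams",
    "CohortResult",
    "generate_genome",
    "generate_cohort",
    "simulate_group_summaries",
    "random_orf",
    "write_genbank",
]

BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


class GenerationError(ValueError):
    """The requested genome spec is infeasible (e.g. extreme GC vs. motif bases)."""


# --------------------------------------------------------------------------
# specs and truth


@dataclass(frozen=True)
class MotifTemplate:
    """Planted frameshift-motif layout (defaults mirror *E. coli prfB*).

    The slippery run's last nucleotide is the premature stop's first, so the
    canonical arrangement reads ``...AGGGGG-TAT-CTT-TGA-C...`` with the stop
    at codon ``stop_codon_index``.
    """

    sd: str = "AGGGGG"
    spacer_len: int = 3
    slippery: str = "CTTT"
    stop: str = "TGA"
    following: str = "C"
    stop_codon_index: int = 26
    per_site_mutation_rate: float = 0.0

    def __post_init__(self):
        if len(self.slippery) != 4 or len(self.stop) != 3:
            raise GenerationError("slippery must be 4 nt and stop 3 nt")
        if self.slippery[-1] != self.stop[0]:
            raise GenerationError("slippery's last nt must equal the stop's first nt")
        if self.stop_codon_index < 4:
            raise GenerationError("stop_codon_index must be >= 4 to leave room upstream")
        if not 0.0 <= self.per_site_mutation_rate <= 1.0:
            raise GenerationError("per_site_mutation_rate must be in [0, 1]")

    @property
    def spacer_seq(self) -> str:
        # deterministic low-purine spacer; avoids extending the SD pairing
        return ("TAT" * (self.spacer_len // 3 + 1))[: self.spacer_len]


def _default_stop_probs() -> dict:
    return {"TAA": 0.25, "TAG": 0.15, "TGA": 0.60}


@dataclass
class GenomeSpec:
    """Parameters of one synthetic genome."""

    gc: float = 0.45
    n_cds: int = 20
    stop_probs: dict = field(default_factory=_default_stop_probs)
    transl_table: int = 11
    prfb_present: bool = True
    motif_present: bool = True
    motif: MotifTemplate = field(default_factory=MotifTemplate)
    suppressor_trna: bool = False
    phylum_label: str = "Synthota"
    seed: int = 0
    accession: str = "SYN000001"
    checkm_contamination: float = 1.0
    prfa_present: bool = True
    cds_len_codons: int = 80
    prfb_len_codons: int = 120

    def validate(self) -> None:
        if not 0.05 <= self.gc <= 0.95:
            raise GenerationError(f"target GC {self.gc} infeasible for ORF sampling")
        total = sum(self.stop_probs.get(s, 0.0) for s in ("TAA", "TAG", "TGA"))
        if abs(total - 1.0) > 1e-9:
            raise GenerationError("stop_probs must sum to 1 over TAA/TAG/TGA")
        if self.transl_table == 4:
            if self.stop_probs.get("TGA", 0.0) != 0.0:
                raise GenerationError("table-4 genomes cannot use TGA as a terminal stop")
            if not self.prfb_present and not self.suppressor_trna:
                raise GenerationError(
                    "table-4 genomes without prfB must carry a TGA-suppressor tRNA"
                )
        if self.prfb_len_codons < self.motif.stop_codon_index + 2:
            raise GenerationError("prfB too short for the planted stop codon index")


@dataclass
class SyntheticTruth:
    """Realized (on-disk) parameters of one generated genome."""

    accession: str
    phylum: str
    transl_table: int
    gc_target: float
    prfb_present: bool
    motif_present: bool
    suppressor_trna: bool
    checkm_contamination: float
    n_cds: int
    stop_counts: dict
    premature_stops: list  # [(codon_index, identity), ...] in the prfB frame
    sd: Optional[str] = None
    spacer: Optional[str] = None
    slippery: Optional[str] = None
    stop_identity: Optional[str] = None
    stop_codon_index: Optional[int] = None
    sd_spacer: Optional[int] = None
    following: Optional[str] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["premature_stops"] = [list(p) for p in self.premature_stops]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        d = dict(d)
        d["premature_stops"] = [tuple(p) for p in d.get("premature_stops", [])]
        return cls(**d)


class GenomeResult(NamedTuple):
    seq_record: SeqRecord
    genome: GenomeRecord
    truth: SyntheticTruth


# --------------------------------------------------------------------------
# codon sampling with calibrated GC


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _stop_ids(stop_set: frozenset) -> np.ndarray:
    return np.array(
        sorted(
            _BASE_IDX[c[0]] * 16 + _BASE_IDX[c[1]] * 4 + _BASE_IDX[c[2]]
            for c in stop_set
        )
    )


def _expected_gc_after_rejection(gc_adj: float, stop_set: frozenset) -> float:
    """Expected per-base GC of sense codons drawn at adjusted base GC."""
    p = _base_probs(gc_adj)
    num = 0.0
    den = 0.0
    for i in range(4):
        for j in range(4):
            for k in range(4):
                codon = BASES[i] + BASES[j] + BASES[k]
                if codon in stop_set:
                    continue
                prob = p[i] * p[j] * p[k]
                den += prob
                num += prob * sum(b in "GC" for b in codon)
    return num / (3.0 * den)


@lru_cache(maxsize=128)
def _calibrated_gc(gc_target: float, stop_set: frozenset) -> float:
    """Adjusted base-level GC so sense codons realize the target GC on average."""
    lo, hi = 0.01, 0.99
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _expected_gc_after_rejection(mid, stop_set) < gc_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_sense_codons(
    rng: np.random.Generator, n_codons: int, probs: np.ndarray, stop_ids: np.ndarray
) -> np.ndarray:
    """(n_codons, 3) base indices with no codon in the stop set."""
    idx = rng.choice(4, size=(n_codons, 3), p=probs)
    if n_codons == 0:
        return idx
    codes = idx[:, 0] * 16 + idx[:, 1] * 4 + idx[:, 2]
    bad = np.isin(codes, stop_ids)
    for _ in range(1000):
        if not bad.any():
            return idx
        k = int(bad.sum())
        idx[bad] = rng.choice(4, size=(k, 3), p=probs)
        codes[bad] = idx[bad, 0] * 16 + idx[bad, 1] * 4 + idx[bad, 2]
        bad = np.isin(codes, stop_ids)
    raise GenerationError("could not sample sense codons (degenerate base probabilities)")


def _draw_terminal_stop(rng: np.random.Generator, stop_probs: dict) -> str:
    stops = ("TAA", "TAG", "TGA")
    p = np.array([stop_probs.get(s, 0.0) for s in stops])
    return stops[rng.choice(3, p=p / p.sum())]


def random_orf(
    rng: np.random.Generator,
    n_codons: int,
    gc: float,
    table_id: int,
    terminal_stop: str,
) -> str:
    """A random ORF: ATG + sense codons (no in-frame stop) + terminal stop."""
    if n_codons < 3:
        raise GenerationError("ORF needs at least 3 codons")
    stop_set = stop_codons_of_table(table_id)
    probs = _base_probs(_calibrated_gc(round(gc, 6), stop_set))
    idx = _sample_sense_codons(rng, n_codons - 2, probs, _stop_ids(stop_set))
    return "ATG" + "".join(BASES[idx].ravel()) + terminal_stop


# --------------------------------------------------------------------------
# prfB construction


def _build_prfb(
    rng: np.random.Generator, spec: GenomeSpec, terminal_stop: str
) -> tuple[str, dict]:
    """prfB CDS string plus realized-motif bookkeeping.

    When the motif is planted, element bases are written over the sampled
    sense codons at fixed coordinates, partially-overwritten codons that
    happen to spell a stop are re-resolved in their free positions, and
    per-site mutations are applied to the element block afterwards; realized
    values are then read back off the final sequence.
    """
    t = spec.motif
    n = spec.prfb_len_codons
    stop_set = stop_codons_of_table(spec.transl_table)
    probs = _base_probs(_calibrated_gc(round(spec.gc, 6), stop_set))
    idx = _sample_sense_codons(rng, n - 2, probs, _stop_ids(stop_set))
    seq = list("ATG" + "".join(BASES[idx].ravel()) + terminal_stop)
    fixed = np.zeros(len(seq), dtype=bool)
    fixed[:3] = True
    fixed[-3:] = True

    realized: dict = {}
    if spec.motif_present:
        stop_off = (t.stop_codon_index - 1) * 3
        slip_start = stop_off - 3
        sd_end = slip_start - t.spacer_len  # exclusive
        sd_start = sd_end - len(t.sd)
        if sd_start < 3:
            raise GenerationError("motif does not fit: SD would overlap the start codon")
        block = t.sd + t.spacer_seq + t.slippery + t.stop[1:] + t.following
        lo, hi = sd_start, stop_off + 4
        if hi > len(seq) - 3:
            raise GenerationError("motif does not fit before the terminal stop")
        seq[lo:hi] = list(block)
        fixed[lo:hi] = True

        # resolve accidental stops in codons that mix planted and free bases
        for _ in range(1000):
            dirty = False
            for i in range(1, n - 1):
                if i == t.stop_codon_index - 1:
                    continue
                codon = "".join(seq[3 * i : 3 * i + 3])
                if codon in stop_set:
                    free = [p for p in range(3 * i, 3 * i + 3) if not fixed[p]]
                    if not free:
                        raise GenerationError(
                            f"planted motif forces a stop codon at codon {i + 1}"
                        )
                    for p in free:
                        seq[p] = BASES[rng.choice(4, p=probs)]
                    dirty = True
            if not dirty:
                break
        else:
            raise GenerationError("could not resolve accidental stop codons")

        # per-site mutation of the element block; truth = post-mutation reality
        if t.per_site_mutation_rate > 0:
            for p in range(lo, hi):
                if rng.random() < t.per_site_mutation_rate:
                    others = [b for b in "ACGT" if b != seq[p]]
                    seq[p] = others[rng.choice(3)]

        realized = {
            "sd": "".join(seq[sd_start:sd_end]),
            "spacer": "".join(seq[sd_end:slip_start]),
            "slippery": "".join(seq[slip_start : stop_off + 1]),
            "stop_identity": "".join(seq[stop_off : stop_off + 3]),
            "stop_codon_index": t.stop_codon_index,
            "sd_spacer": t.spacer_len,
            "following": seq[stop_off + 3],
        }
        if realized["stop_identity"] not in stop_set:
            realized["stop_codon_index"] = None  # mutated away

    cds = "".join(seq)
    # realized premature stops, by direct codon enumeration on the final string
    premature = [
        (i + 1, cds[3 * i : 3 * i + 3])
        for i in range(n - 1)
        if cds[3 * i : 3 * i + 3] in stop_set
    ]
    realized["premature_stops"] = premature
    return cds, realized


# --------------------------------------------------------------------------
# genome assembly


def _intergenic(rng: np.random.Generator, gc: float) -> str:
    length = int(rng.integers(20, 61))
    probs = _base_probs(gc)
    return "".join(BASES[rng.choice(4, size=length, p=probs)])


def _cds_feature(start0: int, end0: int, strand: int, qualifiers: dict) -> SeqFeature:
    return SeqFeature(
        FeatureLocation(start0, end0, strand=strand), type="CDS", qualifiers=qualifiers
    )


def generate_genome(spec: GenomeSpec) -> GenomeResult:
    """Emit one synthetic genome: GenBank-writable record, parsed form, truth.

    Deterministic for a fixed ``spec.seed``; genes are placed on random
    strands with random intergenic spacers so strand resolution in the
    parser is exercised.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    stop_counts = {"TAA": 0, "TAG": 0, "TGA": 0}
    parts: list = []  # sequence chunks
    features: list = []
    cursor = 0

    def emit(chunk: str) -> None:
        nonlocal cursor
        parts.append(chunk)
        cursor += len(chunk)

    def place_gene(cds: str, qualifiers: dict) -> None:
        emit(_intergenic(rng, spec.gc))
        strand = 1 if rng.random() < 0.5 else -1
        genomic = cds if strand == 1 else str(Seq(cds).reverse_complement())
        start0 = cursor
        emit(genomic)
        features.append(_cds_feature(start0, cursor, strand, qualifiers))

    def place_trna(anticodon: str, aa: str = "Trp") -> None:
        emit(_intergenic(rng, spec.gc))
        strand = 1 if rng.random() < 0.5 else -1
        body = "".join(BASES[rng.choice(4, size=76, p=_base_probs(spec.gc))])
        start0 = cursor
        emit(body)
        features.append(
            SeqFeature(
                FeatureLocation(start0, cursor, strand=strand),
                type="tRNA",
                qualifiers={
                    "product": [f"tRNA-{aa}"],
                    "anticodon": [
                        f"(pos:{start0 + 34}..{start0 + 36},aa:{aa},seq:{anticodon.lower()})"
                    ],
                },
            )
        )

    table_q = [str(spec.transl_table)]
    realized_motif: dict = {"premature_stops": []}
    n_cds_emitted = 0

    if spec.prfb_present:
        terminal = _draw_terminal_stop(rng, spec.stop_probs)
        stop_counts[terminal] += 1
        cds, realized_motif = _build_prfb(rng, spec, terminal)
        place_gene(cds, {
            "gene": ["prfB"],
            "product": ["peptide chain release factor 2"],
            "transl_table": table_q,
            "codon_start": ["1"],
        })
        n_cds_emitted += 1

    if spec.prfa_present:
        terminal = _draw_terminal_stop(rng, spec.stop_probs)
        stop_counts[terminal] += 1
        cds = random_orf(rng, spec.prfb_len_codons, spec.gc, spec.transl_table, terminal)
        place_gene(cds, {
            "gene": ["prfA"],
            "product": ["peptide chain release factor 1"],
            "transl_table": table_q,
            "codon_start": ["1"],
        })
        n_cds_emitted += 1

    n_plain = max(0, spec.n_cds - n_cds_emitted)
    for k in range(n_plain):
        terminal = _draw_terminal_stop(rng, spec.stop_probs)
        stop_counts[terminal] += 1
        cds = random_orf(rng, spec.cds_len_codons, spec.gc, spec.transl_table, terminal)
        place_gene(cds, {
            "product": ["hypothetical protein"],
            "transl_table": table_q,
            "codon_start": ["1"],
        })
        n_cds_emitted += 1

    place_trna("CCA", "Trp")  # standard Trp tRNA, always present
    if spec.suppressor_trna:
        place_trna("TCA", "Trp")  # TGA-suppressor
    emit(_intergenic(rng, spec.gc))

    genome_seq = "".join(parts)
    source = SeqFeature(
        FeatureLocation(0, len(genome_seq), strand=1),
        type="source",
        qualifiers={
            "organism": [f"synthetic bacterium {spec.accession}"],
            "mol_type": ["genomic DNA"],
            "note": [
                f"phylum={spec.phylum_label}",
                f"checkm_contamination={spec.checkm_contamination:g}",
            ],
        },
    )
    record = SeqRecord(
        Seq(genome_seq),
        id=spec.accession,
        name=spec.accession[:16],
        description="synthetic annotated genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "linear",
            "data_file_division": "BCT",
            "date": "01-JAN-2025",  # fixed so reruns are byte-identical
        },
        features=[source] + features,
    )

    truth = SyntheticTruth(
        accession=spec.accession,
        phylum=spec.phylum_label,
        transl_table=spec.transl_table,
        gc_target=spec.gc,
        prfb_present=spec.prfb_present,
        motif_present=spec.motif_present and spec.prfb_present,
        suppressor_trna=spec.suppressor_trna,
        checkm_contamination=spec.checkm_contamination,
        n_cds=n_cds_emitted,
        stop_counts=stop_counts,
        premature_stops=realized_motif.get("premature_stops", []),
        sd=realized_motif.get("sd"),
        spacer=realized_motif.get("spacer"),
        slippery=realized_motif.get("slippery"),
        stop_identity=realized_motif.get("stop_identity"),
        stop_codon_index=realized_motif.get("stop_codon_index"),
        sd_spacer=realized_motif.get("sd_spacer"),
        following=realized_motif.get("following"),
    )
    genome = genome_from_seqrecords([record])
    return GenomeResult(record, genome, truth)


def write_genbank(result: GenomeResult, path) -> None:
    SeqIO.write([result.seq_record], str(path), "genbank")


# --------------------------------------------------------------------------
# cohorts


def _default_phylum_mix() -> dict:
    return {"Synthota_A": 0.5, "Synthota_B": 0.5}


def _default_identity_probs() -> dict:
    return {"TGA": 0.986, "TAA": 0.014, "TAG": 0.0}


@dataclass
class CohortParams:
    """Population structure of a generated cohort.

    Defaults reflect the observed study conditions: motif prevalence 0.64,
    premature-stop identities overwhelmingly TGA with a small TAA minority
    and no TAG, motif-negative genomes drawn from a higher-GC distribution
    (means 0.45 vs 0.62), and terminal TGA usage tied to GC by a logistic
    link so high-GC genomes use more RF2-specific stops.
    """

    n_cds: int = 20
    motif_prevalence: float = 0.64
    motif_prevalence_by_phylum: Optional[dict] = None
    stop_identity_probs: dict = field(default_factory=_default_identity_probs)
    gc_mean_motif: float = 0.45
    gc_mean_no_motif: float = 0.62
    gc_sd: float = 0.05
    tga_link_k: float = 12.0
    tga_link_mid: float = 0.52
    per_site_mutation_rate: float = 0.0
    # small minority of reduced table-4 genomes lacking prfB (suppressor tRNA
    # instead), matching their rarity among representative bacterial genomes
    table4_fraction: float = 0.01
    phylum_mix: dict = field(default_factory=_default_phylum_mix)
    cds_len_codons: int = 80
    prfb_len_codons: int = 120


def _logistic_tga(gc: float, k: float, mid: float) -> float:
    return 1.0 / (1.0 + math.exp(-k * (gc - mid)))


def _terminal_probs_for_gc(gc: float, params: CohortParams, table4: bool) -> dict:
    if table4:
        return {"TAA": 0.85, "TAG": 0.15, "TGA": 0.0}
    p_tga = _logistic_tga(gc, params.tga_link_k, params.tga_link_mid)
    return {"TGA": p_tga, "TAA": 0.8 * (1 - p_tga), "TAG": 0.2 * (1 - p_tga)}


@dataclass
class CohortResult:
    genomes: list  # list[GenomeResult]
    manifest: dict
    paths: list = field(default_factory=list)


def generate_cohort(
    n: int,
    params: Optional[CohortParams] = None,
    seed: int = 0,
    out_dir=None,
) -> CohortResult:
    """Generate ``n`` genomes with independent per-genome specs.

    Per-genome RNG streams are spawned from one root ``numpy`` SeedSequence
    (child ``i`` of the root seed), so cohorts are reproducible piecewise.
    When ``out_dir`` is given, genomes are written as GenBank flat files
    plus a ``truth_manifest.json``.
    """
    if n <= 0:
        raise ValueError("cohort size n must be positive")
    params = params or CohortParams()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n)
    phyla = sorted(params.phylum_mix)
    mix = np.array([params.phylum_mix[p] for p in phyla], dtype=float)
    mix = mix / mix.sum()

    results: list = []
    for i, child in enumerate(children):
        draw_rng = np.random.default_rng(child)
        genome_seed = int(draw_rng.integers(0, 2**31 - 1))
        phylum = phyla[draw_rng.choice(len(phyla), p=mix)]
        table4 = draw_rng.random() < params.table4_fraction
        if table4:
            motif = False
            prfb = False
            gc = float(np.clip(draw_rng.normal(0.30, 0.03), 0.25, 0.40))
        else:
            prevalence = params.motif_prevalence
            if params.motif_prevalence_by_phylum is not None:
                prevalence = params.motif_prevalence_by_phylum.get(phylum, prevalence)
            motif = draw_rng.random() < prevalence
            prfb = True
            mean = params.gc_mean_motif if motif else params.gc_mean_no_motif
            gc = float(np.clip(draw_rng.normal(mean, params.gc_sd), 0.25, 0.75))
        identities = sorted(params.stop_identity_probs)
        id_p = np.array([params.stop_identity_probs[s] for s in identities])
        identity = identities[draw_rng.choice(len(identities), p=id_p / id_p.sum())]
        spec = GenomeSpec(
            gc=gc,
            n_cds=params.n_cds,
            stop_probs=_terminal_probs_for_gc(gc, params, table4),
            transl_table=4 if table4 else 11,
            prfb_present=prfb,
            motif_present=motif,
            motif=MotifTemplate(
                stop=identity, per_site_mutation_rate=params.per_site_mutation_rate
            ),
            suppressor_trna=table4,
            phylum_label=phylum,
            seed=genome_seed,
            accession=f"SYN{i:06d}",
            checkm_contamination=float(draw_rng.uniform(0.0, 5.0)),
            cds_len_codons=params.cds_len_codons,
            prfb_len_codons=params.prfb_len_codons,
        )
        results.append(generate_genome(spec))

    manifest = {
        "seed": seed,
        "n": n,
        "params": dataclasses.asdict(params),
        "genomes": [r.truth.to_dict() for r in results],
    }
    paths = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for r in results:
            p = out_dir / f"{r.truth.accession}.gbk"
            write_genbank(r, p)
            paths.append(p)
        (out_dir / "truth_manifest.json").write_text(json.dumps(manifest, indent=1))
    return CohortResult(genomes=results, manifest=manifest, paths=paths)


# --------------------------------------------------------------------------
# summary-level cohorts (for statistical power studies)


def simulate_group_summaries(
    n_per_group: int,
    gc_mean_motif: float = 0.45,
    gc_mean_no_motif: float = 0.55,
    gc_sd: float = 0.05,
    n_cds: int = 20,
    tga_link_k: float = 12.0,
    tga_link_mid: float = 0.52,
    seed: int = 0,
):
    """Per-genome (GC, terminal-TGA fraction) summaries for two groups.

    Draws exactly the quantities the group comparison consumes -- GC from
    the group's normal, TGA terminal usage as a binomial fraction at the
    logistic link probability -- without emitting sequences, which makes
    replicate-heavy power studies cheap while keeping the same generative
    law as :func:`generate_cohort`.

    Returns ``(gc_motif, tga_motif, gc_no_motif, tga_no_motif)`` arrays.
    """
    rng = np.random.default_rng(seed)
    out = []
    for mean in (gc_mean_motif, gc_mean_no_motif):
        gc = np.clip(rng.normal(mean, gc_sd, size=n_per_group), 0.25, 0.75)
        p = 1.0 / (1.0 + np.exp(-tga_link_k * (gc - tga_link_mid)))
        tga = rng.binomial(n_cds, p) / n_cds
        out.extend([gc, tga])
    return tuple(out)
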