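"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are 1-based inclusive (GFF3/VCF convention); only BED
output converts to 0-based half-open, once, at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("teparyscan")

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

MISSING = -1  # genotype code for ./.


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One FASTA record; ``kind`` is 'nucleotide', 'cds' or 'protein'."""

    id: str
    seq: str
    kind: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"record '{self.id}': empty sequence")
        alphabet = PROTEIN_ALPHABET if self.kind == "protein" else NUCLEOTIDE_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise FormatError(
                f"record '{self.id}': characters {sorted(bad)} outside the "
                f"{self.kind} alphabet"
            )
        if self.kind == "cds" and len(self.seq) % 3 != 0:
            raise FormatError(
                f"record '{self.id}': CDS length {len(self.seq)} not a multiple of 3"
            )


def read_fasta(path: str | Path, kind: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    ``kind`` is one of ``nucleotide``, ``cds`` (nucleotide + length % 3 == 0)
    or ``protein``. Duplicate ids, empty sequences, and CDS length violations
    are hard errors.
    """
    if kind not in {"nucleotide", "cds", "protein"}:
        raise ValueError(f"unknown sequence kind '{kind}'")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id '{rec.id}'")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), kind))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene loci (GFF3)
# ---------------------------------------------------------------------------

@dataclass
class GeneLocus:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"
    rank: int = -1  # 0-based order along the chromosome, assigned after sorting

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene '{self.gene_id}': start {self.start} > end {self.end}"
            )


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        k, _, v = part.strip().partition("=")
        if k == key:
            return v
    return None


def read_gff_genes(path: str | Path) -> list[GeneLocus]:
    """Read ``gene`` features from a GFF3 file and rank them per chromosome.

    Ranks are consecutive 0-based integers per chromosome, assigned by
    ascending start, ties broken by ascending end then gene_id.
    """
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            if cols[2] != "gene":
                continue
            gene_id = _gff_attr(cols[8], "ID")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            loci.append(GeneLocus(gene_id, cols[0], start, end, cols[6]))
    return assign_ranks(loci)


def assign_ranks(loci: Sequence[GeneLocus]) -> list[GeneLocus]:
    """Assign per-chromosome 0-based ranks by (start, end, gene_id)."""
    out: list[GeneLocus] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        for rank, locus in enumerate(ordered):
            locus.rank = rank
            out.append(locus)
    return out


def write_gff_genes(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in loci:
            fh.write(
                f"{g.chrom}\tteparyscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# protein domain hits
# ---------------------------------------------------------------------------

@dataclass
class DomainHit:
    protein_id: str
    domain_name: str
    domain_acc: str  # Pfam-style accession; empty for COILS
    evalue: float  # per-domain independent E-value; 1 - probability for COILS
    ali_start: int  # 1-based inclusive aa
    ali_end: int  # 1-based inclusive aa
    source: str  # generic_pass | profile_pass | coils

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise FormatError(
                f"hit {self.domain_name} on '{self.protein_id}': "
                f"ali_start {self.ali_start} > ali_end {self.ali_end}"
            )
        if not np.isfinite(self.evalue) or self.evalue < 0:
            raise FormatError(
                f"hit {self.domain_name} on '{self.protein_id}': bad E-value {self.evalue}"
            )

    @property
    def probability(self) -> float:
        """COILS probability, re-derived from the stored 1 - evalue."""
        return 1.0 - self.evalue


# hmmscan-orientation domtblout: target = domain profile, query = protein.
_DOMTBL_MIN_COLS = 22
_DOMTBL_TARGET, _DOMTBL_TACC, _DOMTBL_QUERY = 0, 1, 3
_DOMTBL_IEVALUE, _DOMTBL_ALI_FROM, _DOMTBL_ALI_TO = 12, 17, 18


def read_domain_table(path: str | Path, source_label: str) -> list[DomainHit]:
    """Parse a domtblout-dialect domain table (one :class:`DomainHit` per row).

    Columns follow the hmmscan orientation: target name = domain, target
    accession = Pfam accession, query name = protein. The per-domain
    independent E-value column and the alignment (ali) coordinate columns are
    used. Comment lines start with '#'. Unparsable rows are hard errors with
    the line number.
    """
    if source_label not in {"generic_pass", "profile_pass"}:
        raise ValueError(f"unknown source label '{source_label}'")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, got {len(cols)}"
                )
            try:
                evalue = float(cols[_DOMTBL_IEVALUE])
                ali_start = int(cols[_DOMTBL_ALI_FROM])
                ali_end = int(cols[_DOMTBL_ALI_TO])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable numeric field") from exc
            if ali_start < 0 or ali_end < 0:
                raise FormatError(f"{path}:{lineno}: negative alignment coordinate")
            acc = cols[_DOMTBL_TACC]
            hits.append(
                DomainHit(
                    protein_id=cols[_DOMTBL_QUERY],
                    domain_name=cols[_DOMTBL_TARGET],
                    domain_acc="" if acc == "-" else acc.split(".")[0],
                    evalue=evalue,
                    ali_start=ali_start,
                    ali_end=ali_end,
                    source=source_label,
                )
            )
    return hits


def read_coils_table(path: str | Path) -> list[DomainHit]:
    """Read a COILS segment table (TSV: protein, start, end, probability).

    The probability is stored as ``1 - evalue`` so the single threshold
    machinery of the classifier serves both Pfam and COILS evidence.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "protein\t")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            try:
                start, end, prob = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable field") from exc
            if not 0.0 <= prob <= 1.0:
                raise FormatError(f"{path}:{lineno}: probability {prob} outside [0, 1]")
            hits.append(
                DomainHit(cols[0], "COILS", "", 1.0 - prob, start, end, "coils")
            )
    return hits


# ---------------------------------------------------------------------------
# tabular BLAST (12-column outfmt 6)
# ---------------------------------------------------------------------------

@dataclass
class SimilarityEdge:
    query: str
    subject: str
    bitscore: float
    evalue: float


def read_blast_tab(path: str | Path, evalue_cutoff: float = 1e-10) -> list[SimilarityEdge]:
    """Read a 12-column tabular BLAST file, keeping edges with E <= cutoff."""
    edges: list[SimilarityEdge] = []
    n_filtered = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                evalue, bitscore = float(cols[10]), float(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable score field") from exc
            if evalue > evalue_cutoff:
                n_filtered += 1
                continue
            edges.append(SimilarityEdge(cols[0], cols[1], bitscore, evalue))
    if n_filtered:
        logger.info("%s: filtered %d edges above E-value cutoff %g", path, n_filtered, evalue_cutoff)
    return edges


# ---------------------------------------------------------------------------
# population map and VCF
# ---------------------------------------------------------------------------

POPULATIONS = ("wild", "landrace")


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping sample_id -> population (wild/landrace)."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "sample_id\t")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            sample, pop = cols
            if pop not in POPULATIONS:
                raise FormatError(f"{path}:{lineno}: unknown population '{pop}'")
            if sample in popmap:
                raise FormatError(f"{path}:{lineno}: duplicate sample '{sample}'")
            popmap[sample] = pop
    for pop in POPULATIONS:
        if pop not in popmap.values():
            raise FormatError(f"{path}: population '{pop}' has no samples")
    return popmap


@dataclass
class SiteRecord:
    """One biallelic SNP; genotypes are per-sample codes.

    Codes: 0 = hom ref, 1 = het, 2 = hom alt, -1 = missing. The sample order
    is carried by the enclosing :class:`VariantTable`.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray  # int8 array over samples


class VariantTable(Sequence):
    """Ordered collection of :class:`SiteRecord` plus the shared sample order."""

    def __init__(self, samples: list[str], sites: list[SiteRecord]):
        self.samples = list(samples)
        self.sites = sites

    def __len__(self) -> int:
        return len(self.sites)

    def __getitem__(self, i):
        return self.sites[i]

    def __iter__(self):
        return iter(self.sites)


def read_vcf_biallelic(path: str | Path, popmap: dict[str, str]) -> VariantTable:
    """Read biallelic SNPs from a VCF v4.x file.

    Multi-allelic and non-SNP records are skipped with a logged count; phased
    separators are treated as unphased. A VCF sample absent from ``popmap``
    and unsorted positions are hard errors.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for sample in samples:
        if sample not in popmap:
            raise FormatError(f"{path}: sample '{sample}' absent from population map")
    sites: list[SiteRecord] = []
    n_skipped = 0
    last: dict[str, int] = {}
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        if var.CHROM in last and var.POS <= last[var.CHROM]:
            raise FormatError(
                f"{path}: unsorted positions on {var.CHROM} at {var.POS}"
            )
        last[var.CHROM] = var.POS
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types)
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        codes[gt == 0] = 0
        codes[gt == 1] = 1
        codes[gt == 3] = 2
        sites.append(SiteRecord(var.CHROM, var.POS, var.REF, var.ALT[0], codes))
    if n_skipped:
        logger.info("%s: skipped %d non-SNP/multi-allelic records", path, n_skipped)
    return VariantTable(samples, sites)


# ---------------------------------------------------------------------------
# generic tabular output
# ---------------------------------------------------------------------------

def write_tsv(rows: Iterable[Sequence], columns: Sequence[str], path: str | Path,
              header_lines: Sequence[str] = ()) -> None:
    """Write rows as TSV with optional '#'-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path,
              header_lines: Sequence[str] = ()) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED4."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
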