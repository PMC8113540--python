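"""Rule-based NLR repertoire classification and physical clustering.

The engine mirrors the two-pass domain-annotation strategy used for plant
disease-resistance (NB-ARC) gene surveys: a generic Pfam scan seeds the
protein universe at a strict E-value, a lineage-specific NB-ARC profile scan
rescues divergent domains and replaces the generic NB-ARC hits, and a set of
positional rules then derives the canonical architecture class (CNL, TNL,
RNL, NL, CN, TN, RN, N), the NB-ARC motif signatures (P-loop, kinase-2,
ARC1, ARC2), integrated (non-canonical, non-overlapping) domains, and
physical gene clusters along the chromosomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io import DomainHit, GeneLocus

# Canonical NLR-associated Pfam accessions. NB-ARC is configurable via
# NlrThresholds; COILS is a synthetic label for coiled-coil segments.
CANONICAL_ACCESSIONS: dict[str, str] = {
    "TIR": "PF01582",
    "TIR_2": "PF13676",
    "LRR_3": "PF07725",
    "LRR_4": "PF12799",
    "LRR_5": "PF13306",
    "LRR_8": "PF13855",
    "RPW8": "PF05659",
}
DEFAULT_NBARC_ACC = "PF00931"

TIR_NAMES = frozenset({"TIR", "TIR_2"})
LRR_NAMES = frozenset({"LRR_3", "LRR_4", "LRR_5", "LRR_8"})

DEFAULT_MOTIFS: dict[str, str] = {
    "P-loop": "GTTK",
    "kinase2": "VLDD",
    "ARC1": "GLPL",
    "ARC2": "MHD",
}

CLUSTER_MAX_GAP_BP = 200_000
CLUSTER_MAX_INTERVENING = 9
CLUSTER_MIN_GENES = 3


class NlrError(ValueError):
    pass


@dataclass
class NlrThresholds:
    """Thresholds of the classification rules.

    seed_evalue gates the generic-pass NB-ARC universe; id_evalue gates every
    other Pfam domain; coils_prob is the minimum COILS segment probability.
    """

    seed_evalue: float = 1e-60
    id_evalue: float = 1.0
    coils_prob: float = 0.90
    motifs: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    nbarc_acc: str = DEFAULT_NBARC_ACC

    def __post_init__(self) -> None:
        if self.seed_evalue > self.id_evalue:
            raise NlrError("seed_evalue must be <= id_evalue")

    def is_nbarc(self, hit: DomainHit) -> bool:
        return hit.domain_acc == self.nbarc_acc or hit.domain_name == "NB-ARC"


@dataclass
class NlrRecord:
    protein_id: str
    nbarc_hits: list[DomainHit]
    arch_class: str
    domain_string: str  # e.g. "C-N-N-L"; records all canonical hits in order
    motifs_present: set[str]
    integrated_domains: list[tuple[str, str, int, int]]  # (name, acc, start, end)
    is_nlr: bool  # has >= 1 LRR-family domain


@dataclass
class NbarcCluster:
    cluster_id: str  # chromosome number + letter, e.g. "4A"
    members: list[str]  # gene ids in positional order
    chrom: str
    span: tuple[int, int]


@dataclass
class ClusterPairing:
    cluster_a: str
    cluster_b: str
    supporting_rbh_pairs: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# two-pass merge and universe selection
# ---------------------------------------------------------------------------

def merge_domain_passes(
    generic_hits: list[DomainHit],
    profile_hits: list[DomainHit],
    thresholds: NlrThresholds | None = None,
) -> dict[str, list[DomainHit]]:
    """Substitute profile-pass NB-ARC hits for the generic-pass NB-ARC hits.

    For every protein with at least one profile-pass NB-ARC hit, the generic
    NB-ARC hits are dropped and replaced by the profile hits; all non-NB-ARC
    generic hits are retained unchanged.
    """
    thresholds = thresholds or NlrThresholds()
    merged: dict[str, list[DomainHit]] = {}
    profile_by_protein: dict[str, list[DomainHit]] = {}
    for hit in profile_hits:
        if not thresholds.is_nbarc(hit):
            raise NlrError(
                f"profile pass contains a non-NB-ARC hit '{hit.domain_name}'"
            )
        profile_by_protein.setdefault(hit.protein_id, []).append(hit)
    for hit in generic_hits:
        if thresholds.is_nbarc(hit) and hit.protein_id in profile_by_protein:
            continue  # substituted by the profile pass
        merged.setdefault(hit.protein_id, []).append(hit)
    for protein_id, hits in profile_by_protein.items():
        merged.setdefault(protein_id, []).extend(hits)
    for hits in merged.values():
        hits.sort(key=lambda h: (h.ali_start, h.ali_end, h.domain_name))
    return merged


def select_universe(
    generic_hits: list[DomainHit],
    profile_hits: list[DomainHit],
    thresholds: NlrThresholds | None = None,
) -> set[str]:
    """Proteins entering classification: generic NB-ARC below the seed
    E-value, plus every protein rescued by the NB-ARC profile pass."""
    thresholds = thresholds or NlrThresholds()
    universe = {
        h.protein_id
        for h in generic_hits
        if thresholds.is_nbarc(h) and h.evalue < thresholds.seed_evalue
    }
    universe.update(h.protein_id for h in profile_hits)
    return universe


# ---------------------------------------------------------------------------
# per-protein classification
# ---------------------------------------------------------------------------

def _canonical_letter(hit: DomainHit, thresholds: NlrThresholds) -> str | None:
    """Letter of a canonical hit passing its threshold, else None."""
    if thresholds.is_nbarc(hit):
        return "N"
    if hit.source == "coils" or hit.domain_name == "COILS":
        return "C" if hit.probability >= thresholds.coils_prob else None
    if hit.evalue >= thresholds.id_evalue:
        return None
    if hit.domain_name in TIR_NAMES or hit.domain_acc in (
        CANONICAL_ACCESSIONS["TIR"], CANONICAL_ACCESSIONS["TIR_2"]):
        return "T"
    if hit.domain_name == "RPW8" or hit.domain_acc == CANONICAL_ACCESSIONS["RPW8"]:
        return "R"
    if hit.domain_name in LRR_NAMES or hit.domain_acc in (
        CANONICAL_ACCESSIONS["LRR_3"], CANONICAL_ACCESSIONS["LRR_4"],
        CANONICAL_ACCESSIONS["LRR_5"], CANONICAL_ACCESSIONS["LRR_8"]):
        return "L"
    return None


def classify_architecture(
    protein_id: str,
    hits: list[DomainHit],
    thresholds: NlrThresholds | None = None,
) -> NlrRecord:
    """Derive the architecture class of one NB-ARC protein from its hits.

    Presence flags: T (TIR/TIR_2), R (RPW8), C (COILS >= coils_prob),
    L (any LRR family). The N-terminal letter of the core class follows the
    precedence TIR > RPW8 > COILS; the domain string records every canonical
    hit left-to-right so composite architectures (e.g. C-N-N-L) stay visible.
    """
    thresholds = thresholds or NlrThresholds()
    nbarc_hits = [h for h in hits if thresholds.is_nbarc(h)]
    if not nbarc_hits:
        raise NlrError(f"'{protein_id}' has no NB-ARC hit; not classifiable")
    letters: list[str] = []
    for hit in sorted(hits, key=lambda h: (h.ali_start, h.ali_end, h.domain_name)):
        letter = _canonical_letter(hit, thresholds)
        if letter is not None:
            letters.append(letter)
    flags = set(letters)
    if "T" in flags:
        nterm = "T"
    elif "R" in flags:
        nterm = "R"
    else:
        nterm = "C" if "C" in flags else ""
    arch_class = nterm + "N" + ("L" if "L" in flags else "")
    return NlrRecord(
        protein_id=protein_id,
        nbarc_hits=sorted(nbarc_hits, key=lambda h: h.ali_start),
        arch_class=arch_class,
        domain_string="-".join(letters),
        motifs_present=set(),
        integrated_domains=[],
        is_nlr="L" in flags,
    )


def detect_motifs(
    protein_seq: str,
    nbarc_hits: list[DomainHit],
    thresholds: NlrThresholds | None = None,
) -> set[str]:
    """Motifs whose exact amino-acid string occurs inside any NB-ARC span."""
    thresholds = thresholds or NlrThresholds()
    present: set[str] = set()
    for hit in nbarc_hits:
        if hit.ali_start < 1 or hit.ali_end > len(protein_seq):
            raise NlrError(
                f"NB-ARC span {hit.ali_start}-{hit.ali_end} outside "
                f"'{hit.protein_id}' (length {len(protein_seq)})"
            )
        span = protein_seq[hit.ali_start - 1 : hit.ali_end]
        for name, motif in thresholds.motifs.items():
            if motif in span:
                present.add(name)
    return present


def _is_canonical(hit: DomainHit, thresholds: NlrThresholds) -> bool:
    return (
        thresholds.is_nbarc(hit)
        or hit.source == "coils"
        or hit.domain_name == "COILS"
        or hit.domain_name in TIR_NAMES
        or hit.domain_name in LRR_NAMES
        or hit.domain_name == "RPW8"
        or hit.domain_acc in CANONICAL_ACCESSIONS.values()
    )


def find_integrated_domains(
    hits: list[DomainHit],
    thresholds: NlrThresholds | None = None,
) -> list[tuple[str, str, int, int]]:
    """Non-canonical domains (E < id_evalue) overlapping no other hit.

    Overlap means sharing at least one amino-acid position with ANY other
    hit, canonical or not, COILS included.
    """
    thresholds = thresholds or NlrThresholds()
    out: list[tuple[str, str, int, int]] = []
    for i, hit in enumerate(hits):
        if _is_canonical(hit, thresholds) or hit.evalue >= thresholds.id_evalue:
            continue
        overlapping = any(
            j != i
            and other.ali_start <= hit.ali_end
            and hit.ali_start <= other.ali_end
            for j, other in enumerate(hits)
        )
        if not overlapping:
            out.append((hit.domain_name, hit.domain_acc, hit.ali_start, hit.ali_end))
    return sorted(out, key=lambda d: d[2])


def classify_proteome(
    generic_hits: list[DomainHit],
    profile_hits: list[DomainHit],
    coils_hits: list[DomainHit],
    sequences: dict[str, str] | None = None,
    thresholds: NlrThresholds | None = None,
) -> dict[str, NlrRecord]:
    """Run the full per-protein engine: merge, classify, motifs, IDs."""
    thresholds = thresholds or NlrThresholds()
    universe = select_universe(generic_hits, profile_hits, thresholds)
    merged = merge_domain_passes(generic_hits, profile_hits, thresholds)
    for hit in coils_hits:
        if hit.protein_id in universe:
            merged.setdefault(hit.protein_id, []).append(hit)
    records: dict[str, NlrRecord] = {}
    for protein_id in sorted(universe):
        hits = sorted(
            merged.get(protein_id, []),
            key=lambda h: (h.ali_start, h.ali_end, h.domain_name),
        )
        record = classify_architecture(protein_id, hits, thresholds)
        record.integrated_domains = find_integrated_domains(hits, thresholds)
        if sequences is not None and protein_id in sequences:
            record.motifs_present = detect_motifs(
                sequences[protein_id], record.nbarc_hits, thresholds
            )
        records[protein_id] = record
    return records


# ---------------------------------------------------------------------------
# physical clusters
# ---------------------------------------------------------------------------

def _chrom_number(chrom: str) -> str:
    digits = re.sub(r"\D", "", chrom)
    return str(int(digits)) if digits else chrom


def _letters(index: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ..."""
    label = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def intergene_distance(upstream: GeneLocus, downstream: GeneLocus) -> int:
    """bp from the end of the upstream gene to the start of the downstream
    gene; overlapping genes count as distance 0."""
    return max(downstream.start - upstream.end, 0)


def find_clusters(
    nbarc_gene_ids: set[str] | list[str],
    all_loci: list[GeneLocus],
) -> list[NbarcCluster]:
    """Chain NB-ARC genes into physical clusters.

    Per chromosome, NB-ARC genes are scanned in rank order; two consecutive
    NB-ARC genes are chained iff they lie < 200 kb apart AND no more than 9
    other gene models sit between them. Maximal chains of >= 3 genes become
    clusters, lettered A, B, ... in positional order per chromosome.
    """
    nbarc_ids = set(nbarc_gene_ids)
    by_id = {g.gene_id: g for g in all_loci}
    missing = nbarc_ids - set(by_id)
    if missing:
        raise NlrError(f"gene ids absent from loci: {sorted(missing)[:5]}")
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in all_loci:
        if g.gene_id in nbarc_ids:
            by_chrom.setdefault(g.chrom, []).append(g)
    clusters: list[NbarcCluster] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: g.rank)
        chains: list[list[GeneLocus]] = []
        chain = [genes[0]] if genes else []
        for prev, cur in zip(genes, genes[1:]):
            linked = (
                intergene_distance(prev, cur) < CLUSTER_MAX_GAP_BP
                and (cur.rank - prev.rank - 1) <= CLUSTER_MAX_INTERVENING
            )
            if linked:
                chain.append(cur)
            else:
                chains.append(chain)
                chain = [cur]
        if chain:
            chains.append(chain)
        letter_idx = 0
        for members in chains:
            if len(members) < CLUSTER_MIN_GENES:
                continue
            clusters.append(
                NbarcCluster(
                    cluster_id=f"{_chrom_number(chrom)}{_letters(letter_idx)}",
                    members=[g.gene_id for g in members],
                    chrom=chrom,
                    span=(min(g.start for g in members), max(g.end for g in members)),
                )
            )
            letter_idx += 1
    return clusters


def clustered_fraction(clusters: list[NbarcCluster], nbarc_gene_ids) -> float:
    """Fraction of NB-ARC genes located in clusters."""
    total = len(set(nbarc_gene_ids))
    if total == 0:
        return 0.0
    in_clusters = sum(len(c.members) for c in clusters)
    return in_clusters / total


def relate_clusters(
    clusters_a: list[NbarcCluster],
    clusters_b: list[NbarcCluster],
    rbh_pairs: list[tuple[str, str]],
) -> list[ClusterPairing]:
    """Pair clusters across species sharing >= 1 reciprocal-best-hit pair."""
    gene_to_cluster_a = {g: c.cluster_id for c in clusters_a for g in c.members}
    gene_to_cluster_b = {g: c.cluster_id for c in clusters_b for g in c.members}
    support: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for a, b in rbh_pairs:
        ca, cb = gene_to_cluster_a.get(a), gene_to_cluster_b.get(b)
        if ca is not None and cb is not None:
            support.setdefault((ca, cb), []).append((a, b))
    return [
        ClusterPairing(ca, cb, sorted(pairs))
        for (ca, cb), pairs in sorted(support.items())
    ]
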