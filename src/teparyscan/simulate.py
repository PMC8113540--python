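"""Synthetic-data generators with known ground truth for every stage.

Three generators emulate the pipeline's real inputs at desk scale:

* ortholog CDS pairs diverged by an explicit Poisson substitution process on
  codon positions, so the planted synonymous divergence is exact event
  arithmetic;
* a proteome with planted NLR domain architectures, motifs, integrated
  domains and physical gene clusters (plus negative controls violating each
  clustering and classification sub-rule), emitted as domain tables in the
  domtblout dialect, a COILS table, GFF3 and BLAST-tabular files;
* a two-population genotype matrix with planted diversity-reduction (sweep)
  blocks and fixed-difference sites, emitted as VCF + popmap + GFF3.

Every generator writes a truth file sufficient for downstream assertions;
fixed seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .io import (
    DomainHit,
    GeneLocus,
    SequenceRecord,
    SiteRecord,
    VariantTable,
    assign_ranks,
    write_fasta,
    write_gff_genes,
    write_tsv,
)
from .ks import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    synonymous_site_fraction,
)
from .popgen import harmonic

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# ortholog pair simulation
# ---------------------------------------------------------------------------

@dataclass
class OrthologSimSpec:
    """Study conditions for one batch of simulated ortholog pairs.

    ``p_s``/``p_n`` are the per-branch expected numbers of synonymous /
    non-synonymous substitutions per (synonymous / non-synonymous) site, so
    the planted pairwise synonymous divergence is 2 * p_s.
    """

    n_pairs: int
    n_codons: int = 300  # median gene length in codons
    p_s: float = 0.16
    p_n: float = 0.02
    seed: int = 0
    indel_rate: float = 0.0  # per-pair probability of a 1-3 codon deletion in b
    length_log_sd: float = 0.35  # log-normal spread of gene lengths, as in a
    # real proteome; 0 gives fixed-length genes

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_s <= 0.5 and 0.0 <= self.p_n <= 0.5):
            raise ValueError("p_s and p_n must lie in [0, 0.5]")
        if self.n_codons < 50:
            raise ValueError("n_codons must be >= 50")
        if self.length_log_sd < 0:
            raise ValueError("length_log_sd must be >= 0")


@lru_cache(maxsize=None)
def _position_alternatives(codon: str, pos: int) -> tuple[float, tuple[str, ...], tuple[str, ...]]:
    """(syn site fraction, synonymous targets, non-synonymous targets) for
    one position of a sense codon; targets exclude stop codons."""
    aa = CODON_TO_AA[codon]
    syn, nonsyn = [], []
    for base in BASES:
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        (syn if CODON_TO_AA[alt] == aa else nonsyn).append(alt)
    valid = len(syn) + len(nonsyn)
    frac = len(syn) / valid if valid else 0.0
    return frac, tuple(syn), tuple(nonsyn)


def _evolve_codon(codon: str, p_s: float, p_n: float, rng: np.random.Generator) -> tuple[str, int, int]:
    """Apply Poisson substitution events to one codon along one branch.

    Event counts are drawn per position at rate p_s * f (synonymous) and
    p_n * (1 - f) (non-synonymous), with f the position's synonymous site
    fraction; each event jumps to a uniformly chosen alternative of the
    matching class for the codon's current state. Returns the evolved codon
    and the realized (synonymous, non-synonymous) event counts.
    """
    n_syn = n_nonsyn = 0
    for pos in range(3):
        frac, _, _ = _position_alternatives(codon, pos)
        k_syn = rng.poisson(p_s * frac)
        k_nonsyn = rng.poisson(p_n * (1.0 - frac))
        for _ in range(k_syn):
            _, syn_alts, _ = _position_alternatives(codon, pos)
            if syn_alts:
                codon = syn_alts[rng.integers(len(syn_alts))]
                n_syn += 1
        for _ in range(k_nonsyn):
            _, _, nonsyn_alts = _position_alternatives(codon, pos)
            if nonsyn_alts:
                codon = nonsyn_alts[rng.integers(len(nonsyn_alts))]
                n_nonsyn += 1
    return codon, n_syn, n_nonsyn


@dataclass
class SimulatedOrthologs:
    records_a: list[SequenceRecord]
    records_b: list[SequenceRecord]
    truth: list[dict]  # per pair: ids, true_ks, true_ka, s_sites, event counts

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records_a, outdir / "species_a.cds.fasta")
        write_fasta(self.records_b, outdir / "species_b.cds.fasta")
        write_tsv(
            [
                (t["id_a"], t["id_b"], f"{t['true_ks']:.6g}", f"{t['true_ka']:.6g}",
                 f"{t['s_sites']:.4f}", t["events_s"], t["events_n"])
                for t in self.truth
            ],
            ["id_a", "id_b", "true_ks", "true_ka", "s_sites", "events_s", "events_n"],
            outdir / "truth.tsv",
        )
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def simulate_ortholog_pairs(spec: OrthologSimSpec) -> SimulatedOrthologs:
    """Simulate CDS ortholog pairs with exactly known synonymous divergence.

    The ancestor is codon-uniform over the 61 sense codons; each descendant
    evolves by the Poisson event process of :func:`_evolve_codon` (no indels
    by default; ``indel_rate`` enables a 1-3 codon deletion in descendant b
    to exercise alignment back-projection). The truth Ks of a pair is the
    realized synonymous event count over the ancestor's synonymous site
    count, restricted to codons surviving in both descendants.
    """
    rng = np.random.default_rng(spec.seed)
    records_a, records_b, truth = [], [], []
    for i in range(spec.n_pairs):
        if spec.length_log_sd > 0:
            n_codons = max(50, int(round(spec.n_codons * np.exp(rng.normal(0.0, spec.length_log_sd)))))
        else:
            n_codons = spec.n_codons
        ancestor = [SENSE_CODONS[k] for k in rng.integers(len(SENSE_CODONS), size=n_codons)]
        deleted: set[int] = set()
        if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
            del_len = int(rng.integers(1, 4))
            del_start = int(rng.integers(1, n_codons - del_len))  # keep termini
            deleted = set(range(del_start, del_start + del_len))
        codons_a, codons_b = [], []
        events_s = events_n = 0
        s_sites = 0.0
        for j, codon in enumerate(ancestor):
            ca, sa, na = _evolve_codon(codon, spec.p_s, spec.p_n, rng)
            cb, sb, nb = _evolve_codon(codon, spec.p_s, spec.p_n, rng)
            codons_a.append(ca)
            if j not in deleted:
                codons_b.append(cb)
                events_s += sa + sb
                events_n += na + nb
                s_sites += synonymous_site_fraction(codon)
        n_kept = n_codons - len(deleted)
        n_sites = 3.0 * n_kept - s_sites
        id_a, id_b = f"geneA_{i:05d}", f"geneB_{i:05d}"
        records_a.append(SequenceRecord(id_a, "".join(codons_a), "cds"))
        records_b.append(SequenceRecord(id_b, "".join(codons_b), "cds"))
        truth.append(
            {
                "id_a": id_a,
                "id_b": id_b,
                "true_ks": events_s / s_sites if s_sites else 0.0,
                "true_ka": events_n / n_sites if n_sites else 0.0,
                "s_sites": s_sites,
                "events_s": int(events_s),
                "events_n": int(events_n),
                "n_codons": n_kept,
            }
        )
    return SimulatedOrthologs(records_a, records_b, truth)


# ---------------------------------------------------------------------------
# NLR genome simulation
# ---------------------------------------------------------------------------

CORE_CLASSES = ("CNL", "TNL", "RNL", "NL", "CN", "TN", "RN", "N")
CORE_CLASS_WEIGHTS = (0.25, 0.20, 0.05, 0.20, 0.10, 0.05, 0.02, 0.13)

# non-canonical Pfam domains available for integration, with typical lengths
INTEGRATED_POOL = (
    ("zf-BED", "PF02892", 45),
    ("Pkinase", "PF00069", 80),
    ("WRKY", "PF03106", 60),
    ("zf-RVT", "PF13966", 50),
    ("Thioredoxin", "PF00085", 70),
)

_DOMAIN_LEN = {"T": 170, "R": 140, "C": 40, "N": 280, "L": 60}
_MOTIF_OFFSETS = {"P-loop": 10, "kinase2": 60, "ARC1": 130, "ARC2": 210}
_MOTIFS = {"P-loop": "GTTK", "kinase2": "VLDD", "ARC1": "GLPL", "ARC2": "MHD"}


@dataclass
class NlrSimSpec:
    n_proteins: int = 200
    seed: int = 0
    n_chroms: int = 5
    two_species: bool = True
    frac_double_nbarc: float = 0.10  # NN architectures
    frac_integrated: float = 0.20
    frac_profile_rescued: float = 0.15  # divergent NB-ARC, generic pass fails the seed


def _random_protein_segment(length: int, rng: np.random.Generator) -> str:
    seg = "".join(AMINO_ACIDS[k] for k in rng.integers(len(AMINO_ACIDS), size=length))
    # reject accidental motif occurrences so planted motifs are the only ones
    while any(m in seg for m in _MOTIFS.values()):
        seg = "".join(AMINO_ACIDS[k] for k in rng.integers(len(AMINO_ACIDS), size=length))
    return seg


def _domtbl_row(protein: str, prot_len: int, domain: str, acc: str, evalue: float,
                start: int, end: int) -> str:
    # hmmscan-orientation domtblout: target = domain profile, query = protein
    cols = [
        domain, acc if acc else "-", str(_DOMAIN_LEN.get(domain, end - start + 1)),
        protein, "-", str(prot_len),
        f"{evalue:.2g}", "200.0", "0.1", "1", "1",
        f"{evalue:.2g}", f"{evalue:.2g}", "199.0", "0.1",
        "1", str(end - start + 1), str(start), str(end), str(start), str(end),
        "0.98", "-",
    ]
    return " ".join(cols)


@dataclass
class SimulatedSpecies:
    prefix: str
    proteins: list[SequenceRecord]
    generic_hits: list[DomainHit]
    profile_hits: list[DomainHit]
    coils_hits: list[DomainHit]
    loci: list[GeneLocus]
    truth_proteins: dict[str, dict]
    truth_clusters: dict[str, list[str]]
    excluded: list[str]
    generic_rows: list[str] = field(default_factory=list)
    profile_rows: list[str] = field(default_factory=list)


@dataclass
class SimulatedNlrGenome:
    species_a: SimulatedSpecies
    species_b: SimulatedSpecies | None
    rbh_truth: list[tuple[str, str]]
    pairing_truth: list[tuple[str, str]]
    blast_ab_rows: list[str] = field(default_factory=list)
    blast_ba_rows: list[str] = field(default_factory=list)

    def truth_dict(self) -> dict:
        def species_dict(sp: SimulatedSpecies) -> dict:
            return {
                "proteins": sp.truth_proteins,
                "clusters": sp.truth_clusters,
                "excluded_proteins": sp.excluded,
            }

        out = {"species_a": species_dict(self.species_a)}
        if self.species_b is not None:
            out["species_b"] = species_dict(self.species_b)
            out["rbh_pairs"] = [list(p) for p in self.rbh_truth]
            out["cluster_pairings"] = [list(p) for p in self.pairing_truth]
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in filter(None, (self.species_a, self.species_b)):
            tag = sp.prefix.rstrip("_")
            write_fasta(sp.proteins, outdir / f"{tag}.proteins.fasta")
            for rows, name in ((sp.generic_rows, "generic"), (sp.profile_rows, "profile")):
                with open(outdir / f"{tag}.{name}.domtblout", "w") as fh:
                    fh.write("# simulated domain table (domtblout dialect)\n")
                    fh.write("\n".join(rows) + ("\n" if rows else ""))
            write_tsv(
                [(h.protein_id, h.ali_start, h.ali_end, f"{h.probability:.2f}")
                 for h in sp.coils_hits],
                ["protein", "start", "end", "probability"],
                outdir / f"{tag}.coils.tsv",
            )
            write_gff_genes(sp.loci, outdir / f"{tag}.genes.gff3")
        if self.species_b is not None:
            with open(outdir / "blast_ab.tsv", "w") as fh:
                fh.write("\n".join(self.blast_ab_rows) + "\n")
            with open(outdir / "blast_ba.tsv", "w") as fh:
                fh.write("\n".join(self.blast_ba_rows) + "\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth_dict(), fh, indent=1)


def _plan_architectures(spec: NlrSimSpec, rng: np.random.Generator) -> list[dict]:
    """Per-protein plan: core class, NB-ARC copies, motifs, IDs, controls."""
    plans = []
    classes = rng.choice(len(CORE_CLASSES), size=spec.n_proteins, p=CORE_CLASS_WEIGHTS)
    for i in range(spec.n_proteins):
        core = CORE_CLASSES[classes[i]]
        n_nbarc = 2 if rng.random() < spec.frac_double_nbarc else 1
        motifs = sorted(m for m in _MOTIFS if rng.random() < 0.7)
        integrated = None
        if rng.random() < spec.frac_integrated:
            integrated = INTEGRATED_POOL[rng.integers(len(INTEGRATED_POOL))]
        plans.append(
            {
                "core": core,
                "n_nbarc": n_nbarc,
                "motifs": motifs,
                "integrated": integrated,
                "rescued": rng.random() < spec.frac_profile_rescued,
                # negative controls, assigned below
                "overlap_pair": False,
                "weak_coils": False,
                "weak_tir": False,
            }
        )
    # deterministic negative controls on the first few suitable proteins
    if plans:
        plans[0]["overlap_pair"] = True  # two mutually overlapping non-canonical hits
    for p in plans:
        if p["core"].startswith("C"):
            p["weak_coils"] = True  # extra COILS segment below the probability cut
            break
    for p in plans:
        if not p["core"].startswith("T"):
            p["weak_tir"] = True  # TIR hit at E >= 1.0, must not make the class T
            break
    return plans


def _build_protein(pid: str, plan: dict, rng: np.random.Generator):
    """Lay out one protein left-to-right; returns sequence, hits and truth."""
    core, n_nbarc = plan["core"], plan["n_nbarc"]
    order: list[str] = []
    if core[0] in "TRC" and core[0] != "N":
        order.append(core[0])
    order.extend(["N"] * n_nbarc)
    has_lrr = core.endswith("L")
    if has_lrr:
        order.extend(["L", "L"])
    segments: list[str] = []
    hits: list[tuple] = []  # (kind, name, acc, evalue_or_prob, start, end)
    cursor = 1
    letters: list[str] = []

    def filler(length: int) -> None:
        nonlocal cursor
        segments.append(_random_protein_segment(length, rng))
        cursor += length

    def place(length: int) -> tuple[int, int]:
        nonlocal cursor
        start, end = cursor, cursor + length - 1
        cursor = end + 1
        return start, end

    filler(int(rng.integers(15, 40)))
    integrated_truth = []
    nbarc_spans = []
    for idx, letter in enumerate(order):
        length = _DOMAIN_LEN[letter]
        start, end = place(length)
        if letter == "N":
            seg = _random_protein_segment(length, rng)
            for m in plan["motifs"] if not nbarc_spans else ():
                off = _MOTIF_OFFSETS[m]
                seg = seg[:off] + _MOTIFS[m] + seg[off + len(_MOTIFS[m]):]
            segments.append(seg)
            nbarc_spans.append((start, end))
            evalue = 10 ** -float(rng.uniform(61, 120))
            if plan["rescued"]:
                hits.append(("generic", "NB-ARC", "PF00931", 1e-30, start, end))
            else:
                hits.append(("generic", "NB-ARC", "PF00931", evalue, start, end))
            hits.append(("profile", "NB-ARC", "PF00931", 10 ** -float(rng.uniform(85, 130)), start, end))
        elif letter == "C":
            segments.append(_random_protein_segment(length, rng))
            hits.append(("coils", "COILS", "", float(rng.uniform(0.92, 0.99)), start, end))
        else:
            segments.append(_random_protein_segment(length, rng))
            name = {"T": "TIR", "R": "RPW8", "L": ("LRR_8", "LRR_4")[idx % 2]}[letter]
            acc = {"TIR": "PF01582", "RPW8": "PF05659", "LRR_8": "PF13855", "LRR_4": "PF12799"}[name]
            hits.append(("generic", name, acc, 10 ** -float(rng.uniform(8, 40)), start, end))
        letters.append(letter)
        filler(int(rng.integers(12, 30)))
    if plan["integrated"] is not None:
        name, acc, length = plan["integrated"]
        filler(30)  # guaranteed clearance from every other domain
        start, end = place(length)
        segments.append(_random_protein_segment(length, rng))
        hits.append(("generic", name, acc, 10 ** -float(rng.uniform(3, 20)), start, end))
        integrated_truth.append([name, acc, start, end])
        filler(30)
    if plan["overlap_pair"]:
        # two non-canonical domains overlapping each other: neither is an ID
        start, end = place(60)
        segments.append(_random_protein_segment(60, rng))
        hits.append(("generic", "DUF3542", "PF12063", 1e-5, start, end))
        hits.append(("generic", "DUF594", "PF04578", 1e-4, start + 20, end + 20))
        filler(40)
    if plan["weak_coils"]:
        start, end = place(40)
        segments.append(_random_protein_segment(40, rng))
        hits.append(("coils", "COILS", "", 0.80, start, end))
        letters.append("c_below_threshold")
        filler(15)
    if plan["weak_tir"]:
        start, end = place(80)
        segments.append(_random_protein_segment(80, rng))
        hits.append(("generic", "TIR", "PF01582", 2.0, start, end))
        filler(15)
    filler(int(rng.integers(10, 30)))
    seq = "".join(segments)
    domain_string = "-".join(l for l in letters if l in "TRCNL")
    truth = {
        "arch_class": core,
        "domain_string": domain_string,
        "motifs": plan["motifs"],
        "integrated_domains": integrated_truth,
        "is_nlr": has_lrr,
    }
    return seq, hits, truth


def _layout_genome(pids: list[str], spec: NlrSimSpec, rng: np.random.Generator,
                   prefix: str):
    """Place NB-ARC genes and filler gene models; return loci + cluster truth.

    Planted clusters obey the chaining rule by construction; three negative
    controls violate, in turn, the 200 kb gap rule, the nine-intervening-gene
    rule, and the minimum-size rule.
    """
    loci: list[GeneLocus] = []
    truth_clusters: dict[str, list[str]] = {}
    chroms = [f"Chr{c + 1:02d}" for c in range(spec.n_chroms)]
    queue = list(pids)
    filler_count = 0

    def add_filler(chrom: str, start: int) -> int:
        nonlocal filler_count
        filler_count += 1
        loci.append(GeneLocus(f"{prefix}filler_{filler_count:05d}", chrom, start, start + 2000))
        return start + 2000

    def place_group(chrom: str, cursor: int, size: int, gaps_bp: list[int],
                    intervening: list[int]) -> tuple[int, list[str]]:
        members = []
        for k in range(size):
            if not queue:
                break
            pid = queue.pop(0)
            start = cursor
            end = start + 4000
            loci.append(GeneLocus(pid, chrom, start, end))
            members.append(pid)
            if k < size - 1:
                gap, n_between = gaps_bp[k], intervening[k]
                inner = end + 1000
                for _ in range(n_between):
                    inner = add_filler(chrom, inner) + max(
                        (gap - 2000 * (n_between + 1)) // max(n_between, 1), 100
                    )
                cursor = end + gap
            else:
                cursor = end
        return cursor, members

    cluster_letter: dict[str, int] = {c: 0 for c in chroms}
    chrom_cycle = 0
    group_specs: list[tuple[str, int]] = []
    # planted clusters of size 3-6 consume ~60% of the proteins
    n_cluster_genes = int(0.6 * len(pids))
    consumed = 0
    while consumed < n_cluster_genes:
        size = int(rng.integers(3, 7))
        group_specs.append(("cluster", size))
        consumed += size
    group_specs.append(("neg_gap", 3))  # one junction at 250 kb: breaks
    group_specs.append(("neg_intervening", 3))  # one junction with 10 fillers
    group_specs.append(("neg_pair", 2))  # below minimum size
    while True:  # remaining proteins become singletons
        group_specs.append(("singleton", 1))
        if sum(s for _, s in group_specs) >= len(pids):
            break
    cursor_by_chrom = {c: 50_000 for c in chroms}
    for kind, size in group_specs:
        if not queue:
            break
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        cursor = cursor_by_chrom[chrom]
        if kind == "cluster":
            gaps = [int(rng.integers(20_000, 150_000)) for _ in range(size - 1)]
            betweens = [int(rng.integers(0, 6)) for _ in range(size - 1)]
            cursor, members = place_group(chrom, cursor, size, gaps, betweens)
            if len(members) >= 3:
                cid = f"{int(chrom[3:])}{chr(ord('A') + cluster_letter[chrom])}"
                cluster_letter[chrom] += 1
                truth_clusters[cid] = members
        elif kind == "neg_gap":
            cursor, _ = place_group(chrom, cursor, size, [50_000, 250_000], [1, 1])
        elif kind == "neg_intervening":
            cursor, _ = place_group(chrom, cursor, size, [60_000, 120_000], [1, 10])
        elif kind == "neg_pair":
            cursor, _ = place_group(chrom, cursor, size, [40_000], [0])
        else:
            cursor, _ = place_group(chrom, cursor, size, [], [])
        cursor_by_chrom[chrom] = cursor + 400_000  # isolates groups from one another
    return assign_ranks(loci), truth_clusters


def _simulate_species(spec: NlrSimSpec, prefix: str, seed: int) -> SimulatedSpecies:
    rng = np.random.default_rng(seed)
    plans = _plan_architectures(spec, rng)
    pids = [f"{prefix}nbarc_{i:04d}" for i in range(spec.n_proteins)]
    proteins, generic, profile, coils = [], [], [], []
    generic_rows, profile_rows = [], []
    truth_proteins: dict[str, dict] = {}
    for pid, plan in zip(pids, plans):
        seq, hits, truth = _build_protein(pid, plan, rng)
        proteins.append(SequenceRecord(pid, seq, "protein"))
        for kind, name, acc, ev_or_p, start, end in hits:
            if kind == "coils":
                coils.append(DomainHit(pid, "COILS", "", 1.0 - ev_or_p, start, end, "coils"))
            elif kind == "generic":
                generic.append(DomainHit(pid, name, acc, ev_or_p, start, end, "generic_pass"))
                generic_rows.append(_domtbl_row(pid, len(seq), name, acc, ev_or_p, start, end))
            else:
                profile.append(DomainHit(pid, name, acc, ev_or_p, start, end, "profile_pass"))
                profile_rows.append(_domtbl_row(pid, len(seq), name, acc, ev_or_p, start, end))
        truth_proteins[pid] = truth
    # decoys outside the universe: a kinase-only protein, and an NB-ARC hit
    # that fails the seed E-value with no profile rescue
    excluded = []
    for tag, name, acc, evalue in (
        ("decoy_kinase", "Pkinase", "PF00069", 1e-50),
        ("decoy_weak_nbarc", "NB-ARC", "PF00931", 1e-30),
    ):
        pid = f"{prefix}{tag}"
        seq = _random_protein_segment(400, rng)
        proteins.append(SequenceRecord(pid, seq, "protein"))
        generic.append(DomainHit(pid, name, acc, evalue, 50, 340, "generic_pass"))
        generic_rows.append(_domtbl_row(pid, len(seq), name, acc, evalue, 50, 340))
        excluded.append(pid)
    loci, truth_clusters = _layout_genome(pids, spec, rng, prefix)
    return SimulatedSpecies(
        prefix, proteins, generic, profile, coils, loci,
        truth_proteins, truth_clusters, excluded, generic_rows, profile_rows,
    )


def simulate_nlr_genome(spec: NlrSimSpec) -> SimulatedNlrGenome:
    """Generate one (or two mirrored) synthetic NLR genome(s) with truth.

    With ``two_species`` the second species shares the architecture and
    layout plan (same seed-derived stream), protein ``i`` of each species is
    the other's reciprocal best hit, and planted clusters correspond
    one-to-one, giving exact cluster-pairing truth.
    """
    species_a = _simulate_species(spec, "spA_", spec.seed)
    if not spec.two_species:
        return SimulatedNlrGenome(species_a, None, [], [])
    species_b = _simulate_species(spec, "spB_", spec.seed)
    rbh_truth = [
        (a, a.replace("spA_", "spB_"))
        for a in sorted(species_a.truth_proteins)
    ]
    pairing_truth = sorted(
        (cid, cid) for cid in species_a.truth_clusters
    )
    blast_ab, blast_ba = [], []
    ids_a = sorted(species_a.truth_proteins)
    for i, a in enumerate(ids_a):
        b = a.replace("spA_", "spB_")
        blast_ab.append(f"{a}\t{b}\t98.0\t400\t8\t0\t1\t400\t1\t400\t1e-120\t500.0")
        blast_ba.append(f"{b}\t{a}\t98.0\t400\t8\t0\t1\t400\t1\t400\t1e-120\t500.0")
        decoy_b = ids_a[(i + 1) % len(ids_a)].replace("spA_", "spB_")
        blast_ab.append(f"{a}\t{decoy_b}\t45.0\t380\t200\t4\t1\t380\t1\t380\t1e-20\t120.0")
        blast_ba.append(f"{decoy_b}\t{a}\t45.0\t380\t200\t4\t1\t380\t1\t380\t1e-20\t120.0")
    return SimulatedNlrGenome(species_a, species_b, rbh_truth, pairing_truth, blast_ab, blast_ba)


# ---------------------------------------------------------------------------
# two-population VCF simulation
# ---------------------------------------------------------------------------

@dataclass
class PopSimSpec:
    """Study conditions for the two-population resequencing panel.

    Defaults mirror the pipeline's target panel: 16 wild and 39 landrace
    diploids, wild background diversity 0.0018/bp, and a 10 Mb genome.
    ``sweep_blocks`` are (chrom, start, end, landrace diversity multiplier);
    a multiplier of 0 collapses landrace diversity completely.
    """

    n_wild: int = 16
    n_landrace: int = 39
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"Chr01": 5_000_000, "Chr02": 5_000_000}
    )
    theta_bg: float = 0.0018
    sweep_blocks: list[tuple[str, int, int, float]] = field(default_factory=list)
    fixed_sites: list[tuple[str, int]] = field(default_factory=list)
    missing_rate: float = 0.02
    seed: int = 0
    gene_spacing: int = 25_000
    gene_length: int = 5_000

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.sweep_blocks:
            for s0, e0 in by_chrom.get(chrom, []):
                if start <= e0 and s0 <= end:
                    raise ValueError("sweep blocks must not overlap")
            by_chrom.setdefault(chrom, []).append((start, end))


@dataclass
class SimulatedPanel:
    table: VariantTable
    popmap: dict[str, str]
    loci: list[GeneLocus]
    chrom_lengths: dict[str, int]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(self.table, self.chrom_lengths, outdir / "panel.vcf")
        write_tsv(
            sorted(self.popmap.items()), ["sample_id", "population"], outdir / "popmap.tsv"
        )
        write_gff_genes(self.loci, outdir / "genes.gff3")
        write_tsv(
            sorted(self.chrom_lengths.items()), ["chrom", "length"], outdir / "chrom_lengths.tsv"
        )
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def write_vcf(table: VariantTable, chrom_lengths: dict[str, int], path: str | Path) -> None:
    """Write a minimal GT-only VCF v4.2 text file."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in sorted(chrom_lengths.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples) + "\n")
        for site in table:
            gts = "\t".join(code_to_gt[int(g)] for g in site.genotypes)
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t{site.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _neutral_alt_counts(n_sites: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw alternate-allele haplotype counts from the neutral 1/j spectrum."""
    j = np.arange(1, m)
    p = (1.0 / j) / np.sum(1.0 / j)
    return rng.choice(j, size=n_sites, p=p)


def _genotypes_from_counts(counts: np.ndarray, n_diploid: int, rng: np.random.Generator) -> np.ndarray:
    """Assign alt alleles to random haplotypes; fold to diploid codes."""
    n_sites = len(counts)
    m = 2 * n_diploid
    u = rng.random((n_sites, m))
    order = np.argsort(u, axis=1)
    hap_alt = np.zeros((n_sites, m), dtype=np.int8)
    rows = np.repeat(np.arange(n_sites), counts)
    cols = np.concatenate([order[i, : counts[i]] for i in range(n_sites)]) if n_sites else np.zeros(0, dtype=int)
    hap_alt[rows, cols] = 1
    return hap_alt[:, 0::2] + hap_alt[:, 1::2]


def simulate_two_population_vcf(spec: PopSimSpec) -> SimulatedPanel:
    """Simulate the two-population SNP panel with planted sweeps/fixed sites.

    Segregating sites are placed by a Poisson process at density
    theta_bg * a_(2*n_wild - 1) per bp; allele frequencies are drawn from the
    neutral 1/j spectrum independently per population (sites are unlinked).
    Inside sweep blocks the landrace genotypes collapse to the reference
    allele with probability 1 - multiplier per site. Listed fixed-difference
    sites are emitted with opposite fixed alleles. Missing calls are
    sprinkled at the stated rate.
    """
    rng = np.random.default_rng(spec.seed)
    m_w, m_l = 2 * spec.n_wild, 2 * spec.n_landrace
    samples = [f"wild_{i + 1:02d}" for i in range(spec.n_wild)] + [
        f"land_{i + 1:02d}" for i in range(spec.n_landrace)
    ]
    popmap = {s: ("wild" if s.startswith("wild") else "landrace") for s in samples}
    density = spec.theta_bg * harmonic(m_w - 1)
    sites: list[SiteRecord] = []
    fixed_by_chrom: dict[str, set[int]] = {}
    for chrom, pos in spec.fixed_sites:
        fixed_by_chrom.setdefault(chrom, set()).add(pos)
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        n_sites = int(rng.poisson(density * length))
        pos = np.unique(rng.integers(1, length + 1, size=n_sites))
        pos = pos[~np.isin(pos, sorted(fixed_by_chrom.get(chrom, ())))]
        n_sites = len(pos)
        counts_w = _neutral_alt_counts(n_sites, m_w, rng)
        geno_w = _genotypes_from_counts(counts_w, spec.n_wild, rng)
        geno_l = _genotypes_from_counts(_neutral_alt_counts(n_sites, m_l, rng), spec.n_landrace, rng)
        # sweep collapse: landrace diversity lost with prob (1 - multiplier);
        # the bottleneck fixes the allele that is major in the wild pool
        for b_chrom, b_start, b_end, mult in spec.sweep_blocks:
            if b_chrom != chrom:
                continue
            in_block = (pos >= b_start) & (pos <= b_end)
            collapse = in_block & (rng.random(n_sites) < (1.0 - mult))
            fixed_code = np.where(counts_w > m_w // 2, 2, 0).astype(np.int8)
            geno_l[collapse, :] = fixed_code[collapse, None]
        # planted fixed differences: wild fixed ref, landrace fixed alt
        extra_pos = sorted(fixed_by_chrom.get(chrom, ()))
        all_pos = np.concatenate([pos, np.array(extra_pos, dtype=int)]) if extra_pos else pos
        order = np.argsort(all_pos, kind="stable")
        geno_w_extra = np.zeros((len(extra_pos), spec.n_wild), dtype=np.int8)
        geno_l_extra = np.full((len(extra_pos), spec.n_landrace), 2, dtype=np.int8)
        geno_w_all = np.vstack([geno_w, geno_w_extra]) if extra_pos else geno_w
        geno_l_all = np.vstack([geno_l, geno_l_extra]) if extra_pos else geno_l
        geno = np.hstack([geno_w_all, geno_l_all]).astype(np.int8)
        if spec.missing_rate > 0:
            miss = rng.random(geno.shape) < spec.missing_rate
            geno[miss] = -1
        ref_alt = rng.integers(0, 4, size=(len(all_pos), 2))
        ref_alt[:, 1] = (ref_alt[:, 0] + 1 + rng.integers(0, 3, size=len(all_pos))) % 4
        for k in order:
            sites.append(
                SiteRecord(
                    chrom,
                    int(all_pos[k]),
                    "ACGT"[ref_alt[k, 0]],
                    "ACGT"[ref_alt[k, 1]],
                    geno[k],
                )
            )
    table = VariantTable(samples, sites)
    loci = _tile_genes(spec)
    truth = _panel_truth(spec, table, loci, popmap)
    return SimulatedPanel(table, popmap, loci, dict(spec.chrom_lengths), truth)


def _tile_genes(spec: PopSimSpec) -> list[GeneLocus]:
    loci = []
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        idx = 0
        for start in range(10_000, length - spec.gene_length, spec.gene_spacing):
            idx += 1
            loci.append(
                GeneLocus(f"gene_{chrom}_{idx:04d}", chrom, start, start + spec.gene_length - 1)
            )
    return assign_ranks(loci)


def _panel_truth(spec: PopSimSpec, table: VariantTable, loci, popmap) -> dict:
    from .popgen import _pop_indices, _pop_state

    _, land_idx = _pop_indices(table.samples, popmap)
    pos_by_chrom: dict[str, list[tuple[int, bool]]] = {}
    for site in table:
        poly = _pop_state(site.genotypes[land_idx]) == "poly"
        pos_by_chrom.setdefault(site.chrom, []).append((site.pos, poly))
    monomorphic_genes, no_data_genes = [], []
    for gene in loci:
        in_span = [
            poly for p, poly in pos_by_chrom.get(gene.chrom, [])
            if gene.start <= p <= gene.end
        ]
        if not in_span:
            no_data_genes.append(gene.gene_id)
        elif not any(in_span):
            monomorphic_genes.append(gene.gene_id)
    return {
        "sweep_blocks": [list(b) for b in spec.sweep_blocks],
        "fixed_sites": [list(f) for f in spec.fixed_sites],
        "monomorphic_genes": monomorphic_genes,
        "no_data_genes": no_data_genes,
        "theta_bg": spec.theta_bg,
        "seed": spec.seed,
        "n_sites": len(table),
    }
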