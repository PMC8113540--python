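"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives its quantity from first principles (enumeration,
exhaustive search, or averaging over all pairs) without touching the
implementation modules' internals, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

# standard genetic code, written out independently of the package
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE = sorted(c for c, aa in _CODE.items() if aa != "*")


def oracle_syn_sites(codon: str) -> float:
    """Synonymous site count of one codon; stop-codon changes excluded from
    the per-position denominator."""
    total = 0.0
    for pos in range(3):
        outcomes = []
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if _CODE[mutant] == "*":
                continue
            outcomes.append(_CODE[mutant] == _CODE[codon])
        if outcomes:
            total += sum(outcomes) / len(outcomes)
    return total


def oracle_pathways(a: str, b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over stop-free minimal pathways."""
    positions = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(positions):
        cur, sd, nd, blocked = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _CODE[nxt] == "*":
                blocked = True
                nd += 1
            elif _CODE[cur] != "*" and _CODE[cur] == _CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, blocked))
    clean = [r for r in results if not r[2]]
    use = clean if clean else results
    return (
        sum(r[0] for r in use) / len(use),
        sum(r[1] for r in use) / len(use),
    )


def oracle_ng86(columns: list[tuple[str, str]]):
    """Full NG86 + Jukes-Cantor on aligned codon columns.

    Returns (ks, ka, S, N, saturated); ks/ka are math.nan when saturated.
    """
    S = sum((oracle_syn_sites(a) + oracle_syn_sites(b)) / 2 for a, b in columns)
    N = 3 * len(columns) - S
    Sd = sum(oracle_pathways(a, b)[0] for a, b in columns)
    Nd = sum(oracle_pathways(a, b)[1] for a, b in columns)
    ps = Sd / S if S else (0.0 if Sd == 0 else 1.0)
    pn = Nd / N if N else (0.0 if Nd == 0 else 1.0)
    if ps >= 0.75 or pn >= 0.75:
        return math.nan, math.nan, S, N, True
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return jc(ps), jc(pn), S, N, False


def oracle_site_pi(genotypes: list[int]) -> float | None:
    """Mean difference over all haplotype pairs; codes 0/1/2/-1 (missing)."""
    haps: list[int] = []
    for g in genotypes:
        if g == -1:
            continue
        haps.extend({0: [0, 0], 1: [0, 1], 2: [1, 1]}[g])
    if len(haps) < 2:
        return None
    pairs = list(itertools.combinations(haps, 2))
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def oracle_clusters(
    nbarc: list[tuple[str, int, int, int]],  # (gene_id, start, end, rank) one chromosome
    max_gap: int = 200_000,
    max_intervening: int = 9,
    min_genes: int = 3,
) -> list[list[str]]:
    """Every maximal contiguous run whose consecutive pairs satisfy both
    rules, found by exhaustive testing of all runs."""
    genes = sorted(nbarc, key=lambda g: g[3])

    def pair_ok(u, v) -> bool:
        distance = max(v[1] - u[2], 0)
        return distance < max_gap and (v[3] - u[3] - 1) <= max_intervening

    def run_ok(i: int, j: int) -> bool:
        return all(pair_ok(genes[k], genes[k + 1]) for k in range(i, j))

    out = []
    n = len(genes)
    for i in range(n):
        for j in range(i + min_genes - 1, n):
            if not run_ok(i, j):
                continue
            maximal = not (
                (i > 0 and pair_ok(genes[i - 1], genes[i]))
                or (j < n - 1 and pair_ok(genes[j], genes[j + 1]))
            )
            if maximal:
                out.append([g[0] for g in genes[i : j + 1]])
    return out


def oracle_integrated(
    hits: list[tuple[str, int, int, bool, float]],  # (name, start, end, canonical, evalue)
    id_evalue: float = 1.0,
) -> list[str]:
    """Non-canonical hits below the E cutoff overlapping no other hit."""
    out = []
    for i, (name, s, e, canonical, ev) in enumerate(hits):
        if canonical or ev >= id_evalue:
            continue
        clash = any(
            j != i and not (e < s2 or e2 < s)
            for j, (_, s2, e2, _, _) in enumerate(hits)
        )
        if not clash:
            out.append(name)
    return sorted(out)


def oracle_rbh(scores_ab: dict[tuple[str, str], float],
               scores_ba: dict[tuple[str, str], float]) -> set[tuple[str, str]]:
    """Mutual argmax over explicit score dictionaries; ties by subject id."""
    def best(scores, query):
        cands = [(s, subj) for (q, subj), s in scores.items() if q == query]
        if not cands:
            return None
        top = max(s for s, _ in cands)
        return min(subj for s, subj in cands if s == top)

    queries_a = {q for q, _ in scores_ab}
    out = set()
    for a in queries_a:
        b = best(scores_ab, a)
        if b is not None and best(scores_ba, b) == a:
            out.add((a, b))
    return out
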