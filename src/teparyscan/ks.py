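"""Pairwise synonymous divergence, Ks-peak mixture modelling, and the clock.

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor multiple-hit
correction: fractional synonymous site counts per codon (changes to stop
codons excluded from the possible-change denominator), and multi-nucleotide
codon differences averaged over all minimal mutational pathways that avoid
stop codons. Peaks of the Ks distribution are found with a Gaussian mixture
on log(Ks), so a component mean exponentiates to a geometric-mean Ks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

logger = logging.getLogger("teparyscan")

BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))  # 61 sense codons


class KsError(ValueError):
    """Raised on invalid input to the Ks machinery."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class OrthologPair:
    id_a: str
    id_b: str
    cds_a: str
    cds_b: str

    def __post_init__(self) -> None:
        for name, cds in ((self.id_a, self.cds_a), (self.id_b, self.cds_b)):
            if len(cds) % 3 != 0:
                raise KsError(f"'{name}': CDS length {len(cds)} not a multiple of 3")
            codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
            if any(c in STOP_CODONS for c in codons):
                raise KsError(f"'{name}': internal stop codon")


@dataclass
class AlignedCodonPair:
    """Gap-free, unambiguous codon columns of one aligned ortholog pair."""

    codon_columns: list[tuple[str, str]]

    @property
    def n_codons(self) -> int:
        return len(self.codon_columns)


@dataclass
class KsEstimate:
    ks: float
    ka: float
    s_sites: float
    n_sites: float
    saturated: bool


@dataclass
class MixtureFit:
    """Gaussian components of the log-Ks distribution."""

    components: list[tuple[float, float, float]]  # (weight, mean, sd) on log-Ks
    bic: float
    loglik: float
    n_used: int

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def peak_ks(self) -> float:
        """Geometric-mean Ks of the highest-weight component."""
        w, mu, _ = max(self.components, key=lambda c: c[0])
        return float(np.exp(mu))


@dataclass
class MolecularClock:
    lam: float  # substitutions / synonymous site / year
    calib_ks: float
    calib_T: float


@dataclass
class DivergenceEstimate:
    T: float  # years
    ks_used: float


# ---------------------------------------------------------------------------
# codon bookkeeping (NG86)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """NG86 synonymous site count of one sense codon (0..3).

    Per position: the fraction of the possible single-nucleotide changes that
    are synonymous, with changes producing stop codons excluded from the
    denominator.
    """
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        total += syn / valid if valid else 0.0
    return total


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Counts are averaged over all minimal single-step mutational pathways; a
    pathway passing through a stop codon is discarded unless every pathway
    does, in which case all pathways are used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float, bool]] = []  # (sd, nd, hits_stop)
    for order in itertools.permutations(diff_pos):
        current = codon_a
        sd = nd = 0.0
        hits_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                hits_stop = True
                aa_equal = False
            else:
                aa_a = CODON_TO_AA.get(current)
                aa_b = CODON_TO_AA.get(nxt)
                aa_equal = aa_a is not None and aa_a == aa_b
            if aa_equal:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        paths.append((sd, nd, hits_stop))
    usable = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor correction d = -3/4 ln(1 - 4p/3); requires p < 3/4."""
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def estimate_ks(aln: AlignedCodonPair) -> KsEstimate:
    """NG86 Ks/Ka with Jukes–Cantor correction for one aligned pair.

    ``saturated`` is set (Ks/Ka left as nan) when the proportion of
    synonymous or non-synonymous differences reaches 3/4, where the
    correction is undefined.
    """
    if aln.n_codons < 1:
        raise KsError("empty codon alignment")
    S = N = Sd = Nd = 0.0
    for ca, cb in aln.codon_columns:
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            raise KsError(f"non-sense codon in alignment: {ca}/{cb}")
        s = 0.5 * (synonymous_site_fraction(ca) + synonymous_site_fraction(cb))
        S += s
        N += 3.0 - s
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    # zero observed differences means zero distance even if a site class is empty
    p_s = Sd / S if S > 0 else (0.0 if Sd == 0 else 1.0)
    p_n = Nd / N if N > 0 else (0.0 if Nd == 0 else 1.0)
    saturated = p_s >= 0.75 or p_n >= 0.75
    if saturated:
        ks = ka = float("nan")
    else:
        ks = float(jukes_cantor(p_s))
        ka = float(jukes_cantor(p_n))
    return KsEstimate(ks=ks, ka=ka, s_sites=S, n_sites=N, saturated=saturated)


# ---------------------------------------------------------------------------
# protein-space alignment, back-projected to codons
# ---------------------------------------------------------------------------

@dataclass
class ScoringConfig:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


def _split_codons(cds: str) -> list[str]:
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]  # terminal stop carries no alignable residue
    return codons


def _translate(codons: list[str], name: str) -> str:
    aas = []
    for codon in codons:
        if codon in STOP_CODONS:
            raise KsError(f"'{name}': internal stop codon {codon}")
        aas.append(str(Seq(codon).translate()) if "N" in codon else CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def align_codon_pair(pair: OrthologPair, scoring: ScoringConfig | None = None) -> AlignedCodonPair:
    """Globally align the pair in protein space and project back to codons.

    Columns containing a gap in either sequence, or any ambiguous base (N)
    in either codon, are dropped.
    """
    scoring = scoring or ScoringConfig()
    codons_a = _split_codons(pair.cds_a)
    codons_b = _split_codons(pair.cds_b)
    prot_a = _translate(codons_a, pair.id_a)
    prot_b = _translate(codons_b, pair.id_b)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    alignment = aligner.align(prot_a, prot_b)[0]
    columns: list[tuple[str, str]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            ca, cb = codons_a[i], codons_b[j]
            if "N" in ca or "N" in cb:
                continue
            columns.append((ca, cb))
    if not columns:
        raise KsError(f"{pair.id_a}/{pair.id_b}: no alignable codons")
    return AlignedCodonPair(columns)


def ks_for_pairs(pairs: list[OrthologPair], scoring: ScoringConfig | None = None) -> list[KsEstimate]:
    return [estimate_ks(align_codon_pair(p, scoring)) for p in pairs]


# ---------------------------------------------------------------------------
# Gaussian mixture on log(Ks)
# ---------------------------------------------------------------------------

KS_FLOOR = 0.001  # values at/below this are rounding artefacts and are dropped


class ConvergenceError(RuntimeError):
    pass


def _em_gaussian_1d(x: np.ndarray, k: int, rng: np.random.Generator,
                    max_iter: int = 500, tol: float = 1e-5,
                    n_restarts: int = 5) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Best-of-restarts EM fit of a k-component 1-D Gaussian mixture.

    The first restart initializes means at evenly spaced quantiles of the
    data (quantile-spread initialization); the rest draw means from the data.
    Convergence is a relative change in total log-likelihood below ``tol``
    (the criterion mclust uses). Returns (weights, means, sds, loglik).
    """
    n = len(x)
    sd_floor = 1e-6
    if k == 1:
        n_restarts = 1  # the k=1 optimum is unique; restarts are redundant
    # all restarts iterate together as a batched (restart, obs, component) array
    means = np.empty((n_restarts, k))
    means[0] = np.quantile(x, (np.arange(k) + 0.5) / k)
    for r in range(1, n_restarts):
        means[r] = rng.choice(x, size=k, replace=False)
    sds = np.full((n_restarts, k), max(np.std(x) / k, sd_floor))
    weights = np.full((n_restarts, k), 1.0 / k)
    prev_ll = np.full(n_restarts, -np.inf)
    loglik = np.full(n_restarts, -np.inf)
    active = np.ones(n_restarts, dtype=bool)
    xo = x[None, :, None]
    log_2pi_half = 0.5 * np.log(2 * np.pi)
    for iteration in range(max_iter):
        idx = np.flatnonzero(active)
        m = means[idx][:, None, :]
        s = sds[idx][:, None, :]
        z = (xo - m) / s
        log_dens = (np.log(weights[idx][:, None, :] / s) - log_2pi_half) - 0.5 * z * z
        mx = log_dens.max(axis=2)
        resp = np.exp(log_dens - mx[:, :, None], out=log_dens)
        denom = resp.sum(axis=2)
        cur_ll = (np.log(denom) + mx).sum(axis=1)
        resp /= denom[:, :, None]
        nk = np.maximum(resp.sum(axis=1), 1e-300)
        weights[idx] = nk / n
        mu = (resp * xo).sum(axis=1) / nk
        means[idx] = mu
        d = xo - mu[:, None, :]
        var = (resp * d * d).sum(axis=1) / nk
        sds[idx] = np.sqrt(np.maximum(var, sd_floor**2))
        loglik[idx] = cur_ll
        done = np.abs(cur_ll - prev_ll[idx]) < tol * (1.0 + np.abs(cur_ll))
        prev_ll[idx] = cur_ll
        active[idx[done]] = False
        if not active.any():
            break
    converged = ~active
    if not converged.any():
        raise ConvergenceError(
            f"EM (k={k}) did not converge within {max_iter} iterations"
        )
    loglik[~converged] = -np.inf
    best = int(np.argmax(loglik))
    return weights[best], means[best], sds[best], float(loglik[best])


def merge_overlapping_components(
    components: list[tuple[float, float, float]]
) -> list[tuple[float, float, float]]:
    """Merge overlapping components into their moment-matched mixture.

    Two adjacent components overlap when their means differ by less than the
    sum of their standard deviations — the regime in which the pair forms a
    single skewed peak rather than two resolvable ones. The merged component
    carries the moment-matched mean and standard deviation of the weighted
    Gaussian mixture of its members.
    """
    comps = sorted(components, key=lambda c: c[1])
    changed = True
    while changed and len(comps) > 1:
        changed = False
        for i in range(len(comps) - 1):
            (w1, m1, s1), (w2, m2, s2) = comps[i], comps[i + 1]
            if abs(m2 - m1) < s1 + s2:
                w = w1 + w2
                mean = (w1 * m1 + w2 * m2) / w
                second = (w1 * (s1**2 + m1**2) + w2 * (s2**2 + m2**2)) / w
                sd = float(np.sqrt(max(second - mean**2, 1e-12)))
                comps[i : i + 2] = [(w, mean, sd)]
                changed = True
                break
    return comps


def fit_ks_mixture(ks_values, k_max: int = 4, seed: int = 0,
                   min_values: int = 20) -> MixtureFit:
    """Fit Gaussian mixtures to log(Ks), select by BIC, merge overlaps.

    Ks values <= 0.001 and saturated (nan) estimates are dropped first.
    Models with k = 1..k_max are fitted by EM (quantile-spread init, seeded
    restarts); the minimum-BIC model is selected and components closer than
    the larger of their sds are combined into their moment-matched mixture.
    """
    values = np.asarray([v for v in ks_values if np.isfinite(v) and v > KS_FLOOR], dtype=float)
    if len(values) < min_values:
        raise KsError(
            f"only {len(values)} usable Ks values after filtering (> {KS_FLOOR}); "
            f"need at least {min_values}"
        )
    x = np.log(values)
    rng = np.random.default_rng(seed)
    best_fit = None
    for k in range(1, k_max + 1):
        try:
            weights, means, sds, ll = _em_gaussian_1d(x, k, rng)
        except ConvergenceError:
            if k == 1:
                raise
            break  # an over-specified k crawls without converging; larger k only more so
        n_params = 3 * k - 1
        bic = -2.0 * ll + n_params * np.log(len(x))
        if best_fit is None or bic < best_fit.bic:
            best_fit = MixtureFit(
                components=list(zip(weights.tolist(), means.tolist(), sds.tolist())),
                bic=float(bic),
                loglik=ll,
                n_used=len(x),
            )
    merged = merge_overlapping_components(best_fit.components)
    return MixtureFit(merged, best_fit.bic, best_fit.loglik, best_fit.n_used)


# ---------------------------------------------------------------------------
# molecular clock
# ---------------------------------------------------------------------------

def calibrate_rate(peak_ks: float, T_years: float) -> MolecularClock:
    """Calibrate the silent substitution rate: lambda = Ks / (2 T)."""
    if peak_ks <= 0 or T_years <= 0:
        raise KsError("peak_ks and T_years must be positive")
    return MolecularClock(lam=peak_ks / (2.0 * T_years), calib_ks=peak_ks, calib_T=T_years)


def estimate_divergence(peak_ks: float, clock: MolecularClock) -> DivergenceEstimate:
    """Date a divergence from its Ks peak: T = Ks / (2 lambda)."""
    if peak_ks <= 0:
        raise KsError("peak_ks must be positive")
    return DivergenceEstimate(T=peak_ks / (2.0 * clock.lam), ks_used=peak_ks)


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def _best_hits(edges) -> dict[str, str]:
    """Best subject per query: max bitscore, then min evalue, then subject id."""
    best: dict[str, tuple[float, float, str]] = {}
    for e in edges:
        key = (-e.bitscore, e.evalue, e.subject)
        if e.query not in best or key < best[e.query]:
            best[e.query] = key
    return {q: key[2] for q, key in best.items()}


def reciprocal_best_hits(edges_ab, edges_ba) -> list[tuple[str, str]]:
    """Mutual best-hit pairs (a, b) between the two edge sets.

    Best = maximum bitscore; ties broken by minimum evalue, then
    lexicographically smallest subject id.
    """
    best_ab = _best_hits(edges_ab)
    best_ba = _best_hits(edges_ba)
    pairs = [
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    ]
    return sorted(pairs)
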