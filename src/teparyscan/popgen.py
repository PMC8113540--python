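"""Two-population windowed diversity scan: pi, Watterson theta, pi-ratio
with bootstrap tails and block merging (domestication), and the
fixed-difference SNP scan (adaptation).

Diversity is reported per bp of window width. Missing genotypes are
first-class: every statistic is computed pairwise-complete within a site,
with no imputation anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import GeneLocus, SiteRecord, VariantTable

logger = logging.getLogger("teparyscan")


class ScanError(ValueError):
    pass


@dataclass
class ScanConfig:
    window_bp: int = 100_000
    step_bp: int = 10_000
    tail_strict: float = 0.001
    tail_loose: float = 0.01
    n_bootstrap: int = 1_000
    seed: int = 0
    min_sites_per_window: int = 5

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ScanError("step_bp must be <= window_bp")
        if not 0 < self.tail_strict < self.tail_loose < 1:
            raise ScanError("need 0 < tail_strict < tail_loose < 1")


@dataclass
class WindowDiversity:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    n_snps: int
    pi_wild: float
    pi_landrace: float
    theta_wild: float
    theta_landrace: float
    ratio: float | None  # pi_wild / pi_landrace; inf if landrace 0; None if both 0
    low_confidence: bool = False
    tail_strict: bool = False
    tail_loose: bool = False


@dataclass
class DomesticationBlock:
    chrom: str
    start: int
    end: int
    member_windows: list[WindowDiversity]
    genes_overlapping: list[str] = field(default_factory=list)
    genes_monomorphic: list[str] = field(default_factory=list)


@dataclass
class FixedSite:
    chrom: str
    pos: int
    wild_allele: str
    landrace_allele: str


@dataclass
class RatioScanResult:
    threshold_strict: float
    threshold_loose: float
    windows: list[WindowDiversity]  # with tail flags set
    blocks: list[DomesticationBlock]


@dataclass
class FixedScanResult:
    fixed_sites: list[FixedSite]
    window_counts: list[tuple[str, int, int, int]]  # chrom, start, end, count
    threshold_strict: float | None = None
    threshold_loose: float | None = None


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i (Watterson uses a_{haplotypes-1})."""
    return float(sum(1.0 / i for i in range(1, n + 1)))


# ---------------------------------------------------------------------------
# per-site machinery
# ---------------------------------------------------------------------------

def allele_counts(genotypes: np.ndarray) -> tuple[int, int]:
    """(alt allele count j, non-missing haplotype count m) for diploid codes.

    Codes: 0 hom ref, 1 het, 2 hom alt, -1 missing; each diploid contributes
    two haplotypes, a heterozygote one of each allele.
    """
    called = genotypes >= 0
    m = 2 * int(called.sum())
    j = int(genotypes[called].sum())
    return j, m


def site_pi(genotypes: np.ndarray) -> float | None:
    """Unbiased per-site pi: 2 j (m - j) / (m (m - 1)).

    Equals the mean pairwise difference over all haplotype pairs. Returns
    None (site skipped) with fewer than two called haplotypes.
    """
    j, m = allele_counts(genotypes)
    if m < 2:
        return None
    return 2.0 * j * (m - j) / (m * (m - 1))


def _pop_indices(samples: list[str], popmap: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
    wild = np.array([i for i, s in enumerate(samples) if popmap[s] == "wild"], dtype=int)
    landrace = np.array([i for i, s in enumerate(samples) if popmap[s] == "landrace"], dtype=int)
    if len(wild) == 0 or len(landrace) == 0:
        raise ScanError("both populations must be non-empty")
    return wild, landrace


# ---------------------------------------------------------------------------
# windowed diversity
# ---------------------------------------------------------------------------

def _per_site_arrays(sites: list[SiteRecord], idx: np.ndarray):
    """Vectorized per-site (pi, segregating, called haplotypes) for one pop."""
    if not sites:
        z = np.zeros(0)
        return z, z.astype(bool), z
    geno = np.stack([s.genotypes[idx] for s in sites])  # (n_sites, n_pop)
    called = geno >= 0
    m = 2 * called.sum(axis=1)
    j = np.where(called, geno, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(m >= 2, 2.0 * j * (m - j) / np.maximum(m * (m - 1), 1), np.nan)
    seg = (m >= 2) & (j > 0) & (j < m)
    n_skipped = int((m < 2).sum())
    if n_skipped:
        logger.info("skipped %d sites with < 2 called haplotypes in one population", n_skipped)
    return pi, seg, m


def window_starts(chrom_len: int, config: ScanConfig) -> np.ndarray:
    """Tile window start positions from 1 with the configured stride."""
    return np.arange(1, chrom_len + 1, config.step_bp, dtype=int)


def window_diversity(
    table: VariantTable,
    popmap: dict[str, str],
    config: ScanConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowDiversity]:
    """Sliding-window pi and Watterson theta for both populations.

    Windows are tiled from position 1 per chromosome (width window_bp,
    stride step_bp, last window truncated at the chromosome end). pi is the
    summed per-site pi over the window length in bp; theta is S/(a_m * L)
    with a_m the harmonic number of the median called haplotype count minus
    one across the window's sites, and S the population's segregating sites.
    """
    config = config or ScanConfig()
    wild_idx, land_idx = _pop_indices(table.samples, popmap)
    by_chrom: dict[str, list[SiteRecord]] = {}
    for site in table:
        by_chrom.setdefault(site.chrom, []).append(site)
    windows: list[WindowDiversity] = []
    for chrom in sorted(by_chrom):
        sites = by_chrom[chrom]
        pos = np.array([s.pos for s in sites])
        if chrom_lengths and chrom in chrom_lengths:
            chrom_len = chrom_lengths[chrom]
        else:
            chrom_len = int(pos.max())
            logger.info("%s: length unknown, inferred %d from max site position", chrom, chrom_len)
        pi_w, seg_w, m_w = _per_site_arrays(sites, wild_idx)
        pi_l, seg_l, m_l = _per_site_arrays(sites, land_idx)
        cum_pi_w = np.concatenate([[0.0], np.nancumsum(pi_w)])
        cum_pi_l = np.concatenate([[0.0], np.nancumsum(pi_l)])
        cum_seg_w = np.concatenate([[0], np.cumsum(seg_w)])
        cum_seg_l = np.concatenate([[0], np.cumsum(seg_l)])
        for start in window_starts(chrom_len, config):
            end = min(start + config.window_bp - 1, chrom_len)
            L = end - start + 1
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, end, side="right"))
            n_snps = hi - lo
            sum_pi_w = cum_pi_w[hi] - cum_pi_w[lo]
            sum_pi_l = cum_pi_l[hi] - cum_pi_l[lo]
            S_w = int(cum_seg_w[hi] - cum_seg_w[lo])
            S_l = int(cum_seg_l[hi] - cum_seg_l[lo])
            theta_w = theta_l = 0.0
            if n_snps > 0:
                med_w = int(np.median(m_w[lo:hi]))
                med_l = int(np.median(m_l[lo:hi]))
                if med_w >= 2:
                    theta_w = S_w / (harmonic(med_w - 1) * L)
                if med_l >= 2:
                    theta_l = S_l / (harmonic(med_l - 1) * L)
            piw = sum_pi_w / L
            pil = sum_pi_l / L
            if pil > 0:
                ratio: float | None = piw / pil
            elif piw > 0:
                ratio = math.inf
            else:
                ratio = None  # both monomorphic: excluded from the ratio scan
            windows.append(
                WindowDiversity(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    n_snps=n_snps,
                    pi_wild=float(piw),
                    pi_landrace=float(pil),
                    theta_wild=float(theta_w),
                    theta_landrace=float(theta_l),
                    ratio=ratio,
                    low_confidence=n_snps < config.min_sites_per_window,
                )
            )
    return windows


# ---------------------------------------------------------------------------
# bootstrap tails and domestication blocks
# ---------------------------------------------------------------------------

def bootstrap_thresholds(
    values: np.ndarray, config: ScanConfig
) -> tuple[float, float]:
    """(strict, loose) upper-tail thresholds from a pooled window bootstrap.

    The window values are resampled with replacement n_bootstrap times, the
    resamples pooled, and the (1 - tail) empirical quantiles taken.
    """
    rng = np.random.default_rng(config.seed)
    pooled = rng.choice(values, size=(config.n_bootstrap, len(values)), replace=True).ravel()
    finite = pooled[np.isfinite(pooled)]
    inf_frac = 1.0 - len(finite) / len(pooled)
    strict, loose = [
        math.inf if inf_frac >= tail else float(np.quantile(finite, (1.0 - tail) / (1.0 - inf_frac)))
        for tail in (config.tail_strict, config.tail_loose)
    ]
    return strict, loose


def _merge_tail_runs(windows: list[WindowDiversity], config: ScanConfig) -> list[DomesticationBlock]:
    """Merge maximal runs of consecutive strict-tail windows into blocks."""
    blocks: list[DomesticationBlock] = []
    run: list[WindowDiversity] = []

    def flush() -> None:
        if run:
            blocks.append(
                DomesticationBlock(
                    chrom=run[0].chrom,
                    start=min(w.start for w in run),
                    end=max(w.end for w in run),
                    member_windows=list(run),
                )
            )
            run.clear()

    for w in windows:
        if not w.tail_strict:
            flush()
            continue
        consecutive = (
            run
            and run[-1].chrom == w.chrom
            and w.start == run[-1].start + config.step_bp
        )
        if not consecutive:
            flush()
        run.append(w)
    flush()
    return blocks


def ratio_scan(
    windows: list[WindowDiversity],
    config: ScanConfig | None = None,
) -> RatioScanResult:
    """Bootstrap the pi_wild/pi_landrace ratios and call tail windows/blocks.

    Windows with ratio >= the strict/loose threshold (infinite ratios always
    count as strict) are flagged; maximal runs of consecutive strict-tail
    windows are merged into domestication blocks.
    """
    config = config or ScanConfig()
    valid = [w for w in windows if w.ratio is not None]
    if len(valid) < 100:
        raise ScanError(f"ratio scan needs >= 100 valid windows, got {len(valid)}")
    ratios = np.array([w.ratio for w in valid], dtype=float)
    strict, loose = bootstrap_thresholds(ratios, config)
    # a threshold equal to the distribution minimum means the distribution is
    # degenerate and has no tail; infinite ratios (complete landrace
    # diversity loss) always qualify
    finite = ratios[np.isfinite(ratios)]
    floor = float(finite.min()) if len(finite) else math.inf
    for w in windows:
        if w.ratio is None:
            continue
        w.tail_strict = math.isinf(w.ratio) or (strict > floor and w.ratio >= strict)
        w.tail_loose = w.tail_strict or (loose > floor and w.ratio >= loose)
    blocks = _merge_tail_runs(windows, config)
    return RatioScanResult(strict, loose, windows, blocks)


# ---------------------------------------------------------------------------
# fixed differences and SNP polymorphism classes
# ---------------------------------------------------------------------------

def _pop_state(genotypes: np.ndarray) -> str | None:
    """'poly', 'ref', 'alt' (monomorphic states) or None (no calls)."""
    j, m = allele_counts(genotypes)
    if m == 0:
        return None
    if j == 0:
        return "ref"
    if j == m:
        return "alt"
    return "poly"


def fixed_difference_scan(
    table: VariantTable,
    popmap: dict[str, str],
    config: ScanConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> FixedScanResult:
    """SNPs fixed for one allele in all wild and the other in all landraces.

    A site qualifies iff it has no heterozygous call, at least one call in
    each population, all called wild genotypes are homozygous for one allele
    and all called landrace genotypes homozygous for the other. Counts are
    aggregated per window; when a config is given, the same pooled-bootstrap
    machinery as the ratio scan sets tail thresholds on the counts.
    """
    wild_idx, land_idx = _pop_indices(table.samples, popmap)
    fixed: list[FixedSite] = []
    for site in table:
        if (site.genotypes == 1).any():
            continue
        sw = _pop_state(site.genotypes[wild_idx])
        sl = _pop_state(site.genotypes[land_idx])
        if sw in ("ref", "alt") and sl in ("ref", "alt") and sw != sl:
            wild_allele = site.ref_allele if sw == "ref" else site.alt_allele
            land_allele = site.ref_allele if sl == "ref" else site.alt_allele
            fixed.append(FixedSite(site.chrom, site.pos, wild_allele, land_allele))
    config = config or ScanConfig()
    window_counts: list[tuple[str, int, int, int]] = []
    by_chrom: dict[str, list[int]] = {}
    for site in table:
        by_chrom.setdefault(site.chrom, []).append(site.pos)
    fixed_by_chrom: dict[str, np.ndarray] = {}
    for f in fixed:
        fixed_by_chrom.setdefault(f.chrom, [])
    for chrom in fixed_by_chrom:
        fixed_by_chrom[chrom] = np.array(sorted(f.pos for f in fixed if f.chrom == chrom))
    for chrom in sorted(by_chrom):
        if chrom_lengths and chrom in chrom_lengths:
            chrom_len = chrom_lengths[chrom]
        else:
            chrom_len = max(by_chrom[chrom])
        fpos = fixed_by_chrom.get(chrom, np.zeros(0, dtype=int))
        for start in window_starts(chrom_len, config):
            end = min(start + config.window_bp - 1, chrom_len)
            lo = int(np.searchsorted(fpos, start, side="left"))
            hi = int(np.searchsorted(fpos, end, side="right"))
            window_counts.append((chrom, int(start), int(end), hi - lo))
    counts = np.array([c[3] for c in window_counts], dtype=float)
    strict = loose = None
    if len(counts) >= 100:
        strict, loose = bootstrap_thresholds(counts, config)
    return FixedScanResult(fixed, window_counts, strict, loose)


POLYMORPHISM_LABELS = (
    "poly_both",
    "poly_wild_only",
    "poly_landrace_only",
    "mono_both",
    "fixed_difference",
)


def classify_snp_polymorphism(
    table: VariantTable, popmap: dict[str, str]
) -> dict[str, int]:
    """Tally each SNP into the five mutually exclusive polymorphism classes.

    Sites with no called genotype in either population are unclassifiable
    and excluded (logged).
    """
    wild_idx, land_idx = _pop_indices(table.samples, popmap)
    tally = {label: 0 for label in POLYMORPHISM_LABELS}
    n_unclassified = 0
    for site in table:
        sw = _pop_state(site.genotypes[wild_idx])
        sl = _pop_state(site.genotypes[land_idx])
        if sw is None or sl is None:
            n_unclassified += 1
            continue
        if sw == "poly" and sl == "poly":
            tally["poly_both"] += 1
        elif sw == "poly":
            tally["poly_wild_only"] += 1
        elif sl == "poly":
            tally["poly_landrace_only"] += 1
        elif sw == sl:
            tally["mono_both"] += 1
        else:
            tally["fixed_difference"] += 1
    if n_unclassified:
        logger.info("excluded %d sites with no calls in one population", n_unclassified)
    return tally


def polymorphism_summary(tally: dict[str, int]) -> list[tuple[str, int, float]]:
    """(label, count, percent-of-classified to 1 decimal) summary rows."""
    total = sum(tally.values())
    return [
        (label, count, round(100.0 * count / total, 1) if total else 0.0)
        for label, count in tally.items()
    ]


# ---------------------------------------------------------------------------
# gene-level report over domestication blocks
# ---------------------------------------------------------------------------

@dataclass
class GeneBlockReport:
    gene_rows: list[tuple[str, str, str]]  # gene_id, block_id-ish chrom:start-end, status
    n_genes_in_blocks: int
    n_monomorphic: int
    n_no_data: int
    monomorphic_block_span_bp: int


def gene_block_report(
    blocks: list[DomesticationBlock],
    loci: list[GeneLocus],
    table: VariantTable,
    popmap: dict[str, str],
) -> GeneBlockReport:
    """Classify genes overlapping domestication blocks by landrace diversity.

    A gene overlaps a block iff their spans share >= 1 bp. A gene is
    monomorphic iff no SNP within its span is polymorphic among landrace
    samples; genes containing zero SNPs are labeled no_data and reported
    separately. Also returns the summed length of blocks containing >= 1
    monomorphic gene.
    """
    _, land_idx = _pop_indices(table.samples, popmap)
    pos_by_chrom: dict[str, np.ndarray] = {}
    poly_by_chrom: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[SiteRecord]] = {}
    for site in table:
        by_chrom.setdefault(site.chrom, []).append(site)
    for chrom, sites in by_chrom.items():
        pos_by_chrom[chrom] = np.array([s.pos for s in sites])
        poly_by_chrom[chrom] = np.array(
            [_pop_state(s.genotypes[land_idx]) == "poly" for s in sites]
        )
    rows: list[tuple[str, str, str]] = []
    n_mono = n_no_data = 0
    mono_blocks: set[int] = set()
    for gene in loci:
        for bi, block in enumerate(blocks):
            if block.chrom != gene.chrom or gene.start > block.end or block.start > gene.end:
                continue
            pos = pos_by_chrom.get(gene.chrom, np.zeros(0, dtype=int))
            lo = int(np.searchsorted(pos, gene.start, side="left"))
            hi = int(np.searchsorted(pos, gene.end, side="right"))
            block_tag = f"{block.chrom}:{block.start}-{block.end}"
            block.genes_overlapping.append(gene.gene_id)
            if hi == lo:
                status = "no_data"
                n_no_data += 1
            elif not poly_by_chrom[gene.chrom][lo:hi].any():
                status = "monomorphic"
                n_mono += 1
                mono_blocks.add(bi)
                block.genes_monomorphic.append(gene.gene_id)
            else:
                status = "polymorphic"
            rows.append((gene.gene_id, block_tag, status))
            break  # a gene is counted against the first overlapping block
    span = sum(blocks[bi].end - blocks[bi].start + 1 for bi in mono_blocks)
    return GeneBlockReport(
        gene_rows=rows,
        n_genes_in_blocks=len(rows),
        n_monomorphic=n_mono,
        n_no_data=n_no_data,
        monomorphic_block_span_bp=span,
    )
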