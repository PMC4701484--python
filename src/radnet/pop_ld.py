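"""LD decay, haplotype blocks, PIC, heritability and GWAS-threshold arithmetic.

LD decay
--------
The expected squared allele correlation between two loci separated by a
recombination-scaled distance C = rho * d (rho per bp, d in bp) under drift
with sample size n follows the Hill–Weir expectation

    E(r^2) = (10 + C) / ((2 + C)(11 + C))
             * [1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C))]

which is monotone decreasing in distance.  ``fit_ld_decay`` estimates rho by
nonlinear least squares over observed (distance, r^2) pairs and reports the
distance at which the fitted curve falls to a background r^2 (the panel's
unlinked-marker level) — the "LD decay distance".

Haplotype blocks
----------------
Blocks are found with the confidence-interval (CI) model: for every marker
pair within a physical window, a 90% likelihood interval on |D'| is computed
from the two-locus haploid haplotype counts.  A pair is *strong LD* when the
interval is [>= 0.70, >= 0.98] and *strong recombination* when its upper
bound is < 0.90.  A run of markers is a block when at least 95% of its
informative pairs are strong LD; overlapping candidates are resolved longest
first, and blocks shorter than a minimum physical length (default 100 kb)
are discarded.  Blocks found separately in two population groups are then
classified as group-specific, common, or group-preferential (common but with
major-haplotype frequency differing by more than 0.40).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ld_map import HaploidPanel

__all__ = [
    "DecayFit",
    "HaplotypeBlock",
    "VarianceComponents",
    "hill_weir_expected_r2",
    "fit_ld_decay",
    "dprime_confidence_intervals",
    "gabriel_blocks",
    "classify_blocks",
    "haplotype_frequencies",
    "pic",
    "haplotype_phenotype_summary",
    "heritability",
    "bonferroni_threshold",
]


# ---------------------------------------------------------------------------
# LD decay


def hill_weir_expected_r2(distance_bp, rho: float, n: float):
    """Drift expectation of r^2 at recombination-scaled distance C = rho*d."""
    C = rho * np.asarray(distance_bp, dtype=np.float64)
    denom = (2.0 + C) * (11.0 + C)
    term = ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (n * denom)
    return (10.0 + C) / denom * (1.0 + term)


@dataclass
class DecayFit:
    rho: float
    n_eff: float
    residual_sse: float
    background: float
    decay_distance_bp: Optional[float]
    n_pairs: int = 0

    def expected_r2(self, distance_bp):
        return hill_weir_expected_r2(distance_bp, self.rho, self.n_eff)


def fit_ld_decay(
    distances_bp: Sequence[float],
    r2_values: Sequence[float],
    n_lines: int,
    background: float = 0.26,
    min_pairs: int = 50,
) -> DecayFit:
    """Fit the Hill–Weir decay curve and locate the background crossing.

    ``n_lines`` enters the expectation as its sample-size term and is held
    fixed; only rho is free.  The decay distance solves
    E(r^2)(d) = background on the fitted monotone curve (bisection); when the
    curve never reaches the background — e.g. background above E(r^2)(0) —
    ``decay_distance_bp`` is None.
    """
    d = np.asarray(distances_bp, dtype=np.float64)
    y = np.asarray(r2_values, dtype=np.float64)
    ok = np.isfinite(d) & np.isfinite(y) & (d > 0)
    d, y = d[ok], y[ok]
    if d.size < min_pairs:
        raise ValueError(f"need >= {min_pairs} intra-chromosomal pairs, got {d.size}")

    def residuals(log_rho):
        return hill_weir_expected_r2(d, math.exp(log_rho[0]), n_lines) - y

    # initial scale: put C ~ 1 at the median distance
    x0 = [math.log(1.0 / np.median(d))]
    sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=10_000)
    if not sol.success:
        raise RuntimeError(f"LD-decay fit did not converge: {sol.message}; "
                           f"last rho = {math.exp(sol.x[0]):.3g}")
    rho = math.exp(sol.x[0])
    sse = float(np.sum(sol.fun**2))

    decay = _decay_crossing(rho, n_lines, background, d.max())
    return DecayFit(
        rho=rho,
        n_eff=float(n_lines),
        residual_sse=sse,
        background=background,
        decay_distance_bp=decay,
        n_pairs=int(d.size),
    )


def _decay_crossing(
    rho: float, n: float, background: float, d_hint: float
) -> Optional[float]:
    """Distance where the Hill–Weir curve crosses the background, or None."""
    f = lambda dd: hill_weir_expected_r2(dd, rho, n) - background
    lo = 1e-9
    if f(lo) <= 0:  # background at or above the curve's ceiling
        return None
    hi = max(d_hint, 1.0)
    for _ in range(200):
        if f(hi) < 0:
            break
        hi *= 2.0
    else:
        return None  # curve asymptote stays above background
    return float(optimize.brentq(f, lo, hi, xtol=1e-6, rtol=1e-12))


# ---------------------------------------------------------------------------
# D' confidence intervals and Gabriel blocks

_DPRIME_GRID = np.linspace(0.0, 1.0, 101)


def _pair_counts(X: np.ndarray) -> Tuple[np.ndarray, ...]:
    """Two-locus haploid haplotype counts for every column pair of X.

    Returns (n11, n10, n01, n00) as m x m arrays over pairwise-complete lines.
    """
    M = (~np.isnan(X)).astype(np.float64)
    X0 = np.nan_to_num(X)
    X1 = M - X0  # indicator of allele 0, masked
    n11 = X0.T @ X0
    n10 = X0.T @ X1
    n01 = X1.T @ X0
    n00 = X1.T @ X1
    return n11, n10, n01, n00


def dprime_confidence_intervals(
    X: np.ndarray, min_lines: int = 10
) -> Tuple[np.ndarray, np.ndarray]:
    """90% likelihood intervals on |D'| for every column pair.

    For each pair, the two-locus haplotype counts define a likelihood over
    |D'| in {0, 0.01, ..., 1} (haplotype probabilities moved from linkage
    equilibrium toward the maximal D of the observed sign).  The interval is
    [low, high] where the lower 5% and upper 5% of the normalised likelihood
    mass are trimmed.  Returns (ci_low, ci_high), NaN for non-informative
    pairs (monomorphic or fewer than ``min_lines`` complete lines).
    """
    n11, n10, n01, n00 = _pair_counts(X)
    n = n11 + n10 + n01 + n00
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = (n11 + n10) / n
        pB = (n11 + n01) / n
        D = n11 / n - pA * pB
    informative = (
        (n >= min_lines) & (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
    )
    iu, ju = np.where(np.triu(informative, k=1))
    m = X.shape[1]
    ci_low = np.full((m, m), np.nan)
    ci_high = np.full((m, m), np.nan)
    if iu.size == 0:
        return ci_low, ci_high

    # flip allele labels at one locus so D >= 0, then Dmax is one-sided
    pa, pb, dd = pA[iu, ju], pB[iu, ju], D[iu, ju]
    c11, c10, c01, c00 = n11[iu, ju], n10[iu, ju], n01[iu, ju], n00[iu, ju]
    neg = dd < 0
    pb = np.where(neg, 1.0 - pb, pb)
    c11_, c10_ = np.where(neg, c10, c11), np.where(neg, c11, c10)
    c01_, c00_ = np.where(neg, c00, c01), np.where(neg, c01, c00)
    dmax = np.minimum(pa * (1 - pb), (1 - pa) * pb)

    grid = _DPRIME_GRID[None, :]  # (1, G)
    Dg = grid * dmax[:, None]  # (P, G)
    eps = 1e-12
    h11 = np.clip(pa[:, None] * pb[:, None] + Dg, eps, None)
    h10 = np.clip(pa[:, None] * (1 - pb[:, None]) - Dg, eps, None)
    h01 = np.clip((1 - pa[:, None]) * pb[:, None] - Dg, eps, None)
    h00 = np.clip((1 - pa[:, None]) * (1 - pb[:, None]) + Dg, eps, None)
    loglik = (
        c11_[:, None] * np.log(h11)
        + c10_[:, None] * np.log(h10)
        + c01_[:, None] * np.log(h01)
        + c00_[:, None] * np.log(h00)
    )
    loglik -= loglik.max(axis=1, keepdims=True)
    lik = np.exp(loglik)
    lik /= lik.sum(axis=1, keepdims=True)
    cum = np.cumsum(lik, axis=1)
    # lower bound: first grid point where >5% of mass lies at or below
    low_idx = np.argmax(cum > 0.05, axis=1)
    # upper bound: last grid point where >5% of mass lies at or above
    tail = 1.0 - cum + lik
    high_idx = lik.shape[1] - 1 - np.argmax(tail[:, ::-1] > 0.05, axis=1)
    ci_low[iu, ju] = _DPRIME_GRID[low_idx]
    ci_high[iu, ju] = _DPRIME_GRID[high_idx]
    ci_low[ju, iu] = ci_low[iu, ju]
    ci_high[ju, iu] = ci_high[iu, ju]
    return ci_low, ci_high


@dataclass
class HaplotypeBlock:
    chromosome: str
    start_bp: int
    end_bp: int  # 1-based inclusive
    snp_ids: List[str]
    haplotypes: pd.DataFrame = field(default_factory=pd.DataFrame)
    label: str = "entire_panel"

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def overlaps(self, other: "HaplotypeBlock") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )


def haplotype_frequencies(
    panel: HaploidPanel, snp_ids: Sequence[str]
) -> pd.DataFrame:
    """Haplotype counts/frequencies over lines with no missing call in the
    block (columns: haplotype, count, frequency)."""
    sub = panel.subset(snp_ids)
    complete = ~np.isnan(sub.alleles).any(axis=1)
    rows = sub.alleles[complete].astype(int)
    if rows.size == 0:
        return pd.DataFrame(columns=["haplotype", "count", "frequency"])
    haps, counts = np.unique(
        ["".join(map(str, row)) for row in rows], return_counts=True
    )
    order = np.argsort(-counts, kind="stable")
    total = counts.sum()
    return pd.DataFrame(
        {
            "haplotype": haps[order],
            "count": counts[order],
            "frequency": counts[order] / total,
        }
    )


def gabriel_blocks(
    panel: HaploidPanel,
    positions: pd.DataFrame,
    window_bp: int = 10_000_000,
    min_block_bp: int = 100_000,
    strong_low: float = 0.70,
    strong_high: float = 0.98,
    recomb_high: float = 0.90,
    min_strong_fraction: float = 0.95,
    min_informative_lines: int = 10,
) -> List[HaplotypeBlock]:
    """Confidence-interval haplotype blocks per chromosome.

    ``positions`` maps marker_id -> (chromosome, bp); markers must be sorted
    by bp within each chromosome.  A candidate interval [i..j] (span within
    ``window_bp``) is a block when >= ``min_strong_fraction`` of its
    informative pairs are strong LD and its bounding pair is itself strong
    LD; overlapping candidates are resolved longest first; blocks shorter
    than ``min_block_bp`` are discarded.
    """
    pos = positions.set_index("marker_id")
    blocks: List[HaplotypeBlock] = []
    for chrom, group in positions.groupby("chromosome", sort=True):
        ids = list(group["marker_id"])
        bp = np.asarray(group["bp"], dtype=np.int64)
        if np.any(np.diff(bp) < 0):
            raise ValueError(f"{chrom}: marker positions are not sorted by bp")
        idx = [panel.marker_ids.index(m) for m in ids]
        X = panel.alleles[:, idx].astype(np.float64)
        m = len(ids)
        if m < 2:
            continue
        ci_low, ci_high = dprime_confidence_intervals(X, min_informative_lines)
        strong = (ci_low >= strong_low) & (ci_high >= strong_high)
        informative = ~np.isnan(ci_low) & (
            strong | (ci_high < recomb_high)
        )
        # 2-D prefix sums so any interval's pair tallies are O(1)
        S = np.zeros((m + 1, m + 1))
        I = np.zeros((m + 1, m + 1))
        S[1:, 1:] = np.cumsum(np.cumsum(np.triu(strong, 1), axis=0), axis=1)
        I[1:, 1:] = np.cumsum(np.cumsum(np.triu(informative, 1), axis=0), axis=1)

        def n_in(P, i, j):  # pairs (a, b), i <= a < b <= j
            return P[j + 1, j + 1] - P[i, j + 1] - P[j + 1, i] + P[i, i]

        candidates = []
        for i in range(m - 1):
            for j in range(i + 1, m):
                if bp[j] - bp[i] > window_bp:
                    break
                if not strong[i, j]:
                    continue
                n_inf = n_in(I, i, j)
                if n_inf == 0:
                    continue
                if n_in(S, i, j) / n_inf >= min_strong_fraction:
                    candidates.append((i, j))
        # longest (physical span) first; ties by position
        candidates.sort(key=lambda ij: (-(bp[ij[1]] - bp[ij[0]]), ij[0], ij[1]))
        taken = np.zeros(m, dtype=bool)
        for i, j in candidates:
            if taken[i : j + 1].any():
                continue
            length = int(bp[j] - bp[i] + 1)
            if length < min_block_bp:
                continue
            taken[i : j + 1] = True
            snp_ids = ids[i : j + 1]
            blocks.append(
                HaplotypeBlock(
                    chromosome=str(chrom),
                    start_bp=int(bp[i]),
                    end_bp=int(bp[j]),
                    snp_ids=snp_ids,
                    haplotypes=haplotype_frequencies(panel, snp_ids),
                )
            )
    blocks.sort(key=lambda b: (b.chromosome, b.start_bp))
    return blocks


def _major_freq_by_group(
    block_snps: List[str],
    panel_p1: HaploidPanel,
    panel_p2: HaploidPanel,
) -> Tuple[float, float]:
    """Frequency in each group of the pooled-majority haplotype on the SNPs."""
    shared = [m for m in block_snps
              if m in panel_p1.marker_ids and m in panel_p2.marker_ids]
    f1 = haplotype_frequencies(panel_p1, shared)
    f2 = haplotype_frequencies(panel_p2, shared)
    pooled: Dict[str, int] = {}
    for df in (f1, f2):
        for hap, cnt in zip(df["haplotype"], df["count"]):
            pooled[hap] = pooled.get(hap, 0) + int(cnt)
    if not pooled:
        return math.nan, math.nan
    major = max(sorted(pooled), key=lambda h: pooled[h])
    get = lambda df: float(df.loc[df["haplotype"] == major, "frequency"].sum())
    return get(f1), get(f2)


def classify_blocks(
    blocks_p1: Sequence[HaplotypeBlock],
    blocks_p2: Sequence[HaplotypeBlock],
    panel_p1: HaploidPanel,
    panel_p2: HaploidPanel,
    freq_diff: float = 0.40,
    min_specific_bp: int = 50_000,
) -> List[HaplotypeBlock]:
    """Label per-group blocks as group-specific, common or preferential.

    A block seen in one group with no overlapping (>= 1 bp) block in the
    other group, and at least ``min_specific_bp`` long, is group-specific.
    Overlapping blocks are common; a common pair whose pooled-major
    haplotype frequency differs between groups by more than ``freq_diff``
    is group-preferential (both members labelled).
    """
    out: List[HaplotypeBlock] = []
    for own, other, own_label in (
        (blocks_p1, blocks_p2, "p1_specific"),
        (blocks_p2, blocks_p1, "p2_specific"),
    ):
        p_own = panel_p1 if own_label == "p1_specific" else panel_p2
        for block in own:
            partners = [b for b in other if block.overlaps(b)]
            labelled = HaplotypeBlock(
                block.chromosome, block.start_bp, block.end_bp,
                list(block.snp_ids), block.haplotypes,
            )
            if not partners:
                if block.length_bp >= min_specific_bp:
                    labelled.label = own_label
                    out.append(labelled)
                continue
            f1, f2 = _major_freq_by_group(block.snp_ids, panel_p1, panel_p2)
            labelled.label = (
                "preferential"
                if (np.isfinite(f1) and np.isfinite(f2) and abs(f1 - f2) > freq_diff)
                else "common"
            )
            out.append(labelled)
    out.sort(key=lambda b: (b.chromosome, b.start_bp, b.label))
    return out


# ---------------------------------------------------------------------------
# marker / trait arithmetic


def pic(p: float) -> float:
    """Polymorphism information content of a biallelic marker.

    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2, maximal (0.375) at p = 0.5.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p}")
    q = 1.0 - p
    # cancellation near p in {0, 1} can give a tiny negative; PIC is >= 0
    return max(0.0, 1.0 - (p * p + q * q) - 2.0 * p * p * q * q)


def haplotype_phenotype_summary(
    panel: HaploidPanel,
    snp_ids: Sequence[str],
    phenotypes: Dict[str, float],
    min_lines: int = 2,
) -> Tuple[pd.DataFrame, Optional[dict]]:
    """Per-haplotype phenotype means for a block, plus a major-vs-rest test.

    Lines with any missing call in the block are excluded; haplotypes carried
    by fewer than ``min_lines`` lines are suppressed.  The comparison is a
    Welch t-test between the major haplotype's lines and all other lines
    (pooled), returned as a dict or None when either side is < 2 lines.
    """
    sub = panel.subset(snp_ids)
    complete = ~np.isnan(sub.alleles).any(axis=1)
    groups: Dict[str, List[float]] = {}
    for i in np.flatnonzero(complete):
        line = sub.line_ids[i]
        if line not in phenotypes or not np.isfinite(phenotypes[line]):
            continue
        hap = "".join(str(int(a)) for a in sub.alleles[i])
        groups.setdefault(hap, []).append(phenotypes[line])
    rows = [
        {
            "haplotype": hap,
            "n_lines": len(vals),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan,
        }
        for hap, vals in groups.items()
        if len(vals) >= min_lines
    ]
    table = pd.DataFrame(rows, columns=["haplotype", "n_lines", "mean", "sd"])
    table = table.sort_values(["n_lines", "haplotype"], ascending=[False, True],
                              ignore_index=True)
    test = None
    if len(table) >= 1:
        major = table.loc[0, "haplotype"]
        major_vals = groups[major]
        rest = [v for hap, vals in groups.items() if hap != major for v in vals]
        if len(major_vals) >= 2 and len(rest) >= 2:
            t, p = stats.ttest_ind(major_vals, rest, equal_var=False)
            test = {
                "major_haplotype": major,
                "mean_major": float(np.mean(major_vals)),
                "mean_rest": float(np.mean(rest)),
                "difference": float(np.mean(major_vals) - np.mean(rest)),
                "t": float(t),
                "p_value": float(p),
            }
    return table, test


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    n_env: int
    n_rep: int

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability across environments and replicates.

    H^2 = sg^2 / (sg^2 + sge^2/n + se^2/(n r)) for n environments and r
    replicates per environment.
    """
    denom = vc.sigma2_g + vc.sigma2_ge / vc.n_env + vc.sigma2_e / (vc.n_env * vc.n_rep)
    if denom == 0:
        raise ValueError("all variance components are zero; H^2 undefined")
    return vc.sigma2_g / denom


def bonferroni_threshold(n_markers: int) -> float:
    """Genome-wide significance threshold 1/n for n markers."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    return 1.0 / n_markers
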