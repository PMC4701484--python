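"""Synthetic ddRAD panels and genotype matrices with known truth.

Two generators cover the two halves of the toolkit:

* :func:`simulate_read_panel` writes barcoded 90 bp paired-end FASTQ for an
  inbred two-group panel.  Each allelic locus is a pair of 80+80 nt tags
  differing at 1–3 planted positions; each homeolog family is a set of 2–4
  mutually similar tags co-present in *every* line — the worst case for the
  relative-heterozygosity discriminator, because such families look like
  constitutive heterozygotes.  Reads carry Poisson depth per present tag and
  uniform substitution errors.

* :func:`simulate_ld_genotypes` lays markers along chromosomes with physical
  positions and generates haploid genotypes through a Gaussian-copula
  threshold model: adjacent markers share a latent correlation taken from
  the drift expectation of r^2 at the configured rho, so LD decays with
  distance; perfect-LD blocks, group-specific blocks and phenotype effects
  can be planted.  It is not a coalescent — distant-pair correlation decays
  as a product over adjacent pairs, i.e. slightly faster than the drift
  curve — but every planted feature is recorded in machine-readable truth
  tables, which is what the tests consume.

Group allele frequencies follow a Balding–Nichols-style divergence model:
ancestral frequency p, per-group frequency Beta(p(1-F)/F, (1-p)(1-F)/F).

All randomness flows from the explicit ``seed``; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_demux import BarcodeSpec, GenotypeMatrix, HOM1, HOM2, MISSING
from .ld_map import HaploidPanel
from .pop_ld import hill_weir_expected_r2

__all__ = [
    "SimConfig",
    "TruthTables",
    "simulate_read_panel",
    "simulate_ld_genotypes",
    "simulate_decay_r2_pairs",
    "SACI_REMNANT",
    "MSEI_REMNANT",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# restriction-site remnants left after adaptor ligation (SacI / MseI digest)
SACI_REMNANT = "AGCTC"
MSEI_REMNANT = "TAA"

TAG_LEN = 80
READ_LEN = 90
BARCODE_LEN = 5


@dataclass
class SimConfig:
    """Stated world for the read-panel generator.

    Defaults describe the reference scenario used throughout the test suite:
    96 inbred lines in two groups (72/28 split mirroring a semi-winter vs
    spring panel), 500 true allelic loci with 1–3 SNPs each, 100 homeolog
    families co-present in all lines, 0.2% per-base substitution error and
    Poisson(8) read depth per present tag.
    """

    n_lines: int = 96
    n_loci_allelic: int = 500
    n_homeolog_families: int = 100
    n_snps_per_locus: Tuple[int, int] = (1, 3)  # inclusive range
    error_rate: float = 0.002
    depth_mean: float = 8.0
    split_fraction: float = 0.72  # fraction of lines in group P1
    fst: float = 0.15  # Balding–Nichols divergence between the groups
    ld_rho: float = 2e-6  # per-bp decay parameter for genotype simulation
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("error_rate", "split_fraction", "fst"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic run")


@dataclass
class TruthTables:
    """Machine-readable ground truth emitted next to every simulation."""

    tag_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: locus_id, tag_a_r1, tag_a_r2, tag_b_r1, tag_b_r2, n_snps
    genotypes: Optional[GenotypeMatrix] = None
    homeolog_families: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: family_id, member, seq_r1, seq_r2
    blocks: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: chromosome, start_bp, end_bp, first_marker, last_marker, group
    phenotype_effects: Dict[str, float] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _mutate(
    rng: np.random.Generator, tag: np.ndarray, positions: Sequence[int]
) -> np.ndarray:
    """Return a copy with a different base planted at each position."""
    out = tag.copy()
    for pos in positions:
        current = out[pos]
        choices = BASES[BASES != current]
        out[pos] = rng.choice(choices)
    return out


def _barcode_set(rng: np.random.Generator, n: int) -> List[str]:
    """n distinct 5-nt barcodes."""
    seen: Dict[str, None] = {}
    while len(seen) < n:
        seen.setdefault(_to_str(_random_seq(rng, BARCODE_LEN)), None)
    return list(seen)[:n]


def _plant_snp_positions(rng: np.random.Generator, n_snps: int) -> List[int]:
    """SNP offsets in the 160-nt concatenated tag, <= 2 per end, outside the
    restriction remnants (so error-free reads always demultiplex)."""
    r1_sites = np.arange(len(SACI_REMNANT), TAG_LEN)
    r2_sites = np.arange(TAG_LEN + len(MSEI_REMNANT), 2 * TAG_LEN)
    n_r1 = int(rng.integers(max(0, n_snps - 2), min(2, n_snps) + 1))
    picks = list(rng.choice(r1_sites, size=n_r1, replace=False)) + list(
        rng.choice(r2_sites, size=n_snps - n_r1, replace=False)
    )
    return sorted(int(p) for p in picks)


def _group_freqs(
    rng: np.random.Generator, n: int, fst: float, smooth: bool = False
) -> Tuple[np.ndarray, np.ndarray]:
    """Balding–Nichols allele-1 frequencies for the two groups.

    With ``smooth`` the ancestral frequency follows a slow logit-scale random
    walk along the chromosome: markers in strong LD share genealogy and hence
    similar allele frequencies, which independent draws would contradict.
    """
    if smooth:
        logit = np.empty(n)
        logit[0] = rng.normal(0.0, 0.8)
        steps = rng.normal(0.0, 0.15, size=n - 1) if n > 1 else []
        for k in range(1, n):
            logit[k] = 0.97 * logit[k - 1] + steps[k - 1]
        p = 1.0 / (1.0 + np.exp(-logit))
        p = np.clip(p, 0.15, 0.85)
    else:
        p = rng.uniform(0.15, 0.85, size=n)
    if fst <= 0:
        return p.copy(), p.copy()
    a, b = p * (1 - fst) / fst, (1 - p) * (1 - fst) / fst
    return rng.beta(a, b), rng.beta(a, b)


def simulate_read_panel(cfg: SimConfig, outdir) -> dict:
    """Write FASTQ pairs + barcode table for a synthetic inbred ddRAD panel.

    Returns a dict with paths (fastq_r1, fastq_r2, barcode_table), the
    barcode specs, line/group assignments and a :class:`TruthTables`.
    """
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    line_ids = [f"L{i:03d}" for i in range(cfg.n_lines)]
    n_p1 = int(round(cfg.split_fraction * cfg.n_lines))
    groups = {line: ("P1" if i < n_p1 else "P2") for i, line in enumerate(line_ids)}

    barcodes = _barcode_set(rng, cfg.n_lines)
    specs = [
        BarcodeSpec(line, bc, SACI_REMNANT, MSEI_REMNANT)
        for line, bc in zip(line_ids, barcodes)
    ]

    # --- allelic loci: tag pairs + inbred genotypes --------------------------
    lo, hi = cfg.n_snps_per_locus
    pair_rows, geno_cols, alleles = [], [], []
    tag_a_seqs, tag_b_seqs = [], []
    p1, p2 = _group_freqs(rng, cfg.n_loci_allelic, cfg.fst)
    remnant1 = np.frombuffer(SACI_REMNANT.encode(), dtype=np.uint8)
    remnant2 = np.frombuffer(MSEI_REMNANT.encode(), dtype=np.uint8)
    for k in range(cfg.n_loci_allelic):
        base = np.concatenate(
            [remnant1, _random_seq(rng, TAG_LEN - len(remnant1)),
             remnant2, _random_seq(rng, TAG_LEN - len(remnant2))]
        )
        n_snps = int(rng.integers(lo, hi + 1))
        alt = _mutate(rng, base, _plant_snp_positions(rng, n_snps))
        tag_a_seqs.append(base)
        tag_b_seqs.append(alt)
        pair_rows.append(
            {
                "locus_id": f"locus{k:04d}",
                "tag_a_r1": _to_str(base[:TAG_LEN]),
                "tag_a_r2": _to_str(base[TAG_LEN:]),
                "tag_b_r1": _to_str(alt[:TAG_LEN]),
                "tag_b_r2": _to_str(alt[TAG_LEN:]),
                "n_snps": n_snps,
            }
        )
        freq = np.where(
            np.array([groups[l] == "P1" for l in line_ids]), p1[k], p2[k]
        )
        # inbred lines: haploid draw doubled into a homozygote
        allele1 = rng.random(cfg.n_lines) < freq  # True -> tag_a
        geno_cols.append(np.where(allele1, HOM1, HOM2).astype(np.int8))
        alleles.append(("A", "B"))
    truth_genotypes = GenotypeMatrix(
        line_ids,
        [row["locus_id"] for row in pair_rows],
        np.stack(geno_cols, axis=1),
        alleles,
    )

    # --- homeolog families: similar tags co-present in every line ------------
    fam_rows = []
    fam_seqs: List[np.ndarray] = []
    for f in range(cfg.n_homeolog_families):
        base = np.concatenate(
            [remnant1, _random_seq(rng, TAG_LEN - len(remnant1)),
             remnant2, _random_seq(rng, TAG_LEN - len(remnant2))]
        )
        n_members = int(rng.integers(2, 5))
        members = [base]
        for _ in range(n_members - 1):
            members.append(
                _mutate(rng, base, _plant_snp_positions(rng, int(rng.integers(1, 4))))
            )
        for m, seq in enumerate(members):
            fam_rows.append(
                {
                    "family_id": f"fam{f:03d}",
                    "member": m,
                    "seq_r1": _to_str(seq[:TAG_LEN]),
                    "seq_r2": _to_str(seq[TAG_LEN:]),
                }
            )
            fam_seqs.append(seq)

    # --- emit reads ----------------------------------------------------------
    fq1_path = outdir / "reads_R1.fastq"
    fq2_path = outdir / "reads_R2.fastq"
    tail1 = _to_str(_random_seq(rng, READ_LEN - BARCODE_LEN - TAG_LEN))
    tail2 = _to_str(_random_seq(rng, READ_LEN - BARCODE_LEN - TAG_LEN))
    qual = "I" * READ_LEN
    read_no = 0
    with open(fq1_path, "w") as f1, open(fq2_path, "w") as f2:
        for i, line in enumerate(line_ids):
            # tags present in this line: its allele at each locus + every family member
            present: List[np.ndarray] = []
            calls = truth_genotypes.calls[i]
            for k in range(cfg.n_loci_allelic):
                present.append(tag_a_seqs[k] if calls[k] == HOM1 else tag_b_seqs[k])
            present.extend(fam_seqs)
            depths = rng.poisson(cfg.depth_mean, size=len(present))
            total = int(depths.sum())
            if total == 0:
                continue
            reads = np.repeat(
                np.stack(present, axis=0), depths, axis=0
            )  # (total, 160) uint8
            if cfg.error_rate > 0:
                err = rng.random(reads.shape) < cfg.error_rate
                n_err = int(err.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                    base_idx = np.searchsorted(BASES, reads[err])
                    reads[err] = BASES[(base_idx + shift) % 4]
            bc = barcodes[i]
            for row in reads:
                read_no += 1
                r1 = bc + _to_str(row[:TAG_LEN]) + tail1
                r2 = bc + _to_str(row[TAG_LEN:]) + tail2
                f1.write(f"@read{read_no}/1\n{r1}\n+\n{qual}\n")
                f2.write(f"@read{read_no}/2\n{r2}\n+\n{qual}\n")

    barcode_path = outdir / "barcodes.tsv"
    pd.DataFrame(
        {
            "line_id": line_ids,
            "barcode": barcodes,
            "remnant_r1": SACI_REMNANT,
            "remnant_r2": MSEI_REMNANT,
        }
    ).to_csv(barcode_path, sep="\t", index=False)

    truth = TruthTables(
        tag_pairs=pd.DataFrame(pair_rows),
        genotypes=truth_genotypes,
        homeolog_families=pd.DataFrame(fam_rows),
    )
    truth.tag_pairs.to_csv(outdir / "truth_tag_pairs.tsv", sep="\t", index=False)
    truth.homeolog_families.to_csv(
        outdir / "truth_homeolog_families.tsv", sep="\t", index=False
    )
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=2)
    return {
        "fastq_r1": fq1_path,
        "fastq_r2": fq2_path,
        "barcode_table": barcode_path,
        "barcodes": specs,
        "line_ids": line_ids,
        "groups": groups,
        "truth": truth,
        "n_reads": read_no,
    }


# ---------------------------------------------------------------------------
# genotype-level simulation


def _copula_haplotypes(
    rng: np.random.Generator,
    n_lines: int,
    freqs: np.ndarray,
    adj_corr: np.ndarray,
) -> np.ndarray:
    """Haploid 0/1 matrix with AR-style latent correlation between markers."""
    m = len(freqs)
    z = np.empty((n_lines, m))
    z[:, 0] = rng.standard_normal(n_lines)
    for k in range(1, m):
        r = adj_corr[k - 1]
        z[:, k] = r * z[:, k - 1] + np.sqrt(1 - r * r) * rng.standard_normal(n_lines)
    from scipy.stats import norm

    thresholds = norm.ppf(freqs)
    return (z < thresholds[None, :]).astype(np.float32)  # P(1) = freq


def simulate_ld_genotypes(
    cfg: SimConfig,
    n_chromosomes: int = 4,
    markers_per_chrom: int = 120,
    spacing_bp: int = 50_000,
    planted_blocks: Optional[Sequence[dict]] = None,
    independent: bool = False,
    phenotype: Optional[dict] = None,
) -> dict:
    """Generate a haploid genotype panel along chromosomes with known truth.

    * LD between adjacent markers comes from a Gaussian copula whose latent
      correlation is sqrt(E(r^2)) of the drift expectation at ``cfg.ld_rho``
      times the marker spacing (``independent=True`` forces zero).
    * ``planted_blocks``: list of dicts(chromosome=idx, start_marker=idx,
      n_markers=k, group=None|"P1"|"P2") — the block's markers are copies of
      its first column (perfect LD).  group=None plants in all lines;
      "P1"/"P2" plants in that group only, the other group keeps independent
      markers there.
    * ``phenotype``: dict(sigma2_g, sigma2_ge, sigma2_e, n_env, n_rep,
      block_effect, effect_block=idx) — emits per-line phenotypes with a
      planted additive effect carried by the first planted block's major
      haplotype.

    Returns dict with 'panel' (HaploidPanel), 'map' (map-table DataFrame),
    'groups', 'truth' (TruthTables) and optionally 'phenotypes'.
    """
    rng = np.random.default_rng(cfg.seed)
    n_lines = cfg.n_lines
    line_ids = [f"L{i:03d}" for i in range(n_lines)]
    n_p1 = int(round(cfg.split_fraction * n_lines))
    groups = {line: ("P1" if i < n_p1 else "P2") for i, line in enumerate(line_ids)}
    is_p1 = np.array([groups[l] == "P1" for l in line_ids])

    marker_ids, chroms, bps = [], [], []
    columns: List[np.ndarray] = []
    block_rows = []
    planted = list(planted_blocks or [])

    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        m = markers_per_chrom
        bp = (np.arange(m) + 1) * spacing_bp
        p1_f, p2_f = _group_freqs(rng, m, cfg.fst, smooth=not independent)
        if independent:
            adj = np.zeros(m - 1)
        else:
            e_r2 = hill_weir_expected_r2(np.diff(bp).astype(float), cfg.ld_rho, n_lines)
            # inverse tetrachoric reduction: with latent corr sin(pi/2 * r)
            # the thresholded binary correlation is ~r (exact at freq 0.5)
            adj = np.sin(np.pi / 2.0 * np.sqrt(np.clip(e_r2, 0.0, 0.96)))
        hap_p1 = _copula_haplotypes(rng, int(is_p1.sum()), p1_f, adj)
        hap_p2 = _copula_haplotypes(rng, int((~is_p1).sum()), p2_f, adj)
        X = np.empty((n_lines, m), dtype=np.float32)
        X[is_p1] = hap_p1
        X[~is_p1] = hap_p2

        for spec in [b for b in planted if b.get("chromosome", 0) == c]:
            i0 = spec["start_marker"]
            k = spec["n_markers"]
            group = spec.get("group")
            # perfect LD: every member column copies the first, with a
            # mid-range frequency so the block survives MAF filtering
            seed_col = (rng.random(n_lines) < rng.uniform(0.3, 0.7)).astype(np.float32)
            rows = (
                slice(None) if group is None
                else is_p1 if group == "P1"
                else ~is_p1
            )
            for j in range(i0, i0 + k):
                X[rows, j] = seed_col[rows] if group is not None else seed_col
            block_rows.append(
                {
                    "chromosome": chrom,
                    "start_bp": int(bp[i0]),
                    "end_bp": int(bp[i0 + k - 1]),
                    "first_marker": f"{chrom}_m{i0:04d}",
                    "last_marker": f"{chrom}_m{i0 + k - 1:04d}",
                    "n_markers": k,
                    "group": group or "all",
                }
            )

        columns.append(X)
        marker_ids.extend(f"{chrom}_m{j:04d}" for j in range(m))
        chroms.extend([chrom] * m)
        bps.extend(int(b) for b in bp)

    alleles_matrix = np.concatenate(columns, axis=1)
    panel = HaploidPanel(line_ids, marker_ids, alleles_matrix)
    map_table = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "chromosome": chroms,
            "cm": np.asarray(bps, dtype=float) * 2.5e-6,  # ~2.5 cM / Mb
            "bp": bps,
            "source": "anchor",
        }
    )
    truth = TruthTables(blocks=pd.DataFrame(block_rows))
    out = {"panel": panel, "map": map_table, "groups": groups, "truth": truth}

    if phenotype is not None:
        ph = dict(phenotype)
        n_env, n_rep = ph.get("n_env", 3), ph.get("n_rep", 3)
        sg, sge, se = ph.get("sigma2_g", 4.0), ph.get("sigma2_ge", 1.0), ph.get("sigma2_e", 1.0)
        g = rng.normal(0.0, np.sqrt(sg), size=n_lines)
        effect = ph.get("block_effect", 0.0)
        carrier = np.zeros(n_lines)
        if effect and block_rows:
            spec = block_rows[ph.get("effect_block", 0)]
            col = panel.alleles[:, marker_ids.index(spec["first_marker"])]
            major = 1.0 if np.nanmean(col) >= 0.5 else 0.0
            carrier = (col == major).astype(float)
            truth.phenotype_effects = {"block_effect": effect,
                                       "block": spec["first_marker"]}
        records = []
        for e in range(n_env):
            ge = rng.normal(0.0, np.sqrt(sge), size=n_lines)
            for r in range(n_rep):
                eps = rng.normal(0.0, np.sqrt(se), size=n_lines)
                y = ph.get("mu", 40.0) + g + effect * carrier + ge + eps
                records.append(
                    pd.DataFrame({"line_id": line_ids, "env": e, "rep": r, "value": y})
                )
        obs = pd.concat(records, ignore_index=True)
        out["phenotypes"] = obs
        out["phenotype_line_means"] = obs.groupby("line_id")["value"].mean().to_dict()
    return out


def simulate_decay_r2_pairs(
    rho: float,
    n_lines: int,
    n_pairs: int,
    max_bp: float,
    seed: int,
    noise: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """(distance, observed r^2) pairs for decay-fit validation.

    Distances are uniform on (0, max_bp].  For each pair the target r^2 is
    the drift expectation; with ``noise`` the observation is the sample r^2
    of two-locus haplotype counts drawn multinomially (both frequencies 0.5,
    D chosen to match the target) over ``n_lines`` haploid lines — a
    binomial-sampling noise model.  Without noise the curve is returned
    exactly.
    """
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.0, max_bp, size=n_pairs) + 1.0
    target = hill_weir_expected_r2(d, rho, n_lines)
    if not noise:
        return d, target
    # p = q = 0.5: r2 = 16 D^2 -> D = sqrt(target)/4
    D = np.sqrt(target) / 4.0
    probs = np.stack(
        [0.25 + D, 0.25 - D, 0.25 - D, 0.25 + D], axis=1
    )  # h11, h10, h01, h00
    obs = np.empty(n_pairs)
    for i in range(n_pairs):
        c = rng.multinomial(n_lines, probs[i])
        n11, n10, n01, n00 = c
        n = c.sum()
        pA, pB = (n11 + n10) / n, (n11 + n01) / n
        denom = pA * (1 - pA) * pB * (1 - pB)
        if denom <= 0:
            obs[i] = np.nan
            continue
        Dhat = n11 / n - pA * pB
        obs[i] = Dhat * Dhat / denom
    return d, obs
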