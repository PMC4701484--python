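"""Discriminating allelic tag pairs from homeologs via relative heterozygosity.

In a panel of fully inbred lines, the two alleles of a genuine locus are
almost never observed together within one line: a line carries tag A or
tag B, rarely both.  Homeologous or paralogous tags, by contrast, sit at
*different* loci of a polyploid genome and are co-present in most lines —
they masquerade as constitutive "heterozygotes".

For every tag pair in a network we therefore count, across lines,

* ``n_het``   — lines where both tags are present,
* ``n_hom_a`` — lines with only tag A,
* ``n_hom_b`` — lines with only tag B,

and form the relative heterozygosity ``H_R = n_het / min(n_hom_a, n_hom_b)``.
True allelic pairs in an inbred panel have H_R near zero; homeolog pairs have
H_R far above one.  Pairs with H_R strictly below the threshold (default
0.20) are accepted as allelic, greedily and disjointly within each network,
and genotyped per line from tag presence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io_demux import GenotypeMatrix, HET, HOM1, HOM2, MISSING
from .tag_network import Network, Tag

__all__ = [
    "PresenceMatrix",
    "CooccurrenceRecord",
    "AllelicPair",
    "presence_matrix",
    "cooccurrence",
    "relative_heterozygosity",
    "call_allelic_pairs",
    "extract_snps",
    "genotype_panel",
    "call_panel",
]


@dataclass
class PresenceMatrix:
    """Presence/absence of each network tag in each line (count >= min_depth)."""

    tags: List[Tag]
    line_ids: List[str]
    presence: np.ndarray  # bool, lines x tags
    min_depth: int = 1


@dataclass
class CooccurrenceRecord:
    tag_a: int  # index into the network's tag list
    tag_b: int
    n_het: int
    n_hom_a: int
    n_hom_b: int

    @property
    def h_r(self) -> float:
        return relative_heterozygosity(self)


@dataclass
class AllelicPair:
    """An accepted allelic tag pair and the SNPs it carries.

    SNP offsets are 0-based within the concatenated 160-nt tag (r1 then r2).
    """

    pair_id: str
    tag_a: Tag
    tag_b: Tag
    h_r: float
    snps: List[Tuple[int, str, str, str]] = field(default_factory=list)
    # each snp: (offset, end in {"r1","r2"}, allele_a, allele_b)
    representative_snp: int = 0


def presence_matrix(
    network: Network, line_ids: Sequence[str], min_depth: int = 1
) -> PresenceMatrix:
    """Score each tag as present in a line iff its read count >= min_depth."""
    pres = np.zeros((len(line_ids), network.n_tags), dtype=bool)
    index = {line: i for i, line in enumerate(line_ids)}
    for j, tag in enumerate(network.tags):
        for line, count in tag.counts.items():
            if count >= min_depth and line in index:
                pres[index[line], j] = True
    return PresenceMatrix(list(network.tags), list(line_ids), pres, min_depth)


def cooccurrence(pm: PresenceMatrix) -> List[CooccurrenceRecord]:
    """Pairwise co-occurrence counts for all unordered tag pairs of a network.

    Lines carrying neither tag are ignored; lines carrying a third network
    tag as well are still counted by their pairwise pattern.
    """
    P = pm.presence.astype(np.int64)
    both = P.T @ P  # lines with both tags
    only = P.T @ (1 - P)  # only[i, j] = lines with tag i but not tag j
    records = []
    n = P.shape[1]
    for a in range(n):
        for b in range(a + 1, n):
            records.append(
                CooccurrenceRecord(
                    tag_a=a,
                    tag_b=b,
                    n_het=int(both[a, b]),
                    n_hom_a=int(only[a, b]),
                    n_hom_b=int(only[b, a]),
                )
            )
    return records


def relative_heterozygosity(rec: CooccurrenceRecord) -> float:
    """H_R = heterozygote count over the smaller homozygote count.

    A pair with no homozygotes on either side is uninformative and gets +inf
    (it can never be called allelic), whether or not heterozygotes exist.
    """
    smaller = min(rec.n_hom_a, rec.n_hom_b)
    return math.inf if smaller == 0 else rec.n_het / smaller


def call_allelic_pairs(
    network: Network,
    pm: PresenceMatrix,
    h_r_threshold: float = 0.20,
) -> List[AllelicPair]:
    """Accept tag pairs with H_R strictly below the threshold, greedily.

    Candidates are ordered by ascending H_R (ties: larger homozygote support
    first, then lexicographic tag sequences) and accepted only while both
    tags are unconsumed, so one network can yield several disjoint allelic
    pairs — the homeologous-loci case.
    """
    records = cooccurrence(pm)
    candidates = [r for r in records if relative_heterozygosity(r) < h_r_threshold]
    candidates.sort(
        key=lambda r: (
            relative_heterozygosity(r),
            -(r.n_hom_a + r.n_hom_b),
            pm.tags[r.tag_a].key,
            pm.tags[r.tag_b].key,
        )
    )
    consumed: set = set()
    pairs = []
    for rec in candidates:
        if rec.tag_a in consumed or rec.tag_b in consumed:
            continue
        consumed.update((rec.tag_a, rec.tag_b))
        tag_a, tag_b = pm.tags[rec.tag_a], pm.tags[rec.tag_b]
        pair = extract_snps(tag_a, tag_b, h_r=relative_heterozygosity(rec))
        pairs.append(pair)
    return pairs


def extract_snps(tag_a: Tag, tag_b: Tag, h_r: float = math.nan,
                 pair_id: Optional[str] = None) -> AllelicPair:
    """Every mismatching position between the two tags becomes a biallelic SNP.

    The representative SNP is the one with the lowest offset on the r1 end
    (falling back to r2) — an arbitrary but fixed choice standing in for
    "one SNP per tag pair represents the locus".
    """
    snps = []
    for offset, (a, b) in enumerate(zip(tag_a.seq_r1, tag_b.seq_r1)):
        if a != b:
            snps.append((offset, "r1", a, b))
    L1 = len(tag_a.seq_r1)
    for offset, (a, b) in enumerate(zip(tag_a.seq_r2, tag_b.seq_r2)):
        if a != b:
            snps.append((L1 + offset, "r2", a, b))
    if not snps:
        raise ValueError("identical tags cannot form an allelic pair")
    if pair_id is None:
        pair_id = f"pair_{tag_a.seq_r1[:8]}_{snps[0][0]}"
    return AllelicPair(
        pair_id=pair_id, tag_a=tag_a, tag_b=tag_b, h_r=h_r, snps=snps,
        representative_snp=0,
    )


def genotype_panel(
    pairs: Sequence[AllelicPair],
    line_ids: Sequence[str],
    min_depth: int = 1,
) -> GenotypeMatrix:
    """Genotype every line at every accepted pair from tag presence.

    only tag_a -> hom_allele1; only tag_b -> hom_allele2; both -> het;
    neither -> missing.
    """
    calls = np.full((len(line_ids), len(pairs)), MISSING, dtype=np.int8)
    alleles = []
    marker_ids = []
    for j, pair in enumerate(pairs):
        offset, _end, a1, a2 = pair.snps[pair.representative_snp]
        alleles.append((a1, a2))
        marker_ids.append(pair.pair_id)
        for i, line in enumerate(line_ids):
            has_a = pair.tag_a.counts.get(line, 0) >= min_depth
            has_b = pair.tag_b.counts.get(line, 0) >= min_depth
            if has_a and has_b:
                calls[i, j] = HET
            elif has_a:
                calls[i, j] = HOM1
            elif has_b:
                calls[i, j] = HOM2
    return GenotypeMatrix(list(line_ids), marker_ids, calls, alleles)


def call_panel(
    networks: Sequence[Network],
    line_ids: Sequence[str],
    h_r_threshold: float = 0.20,
    min_depth: int = 1,
) -> Tuple[GenotypeMatrix, List[AllelicPair]]:
    """Convenience wrapper: call allelic pairs in every network and genotype.

    Pair ids are made unique across networks (net<k>_pair<m>).
    """
    all_pairs: List[AllelicPair] = []
    for k, network in enumerate(networks):
        pm = presence_matrix(network, line_ids, min_depth=min_depth)
        for m, pair in enumerate(call_allelic_pairs(network, pm, h_r_threshold)):
            pair.pair_id = f"net{k}_pair{m}"
            all_pairs.append(pair)
    return genotype_panel(all_pairs, line_ids, min_depth=min_depth), all_pairs
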