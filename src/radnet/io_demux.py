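"""Reading, demultiplexing and trimming of paired-end ddRAD reads, plus
genotype-matrix / map-table serialisation.

ddRAD reads in this design are 90 bp paired-end: a 5 bp inline barcode, the
restriction-site remnant left by the enzyme (SacI on read 1, MseI on read 2),
and genomic sequence.  Demultiplexing requires the barcode *and* the remnant
to match exactly at both ends; trimming removes the barcode and the 5
error-enriched bases at the 3' end, leaving the 80 nt that become the tag.

Genotype matrices use a closed four-state call code per (line, marker):
homozygous allele 1, homozygous allele 2, heterozygous, or missing.  They can
be written either as a HapMap-style TSV or as VCF 4.2 (GT codes 0/0, 1/1,
0/1, ./.).
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "BarcodeSpec",
    "ReadPair",
    "GenotypeMatrix",
    "DemuxResult",
    "HOM1",
    "HOM2",
    "HET",
    "MISSING",
    "read_barcode_table",
    "demultiplex",
    "demultiplex_stream",
    "trim_read_pair",
    "trim_stream",
    "write_genotypes",
    "read_genotypes",
    "write_map_table",
    "read_map_table",
]

# genotype call codes (int8): closed set
HOM1 = 0  # homozygous allele 1
HOM2 = 1  # homozygous allele 2
HET = 2
MISSING = -1

_GT_TO_VCF = {HOM1: "0/0", HOM2: "1/1", HET: "0/1", MISSING: "./."}
_VCF_TO_GT = {v: k for k, v in _GT_TO_VCF.items()}
_GT_TO_HAPMAP = {HOM1: "AA", HOM2: "BB", HET: "AB", MISSING: "NN"}
_HAPMAP_TO_GT = {v: k for k, v in _GT_TO_HAPMAP.items()}

MAP_COLUMNS = ["marker_id", "chromosome", "cm", "bp", "source"]


class FastqFormatError(ValueError):
    """Raised for unpaired or truncated FASTQ input."""


@dataclass(frozen=True)
class BarcodeSpec:
    """Inline barcode plus restriction-site remnants for one inbred line."""

    line_id: str
    barcode: str
    site_remnant_r1: str
    site_remnant_r2: str

    def __post_init__(self) -> None:
        if len(self.barcode) != 5:
            raise ValueError(
                f"barcode for {self.line_id!r} must be 5 nt, got {self.barcode!r}"
            )
        if not self.site_remnant_r1 or not self.site_remnant_r2:
            raise ValueError(f"empty restriction-site remnant for {self.line_id!r}")


@dataclass
class ReadPair:
    r1: str
    r2: str
    q1: Optional[str] = None
    q2: Optional[str] = None


@dataclass
class DemuxResult:
    """Outcome of demultiplexing one FASTQ pair."""

    assigned: list  # list of (line_id, ReadPair)
    n_rejected: int
    n_total: int

    @property
    def n_assigned(self) -> int:
        return len(self.assigned)


@dataclass
class GenotypeMatrix:
    """Lines x markers genotype calls with per-marker allele labels.

    ``calls`` is int8 with the closed code set {HOM1, HOM2, HET, MISSING}.
    ``alleles[j]`` is the (allele1, allele2) pair for marker j — nucleotides
    or tag labels.
    """

    line_ids: list
    marker_ids: list
    calls: np.ndarray
    alleles: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if not self.alleles:
            self.alleles = [("A", "B")] * len(self.marker_ids)
        if len(self.alleles) != len(self.marker_ids):
            raise ValueError("one (allele1, allele2) pair required per marker")
        bad = set(np.unique(self.calls)) - {HOM1, HOM2, HET, MISSING}
        if bad:
            raise ValueError(f"unknown call codes {sorted(bad)}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
            and [tuple(a) for a in self.alleles] == [tuple(a) for a in other.alleles]
        )


# ---------------------------------------------------------------------------
# barcode tables and demultiplexing


def read_barcode_table(path) -> list:
    """Read a barcode TSV (line_id, barcode, remnant_r1, remnant_r2)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    return [
        BarcodeSpec(
            line_id=row["line_id"],
            barcode=row["barcode"],
            site_remnant_r1=row["remnant_r1"],
            site_remnant_r2=row["remnant_r2"],
        )
        for _, row in df.iterrows()
    ]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _check_barcodes(barcodes: Sequence[BarcodeSpec]) -> dict:
    seen = {}
    for spec in barcodes:
        if spec.barcode in seen:
            raise ValueError(
                f"duplicate barcode {spec.barcode!r} for lines "
                f"{seen[spec.barcode].line_id!r} and {spec.line_id!r}"
            )
        seen[spec.barcode] = spec
    return seen


def demultiplex_stream(
    fastq_r1_path,
    fastq_r2_path,
    barcodes: Sequence[BarcodeSpec],
    counter: Optional[dict] = None,
) -> Iterator[tuple]:
    """Yield (line_id, ReadPair) for every pair whose barcode + remnant match
    exactly at both ends.

    Matching is exact (0 mismatches) on barcode and restriction-site remnant,
    on read 1 and read 2 alike.  If ``counter`` is supplied it is updated in
    place with 'assigned' / 'rejected' / 'total' once the stream is consumed.
    """
    by_barcode = _check_barcodes(barcodes)
    # pre-built exact prefixes: barcode + remnant per end
    prefix1 = {bc: spec.barcode + spec.site_remnant_r1 for bc, spec in by_barcode.items()}
    prefix2 = {bc: spec.barcode + spec.site_remnant_r2 for bc, spec in by_barcode.items()}

    stats = counter if counter is not None else {}
    stats.update({"assigned": 0, "rejected": 0, "total": 0})

    with _open_text(fastq_r1_path) as fh1, _open_text(fastq_r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for idx, (rec1, rec2) in enumerate(itertools.zip_longest(it1, it2)):
            if rec1 is None or rec2 is None:
                raise FastqFormatError(
                    f"FASTQ files out of sync: record {idx} missing in one mate file"
                )
            (_t1, seq1, qual1), (_t2, seq2, qual2) = rec1, rec2
            stats["total"] += 1
            bc = seq1[:5]
            spec = by_barcode.get(bc)
            if (
                spec is not None
                and seq1.startswith(prefix1[bc])
                and seq2.startswith(prefix2[bc])
            ):
                stats["assigned"] += 1
                yield spec.line_id, ReadPair(seq1, seq2, qual1, qual2)
            else:
                stats["rejected"] += 1


def demultiplex(fastq_r1_path, fastq_r2_path, barcodes) -> DemuxResult:
    """Materialised :func:`demultiplex_stream`; returns assignments + counts."""
    counter: dict = {}
    assigned = list(
        demultiplex_stream(fastq_r1_path, fastq_r2_path, barcodes, counter=counter)
    )
    return DemuxResult(
        assigned=assigned, n_rejected=counter["rejected"], n_total=counter["total"]
    )


def trim_read_pair(
    pair: ReadPair, barcode_len: int = 5, tail_trim: int = 5
) -> Optional[ReadPair]:
    """Strip the barcode from the 5' end and ``tail_trim`` bases from the 3'
    end of both mates (90 nt in -> 80 nt out).  Returns None for reads too
    short to survive trimming (the caller counts skips).
    """
    min_len = barcode_len + tail_trim + 1
    if len(pair.r1) < min_len or len(pair.r2) < min_len:
        return None
    sl = slice(barcode_len, -tail_trim if tail_trim else None)
    return ReadPair(
        pair.r1[sl],
        pair.r2[sl],
        pair.q1[sl] if pair.q1 else None,
        pair.q2[sl] if pair.q2 else None,
    )


def trim_stream(
    stream: Iterable, barcode_len: int = 5, tail_trim: int = 5,
    counter: Optional[dict] = None,
) -> Iterator[tuple]:
    """Trim a (line_id, ReadPair) stream, dropping too-short pairs."""
    stats = counter if counter is not None else {}
    stats.setdefault("skipped_short", 0)
    for line_id, pair in stream:
        trimmed = trim_read_pair(pair, barcode_len, tail_trim)
        if trimmed is None:
            stats["skipped_short"] += 1
            continue
        yield line_id, trimmed


# ---------------------------------------------------------------------------
# genotype matrices


def write_genotypes(
    matrix: GenotypeMatrix,
    path,
    fmt: str = "hapmap_tsv",
    map_table: Optional[pd.DataFrame] = None,
) -> None:
    if fmt == "hapmap_tsv":
        _write_hapmap(matrix, path)
    elif fmt == "vcf":
        _write_vcf(matrix, path, map_table)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def read_genotypes(path, fmt: str = "hapmap_tsv") -> GenotypeMatrix:
    if fmt == "hapmap_tsv":
        return _read_hapmap(path)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _write_hapmap(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\talleles\t" + "\t".join(matrix.line_ids) + "\n")
        for j, marker in enumerate(matrix.marker_ids):
            a1, a2 = matrix.alleles[j]
            calls = "\t".join(_GT_TO_HAPMAP[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{marker}\t{a1}/{a2}\t{calls}\n")


def _read_hapmap(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["marker_id", "alleles"]:
            raise ValueError(f"{path}: line 1: not a HapMap-style genotype TSV")
        line_ids = header[2:]
        marker_ids, alleles, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2 + len(line_ids):
                raise ValueError(
                    f"{path}: line {lineno}: expected {2 + len(line_ids)} fields, "
                    f"got {len(fields)}"
                )
            marker_ids.append(fields[0])
            a1, _, a2 = fields[1].partition("/")
            alleles.append((a1, a2))
            try:
                rows.append([_HAPMAP_TO_GT[c] for c in fields[2:]])
            except KeyError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad genotype code {exc}"
                ) from None
    calls = np.array(rows, dtype=np.int8).T if rows else np.empty((len(line_ids), 0), np.int8)
    return GenotypeMatrix(line_ids, marker_ids, calls, alleles)


def _positions_for_vcf(matrix: GenotypeMatrix, map_table: Optional[pd.DataFrame]):
    """(chrom, pos) per marker: map-table bp when known, else marker ordinal."""
    chroms, positions = [], []
    if map_table is not None:
        mt = map_table.set_index("marker_id")
    else:
        mt = None
    for j, marker in enumerate(matrix.marker_ids):
        if mt is not None and marker in mt.index and pd.notna(mt.loc[marker, "bp"]):
            chroms.append(str(mt.loc[marker, "chromosome"]))
            positions.append(int(mt.loc[marker, "bp"]))
        else:
            chroms.append("un")
            positions.append(j + 1)
    return chroms, positions


def _write_vcf(matrix: GenotypeMatrix, path, map_table: Optional[pd.DataFrame]) -> None:
    chroms, positions = _positions_for_vcf(matrix, map_table)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(chroms):  # insertion order, unique
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.line_ids)
            + "\n"
        )
        for j, marker in enumerate(matrix.marker_ids):
            a1, a2 = matrix.alleles[j]
            ref = a1 if len(a1) == 1 and a1 in "ACGT" else "A"
            alt = a2 if len(a2) == 1 and a2 in "ACGT" else "T"
            gts = "\t".join(_GT_TO_VCF[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{chroms[j]}\t{positions[j]}\t{marker}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids, alleles, columns = [], [], []
    for variant in vcf:
        marker_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        alleles.append((variant.REF, variant.ALT[0] if variant.ALT else "."))
        col = np.empty(len(line_ids), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col[i] = MISSING
            elif a == b == 0:
                col[i] = HOM1
            elif a == b == 1:
                col[i] = HOM2
            else:
                col[i] = HET
        columns.append(col)
    vcf.close()
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(line_ids), 0), np.int8)
    )
    return GenotypeMatrix(line_ids, marker_ids, calls, alleles)


# ---------------------------------------------------------------------------
# map tables


def write_map_table(table: pd.DataFrame, path) -> None:
    table.loc[:, MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_map_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str,
                                            "source": str})
    missing = set(["marker_id", "chromosome", "cm"]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: map table lacks columns {sorted(missing)}")
    if "bp" not in df.columns:
        df["bp"] = np.nan
    if "source" not in df.columns:
        df["source"] = "anchor"
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"{path}: duplicate marker_id {dup!r}")
    return df.loc[:, MAP_COLUMNS]
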