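"""Cohort count tensor: pileup ingestion, count tables and VCF emission.

Internal coordinates are 0-based half-open everywhere; every file interface
(count-table ``pos``, VCF ``POS``, hotspot catalogues) is 1-based.  The
allele alphabet is fixed to A, C, G, T and the single-base deletion DEL;
insertions are not tallied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

ALLELES: tuple[str, ...] = ("A", "C", "G", "T", "DEL")
ALLELE_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALLELES)}
FWD, REV = 0, 1
_STRAND_LABELS = ("fwd", "rev")

_TABLE_COLUMNS = ["sample", "chrom", "pos", "strand", "A", "C", "G", "T", "DEL", "coverage"]

__all__ = [
    "ALLELES",
    "ALLELE_INDEX",
    "FWD",
    "REV",
    "RegionSet",
    "CountTensor",
    "pileup_counts",
    "read_count_table",
    "write_count_table",
    "write_vcf",
]


@dataclass
class RegionSet:
    """Sorted, merged set of 0-based half-open target intervals."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("region set must contain at least one interval")
        norm: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(self.intervals):
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            if norm and norm[-1][0] == chrom and start <= norm[-1][2]:
                prev = norm.pop()
                norm.append((chrom, prev[1], max(prev[2], end)))
            else:
                norm.append((chrom, start, end))
        self.intervals = norm

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        intervals = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: BED line has fewer than 3 columns")
                try:
                    intervals.append((parts[0], int(parts[1]), int(parts[2])))
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: malformed BED coordinates") from exc
        return cls(intervals)

    def positions(self) -> list[tuple[str, int]]:
        """All (chrom, pos) covered, ordered by (chrom, pos)."""
        return [(c, p) for c, s, e in self.intervals for p in range(s, e)]


@dataclass
class CountTensor:
    """Per (sample, site, allele, strand) nucleotide counts for a cohort.

    ``counts`` has shape (n_samples, n_sites, 5, 2) and ``coverage``
    (n_samples, n_sites, 2); strand 0 is forward, 1 reverse.  On data where
    no bases were quality-filtered, coverage equals the allele-count sum
    for every strand; filtered bases are removed from both, so the sum
    never exceeds coverage.  ``ref_allele`` (one base per site) is optional
    until a reference is attached; variant calling requires it.
    """

    sample_ids: list[str]
    sites: list[tuple[str, int]]
    counts: np.ndarray
    coverage: np.ndarray
    ref_allele: list[str] | None = None
    _site_index: dict[tuple[str, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        s, j = len(self.sample_ids), len(self.sites)
        if self.counts.shape != (s, j, len(ALLELES), 2):
            raise ValueError(f"counts shape {self.counts.shape} != {(s, j, len(ALLELES), 2)}")
        if self.coverage.shape != (s, j, 2):
            raise ValueError(f"coverage shape {self.coverage.shape} != {(s, j, 2)}")
        if len(set(self.sample_ids)) != s:
            raise ValueError("sample_ids must be unique")
        if any(self.sites[i] >= self.sites[i + 1] for i in range(j - 1)):
            raise ValueError("sites must be strictly ordered by (chrom, pos)")
        if np.any(self.counts < 0) or np.any(self.coverage < 0):
            raise ValueError("counts and coverage must be non-negative")
        if np.any(self.counts.sum(axis=2) > self.coverage):
            raise ValueError("allele counts exceed coverage for some (sample, site, strand)")
        if self.ref_allele is not None and len(self.ref_allele) != j:
            raise ValueError("ref_allele must have one base per site")
        self._site_index = {site: idx for idx, site in enumerate(self.sites)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self, chrom: str, pos: int) -> int:
        return self._site_index[(chrom, pos)]

    def attach_reference(self, fasta_path) -> None:
        """Fill ``ref_allele`` from a FASTA (indexed on demand)."""
        with pysam.FastaFile(str(fasta_path)) as fa:
            self.ref_allele = [fa.fetch(c, p, p + 1).upper() for c, p in self.sites]


def pileup_counts(
    alignments: dict[str, str],
    regions: RegionSet,
    min_base_quality: int = 25,
    min_mapping_quality: int = 30,
    reference: str | None = None,
) -> CountTensor:
    """Tally strand-specific allele counts from indexed BAM files.

    ``alignments`` maps sample id to BAM path.  A read base contributes to
    exactly one allele slot on the strand given by its read orientation;
    bases with quality below ``min_base_quality`` (or base N), and reads
    below ``min_mapping_quality``, contribute to neither counts nor
    coverage.  A deletion (CIGAR D) spanning a site contributes to DEL;
    reference skips (CIGAR N) contribute nothing.
    """
    sites = regions.positions()
    site_index = {site: j for j, site in enumerate(sites)}
    sample_ids = list(alignments)
    counts = np.zeros((len(sample_ids), len(sites), len(ALLELES), 2), dtype=np.int64)
    coverage = np.zeros((len(sample_ids), len(sites), 2), dtype=np.int64)

    for i, sid in enumerate(sample_ids):
        path = alignments[sid]
        with pysam.AlignmentFile(str(path)) as bam:
            if not bam.has_index():
                raise FileNotFoundError(f"alignment file is not indexed: {path}")
            lengths = dict(zip(bam.references, bam.lengths))
            for chrom, start, end in regions.intervals:
                if chrom not in lengths:
                    raise ValueError(f"region {chrom}:{start}-{end} not in reference of {path}")
                if end > lengths[chrom]:
                    raise ValueError(
                        f"region {chrom}:{start}-{end} beyond contig end ({lengths[chrom]}) in {path}"
                    )
                for read in bam.fetch(chrom, start, end):
                    if (
                        read.is_unmapped
                        or read.is_secondary
                        or read.is_supplementary
                        or read.mapping_quality < min_mapping_quality
                    ):
                        continue
                    _tally_read(read, chrom, site_index, counts[i], coverage[i], min_base_quality)

    tensor = CountTensor(sample_ids, sites, counts, coverage)
    if reference is not None:
        tensor.attach_reference(reference)
    return tensor


def _tally_read(read, chrom, site_index, counts_i, coverage_i, min_bq) -> None:
    strand = REV if read.is_reverse else FWD
    seq = read.query_sequence
    quals = read.query_qualities
    qpos, rpos = 0, read.reference_start
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X consume both query and reference
            for t in range(length):
                j = site_index.get((chrom, rpos + t))
                if j is None:
                    continue
                base = seq[qpos + t]
                if base == "N" or (quals is not None and quals[qpos + t] < min_bq):
                    continue
                k = ALLELE_INDEX.get(base)
                if k is None:
                    continue
                counts_i[j, k, strand] += 1
                coverage_i[j, strand] += 1
            qpos += length
            rpos += length
        elif op in (1, 4):  # I, S consume query only
            qpos += length
        elif op == 2:  # D: deletion spans reference positions
            for t in range(length):
                j = site_index.get((chrom, rpos + t))
                if j is not None:
                    counts_i[j, ALLELE_INDEX["DEL"], strand] += 1
                    coverage_i[j, strand] += 1
            rpos += length
        elif op == 3:  # N: intron/skip, contributes nothing
            rpos += length
        # H (5), P (6): consume neither


def read_count_table(path) -> CountTensor:
    """Read a per-(sample, site, strand) TSV of allele counts.

    Header columns: sample, chrom, pos, strand, A, C, G, T, DEL, coverage;
    ``pos`` is 1-based in the file and stored 0-based.  Missing strand or
    (sample, site) rows are zero-filled; duplicates and rows with coverage
    below the allele-count sum are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    records = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            pos = int(row["pos"])
            vals = {a: int(row[a]) for a in ALLELES}
            cov = int(row["coverage"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}") from exc
        strand = str(row["strand"])
        if strand not in _STRAND_LABELS:
            raise ValueError(f"{path}: unknown strand {strand!r} at line {lineno}")
        if pos < 1 or cov < 0 or any(v < 0 for v in vals.values()):
            raise ValueError(f"{path}: negative or out-of-range value at line {lineno}")
        if sum(vals.values()) > cov:
            raise ValueError(f"{path}: coverage below allele-count sum at line {lineno}")
        records.append((str(row["sample"]), str(row["chrom"]), pos - 1, strand, vals, cov))

    seen = set()
    for sid, chrom, pos, strand, _, _ in records:
        key = (sid, chrom, pos, strand)
        if key in seen:
            raise ValueError(f"{path}: duplicate row for sample={sid} {chrom}:{pos + 1} {strand}")
        seen.add(key)

    sample_ids = list(dict.fromkeys(r[0] for r in records))
    sites = sorted({(r[1], r[2]) for r in records})
    counts = np.zeros((len(sample_ids), len(sites), len(ALLELES), 2), dtype=np.int64)
    coverage = np.zeros((len(sample_ids), len(sites), 2), dtype=np.int64)
    sidx = {s: i for i, s in enumerate(sample_ids)}
    jidx = {s: j for j, s in enumerate(sites)}
    for sid, chrom, pos, strand, vals, cov in records:
        i, j, s = sidx[sid], jidx[(chrom, pos)], _STRAND_LABELS.index(strand)
        for a, v in vals.items():
            counts[i, j, ALLELE_INDEX[a], s] = v
        coverage[i, j, s] = cov
    return CountTensor(sample_ids, sites, counts, coverage)


def write_count_table(tensor: CountTensor, path) -> None:
    """Inverse of :func:`read_count_table` (pos written 1-based)."""
    rows = []
    for i, sid in enumerate(tensor.sample_ids):
        for j, (chrom, pos) in enumerate(tensor.sites):
            for s, label in enumerate(_STRAND_LABELS):
                row = {"sample": sid, "chrom": chrom, "pos": pos + 1, "strand": label}
                row.update({a: int(tensor.counts[i, j, k, s]) for k, a in enumerate(ALLELES)})
                row["coverage"] = int(tensor.coverage[i, j, s])
                rows.append(row)
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


_VCF_FORMAT_KEYS = ("BF", "PM0", "VF", "FD", "RD", "FC", "RC")

_VCF_HEADER_META = [
    '##INFO=<ID=PI,Number=1,Type=Float,Description="Prior probability of a variant at this site and allele">',
    '##FORMAT=<ID=BF,Number=1,Type=Float,Description="Bayes factor P(D|M0)/P(D|M1); small favors a variant">',
    '##FORMAT=<ID=PM0,Number=1,Type=Float,Description="Posterior probability of the null model M0">',
    '##FORMAT=<ID=VF,Number=1,Type=Float,Description="Combined-strand variant allele frequency">',
    '##FORMAT=<ID=FD,Number=1,Type=Integer,Description="Variant read depth, forward strand">',
    '##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Variant read depth, reverse strand">',
    '##FORMAT=<ID=FC,Number=1,Type=Integer,Description="Coverage, forward strand">',
    '##FORMAT=<ID=RC,Number=1,Type=Integer,Description="Coverage, reverse strand">',
]


def _fmt_float(v: float) -> str:
    return repr(float(v))


def write_vcf(calls, reference, path, sample_ids: list[str] | None = None) -> None:
    """Write calls as a VCF 4.2 file (text, deterministic byte-for-byte).

    One record per (site, alt allele) with per-sample FORMAT fields
    BF:PM0:VF:FD:RD:FC:RC and the prior in INFO/PI.  SNVs are written at
    POS = internal pos + 1.  A single-base deletion at internal pos p is
    anchored one base upstream: POS = p (1-based anchor), REF is the
    anchor plus the deleted base, ALT the anchor alone.
    """
    with pysam.FastaFile(str(reference)) as fa:
        contigs = list(zip(fa.references, fa.lengths))

        def _refbase(chrom, pos):
            return fa.fetch(chrom, pos, pos + 1).upper()

        groups: dict[tuple[str, int, str], list] = {}
        for call in calls:
            groups.setdefault((call.chrom, call.pos, call.alt), []).append(call)

        if sample_ids is None:
            sample_ids = sorted({c.sample for c in calls})

        lines = ["##fileformat=VCFv4.2", "##source=shearwater"]
        lines += [f"##contig=<ID={name},length={length}>" for name, length in contigs]
        lines += _VCF_HEADER_META
        header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_ids:
            header_cols += ["FORMAT"] + list(sample_ids)
        lines.append("\t".join(header_cols))

        for (chrom, pos, alt), group in sorted(groups.items()):
            first = group[0]
            fa_base = _refbase(chrom, pos)
            if fa_base != first.ref:
                raise ValueError(
                    f"REF mismatch at {chrom}:{pos + 1}: call has {first.ref}, reference has {fa_base}"
                )
            if alt == "DEL":
                if pos == 0:
                    raise ValueError(f"cannot anchor a deletion at the first base of {chrom}")
                anchor = _refbase(chrom, pos - 1)
                pos_out, ref_out, alt_out = pos, anchor + fa_base, anchor
            else:
                pos_out, ref_out, alt_out = pos + 1, fa_base, alt
            info = f"PI={_fmt_float(first.pi)}"
            fields = [chrom, str(pos_out), ".", ref_out, alt_out, ".", "PASS", info]
            if sample_ids:
                fields.append(":".join(_VCF_FORMAT_KEYS))
                by_sample = {c.sample: c for c in group}
                for sid in sample_ids:
                    c = by_sample.get(sid)
                    if c is None:
                        fields.append(".")
                    else:
                        fields.append(
                            ":".join(
                                [
                                    _fmt_float(c.bf),
                                    _fmt_float(c.posterior_m0),
                                    _fmt_float(c.vaf_combined),
                                    str(c.x_fwd),
                                    str(c.x_rev),
                                    str(c.n_fwd),
                                    str(c.n_rev),
                                ]
                            )
                        )
            lines.append("\t".join(fields))

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
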