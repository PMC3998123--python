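"""Shared fixtures: in-memory tensors, on-the-fly BAM/FASTA fixtures."""

from __future__ import annotations

import numpy as np
import pysam
import pytest
from hypothesis import HealthCheck, settings

from shearwater import ALLELES, CountTensor
from shearwater.count_data import ALLELE_INDEX

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

REF_SEQ = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 60 bp


@pytest.fixture
def reference_fasta(tmp_path):
    """Small single-contig FASTA; pysam builds the .fai on first open."""
    path = tmp_path / "ref.fa"
    path.write_text(f">chr1\n{REF_SEQ}\n")
    return str(path)


@pytest.fixture
def make_tensor():
    """Build a CountTensor from sparse (sample, site, allele, strand) counts.

    ``entries`` maps (sample_idx, site_idx, allele, strand) -> count; the
    per-site reference allele absorbs ``base_coverage`` minus the
    non-reference counts so coverage equals the allele-count sum.
    """

    def _build(n_samples, sites, ref_alleles, entries=None, base_coverage=100):
        entries = entries or {}
        J = len(sites)
        counts = np.zeros((n_samples, J, len(ALLELES), 2), dtype=np.int64)
        coverage = np.full((n_samples, J, 2), base_coverage, dtype=np.int64)
        for (i, j, allele, strand), value in entries.items():
            counts[i, j, ALLELE_INDEX[allele], strand] = value
        for j, ref in enumerate(ref_alleles):
            k = ALLELE_INDEX[ref]
            nonref = counts[:, j, :, :].sum(axis=1) - counts[:, j, k, :]
            counts[:, j, k, :] = coverage[:, j, :] - nonref
        return CountTensor(
            sample_ids=[f"S{i}" for i in range(n_samples)],
            sites=list(sites),
            counts=counts,
            coverage=coverage,
            ref_allele=list(ref_alleles),
        )

    return _build


@pytest.fixture
def make_bam(tmp_path, reference_fasta):
    """Write an indexed BAM of short reads on chr1 and return its path.

    Each read spec is (start, seq, cigar, reverse, base_quals, mapq);
    quals default to 40, mapq to 60.
    """
    counter = {"n": 0}

    def _build(reads, index=True):
        counter["n"] += 1
        path = tmp_path / f"fixture{counter['n']}.bam"
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chr1", "LN": len(REF_SEQ)}]}
        segs = []
        for ridx, spec in enumerate(reads):
            start, seq = spec[0], spec[1]
            cigar = spec[2] if len(spec) > 2 else f"{len(seq)}M"
            reverse = spec[3] if len(spec) > 3 else False
            quals = spec[4] if len(spec) > 4 else [40] * len(seq)
            mapq = spec[5] if len(spec) > 5 else 60
            a = pysam.AlignedSegment()
            a.query_name = f"read{ridx}"
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigarstring = cigar
            a.flag = 16 if reverse else 0
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            segs.append(a)
        segs.sort(key=lambda a: a.reference_start)
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for a in segs:
                bam.write(a)
        if index:
            pysam.index(str(path))
        return str(path)

    return _build
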