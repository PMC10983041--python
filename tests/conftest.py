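"""Shared fixtures and random-instance helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from svimpact.breakpoint_matrix import GeneModel
from svimpact.sv_io import SVRecord


def random_sv_records(
    rng: np.random.Generator,
    n: int,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    max_pos: int = 1_000_000,
    n_patients: int = 5,
    origin: str = "germline",
    tra_fraction: float = 0.1,
) -> list[SVRecord]:
    """Random canonical SV records across a few patients."""
    records = []
    for i in range(n):
        patient = f"P{int(rng.integers(n_patients)):03d}"
        if len(chroms) > 1 and rng.random() < tra_fraction:
            ca, cb = rng.choice(len(chroms), size=2, replace=False)
            records.append(SVRecord(
                f"sv{i}", patient, chroms[ca], int(rng.integers(max_pos)),
                chroms[cb], int(rng.integers(max_pos)), "TRA", origin))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            pa = int(rng.integers(max_pos - 1))
            pb = int(rng.integers(pa + 1, max_pos))
            cls = ["DEL", "DUP", "INV"][int(rng.integers(3))]
            records.append(SVRecord(
                f"sv{i}", patient, chrom, pa, chrom, pb, cls, origin))
    return records


def random_genes(
    rng: np.random.Generator,
    n: int,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    max_pos: int = 1_000_000,
) -> list[GeneModel]:
    genes = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(max_pos - 20_000))
        length = int(rng.integers(1_000, 20_000))
        end = min(start + length, max_pos)
        strand = "+" if rng.random() < 0.5 else "-"
        utr3 = None
        if rng.random() < 0.5 and end - start > 600:
            ulen = int(rng.integers(100, (end - start) // 2))
            utr3 = (end - ulen, end) if strand == "+" else (start, start + ulen)
        genes.append(GeneModel(f"g{i}", chrom, start, end, strand, utr3=utr3))
    return genes


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)
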