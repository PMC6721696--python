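"""Shared fixtures and builders for the test suite.

All fixture data is generated programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hapedit.pedigree_io import Marker
from hapedit.phasing import FounderHaplotypeSet


def make_markers(n: int, spacing: int = 100, alleles=("A", "G")) -> list[Marker]:
    return [
        Marker(
            marker_id=f"rs{j + 1}",
            chromosome="6",
            position_bp=(j + 1) * spacing,
            allele_a=alleles[0],
            allele_b=alleles[1],
        )
        for j in range(n)
    ]


def make_founder_set(
    sequences: list[str],
    counts: list[int] | None = None,
    markers: list[Marker] | None = None,
) -> FounderHaplotypeSet:
    """A founder haplotype set holding the given sequences (with repeats)."""
    counts = counts if counts is not None else [1] * len(sequences)
    rows = []
    for s, c in zip(sequences, counts):
        rows.extend([list(s)] * c)
    if rows:
        alleles = np.array(rows, dtype="<U1")
    else:
        alleles = np.empty((0, len(markers) if markers else 0), dtype="<U1")
    n, m = alleles.shape
    markers = markers if markers is not None else make_markers(m)
    index = pd.DataFrame(
        {
            "family_id": [f"f{i // 2 + 1}" for i in range(n)],
            "founder_id": ["fa" if i % 4 < 2 else "mo" for i in range(n)],
            "hap_index": [i % 2 + 1 for i in range(n)],
            "genotyped": True,
            "all_undefined": (alleles == ".").all(axis=1),
        }
    )
    return FounderHaplotypeSet(markers, index, alleles, [[] for _ in range(n)])


def write_pedmap_text(tmp_path, ped_lines: list[str], map_lines: list[str]):
    ped = tmp_path / "test.ped"
    mp = tmp_path / "test.map"
    ped.write_text("\n".join(ped_lines) + "\n")
    mp.write_text("\n".join(map_lines) + "\n")
    return ped, mp


@pytest.fixture
def trio_files(tmp_path):
    """Two markers, one fully typed trio plus an extra unaffected child."""
    map_lines = ["6 rs1 0 1000", "6 rs2 0 2000"]
    ped_lines = [
        "fam1 dad 0 0 1 1 A G C C",
        "fam1 mom 0 0 2 1 A A C T",
        "fam1 kid1 dad mom 1 2 A A C C",
        "fam1 kid2 dad mom 2 1 A G C T",
    ]
    return write_pedmap_text(tmp_path, ped_lines, map_lines)
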