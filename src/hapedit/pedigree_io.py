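"""Reading and writing pedigree genotype data and the pipeline's tabular outputs.

The entry format is the whitespace-delimited PED/MAP text dialect used by
PLINK: one MAP line per biallelic SNP (chromosome, marker id, [genetic
distance,] base-pair position) and one PED row per subject (family id,
subject id, father id, mother id, sex, phenotype, then two allele fields per
marker).  Alleles are nucleotide letters with ``0`` for a missing call;
numeric codes 1--4 are accepted on read and normalized to A, C, G, T.

Positions are 1-based.  Phenotype codes: ``2`` affected, ``1`` unaffected,
``0``/``-9`` unknown.  A genotype with either allele missing is treated as
fully missing.  Parents referenced by a child but absent from the PED file
are materialized as placeholder founders with all-missing genotypes, so that
every nuclear family carries exactly two founder slots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hapedit")

MISSING_ALLELE = "0"
UNDEFINED = "."
VALID_ALLELES = frozenset("ACGT0")
_NUMERIC_CODES = {"1": "A", "2": "C", "3": "G", "4": "T", "0": "0"}

SEX_CODES = {"1": "male", "2": "female"}
PHENOTYPE_CODES = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}


class PedigreeFormatError(ValueError):
    """Malformed PED/MAP content (column counts, alleles, duplicate ids)."""


@dataclass
class Marker:
    """A biallelic SNP on the panel.

    ``allele_a``/``allele_b`` are the two observed nucleotides (``allele_b``
    may be None for a marker that is monomorphic in the data at hand);
    ``maf`` is the minor-allele frequency as a fraction in (0, 0.5].
    """

    marker_id: str
    chromosome: str
    position_bp: int
    allele_a: str | None = None
    allele_b: str | None = None
    maf: float | None = None


@dataclass
class Subject:
    family_id: str
    subject_id: str
    father_id: str | None
    mother_id: str | None
    sex: str = "unknown"
    phenotype: str = "unknown"
    genotyped: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class PedigreeDataset:
    """Markers, family structure and per-subject genotypes.

    ``genotypes`` maps ``(family_id, subject_id)`` to an ``(n_markers, 2)``
    array of single-character alleles (``"0"`` = missing, unordered pair).
    """

    markers: list[Marker]
    families: dict[str, list[Subject]] = field(default_factory=dict)
    genotypes: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_subjects(self) -> int:
        return sum(len(s) for s in self.families.values())

    def subject(self, family_id: str, subject_id: str) -> Subject:
        for s in self.families[family_id]:
            if s.subject_id == subject_id:
                return s
        raise KeyError((family_id, subject_id))

    def founders(self, family_id: str) -> list[Subject]:
        return [s for s in self.families[family_id] if s.is_founder]

    def children(self, family_id: str) -> list[Subject]:
        return [s for s in self.families[family_id] if not s.is_founder]

    @property
    def placeholder_count(self) -> int:
        return sum(
            1 for subs in self.families.values() for s in subs if not s.genotyped
        )


def _parse_map(map_path: str | Path) -> list[Marker]:
    markers: list[Marker] = []
    with open(map_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom, mid, _cm, pos = fields
            elif len(fields) == 3:
                chrom, mid, pos = fields
            else:
                raise PedigreeFormatError(
                    f"{map_path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
                )
            markers.append(Marker(marker_id=mid, chromosome=chrom, position_bp=int(pos)))
    markers.sort(key=lambda m: (m.chromosome, m.position_bp))
    return markers


def _normalize_allele(token: str, path, lineno: int) -> str:
    a = _NUMERIC_CODES.get(token, token).upper()
    if a not in VALID_ALLELES:
        raise PedigreeFormatError(f"{path}:{lineno}: invalid allele {token!r}")
    return a


def read_pedmap(
    ped_path: str | Path,
    map_path: str | Path,
    region_start: int | None = None,
    region_end: int | None = None,
) -> PedigreeDataset:
    """Read a PED/MAP pair into a :class:`PedigreeDataset`.

    ``region_start``/``region_end`` optionally restrict the panel to markers
    with ``region_start <= position_bp <= region_end`` (both inclusive,
    mirroring boundary-SNP extraction).
    """
    markers = _parse_map(map_path)
    keep = list(range(len(markers)))
    if region_start is not None or region_end is not None:
        lo = region_start if region_start is not None else -np.inf
        hi = region_end if region_end is not None else np.inf
        keep = [i for i, m in enumerate(markers) if lo <= m.position_bp <= hi]
    n_total = len(markers)
    markers = [markers[i] for i in keep]

    families: dict[str, list[Subject]] = {}
    genotypes: dict[tuple[str, str], np.ndarray] = {}
    expected = 6 + 2 * n_total
    with open(ped_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            fields = raw.split()
            if not fields:
                continue
            if len(fields) != expected:
                raise PedigreeFormatError(
                    f"{ped_path}:{lineno}: expected {expected} columns "
                    f"(6 + 2 x {n_total} markers), got {len(fields)}"
                )
            fid, iid, pat, mat, sex, pheno = fields[:6]
            subs = families.setdefault(fid, [])
            if any(s.subject_id == iid for s in subs):
                raise PedigreeFormatError(
                    f"{ped_path}:{lineno}: duplicate subject id {iid!r} in family {fid!r}"
                )
            subs.append(
                Subject(
                    family_id=fid,
                    subject_id=iid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=SEX_CODES.get(sex, "unknown"),
                    phenotype=PHENOTYPE_CODES.get(pheno, "unknown"),
                )
            )
            geno = np.empty((n_total, 2), dtype="<U1")
            toks = fields[6:]
            for j in range(n_total):
                a1 = _normalize_allele(toks[2 * j], ped_path, lineno)
                a2 = _normalize_allele(toks[2 * j + 1], ped_path, lineno)
                if a1 == MISSING_ALLELE or a2 == MISSING_ALLELE:
                    a1 = a2 = MISSING_ALLELE  # half-typed calls treated as missing
                geno[j, 0], geno[j, 1] = a1, a2
            genotypes[(fid, iid)] = geno[keep]

    _materialize_placeholders(markers, families, genotypes)
    _infer_marker_alleles(markers, genotypes)
    return PedigreeDataset(markers=markers, families=families, genotypes=genotypes)


def _materialize_placeholders(
    markers: Sequence[Marker],
    families: dict[str, list[Subject]],
    genotypes: dict[tuple[str, str], np.ndarray],
) -> None:
    """Create all-missing founder rows for parents referenced but not listed."""
    n = len(markers)
    n_placeholders = 0
    for fid, subs in families.items():
        present = {s.subject_id for s in subs}
        for s in list(subs):
            for pid, sex in ((s.father_id, "male"), (s.mother_id, "female")):
                if pid is not None and pid not in present:
                    subs.append(
                        Subject(
                            family_id=fid,
                            subject_id=pid,
                            father_id=None,
                            mother_id=None,
                            sex=sex,
                            phenotype="unknown",
                            genotyped=False,
                        )
                    )
                    genotypes[(fid, pid)] = np.full((n, 2), MISSING_ALLELE, dtype="<U1")
                    present.add(pid)
                    n_placeholders += 1
    if n_placeholders:
        logger.info("materialized %d non-genotyped founder placeholders", n_placeholders)


def _infer_marker_alleles(
    markers: Sequence[Marker], genotypes: Mapping[tuple[str, str], np.ndarray]
) -> None:
    """Fill allele_a/allele_b from observed calls (most frequent first)."""
    if not genotypes:
        return
    stack = np.stack(list(genotypes.values()))  # (subjects, markers, 2)
    for j, marker in enumerate(markers):
        vals, counts = np.unique(stack[:, j, :], return_counts=True)
        obs = sorted(
            ((c, v) for v, c in zip(vals, counts) if v != MISSING_ALLELE),
            key=lambda t: (-t[0], t[1]),
        )
        if obs:
            marker.allele_a = obs[0][1]
        if len(obs) > 1:
            marker.allele_b = obs[1][1]
        if len(obs) > 2:
            raise PedigreeFormatError(
                f"marker {marker.marker_id}: more than two alleles observed"
            )


def read_maf_table(path: str | Path) -> dict[str, float]:
    """Read a TSV with columns ``marker_id`` and ``maf``.

    Values given on the percent scale (>1 and <=50) are divided by 100;
    values in (0.5, 1] are ambiguous between the two scales and rejected.
    After normalization a MAF must lie in (0, 0.5].
    """
    df = pd.read_csv(path, sep=r"\s+")
    if not {"marker_id", "maf"}.issubset(df.columns):
        raise PedigreeFormatError(f"{path}: expected header columns marker_id, maf")
    out: dict[str, float] = {}
    for mid, maf in zip(df["marker_id"].astype(str), df["maf"].astype(float)):
        if 1.0 < maf <= 50.0:
            maf = maf / 100.0
        if not (0.0 < maf <= 0.5):
            raise ValueError(f"{path}: {mid}: {maf} is not a minor allele frequency")
        out[mid] = maf
    return out


def attach_mafs(dataset: PedigreeDataset, mafs: Mapping[str, float]) -> None:
    for m in dataset.markers:
        if m.marker_id in mafs:
            m.maf = mafs[m.marker_id]


def write_table(records, path: str | Path) -> None:
    """Write any pipeline table as a deterministic, UTF-8, tab-separated file.

    ``records`` may be a DataFrame, a list of dataclasses/dicts, or empty
    (header-only output requires a DataFrame so the header is known).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [r.__dict__ if hasattr(r, "__dict__") else dict(r) for r in records]
        df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- PED/MAP emission (used by the simulator and for round-trip checks) -------

_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_PHENO_OUT = {"affected": "2", "unaffected": "1", "unknown": "0"}


def write_pedmap(
    dataset: PedigreeDataset,
    ped_path: str | Path,
    map_path: str | Path,
    include_placeholders: bool = False,
) -> None:
    """Write a dataset back to PED/MAP text.

    Placeholder founders are omitted by default so that re-reading exercises
    the same placeholder-materialization path as real data.
    """
    with open(map_path, "w") as fh:
        for m in dataset.markers:
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position_bp}\n")
    with open(ped_path, "w") as fh:
        for fid in dataset.families:
            for s in dataset.families[fid]:
                if not s.genotyped and not include_placeholders:
                    continue
                geno = dataset.genotypes[(fid, s.subject_id)]
                row = [
                    fid,
                    s.subject_id,
                    s.father_id or "0",
                    s.mother_id or "0",
                    _SEX_OUT[s.sex],
                    _PHENO_OUT[s.phenotype],
                ]
                row.extend(geno.reshape(-1))
                fh.write(" ".join(row) + "\n")


def write_maf_table(markers: Iterable[Marker], path: str | Path) -> None:
    rows = [
        {"marker_id": m.marker_id, "maf": round(m.maf, 6)}
        for m in markers
        if m.maf is not None
    ]
    write_table(pd.DataFrame(rows, columns=["marker_id", "maf"]), path)


def drop_families(dataset: PedigreeDataset, family_ids) -> PedigreeDataset:
    """Return a copy of the dataset without the given families."""
    family_ids = set(family_ids)
    families = {
        fid: [replace(s) for s in subs]
        for fid, subs in dataset.families.items()
        if fid not in family_ids
    }
    genotypes = {
        key: geno.copy() for key, geno in dataset.genotypes.items() if key[0] not in family_ids
    }
    return PedigreeDataset(
        markers=[replace(m) for m in dataset.markers],
        families=families,
        genotypes=genotypes,
    )
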