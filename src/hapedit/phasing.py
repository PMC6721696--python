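"""Deterministic rule-based phasing of nuclear-family SNP genotypes.

Each family contributes two founders (parents, possibly non-genotyped
placeholders) and their children.  The phaser assigns founder haplotype
alleles only where they are forced by Mendelian transmission logic plus a
single region-wide hap1/hap2 origin labeling per meiosis: the first
informative marker of the first informative meiosis anchors the labeling,
and subsequent informative markers either agree with it or reveal an
apparent within-region crossover.  Everything not forced stays at the
explicit undefined sentinel ``"."``, so downstream coverage-driven panel
editing sees exactly the ambiguity that is really present.

A Mendelian inconsistency (a child allele impossible given its parents)
nulls that marker for the whole family rather than dropping the family,
since isolated genotyping errors would otherwise only produce unphased or
singleton variants downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree_io import (
    MISSING_ALLELE,
    UNDEFINED,
    Marker,
    PedigreeDataset,
    Subject,
    drop_families,
)

logger = logging.getLogger("hapedit")

_MAX_FIXPOINT_SWEEPS = 64


@dataclass
class PhasedHaplotype:
    family_id: str
    founder_id: str
    haplotype_index: int  # 1 or 2
    alleles: np.ndarray  # (n_markers,) '<U1', "." = undefined


@dataclass
class MeiosisOrigin:
    """Per-meiosis parental-haplotype origin calls.

    ``origin`` has one entry per marker: 1/2 where the transmitted allele
    matches exactly one parental haplotype, 0 where the marker is
    uninformative or unresolvable.  ``assigned`` is the single region-wide
    label used when placing transmitted alleles (0 if never resolved).
    """

    child_id: str
    parent_id: str
    origin: np.ndarray  # (n_markers,) int8 in {0, 1, 2}
    assigned: int = 0
    family_id: str = ""

    @property
    def is_crossover(self) -> bool:
        vals = set(self.origin[self.origin != 0].tolist())
        return vals == {1, 2}


@dataclass
class FamilyPhase:
    family_id: str
    father_id: str
    mother_id: str
    haplotypes: list[PhasedHaplotype]
    origins: list[MeiosisOrigin]
    mendel_error_markers: np.ndarray
    # child_id -> (father hap index, mother hap index), defaulting to 1 when
    # the origin was unresolvable (used for DIS/FC bookkeeping only)
    transmissions: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class PhasingResult:
    families: dict[str, FamilyPhase]
    n_mendel_errors: int = 0

    @property
    def origins(self) -> list[MeiosisOrigin]:
        return [o for fp in self.families.values() for o in fp.origins]


def _resolve_transmissions(
    child: np.ndarray, father: np.ndarray, mother: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forced transmitted alleles (father, mother) per marker, "0" if ambiguous.

    Also returns the per-marker Mendelian-error mask.
    """
    c0, c1 = child[:, 0], child[:, 1]
    missing = c0 == MISSING_ALLELE

    def feasible(x: np.ndarray, parent: np.ndarray) -> np.ndarray:
        p_missing = parent[:, 0] == MISSING_ALLELE
        return p_missing | (x == parent[:, 0]) | (x == parent[:, 1])

    feas_a = feasible(c0, father) & feasible(c1, mother)
    feas_b = feasible(c1, father) & feasible(c0, mother)
    err = ~missing & ~feas_a & ~feas_b

    t_f = np.full(len(c0), MISSING_ALLELE, dtype="<U1")
    t_m = np.full(len(c0), MISSING_ALLELE, dtype="<U1")
    only_a = feas_a & ~feas_b & ~missing
    only_b = feas_b & ~feas_a & ~missing
    hom = feas_a & feas_b & (c0 == c1) & ~missing
    t_f[only_a | hom] = c0[only_a | hom]
    t_m[only_a | hom] = c1[only_a | hom]
    t_f[only_b] = c1[only_b]
    t_m[only_b] = c0[only_b]
    return t_f, t_m, err


def _build_parent_haplotypes(
    parent_geno: np.ndarray,
    parent_typed: bool,
    transmissions: list[np.ndarray],
    usable: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixpoint propagation of forced assignments for one parent.

    Returns the (2, n_markers) haplotype array and the per-meiosis
    region-wide origin labels (0 = unresolved).
    """
    n_markers = parent_geno.shape[0]
    hap = np.full((2, n_markers), UNDEFINED, dtype="<U1")
    typed = parent_geno[:, 0] != MISSING_ALLELE
    hom = typed & (parent_geno[:, 0] == parent_geno[:, 1])
    het = typed & ~hom
    hap[0, hom & usable] = parent_geno[hom & usable, 0]
    hap[1, hom & usable] = parent_geno[hom & usable, 0]

    origin = np.zeros(len(transmissions), dtype=np.int8)
    anchored = False
    for _sweep in range(_MAX_FIXPOINT_SWEEPS):
        changed = False
        for c, t in enumerate(transmissions):
            informative = (t != MISSING_ALLELE) & usable & (het | ~typed)
            if not informative.any():
                continue
            if origin[c]:
                o = origin[c] - 1
                fill = informative & (hap[o] == UNDEFINED)
                if fill.any():
                    hap[o, fill] = t[fill]
                    comp = np.where(
                        t == parent_geno[:, 0], parent_geno[:, 1], parent_geno[:, 0]
                    )
                    fill_other = fill & het & (hap[1 - o] == UNDEFINED)
                    hap[1 - o, fill_other] = comp[fill_other]
                    changed = True
                continue
            conflict1 = informative & (hap[0] != UNDEFINED) & (hap[0] != t)
            conflict2 = informative & (hap[1] != UNDEFINED) & (hap[1] != t)
            fits1, fits2 = not conflict1.any(), not conflict2.any()
            if fits1 and not fits2:
                origin[c] = 1
            elif fits2 and not fits1:
                origin[c] = 2
            elif fits1 and fits2:
                if not anchored:
                    origin[c] = 1  # first informative meiosis anchors hap1
                elif not parent_typed and not (hap[1] != UNDEFINED).any():
                    # compatible siblings of a non-genotyped parent are merged
                    # onto the same (hap1) transmitted haplotype
                    origin[c] = 1
            # conflicts with both haplotypes: apparent crossover; leave
            # unresolved so nothing recombinant is written into a founder
            if origin[c]:
                anchored = True
                changed = True
        if not changed:
            break
    return hap, origin


def _origin_vector(
    t: np.ndarray, hap: np.ndarray, usable: np.ndarray
) -> np.ndarray:
    vec = np.zeros(t.shape[0], dtype=np.int8)
    informative = (
        (t != MISSING_ALLELE)
        & usable
        & (hap[0] != UNDEFINED)
        & (hap[1] != UNDEFINED)
        & (hap[0] != hap[1])
    )
    vec[informative & (t == hap[0])] = 1
    vec[informative & (t == hap[1])] = 2
    return vec


def phase_family(
    subjects: list[Subject],
    genotypes: dict[tuple[str, str], np.ndarray],
    n_markers: int,
) -> FamilyPhase:
    """Phase one nuclear family into founder haplotypes and meiosis origins."""
    family_id = subjects[0].family_id
    founders = [s for s in subjects if s.is_founder]
    children = [s for s in subjects if not s.is_founder]
    if len(founders) != 2:
        raise ValueError(
            f"family {family_id}: expected exactly two founder slots, got {len(founders)}"
        )
    father = mother = None
    if children:
        father_id, mother_id = children[0].father_id, children[0].mother_id
        for ch in children:
            if ch.father_id != father_id or ch.mother_id != mother_id:
                raise ValueError(f"family {family_id}: not a single nuclear family")
        father = next(s for s in founders if s.subject_id == father_id)
        mother = next(s for s in founders if s.subject_id == mother_id)
    else:
        males = [s for s in founders if s.sex == "male"]
        father = males[0] if males else founders[0]
        mother = next(s for s in founders if s is not father)

    g_f = genotypes[(family_id, father.subject_id)]
    g_m = genotypes[(family_id, mother.subject_id)]

    err = np.zeros(n_markers, dtype=bool)
    t_father, t_mother = [], []
    for ch in children:
        tf, tm, e = _resolve_transmissions(
            genotypes[(family_id, ch.subject_id)], g_f, g_m
        )
        t_father.append(tf)
        t_mother.append(tm)
        err |= e
    if err.any():
        logger.warning(
            "family %s: Mendelian inconsistency at %d marker(s); nulled for family",
            family_id,
            int(err.sum()),
        )
        for t in t_father + t_mother:
            t[err] = MISSING_ALLELE
    usable = ~err

    hap_f, origin_f = _build_parent_haplotypes(g_f, father.genotyped, t_father, usable)
    hap_m, origin_m = _build_parent_haplotypes(g_m, mother.genotyped, t_mother, usable)

    haplotypes = [
        PhasedHaplotype(family_id, father.subject_id, 1, hap_f[0]),
        PhasedHaplotype(family_id, father.subject_id, 2, hap_f[1]),
        PhasedHaplotype(family_id, mother.subject_id, 1, hap_m[0]),
        PhasedHaplotype(family_id, mother.subject_id, 2, hap_m[1]),
    ]
    origins: list[MeiosisOrigin] = []
    transmissions: dict[str, tuple[int, int]] = {}
    for c, ch in enumerate(children):
        vec_f = _origin_vector(t_father[c], hap_f, usable)
        vec_m = _origin_vector(t_mother[c], hap_m, usable)
        origins.append(
            MeiosisOrigin(
                ch.subject_id, father.subject_id, vec_f, int(origin_f[c]), family_id
            )
        )
        origins.append(
            MeiosisOrigin(
                ch.subject_id, mother.subject_id, vec_m, int(origin_m[c]), family_id
            )
        )
        transmissions[ch.subject_id] = (
            int(origin_f[c]) or 1,
            int(origin_m[c]) or 1,
        )
    return FamilyPhase(
        family_id=family_id,
        father_id=father.subject_id,
        mother_id=mother.subject_id,
        haplotypes=haplotypes,
        origins=origins,
        mendel_error_markers=np.flatnonzero(err),
        transmissions=transmissions,
    )


def phase_dataset(dataset: PedigreeDataset) -> PhasingResult:
    families: dict[str, FamilyPhase] = {}
    n_err = 0
    for fid, subs in dataset.families.items():
        fp = phase_family(subs, dataset.genotypes, dataset.n_markers)
        families[fid] = fp
        n_err += len(fp.mendel_error_markers)
    return PhasingResult(families=families, n_mendel_errors=n_err)


def detect_crossover_families(origins: list[MeiosisOrigin], panel=None) -> set[str]:
    """Families in which any meiosis switches parental-haplotype origin.

    A meiosis is an apparent crossover when its origin vector contains both
    hap1 and hap2 calls anywhere within the panel.
    """
    if isinstance(origins, PhasingResult):
        origins = origins.origins
    return {o.family_id for o in origins if o.is_crossover}


def filter_crossover_families(
    dataset: PedigreeDataset, flagged: set[str]
) -> PedigreeDataset:
    """Remove all subjects of crossover-flagged families."""
    n = dataset.n_families
    reduced = drop_families(dataset, flagged)
    pct = 100.0 * len(flagged) / n if n else 0.0
    logger.info(
        "removed %d of %d families with apparent crossovers (%.1f%%)",
        len(flagged),
        n,
        pct,
    )
    return reduced


class FounderHaplotypeSet:
    """All founder chromosomes of the retained families, two per founder slot.

    The unit of every downstream count: ``alleles`` is an
    ``(n_haplotypes, n_markers)`` single-character array with ``"."`` for
    undefined positions; ``index`` carries one row per haplotype
    (family_id, founder_id, hap_index, genotyped, all_undefined);
    ``recipients`` lists, per haplotype, the (child_id, phenotype) pairs of
    children to whom it was transmitted.
    """

    def __init__(
        self,
        markers: list[Marker],
        index: pd.DataFrame,
        alleles: np.ndarray,
        recipients: list[list[tuple[str, str]]],
    ):
        self.markers = markers
        self.index = index.reset_index(drop=True)
        self.alleles = alleles
        self.recipients = recipients

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def fully_phased_mask(self) -> np.ndarray:
        return ~(self.alleles == UNDEFINED).any(axis=1)

    def restrict(self, marker_ids: list[str]) -> "FounderHaplotypeSet":
        """A new set over the given marker subset (panel order preserved)."""
        wanted = set(marker_ids)
        cols = [j for j, m in enumerate(self.markers) if m.marker_id in wanted]
        return FounderHaplotypeSet(
            markers=[self.markers[j] for j in cols],
            index=self.index.copy(),
            alleles=self.alleles[:, cols].copy(),
            recipients=[list(r) for r in self.recipients],
        )

    def sequences(self) -> np.ndarray:
        """Haplotypes as joined strings (undefined positions as '.')."""
        return np.array(["".join(row) for row in self.alleles])

    def to_frame(self) -> pd.DataFrame:
        df = self.index[["family_id", "founder_id", "hap_index"]].copy()
        for j, mid in enumerate(self.marker_ids):
            df[mid] = self.alleles[:, j]
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, markers: list[Marker] | None = None):
        """Read externally phased haplotypes in the pipeline's TSV layout.

        This is an accepted entry point, so haplotypes phased elsewhere
        (e.g. by a likelihood-based phaser) can be substituted.
        """
        df = pd.read_csv(path, sep="\t", dtype=str)
        marker_cols = [c for c in df.columns if c not in ("family_id", "founder_id", "hap_index")]
        if markers is None:
            markers = [Marker(marker_id=c, chromosome="?", position_bp=j + 1) for j, c in enumerate(marker_cols)]
        alleles = df[marker_cols].to_numpy(dtype="<U1")
        index = pd.DataFrame(
            {
                "family_id": df["family_id"],
                "founder_id": df["founder_id"],
                "hap_index": df["hap_index"].astype(int),
                "genotyped": True,
                "all_undefined": (alleles == UNDEFINED).all(axis=1),
            }
        )
        recipients: list[list[tuple[str, str]]] = [[] for _ in range(len(df))]
        return cls(markers, index, alleles, recipients)


def extract_founder_haplotypes(
    dataset: PedigreeDataset, phasing: PhasingResult
) -> FounderHaplotypeSet:
    """Collect exactly two haplotypes per founder slot per retained family."""
    rows = []
    allele_rows = []
    recipients: list[list[tuple[str, str]]] = []
    pheno = {
        (s.family_id, s.subject_id): s.phenotype
        for subs in dataset.families.values()
        for s in subs
    }
    genotyped = {
        (s.family_id, s.subject_id): s.genotyped
        for subs in dataset.families.values()
        for s in subs
    }
    for fid, fp in phasing.families.items():
        received: dict[tuple[str, int], list[tuple[str, str]]] = {}
        for child_id, (of, om) in fp.transmissions.items():
            received.setdefault((fp.father_id, of), []).append(
                (child_id, pheno[(fid, child_id)])
            )
            received.setdefault((fp.mother_id, om), []).append(
                (child_id, pheno[(fid, child_id)])
            )
        for ph in fp.haplotypes:
            rows.append(
                {
                    "family_id": fid,
                    "founder_id": ph.founder_id,
                    "hap_index": ph.haplotype_index,
                    "genotyped": genotyped[(fid, ph.founder_id)],
                    "all_undefined": bool((ph.alleles == UNDEFINED).all()),
                }
            )
            allele_rows.append(ph.alleles)
            recipients.append(received.get((ph.founder_id, ph.haplotype_index), []))
    index = pd.DataFrame(rows)
    alleles = (
        np.vstack(allele_rows)
        if allele_rows
        else np.empty((0, dataset.n_markers), dtype="<U1")
    )
    n_blank = int(index["all_undefined"].sum()) if len(index) else 0
    logger.info(
        "extracted %d founder haplotypes (%d undefined at all positions)",
        len(index),
        n_blank,
    )
    return FounderHaplotypeSet(
        markers=dataset.markers, index=index, alleles=alleles, recipients=recipients
    )
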