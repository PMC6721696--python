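"""Cataloging fully-phased haplotype variants and correlating them with
reference multi-locus haplotype labels.

A *variant* is a distinct fully-phased allele sequence over the retained
SNP panel.  Variants are named "Variant k" in descending-count order at
first cataloging and the names are then frozen; ranks are competition-style
(tied counts share a rank, the following rank is skipped).  Cross-tabulation
against reference labels (opaque strings such as ``DR4,DQ8``, joined on
family / founder / haplotype index) quantifies how well the SNP variants
act as surrogates for classically typed haplotypes, and
:func:`find_discriminating_snps` searches for a small SNP subset whose
per-class dominant sequences separate two labeled haplotype classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree_io import UNDEFINED
from .phasing import FounderHaplotypeSet

logger = logging.getLogger("hapedit")


def competition_ranks(counts: np.ndarray) -> np.ndarray:
    """Competition ("1224") ranking: rank = 1 + number of strictly larger."""
    counts = np.asarray(counts)
    return np.array([1 + int((counts > c).sum()) for c in counts])


@dataclass
class VariantCatalog:
    """Distinct fully-phased haplotype sequences with counts, ranks, names.

    ``table`` columns: name, sequence, count, rank, percentage (percent of
    all fully-phased haplotypes, 1 decimal).  ``assignments`` aligns with
    the originating FounderHaplotypeSet rows: the variant name per
    haplotype, or None where the haplotype is not fully phased.
    """

    marker_ids: list[str]
    table: pd.DataFrame
    total: int  # number of fully-phased haplotypes
    n_input_haplotypes: int
    assignments: list[str | None] = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def singleton_count(self) -> int:
        return int((self.table["count"] == 1).sum())

    def sequence_matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.table["sequence"]], dtype="<U1")

    def name_of(self, sequence: str) -> str | None:
        hit = self.table.loc[self.table["sequence"] == sequence, "name"]
        return None if hit.empty else str(hit.iloc[0])


def build_catalog(haps: FounderHaplotypeSet) -> VariantCatalog:
    """Catalog the fully-phased haplotypes of a founder set.

    Only haplotypes defined at every marker of the panel enter; variants are
    ordered by descending count with ties broken by lexicographic sequence
    order so repeated runs are bit-identical.
    """
    mask = haps.fully_phased_mask()
    seqs = haps.sequences()
    phased = seqs[mask]
    uniq, counts = np.unique(phased, return_counts=True) if phased.size else (
        np.array([], dtype="<U1"),
        np.array([], dtype=int),
    )
    order = np.lexsort((uniq, -counts))
    uniq, counts = uniq[order], counts[order]
    total = int(counts.sum())
    names = [f"Variant {k + 1}" for k in range(len(uniq))]
    table = pd.DataFrame(
        {
            "name": names,
            "sequence": uniq,
            "count": counts.astype(int),
            "rank": competition_ranks(counts),
            "percentage": np.round(100.0 * counts / total, 1) if total else [],
        }
    )
    by_seq = dict(zip(uniq, names))
    assignments = [
        by_seq[s] if ok else None for s, ok in zip(seqs, mask)
    ]
    logger.info(
        "cataloged %d fully-phased haplotypes (%.0f%% of %d): %d variants, "
        "%d singletons",
        total,
        100.0 * total / max(haps.n_haplotypes, 1),
        haps.n_haplotypes,
        len(uniq),
        int((counts == 1).sum()),
    )
    return VariantCatalog(
        marker_ids=haps.marker_ids,
        table=table,
        total=total,
        n_input_haplotypes=haps.n_haplotypes,
        assignments=assignments,
    )


def _attach_labels(haps: FounderHaplotypeSet, labels: pd.DataFrame) -> pd.DataFrame:
    """Join hap rows with the reference-label table on family/founder/index."""
    df = haps.index[["family_id", "founder_id", "hap_index"]].copy()
    df["row"] = np.arange(len(df))
    lab = labels.copy()
    lab["hap_index"] = lab["hap_index"].astype(int)
    merged = df.merge(
        lab[["family_id", "founder_id", "hap_index", "label"]],
        on=["family_id", "founder_id", "hap_index"],
        how="left",
    )
    return merged


def crosstab_variant_to_reference(
    catalog: VariantCatalog,
    labels: pd.DataFrame,
    haps: FounderHaplotypeSet,
) -> pd.DataFrame:
    """Per variant: the dominant reference label among its labeled copies.

    Columns: variant, n (labeled copies), dominant_label, dominant_n,
    pct_dominant (percent of labeled copies), unlabeled_n, tie (True when
    the mode was split and broken lexicographically).
    """
    merged = _attach_labels(haps, labels)
    merged["variant"] = catalog.assignments
    rows = []
    name_rank = {n: i for i, n in enumerate(catalog.table["name"])}
    for variant, grp in merged[merged["variant"].notna()].groupby("variant"):
        labeled = grp[grp["label"].notna()]
        n_labeled = len(labeled)
        if n_labeled:
            vc = labeled["label"].value_counts()
            top_count = int(vc.iloc[0])
            candidates = sorted(vc[vc == top_count].index)
            dominant = candidates[0]
            tie = len(candidates) > 1
            pct = round(100.0 * top_count / n_labeled, 1)
        else:
            dominant, top_count, tie, pct = None, 0, False, float("nan")
        rows.append(
            {
                "variant": variant,
                "n": n_labeled,
                "dominant_label": dominant,
                "dominant_n": top_count,
                "pct_dominant": pct,
                "unlabeled_n": int(grp["label"].isna().sum()),
                "tie": tie,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            "variant", key=lambda s: s.map(name_rank), kind="stable"
        ).reset_index(drop=True)
    return out


def crosstab_reference_to_variant(
    catalog: VariantCatalog,
    labels: pd.DataFrame,
    haps: FounderHaplotypeSet,
) -> pd.DataFrame:
    """Per reference label: its dominant SNP variant and coverage of the group.

    Columns: label, n (all haplotypes carrying the label), pct_of_labeled,
    dominant_variant, dominant_n, pct_of_group, pct_of_fully_defined,
    unphased_n (label members not fully phased on the panel).
    """
    merged = _attach_labels(haps, labels)
    merged["variant"] = catalog.assignments
    labeled = merged[merged["label"].notna()]
    n_labeled_total = len(labeled)
    rows = []
    for label, grp in labeled.groupby("label"):
        n = len(grp)
        defined = grp[grp["variant"].notna()]
        n_def = len(defined)
        if n_def:
            vc = defined["variant"].value_counts()
            top_count = int(vc.iloc[0])
            name_rank = {nme: i for i, nme in enumerate(catalog.table["name"])}
            candidates = sorted(vc[vc == top_count].index, key=lambda v: name_rank[v])
            dominant = candidates[0]
            tie = len(candidates) > 1
            pct_group = round(100.0 * top_count / n, 1)
            pct_def = round(100.0 * top_count / n_def, 1)
        else:
            dominant, top_count, tie = None, 0, False
            pct_group = pct_def = float("nan")
        rows.append(
            {
                "label": label,
                "n": n,
                "pct_of_labeled": round(100.0 * n / n_labeled_total, 1),
                "dominant_variant": dominant,
                "dominant_n": top_count,
                "pct_of_group": pct_group,
                "pct_of_fully_defined": pct_def,
                "unphased_n": n - n_def,
                "tie": tie,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["n", "label"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return out


@dataclass
class DiscriminatingSNPResult:
    marker_ids: list[str]
    dominant_a: str
    dominant_b: str
    pct_dominant: tuple[float, float]
    pct_other: tuple[float, float]
    pct_unphased: tuple[float, float]
    shared: bool  # True when no subset achieved zero dominant-sequence sharing


def _class_summary(alleles: np.ndarray, cols: tuple[int, ...]):
    sub = alleles[:, cols]
    defined = ~(sub == UNDEFINED).any(axis=1)
    n = len(sub)
    seqs = np.array(["".join(r) for r in sub[defined]])
    if seqs.size == 0:
        return None, 0.0, 0.0, 100.0, frozenset()
    uniq, counts = np.unique(seqs, return_counts=True)
    order = np.lexsort((uniq, -counts))
    dom = uniq[order[0]]
    dom_n = int(counts[order[0]])
    pct_dom = 100.0 * dom_n / n
    pct_other = 100.0 * (int(defined.sum()) - dom_n) / n
    pct_unph = 100.0 * (n - int(defined.sum())) / n
    return dom, pct_dom, pct_other, pct_unph, frozenset(uniq.tolist())


def find_discriminating_snps(
    class_a: FounderHaplotypeSet | np.ndarray,
    class_b: FounderHaplotypeSet | np.ndarray,
    k: int,
    marker_ids: list[str] | None = None,
    max_exhaustive: int = 200_000,
) -> DiscriminatingSNPResult:
    """Find k SNPs whose dominant per-class sequences separate two classes.

    Separation means no class-a haplotype carries class-b's dominant
    k-sequence and vice versa; among separating subsets the one maximizing
    the summed dominant-sequence fractions is returned, preferring dominant
    sequences that differ at more of the k positions (ties: lexicographic
    marker order).  When the exhaustive search space exceeds
    ``max_exhaustive`` subsets, a deterministic greedy forward selection is
    used instead.  If no subset separates, the best-effort subset is
    returned with ``shared=True``.
    """
    a = class_a.alleles if isinstance(class_a, FounderHaplotypeSet) else np.asarray(class_a)
    b = class_b.alleles if isinstance(class_b, FounderHaplotypeSet) else np.asarray(class_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be non-empty")
    m = a.shape[1]
    if k > m:
        raise ValueError(f"k={k} exceeds panel size {m}")
    if marker_ids is None:
        if isinstance(class_a, FounderHaplotypeSet):
            marker_ids = class_a.marker_ids
        else:
            marker_ids = [f"m{j + 1}" for j in range(m)]

    def score(cols: tuple[int, ...]):
        dom_a, pa, oa, ua, seqs_a = _class_summary(a, cols)
        dom_b, pb, ob, ub, seqs_b = _class_summary(b, cols)
        if dom_a is None or dom_b is None:
            sharing, n_diff = 2, 0
        else:
            sharing = int(dom_b in seqs_a) + int(dom_a in seqs_b)
            n_diff = sum(x != y for x, y in zip(dom_a, dom_b))
        return (-sharing, pa + pb, n_diff), (
            dom_a,
            dom_b,
            (pa, pb),
            (oa, ob),
            (ua, ub),
        )

    from math import comb

    if comb(m, k) <= max_exhaustive:
        best_cols, best_key, best_info = None, None, None
        for cols in itertools.combinations(range(m), k):
            key, info = score(cols)
            if best_key is None or key > best_key:
                best_cols, best_key, best_info = cols, key, info
    else:
        cols: list[int] = []
        while len(cols) < k:
            best_j, best_key = None, None
            for j in range(m):
                if j in cols:
                    continue
                key, _ = score(tuple(sorted(cols + [j])))
                if best_key is None or key > best_key:
                    best_j, best_key = j, key
            cols.append(best_j)
        best_cols = tuple(sorted(cols))
        best_key, best_info = score(best_cols)

    dom_a, dom_b, pcts, others, unph = best_info
    return DiscriminatingSNPResult(
        marker_ids=[marker_ids[j] for j in best_cols],
        dominant_a=dom_a,
        dominant_b=dom_b,
        pct_dominant=(round(pcts[0], 1), round(pcts[1], 1)),
        pct_other=(round(others[0], 1), round(others[1], 1)),
        pct_unphased=(round(unph[0], 1), round(unph[1], 1)),
        shared=best_key[0] != 0,
    )
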