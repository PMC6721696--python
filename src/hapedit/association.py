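"""Disease vs. family-control (DIS/FC) haplotype association assay.

Every fully-phased founder haplotype in the retained families is labeled:
DIS if it was transmitted to at least one affected child, FC otherwise
(transmitted only to unaffected or unknown-status children, or never
transmitted; unknown phenotypes count as unaffected).  Founders are then
*equalized*: only founders contributing exactly one DIS and one FC
haplotype are retained, so the DIS and FC totals are equal and ethnically
matched within founders.

The test statistic per variant is the Pearson goodness-of-fit chi-square of
the DIS and FC counts against equal expected counts E = (D + F)/2, i.e.
(D - F)^2 / (D + F); variants with both counts >= ``min_count`` contribute,
the statistics are summed, and the sum is referred to a chi-square
distribution with (number of contributing variants - 1) degrees of freedom.
A Bonferroni adjustment multiplies the p-value by the number of
contributing variants.  A DIS/FC ratio > 1 marks a susceptibility variant,
< 0.5 a protective one, and [0.5, 1] neutral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .haplotype_catalog import VariantCatalog, competition_ranks
from .phasing import FounderHaplotypeSet

logger = logging.getLogger("hapedit")

DEFAULT_MIN_COUNT = 5
SUSCEPTIBILITY_THRESHOLD = 1.0
PROTECTIVE_THRESHOLD = 0.5


def assign_dis_fc(
    haps: FounderHaplotypeSet,
    subjects=None,
    catalog: VariantCatalog | None = None,
) -> pd.DataFrame:
    """Label every founder haplotype DIS or FC.

    ``subjects`` may override the recipient phenotypes recorded on the
    haplotype set (mapping (family_id, child_id) -> phenotype); unknown
    phenotypes are treated as unaffected at this point, not earlier.
    Columns: family_id, founder_id, hap_index, status, variant (None when
    the haplotype is not fully phased or no catalog was given).
    """
    statuses = []
    for i in range(haps.n_haplotypes):
        fam = haps.index.at[i, "family_id"]
        affected = False
        for child_id, pheno in haps.recipients[i]:
            if subjects is not None:
                pheno = subjects.get((fam, child_id), pheno)
            if pheno == "affected":
                affected = True
                break
        statuses.append("DIS" if affected else "FC")
    out = haps.index[["family_id", "founder_id", "hap_index"]].copy()
    out["status"] = statuses
    if catalog is not None:
        out["variant"] = catalog.assignments
    else:
        mask = haps.fully_phased_mask()
        out["variant"] = [s if ok else None for s, ok in zip(haps.sequences(), mask)]
    n_def = out["variant"].notna().sum()
    logger.info(
        "assigned status to %d haplotypes (%d fully phased: %d DIS, %d FC)",
        len(out),
        n_def,
        int(((out["status"] == "DIS") & out["variant"].notna()).sum()),
        int(((out["status"] == "FC") & out["variant"].notna()).sum()),
    )
    return out


def equalize_founders(labeled: pd.DataFrame) -> pd.DataFrame:
    """Keep only founders with exactly one fully-phased DIS and one FC haplotype.

    The result has exactly equal DIS and FC totals; every retained founder
    contributes both of its haplotypes.
    """
    phased = labeled[labeled["variant"].notna()]
    keep_keys = set()
    for key, grp in phased.groupby(["family_id", "founder_id"]):
        if len(grp) == 2 and set(grp["status"]) == {"DIS", "FC"}:
            keep_keys.add(key)
    mask = np.fromiter(
        (
            (fam, fo) in keep_keys
            for fam, fo in zip(phased["family_id"], phased["founder_id"])
        ),
        dtype=bool,
        count=len(phased),
    )
    out = phased[mask].reset_index(drop=True)
    n_dis = int((out["status"] == "DIS").sum())
    n_fc = int((out["status"] == "FC").sum())
    assert n_dis == n_fc, "equalization must balance DIS and FC totals"
    logger.info(
        "equalization: %d of %d fully-phased haplotypes retained "
        "(%d DIS, %d FC) from %d founders",
        len(out),
        len(phased),
        n_dis,
        n_fc,
        len(keep_keys),
    )
    return out


def variant_chi_square(dis_n: int, fc_n: int) -> float:
    """Goodness-of-fit chi-square of one variant's DIS/FC counts against
    equal expected counts E = (D + F) / 2."""
    if dis_n < 0 or fc_n < 0:
        raise ValueError("counts must be non-negative")
    if dis_n == 0 and fc_n == 0:
        raise ValueError("chi-square undefined for two zero counts")
    expected = (dis_n + fc_n) / 2.0
    return (dis_n - expected) ** 2 / expected + (fc_n - expected) ** 2 / expected


def classify_row(ratio: float, dis_n: int | None = None, fc_n: int | None = None) -> str:
    """Susceptibility (ratio > 1), protective (ratio < 0.5), else neutral;
    both boundaries classify as neutral.  A zero FC count is susceptibility
    (infinite ratio); a zero DIS count is protective."""
    if fc_n == 0 and (dis_n or 0) > 0:
        return "susceptibility"
    if dis_n == 0:
        return "protective"
    if ratio > SUSCEPTIBILITY_THRESHOLD:
        return "susceptibility"
    if ratio < PROTECTIVE_THRESHOLD:
        return "protective"
    return "neutral"


@dataclass
class AssociationResult:
    """Per-variant DIS/FC table plus the summed goodness-of-fit test."""

    rows: pd.DataFrame
    total_chi2: float | None
    df: int | None
    p_value: float | None
    p_adjusted: float | None
    n_tested: int
    min_count: int

    @property
    def tested(self) -> pd.DataFrame:
        return self.rows[self.rows["chi2"].notna()]

    def summary(self) -> str:
        if self.total_chi2 is None:
            return "association test not computed (<2 variants passed the count threshold)"
        return (
            f"chi2 = {self.total_chi2:.2f}, df = {self.df}, "
            f"p = {self.p_value:.3g}, p-adjusted = {self.p_adjusted:.3g} "
            f"({self.n_tested} variants with DIS and FC each >= {self.min_count})"
        )


def _build_rows(counts: pd.DataFrame, min_count: int) -> pd.DataFrame:
    dis = counts["dis_n"].to_numpy(dtype=int)
    fc = counts["fc_n"].to_numpy(dtype=int)
    with np.errstate(divide="ignore"):
        ratio = np.where(fc > 0, dis / np.maximum(fc, 1), np.inf)
    ratio = np.where(dis == 0, 0.0, ratio)
    rows = pd.DataFrame(
        {
            "variant": counts["variant"].to_numpy(),
            "dis_n": dis,
            "fc_n": fc,
            "total": dis + fc,
            "ratio": np.round(np.where(np.isfinite(ratio), ratio, np.nan), 2),
            "dis_rank": competition_ranks(dis),
            "fc_rank": competition_ranks(fc),
        }
    )
    passing = (dis >= min_count) & (fc >= min_count)
    chi2 = np.full(len(rows), np.nan)
    for i in np.flatnonzero(passing):
        chi2[i] = variant_chi_square(int(dis[i]), int(fc[i]))
    rows["chi2"] = np.round(chi2, 2)
    rows["classification"] = [
        classify_row(r, d, f) for r, d, f in zip(ratio, dis, fc)
    ]
    order = np.lexsort((rows["variant"].to_numpy(), -rows["total"].to_numpy()))
    return rows.iloc[order].reset_index(drop=True)


def association_test(
    counts,
    min_count: int = DEFAULT_MIN_COUNT,
) -> AssociationResult:
    """Summed goodness-of-fit test over per-variant DIS/FC counts.

    ``counts`` is a DataFrame with columns variant, dis_n, fc_n — or a
    sequence of ``(variant, dis_n, fc_n)`` tuples, or an equalized labeled
    haplotype table (columns variant, status) which is tallied first.
    """
    if isinstance(counts, pd.DataFrame) and {"variant", "status"}.issubset(counts.columns):
        counts = tally_counts(counts)
    elif not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(counts, columns=["variant", "dis_n", "fc_n"])
    rows = _build_rows(counts, min_count)
    tested = rows[rows["chi2"].notna()]
    n_tested = len(tested)
    if n_tested < 2:
        logger.warning(
            "association test not computed: only %d variant(s) with DIS and "
            "FC counts each >= %d",
            n_tested,
            min_count,
        )
        return AssociationResult(rows, None, None, None, None, n_tested, min_count)
    # totals are accumulated from unrounded per-variant statistics
    total = float(
        sum(
            variant_chi_square(int(d), int(f))
            for d, f in zip(tested["dis_n"], tested["fc_n"])
        )
    )
    df = n_tested - 1
    p = float(chi2_dist.sf(total, df))
    p_adj = min(1.0, p * n_tested)
    result = AssociationResult(rows, total, df, p, p_adj, n_tested, min_count)
    logger.info("association: %s", result.summary())
    return result


def tally_counts(equalized: pd.DataFrame) -> pd.DataFrame:
    """Per-variant DIS and FC counts from an equalized labeled table."""
    tab = (
        equalized.groupby(["variant", "status"]).size().unstack(fill_value=0)
    )
    for col in ("DIS", "FC"):
        if col not in tab.columns:
            tab[col] = 0
    out = pd.DataFrame(
        {
            "variant": tab.index,
            "dis_n": tab["DIS"].to_numpy(dtype=int),
            "fc_n": tab["FC"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    return out
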