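"""Editing the SNP panel: coverage, MAF-binned pre-triage, redundancy removal.

The goal of this stage is an edited SNP subset whose fully-phased founder
haplotypes are maximally informative: SNPs are first *pre-triaged* within
six minor-allele-frequency categories, keeping the highest-coverage SNPs in
each category under a per-category quota while avoiding grossly asymmetric
spatial gaps, and then iteratively stripped of *redundant* SNPs — SNPs that
are biallelic as a unit with another SNP (only two joint allele
combinations) across the top 95% (by frequency mass) of the fully-phased
haplotype variants.  A SNP that changes *alone* in some variant of the top
90% mass is protected from removal.  Each removal round re-sorts the
fully-phased haplotypes, so the fully-phased count can only grow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse

from .haplotype_catalog import VariantCatalog, build_catalog
from .pedigree_io import Marker, UNDEFINED
from .phasing import FounderHaplotypeSet

logger = logging.getLogger("hapedit")

#: half-open MAF bins on the percent scale: (0,5], (5,10], ... (40,50]
DEFAULT_MAF_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 5.0),
    (5.0, 10.0),
    (10.0, 20.0),
    (20.0, 30.0),
    (30.0, 40.0),
    (40.0, 50.0),
)

#: bell-shaped per-bin shares of the retained panel (favouring mid-range MAFs)
DEFAULT_BIN_SHARES: tuple[int, ...] = (4, 3, 6, 12, 7, 5)


@dataclass
class TriageConfig:
    maf_bins: tuple[tuple[float, float], ...] = DEFAULT_MAF_BINS
    bin_quotas: tuple[int, ...] | None = None  # explicit; else derived from shares
    bin_shares: tuple[int, ...] = DEFAULT_BIN_SHARES
    retain_fraction_target: float = 0.365
    alone_rule_mass: float = 0.90
    redundancy_mass: float = 0.95
    spatial_gap_factor: float = 3.0
    pre_triage_enabled: bool = True


@dataclass
class CoverageTable:
    """Per-marker fraction of founder haplotypes with a phased allele."""

    table: pd.DataFrame  # columns marker_id, coverage
    n_haplotypes: int

    def __getitem__(self, marker_id: str) -> float:
        return self._map[marker_id]

    def __post_init__(self):
        self._map = dict(zip(self.table["marker_id"], self.table["coverage"]))

    @property
    def min(self) -> float:
        return float(self.table["coverage"].min())

    @property
    def max(self) -> float:
        return float(self.table["coverage"].max())


@dataclass
class RedundancyGroup:
    members: list[str]
    kept: list[str]
    dropped: list[str]


@dataclass
class TriageResult:
    retained_markers: list[str]
    removed_markers: list[dict]  # marker_id, reason, iteration
    iterations: int
    redundancy_groups: list[RedundancyGroup]
    fully_phased_counts: list[int] = field(default_factory=list)

    def report(self) -> pd.DataFrame:
        rows = [
            {"marker_id": mid, "status": "retained", "iteration": None, "partners": ""}
            for mid in self.retained_markers
        ]
        rows += [
            {
                "marker_id": r["marker_id"],
                "status": r["reason"],
                "iteration": r.get("iteration"),
                "partners": ",".join(r.get("partners", [])),
            }
            for r in self.removed_markers
        ]
        return pd.DataFrame(rows)


def compute_coverage(haps: FounderHaplotypeSet, panel: list[Marker] | None = None) -> CoverageTable:
    """Fraction of all founder haplotypes phased at each SNP."""
    if haps.n_haplotypes == 0:
        raise ValueError("empty founder haplotype set")
    markers = panel if panel is not None else haps.markers
    wanted = [m.marker_id for m in markers]
    cols = {m.marker_id: j for j, m in enumerate(haps.markers)}
    defined = haps.alleles != UNDEFINED
    cov = [float(defined[:, cols[mid]].mean()) for mid in wanted]
    table = pd.DataFrame({"marker_id": wanted, "coverage": cov})
    ct = CoverageTable(table=table, n_haplotypes=haps.n_haplotypes)
    logger.info(
        "coverage over %d haplotypes ranged from %.1f to %.1f%%",
        haps.n_haplotypes,
        100 * ct.min,
        100 * ct.max,
    )
    return ct


def categorize_maf(maf: float, bins=DEFAULT_MAF_BINS) -> int:
    """1-based MAF bin index for a fraction-scale MAF in (0, 0.5]."""
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"MAF {maf} outside (0, 0.5]")
    pct = 100.0 * maf
    for i, (lo, hi) in enumerate(bins, start=1):
        if lo < pct <= hi:
            return i
    raise ValueError(f"MAF {maf} not contained in any bin")


def derive_quotas(
    bin_populations: list[int], config: TriageConfig, panel_size: int
) -> list[int]:
    """Per-bin quotas: explicit, or shares scaled to the retain target by the
    largest-remainder method, truncated to each bin's population."""
    n_bins = len(config.maf_bins)
    if config.bin_quotas is not None:
        quotas = list(config.bin_quotas)
    else:
        total = int(round(config.retain_fraction_target * panel_size))
        shares = np.asarray(config.bin_shares, dtype=float)
        raw = shares / shares.sum() * total
        quotas = np.floor(raw).astype(int)
        remainder = total - quotas.sum()
        order = np.argsort(-(raw - quotas), kind="stable")
        for i in order[:remainder]:
            quotas[i] += 1
        quotas = quotas.tolist()
    out = []
    for i in range(n_bins):
        q = quotas[i] if i < len(quotas) else 0
        if q > bin_populations[i]:
            logger.warning(
                "bin %d quota %d exceeds its %d markers; truncated",
                i + 1,
                q,
                bin_populations[i],
            )
            q = bin_populations[i]
        out.append(q)
    return out


def selection_scores(coverage: np.ndarray, n: int) -> np.ndarray:
    """Integer-valued selection objective: coverage at 1e-6 resolution with a
    lower-position tie-break.  Integer scores let the optimizer prove exact
    optimality, and ties in coverage deterministically favour earlier
    positions."""
    if n >= 1000:
        raise ValueError("panel too large for the integer scoring scheme")
    return np.round(np.asarray(coverage) * 1e6).astype(np.int64) * 1000 + (
        n - np.arange(n)
    )


def pre_triage_select(
    panel: list[Marker],
    coverage: CoverageTable,
    mafs: dict[str, float] | None = None,
    config: TriageConfig | None = None,
) -> list[str]:
    """Select the pre-triage SNP subset.

    Within each MAF category the quota-many SNPs of highest coverage are
    retained, subject to the spatial constraint that no gap between
    consecutive retained SNPs — nor between a region boundary and the
    nearest retained SNP — exceeds ``spatial_gap_factor`` times the mean
    expected spacing (region length / retained count).  The selection is the
    exact coverage-sum optimum under those constraints (mixed-integer
    program; ties broken toward lower positions), so the "swap in the
    next-best candidate when the spatial distribution would become grossly
    asymmetric" rule is realized as a well-defined optimization.
    """
    config = config or TriageConfig()
    panel = sorted(panel, key=lambda m: m.position_bp)
    n = len(panel)
    if mafs is None:
        mafs = {m.marker_id: m.maf for m in panel}
    for m in panel:
        if mafs.get(m.marker_id) is None:
            raise ValueError(f"marker {m.marker_id} has no MAF")
    bins = np.array([categorize_maf(mafs[m.marker_id], config.maf_bins) for m in panel])
    positions = np.array([m.position_bp for m in panel], dtype=float)
    cov = np.array([coverage[m.marker_id] for m in panel])

    populations = [int((bins == b).sum()) for b in range(1, len(config.maf_bins) + 1)]
    quotas = derive_quotas(populations, config, n)
    total_quota = sum(quotas)
    if total_quota == 0:
        return []

    region_length = positions[-1] - positions[0]
    gap_limit = config.spatial_gap_factor * region_length / total_quota
    scores = selection_scores(cov, n)

    objective = -scores.astype(float)
    constraints = []
    for b, q in enumerate(quotas, start=1):
        row = np.zeros(n)
        row[bins == b] = 1.0
        constraints.append(scipy.optimize.LinearConstraint(row, q, q))

    gap_rows, gap_lo = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if positions[j] - positions[i] > gap_limit:
                row = np.zeros(n)
                row[i] = row[j] = -1.0
                row[i + 1 : j] = 1.0
                gap_rows.append(row)
                gap_lo.append(-1.0)
    # region boundaries anchor the gap rule: some retained SNP must lie
    # within the gap limit of each end of the region
    for edge_ok in (
        positions - positions[0] <= gap_limit,
        positions[-1] - positions <= gap_limit,
    ):
        if not edge_ok.all():
            row = np.zeros(n)
            row[edge_ok] = 1.0
            gap_rows.append(row)
            gap_lo.append(1.0)
    if gap_rows:
        constraints.append(
            scipy.optimize.LinearConstraint(
                scipy.sparse.csr_matrix(np.array(gap_rows)), np.array(gap_lo), np.inf
            )
        )

    res = scipy.optimize.milp(
        c=objective,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=scipy.optimize.Bounds(0, 1),
        options={"mip_rel_gap": 0.0},
    )
    if not res.success:
        logger.warning(
            "pre-triage spatial constraints infeasible; falling back to "
            "per-bin top coverage without the gap rule"
        )
        selected = np.zeros(n, dtype=bool)
        for b, q in enumerate(quotas, start=1):
            idx = np.flatnonzero(bins == b)
            order = idx[np.argsort(-scores[idx], kind="stable")]
            selected[order[:q]] = True
    else:
        selected = res.x > 0.5
    chosen = [panel[i].marker_id for i in range(n) if selected[i]]
    logger.info("pre-triage retained %d of %d SNPs", len(chosen), n)
    return chosen


def sort_fully_phased_variants(
    haps: FounderHaplotypeSet, marker_ids: list[str] | None = None
) -> VariantCatalog:
    """Catalog of distinct fully-phased haplotype sequences on the panel,
    ordered by descending count (ties by sequence)."""
    sub = haps.restrict(marker_ids) if marker_ids is not None else haps
    return build_catalog(sub)


def find_redundant_groups(
    catalog: VariantCatalog,
    config: TriageConfig | None = None,
    coverage: CoverageTable | None = None,
    positions: dict[str, int] | None = None,
) -> list[RedundancyGroup]:
    """Identify SNP groups that are biallelic as a unit among the top
    redundancy-mass fraction of fully-phased haplotypes.

    A SNP that changes alone (relative to the most frequent variant, all
    other SNPs unchanged) in some variant within the top alone-rule mass is
    protected and never dropped; in each redundant group the member with the
    highest coverage (ties: lower position) — or every protected member — is
    kept and the rest are dropped.
    """
    config = config or TriageConfig()
    if catalog.n_variants == 0:
        return []
    marker_ids = catalog.marker_ids
    m = len(marker_ids)
    seqs = catalog.sequence_matrix()  # (n_variants, m), frequency-sorted
    counts = catalog.table["count"].to_numpy()
    total = counts.sum()

    def prefix_len(mass: float) -> int:
        cum = np.cumsum(counts)
        return int(np.searchsorted(cum, mass * total, side="left") + 1)

    p90 = prefix_len(config.alone_rule_mass)
    p95 = prefix_len(config.redundancy_mass)

    top = seqs[0]
    protected: set[str] = set()
    diff90 = seqs[:p90] != top[None, :]
    lone = diff90.sum(axis=1) == 1
    for v in np.flatnonzero(lone):
        j = int(np.flatnonzero(diff90[v])[0])
        protected.add(marker_ids[j])

    # markers changing together: identical induced partition of the top-95%
    # variants (canonical first-appearance signature), exactly two classes
    prefix = seqs[:p95]
    signatures: dict[tuple, list[int]] = {}
    for j in range(m):
        col = prefix[:, j]
        _, first_idx = np.unique(col, return_index=True)
        order = {col[i]: rank for rank, i in enumerate(sorted(first_idx))}
        if len(order) != 2:
            continue  # constant or (anomalously) multi-allelic: not a pair member
        sig = tuple(order[a] for a in col)
        signatures.setdefault(sig, []).append(j)

    def keep_rank(mid: str) -> tuple:
        cov = -coverage[mid] if coverage is not None else 0.0
        pos = positions[mid] if positions is not None else marker_ids.index(mid)
        return (cov, pos)

    groups: list[RedundancyGroup] = []
    for sig, members_idx in sorted(signatures.items(), key=lambda kv: kv[1][0]):
        if len(members_idx) < 2:
            continue
        members = [marker_ids[j] for j in members_idx]
        prot = [mid for mid in members if mid in protected]
        if prot:
            kept = prot
        else:
            kept = [min(members, key=keep_rank)]
        dropped = [mid for mid in members if mid not in kept]
        groups.append(RedundancyGroup(members=members, kept=kept, dropped=dropped))
    return groups


def triage_iterate(
    haps: FounderHaplotypeSet,
    panel: list[Marker] | None = None,
    config: TriageConfig | None = None,
    mafs: dict[str, float] | None = None,
) -> TriageResult:
    """Full panel edit: optional pre-triage, then iterate
    sort-variants / find-redundancy / drop until no redundant group remains."""
    config = config or TriageConfig()
    panel = panel if panel is not None else haps.markers
    positions = {m.marker_id: m.position_bp for m in panel}
    coverage = compute_coverage(haps, panel)

    removed: list[dict] = []
    if config.pre_triage_enabled:
        current = pre_triage_select(panel, coverage, mafs, config)
        kept_set = set(current)
        for m in panel:
            if m.marker_id not in kept_set:
                removed.append({"marker_id": m.marker_id, "reason": "pre_triage"})
    else:
        current = [m.marker_id for m in sorted(panel, key=lambda m: m.position_bp)]

    all_groups: list[RedundancyGroup] = []
    counts: list[int] = []
    iteration = 0
    while True:
        iteration += 1
        catalog = sort_fully_phased_variants(haps, current)
        counts.append(catalog.total)
        if len(counts) >= 2 and counts[-1] < counts[-2]:
            raise AssertionError(
                "fully-phased haplotype count decreased across a triage iteration"
            )
        groups = find_redundant_groups(catalog, config, coverage, positions)
        dropped = sorted(
            {mid for g in groups for mid in g.dropped},
            key=lambda mid: positions[mid],
        )
        if not dropped:
            break
        all_groups.extend(groups)
        for g in groups:
            for mid in g.dropped:
                removed.append(
                    {
                        "marker_id": mid,
                        "reason": "redundant",
                        "iteration": iteration,
                        "partners": [x for x in g.members if x != mid],
                    }
                )
        current = [mid for mid in current if mid not in set(dropped)]
        logger.info(
            "triage iteration %d: dropped %d redundant SNP(s), %d retained, "
            "%d fully-phased haplotypes",
            iteration,
            len(dropped),
            len(current),
            counts[-1],
        )
        if iteration > len(panel):
            raise RuntimeError("redundancy elimination failed to terminate")
    final_catalog = sort_fully_phased_variants(haps, current)
    logger.info(
        "triage finished after %d iteration(s): %d SNPs retained, "
        "%d fully-phased haplotypes (%.0f%% of %d)",
        iteration,
        len(current),
        final_catalog.total,
        100.0 * final_catalog.total / max(haps.n_haplotypes, 1),
        haps.n_haplotypes,
    )
    return TriageResult(
        retained_markers=current,
        removed_markers=removed,
        iterations=iteration,
        redundancy_groups=all_groups,
        fully_phased_counts=counts,
    )
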