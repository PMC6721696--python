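"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity by exhaustive enumeration in
plain Python, sharing no code path with the package internals they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from hapedit.snp_triage import categorize_maf, derive_quotas, selection_scores


def brute_force_pre_triage(panel, coverage_map, mafs, config):
    """Exhaustive search over per-bin combinations maximizing the coverage
    score subject to the quota and spatial-gap constraints (including the
    region-boundary gaps).  Returns None when no subset satisfies them."""
    panel = sorted(panel, key=lambda m: m.position_bp)
    n = len(panel)
    bins = [categorize_maf(mafs[m.marker_id], config.maf_bins) for m in panel]
    pos = [m.position_bp for m in panel]
    cov = np.array([coverage_map[m.marker_id] for m in panel])
    populations = [bins.count(b) for b in range(1, len(config.maf_bins) + 1)]
    quotas = derive_quotas(populations, config, n)
    total_quota = sum(quotas)
    if total_quota == 0:
        return []
    gap_limit = config.spatial_gap_factor * (pos[-1] - pos[0]) / total_quota
    scores = selection_scores(cov, n)
    per_bin = [
        [i for i in range(n) if bins[i] == b]
        for b in range(1, len(config.maf_bins) + 1)
    ]
    best, best_obj = None, -1
    for combo in itertools.product(
        *[itertools.combinations(pb, q) for pb, q in zip(per_bin, quotas)]
    ):
        sel = sorted(i for group in combo for i in group)
        gaps_ok = (
            pos[sel[0]] - pos[0] <= gap_limit
            and pos[-1] - pos[sel[-1]] <= gap_limit
            and all(
                pos[sel[k + 1]] - pos[sel[k]] <= gap_limit
                for k in range(len(sel) - 1)
            )
        )
        if not gaps_ok:
            continue
        obj = int(scores[sel].sum())
        if obj > best_obj:
            best_obj, best = obj, sel
    if best is None:
        return None
    return [panel[i].marker_id for i in best]


def brute_force_redundant_groups(catalog, config, coverage_map, positions):
    """All maximal marker subsets that are biallelic as a unit over the
    redundancy-mass prefix, with the keep/drop decision re-derived."""
    ids = catalog.marker_ids
    m = len(ids)
    seqs = catalog.sequence_matrix()
    counts = catalog.table["count"].to_numpy()
    total = counts.sum()
    cum = np.cumsum(counts)
    p90 = int(np.searchsorted(cum, config.alone_rule_mass * total, "left") + 1)
    p95 = int(np.searchsorted(cum, config.redundancy_mass * total, "left") + 1)

    top = seqs[0]
    protected = set()
    for v in range(p90):
        diff = np.flatnonzero(seqs[v] != top)
        if len(diff) == 1:
            protected.add(ids[int(diff[0])])

    prefix = seqs[:p95]
    nonconst = [j for j in range(m) if len(set(prefix[:, j])) > 1]
    maximal: list[set] = []
    for r in range(m, 1, -1):
        for sub in itertools.combinations(nonconst, r):
            if any(set(sub) < s for s in maximal):
                continue
            joint = {tuple(prefix[v][list(sub)]) for v in range(len(prefix))}
            if len(joint) == 2:
                maximal.append(set(sub))

    groups = []
    for s in sorted(maximal, key=min):
        members = [ids[j] for j in sorted(s)]
        prot = [x for x in members if x in protected]
        if prot:
            kept = prot
        else:
            kept = [
                min(members, key=lambda mid: (-coverage_map[mid], positions[mid]))
            ]
        dropped = tuple(x for x in members if x not in kept)
        groups.append((tuple(members), tuple(kept), dropped))
    return groups


def brute_force_discriminating(a, b, k):
    """Best k-subset of markers by (separation, summed dominant fractions),
    recomputed with plain loops over all combinations."""
    a = np.asarray(a)
    b = np.asarray(b)
    m = a.shape[1]

    def summarize(mat, cols):
        n = len(mat)
        seqs = {}
        for row in mat:
            sub = tuple(row[list(cols)])
            if "." in sub:
                continue
            seqs[sub] = seqs.get(sub, 0) + 1
        if not seqs:
            return None, 0.0, set()
        dom = min(seqs, key=lambda s: (-seqs[s], s))
        return dom, 100.0 * seqs[dom] / n, set(seqs)

    best_key, best_cols = None, None
    for cols in itertools.combinations(range(m), k):
        dom_a, pa, set_a = summarize(a, cols)
        dom_b, pb, set_b = summarize(b, cols)
        if dom_a is None or dom_b is None:
            sharing, n_diff = 2, 0
        else:
            sharing = int(dom_a in set_b) + int(dom_b in set_a)
            n_diff = sum(x != y for x, y in zip(dom_a, dom_b))
        key = (-sharing, pa + pb, n_diff)
        if best_key is None or key > best_key:
            best_key, best_cols = key, cols
    return best_cols, best_key
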