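"""Coverage, MAF binning, pre-triage optimization, redundancy elimination."""

import numpy as np
import pandas as pd
import pytest

from hapedit.haplotype_catalog import build_catalog
from hapedit.pedigree_io import Marker
from hapedit.phasing import extract_founder_haplotypes, phase_dataset
from hapedit.snp_triage import (
    CoverageTable,
    TriageConfig,
    categorize_maf,
    compute_coverage,
    derive_quotas,
    find_redundant_groups,
    pre_triage_select,
    sort_fully_phased_variants,
    triage_iterate,
)
from hapedit.synthetic_data import build_population, simulate_pedigrees

from conftest import make_founder_set, make_markers
from oracles import brute_force_pre_triage, brute_force_redundant_groups


def coverage_table(cov_map):
    return CoverageTable(
        pd.DataFrame(
            {"marker_id": list(cov_map), "coverage": list(cov_map.values())}
        ),
        n_haplotypes=100,
    )


class TestCoverage:
    def test_three_of_four_defined_is_three_quarters(self):
        haps = make_founder_set(["AG", ".G", "AG", "AG"])
        ct = compute_coverage(haps)
        assert ct["rs1"] == 0.75
        assert ct["rs2"] == 1.0

    def test_full_definition_gives_unit_coverage_everywhere(self):
        haps = make_founder_set(["AGA"] * 5)
        ct = compute_coverage(haps)
        assert ct.min == ct.max == 1.0

    def test_empty_set_rejected(self):
        haps = make_founder_set([], markers=make_markers(2))
        with pytest.raises(ValueError):
            compute_coverage(haps)

    def test_injected_missingness_reported_as_range(self, caplog):
        model = build_population(n_conserved=8, panel_size=10, seed=31,
                                 missing_founder_prob=0.2, missing_call_prob=0.02)
        ds, _ = simulate_pedigrees(model, 80, "affected_sib_pair")
        haps = extract_founder_haplotypes(ds, phase_dataset(ds))
        with caplog.at_level("INFO", logger="hapedit"):
            ct = compute_coverage(haps)
        assert 0 < ct.min <= ct.max < 1
        assert f"ranged from {100 * ct.min:.1f} to {100 * ct.max:.1f}%" in caplog.text


class TestMafBins:
    @pytest.mark.parametrize(
        "maf,expected",
        [
            (0.03, 1),
            (0.05, 1),      # closed upper boundary
            (0.0501, 2),
            (0.10, 2),
            (0.101, 3),
            (0.25, 4),
            (0.35, 5),
            (0.50, 6),
        ],
    )
    def test_bin_membership(self, maf, expected):
        assert categorize_maf(maf) == expected

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.6, 1.0])
    def test_out_of_range_rejected(self, maf):
        with pytest.raises(ValueError):
            categorize_maf(maf)

    def test_default_quota_profile_reproduced_at_reference_panel_size(self):
        # ample bin populations, 37-marker panel, 36.5% target -> the
        # bell-shaped (4, 3, 6, 12, 7, 5) per-bin profile, summing to 37...
        # scaled to a 14-SNP total at this panel size
        cfg = TriageConfig()
        quotas = derive_quotas([37] * 6, cfg, 101)
        assert sum(quotas) == round(0.365 * 101)
        assert quotas == [4, 3, 6, 12, 7, 5]

    def test_quota_truncated_to_bin_population(self, caplog):
        cfg = TriageConfig(bin_quotas=(5, 0, 0, 0, 0, 0))
        with caplog.at_level("WARNING", logger="hapedit"):
            quotas = derive_quotas([2, 0, 0, 0, 0, 0], cfg, 2)
        assert quotas[0] == 2
        assert "truncated" in caplog.text


class TestPreTriage:
    def test_top_coverage_marker_taken_per_bin(self):
        markers = make_markers(6)
        mafs = {f"rs{i}": 0.03 if i <= 3 else 0.25 for i in range(1, 7)}
        cov = {"rs1": 0.7, "rs2": 0.9, "rs3": 0.8, "rs4": 0.6, "rs5": 0.95, "rs6": 0.7}
        cfg = TriageConfig(bin_quotas=(1, 0, 0, 1, 0, 0), spatial_gap_factor=100.0)
        got = pre_triage_select(markers, coverage_table(cov), mafs, cfg)
        assert got == ["rs2", "rs5"]

    def test_coverage_tie_broken_by_lower_position(self):
        markers = make_markers(3)
        mafs = {m.marker_id: 0.2 for m in markers}
        cov = {"rs1": 0.8, "rs2": 0.8, "rs3": 0.8}
        cfg = TriageConfig(bin_quotas=(0, 0, 1, 0, 0, 0), spatial_gap_factor=100.0)
        assert pre_triage_select(markers, coverage_table(cov), mafs, cfg) == ["rs1"]

    def test_gap_constraint_forces_swap(self):
        # the two top-coverage markers cluster at the start; taking both
        # would leave the rest of the region empty, so the selection swaps
        # in a lower-coverage marker to keep the spatial spread
        markers = [
            Marker("rs1", "6", 0), Marker("rs2", "6", 100),
            Marker("rs3", "6", 5_000), Marker("rs4", "6", 10_000),
        ]
        mafs = {m.marker_id: 0.2 for m in markers}
        cov = {"rs1": 0.99, "rs2": 0.98, "rs3": 0.5, "rs4": 0.4}
        cfg = TriageConfig(bin_quotas=(0, 0, 2, 0, 0, 0), spatial_gap_factor=1.1)
        got = pre_triage_select(markers, coverage_table(cov), mafs, cfg)
        # {rs1, rs2} has the highest coverage sum but leaves a 9.9 kb hole
        assert got == ["rs1", "rs3"]

    def test_matches_exhaustive_search_on_random_panels(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(30):
            n = int(rng.integers(6, 13))
            pos = np.sort(rng.choice(100_000, n, replace=False)) + 1
            panel = [Marker(f"rs{i}", "6", int(pos[i])) for i in range(n)]
            mafs = {m.marker_id: float(rng.uniform(0.01, 0.5)) for m in panel}
            cov = {m.marker_id: float(rng.uniform(0.5, 1.0)) for m in panel}
            cfg = TriageConfig(
                retain_fraction_target=float(rng.uniform(0.3, 0.6)),
                spatial_gap_factor=float(rng.uniform(1.5, 4.0)),
            )
            expected = brute_force_pre_triage(panel, cov, mafs, cfg)
            if expected is None:
                continue  # constraints infeasible: fallback path, not optimum
            assert pre_triage_select(panel, coverage_table(cov), mafs, cfg) == expected
            n_checked += 1
        assert n_checked >= 20


class TestSortFullyPhased:
    def test_partially_undefined_haplotypes_excluded(self):
        haps = make_founder_set(["AG", "A.", "AG", "GG"])
        cat = sort_fully_phased_variants(haps)
        assert cat.total == 3
        assert cat.table["count"].tolist() == [2, 1]

    def test_equal_counts_ordered_lexicographically(self):
        haps = make_founder_set(["GA", "AG", "GA", "AG"])
        cat = sort_fully_phased_variants(haps)
        assert cat.table["sequence"].tolist() == ["AG", "GA"]

    def test_dropping_a_marker_never_reduces_fully_phased_count(self):
        model = build_population(n_conserved=8, panel_size=10, seed=37,
                                 missing_founder_prob=0.2, missing_call_prob=0.02)
        ds, _ = simulate_pedigrees(model, 60, "affected_sib_pair")
        haps = extract_founder_haplotypes(ds, phase_dataset(ds))
        ids = haps.marker_ids
        full = sort_fully_phased_variants(haps, ids).total
        for drop in ids:
            sub = [m for m in ids if m != drop]
            assert sort_fully_phased_variants(haps, sub).total >= full


class TestRedundancy:
    def test_perfectly_correlated_pair_drops_lower_coverage(self):
        # rs1 and rs3 always change together; rs3 has lower coverage
        haps = make_founder_set(["AAA", "GAG"], counts=[6, 4])
        cat = build_catalog(haps)
        cov = {"rs1": 0.9, "rs2": 0.8, "rs3": 0.7}
        groups = find_redundant_groups(cat, TriageConfig(), coverage_table(cov),
                                       {"rs1": 100, "rs2": 200, "rs3": 300})
        assert len(groups) == 1
        assert groups[0].members == ["rs1", "rs3"]
        assert groups[0].dropped == ["rs3"]

    def test_three_joint_combinations_not_redundant(self):
        haps = make_founder_set(["AA", "GA", "GG"], counts=[4, 3, 3])
        cat = build_catalog(haps)
        assert find_redundant_groups(cat, TriageConfig()) == []

    def test_rare_variants_outside_mass_prefix_ignored(self):
        # the pair is biallelic-as-a-unit among the top 95% of haplotype
        # mass; a single discordant singleton below the cutoff cannot save it
        haps = make_founder_set(["AA", "GG", "AG"], counts=[60, 39, 1])
        cat = build_catalog(haps)
        cov = {"rs1": 0.9, "rs2": 0.8}
        groups = find_redundant_groups(cat, TriageConfig(), coverage_table(cov),
                                       {"rs1": 100, "rs2": 200})
        assert len(groups) == 1 and groups[0].dropped == ["rs2"]

    def test_alone_rule_protects_member_of_redundant_group(self):
        # with a redundancy prefix shorter than the alone-rule prefix, a SNP
        # changing alone in a rare variant is protected and its
        # higher-coverage partner is dropped instead
        haps = make_founder_set(["AAA", "GAG", "AAG"], counts=[70, 20, 10])
        cfg = TriageConfig(alone_rule_mass=0.99, redundancy_mass=0.80)
        cat = build_catalog(haps)
        cov = {"rs1": 0.95, "rs2": 0.9, "rs3": 0.6}
        groups = find_redundant_groups(cat, cfg, coverage_table(cov),
                                       {"rs1": 100, "rs2": 200, "rs3": 300})
        assert len(groups) == 1
        assert groups[0].kept == ["rs3"]  # protected despite lower coverage
        assert groups[0].dropped == ["rs1"]

    def test_matches_exhaustive_enumeration_on_random_catalogs(self):
        rng = np.random.default_rng(7)
        n_with_groups = 0
        for _ in range(60):
            m = int(rng.integers(4, 11))
            nv = int(rng.integers(3, 21))
            mat = rng.choice(["A", "G"], size=(nv, m))
            if rng.random() < 0.6 and m >= 3:
                j1, j2 = rng.choice(m, 2, replace=False)
                if rng.random() < 0.5:
                    mat[:, j2] = mat[:, j1]
                else:
                    mat[:, j2] = np.where(mat[:, j1] == "A", "G", "A")
            uniq = sorted({"".join(r) for r in mat})
            counts = rng.integers(1, 50, size=len(uniq)).tolist()
            haps = make_founder_set(uniq, counts)
            cat = build_catalog(haps)
            cov = {f"rs{j + 1}": float(rng.uniform(0.5, 1)) for j in range(m)}
            positions = {f"rs{j + 1}": (j + 1) * 100 for j in range(m)}
            cfg = TriageConfig()
            got = [
                (tuple(g.members), tuple(g.kept), tuple(g.dropped))
                for g in find_redundant_groups(cat, cfg, coverage_table(cov), positions)
            ]
            expected = brute_force_redundant_groups(cat, cfg, cov, positions)
            assert sorted(got) == sorted(expected)
            n_with_groups += bool(expected)
        assert n_with_groups >= 20


def planted_redundancy_set(
    n_independent=27, n_planted=10, n_variants=16, seed=101, counts_skew=0.72
):
    """A founder set over n_independent+n_planted markers where exactly the
    planted markers duplicate (or mirror) an independent one."""
    rng = np.random.default_rng(seed)
    total = n_independent + n_planted
    counts = np.maximum((1000 * counts_skew ** np.arange(n_variants)).astype(int), 1)
    # redundancy is judged on the top-95%-mass prefix of variants, so the
    # independent columns must induce pairwise-distinct, non-constant
    # partitions *of that prefix* (and the variant rows must stay distinct)
    cum = np.cumsum(counts)
    p95 = int(np.searchsorted(cum, 0.95 * counts.sum(), "left") + 1)
    for _ in range(500):
        base = rng.choice(["A", "G"], size=(n_variants, n_independent))
        sigs = set()
        ok = len({"".join(r) for r in base}) == n_variants
        for j in range(n_independent):
            if not ok:
                break
            col = tuple(base[:p95, j] == base[0, j])
            if len(set(col)) < 2:
                ok = False
                break
            sig = col if col[0] else tuple(not x for x in col)
            if sig in sigs:
                ok = False
                break
            sigs.add(sig)
        if ok:
            break
    assert ok, "could not construct independent columns"
    donors = rng.choice(n_independent, size=n_planted, replace=False)
    planted_cols = []
    for d in donors:
        col = base[:, d]
        if rng.random() < 0.5:
            col = np.where(col == "A", "G", "A")
        planted_cols.append(col)
    mat = np.concatenate([base, np.stack(planted_cols, axis=1)], axis=1)
    seqs = ["".join(r) for r in mat]
    markers = make_markers(total)
    haps = make_founder_set(seqs, counts.tolist(), markers)
    planted_ids = [f"rs{n_independent + i + 1}" for i in range(n_planted)]
    return haps, planted_ids


class TestTriageIterate:
    def test_redundancy_free_panel_is_identity_in_one_iteration(self):
        haps = make_founder_set(["AAG", "GAA", "GGG"], counts=[5, 3, 2])
        res = triage_iterate(haps, config=TriageConfig(pre_triage_enabled=False))
        assert res.iterations == 1
        assert res.retained_markers == ["rs1", "rs2", "rs3"]
        assert res.removed_markers == []

    def test_planted_redundant_markers_exactly_recovered(self):
        haps, planted = planted_redundancy_set(n_independent=6, n_planted=2,
                                               n_variants=8, seed=11)
        res = triage_iterate(haps, config=TriageConfig(pre_triage_enabled=False))
        dropped = {r["marker_id"] for r in res.removed_markers}
        assert dropped == set(planted)

    def test_termination_within_panel_size_iterations(self):
        haps, _ = planted_redundancy_set(n_independent=8, n_planted=4,
                                         n_variants=10, seed=19)
        res = triage_iterate(haps, config=TriageConfig(pre_triage_enabled=False))
        assert 1 <= res.iterations <= len(haps.markers)

    def test_no_redundancy_remains_after_termination(self):
        model = build_population(n_conserved=10, panel_size=14, seed=41,
                                 missing_founder_prob=0.15)
        ds, _ = simulate_pedigrees(model, 120, "affected_sib_pair")
        haps = extract_founder_haplotypes(ds, phase_dataset(ds))
        for pre in (True, False):
            res = triage_iterate(haps, config=TriageConfig(pre_triage_enabled=pre))
            cat = sort_fully_phased_variants(haps, res.retained_markers)
            leftover = find_redundant_groups(cat, TriageConfig())
            assert leftover == []

    def test_fully_phased_count_nondecreasing_across_iterations(self):
        haps, _ = planted_redundancy_set(n_independent=10, n_planted=5,
                                         n_variants=12, seed=23)
        # blank out some calls so counts can actually move
        rng = np.random.default_rng(5)
        mask = rng.random(haps.alleles.shape) < 0.05
        haps.alleles[mask] = "."
        haps.index["all_undefined"] = (haps.alleles == ".").all(axis=1)
        res = triage_iterate(haps, config=TriageConfig(pre_triage_enabled=False))
        counts = res.fully_phased_counts
        assert all(b >= a for a, b in zip(counts, counts[1:]))
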