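"""Simulation of T1DGC-like affected-sib-pair pedigree SNP datasets.

The generator emulates the statistical structure the pipeline assumes: a
population pool of long conserved haplotype sequences at skewed (geometric)
frequencies plus a tail of rare variants, nuclear families whose founders
draw haplotypes from that pool, Mendelian transmission with an optional
within-region crossover per meiosis, a multiplicative two-haplotype relative
risk model for the disease phenotype, affected-sib-pair ascertainment, and
missingness both as whole ungenotyped founders and as per-call dropouts.

Truth records (founder haplotypes, transmissions, crossovers, phenotypes)
are returned alongside the dataset so every pipeline stage can be checked
against the simulated ground truth.

One master seed governs everything; each family uses a deterministic
substream derived from ``(seed, family index)``, so changing the number of
families never reshuffles earlier families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree_io import MISSING_ALLELE, Marker, PedigreeDataset, Subject

_NUCLEOTIDES = np.array(list("ACGT"))
REGION_START = 32_439_932  # chromosome 6, HLA-DR/DQ region scale


@dataclass
class PopulationModel:
    """A pool of conserved founder haplotypes and the family-generation knobs.

    ``relative_risks`` acts multiplicatively: a subject carrying pool
    haplotypes i and j is affected with probability
    ``min(1, prevalence * rr[i] * rr[j])``.
    """

    markers: list[Marker]
    pool_sequences: np.ndarray  # (n_pool, n_markers) '<U1', fully defined
    pool_frequencies: np.ndarray  # sums to 1
    relative_risks: np.ndarray  # positive, one per pool haplotype
    recombination_fraction: float = 0.0  # per meiosis, across the region
    missing_founder_prob: float = 0.0
    missing_call_prob: float = 0.0
    prevalence: float = 0.05
    n_children: int = 2
    seed: int = 0

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_pool(self) -> int:
        return len(self.pool_frequencies)


@dataclass
class TruthRecords:
    """Ground truth emitted with every simulated dataset."""

    # (family_id, founder_id, hap_index 1|2) -> pool haplotype index
    founder_pool: dict[tuple[str, str, int], int] = field(default_factory=dict)
    # (family_id, founder_id, hap_index) -> full allele sequence
    founder_sequences: dict[tuple[str, str, int], np.ndarray] = field(default_factory=dict)
    # (family_id, child_id, parent_id) ->
    #   (hap_index transmitted at the 5' end, crossover?, breakpoint marker index)
    meioses: dict[tuple[str, str, str], tuple[int, bool, int]] = field(default_factory=dict)
    phenotypes: dict[tuple[str, str], str] = field(default_factory=dict)
    recombinant_families: set[str] = field(default_factory=set)
    missing_founders: set[tuple[str, str]] = field(default_factory=set)


def build_population(
    n_conserved: int = 16,
    panel_size: int = 37,
    frequency_skew: float = 0.717,
    seed: int = 0,
    top_frequency: float | None = None,
    region_length: int = 273_967,
    **kwargs,
) -> PopulationModel:
    """Build a deterministic haplotype pool with geometric frequency decay.

    ``frequency_skew`` is the geometric ratio between successive pool
    frequencies; the default gives a most-frequent haplotype near 28.3% of
    the population, with a tail of rare variants.  ``top_frequency``
    optionally pins the most frequent haplotype exactly, the remainder
    decaying geometrically.  Per-marker minor-allele frequencies emerge from
    the pool composition and are attached to the markers.
    """
    if n_conserved < 2:
        raise ValueError("need at least two conserved haplotypes in the pool")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    spacing = max(region_length // max(panel_size - 1, 1), 1)
    markers = []
    for j in range(panel_size):
        a, b = rng.choice(4, size=2, replace=False)
        markers.append(
            Marker(
                marker_id=f"rs{100000 + j}",
                chromosome="6",
                position_bp=REGION_START + j * spacing,
                allele_a=str(_NUCLEOTIDES[a]),
                allele_b=str(_NUCLEOTIDES[b]),
            )
        )

    # pool sequences: per marker, a target minor-allele proportion drawn
    # uniformly, realized across pool haplotypes; duplicates resampled
    if n_conserved > 2**panel_size:
        raise ValueError("panel too short for the requested number of haplotypes")
    seqs = np.empty((n_conserved, panel_size), dtype="<U1")
    minor_target = rng.uniform(0.05, 0.5, size=panel_size)
    for j in range(panel_size):
        take_b = rng.random(n_conserved) < minor_target[j]
        seqs[:, j] = np.where(take_b, markers[j].allele_b, markers[j].allele_a)
    # resolve duplicate sequences by flipping random positions of later copies
    for _ in range(1000):
        joined = ["".join(r) for r in seqs]
        seen: dict[str, int] = {}
        dups = []
        for i, s in enumerate(joined):
            if s in seen:
                dups.append(i)
            else:
                seen[s] = i
        if not dups:
            break
        for i in dups:
            j = int(rng.integers(panel_size))
            cur = seqs[i, j]
            seqs[i, j] = (
                markers[j].allele_b if cur == markers[j].allele_a else markers[j].allele_a
            )
    else:
        raise RuntimeError("could not draw distinct pool haplotypes")

    k = np.arange(n_conserved)
    if top_frequency is None:
        freqs = frequency_skew**k
    else:
        tail = frequency_skew ** k[1:]
        freqs = np.concatenate(
            [[top_frequency], (1.0 - top_frequency) * tail / tail.sum()]
        )
    freqs = freqs / freqs.sum()

    # emergent per-marker MAFs from the pool
    for j, m in enumerate(markers):
        p_b = float(freqs[seqs[:, j] == m.allele_b].sum())
        maf = min(p_b, 1.0 - p_b)
        m.maf = float(np.clip(maf, 1e-4, 0.5))

    return PopulationModel(
        markers=markers,
        pool_sequences=seqs,
        pool_frequencies=freqs,
        relative_risks=np.ones(n_conserved),
        seed=seed,
        **kwargs,
    )


def _draw_family(rng: np.random.Generator, model: PopulationModel, batch: int):
    """Vectorized draw of `batch` candidate families; returns component arrays."""
    n_c = model.n_children
    fo = rng.choice(model.n_pool, size=(batch, 4), p=model.pool_frequencies)
    hap_choice = rng.integers(0, 2, size=(batch, n_c, 2))  # per child x (father, mother)
    recomb = rng.random(size=(batch, n_c, 2)) < model.recombination_fraction
    breakpoints = rng.integers(1, max(model.n_markers, 2), size=(batch, n_c, 2))
    # child risk: product of the 5'-segment source haplotypes' relative risks
    rr = model.relative_risks
    pat = np.take_along_axis(fo[:, 0:2], hap_choice[:, :, 0], axis=1)
    mat = np.take_along_axis(fo[:, 2:4], hap_choice[:, :, 1], axis=1)
    p_aff = np.clip(model.prevalence * rr[pat] * rr[mat], 0.0, 1.0)
    affected = rng.random(size=(batch, n_c)) < p_aff
    return fo, hap_choice, recomb, breakpoints, affected


def simulate_pedigrees(
    model: PopulationModel,
    n_families: int,
    ascertainment: str = "affected_sib_pair",
    max_attempts: int = 100_000,
) -> tuple[PedigreeDataset, TruthRecords]:
    """Simulate nuclear families; under ``affected_sib_pair`` each family is
    rejection-sampled until at least two children are affected."""
    if ascertainment not in ("affected_sib_pair", "none"):
        raise ValueError(f"unknown ascertainment {ascertainment!r}")
    if ascertainment == "affected_sib_pair" and model.n_children < 2:
        raise ValueError("affected-sib-pair ascertainment needs >= 2 children")

    n_markers = model.n_markers
    truth = TruthRecords()
    families: dict[str, list[Subject]] = {}
    genotypes: dict[tuple[str, str], np.ndarray] = {}

    for fam_idx in range(n_families):
        fid = f"fam{fam_idx + 1:05d}"
        rng = np.random.default_rng(np.random.SeedSequence([int(model.seed), 7919, fam_idx]))
        chosen = None
        attempts = 0
        while chosen is None:
            batch = 1 if ascertainment == "none" else 128
            fo, hap_choice, recomb, bp, affected = _draw_family(rng, model, batch)
            if ascertainment == "none":
                chosen = 0
            else:
                ok = affected.sum(axis=1) >= 2
                hits = np.flatnonzero(ok)
                if hits.size:
                    chosen = int(hits[0])
            attempts += batch
            if chosen is None and attempts >= max_attempts:
                raise RuntimeError(
                    f"family {fid}: ascertainment unattainable after {attempts} attempts"
                )
            if chosen is not None:
                fo, hap_choice, recomb, bp, affected = (
                    fo[chosen],
                    hap_choice[chosen],
                    recomb[chosen],
                    bp[chosen],
                    affected[chosen],
                )

        father_id, mother_id = "fa", "mo"
        founder_ids = (father_id, father_id, mother_id, mother_id)
        founder_seq = model.pool_sequences[fo]  # (4, m)
        for slot, (pid, hap_i) in enumerate(zip(founder_ids, (1, 2, 1, 2))):
            truth.founder_pool[(fid, pid, hap_i)] = int(fo[slot])
            truth.founder_sequences[(fid, pid, hap_i)] = founder_seq[slot].copy()

        subs = [
            Subject(fid, father_id, None, None, "male", "unaffected"),
            Subject(fid, mother_id, None, None, "female", "unaffected"),
        ]
        genotypes[(fid, father_id)] = founder_seq[0:2].T.copy()
        genotypes[(fid, mother_id)] = founder_seq[2:4].T.copy()
        truth.phenotypes[(fid, father_id)] = "unaffected"
        truth.phenotypes[(fid, mother_id)] = "unaffected"

        fam_recomb = False
        for c in range(model.n_children):
            cid = f"c{c + 1}"
            child_hap = np.empty((2, n_markers), dtype="<U1")
            for side, (pid, base) in enumerate(((father_id, 0), (mother_id, 2))):
                h = int(hap_choice[c, side])
                seq = founder_seq[base + h].copy()
                is_rec = bool(recomb[c, side]) and n_markers > 1
                cut = int(bp[c, side]) if is_rec else 0
                if is_rec:
                    seq[cut:] = founder_seq[base + (1 - h)][cut:]
                    fam_recomb = True
                child_hap[side] = seq
                truth.meioses[(fid, cid, pid)] = (h + 1, is_rec, cut)
            pheno = "affected" if affected[c] else "unaffected"
            subs.append(Subject(fid, cid, father_id, mother_id, "unknown", pheno))
            genotypes[(fid, cid)] = child_hap.T.copy()
            truth.phenotypes[(fid, cid)] = pheno
        if fam_recomb:
            truth.recombinant_families.add(fid)

        # missingness injected last: whole founders, then per-call dropouts
        for pid in (father_id, mother_id):
            if rng.random() < model.missing_founder_prob:
                for s in subs:
                    if s.subject_id == pid:
                        s.genotyped = False
                genotypes[(fid, pid)] = np.full(
                    (n_markers, 2), MISSING_ALLELE, dtype="<U1"
                )
                truth.missing_founders.add((fid, pid))
        if model.missing_call_prob > 0:
            for s in subs:
                if not s.genotyped:
                    continue
                drop = rng.random(n_markers) < model.missing_call_prob
                genotypes[(fid, s.subject_id)][drop] = MISSING_ALLELE

        families[fid] = subs

    from dataclasses import replace

    dataset = PedigreeDataset(
        markers=[replace(m) for m in model.markers],
        families=families,
        genotypes=genotypes,
    )
    return dataset, truth
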