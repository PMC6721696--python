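"""End-to-end orchestration: phase, edit, catalog, associate.

:class:`RunConfig` gathers every pipeline threshold in one serializable
object (YAML round-trip) so each run's outputs carry the exact
configuration that produced them.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import association as assoc
from . import haplotype_catalog as cat
from . import phasing as ph
from . import snp_triage as triage
from .pedigree_io import PedigreeDataset, attach_mafs

logger = logging.getLogger("hapedit")


@dataclass
class RunConfig:
    """All pipeline thresholds, with the standard assay values as defaults."""

    maf_bins: tuple = triage.DEFAULT_MAF_BINS
    bin_quotas: tuple | None = None
    bin_shares: tuple = triage.DEFAULT_BIN_SHARES
    retain_fraction_target: float = 0.365
    alone_rule_mass: float = 0.90
    redundancy_mass: float = 0.95
    spatial_gap_factor: float = 3.0
    pre_triage_enabled: bool = True
    min_count: int = assoc.DEFAULT_MIN_COUNT
    region_start: int | None = None
    region_end: int | None = None
    seed: int = 0

    def triage_config(self) -> triage.TriageConfig:
        return triage.TriageConfig(
            maf_bins=tuple(tuple(b) for b in self.maf_bins),
            bin_quotas=tuple(self.bin_quotas) if self.bin_quotas else None,
            bin_shares=tuple(self.bin_shares),
            retain_fraction_target=self.retain_fraction_target,
            alone_rule_mass=self.alone_rule_mass,
            redundancy_mass=self.redundancy_mass,
            spatial_gap_factor=self.spatial_gap_factor,
            pre_triage_enabled=self.pre_triage_enabled,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    dataset: PedigreeDataset
    phasing: ph.PhasingResult
    crossover_families: set[str]
    founder_haplotypes: ph.FounderHaplotypeSet
    triage: triage.TriageResult
    catalog: cat.VariantCatalog
    labeled: pd.DataFrame
    equalized: pd.DataFrame
    association: assoc.AssociationResult
    crosstab_v2r: pd.DataFrame | None = None
    crosstab_r2v: pd.DataFrame | None = None


def run_pipeline(
    dataset: PedigreeDataset,
    config: RunConfig | None = None,
    mafs: dict[str, float] | None = None,
    labels: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full pipeline on a dataset already read into memory."""
    config = config or RunConfig()
    if mafs:
        attach_mafs(dataset, mafs)

    phasing = ph.phase_dataset(dataset)
    flagged = ph.detect_crossover_families(phasing.origins)
    retained = ph.filter_crossover_families(dataset, flagged)
    phasing_kept = ph.PhasingResult(
        families={f: p for f, p in phasing.families.items() if f not in flagged},
        n_mendel_errors=phasing.n_mendel_errors,
    )
    haps = ph.extract_founder_haplotypes(retained, phasing_kept)

    tri = triage.triage_iterate(
        haps, retained.markers, config.triage_config(), mafs=mafs
    )
    edited = haps.restrict(tri.retained_markers)
    catalog = cat.build_catalog(edited)

    labeled = assoc.assign_dis_fc(edited, catalog=catalog)
    equalized = assoc.equalize_founders(labeled)
    result = assoc.association_test(equalized, min_count=config.min_count)

    v2r = r2v = None
    if labels is not None:
        v2r = cat.crosstab_variant_to_reference(catalog, labels, edited)
        r2v = cat.crosstab_reference_to_variant(catalog, labels, edited)

    return PipelineResult(
        dataset=retained,
        phasing=phasing_kept,
        crossover_families=flagged,
        founder_haplotypes=haps,
        triage=tri,
        catalog=catalog,
        labeled=labeled,
        equalized=equalized,
        association=result,
        crosstab_v2r=v2r,
        crosstab_r2v=r2v,
    )
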