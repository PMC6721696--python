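"""Worked-example DIS/FC count tables from a published T1D family study.

These are the per-variant disease (DIS) and family-control (FC) haplotype
counts of the equalized assay on T1DGC family data: edited 27-SNP
haplotype variants over the full ImmunoChip family set, the same variants
restricted to the families overlapping the MHC Fine Mapping study, and the
classically typed HLA-DR,DQ haplotype groups for those overlapping
families.  They serve as ready-made inputs for
:func:`hapedit.association.association_test` — the summed goodness-of-fit
statistic, degrees of freedom and p-values are recomputed from these raw
counts at run time.

Each table is a list of ``(variant name, dis_n, fc_n)`` tuples, ordered by
total count as published ("Misc." pooled rows are excluded; they never
enter ranking or testing).
"""

# Edited 27-SNP haplotypes, full family set (2004 DIS / 2004 FC equalized)
IMMUNOCHIP_SNP_COUNTS: list[tuple[str, int, int]] = [
    ("Variant 1", 916, 238),
    ("Variant 2", 416, 204),
    ("Variant 3", 108, 190),
    ("Variant 4", 249, 46),
    ("Variant 7", 5, 254),
    ("Variant 5", 47, 190),
    ("Variant 8", 18, 195),
    ("Variant 6", 73, 120),
    ("Variant 11", 8, 71),
    ("Variant 9", 45, 32),
    ("Variant 14", 2, 68),
    ("Variant 10", 25, 43),
    ("Variant 12", 20, 39),
    ("Variant 13", 4, 52),
    ("Variant 18", 1, 49),
    ("Variant 15", 18, 24),
    ("Variant 17", 5, 26),
    ("Variant 16", 9, 17),
    ("Variant 19", 4, 16),
    ("Variant 20", 1, 19),
    ("Variant 21", 1, 10),
    ("Variant 23", 1, 10),
    ("Variant 25", 5, 1),
    ("Variant 29", 1, 5),
    ("Variant 28", 2, 3),
    ("Variant 33", 2, 2),
    ("Variant 31", 1, 3),
    ("Variant 27", 1, 3),
    ("Variant 32", 1, 2),
]

# Edited 27-SNP haplotypes, overlapping families only (808 / 808 equalized)
OVERLAP_SNP_COUNTS: list[tuple[str, int, int]] = [
    ("Variant 1", 373, 102),
    ("Variant 2", 169, 84),
    ("Variant 4", 105, 24),
    ("Variant 3", 44, 72),
    ("Variant 7", 1, 103),
    ("Variant 5", 21, 78),
    ("Variant 8", 11, 70),
    ("Variant 6", 26, 47),
    ("Variant 9", 17, 16),
    ("Variant 11", 2, 30),
    ("Variant 10", 10, 16),
    ("Variant 12", 6, 18),
    ("Variant 13", 2, 20),
    ("Variant 18", 1, 19),
    ("Variant 15", 3, 12),
    ("Variant 17", 1, 11),
    ("Variant 19", 4, 5),
    ("Variant 16", 2, 6),
    ("Variant 28", 2, 1),
    ("Variant 27", 1, 1),
]

# HLA-DR,DQ haplotype groups, overlapping families (1171 / 1171 equalized)
OVERLAP_HLA_COUNTS: list[tuple[str, int, int]] = [
    ("DR4,DQ8", 508, 87),
    ("DR3,DQ2", 416, 133),
    ("DR0405,DQ2", 7, 4),
    ("DR8,DQ4", 30, 26),
    ("DR13,DQ0604", 21, 30),
    ("DR0901,DQ0303", 11, 19),
    ("DR1,DQ0501", 72, 132),
    ("DR16,DQ0502", 13, 25),
    ("DR4,DQ7", 27, 68),
    ("DR7,DQ2", 31, 118),
    ("DR13,DQ0603", 8, 77),
    ("DR11,DQ0301", 12, 132),
    ("DR12,DQ0301", 1, 17),
    ("DR14,DQ0503", 1, 30),
    ("DR15,DQ0602", 1, 166),
    ("DR0701,DQ0303", 0, 49),
]
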