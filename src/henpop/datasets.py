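"""Reference design of the four-breed laying-hen NPY candidate-gene study.

These tables define the study structure the package targets and the defaults
the simulator emulates: 117 hens across four breeds — Pradu Hang Dum (PH,
n=59), Chee (C, n=20), black-bone (BB, n=20) and commercial Hy-Line Brown
layers (LC, n=18) — genotyped at seven biallelic SNPs in the NPY coding
region, with eight egg-production traits recorded over a 365-day laying
period.

``GENOTYPE_COUNTS`` holds the published per-breed genotype counts (ref-hom,
het, alt-hom) at each locus; ``TRAIT_BASELINES`` holds the published
per-breed trait means and standard deviations. ``counts_fixture_table``
expands the counts into a full per-sample :class:`~henpop.core_data.GenotypeTable`,
which makes every diversity statistic of the published genotype summary
exactly recomputable.
"""

from __future__ import annotations

from .core_data import GenotypeCall, GenotypeTable, LocusDef, SampleRecord

__all__ = [
    "STUDY_LOCI",
    "BREEDS",
    "BREED_SIZES",
    "GENOTYPE_COUNTS",
    "TRAIT_BASELINES",
    "counts_fixture_table",
]

#: The seven biallelic SNPs of the NPY coding region, named by their 1-based
#: coding-sequence position (g.<pos> <ref>><alt>).
STUDY_LOCI = (
    LocusDef("SNP1", 130, "A", "G"),
    LocusDef("SNP2", 301, "C", "T"),
    LocusDef("SNP3", 389, "G", "A"),
    LocusDef("SNP4", 404, "G", "T"),
    LocusDef("SNP5", 427, "G", "A"),
    LocusDef("SNP6", 596, "G", "A"),
    LocusDef("SNP7", 647, "G", "T"),
)

BREEDS = ("PH", "C", "BB", "LC")
BREED_SIZES = {"PH": 59, "C": 20, "BB": 20, "LC": 18}

#: Per-breed genotype counts (n_refref, n_refalt, n_altalt) at each locus.
GENOTYPE_COUNTS = {
    ("SNP1", "PH"): (41, 8, 10),
    ("SNP1", "C"): (14, 5, 1),
    ("SNP1", "BB"): (15, 2, 3),
    ("SNP1", "LC"): (11, 2, 5),
    ("SNP2", "PH"): (37, 7, 15),
    ("SNP2", "C"): (10, 7, 3),
    ("SNP2", "BB"): (13, 1, 6),
    ("SNP2", "LC"): (14, 1, 3),
    ("SNP3", "PH"): (27, 9, 23),
    ("SNP3", "C"): (7, 7, 6),
    ("SNP3", "BB"): (7, 2, 11),
    ("SNP3", "LC"): (8, 4, 6),
    ("SNP4", "PH"): (31, 2, 26),
    ("SNP4", "C"): (14, 3, 3),
    ("SNP4", "BB"): (13, 2, 5),
    ("SNP4", "LC"): (10, 4, 4),
    ("SNP5", "PH"): (25, 5, 29),
    ("SNP5", "C"): (6, 7, 7),
    ("SNP5", "BB"): (9, 3, 8),
    ("SNP5", "LC"): (4, 5, 9),
    ("SNP6", "PH"): (21, 11, 27),
    ("SNP6", "C"): (2, 8, 10),
    ("SNP6", "BB"): (1, 4, 15),
    ("SNP6", "LC"): (9, 4, 5),
    ("SNP7", "PH"): (34, 14, 11),
    ("SNP7", "C"): (13, 4, 3),
    ("SNP7", "BB"): (14, 5, 1),
    ("SNP7", "LC"): (10, 7, 1),
}

#: Per-breed (mean, SD) of the eight egg-production traits.
TRAIT_BASELINES = {
    "AFEP": {"PH": (151.89, 9.59), "C": (188.05, 24.14), "BB": (170.60, 12.41), "LC": (140.44, 5.18)},
    "FEW": {"PH": (33.29, 6.07), "C": (35.08, 3.86), "BB": (41.55, 1.05), "LC": (43.77, 7.05)},
    "EW_9M": {"PH": (44.81, 3.10), "C": (41.15, 2.94), "BB": (44.45, 1.09), "LC": (51.48, 6.91)},
    "EW_12M": {"PH": (44.95, 3.06), "C": (43.30, 3.16), "BB": (48.55, 1.05), "LC": (53.50, 6.91)},
    "NE_9M": {"PH": (159.61, 35.49), "C": (55.30, 23.01), "BB": (52.85, 19.59), "LC": (195.61, 15.79)},
    "NE_12M": {"PH": (196.90, 43.32), "C": (73.70, 30.70), "BB": (87.55, 28.78), "LC": (254.44, 14.08)},
    "EperM": {"PH": (16.40, 3.61), "C": (6.14, 2.55), "BB": (7.29, 2.39), "LC": (21.20, 1.17)},
    "EMs": {"PH": (42.63, 9.82), "C": (17.95, 5.76), "BB": (22.06, 6.03), "LC": (60.67, 8.76)},
}


def counts_fixture_table() -> GenotypeTable:
    """Expand the published genotype counts into a per-sample table.

    Within each breed, genotypes at each locus are assigned to samples in
    order (ref-homs first, then heterozygotes, then alt-homs). Loci are
    assigned independently: marginal counts match the published table
    exactly; multi-locus joint genotypes carry no information.
    """
    samples = []
    for breed in BREEDS:
        n = BREED_SIZES[breed]
        for i in range(n):
            samples.append(SampleRecord(f"{breed}{i + 1:03d}", breed, {}))
    offset = {b: sum(BREED_SIZES[x] for x in BREEDS[: BREEDS.index(b)]) for b in BREEDS}
    for locus in STUDY_LOCI:
        for breed in BREEDS:
            rr, ra, aa = GENOTYPE_COUNTS[(locus.locus_id, breed)]
            if rr + ra + aa != BREED_SIZES[breed]:
                raise AssertionError(
                    f"counts for {locus.locus_id}/{breed} do not sum to breed size"
                )
            calls = (
                [GenotypeCall.from_string(locus.ref_allele * 2)] * rr
                + [GenotypeCall.from_string(locus.ref_allele + locus.alt_allele)] * ra
                + [GenotypeCall.from_string(locus.alt_allele * 2)] * aa
            )
            for i, call in enumerate(calls):
                samples[offset[breed] + i].calls[locus.locus_id] = call
    return GenotypeTable(list(STUDY_LOCI), samples)
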