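"""Published summary data from the CDH1 gastric-cancer case-control study.

The study this package models genotyped five CDH1 polymorphisms by direct
sequencing in 107 diffuse-type gastric cancer cases, 60 intestinal-type
cases and 134 healthy controls (Taiwanese Han population) and published
genotype count tables, clinicopathologic comparisons and EM haplotype
frequency tables.  The raw individual-level genotypes were never
deposited, so these printed summaries are the only real-data anchors
available: they serve as fixtures for the single-locus statistics and as
the default frequency pools for the synthetic-data generator.

Haplotype frequency pools are taken from the first three-marker set
(-160C>A, 48+6T>C, 2076C>T), whose printed case and control columns are
internally consistent (margins match the genotype counts to <=0.1%).  The
second set's control column is shipped for odds-ratio arithmetic only:
it sums to ~115% and its ACC entry (16.79) is almost certainly a
misprint, so it is never used to generate data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeCounts, GenotypeDataset, Marker

__all__ = [
    "MARKERS",
    "MARKER_IDS",
    "GENOTYPE_COUNTS",
    "MARKER_SETS",
    "HAPLOTYPE_FREQS_PCT",
    "INDEPENDENT_CONTROL_ALLELE_FREQS",
    "GENDER_2X2",
    "STAGE_2X2",
    "ECADHERIN_2X2",
    "AGE_SUMMARY",
    "GROUP_SIZES",
    "counts_dataset",
]

#: The five CDH1 polymorphisms, in the study's table order.  allele_a is
#: the common allele, allele_b the variant.
MARKERS: list[Marker] = [
    Marker("rs16260", "C", "A", "promoter -160C>A"),
    Marker("rs3743674", "T", "C", "intron 1 48+6T>C"),
    Marker("rs1801552", "C", "T", "exon 13 2076C>T"),
    Marker("rs2276330", "T", "C", "intron 12 1937-13T>C"),
    Marker("rs33964119", "C", "T", "exon 14 2253C>T"),
]

MARKER_IDS = [m.id for m in MARKERS]

GROUP_SIZES = {"diffuse": 107, "intestinal": 60, "control": 134}

#: Published genotype counts (aa, ab, bb) for diffuse cases and controls.
GENOTYPE_COUNTS: dict[str, dict[str, GenotypeCounts]] = {
    "rs16260": {
        "diffuse": GenotypeCounts(48, 44, 15),
        "control": GenotypeCounts(84, 44, 6),
    },
    "rs3743674": {
        "diffuse": GenotypeCounts(71, 32, 4),
        "control": GenotypeCounts(92, 33, 9),
    },
    "rs1801552": {
        "diffuse": GenotypeCounts(45, 48, 14),
        "control": GenotypeCounts(55, 66, 13),
    },
    "rs2276330": {
        "diffuse": GenotypeCounts(89, 18, 0),
        "control": GenotypeCounts(120, 14, 0),
    },
    "rs33964119": {
        "diffuse": GenotypeCounts(89, 17, 1),
        "control": GenotypeCounts(111, 22, 1),
    },
}

#: The four published three-marker haplotype analysis sets.
MARKER_SETS: dict[str, list[str]] = {
    "set1": ["rs16260", "rs3743674", "rs1801552"],   # -160, 48+6, 2076
    "set2": ["rs16260", "rs2276330", "rs33964119"],  # -160, 1937-13, 2253
    "set3": ["rs16260", "rs1801552", "rs33964119"],  # -160, 2076, 2253
    "set4": ["rs16260", "rs3743674", "rs2276330"],   # -160, 48+6, 1937-13
}

#: Published EM haplotype frequencies (percent, as printed) for diffuse
#: cases and controls.  Haplotype strings follow the marker-set order.
HAPLOTYPE_FREQS_PCT: dict[str, dict[str, dict[str, float]]] = {
    "set1": {
        "case": {
            "CTT": 24.70, "ATT": 5.93, "CCC": 12.07, "CTC": 31.78,
            "CCT": 3.80, "ATC": 18.81, "ACC": 2.52, "ACT": 0.38,
        },
        "control": {
            "CTT": 25.0, "ATT": 4.48, "CCC": 13.27, "CTC": 36.38,
            "CCT": 4.48, "ATC": 15.11, "ACC": 0.93, "ACT": 0.37,
        },
    },
    # set2 control column is internally inconsistent as printed (sums to
    # ~115%); retained verbatim for ratio arithmetic, never for simulation.
    "set2": {
        "case": {
            "CTT": 7.72, "ATT": 1.41, "CCC": 3.20, "CTC": 61.22,
            "CCT": 0.21, "ATC": 23.34, "ACC": 2.86, "ACT": 0.04,
        },
        "control": {
            "CTT": 8.02, "ATT": 0.75, "CCC": 3.36, "CTC": 67.53,
            "CCT": 0.19, "ATC": 18.47, "ACC": 16.79, "ACT": 0.0,
        },
    },
}

#: Control variant-allele frequencies for the two markers outside the
#: default haplotype set, from the published control genotype counts
#: (het/2 + hom over samples).
INDEPENDENT_CONTROL_ALLELE_FREQS: dict[str, float] = {
    "rs2276330": (14 / 2 + 0) / 134,
    "rs33964119": (22 / 2 + 1) / 134,
}

#: Clinicopathologic 2x2 tables: rows (intestinal, diffuse), columns as noted.
GENDER_2X2 = ((46, 14), (68, 39))            # male, female
STAGE_2X2 = {                                # this stage, other stages
    "I": ((16, 44), (16, 91)),
    "II": ((8, 52), (24, 83)),
    "III": ((28, 32), (35, 72)),
    "IV": ((8, 52), (32, 75)),
}
ECADHERIN_2X2 = ((32, 28), (93, 14))         # reduced, preserved

#: Age (mean, sd, n) by group.
AGE_SUMMARY = {
    "control": (51.06, 13.04, 134),
    "diffuse": (66.87, 13.81, 107),
    "intestinal": (73.82, 9.76, 60),
}


def counts_dataset() -> GenotypeDataset:
    """A dataset reproducing the published diffuse/control genotype counts.

    Genotypes are assigned marker-wise (the published tables are
    per-marker margins; the joint phase structure is unknowable), so this
    fixture is valid for single-locus statistics only — not for haplotype
    estimation.
    """
    rows = []
    for group, status, subtype in (
        ("diffuse", "case", "diffuse"),
        ("control", "control", "none"),
    ):
        n = GROUP_SIZES[group]
        for i in range(n):
            rows.append((f"{group}{i + 1:03d}", status, subtype, np.nan, None))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "status", "subtype", "age", "sex"]
    )
    genos = np.empty((len(rows), len(MARKERS)), dtype=object)
    offsets = {"diffuse": 0, "control": GROUP_SIZES["diffuse"]}
    for j, marker in enumerate(MARKERS):
        for group, off in offsets.items():
            counts = GENOTYPE_COUNTS[marker.id][group]
            pairs = (
                [(marker.allele_a, marker.allele_a)] * counts.n_aa
                + [(marker.allele_a, marker.allele_b)] * counts.n_ab
                + [(marker.allele_b, marker.allele_b)] * counts.n_bb
            )
            assert len(pairs) == GROUP_SIZES[group]
            for i, pair in enumerate(pairs):
                genos[off + i, j] = pair
    return GenotypeDataset(markers=list(MARKERS), samples=samples, genotypes=genos)
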