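"""Synthetic case-control genotype datasets with known haplotype structure.

The generator draws, for each individual, two haplotypes i.i.d. from the
individual's group-specific frequency pool (Hardy-Weinberg random mating
within group), collapses them to unphased genotypes, and adds covariates
(age ~ truncated Normal, sex ~ Bernoulli) and optional per-call
missingness.  Markers outside the haplotype pool are simulated
independently at fixed variant-allele frequencies, because no joint
distribution across all five study markers was ever published.

:func:`default_scenario` reproduces the study conditions this package was
built around: 107 diffuse-type gastric cancer cases drawn from the
published first-marker-set case haplotype frequencies, 134 controls and
60 intestinal-type cases (a null group) drawn from the control
frequencies, with published group ages/sex ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import studydata
from .genotypes import GenotypeDataset, GenotypeError, Marker

__all__ = ["GroupSpec", "SyntheticScenario", "generate_dataset", "default_scenario"]

MIN_AGE = 18.0  # ages are truncated here (adult study population)


@dataclass(frozen=True)
class GroupSpec:
    """One sampling group: phenotype labels, size, haplotype pool, covariates."""

    label: str
    status: str
    subtype: str
    n_samples: int
    haplotype_frequencies: tuple[float, ...]
    age_mean: float
    age_sd: float
    male_fraction: float

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise GenotypeError("n_samples must be >= 0")
        freqs = np.asarray(self.haplotype_frequencies, dtype=float)
        if (freqs < 0).any():
            raise GenotypeError(f"group {self.label!r}: negative frequency")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise GenotypeError(
                f"group {self.label!r}: haplotype frequencies sum to "
                f"{freqs.sum():.6f}, not 1"
            )
        if not 0.0 <= self.male_fraction <= 1.0:
            raise GenotypeError("male_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticScenario:
    """Full description of a synthetic study.

    ``hap_markers`` (ids, a subset of ``markers``) share a joint haplotype
    pool per group over ``haplotypes`` (allele tuples in hap_marker
    order); every other marker is drawn independently at the
    variant-allele frequency given in ``independent_allele_freqs``.
    """

    markers: tuple[Marker, ...]
    hap_markers: tuple[str, ...]
    haplotypes: tuple[tuple[str, ...], ...]
    group_specs: tuple[GroupSpec, ...]
    independent_allele_freqs: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        marker_ids = [m.id for m in self.markers]
        by_id = {m.id: m for m in self.markers}
        for mid in self.hap_markers:
            if mid not in by_id:
                raise GenotypeError(f"hap marker {mid!r} not among markers")
        for h in self.haplotypes:
            if len(h) != len(self.hap_markers):
                raise GenotypeError(
                    f"haplotype {h} length != {len(self.hap_markers)} hap markers"
                )
            for allele, mid in zip(h, self.hap_markers):
                if allele not in by_id[mid].alleles:
                    raise GenotypeError(
                        f"haplotype {h}: allele {allele!r} invalid for {mid!r}"
                    )
        for g in self.group_specs:
            if len(g.haplotype_frequencies) != len(self.haplotypes):
                raise GenotypeError(
                    f"group {g.label!r}: frequency vector length "
                    f"{len(g.haplotype_frequencies)} != {len(self.haplotypes)} "
                    "haplotypes"
                )
        indep = [m for m in marker_ids if m not in self.hap_markers]
        missing = set(indep) - set(self.independent_allele_freqs)
        if missing:
            raise GenotypeError(
                f"no independent allele frequency for marker(s) {sorted(missing)}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise GenotypeError("missing_rate must be in [0, 1)")


def _truncated_normal(rng, mean, sd, size, lower=MIN_AGE):
    """Normal draws resampled until all exceed ``lower`` (deterministic order)."""
    out = rng.normal(mean, sd, size=size)
    while True:
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def generate_dataset(scenario: SyntheticScenario) -> GenotypeDataset:
    """Draw a :class:`GenotypeDataset` from a scenario, reproducibly.

    All randomness flows from one generator seeded with ``scenario.seed``
    in a fixed draw order (per group: haplotype pairs, independent-marker
    alleles, ages, sexes; then one missingness mask over the whole
    matrix), so identical scenarios give identical datasets.
    """
    rng = np.random.default_rng(scenario.seed)
    markers = list(scenario.markers)
    marker_pos = {m.id: j for j, m in enumerate(markers)}
    hap_cols = [marker_pos[mid] for mid in scenario.hap_markers]
    indep = [m for m in markers if m.id not in scenario.hap_markers]
    rows = []
    n_total = sum(g.n_samples for g in scenario.group_specs)
    genos = np.empty((n_total, len(markers)), dtype=object)
    i0 = 0
    for g in scenario.group_specs:
        n = g.n_samples
        freqs = np.asarray(g.haplotype_frequencies, dtype=float)
        hap_idx = rng.choice(len(scenario.haplotypes), size=(n, 2), p=freqs)
        for i in range(n):
            h1 = scenario.haplotypes[hap_idx[i, 0]]
            h2 = scenario.haplotypes[hap_idx[i, 1]]
            for k, j in enumerate(hap_cols):
                genos[i0 + i, j] = markers[j].normalize_pair((h1[k], h2[k]))
        for m in indep:
            q = scenario.independent_allele_freqs[m.id]
            dosage = rng.binomial(1, q, size=(n, 2))
            j = marker_pos[m.id]
            for i in range(n):
                pair = tuple(
                    m.allele_b if d else m.allele_a for d in dosage[i]
                )
                genos[i0 + i, j] = m.normalize_pair(pair)
        ages = _truncated_normal(rng, g.age_mean, g.age_sd, n)
        males = rng.random(n) < g.male_fraction
        for i in range(n):
            rows.append(
                (
                    f"{g.label}{i + 1:04d}",
                    g.status,
                    g.subtype,
                    float(np.round(ages[i], 1)),
                    "M" if males[i] else "F",
                )
            )
        i0 += n
    if scenario.missing_rate > 0:
        mask = rng.random(genos.shape) < scenario.missing_rate
        genos[mask] = None
    samples = pd.DataFrame(
        rows, columns=["sample_id", "status", "subtype", "age", "sex"]
    )
    return GenotypeDataset(markers=markers, samples=samples, genotypes=genos)


def default_scenario(
    seed: int = 0,
    n_diffuse: int | None = None,
    n_intestinal: int | None = None,
    n_control: int | None = None,
    missing_rate: float = 0.0,
) -> SyntheticScenario:
    """The shipped study-emulation scenario.

    Five CDH1 markers; the first three (-160C>A, 48+6T>C, 2076C>T) share
    the published first-set haplotype pools — diffuse cases draw from the
    case pool, controls and intestinal cases (the null group, for which no
    separate pool was published) from the control pool.  Each printed
    percentage column is renormalised to sum exactly to 1.  The remaining
    two markers are drawn independently at the published control
    variant-allele frequencies for every group (a documented
    simplification: no five-locus joint distribution exists to copy).
    Ages and sex ratios follow the published group summaries.  Group sizes
    default to the study's 107/60/134 and can be overridden (e.g. inflated
    for parameter-recovery checks).
    """
    hap_markers = tuple(studydata.MARKER_SETS["set1"])
    freq_tab = studydata.HAPLOTYPE_FREQS_PCT["set1"]
    hap_strings = sorted(freq_tab["case"])

    def pool(which: str) -> tuple[float, ...]:
        v = np.array([freq_tab[which][h] for h in hap_strings], dtype=float)
        return tuple(v / v.sum())

    case_pool, control_pool = pool("case"), pool("control")
    ages = studydata.AGE_SUMMARY
    sizes = studydata.GROUP_SIZES
    groups = (
        GroupSpec(
            "diffuse", "case", "diffuse",
            sizes["diffuse"] if n_diffuse is None else n_diffuse,
            case_pool, ages["diffuse"][0], ages["diffuse"][1], 68 / 107,
        ),
        GroupSpec(
            "intestinal", "case", "intestinal",
            sizes["intestinal"] if n_intestinal is None else n_intestinal,
            control_pool, ages["intestinal"][0], ages["intestinal"][1], 46 / 60,
        ),
        GroupSpec(
            "control", "control", "none",
            sizes["control"] if n_control is None else n_control,
            control_pool, ages["control"][0], ages["control"][1], 86 / 134,
        ),
    )
    return SyntheticScenario(
        markers=tuple(studydata.MARKERS),
        hap_markers=hap_markers,
        haplotypes=tuple(tuple(h) for h in hap_strings),
        group_specs=groups,
        independent_allele_freqs=dict(studydata.INDEPENDENT_CONTROL_ALLELE_FREQS),
        missing_rate=missing_rate,
        seed=seed,
    )
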