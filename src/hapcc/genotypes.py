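"""Data model for unphased case-control SNP genotype data.

A :class:`GenotypeDataset` holds an ordered list of biallelic markers, a
sample table (case/control status, histologic subtype, age, sex) and a
samples x markers matrix of unphased genotypes.  Genotypes are stored as
unordered allele pairs (``("C", "A")`` normalised so the reference allele
sorts first) rather than 0/1/2 dosages, so heterozygote identity stays
explicit; dosages are derived on demand.

Readers are provided for a simple delimited genotype table (the package's
native format), minimal VCF (GT field only, via pysam) and PED/MAP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeError",
    "Marker",
    "GenotypeCounts",
    "GenotypeDataset",
    "parse_genotype_table",
    "write_dataset",
    "read_vcf_minimal",
    "read_ped",
    "genotype_counts",
    "stratum_mask",
]

#: Strings accepted as a missing genotype / covariate in delimited input.
MISSING_SENTINELS = frozenset({"NA", "", "--", "."})

VALID_STATUS = ("case", "control")
VALID_SUBTYPE = ("diffuse", "intestinal", "none")

#: Named stratum shorthands usable wherever a selector is expected.
STRATUM_ALIASES: Mapping[str, dict] = {
    "all": {},
    "cases": {"status": "case"},
    "controls": {"status": "control"},
    "diffuse": {"status": "case", "subtype": "diffuse"},
    "intestinal": {"status": "case", "subtype": "intestinal"},
}


class GenotypeError(ValueError):
    """Raised on malformed genotype input or invalid dataset operations."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP: two nominal allele symbols plus a free-text label.

    ``allele_a`` is the reference/common symbol (e.g. ``C``), ``allele_b``
    the variant (e.g. ``A``).  Symbols are nominal labels: no strand
    flipping or complementing is ever applied.
    """

    id: str
    allele_a: str
    allele_b: str
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.allele_a) != 1 or len(self.allele_b) != 1:
            raise GenotypeError(
                f"marker {self.id!r}: allele symbols must be single characters"
            )
        if self.allele_a == self.allele_b:
            raise GenotypeError(f"marker {self.id!r}: alleles must differ")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    def normalize(self, raw: str | None) -> tuple[str, str] | None:
        """Normalise a raw two-character genotype string to an unordered pair.

        ``"CA"`` and ``"AC"`` map to the same stored value; missing
        sentinels map to ``None``.
        """
        if raw is None:
            return None
        raw = raw.strip()
        if raw in MISSING_SENTINELS:
            return None
        if len(raw) != 2:
            raise GenotypeError(
                f"marker {self.id!r}: genotype string {raw!r} is not two characters"
            )
        pair = (raw[0], raw[1])
        for allele in pair:
            if allele not in self.alleles:
                raise GenotypeError(
                    f"marker {self.id!r}: unknown allele {allele!r} in genotype {raw!r}"
                )
        return self.normalize_pair(pair)

    def normalize_pair(self, pair: tuple[str, str]) -> tuple[str, str]:
        """Order an allele pair so ``allele_a`` sorts before ``allele_b``."""
        a, b = pair
        if a == self.allele_b and b == self.allele_a:
            return (b, a)
        return (a, b)

    def genotype_string(self, pair: tuple[str, str] | None) -> str:
        return "NA" if pair is None else pair[0] + pair[1]

    def dosage(self, pair: tuple[str, str] | None) -> int:
        """Count of ``allele_b`` copies (-1 for missing)."""
        if pair is None:
            return -1
        return (pair[0] == self.allele_b) + (pair[1] == self.allele_b)

    def category(self, pair: tuple[str, str] | None) -> str | None:
        """Genotype category key: ``aa``, ``ab`` or ``bb`` (None if missing)."""
        d = self.dosage(pair)
        return None if d < 0 else ("aa", "ab", "bb")[d]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one marker in one stratum.

    ``n_aa``/``n_ab``/``n_bb`` count allele_a homozygotes, heterozygotes and
    allele_b homozygotes among non-missing samples; ``n_missing`` the rest.
    """

    n_aa: int
    n_ab: int
    n_bb: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_aa, self.n_ab, self.n_bb, self.n_missing) < 0:
            raise GenotypeError("genotype counts must be non-negative")

    @property
    def n_typed(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    def get(self, category: str) -> int:
        try:
            return {"aa": self.n_aa, "ab": self.n_ab, "bb": self.n_bb}[category]
        except KeyError:
            raise GenotypeError(f"unknown genotype category {category!r}") from None

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_aa, self.n_ab, self.n_bb)

    def fractions(self) -> tuple[float, float, float]:
        n = self.n_typed
        if n == 0:
            raise GenotypeError("no typed samples")
        return (self.n_aa / n, self.n_ab / n, self.n_bb / n)


SAMPLE_COLUMNS = ["sample_id", "status", "subtype", "age", "sex"]


@dataclass
class GenotypeDataset:
    """Samples x markers unphased genotype matrix with phenotype/covariates.

    ``samples`` is a DataFrame with columns sample_id, status
    (case/control), subtype (diffuse/intestinal/none), age (float years,
    NaN if missing) and sex ('M'/'F'/None).  ``genotypes`` is an object
    array of normalised allele pairs or None.
    """

    markers: list[Marker]
    samples: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=object)
        if self.genotypes.ndim != 2 or self.genotypes.shape != (
            len(self.samples),
            len(self.markers),
        ):
            raise GenotypeError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if list(self.samples.columns) != SAMPLE_COLUMNS:
            raise GenotypeError(f"sample table must have columns {SAMPLE_COLUMNS}")
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise GenotypeError(f"duplicate sample_id {dup!r}")
        marker_ids = [m.id for m in self.markers]
        if len(set(marker_ids)) != len(marker_ids):
            raise GenotypeError("marker ids must be unique")
        bad_status = set(self.samples["status"]) - set(VALID_STATUS)
        if bad_status:
            raise GenotypeError(f"invalid status value(s) {sorted(bad_status)}")
        bad_sub = set(self.samples["subtype"]) - set(VALID_SUBTYPE)
        if bad_sub:
            raise GenotypeError(f"invalid subtype value(s) {sorted(bad_sub)}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise GenotypeError(f"unknown marker {marker_id!r}") from None

    def marker(self, marker_id: str) -> Marker:
        return self.markers[self.marker_index(marker_id)]

    def dosages(self, marker_id: str) -> np.ndarray:
        """Vector of allele_b dosages (0/1/2, -1 missing) for one marker."""
        j = self.marker_index(marker_id)
        m = self.markers[j]
        return np.array([m.dosage(g) for g in self.genotypes[:, j]], dtype=int)

    def subset(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            markers=list(self.markers),
            samples=self.samples.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[mask, :].copy(),
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        if [m for m in self.markers] != [m for m in other.markers]:
            return False
        a, b = self.samples, other.samples
        if len(a) != len(b):
            return False
        same_meta = (
            a["sample_id"].tolist() == b["sample_id"].tolist()
            and a["status"].tolist() == b["status"].tolist()
            and a["subtype"].tolist() == b["subtype"].tolist()
            and a["sex"].tolist() == b["sex"].tolist()
            and np.allclose(
                a["age"].to_numpy(dtype=float),
                b["age"].to_numpy(dtype=float),
                equal_nan=True,
            )
        )
        return bool(
            same_meta and (self.genotypes == other.genotypes).all()
        )


def stratum_mask(dataset: GenotypeDataset, stratum) -> np.ndarray:
    """Boolean mask selecting a stratum by status and/or subtype.

    ``stratum`` may be None / ``"all"``, a named alias (``"diffuse"``,
    ``"intestinal"``, ``"cases"``, ``"controls"``) or a dict with keys
    ``status`` and/or ``subtype``.
    """
    if stratum is None:
        spec: Mapping = {}
    elif isinstance(stratum, str):
        try:
            spec = STRATUM_ALIASES[stratum]
        except KeyError:
            raise GenotypeError(
                f"unknown stratum alias {stratum!r}; "
                f"known: {sorted(STRATUM_ALIASES)}"
            ) from None
    elif isinstance(stratum, Mapping):
        unknown = set(stratum) - {"status", "subtype"}
        if unknown:
            raise GenotypeError(f"unknown stratum keys {sorted(unknown)}")
        spec = stratum
    else:
        raise GenotypeError(f"cannot interpret stratum {stratum!r}")
    mask = np.ones(dataset.n_samples, dtype=bool)
    if "status" in spec:
        mask &= (dataset.samples["status"] == spec["status"]).to_numpy()
    if "subtype" in spec:
        mask &= (dataset.samples["subtype"] == spec["subtype"]).to_numpy()
    return mask


def genotype_counts(
    dataset: GenotypeDataset, marker_id: str, stratum=None
) -> GenotypeCounts:
    """Count aa/ab/bb genotypes for one marker within a stratum.

    An empty stratum (no samples at all) raises; a stratum where every
    genotype is missing returns (0, 0, 0) with ``n_missing`` equal to the
    stratum size.
    """
    mask = stratum_mask(dataset, stratum)
    if not mask.any():
        raise GenotypeError(f"empty stratum {stratum!r}: no samples selected")
    j = dataset.marker_index(marker_id)
    marker = dataset.markers[j]
    tallies = {"aa": 0, "ab": 0, "bb": 0}
    missing = 0
    for g in dataset.genotypes[mask, j]:
        cat = marker.category(g)
        if cat is None:
            missing += 1
        else:
            tallies[cat] += 1
    return GenotypeCounts(tallies["aa"], tallies["ab"], tallies["bb"], missing)


# -- delimited genotype table -------------------------------------------


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def parse_genotype_table(path, marker_spec: Sequence[Marker]) -> GenotypeDataset:
    """Read the package's delimited genotype table.

    Expected header: ``sample_id,status,subtype,age,sex`` followed by one
    column per marker (ids matching ``marker_spec`` in order).  Genotype
    cells are two-character allele strings (``CA`` == ``AC``) or a missing
    sentinel (``NA``, ``--`` or empty).  Tab or comma delimited,
    auto-detected from the header line.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise GenotypeError(f"{path}: empty file")
    sep = _detect_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(sep)]
    expected = SAMPLE_COLUMNS + [m.id for m in marker_spec]
    if header != expected:
        raise GenotypeError(
            f"{path}: header {header} does not match expected columns {expected}"
        )
    markers = list(marker_spec)
    rows, genos = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) != len(expected):
            raise GenotypeError(
                f"{path}:{lineno}: expected {len(expected)} fields, got {len(fields)}"
            )
        sid, status, subtype, age_s, sex_s = fields[:5]
        if status not in VALID_STATUS:
            raise GenotypeError(f"{path}:{lineno}: invalid status {status!r}")
        if subtype in MISSING_SENTINELS:
            subtype = "none"
        if subtype not in VALID_SUBTYPE:
            raise GenotypeError(f"{path}:{lineno}: invalid subtype {subtype!r}")
        age = np.nan if age_s in MISSING_SENTINELS else float(age_s)
        sex = None if sex_s in MISSING_SENTINELS else sex_s
        if sex not in (None, "M", "F"):
            raise GenotypeError(f"{path}:{lineno}: invalid sex {sex_s!r}")
        row_genos = []
        for marker, cell in zip(markers, fields[5:]):
            try:
                row_genos.append(marker.normalize(cell))
            except GenotypeError as exc:
                raise GenotypeError(f"{path}: sample {sid!r}: {exc}") from None
        rows.append((sid, status, subtype, age, sex))
        genos.append(row_genos)
    samples = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    geno_arr = np.empty((len(rows), len(markers)), dtype=object)
    for i, row in enumerate(genos):
        geno_arr[i, :] = row
    return GenotypeDataset(markers=markers, samples=samples, genotypes=geno_arr)


def write_dataset(dataset: GenotypeDataset, path, sep: str = "\t") -> None:
    """Write the delimited genotype table (deterministic column order)."""
    lines = [sep.join(SAMPLE_COLUMNS + dataset.marker_ids)]
    for i in range(dataset.n_samples):
        row = dataset.samples.iloc[i]
        age = "NA" if pd.isna(row["age"]) else format(float(row["age"]), "g")
        sex = "NA" if row["sex"] is None or pd.isna(row["sex"]) else str(row["sex"])
        fields = [str(row["sample_id"]), row["status"], row["subtype"], age, sex]
        fields += [
            m.genotype_string(g)
            for m, g in zip(dataset.markers, dataset.genotypes[i, :])
        ]
        lines.append(sep.join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# -- VCF / PED readers ---------------------------------------------------


def read_vcf_minimal(path, permissive: bool = False) -> GenotypeDataset:
    """Read biallelic SNP genotypes from a VCF (GT field only).

    Markers are named ``CHROM:POS:REF:ALT``; phase separators are accepted
    but phase is discarded; ``./.`` becomes missing.  Phenotype and
    covariates are not part of VCF, so samples default to
    status=control/subtype=none; attach real phenotypes afterwards.
    Multi-allelic or non-SNP records raise unless ``permissive`` (then they
    are skipped with a warning).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        markers: list[Marker] = []
        columns: list[list] = []
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                msg = (
                    f"{path}: record {rec.chrom}:{rec.pos} is not a biallelic SNP "
                    f"(REF={rec.ref}, ALT={','.join(alts) or '.'})"
                )
                if permissive:
                    warnings.warn(msg + "; skipped", stacklevel=2)
                    continue
                raise GenotypeError(msg)
            ref, alt = rec.ref, alts[0]
            marker = Marker(
                id=f"{rec.chrom}:{rec.pos}:{ref}:{alt}",
                allele_a=ref,
                allele_b=alt,
                label=rec.id or "",
            )
            col = []
            for sid in sample_ids:
                sample = rec.samples[sid]
                if "GT" not in sample:
                    raise GenotypeError(
                        f"{path}: record {rec.chrom}:{rec.pos} sample {sid!r} "
                        "has no GT field"
                    )
                gt = sample["GT"]
                if gt is None or any(a is None for a in gt):
                    col.append(None)
                    continue
                if len(gt) != 2 or any(a not in (0, 1) for a in gt):
                    raise GenotypeError(
                        f"{path}: record {rec.chrom}:{rec.pos} sample {sid!r}: "
                        f"unsupported GT {gt!r}"
                    )
                pair = tuple((ref, alt)[a] for a in gt)
                col.append(marker.normalize_pair(pair))
            markers.append(marker)
            columns.append(col)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": "control",
            "subtype": "none",
            "age": np.nan,
            "sex": None,
        }
    )
    genos = np.empty((len(sample_ids), len(markers)), dtype=object)
    for j, col in enumerate(columns):
        genos[:, j] = col
    return GenotypeDataset(markers=markers, samples=samples, genotypes=genos)


def read_ped(ped_path, map_path, marker_spec: Sequence[Marker]) -> GenotypeDataset:
    """Read PED/MAP genotypes (two allele columns per marker, 0 = missing).

    The MAP file supplies marker ids, matched against ``marker_spec`` for
    allele validation.  PED phenotype column: 2 = case, anything else
    control; sex column: 1 = M, 2 = F, else missing.
    """
    spec_by_id = {m.id: m for m in marker_spec}
    map_markers = []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split()
        mid = fields[1]
        if mid not in spec_by_id:
            raise GenotypeError(f"{map_path}: marker {mid!r} not in marker spec")
        map_markers.append(spec_by_id[mid])
    rows, genos = [], []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * len(map_markers):
            raise GenotypeError(
                f"{ped_path}:{lineno}: expected {6 + 2 * len(map_markers)} fields"
            )
        _, iid, _, _, sex_s, pheno = fields[:6]
        sex = {"1": "M", "2": "F"}.get(sex_s)
        status = "case" if pheno == "2" else "control"
        row_genos = []
        for k, marker in enumerate(map_markers):
            a1, a2 = fields[6 + 2 * k], fields[6 + 2 * k + 1]
            if a1 == "0" or a2 == "0":
                row_genos.append(None)
                continue
            for allele in (a1, a2):
                if allele not in marker.alleles:
                    raise GenotypeError(
                        f"{ped_path}: sample {iid!r}: marker {marker.id!r}: "
                        f"unknown allele {allele!r}"
                    )
            row_genos.append(marker.normalize_pair((a1, a2)))
        rows.append((iid, status, "none", np.nan, sex))
        genos.append(row_genos)
    samples = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    geno_arr = np.empty((len(rows), len(map_markers)), dtype=object)
    for i, row in enumerate(genos):
        geno_arr[i, :] = row
    return GenotypeDataset(markers=map_markers, samples=samples, genotypes=geno_arr)
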