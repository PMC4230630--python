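"""Full-study orchestration: single-locus tables, haplotype tables, manifest.

``run_full_study`` replays the whole analysis design on one dataset:
a clinicopathologic comparison between the two case subtypes, a
per-marker single-locus association table for each case-vs-control
stratum pair, and a per-marker-set haplotype association table, all
written as TSV with a JSON run manifest.  Identical config + input give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__, studydata
from .genotypes import (
    GenotypeDataset,
    GenotypeError,
    genotype_counts,
    parse_genotype_table,
    stratum_mask,
    write_dataset,
)
from .haplotype_em import global_haplotype_lrt
from .single_locus import (
    allele_frequency,
    compare_groups,
    crude_genotype_or,
    fisher_freeman_halton,
    genotype_association_chi2,
    hwe_test,
)
from .synthetic_data import default_scenario, generate_dataset

__all__ = ["StudyConfig", "run_full_study"]

DEFAULT_STRATA = (("diffuse", "controls"), ("intestinal", "controls"))


def _fmt(x, nd: int) -> str:
    """Fixed-precision float formatting; dash for undefined values."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "-"
    return f"{x:.{nd}f}"


@dataclass
class StudyConfig:
    """Configuration for :func:`run_full_study`.

    Exactly one of ``input_path`` (delimited genotype table over the five
    study markers) or ``use_default_scenario`` must be set.  ``seed``
    drives both the synthetic scenario (if used) and the EM restarts.
    """

    out_dir: str = "hapcc_out"
    input_path: str | None = None
    use_default_scenario: bool = False
    seed: int = 0
    missing_rate: float = 0.0
    marker_sets: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in studydata.MARKER_SETS.items()}
    )
    strata: list[tuple[str, str]] = field(
        default_factory=lambda: [list(p) for p in DEFAULT_STRATA]
    )
    em_tol: float = 1e-8
    em_max_iter: int = 10000
    em_restarts: int = 10
    em_min_freq: float = 1e-4

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise GenotypeError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def validate(self, dataset: GenotypeDataset) -> None:
        if not self.marker_sets:
            raise GenotypeError("config: marker_sets must not be empty")
        known = set(dataset.marker_ids)
        for name, mids in self.marker_sets.items():
            if not mids:
                raise GenotypeError(f"config: marker set {name!r} is empty")
            missing = set(mids) - known
            if missing:
                raise GenotypeError(
                    f"config: marker set {name!r} references unknown "
                    f"marker(s) {sorted(missing)}"
                )
        if not self.strata:
            raise GenotypeError("config: strata must not be empty")


def _load_dataset(config: StudyConfig) -> GenotypeDataset:
    if (config.input_path is None) == (not config.use_default_scenario):
        raise GenotypeError(
            "config: set exactly one of input_path / use_default_scenario"
        )
    if config.input_path is not None:
        return parse_genotype_table(config.input_path, studydata.MARKERS)
    scenario = default_scenario(seed=config.seed, missing_rate=config.missing_rate)
    return generate_dataset(scenario)


def _group_comparison_rows(dataset: GenotypeDataset) -> list[list[str]]:
    rows = [["characteristic", "intestinal", "diffuse", "statistic", "p_value",
             "method"]]
    intest = dataset.samples[stratum_mask(dataset, "intestinal")]
    diff = dataset.samples[stratum_mask(dataset, "diffuse")]
    if len(intest) == 0 or len(diff) == 0:
        return rows
    tab = [
        [(intest["sex"] == "M").sum(), (intest["sex"] == "F").sum()],
        [(diff["sex"] == "M").sum(), (diff["sex"] == "F").sum()],
    ]
    res = compare_groups(tab, "chi2_2x2")
    rows.append(
        ["male_sex", f"{tab[0][0]}/{len(intest)}", f"{tab[1][0]}/{len(diff)}",
         _fmt(res.statistic, 4), _fmt(res.p_value, 4), res.method]
    )
    a1 = intest["age"].dropna().to_numpy(dtype=float)
    a2 = diff["age"].dropna().to_numpy(dtype=float)
    if len(a1) > 1 and len(a2) > 1:
        res = compare_groups((a1, a2), "welch_t")
        rows.append(
            ["age_years", f"{a1.mean():.2f}±{a1.std(ddof=1):.2f}",
             f"{a2.mean():.2f}±{a2.std(ddof=1):.2f}",
             _fmt(res.statistic, 4), _fmt(res.p_value, 4), res.method]
        )
    return rows


def _single_locus_rows(
    dataset: GenotypeDataset, case_stratum: str, control_stratum: str
) -> list[list[str]]:
    header = [
        "marker", "label",
        "case_aa", "case_ab", "case_bb", "ctrl_aa", "ctrl_ab", "ctrl_bb",
        "case_b_freq", "ctrl_b_freq",
        "chi2", "chi2_df", "chi2_p", "fisher_p",
        "or_ab", "or_ab_ci_low", "or_ab_ci_high",
        "or_bb", "or_bb_ci_low", "or_bb_ci_high",
        "hwe_case_p", "hwe_ctrl_p",
    ]
    rows = [header]
    for marker in dataset.markers:
        cc = genotype_counts(dataset, marker.id, case_stratum)
        tc = genotype_counts(dataset, marker.id, control_stratum)
        chi = genotype_association_chi2(cc, tc)
        fis = fisher_freeman_halton(
            [cc.as_tuple(), tc.as_tuple()]
        )
        or_ab = crude_genotype_or(cc, tc, "ab", "aa")
        or_bb = crude_genotype_or(cc, tc, "bb", "aa")
        rows.append(
            [
                marker.id, marker.label,
                *(str(v) for v in cc.as_tuple()),
                *(str(v) for v in tc.as_tuple()),
                _fmt(allele_frequency(cc), 4), _fmt(allele_frequency(tc), 4),
                _fmt(chi.statistic, 4), str(chi.df), _fmt(chi.p_value, 4),
                _fmt(fis.p_value, 4),
                _fmt(or_ab.estimate, 3), _fmt(or_ab.ci_low, 3),
                _fmt(or_ab.ci_high, 3),
                _fmt(or_bb.estimate, 3), _fmt(or_bb.ci_low, 3),
                _fmt(or_bb.ci_high, 3),
                _fmt(hwe_test(cc, "chi2").p_value, 4),
                _fmt(hwe_test(tc, "chi2").p_value, 4),
            ]
        )
    return rows


def _haplotype_rows(
    dataset: GenotypeDataset,
    set_name: str,
    marker_ids: Sequence[str],
    case_stratum: str,
    control_stratum: str,
    config: StudyConfig,
) -> list[list[str]]:
    res = global_haplotype_lrt(
        dataset, marker_ids, case_stratum, control_stratum,
        tol=config.em_tol, max_iter=config.em_max_iter,
        n_restarts=config.em_restarts, seed=config.seed,
        min_freq=config.em_min_freq,
    )
    rows = [[
        "marker_set", "haplotype", "case_pct", "control_pct",
        "OR", "ci_low", "ci_high", "reference",
        "global_statistic", "global_df", "global_p", "method",
    ]]
    order = np.argsort(
        [-(r.case_freq + r.control_freq) for r in res.per_haplotype]
    )
    for k in order:
        r = res.per_haplotype[k]
        is_ref = r.haplotype == res.reference
        rows.append(
            [
                set_name, "".join(r.haplotype),
                _fmt(100 * r.case_freq, 2), _fmt(100 * r.control_freq, 2),
                "1" if is_ref else _fmt(r.odds_ratio.estimate, 3),
                "-" if is_ref else _fmt(r.odds_ratio.ci_low, 3),
                "-" if is_ref else _fmt(r.odds_ratio.ci_high, 3),
                "".join(res.reference),
                _fmt(res.global_statistic, 4), str(res.global_df),
                _fmt(res.global_p, 4), res.method,
            ]
        )
    return rows


def _write_tsv(path: Path, rows: list[list[str]]) -> None:
    path.write_text("\n".join("\t".join(r) for r in rows) + "\n")


def run_full_study(config: StudyConfig) -> dict:
    """Run the complete analysis; returns the manifest dict.

    Writes into ``config.out_dir``: ``dataset.tsv`` (when simulated),
    ``group_comparison.tsv``, one ``single_locus_*.tsv`` and a set of
    ``haplotypes_*.tsv`` per stratum pair, and ``manifest.json``.  Partial
    outputs are removed if any stage fails.
    """
    dataset = _load_dataset(config)
    config.validate(dataset)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if config.use_default_scenario:
            p = out_dir / "dataset.tsv"
            write_dataset(dataset, p)
            written.append(p)
        p = out_dir / "group_comparison.tsv"
        _write_tsv(p, _group_comparison_rows(dataset))
        written.append(p)
        for case_stratum, control_stratum in config.strata:
            tag = f"{case_stratum}_vs_{control_stratum}"
            try:
                p = out_dir / f"single_locus_{tag}.tsv"
                _write_tsv(
                    p, _single_locus_rows(dataset, case_stratum, control_stratum)
                )
                written.append(p)
                for set_name, mids in sorted(config.marker_sets.items()):
                    p = out_dir / f"haplotypes_{set_name}_{tag}.tsv"
                    _write_tsv(
                        p,
                        _haplotype_rows(
                            dataset, set_name, mids,
                            case_stratum, control_stratum, config,
                        ),
                    )
                    written.append(p)
            except GenotypeError as exc:
                raise GenotypeError(f"stratum pair {tag}: {exc}") from exc
        manifest = {
            "hapcc_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "input": config.input_path or "default_scenario",
            "n_samples": dataset.n_samples,
            "markers": dataset.marker_ids,
            "marker_sets": {k: list(v) for k, v in sorted(config.marker_sets.items())},
            "strata": [list(p) for p in config.strata],
            "options": {
                "em_tol": config.em_tol,
                "em_max_iter": config.em_max_iter,
                "em_restarts": config.em_restarts,
                "em_min_freq": config.em_min_freq,
                "missing_rate": config.missing_rate,
            },
            "outputs": sorted(str(p.name) for p in written),
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
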