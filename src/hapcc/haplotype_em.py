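"""EM haplotype-frequency estimation and haplotype association tests.

An individual genotyped at several biallelic loci but heterozygous at k of
them is consistent with 2^(k-1) unordered haplotype pairs (diplotypes).
Under random mating the observed multilocus genotypes follow a multinomial
mixture with likelihood

    L(f) = prod_i sum_{(h1,h2) ~ g_i} c * f(h1) * f(h2)

(c = 2 for heterozygous pairs, 1 for homozygous).  ``em_estimate``
maximises L by expectation-maximisation: the E-step weights each
compatible pair by its posterior probability, the M-step re-estimates
frequencies from expected haplotype counts.  The EM trajectory preserves
the per-marker allele frequencies at every iteration, because every
compatible pair of an individual carries exactly that individual's
alleles.

On top of the frequency estimates the module provides per-haplotype odds
ratios against a reference haplotype, a global case-control
likelihood-ratio test (separate vs pooled fits), a label-permutation
version of the global test, and pairwise linkage disequilibrium
(D, D', r^2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .genotypes import GenotypeDataset, GenotypeError, stratum_mask
from .single_locus import OddsRatioResult, Z_95

__all__ = [
    "Haplotype",
    "HaplotypeTable",
    "EMResult",
    "HaplotypeAssociationResult",
    "LDResult",
    "enumerate_diplotypes",
    "em_estimate",
    "haplotype_or_table",
    "global_haplotype_lrt",
    "permutation_global_test",
    "ld_pairwise",
]

Haplotype = tuple  # ordered tuple of allele symbols, one per analysis marker

#: Individuals heterozygous at more than this many loci are rejected
#: (2^(k-1) pairs each; this package targets small candidate-gene panels).
MAX_HET_LOCI = 12


@dataclass
class HaplotypeTable:
    """Haplotype frequency vector over 2N chromosomes.

    ``rare`` flags haplotypes whose estimated frequency fell below the
    reporting threshold; they are kept in the output (never silently
    dropped) but excluded from df counting in the global test.
    """

    haplotypes: list[Haplotype]
    frequencies: np.ndarray
    n_chromosomes: int
    rare: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.haplotypes) != len(self.frequencies):
            raise GenotypeError("haplotype/frequency length mismatch")
        if (self.frequencies < -1e-12).any():
            raise GenotypeError("negative haplotype frequency")
        if self.frequencies.size and abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise GenotypeError("haplotype frequencies must sum to 1")

    def frequency_of(self, hap: Haplotype) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(tuple(hap))])
        except ValueError:
            return 0.0

    def marker_margin(self, locus: int, allele: str) -> float:
        """Marginal frequency of ``allele`` at position ``locus``."""
        sel = [h[locus] == allele for h in self.haplotypes]
        return float(self.frequencies[np.array(sel, dtype=bool)].sum())


@dataclass
class EMResult:
    table: HaplotypeTable
    log_likelihood: float
    ll_trace: np.ndarray
    n_iterations: int
    converged: bool
    n_restarts: int
    best_restart: int


class HaplotypeOR(NamedTuple):
    haplotype: Haplotype
    case_freq: float
    control_freq: float
    odds_ratio: OddsRatioResult


@dataclass
class HaplotypeAssociationResult:
    per_haplotype: list[HaplotypeOR]
    reference: Haplotype
    global_statistic: float | None = None
    global_df: int | None = None
    global_p: float | None = None
    method: str = "lrt"


class LDResult(NamedTuple):
    """Pairwise linkage disequilibrium; all None if a marker is monomorphic."""

    d: float | None
    d_prime: float | None
    r_squared: float | None


# -- diplotype expansion -------------------------------------------------


def enumerate_diplotypes(genotype: Sequence[tuple[str, str]]):
    """All unordered haplotype pairs consistent with a multilocus genotype.

    Returns a list of ``(h1, h2, is_het)`` with h1 <= h2; a genotype
    heterozygous at k loci yields 2^(k-1) pairs (1 pair if k <= 1).
    Missing genotypes must be filtered by the caller.
    """
    if any(g is None for g in genotype):
        raise GenotypeError("enumerate_diplotypes: missing genotype; filter first")
    het_loci = [i for i, (a, b) in enumerate(genotype) if a != b]
    if len(het_loci) > MAX_HET_LOCI:
        raise GenotypeError(
            f"genotype heterozygous at {len(het_loci)} loci exceeds the "
            f"supported maximum of {MAX_HET_LOCI}"
        )
    base1 = [g[0] for g in genotype]
    base2 = [g[1] for g in genotype]
    if not het_loci:
        h = tuple(base1)
        return [(h, h, False)]
    # fix the first heterozygous locus to break the h1/h2 symmetry
    free = het_loci[1:]
    pairs = []
    for flips in itertools.product((False, True), repeat=len(free)):
        h1, h2 = list(base1), list(base2)
        for locus, flip in zip(free, flips):
            if flip:
                h1[locus], h2[locus] = h2[locus], h1[locus]
        t1, t2 = tuple(h1), tuple(h2)
        pairs.append((t1, t2, True) if t1 <= t2 else ((t2, t1, True)))
    return pairs


# -- internal phase structure (shared by EM, LRT, permutations) ----------


@dataclass
class _PhaseStructure:
    """Pre-expanded diplotype lists for a set of distinct genotype patterns."""

    haplotypes: list[Haplotype]
    pair_h1: np.ndarray      # haplotype index of first member of each pair
    pair_h2: np.ndarray
    pair_coef: np.ndarray    # 2.0 for heterozygous pairs, 1.0 for homozygous
    pair_pattern: np.ndarray  # which genotype pattern each pair belongs to
    n_patterns: int

    @classmethod
    def build(cls, patterns: Sequence[tuple]) -> "_PhaseStructure":
        expansions = [enumerate_diplotypes(p) for p in patterns]
        universe = sorted({h for exp in expansions for h1, h2, _ in exp
                           for h in (h1, h2)})
        index = {h: i for i, h in enumerate(universe)}
        h1s, h2s, coefs, pats = [], [], [], []
        for pi, exp in enumerate(expansions):
            for h1, h2, het in exp:
                h1s.append(index[h1])
                h2s.append(index[h2])
                coefs.append(2.0 if het else 1.0)
                pats.append(pi)
        return cls(
            haplotypes=universe,
            pair_h1=np.array(h1s, dtype=np.intp),
            pair_h2=np.array(h2s, dtype=np.intp),
            pair_coef=np.array(coefs, dtype=float),
            pair_pattern=np.array(pats, dtype=np.intp),
            n_patterns=len(patterns),
        )

    def loglik(self, freqs: np.ndarray, pattern_counts: np.ndarray) -> float:
        w = self.pair_coef * freqs[self.pair_h1] * freqs[self.pair_h2]
        per_pattern = np.bincount(self.pair_pattern, weights=w,
                                  minlength=self.n_patterns)
        active = pattern_counts > 0
        if (per_pattern[active] <= 0).any():
            return -np.inf
        return float(pattern_counts[active] @ np.log(per_pattern[active]))

    def allele_freq_init(self, pattern_counts: np.ndarray) -> np.ndarray:
        """Product-of-allele-frequency initialisation, restricted to the universe."""
        if not self.haplotypes:
            return np.array([])
        n_loci = len(self.haplotypes[0])
        # per-locus allele counts from the pattern expansion are awkward;
        # derive them from any single compatible pair per pattern (allele
        # counts are phase-invariant).
        first_pair = np.zeros(self.n_patterns, dtype=np.intp)
        seen = np.zeros(self.n_patterns, dtype=bool)
        for k, pi in enumerate(self.pair_pattern):
            if not seen[pi]:
                first_pair[pi] = k
                seen[pi] = True
        allele_counts: list[dict] = [dict() for _ in range(n_loci)]
        for pi in range(self.n_patterns):
            cnt = pattern_counts[pi]
            if cnt == 0:
                continue
            k = first_pair[pi]
            for hap in (self.haplotypes[self.pair_h1[k]],
                        self.haplotypes[self.pair_h2[k]]):
                for locus, allele in enumerate(hap):
                    allele_counts[locus][allele] = (
                        allele_counts[locus].get(allele, 0) + cnt
                    )
        freqs = np.empty(len(self.haplotypes))
        for i, hap in enumerate(self.haplotypes):
            p = 1.0
            for locus, allele in enumerate(hap):
                tot = sum(allele_counts[locus].values())
                p *= allele_counts[locus].get(allele, 0) / tot
            freqs[i] = p
        s = freqs.sum()
        if s <= 0:  # all mass outside the universe: fall back to uniform
            return np.full(len(self.haplotypes), 1.0 / len(self.haplotypes))
        return freqs / s


def _em_run(
    struct: _PhaseStructure,
    pattern_counts: np.ndarray,
    f0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, list[float], int, bool]:
    """One EM trajectory; returns (freqs, ll, trace, n_iter, converged)."""
    n_chrom = 2.0 * pattern_counts.sum()
    f = np.maximum(np.asarray(f0, dtype=float), 0.0)
    f = f / f.sum()
    trace: list[float] = []
    converged = False
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        w = struct.pair_coef * f[struct.pair_h1] * f[struct.pair_h2]
        denom = np.bincount(struct.pair_pattern, weights=w,
                            minlength=struct.n_patterns)
        active = pattern_counts > 0
        if (denom[active] <= 0).any():
            raise GenotypeError("em_estimate: non-finite likelihood (zero-"
                                "probability genotype pattern)")
        ll = float(pattern_counts[active] @ np.log(denom[active]))
        trace.append(ll)
        # zero-count patterns may have zero total weight; keep them out of
        # the posterior ratio (0/0 otherwise)
        ratio = np.zeros_like(denom)
        ratio[active] = pattern_counts[active] / denom[active]
        post = w * ratio[struct.pair_pattern]
        expected = (
            np.bincount(struct.pair_h1, weights=post, minlength=f.size)
            + np.bincount(struct.pair_h2, weights=post, minlength=f.size)
        )
        f = expected / n_chrom
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
    # evaluate at the returned frequencies (the loop's ll lags one M-step)
    ll_final = struct.loglik(f, pattern_counts)
    trace.append(ll_final)
    return f, ll_final, trace, it, converged


def _fit(
    struct: _PhaseStructure,
    pattern_counts: np.ndarray,
    *,
    tol: float,
    max_iter: int,
    n_restarts: int,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, float, list[float], int, bool, int]:
    inits = [struct.allele_freq_init(pattern_counts)]
    for _ in range(n_restarts - 1):
        inits.append(rng.dirichlet(np.ones(len(struct.haplotypes))))
    best = None
    for r, f0 in enumerate(inits):
        f, ll, trace, n_iter, conv = _em_run(
            struct, pattern_counts, f0, tol, max_iter
        )
        if best is None or ll > best[1]:
            best = (f, ll, trace, n_iter, conv, r)
    return best


def _complete_case(
    dataset: GenotypeDataset, marker_ids: Sequence[str], mask: np.ndarray
) -> list[tuple]:
    """Multilocus genotype tuples for stratum samples complete at all markers."""
    cols = [dataset.marker_index(m) for m in marker_ids]
    out = []
    for i in np.flatnonzero(mask):
        g = tuple(dataset.genotypes[i, j] for j in cols)
        if all(x is not None for x in g):
            out.append(g)
    return out


def em_estimate(
    dataset: GenotypeDataset,
    markers: Sequence[str],
    stratum=None,
    *,
    tol: float = 1e-8,
    max_iter: int = 10000,
    n_restarts: int = 10,
    seed: int | None = None,
    min_freq: float = 1e-4,
) -> EMResult:
    """Maximum-likelihood haplotype frequencies for a stratum by EM.

    Runs ``n_restarts`` initialisations (the first from the product of
    observed allele frequencies, the rest Dirichlet(1) draws from
    ``seed``) and returns the best by final log-likelihood.  ``seed`` is
    required whenever ``n_restarts > 1`` — there is no hidden global RNG.
    Samples missing any analysis marker are dropped.  Haplotypes with
    final frequency below ``min_freq`` are reported but flagged rare.
    """
    if n_restarts < 1:
        raise GenotypeError("n_restarts must be >= 1")
    if n_restarts > 1 and seed is None:
        raise GenotypeError("seed is required when n_restarts > 1")
    mask = stratum_mask(dataset, stratum)
    genos = _complete_case(dataset, markers, mask)
    if not genos:
        raise GenotypeError(
            f"em_estimate: no samples with complete genotypes at {list(markers)}"
        )
    patterns, counts = _collapse_patterns(genos)
    struct = _PhaseStructure.build(patterns)
    rng = np.random.default_rng(seed) if seed is not None else None
    f, ll, trace, n_iter, conv, best_r = _fit(
        struct, counts, tol=tol, max_iter=max_iter,
        n_restarts=n_restarts, rng=rng,
    )
    table = HaplotypeTable(
        haplotypes=struct.haplotypes,
        frequencies=f,
        n_chromosomes=2 * len(genos),
        rare=f < min_freq,
    )
    return EMResult(
        table=table,
        log_likelihood=ll,
        ll_trace=np.asarray(trace),
        n_iterations=n_iter,
        converged=conv,
        n_restarts=n_restarts,
        best_restart=best_r,
    )


def _collapse_patterns(genos: list[tuple]) -> tuple[list[tuple], np.ndarray]:
    seen: dict[tuple, int] = {}
    counts: list[int] = []
    for g in genos:
        if g in seen:
            counts[seen[g]] += 1
        else:
            seen[g] = len(counts)
            counts.append(1)
    patterns = [None] * len(counts)
    for g, i in seen.items():
        patterns[i] = g
    return patterns, np.array(counts, dtype=float)


# -- haplotype odds ratios ----------------------------------------------


def _align_tables(
    case_table: HaplotypeTable, control_table: HaplotypeTable
) -> tuple[list[Haplotype], np.ndarray, np.ndarray]:
    universe = sorted(set(case_table.haplotypes) | set(control_table.haplotypes))
    cf = np.array([case_table.frequency_of(h) for h in universe])
    tf = np.array([control_table.frequency_of(h) for h in universe])
    return universe, cf, tf


def haplotype_or_table(
    case_table: HaplotypeTable,
    control_table: HaplotypeTable,
    reference: Haplotype | str = "auto",
) -> HaplotypeAssociationResult:
    """Per-haplotype odds ratios against a reference haplotype.

    OR(h) = (case f(h)/f(ref)) / (control f(h)/f(ref)).  CIs are Woolf
    intervals on the expected haplotype counts f * 2N, which ignore phase
    uncertainty in the EM frequencies (a documented limitation).  A
    haplotype absent from either group gets an undefined OR.  With
    ``reference="auto"`` the most frequent pooled haplotype is used.
    """
    universe, cf, tf = _align_tables(case_table, control_table)
    ncase, nctrl = case_table.n_chromosomes, control_table.n_chromosomes
    if reference == "auto":
        pooled = cf * ncase + tf * nctrl
        ref = universe[int(np.argmax(pooled))]
    else:
        ref = tuple(reference)
        if ref not in universe:
            raise GenotypeError(f"reference haplotype {ref} absent from tables")
    ri = universe.index(ref)
    if cf[ri] * ncase < MIN_EXPECTED_COUNT or tf[ri] * nctrl < MIN_EXPECTED_COUNT:
        raise GenotypeError(
            f"reference haplotype {ref} has zero frequency in a group"
        )
    rows: list[HaplotypeOR] = []
    for i, h in enumerate(universe):
        if h == ref:
            or_res = OddsRatioResult(
                1.0, None, None, _hap_str(ref), "haplotype_freq_ratio",
                category=_hap_str(h),
            )
        elif (cf[i] * ncase < MIN_EXPECTED_COUNT
              or tf[i] * nctrl < MIN_EXPECTED_COUNT):
            or_res = OddsRatioResult(
                None, None, None, _hap_str(ref), "haplotype_freq_ratio",
                category=_hap_str(h),
            )
        else:
            est = (cf[i] / cf[ri]) / (tf[i] / tf[ri])
            cells = [cf[i] * ncase, cf[ri] * ncase, tf[i] * nctrl, tf[ri] * nctrl]
            se = float(np.sqrt(sum(1.0 / c for c in cells)))
            log_est = float(np.log(est))
            # clip the exponent: near-zero expected counts give huge but
            # meaningless interval bounds, not overflow
            lo = float(np.exp(max(log_est - Z_95 * se, -700.0)))
            hi = float(np.exp(min(log_est + Z_95 * se, 700.0)))
            or_res = OddsRatioResult(
                float(est),
                lo,
                hi,
                _hap_str(ref),
                "haplotype_freq_ratio",
                category=_hap_str(h),
            )
        rows.append(HaplotypeOR(h, float(cf[i]), float(tf[i]), or_res))
    return HaplotypeAssociationResult(per_haplotype=rows, reference=ref)


def _hap_str(h: Haplotype) -> str:
    return "".join(h)


#: A haplotype whose expected chromosome count (freq x 2N) falls below this
#: is treated as absent from the group: its OR is undefined, as for a true
#: zero.  EM frequencies can converge to arbitrarily small positive values,
#: and a ratio against ~1e-8 of a chromosome is noise, not an estimate.
MIN_EXPECTED_COUNT = 1e-3


# -- global tests --------------------------------------------------------


def _lrt_setup(dataset, markers, case_stratum, control_stratum):
    case_mask = stratum_mask(dataset, case_stratum)
    ctrl_mask = stratum_mask(dataset, control_stratum)
    if (case_mask & ctrl_mask).any():
        raise GenotypeError("case and control strata overlap")
    case_genos = _complete_case(dataset, markers, case_mask)
    ctrl_genos = _complete_case(dataset, markers, ctrl_mask)
    if not case_genos or not ctrl_genos:
        raise GenotypeError("global test: a stratum has no complete genotypes")
    patterns, _ = _collapse_patterns(case_genos + ctrl_genos)
    index = {p: i for i, p in enumerate(patterns)}
    struct = _PhaseStructure.build(patterns)

    def count_vec(genos):
        v = np.zeros(len(patterns))
        for g in genos:
            v[index[g]] += 1
        return v

    return struct, count_vec(case_genos), count_vec(ctrl_genos)


def _lrt_statistic(struct, case_counts, ctrl_counts, *, tol, max_iter,
                   n_restarts, rng, min_freq):
    fits = {}
    for name, counts in (
        ("case", case_counts),
        ("control", ctrl_counts),
        ("pooled", case_counts + ctrl_counts),
    ):
        f, ll, _, _, conv, _ = _fit(
            struct, counts, tol=tol, max_iter=max_iter,
            n_restarts=n_restarts, rng=rng,
        )
        if not conv:
            raise GenotypeError(f"global test: EM did not converge ({name} fit)")
        fits[name] = (f, ll)
    stat = 2.0 * (fits["case"][1] + fits["control"][1] - fits["pooled"][1])
    stat = max(0.0, stat)
    n_common = int((fits["pooled"][0] > min_freq).sum())
    df = max(1, n_common - 1)
    return stat, df, fits


def global_haplotype_lrt(
    dataset: GenotypeDataset,
    markers: Sequence[str],
    case_stratum,
    control_stratum,
    *,
    tol: float = 1e-8,
    max_iter: int = 10000,
    n_restarts: int = 10,
    seed: int | None = None,
    min_freq: float = 1e-4,
    reference: Haplotype | str = "auto",
) -> HaplotypeAssociationResult:
    """Global case-control haplotype test by likelihood ratio.

    Statistic = 2 (ll_case + ll_control - ll_pooled) from three EM fits,
    floored at 0; df = H - 1 where H counts haplotypes with pooled
    frequency above ``min_freq``; p from the chi-square distribution.  The
    per-haplotype OR table from the separate fits is attached.
    """
    if n_restarts > 1 and seed is None:
        raise GenotypeError("seed is required when n_restarts > 1")
    struct, case_counts, ctrl_counts = _lrt_setup(
        dataset, markers, case_stratum, control_stratum
    )
    rng = np.random.default_rng(seed) if seed is not None else None
    stat, df, fits = _lrt_statistic(
        struct, case_counts, ctrl_counts, tol=tol, max_iter=max_iter,
        n_restarts=n_restarts, rng=rng, min_freq=min_freq,
    )
    p = float(stats.chi2.sf(stat, df))
    case_table = HaplotypeTable(
        struct.haplotypes, fits["case"][0], int(2 * case_counts.sum())
    )
    ctrl_table = HaplotypeTable(
        struct.haplotypes, fits["control"][0], int(2 * ctrl_counts.sum())
    )
    result = haplotype_or_table(case_table, ctrl_table, reference=reference)
    result.global_statistic = float(stat)
    result.global_df = df
    result.global_p = p
    result.method = "lrt"
    return result


def permutation_global_test(
    dataset: GenotypeDataset,
    markers: Sequence[str],
    case_stratum,
    control_stratum,
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    tol: float = 1e-8,
    max_iter: int = 10000,
    n_restarts: int = 10,
    min_freq: float = 1e-4,
) -> HaplotypeAssociationResult:
    """Label-permutation version of the global haplotype test.

    Case/control labels are shuffled ``n_perm`` times over the combined
    complete-genotype samples and the LRT statistic recomputed; the
    p-value is (1 + #{perm >= observed}) / (n_perm + 1).  The pooled fit
    is label-invariant so only the two group fits are redone per
    permutation.
    """
    if n_perm < 100:
        raise GenotypeError("n_perm must be >= 100")
    if seed is None:
        raise GenotypeError("permutation_global_test requires a seed")
    struct, case_counts, ctrl_counts = _lrt_setup(
        dataset, markers, case_stratum, control_stratum
    )
    rng = np.random.default_rng(seed)
    stat, df, fits = _lrt_statistic(
        struct, case_counts, ctrl_counts, tol=tol, max_iter=max_iter,
        n_restarts=n_restarts, rng=rng, min_freq=min_freq,
    )
    pooled_counts = case_counts + ctrl_counts
    ll_pooled = fits["pooled"][1]
    n_case = int(case_counts.sum())
    # expand pattern ids per sample for label shuffling
    sample_patterns = np.repeat(
        np.arange(len(pooled_counts)), pooled_counts.astype(int)
    )
    n_total = sample_patterns.size
    n_extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        case_ids = sample_patterns[perm[:n_case]]
        pc = np.bincount(case_ids, minlength=len(pooled_counts)).astype(float)
        tc = pooled_counts - pc
        _, ll_c, _, _, conv_c, _ = _fit(
            struct, pc, tol=tol, max_iter=max_iter,
            n_restarts=n_restarts, rng=rng,
        )
        _, ll_t, _, _, conv_t, _ = _fit(
            struct, tc, tol=tol, max_iter=max_iter,
            n_restarts=n_restarts, rng=rng,
        )
        if not (conv_c and conv_t):
            raise GenotypeError("permutation test: EM did not converge")
        perm_stat = max(0.0, 2.0 * (ll_c + ll_t - ll_pooled))
        if perm_stat >= stat - 1e-12:
            n_extreme += 1
    p = (1 + n_extreme) / (n_perm + 1)
    case_table = HaplotypeTable(
        struct.haplotypes, fits["case"][0], int(2 * case_counts.sum())
    )
    ctrl_table = HaplotypeTable(
        struct.haplotypes, fits["control"][0], int(2 * ctrl_counts.sum())
    )
    result = haplotype_or_table(case_table, ctrl_table)
    result.global_statistic = float(stat)
    result.global_df = df
    result.global_p = float(p)
    result.method = "permutation"
    return result


# -- linkage disequilibrium ----------------------------------------------


def ld_pairwise(
    dataset: GenotypeDataset,
    marker_i: str,
    marker_j: str,
    stratum=None,
    *,
    seed: int | None = None,
    n_restarts: int = 1,
) -> LDResult:
    """Pairwise LD (D, D', r^2) from EM two-locus haplotype frequencies.

    D is computed for the variant (allele_b) alleles of both markers:
    D = f(b_i b_j) - p_i p_j; D' = D / Dmax with the sign-dependent Dmax;
    r^2 = D^2 / (p_i q_i p_j q_j).  Returns an all-None sentinel if either
    marker is monomorphic in the stratum.
    """
    mi = dataset.marker(marker_i)
    mj = dataset.marker(marker_j)
    res = em_estimate(
        dataset, [marker_i, marker_j], stratum,
        n_restarts=n_restarts, seed=seed,
    )
    tab = res.table
    p_i = tab.marker_margin(0, mi.allele_b)
    p_j = tab.marker_margin(1, mj.allele_b)
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        return LDResult(None, None, None)
    p_ij = tab.frequency_of((mi.allele_b, mj.allele_b))
    d = p_ij - p_i * p_j
    if d >= 0:
        d_max = min(p_i * (1 - p_j), (1 - p_i) * p_j)
    else:
        d_max = min(p_i * p_j, (1 - p_i) * (1 - p_j))
    d_prime = d / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_i * (1 - p_i) * p_j * (1 - p_j))
    return LDResult(float(d), float(d_prime), float(r2))
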