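"""Per-marker case-control statistics.

Allele frequencies, Hardy-Weinberg tests (1-df chi-square and full-
enumeration exact), Pearson chi-square and Fisher-Freeman-Halton exact
genotype association, crude cross-product odds ratios with Woolf CIs,
covariate-adjusted odds ratios by unconditional logistic regression, and
generic two-group comparisons (2x2 chi-square/Fisher, pooled/Welch t).

Conventions: all tests are two-sided; Pearson chi-square uses no
continuity correction; genotype categories absent from both groups are
dropped (with the df reduced) before testing; a zero cell makes a crude
OR undefined unless the Haldane-Anscombe +0.5 correction is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .genotypes import GenotypeCounts, GenotypeDataset, GenotypeError

__all__ = [
    "AssociationResult",
    "OddsRatioResult",
    "allele_frequency",
    "hwe_test",
    "genotype_association_chi2",
    "fisher_freeman_halton",
    "crude_genotype_or",
    "adjusted_or_logistic",
    "compare_groups",
    "SeparationError",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: Relative tolerance used when comparing table probabilities for ties in
#: exact tests (floating-point products of factorials are not exact).
EXACT_TIE_RTOL = 1e-7


class SeparationError(RuntimeError):
    """Perfect separation in a logistic fit (diverging coefficient)."""


@dataclass(frozen=True)
class AssociationResult:
    """A contingency/two-sample test result.

    ``statistic`` is in chi-square units for chi-square methods, the
    observed-table probability mass for exact methods, and the t value for
    t methods.  ``df`` is None where not applicable.  ``degenerate`` marks
    results forced by a degenerate input (e.g. a monomorphic marker) rather
    than computed from a proper test.
    """

    table: tuple | None
    statistic: float
    df: int | None
    p_value: float
    method: str
    degenerate: bool = False


@dataclass(frozen=True)
class OddsRatioResult:
    """An odds ratio with 95% CI against a reference category.

    ``estimate`` is None when a required cell is zero and no correction is
    applied (printed as a dash in report tables).
    """

    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    reference: str
    method: str
    category: str = ""
    correction_applied: bool = False


# -- allele frequency and HWE -------------------------------------------


def allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of allele_b: het/2 + hom-variant, as proportions.

    Equivalent to counting variant chromosomes over total chromosomes.
    """
    n = counts.n_typed
    if n == 0:
        raise GenotypeError("allele_frequency: no typed samples")
    return (counts.n_ab / 2 + counts.n_bb) / n


def hwe_test(counts: GenotypeCounts, method: str = "chi2") -> AssociationResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    ``chi2``: 1-df goodness of fit of (n_aa, n_ab, n_bb) against
    (p^2, 2pq, q^2) * n at the sample allele frequency.  ``exact``: full
    enumeration of heterozygote counts conditional on the allele counts,
    two-sided by summing configurations no more probable than the observed
    one.  A monomorphic marker returns p = 1 flagged degenerate.
    """
    if method not in ("chi2", "exact"):
        raise GenotypeError(f"unknown HWE method {method!r}")
    n = counts.n_typed
    if n == 0:
        raise GenotypeError("hwe_test: no typed samples")
    q = allele_frequency(counts)
    label = f"hwe_{method}"
    if q in (0.0, 1.0):
        return AssociationResult(
            counts.as_tuple(), 0.0, None, 1.0, label, degenerate=True
        )
    if method == "chi2":
        p = 1.0 - q
        expected = np.array([p * p, 2 * p * q, q * q]) * n
        observed = np.array(counts.as_tuple(), dtype=float)
        stat = float(((observed - expected) ** 2 / expected).sum())
        return AssociationResult(
            counts.as_tuple(), stat, 1, float(stats.chi2.sf(stat, 1)), label
        )
    p_value = _hwe_exact_p(counts.n_ab, 2 * counts.n_aa + counts.n_ab,
                           counts.n_ab + 2 * counts.n_bb)
    return AssociationResult(counts.as_tuple(), float("nan"), None, p_value, label)


def _hwe_exact_p(n_het: int, n_allele_a: int, n_allele_b: int) -> float:
    """Exact HWE p-value by enumerating heterozygote counts.

    Conditional on the allele counts, the number of heterozygotes under
    random mating follows the distribution
    P(n_ab) ∝ n! / (n_aa! n_ab! n_bb!) * 2^n_ab; all counts with the same
    parity as the rare-allele count are enumerated and those with
    probability <= the observed one (within a tie tolerance) are summed.
    """
    n = (n_allele_a + n_allele_b) // 2
    rare = min(n_allele_a, n_allele_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    n_bb = (rare - hets) // 2
    n_aa = n - n_bb - hets
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb + 1)
        + hets * np.log(2.0)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= obs * (1 + EXACT_TIE_RTOL)].sum()))


# -- case-control genotype tests ----------------------------------------


def _genotype_table(
    case_counts: GenotypeCounts, control_counts: GenotypeCounts
) -> np.ndarray:
    table = np.array([case_counts.as_tuple(), control_counts.as_tuple()], dtype=int)
    return table[:, table.sum(axis=0) > 0]  # drop categories absent everywhere


def genotype_association_chi2(
    case_counts: GenotypeCounts, control_counts: GenotypeCounts
) -> AssociationResult:
    """Pearson chi-square on the 2 x k genotype table, no continuity correction."""
    table = _genotype_table(case_counts, control_counts)
    if table.sum() == 0:
        raise GenotypeError("genotype_association_chi2: all-zero table")
    if (table.sum(axis=1) == 0).any():
        raise GenotypeError("genotype_association_chi2: a group has no typed samples")
    if table.shape[1] < 2:
        return AssociationResult(
            tuple(map(tuple, table)), 0.0, 0, 1.0, "pearson_chi2", degenerate=True
        )
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return AssociationResult(
        tuple(map(tuple, table)), float(stat), int(df), float(p), "pearson_chi2"
    )


def fisher_freeman_halton(
    table, max_tables: int = 2_000_000
) -> AssociationResult:
    """Exact two-sided test on a 2 x k table (Fisher-Freeman-Halton).

    Enumerates every table with the observed margins and sums the
    multivariate-hypergeometric probabilities of tables no more probable
    than the observed one (ties within ``EXACT_TIE_RTOL``).  For k = 2
    this is the standard two-sided Fisher exact test.  Raises when the
    enumeration would exceed ``max_tables`` candidate tables (use a Monte
    Carlo approach for such tables).
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] != 2:
        raise GenotypeError("fisher_freeman_halton expects a 2 x k table")
    if (table < 0).any():
        raise GenotypeError("negative cell count")
    table = table[:, table.sum(axis=0) > 0]
    if table.size == 0 or (table.sum(axis=1) == 0).any():
        raise GenotypeError("fisher_freeman_halton: empty row or table")
    k = table.shape[1]
    if k == 1:
        return AssociationResult(
            tuple(map(tuple, table)), 1.0, None, 1.0,
            "fisher_freeman_halton", degenerate=True,
        )
    col_sums = table.sum(axis=0)
    row1 = int(table.sum(axis=1)[0])
    bound = 1
    for c in col_sums:
        bound *= min(int(c), row1) + 1
        if bound > max_tables:
            raise GenotypeError(
                f"fisher_freeman_halton: enumeration bound exceeds {max_tables} "
                "tables; use a Monte Carlo test for tables this large"
            )
    log_probs = _ffh_log_probs(row1, col_sums)
    obs_lp = _ffh_table_log_prob(table[0], col_sums, row1)
    probs = np.exp(log_probs)
    obs_p = float(np.exp(obs_lp))
    p = float(min(1.0, probs[probs <= obs_p * (1 + EXACT_TIE_RTOL)].sum()))
    return AssociationResult(
        tuple(map(tuple, table)), obs_p, None, p, "fisher_freeman_halton"
    )


def _ffh_table_log_prob(first_row, col_sums, row1: int) -> float:
    n = int(np.sum(col_sums))
    lp = -(gammaln(n + 1) - gammaln(row1 + 1) - gammaln(n - row1 + 1))
    for t, c in zip(first_row, col_sums):
        lp += gammaln(c + 1) - gammaln(t + 1) - gammaln(c - t + 1)
    return float(lp)


def _ffh_log_probs(row1: int, col_sums) -> np.ndarray:
    """Log probabilities of every margin-consistent 2 x k table.

    Iterates a distribution over the running first-row subtotal, column by
    column (a convolution), carrying log binomial weights; equivalent to
    full enumeration but polynomial in the margins.
    """
    col_sums = [int(c) for c in col_sums]
    n = sum(col_sums)
    # partial[s] = list of log-weights of prefixes with subtotal s
    partial: list[list[float]] = [[] for _ in range(row1 + 1)]
    partial[0].append(0.0)
    for c in col_sums:
        lchoose = [
            float(gammaln(c + 1) - gammaln(t + 1) - gammaln(c - t + 1))
            for t in range(c + 1)
        ]
        nxt: list[list[float]] = [[] for _ in range(row1 + 1)]
        for s, weights in enumerate(partial):
            if not weights:
                continue
            for t in range(min(c, row1 - s) + 1):
                w = lchoose[t]
                nxt[s + t].extend(lw + w for lw in weights)
        partial = nxt
    denom = gammaln(n + 1) - gammaln(row1 + 1) - gammaln(n - row1 + 1)
    return np.array(partial[row1]) - float(denom)


# -- odds ratios ---------------------------------------------------------


def _woolf_ci(cells: Sequence[float], log_or: float) -> tuple[float, float]:
    se = float(np.sqrt(sum(1.0 / c for c in cells)))
    return (float(np.exp(log_or - Z_95 * se)), float(np.exp(log_or + Z_95 * se)))


def crude_genotype_or(
    case_counts: GenotypeCounts,
    control_counts: GenotypeCounts,
    category: str,
    reference: str = "aa",
    zero_cell_correction: bool = False,
) -> OddsRatioResult:
    """Crude cross-product odds ratio for one genotype category vs reference.

    The point estimate is computed in exact rational arithmetic before
    conversion to float; the CI is Woolf's log-normal interval.  With a
    zero cell the estimate is undefined unless ``zero_cell_correction``
    adds 0.5 to all four cells (Haldane-Anscombe).
    """
    if category == reference:
        raise GenotypeError("category must differ from reference")
    a = case_counts.get(category)
    b = case_counts.get(reference)
    c = control_counts.get(category)
    d = control_counts.get(reference)
    method = "crude_crossproduct"
    if min(a, b, c, d) == 0:
        if not zero_cell_correction:
            return OddsRatioResult(
                None, None, None, reference, method, category=category
            )
        cells = [a + 0.5, b + 0.5, c + 0.5, d + 0.5]
        est = cells[0] * cells[3] / (cells[1] * cells[2])
        lo, hi = _woolf_ci(cells, float(np.log(est)))
        return OddsRatioResult(
            float(est), lo, hi, reference, method,
            category=category, correction_applied=True,
        )
    est = float(Fraction(a, 1) * Fraction(d, 1) / (Fraction(b, 1) * Fraction(c, 1)))
    lo, hi = _woolf_ci([a, b, c, d], float(np.log(est)))
    return OddsRatioResult(est, lo, hi, reference, method, category=category)


def adjusted_or_logistic(
    dataset: GenotypeDataset,
    marker_id: str,
    reference: str = "aa",
    covariates: Sequence[str] = ("age", "sex"),
) -> list[OddsRatioResult]:
    """Covariate-adjusted genotype ORs by unconditional logistic regression.

    Case status is regressed on genotype-category indicators (vs the
    reference category) plus the requested covariates (age in years; sex
    coded male = 1).  Samples missing the genotype or any covariate are
    dropped; constant covariate columns are dropped (they carry no
    information and would make the design singular).  Fitting is by
    Newton/IRLS; perfect separation raises :class:`SeparationError`.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    for cov in covariates:
        if cov not in ("age", "sex"):
            raise GenotypeError(f"unknown covariate {cov!r}")
    j = dataset.marker_index(marker_id)
    marker = dataset.markers[j]
    cats = np.array(
        [marker.category(g) or "" for g in dataset.genotypes[:, j]], dtype=object
    )
    keep = cats != ""
    cov_cols = {}
    if "age" in covariates:
        age = dataset.samples["age"].to_numpy(dtype=float)
        keep &= ~np.isnan(age)
        cov_cols["age"] = age
    if "sex" in covariates:
        sex = dataset.samples["sex"].to_numpy(dtype=object)
        keep &= np.array([s in ("M", "F") for s in sex])
        cov_cols["sex_male"] = np.array([1.0 if s == "M" else 0.0 for s in sex])
    if keep.sum() == 0:
        raise GenotypeError("adjusted_or_logistic: no usable samples")
    y = (dataset.samples["status"].to_numpy() == "case").astype(float)[keep]
    cats_k = cats[keep]
    present = [c for c in ("aa", "ab", "bb") if (cats_k == c).any()]
    if reference not in present:
        raise GenotypeError(f"reference category {reference!r} absent from data")
    terms = [c for c in present if c != reference]
    if not terms:
        raise GenotypeError("adjusted_or_logistic: fewer than 2 genotype categories")
    cols, names = [], []
    for c in terms:
        cols.append((cats_k == c).astype(float))
        names.append(f"genotype_{c}")
    for name, vals in cov_cols.items():
        v = vals[keep]
        if np.ptp(v) > 0:  # constant covariates dropped
            cols.append(v)
            names.append(name)
    X = sm.add_constant(np.column_stack(cols), prepend=True)
    try:
        fit = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"logistic fit failed for marker {marker_id!r} ({exc}); "
            "check for perfect separation"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise GenotypeError(
            f"adjusted_or_logistic: no convergence after 100 iterations "
            f"for marker {marker_id!r}"
        )
    params = fit.params[1:]
    bse = fit.bse[1:]
    results = []
    for i, c in enumerate(terms):
        coef, se = float(params[i]), float(bse[i])
        if abs(coef) > 15:
            raise SeparationError(
                f"perfect separation for genotype category {c!r} at marker "
                f"{marker_id!r} (|coefficient| = {abs(coef):.1f})"
            )
        results.append(
            OddsRatioResult(
                estimate=float(np.exp(coef)),
                ci_low=float(np.exp(coef - Z_95 * se)),
                ci_high=float(np.exp(coef + Z_95 * se)),
                reference=reference,
                method="logistic_adjusted",
                category=c,
            )
        )
    return results


# -- generic two-group comparisons --------------------------------------


def compare_groups(data, mode: str) -> AssociationResult:
    """Compare two groups: 2x2 chi-square/Fisher or a two-sample t test.

    For ``chi2_2x2``/``fisher_2x2`` pass a 2x2 count table.  For
    ``welch_t``/``pooled_t`` pass either two numeric samples or two
    ``(mean, sd, n)`` summaries (only summaries are usually published).
    """
    if mode in ("chi2_2x2", "fisher_2x2"):
        table = np.asarray(data, dtype=int)
        if table.shape != (2, 2):
            raise GenotypeError(f"{mode} requires a 2x2 table")
        if mode == "chi2_2x2":
            stat, p, df, _ = stats.chi2_contingency(table, correction=False)
            return AssociationResult(
                tuple(map(tuple, table)), float(stat), int(df), float(p),
                "pearson_chi2",
            )
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return AssociationResult(
            tuple(map(tuple, table)), float(odds), None, float(p), "fisher_2x2"
        )
    if mode in ("welch_t", "pooled_t"):
        g1, g2 = data
        if len(g1) == 3 and np.isscalar(g1[0]):
            (m1, s1, n1), (m2, s2, n2) = g1, g2
        else:
            a1, a2 = np.asarray(g1, float), np.asarray(g2, float)
            m1, s1, n1 = a1.mean(), a1.std(ddof=1), len(a1)
            m2, s2, n2 = a2.mean(), a2.std(ddof=1), len(a2)
        if s1 == 0 and s2 == 0:
            raise GenotypeError("zero variance in both groups")
        stat, p = stats.ttest_ind_from_stats(
            m1, s1, n1, m2, s2, n2, equal_var=(mode == "pooled_t")
        )
        return AssociationResult(None, float(stat), None, float(p), mode)
    raise GenotypeError(f"unknown comparison mode {mode!r}")
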