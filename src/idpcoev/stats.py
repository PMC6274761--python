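"""Statistical battery: random-pair distance null, rank-sum and
equal-proportions tests, boxplot outlier flagging, distance histogram,
composition tables and secondary-structure preference.

The central validation asks whether coupled residue pairs sit closer in
space than chance: for each coupling, one IDP interface residue and one
partner interface residue are drawn at random from the same interface, their
shortest heavy-atom distance recorded, and the coupling distances compared
to the random-pair distances with a Mann-Whitney U test; the resampling is
repeated (100 samples by default) to check the comparison is stable.
Proportion comparisons use the two-sample test of equal proportions
(chi-square with continuity correction). P-values are reported raw (no
multiple-testing correction by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alphabet import RESIDUE_GROUPS
from .structure import ComplexStructure, residue_min_distance

ALPHA = 0.05
N_RESAMPLES = 100


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U with midrank ties.

    The p-value is exact (by enumeration) when n1 + n2 <= 12 and there are
    no ties across the pooled sample; otherwise the normal approximation
    with tie and continuity corrections is used. Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def equal_proportions_test(successes_1: int, n_1: int,
                           successes_2: int, n_2: int) -> float:
    """Two-sample test of equal proportions: 2x2 chi-square with continuity
    correction. A zero-margin table returns p = 1 with a warning."""
    if min(n_1, n_2) < 1:
        raise ValueError("sample sizes must be >= 1")
    if successes_1 > n_1 or successes_2 > n_2:
        raise ValueError("successes cannot exceed sample size")
    table = np.array([[successes_1, n_1 - successes_1],
                      [successes_2, n_2 - successes_2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p = 1")
        return 1.0
    _, p, _, _ = sps.chi2_contingency(table, correction=True)
    return float(p)


def flag_outliers(distances) -> tuple[np.ndarray, np.ndarray]:
    """Boxplot rule: values beyond Q1 - 1.5*IQR or Q3 + 1.5*IQR are flagged.

    Quartiles use linear interpolation (type-7). Fewer than 4 values: nothing
    flagged. Returns (kept, outliers); flagging is single-pass.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 4:
        return d.copy(), np.array([])
    q1, q3 = np.quantile(d, [0.25, 0.75])  # numpy default is type-7
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (d < lo) | (d > hi)
    return d[~mask], d[mask]


def distance_histogram(distances) -> tuple[int, int, int]:
    """Counts in the bins [0, 8), [8, 10], (10, inf) Å."""
    d = np.asarray(distances, dtype=float)
    if d.size and d.min() < 0:
        raise ValueError("distances must be non-negative")
    return (int((d < 8).sum()),
            int(((d >= 8) & (d <= 10)).sum()),
            int((d > 10).sum()))


def summary_stats(values) -> dict[str, float]:
    """min / Q1 / mean / median / Q3 / max (type-7 quantiles)."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return {"min": float(v.min()), "q1": float(q1), "mean": float(v.mean()),
            "median": float(med), "q3": float(q3), "max": float(v.max())}


# ---------------------------------------------------------------------------
# random-pair distance null
# ---------------------------------------------------------------------------


@dataclass
class NullDistanceSample:
    """One resample: a random interface pair drawn per coupling."""

    draws: np.ndarray
    summaries: dict[str, float] = field(default_factory=dict)


def random_pair_null(
    s: ComplexStructure,
    interface,
    ec_pairs: list[tuple[int, int]],
    n_resamples: int = N_RESAMPLES,
    seed: int = 0,
) -> list[NullDistanceSample]:
    """Per-coupling random interface-pair distance resamples.

    For each coupling, one IDP interface residue and one partner interface
    residue are drawn uniformly (with replacement across draws) from the
    same interface, and their minimum heavy-atom distance recorded; this is
    repeated ``n_resamples`` times. The RNG is the counter-based Philox
    generator seeded with ``seed``, so runs are reproducible across
    platforms. Couplings are skipped (with a warning) if either interface
    side is empty.
    """
    idp_pool = sorted(interface.idp_if_residues)
    partner_pool = sorted(interface.partner_if_residues)
    n_ecs = len(ec_pairs)
    if not idp_pool or not partner_pool:
        warnings.warn("empty interface side; null sampling skipped")
        return []
    rng = np.random.Generator(np.random.Philox(seed))
    dcache: dict[tuple[int, int], float] = {}

    def dist(ri: int, rj: int) -> float:
        key = (ri, rj)
        if key not in dcache:
            dcache[key] = residue_min_distance(s, ri, rj)
        return dcache[key]

    samples = []
    for _ in range(n_resamples):
        ii = rng.integers(0, len(idp_pool), size=n_ecs)
        jj = rng.integers(0, len(partner_pool), size=n_ecs)
        draws = np.array([dist(idp_pool[a], partner_pool[b])
                          for a, b in zip(ii, jj)])
        samples.append(NullDistanceSample(draws=draws,
                                          summaries=summary_stats(draws)))
    return samples


def dump_null_samples(samples: list[NullDistanceSample], path) -> None:
    """Audit dump: one resample per line, draws tab-separated (Å)."""
    with open(path, "w") as fh:
        for sample in samples:
            fh.write("\t".join(f"{d:.3f}" for d in sample.draws) + "\n")


def null_summary_variation(samples: list[NullDistanceSample]) -> dict[str, float]:
    """Std of each descriptive summary across resamples, plus their average:
    the stability report of the resampling null."""
    keys = ["min", "q1", "mean", "median", "q3", "max"]
    stds = {k: float(np.std([s.summaries[k] for s in samples])) for k in keys}
    stds["average_sd"] = float(np.mean([stds[k] for k in keys]))
    return stds


def compare_ec_distances(
    ec_distances,
    samples: list[NullDistanceSample],
    exclude_outliers: bool = True,
) -> dict:
    """Mann-Whitney comparison of coupling distances against each resample.

    Outliers among the coupling distances (boxplot rule) are excluded from
    the comparison but reported. Returns per-sample p-values and the
    fraction significant at 0.05 and 0.01.
    """
    d = np.asarray(ec_distances, dtype=float)
    kept, outliers = flag_outliers(d) if exclude_outliers else (d, np.array([]))
    pvals = []
    for sample in samples:
        _, p = mann_whitney_u(kept, sample.draws)
        pvals.append(p)
    pvals = np.array(pvals)
    return {
        "n_ecs": int(len(kept)),
        "outliers": outliers.tolist(),
        "p_values": pvals,
        "frac_p_below_0.05": float((pvals < 0.05).mean()) if len(pvals) else np.nan,
        "frac_p_below_0.01": float((pvals < 0.01).mean()) if len(pvals) else np.nan,
        "median_p": float(np.median(pvals)) if len(pvals) else np.nan,
    }


# ---------------------------------------------------------------------------
# composition & secondary-structure preference
# ---------------------------------------------------------------------------

CATEGORIES = ["analyzed_range", "all_IF", "noEC_IF", "EC_IF", "EC_residues"]


def composition_table(residues_by_category: dict[str, list[str]]) -> pd.DataFrame:
    """Per-residue and per-group composition fractions for each category.

    Input: category -> list of one-letter residue codes (a multiset).
    Output rows: 20 residues then the 5 groups; columns: categories, values
    are fractions of the category total.
    """
    from .alphabet import AMINO_ACIDS

    rows = list(AMINO_ACIDS) + list(RESIDUE_GROUPS)
    out = pd.DataFrame(index=rows, columns=list(residues_by_category), dtype=float)
    for cat, residues in residues_by_category.items():
        n = len(residues)
        if n == 0:
            warnings.warn(f"empty composition category {cat!r}")
            out[cat] = np.nan
            continue
        counts = pd.Series(list(residues)).value_counts()
        for aa in AMINO_ACIDS:
            out.loc[aa, cat] = counts.get(aa, 0) / n
        for group, members in RESIDUE_GROUPS.items():
            out.loc[group, cat] = sum(counts.get(aa, 0) for aa in members) / n
    return out


def composition_analysis(residues_by_category: dict[str, list[str]]) -> dict:
    """Composition table plus pairwise equal-proportion p-values for the
    standard comparisons (EC_IF vs all_IF, EC_residues vs all_IF,
    EC_IF vs noEC_IF), per residue group."""
    table = composition_table(residues_by_category)
    comparisons = [("EC_IF", "all_IF"), ("EC_residues", "all_IF"),
                   ("EC_IF", "noEC_IF")]
    pvalues: dict[tuple[str, str, str], float] = {}
    for cat1, cat2 in comparisons:
        r1 = residues_by_category.get(cat1, [])
        r2 = residues_by_category.get(cat2, [])
        if not r1 or not r2:
            warnings.warn(f"comparison {cat1} vs {cat2} skipped (empty category)")
            continue
        for group, members in RESIDUE_GROUPS.items():
            s1 = sum(1 for aa in r1 if aa in members)
            s2 = sum(1 for aa in r2 if aa in members)
            pvalues[(cat1, cat2, group)] = equal_proportions_test(
                s1, len(r1), s2, len(r2))
    return {"table": table, "p_values": pvalues}


def ss_preference(ss, ec_residues: list[int], other_residues: list[int]) -> dict:
    """Three-class secondary-structure proportions of coupled vs other
    residues, with the helix-class equal-proportions p-value."""
    if not ec_residues:
        warnings.warn("no EC residues; secondary-structure preference skipped")
        return {}
    ec_counts = ss.counts_by_class(ec_residues)
    other_counts = ss.counts_by_class(other_residues)
    n_ec, n_other = len(ec_residues), len(other_residues)
    out = {
        "ec_proportions": {k: v / n_ec for k, v in ec_counts.items()},
        "other_proportions": {k: v / n_other for k, v in other_counts.items()}
        if n_other else {},
    }
    if n_other:
        out["p_helix"] = equal_proportions_test(
            ec_counts["helix"], n_ec, other_counts["helix"], n_other)
        out["p_strand"] = equal_proportions_test(
            ec_counts["strand"], n_ec, other_counts["strand"], n_other)
        out["p_loop"] = equal_proportions_test(
            ec_counts["loop"], n_ec, other_counts["loop"], n_other)
    return out
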