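"""Cohort comparison machinery.

Monte-Carlo permutation tests with Benjamini-Hochberg false-discovery-rate
control, Cohen's d effect sizes, a minimum-detectable-effect convenience, the
cortical hierarchy (regions ranked by cohort-mean node-metastability) and the
Hierarchy Disruption Factor (HDF), the l2 distance between two rank-aligned
hierarchies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, ContractError, DegenerateSignalError, ParameterError
from .ignition import IgnitionProfile

__all__ = [
    "CohortHierarchy",
    "permutation_test",
    "bh_fdr",
    "cohen_d",
    "cohen_d_from_summary",
    "min_detectable_d",
    "build_hierarchy",
    "hdf",
    "compare_groups",
]


@dataclass
class CohortHierarchy:
    """Regions ranked by cohort-mean node-metastability, descending."""

    region_ids: list[str]
    values: np.ndarray
    top_regions: list[str]

    def __len__(self) -> int:
        return len(self.region_ids)


def permutation_test(
    a, b, n_perm: int = 10_000, rng: np.random.Generator | int | None = None
) -> float:
    """Two-sided Monte-Carlo permutation p-value for a difference of means.

    Group labels are shuffled ``n_perm`` times; the p-value is
    ``(1 + #{|Δ_perm| >= |Δ_obs|}) / (n_perm + 1)`` (add-one corrected, so it
    is never exactly zero).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both samples must be non-empty")
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n_a, n_tot = a.size, pooled.size
    # vectorised label shuffles: argsort of uniforms is a uniform permutation
    idx = np.argsort(rng.random((n_perm, n_tot)), axis=1)
    perm = pooled[idx]
    diffs = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    exceed = np.count_nonzero(np.abs(diffs) >= obs - 1e-12)
    return (1 + exceed) / (n_perm + 1)


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (rejection mask, adjusted p-values); adjusted p-values are
    monotone in the raw ones.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ContractError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def cohen_d(a, b) -> float:
    """Cohen's d with Bessel-corrected pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each sample needs at least 2 values")
    return cohen_d_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def cohen_d_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Cohen's d from group summary statistics (printed means/sds/sizes)."""
    pooled = np.sqrt(
        ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    )
    if pooled == 0:
        raise DegenerateSignalError("pooled standard deviation is zero")
    return float((mean_a - mean_b) / pooled)


def min_detectable_d(
    n_a: int, n_b: int, alpha: float = 0.05, power: float = 0.8, wilcoxon_are: bool = False
) -> float:
    """Minimum detectable Cohen's d for a two-sample comparison.

    Normal-approximation formula d = (z_{1-α/2} + z_{power})·√(1/n_a + 1/n_b);
    with ``wilcoxon_are`` the result is divided by √0.955, the asymptotic
    relative efficiency of the Wilcoxon-Mann-Whitney test under normality.
    """
    if n_a < 2 or n_b < 2:
        raise ParameterError("each group needs at least 2 subjects")
    d = (sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)) * np.sqrt(1 / n_a + 1 / n_b)
    if wilcoxon_are:
        d /= np.sqrt(0.955)
    return float(d)


def build_hierarchy(profiles: list[IgnitionProfile], n_top: int = 10) -> CohortHierarchy:
    """Cohort hierarchy: per-region mean node-metastability, sorted descending.

    Regions with missing metastability in a subject are averaged over the
    subjects that do carry a value.  Also reports the ``n_top`` regions with
    the highest cohort-mean metastability.
    """
    if not profiles:
        raise ParameterError("need at least one profile")
    ref = list(profiles[0].region_ids)
    for p in profiles[1:]:
        if list(p.region_ids) != ref:
            missing = set(ref).symmetric_difference(p.region_ids)
            raise AlignmentError(f"profile region sets differ: {sorted(missing)[:5]}")
    stacked = np.vstack([p.node_metastability for p in profiles])
    means = np.nanmean(stacked, axis=0)
    order = np.argsort(-means, kind="stable")
    region_ids = [ref[i] for i in order]
    return CohortHierarchy(
        region_ids=region_ids,
        values=means[order],
        top_regions=region_ids[:n_top],
    )


def hdf(a: CohortHierarchy | np.ndarray, b: CohortHierarchy | np.ndarray) -> float:
    """Hierarchy Disruption Factor: l2 distance between rank-aligned hierarchies.

    HDF(a, b) = √(Σ_r (a_r − b_r)²) over the sorted metastability values;
    hierarchies are compared rank against rank, not region against region.
    """
    va = a.values if isinstance(a, CohortHierarchy) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, CohortHierarchy) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ContractError(f"hierarchy lengths differ: {va.shape} vs {vb.shape}")
    return float(np.sqrt(np.nansum((va - vb) ** 2)))


def compare_groups(
    values: dict[str, np.ndarray],
    n_perm: int = 10_000,
    fdr_q: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """All pairwise permutation comparisons with BH-FDR across the family.

    ``values`` maps group name to a 1-D array of per-subject statistics
    (e.g. whole-brain mean node-metastability).  Returns one row per group
    pair with observed difference, permutation p, FDR-adjusted p and decision,
    and Cohen's d.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    names = list(values)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            a, b = np.asarray(values[ga]), np.asarray(values[gb])
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "observed_diff": a.mean() - b.mean(),
                    "p_perm": permutation_test(a, b, n_perm, rng),
                    "cohen_d": cohen_d(a, b),
                }
            )
    out = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(out["p_perm"].to_numpy(), fdr_q)
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out
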