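"""Per-site omega profiles, random-cohort nulls, and group comparisons.

The average omega over the ten key binding-cavity columns, <omega_key>, is
contrasted with the distribution of averages from 200 random cohorts of ten
7TM columns, <omega_random7TM>, giving a z-offset in units of the cohort
standard deviation and a 2-sigma flag. Subgroup-level summaries are compared
across natural-ligand categories with the Kruskal-Wallis rank test, and
trends are summarized by ordinary least squares. Receptor subgroups whose
key positions are not under strong negative selection (omega above 0.1) are
flagged as predicted non-small-molecule binders.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STRONG_NEGATIVE_THRESHOLD = 0.1


class ProfileError(ValueError):
    pass


def site_omega_profile(fit) -> np.ndarray:
    """NEB posterior-mean omega per MSA column from a converged fit."""
    profile = np.asarray(fit.neb_omega, dtype=float)
    if profile.ndim != 1 or profile.size == 0:
        raise ProfileError("empty omega profile")
    return profile


@dataclass
class CohortComparison:
    """<omega_key> against the random-cohort null for one subgroup."""

    subgroup_id: str
    omega_key_mean: float
    random_means: np.ndarray
    cohort_size: int
    seed: int

    @property
    def random_mean(self) -> float:
        return float(np.mean(self.random_means))

    @property
    def random_sd(self) -> float:
        return float(np.std(self.random_means, ddof=0))

    @property
    def z_offset(self) -> float:
        sd = self.random_sd
        diff = self.omega_key_mean - self.random_mean
        scale = max(abs(self.random_mean), 1.0)
        if abs(diff) <= 1e-12 * scale:
            return 0.0
        if sd <= 1e-12 * scale:
            return np.inf if diff > 0 else -np.inf
        return diff / sd

    @property
    def outside_2sigma(self) -> bool:
        return abs(self.z_offset) > 2.0

    @property
    def ratio(self) -> float:
        return self.omega_key_mean / self.random_mean

    @property
    def predicted_non_small_molecule(self) -> bool:
        return self.omega_key_mean > STRONG_NEGATIVE_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "subgroup_id": self.subgroup_id,
            "omega_key_mean": self.omega_key_mean,
            "random_mean": self.random_mean,
            "random_sd": self.random_sd,
            "z_offset": self.z_offset,
            "outside_2sigma": self.outside_2sigma,
            "ratio": self.ratio,
            "n_cohorts": int(len(self.random_means)),
            "cohort_size": self.cohort_size,
            "seed": self.seed,
            "omega_gt_0.1": self.predicted_non_small_molecule,
        }


def cohort_null(
    profile: np.ndarray,
    key_columns: list[int],
    n_cohorts: int = 200,
    cohort_size: int = 10,
    seed: int = 0,
    subgroup_id: str = "",
    exclude_key: bool = False,
) -> CohortComparison:
    """Random-cohort null for <omega_key>.

    Cohorts of ``cohort_size`` columns are sampled uniformly without
    replacement within a cohort (with replacement across cohorts) from all
    7TM columns; key columns are included in the pool unless
    ``exclude_key``. Deterministic under ``seed``.
    """
    profile = np.asarray(profile, dtype=float)
    L = profile.size
    key_idx = np.array(sorted(set(int(c) - 1 for c in key_columns)), dtype=int)
    if key_idx.size == 0 or key_idx.min() < 0 or key_idx.max() >= L:
        raise ProfileError("key columns outside the profile")
    pool = np.arange(L)
    if exclude_key:
        pool = np.setdiff1d(pool, key_idx)
    if cohort_size > pool.size:
        raise ProfileError(
            f"cohort_size {cohort_size} exceeds available columns {pool.size}"
        )
    rng = np.random.default_rng(seed)
    means = np.empty(n_cohorts)
    for i in range(n_cohorts):
        cols = rng.choice(pool, size=cohort_size, replace=False)
        means[i] = profile[cols].mean()
    return CohortComparison(
        subgroup_id=subgroup_id,
        omega_key_mean=float(profile[key_idx].mean()),
        random_means=means,
        cohort_size=cohort_size,
        seed=seed,
    )


def category_comparison(values_by_category: dict[str, list[float]]) -> dict:
    """Kruskal-Wallis rank test of <omega_key> across ligand categories.

    Returns the H statistic, p-value, and per-group mean ranks with pairwise
    direction summaries. Requires at least two groups of two values each.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_category.items() if len(v)}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ProfileError("need >= 2 groups with >= 2 values each")
    names = list(groups)
    data = [groups[n] for n in names]
    pooled = np.concatenate(data)
    if np.allclose(pooled, pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*data)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    k = 0
    for n, v in zip(names, data):
        mean_ranks[n] = float(np.mean(ranks[k : k + len(v)]))
        k += len(v)
    directions = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            directions[f"{a}_vs_{b}"] = (
                "lower" if mean_ranks[a] < mean_ranks[b] else "higher"
            )
    return {
        "H": float(H),
        "p_value": float(p),
        "mean_ranks": mean_ranks,
        "directions": directions,
        "group_sizes": {n: int(len(groups[n])) for n in names},
    }


def _ols(x: np.ndarray, y: np.ndarray) -> dict:
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": int(len(x)),
    }


def trend_report(
    comparisons: list[CohortComparison],
    exclusions: list[str] | None = None,
) -> dict:
    """Regression summaries over subgroup cohort comparisons.

    Ordinary least squares of <omega_key> on <omega_random7TM>, plus log-log
    regressions of the ratio <omega_key>/<omega_random7TM> on each mean
    (positively selected subgroups are normally excluded, recorded in the
    report).
    """
    exclusions = set(exclusions or [])
    kept = [c for c in comparisons if c.subgroup_id not in exclusions]
    if len(kept) < 3:
        raise ProfileError("need >= 3 subgroups after exclusions")
    key = np.array([c.omega_key_mean for c in kept])
    rnd = np.array([c.random_mean for c in kept])
    ratio = key / rnd
    out = {
        "excluded": sorted(exclusions),
        "key_vs_random": _ols(rnd, key),
    }
    ok = (key > 0) & (rnd > 0) & (ratio > 0)
    if ok.sum() >= 3:
        out["log_ratio_vs_log_key"] = _ols(np.log10(key[ok]), np.log10(ratio[ok]))
        out["log_ratio_vs_log_random"] = _ols(np.log10(rnd[ok]), np.log10(ratio[ok]))
    return out


def profile_table(
    comparisons: list[CohortComparison],
    categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-subgroup summary table (one row per cohort comparison)."""
    rows = []
    for c in comparisons:
        d = c.to_dict()
        d["category"] = (categories or {}).get(c.subgroup_id, "")
        d["two_sigma"] = 2.0 * c.random_sd
        rows.append(d)
    return pd.DataFrame(rows)
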