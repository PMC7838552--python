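"""Monte-Carlo nonparametric test battery and Kendall W effect size.

Group-level contrasts between motion conditions use rank tests whose
p-values are computed by random permutation rather than asymptotic
approximations (10,000 permutations by default, with the add-one estimator
p = (1 + #{T_perm >= T_obs}) / (1 + n_perm), which never returns 0):

* Friedman chi-square over a subject x condition matrix of per-subject
  medians, null generated by permuting each subject's condition labels
  independently.  The chi-square is computed for k = 2 contrasts as well,
  so the same effect-size transformation applies throughout.
* Wilcoxon signed-rank for pairwise within-subject contrasts, null by
  random sign flips (pairwise decision criterion alpha / #pairs).
* Kruskal-Wallis and Wilcoxon-Mann-Whitney for fixation-level,
  single-subject contrasts, null by pooled-label permutation.

Effect size follows the Kendall W transformation of the Friedman statistic,
W = chi2 / (N (k - 1)), which is 1 at perfect concordance.  Ties are
mid-ranked everywhere and no continuity corrections are applied (the
permutation null makes them unnecessary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    AllZeroDifferencesError,
    BadArgsError,
    EmptyGroupError,
    IncompleteMatrixError,
)

DEFAULT_N_PERM = 10_000


@dataclass
class SubjectConditionMatrix:
    """Per-subject summary values (e.g. medians) by condition."""

    values: np.ndarray              # (N subjects, k conditions)
    conditions: tuple[str, ...]
    subjects: tuple = ()
    experiment: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise IncompleteMatrixError("need a 2-D matrix with >= 2 conditions")
        if np.isnan(self.values).any():
            raise IncompleteMatrixError("matrix has missing cells")
        if not self.subjects:
            self.subjects = tuple(range(self.values.shape[0]))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        metric: str,
        conditions: Sequence[str],
        subject_col: str = "subject",
        condition_col: str = "condition",
        agg: str = "median",
        experiment: str | None = None,
    ) -> "SubjectConditionMatrix":
        """Aggregate a fixation-level table to per-subject condition medians."""
        pivot = table.pivot_table(
            index=subject_col, columns=condition_col, values=metric, aggfunc=agg
        )
        missing = [c for c in conditions if c not in pivot.columns]
        if missing:
            raise IncompleteMatrixError(f"conditions absent from table: {missing}")
        pivot = pivot[list(conditions)].dropna()
        return cls(
            values=pivot.to_numpy(),
            conditions=tuple(conditions),
            subjects=tuple(pivot.index),
            experiment=experiment,
        )


@dataclass
class TestResult:
    """A statistic with its Monte-Carlo p-value and permutation metadata."""

    test: str
    statistic: float
    p_mc: float
    n_perm: int
    seed: Optional[int]
    effect_size_w: Optional[float] = None
    labels: tuple = ()
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_mc < self.extra.get("alpha", 0.05)


def _mc_p(null_ge_obs: int, n_perm: int) -> float:
    return (1 + null_ge_obs) / (1 + n_perm)


def _friedman_chi2_from_ranks(ranks: np.ndarray) -> np.ndarray:
    """Friedman chi-square from within-subject ranks, last axis = conditions."""
    n, k = ranks.shape[-2], ranks.shape[-1]
    rj = ranks.sum(axis=-2)
    return 12.0 / (n * k * (k + 1)) * (rj**2).sum(axis=-1) - 3.0 * n * (k + 1)


def friedman_mc(
    m: SubjectConditionMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> TestResult:
    """Monte-Carlo Friedman test over a complete subject x condition matrix.

    The observed statistic is the classical Friedman chi-square computed
    from mid-ranked within-subject ranks; the null permutes each subject's
    condition labels independently.
    """
    if m.n_subjects < 2:
        raise IncompleteMatrixError("Friedman needs >= 2 subjects")
    ranks = rankdata(m.values, axis=1)
    obs = float(_friedman_chi2_from_ranks(ranks))
    rng = np.random.default_rng(seed)
    n, k = ranks.shape
    keys = rng.random((n_perm, n, k))
    perm_idx = np.argsort(keys, axis=-1)
    perm_ranks = np.take_along_axis(
        np.broadcast_to(ranks, (n_perm, n, k)), perm_idx, axis=-1
    )
    null = _friedman_chi2_from_ranks(perm_ranks)
    p = _mc_p(int((null >= obs - 1e-12).sum()), n_perm)
    w = kendall_w(obs, n, k)
    return TestResult(
        test="friedman_mc", statistic=obs, p_mc=p, n_perm=n_perm, seed=seed,
        effect_size_w=w, labels=m.conditions,
    )


def kendall_w(chi2: float, n: int, k: int) -> float:
    """Kendall's W from the Friedman chi-square: W = chi2 / (N (k - 1))."""
    if n < 1 or k < 2 or chi2 < 0:
        raise BadArgsError("need n >= 1, k >= 2, chi2 >= 0")
    w = chi2 / (n * (k - 1))
    if w > 1 + 1e-12:
        raise BadArgsError(f"chi2 {chi2:g} exceeds the maximum N(k-1) = {n * (k - 1)}")
    return min(float(w), 1.0)


def wilcoxon_signed_rank_mc(
    a: np.ndarray,
    b: np.ndarray | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> TestResult:
    """Monte-Carlo Wilcoxon signed-rank test on paired values.

    Pass two paired arrays (differences taken as a - b) or a single array
    of differences.  Zero differences are dropped; the statistic is
    Z = sum(sign * rank|d|) / sqrt(sum rank^2), two-sided null by random
    sign flips.
    """
    d = np.asarray(a, float) - (np.asarray(b, float) if b is not None else 0.0)
    d = d[d != 0]
    if len(d) < 2:
        raise AllZeroDifferencesError("fewer than 2 non-zero differences")
    r = rankdata(np.abs(d))
    denom = np.sqrt((r**2).sum())
    obs = float((np.sign(d) * r).sum() / denom)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, len(d))) * 2 - 1
    null = (signs * r).sum(axis=1) / denom
    p = _mc_p(int((np.abs(null) >= abs(obs) - 1e-12).sum()), n_perm)
    return TestResult(
        test="wilcoxon_signed_rank_mc", statistic=obs, p_mc=p,
        n_perm=n_perm, seed=seed,
    )


def _kw_statistic(rank_sums, sizes, n, tie_corr):
    rbar = rank_sums / sizes
    h = 12.0 / (n * (n + 1)) * (sizes * rbar**2).sum(axis=-1) - 3 * (n + 1)
    return h / tie_corr


def kruskal_wallis_mc(
    groups: Sequence[np.ndarray],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> TestResult:
    """Monte-Carlo Kruskal-Wallis test, null by pooled-label permutation."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise EmptyGroupError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    sizes = np.array([len(g) for g in groups])
    ranks = rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n) if n > 1 else 1.0
    if tie_corr == 0:
        tie_corr = 1.0  # all values identical; H is 0 anyway
    edges = np.concatenate([[0], np.cumsum(sizes)])
    obs_sums = np.array([ranks[edges[i]:edges[i + 1]].sum() for i in range(len(sizes))])
    obs = float(_kw_statistic(obs_sums, sizes, n, tie_corr))
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    permuted = ranks[perm]
    null_sums = np.stack(
        [permuted[:, edges[i]:edges[i + 1]].sum(axis=1) for i in range(len(sizes))],
        axis=1,
    )
    null = _kw_statistic(null_sums, sizes, n, tie_corr)
    p = _mc_p(int((null >= obs - 1e-12).sum()), n_perm)
    return TestResult(
        test="kruskal_wallis_mc", statistic=obs, p_mc=p, n_perm=n_perm,
        seed=seed, extra={"null_quantile_95": float(np.quantile(null, 0.95)),
                          "null": None},
    )


def mann_whitney_mc(
    g1: np.ndarray,
    g2: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> TestResult:
    """Monte-Carlo Wilcoxon-Mann-Whitney test (two-sided, Z statistic)."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if len(g1) == 0 or len(g2) == 0:
        raise EmptyGroupError("both groups must be non-empty")
    n1, n2 = len(g1), len(g2)
    n = n1 + n2
    ranks = rankdata(np.concatenate([g1, g2]))
    mu = n1 * (n + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n + 1) / 12.0)
    obs = float((ranks[:n1].sum() - mu) / sd)
    rng = np.random.default_rng(seed)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    null = (ranks[perm[:, :n1]].sum(axis=1) - mu) / sd
    p = _mc_p(int((np.abs(null) >= abs(obs) - 1e-12).sum()), n_perm)
    return TestResult(
        test="mann_whitney_mc", statistic=obs, p_mc=p, n_perm=n_perm, seed=seed,
        extra={"null_quantile_95": float(np.quantile(np.abs(null), 0.95))},
    )


def pairwise_battery(
    m: SubjectConditionMatrix,
    alpha: float = 0.05,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> list[TestResult]:
    """All pairwise signed-rank contrasts with a Bonferroni criterion.

    With k conditions there are k(k-1)/2 pairs; each is flagged
    significant iff p_mc < alpha / #pairs (e.g. 0.05/3 ~= 0.017 for k=3).
    """
    pairs = list(combinations(range(m.n_conditions), 2))
    crit = alpha / len(pairs)
    ss = np.random.SeedSequence(seed)
    out = []
    for (i, j), child in zip(pairs, ss.spawn(len(pairs))):
        res = wilcoxon_signed_rank_mc(
            m.values[:, i], m.values[:, j], n_perm=n_perm,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        res.labels = (m.conditions[i], m.conditions[j])
        res.extra["alpha"] = crit
        res.extra["flagged"] = res.p_mc < crit
        out.append(res)
    return out


def individual_analysis(
    table: pd.DataFrame,
    metric: str,
    conditions: Sequence[str] = ("FX", "RW", "LJ"),
    mpc_conditions: tuple[str, str] = ("RW", "LJ"),
    alpha: float = 0.05,
    n_tests: int | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    subject_col: str = "subject",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Per-subject tests on fixation-level metric values.

    Inertia metrics get a Kruskal-Wallis test over all conditions; MPC
    metrics (undefined under a static stimulus) get a Mann-Whitney
    contrast between the two motion conditions.  Returns one row per
    subject with the statistic, Monte-Carlo p, and significance flags at
    ``alpha`` and at the Bonferroni level ``alpha / n_tests`` (``n_tests``
    defaults to the number of subjects, one test per subject).
    """
    is_mpc = metric.startswith("mpc") or metric.startswith("binocular")
    subjects = sorted(table[subject_col].unique())
    if n_tests is None:
        n_tests = len(subjects)
    bonf = alpha / n_tests
    ss = np.random.SeedSequence(seed)
    rows = []
    for subj, child in zip(subjects, ss.spawn(len(subjects))):
        sub = table[table[subject_col] == subj]
        sd = int(child.generate_state(1)[0] % (2**31))
        if is_mpc:
            c1, c2 = mpc_conditions
            g1 = sub.loc[sub[condition_col] == c1, metric].dropna().to_numpy()
            g2 = sub.loc[sub[condition_col] == c2, metric].dropna().to_numpy()
            res = mann_whitney_mc(g1, g2, n_perm=n_perm, seed=sd)
        else:
            groups = [
                sub.loc[sub[condition_col] == c, metric].dropna().to_numpy()
                for c in conditions
            ]
            res = kruskal_wallis_mc(groups, n_perm=n_perm, seed=sd)
        rows.append(
            {
                "subject": subj,
                "test": res.test,
                "statistic": res.statistic,
                "p_mc": res.p_mc,
                "significant": res.p_mc < alpha,
                "significant_bonferroni": res.p_mc < bonf,
                "stat_crit_95": res.extra.get("null_quantile_95", np.nan),
            }
        )
    return pd.DataFrame(rows)
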