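"""Group comparison and association statistics for network AUC values.

Group differences are assessed with nonparametric permutation tests on
the difference of group means (two-tailed, add-one p-value correction),
corrected across the whole family of contrasts x measures x delays with
the Benjamini-Hochberg step-up procedure at q < 0.05.

Associations between network AUCs and continuous outcomes (PET uptake
ratios, cognitive scores) are modelled with ordinary least squares on
[intercept, AUC terms, their squares, covariates]; subjects whose outcome
lies outside the 1.5 x IQR fences are screened out first.  The candidate
term sets over {clustering AUC, its square, efficiency AUC, its square}
are enumerated under a hierarchy rule (a square is admitted only together
with its linear term) with covariates always present, and the model
minimising the AIC is selected; ties break toward fewer terms.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: canonical group display order (unknown labels sort after, alphabetically)
GROUP_ORDER = ("CN_Abeta_neg", "CN_Abeta_pos", "MCI_Abeta_pos", "AD_Abeta_pos")


@dataclass(frozen=True)
class PermutationResult:
    group_a: str
    group_b: str
    measure: str
    delay: int
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        lower = 1.0 / (self.n_permutations + 1)
        if not lower <= self.p_value <= 1.0:
            raise ValueError("p-value outside achievable range")


@dataclass(frozen=True)
class ModelFit:
    """An OLS fit with its inferential summary.

    ``aic`` is on the ``n·ln(RSS/n) + 2k`` scale (``k`` mean parameters
    including the intercept); constant offsets are irrelevant when
    ranking models at fixed ``n``.
    """

    outcome_name: str
    predictor_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    coef_p_values: np.ndarray
    f_statistic: float
    model_p_value: float
    r_squared_adj: float
    aic: float
    n_used: int
    excluded_outliers: int = 0
    term_names: tuple[str, ...] = field(default_factory=tuple)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.predictor_names.index(name)])

    def coef_ci(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        from scipy import stats as sps

        i = self.predictor_names.index(name)
        dof = self.n_used - len(self.predictor_names)
        half = sps.t.ppf(1 - alpha / 2, dof) * self.standard_errors[i]
        return float(self.coefficients[i] - half), float(self.coefficients[i] + half)


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
    *,
    exact: bool = False,
    group_a: str = "a",
    group_b: str = "b",
    measure: str = "",
    delay: int = -1,
) -> PermutationResult:
    """Two-tailed permutation test on the difference of group means.

    Labels are permuted uniformly; the p-value uses the add-one
    convention ``(1 + #{|T_perm| >= |T_obs|}) / (1 + n_permutations)`` so
    it can never be 0 and is exact under exchangeability.  With
    ``exact=True`` all ``C(n_a + n_b, n_a)`` label splits are enumerated
    instead (feasible for small groups) and the p-value is the exact
    fraction of splits at least as extreme (the identity split counts,
    so p can never be 0 here either).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a, n_tot = a.size, a.size + b.size
    if exact:
        from math import comb

        n_splits = comb(n_tot, n_a)
        if n_splits > 200_000:
            raise ValueError(f"{n_splits} label splits: too many for exact enumeration")
        total = pooled.sum()
        diffs = np.array(
            [
                pooled[list(c)].mean() - (total - pooled[list(c)].sum()) / (n_tot - n_a)
                for c in itertools.combinations(range(n_tot), n_a)
            ]
        )
        exceed = np.abs(diffs) >= np.abs(observed) - 1e-12
        return PermutationResult(
            group_a=group_a,
            group_b=group_b,
            measure=measure,
            delay=delay,
            observed_diff=observed,
            p_value=int(exceed.sum()) / n_splits,
            n_permutations=n_splits,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    idx = rng.permuted(
        np.broadcast_to(np.arange(n_tot), (n_permutations, n_tot)).copy(), axis=1
    )
    perm_a = pooled[idx[:, :n_a]].mean(axis=1)
    perm_b = pooled[idx[:, n_a:]].mean(axis=1)
    diffs = perm_a - perm_b
    # tolerance absorbs floating error in ties with the observed statistic
    exceed = np.abs(diffs) >= np.abs(observed) - 1e-12
    p = (1 + int(exceed.sum())) / (1 + n_permutations)
    return PermutationResult(
        group_a=group_a,
        group_b=group_b,
        measure=measure,
        delay=delay,
        observed_diff=observed,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(rejected, p_adjusted)``; adjusted p-values are monotone
    and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, p_adj


def iqr_filter(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Flag values inside the Tukey fences ``[Q1 − k·IQR, Q3 + k·IQR]``.

    Quartiles use linear interpolation between order statistics.  With
    fewer than 4 values the screen is skipped (all included) with a
    warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        logger.warning("fewer than 4 values: IQR screen skipped, all included")
        return np.ones(v.size, dtype=bool)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - k * iqr) & (v <= q3 + k * iqr)


def _expand_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical covariates to indicators with a stated reference.

    The reference level is the first in canonical group order (for group
    labels) or the lexicographically first level otherwise; it is dropped.
    """
    cols: list[pd.Series] = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and col.dtype != bool:
            cols.append(col.astype(float))
            continue
        levels = sorted(col.astype(str).unique(), key=_level_key)
        for level in levels[1:]:
            cols.append(
                pd.Series(
                    (col.astype(str) == level).astype(float),
                    index=col.index,
                    name=f"{name}[{level}]",
                )
            )
    if not cols:
        return pd.DataFrame(index=covariates.index)
    return pd.concat(cols, axis=1)


def _level_key(level: str) -> tuple[int, str]:
    try:
        return (GROUP_ORDER.index(level), level)
    except ValueError:
        return (len(GROUP_ORDER), level)


def _ols_fit(
    y: np.ndarray,
    design: pd.DataFrame,
    outcome_name: str,
    *,
    excluded_outliers: int = 0,
    term_names: tuple[str, ...] = (),
) -> ModelFit:
    y = np.asarray(y, dtype=float)
    n, k = design.shape[0], design.shape[1]
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} predictors")
    if np.var(y) == 0:
        raise ValueError("outcome has zero variance")
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        bad = _deficient_columns(X, list(design.columns))
        raise ValueError(f"rank-deficient design; offending column(s): {bad}")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    return ModelFit(
        outcome_name=outcome_name,
        predictor_names=tuple(design.columns),
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        t_values=np.asarray(res.tvalues),
        coef_p_values=np.asarray(res.pvalues),
        f_statistic=float(res.fvalue) if np.isfinite(res.fvalue) else np.nan,
        model_p_value=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else np.nan,
        r_squared_adj=float(res.rsquared_adj),
        aic=float(aic),
        n_used=n,
        excluded_outliers=excluded_outliers,
        term_names=term_names,
    )


def _deficient_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns that do not enlarge the column space."""
    bad: list[str] = []
    kept: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, kept + [j]])
        if r > rank:
            kept.append(j)
            rank = r
        else:
            bad.append(names[j])
    return bad


def fit_quadratic_model(
    outcome: np.ndarray,
    measure_auc: np.ndarray,
    covariates: pd.DataFrame | None = None,
    include_square: bool = True,
    *,
    outcome_name: str = "outcome",
    measure_name: str = "measure",
) -> ModelFit:
    """OLS of outcome on [intercept, AUC, AUC² (optional), covariates].

    Categorical covariates are expanded to indicator columns (reference
    level dropped).  Reports per-coefficient t-tests, the overall F-test,
    adjusted R² and AIC.
    """
    y = np.asarray(outcome, dtype=float)
    m = np.asarray(measure_auc, dtype=float)
    if y.shape != m.shape:
        raise ValueError("outcome and measure_auc must be aligned")
    idx = pd.RangeIndex(y.size)
    parts = {"const": pd.Series(1.0, index=idx), measure_name: pd.Series(m, index=idx)}
    terms = [measure_name]
    if include_square:
        parts[f"{measure_name}_sq"] = pd.Series(m**2, index=idx)
        terms.append(f"{measure_name}_sq")
    design = pd.DataFrame(parts)
    if covariates is not None and covariates.shape[1]:
        if len(covariates) != y.size:
            raise ValueError("covariates must be aligned with outcome")
        design = pd.concat(
            [design, _expand_covariates(covariates.reset_index(drop=True))], axis=1
        )
    return _ols_fit(y, design, outcome_name, term_names=tuple(terms))


def candidate_term_sets(term_names: tuple[str, ...] = ("CC_auc", "GE_auc")) -> list[tuple[str, ...]]:
    """Admissible AUC term subsets under the hierarchy rule.

    A squared term (``X_sq``) is admitted only alongside its linear term.
    Sets are ordered by size, then by enumeration order, which fixes the
    tie-break of the AIC selection.
    """
    per_term = [((), (t,), (t, f"{t}_sq")) for t in term_names]
    combos = [tuple(itertools.chain.from_iterable(c)) for c in itertools.product(*per_term)]
    order = {c: i for i, c in enumerate(combos)}
    return sorted(combos, key=lambda c: (len(c), order[c]))


def aic_select(
    outcome: np.ndarray,
    term_values: dict[str, np.ndarray],
    forced_covariates: pd.DataFrame | None = None,
    *,
    outcome_name: str = "outcome",
) -> ModelFit:
    """Pick the AUC-term subset minimising the AIC, covariates always in.

    ``term_values`` maps linear term names (e.g. ``CC_auc``, ``GE_auc``)
    to their per-subject values; squares are derived internally.  The
    empty set (covariates-only model) is admissible.  Ties break toward
    fewer terms, then enumeration order.
    """
    names = tuple(term_values.keys())
    y = np.asarray(outcome, dtype=float)
    idx = pd.RangeIndex(y.size)
    columns = {"const": pd.Series(1.0, index=idx)}
    for t, v in term_values.items():
        v = np.asarray(v, dtype=float)
        if v.shape != y.shape:
            raise ValueError(f"term {t!r} not aligned with outcome")
        columns[t] = pd.Series(v, index=idx)
        columns[f"{t}_sq"] = pd.Series(v**2, index=idx)
    cov = (
        _expand_covariates(forced_covariates.reset_index(drop=True))
        if forced_covariates is not None and forced_covariates.shape[1]
        else pd.DataFrame(index=idx)
    )
    best: ModelFit | None = None
    last_error: ValueError | None = None
    for subset in candidate_term_sets(names):
        design = pd.concat(
            [pd.DataFrame({k: columns[k] for k in ("const", *subset)}), cov], axis=1
        )
        try:
            fit = _ols_fit(y, design, outcome_name, term_names=subset)
        except ValueError as exc:
            msg = str(exc)
            if "rank-deficient" in msg or "too small" in msg:
                # collinear or oversized candidate subsets are
                # unfittable at this sample, not fatal
                logger.debug("skipping candidate %s: %s", subset, exc)
                last_error = exc
                continue
            raise
        if best is None or fit.aic < best.aic:
            best = fit
    if best is None:
        raise last_error if last_error else ValueError("no fittable candidate model")
    return best


def compare_all_groups(
    auc_table: pd.DataFrame,
    group_labels: dict[str, str] | None = None,
    delays: list[int] | None = None,
    measures: list[str] | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Permutation tests for every group pair x measure x delay, FDR-corrected.

    ``auc_table`` is long-format with columns ``subject_id, measure,
    delay, auc`` and either a ``group`` column or a ``group_labels``
    mapping.  BH-FDR is applied across the whole family of rows.  Returns
    a table with columns ``contrast, group_a, group_b, measure, delay,
    observed_diff, p_raw, p_fdr, significant_at_q05``.
    """
    table = auc_table.copy()
    if "group" not in table.columns:
        if group_labels is None:
            raise ValueError("need a 'group' column or a group_labels mapping")
        table["group"] = table["subject_id"].map(group_labels)
    groups = sorted(table["group"].dropna().unique(), key=_level_key)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if delays is None:
        delays = sorted(table["delay"].unique())
    if measures is None:
        measures = sorted(table["measure"].unique())
    pairs = list(itertools.combinations(groups, 2))
    seeds = np.random.SeedSequence(seed).generate_state(
        len(pairs) * len(measures) * len(delays)
    )
    rows = []
    i = 0
    for ga, gb in pairs:
        for measure in measures:
            for delay in delays:
                sub = table[(table["measure"] == measure) & (table["delay"] == delay)]
                va = sub.loc[sub["group"] == ga, "auc"].to_numpy()
                vb = sub.loc[sub["group"] == gb, "auc"].to_numpy()
                res = permutation_test(
                    va,
                    vb,
                    n_permutations,
                    int(seeds[i] % (2**31)),
                    group_a=ga,
                    group_b=gb,
                    measure=measure,
                    delay=delay,
                )
                rows.append(
                    {
                        "contrast": f"{ga} vs {gb}",
                        "group_a": ga,
                        "group_b": gb,
                        "measure": measure,
                        "delay": delay,
                        "observed_diff": res.observed_diff,
                        "p_raw": res.p_value,
                    }
                )
                i += 1
    out = pd.DataFrame(rows)
    rejected, p_adj = fdr_bh(out["p_raw"].to_numpy(), q)
    out["p_fdr"] = p_adj
    out["significant_at_q05"] = rejected
    return out
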