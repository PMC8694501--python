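"""Survival and genomics statistics for the final subtypes.

Kaplan-Meier curves and the G-group log-rank test for recurrence-free
survival, multivariable Cox proportional-hazards adjustment for clinical
covariates (Efron tie handling), per-sample tumour mutation burden and
per-gene mutation enrichment across subtypes (chi-square with an exact
multivariate-hypergeometric fallback for sparse tables).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import OmicsLayer


@dataclass
class KMLogrankResult:
    curves: dict  # group -> DataFrame with timeline index and KM_estimate
    chi_square: float
    p_value: float
    df: int


def km_logrank(time, event, group) -> KMLogrankResult:
    """Per-group Kaplan-Meier estimates and the global G-group log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    groups = np.unique(group)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    curves = {}
    for g in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(time[group == g], event[group == g], label=str(g))
        curves[g] = kmf.survival_function_
    res = multivariate_logrank_test(time, group, event)
    return KMLogrankResult(
        curves=curves,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        df=int(groups.size - 1),
    )


@dataclass
class CoxFit:
    """Multivariable Cox fit: per-level hazard ratios with 95% CIs."""

    summary: pd.DataFrame  # index covariate level; columns HR, ci_low, ci_high, p_value
    converged: bool
    message: str = ""
    references: dict = field(default_factory=dict)


def _expand_design(df: pd.DataFrame, covariates, references) -> tuple[pd.DataFrame, dict]:
    design = pd.DataFrame(index=df.index)
    refs = {}
    for cov in covariates:
        col = df[cov]
        is_cat = (col.dtype == object) or isinstance(col.dtype, pd.CategoricalDtype) or (
            cov in references
        )
        if is_cat:
            ref = references.get(cov, sorted(col.unique())[0])
            refs[cov] = ref
            for level in sorted(col.unique(), key=str):
                if level == ref:
                    continue
                design[f"{cov}_{level}"] = (col == level).astype(float)
        else:
            design[cov] = col.astype(float)
    return design, refs


def cox_multivariable(
    table: pd.DataFrame,
    covariates: list[str],
    references: dict | None = None,
    time_col: str = "rfs_months",
    event_col: str = "rfs_event",
) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie handling.

    Categorical covariates (object/categorical dtype, or any covariate with
    an entry in ``references``) are expanded to indicators against the
    stated reference level. Non-convergence or separation (monotone
    likelihood) yields a flagged fit instead of an exception.
    """
    references = references or {}
    n_events = int(table[event_col].sum())
    design, refs = _expand_design(table, covariates, references)
    if n_events < design.shape[1] + 1:
        return CoxFit(summary=pd.DataFrame(), converged=False,
                      message=f"too few events ({n_events}) for {design.shape[1]} parameters",
                      references=refs)
    data = design.copy()
    data[time_col] = table[time_col].to_numpy(dtype=float)
    data[event_col] = table[event_col].to_numpy(dtype=int)

    cph = CoxPHFitter()  # lifelines default partial likelihood uses Efron ties
    message = ""
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col=time_col, event_col=event_col)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            return CoxFit(summary=pd.DataFrame(), converged=False,
                          message=f"fit failed: {exc}", references=refs)
    conv_warnings = [str(w.message) for w in caught if "onverg" in str(w.message) or
                     "complete separation" in str(w.message).lower()]
    if conv_warnings:
        converged = False
        message = "; ".join(conv_warnings[:2])
    betas = cph.params_
    if np.abs(betas).max() > 10:
        converged = False
        message = message or "extreme coefficients suggest monotone likelihood / separation"
    s = cph.summary
    summary = pd.DataFrame(
        {
            "HR": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
            "ci_high": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
            "p_value": s["p"],
        },
        index=s.index,
    )
    return CoxFit(summary=summary, converged=converged, message=message, references=refs)


# ---------------------------------------------------------------------------
# mutation statistics


def _log_comb(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def exact_kx2_test(mutated: np.ndarray, totals: np.ndarray) -> float:
    """Exact conditional test of homogeneity for a k x 2 table.

    Enumerates all allocations of the total mutated count across groups
    (multivariate hypergeometric null, Freeman-Halton construction) and
    sums the probabilities of tables no more probable than the observed
    one. Equivalent to the two-sided Fisher exact test for k = 2.
    """
    mutated = np.asarray(mutated, dtype=int)
    totals = np.asarray(totals, dtype=int)
    m = int(mutated.sum())
    n = int(totals.sum())

    def log_prob(xs: tuple[int, ...]) -> float:
        return float(_log_comb(totals, np.array(xs)).sum() - _log_comb(n, np.array([m]))[0])

    lp_obs = log_prob(tuple(mutated))
    total = 0.0
    ranges = [range(0, min(t, m) + 1) for t in totals[:-1]]
    for head in itertools.product(*ranges):
        last = m - sum(head)
        if last < 0 or last > totals[-1]:
            continue
        lp = log_prob(head + (last,))
        if lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return min(1.0, total)


@dataclass
class MutationSummary:
    per_gene: pd.DataFrame  # index gene; fraction_<subtype>..., p_value, fdr, test
    tmb: pd.Series          # per-sample mutated gene count


def mutation_stats(
    layer: OmicsLayer, labels, exact_max_mutated: int = 80,
) -> MutationSummary:
    """Tumour mutation burden and per-gene mutation enrichment by subtype.

    Per gene a subtype x (mutated, wild-type) contingency table is tested by
    chi-square; when any expected cell count is < 5 and the mutated total is
    small enough to enumerate, the exact conditional test is used instead.
    BH correction across genes.
    """
    if layer.kind != "binary":
        raise TypeError(f"mutation layer must be binary, got {layer.kind!r}")
    labels = np.asarray(labels)
    X = layer.values.to_numpy(dtype=int)
    subtypes = np.unique(labels)
    totals = np.array([(labels == s).sum() for s in subtypes])

    tmb = pd.Series(X.sum(axis=0), index=layer.sample_ids, name="tmb")

    rows = []
    for gi, gene in enumerate(layer.feature_ids):
        mutated = np.array([X[gi, labels == s].sum() for s in subtypes])
        fractions = mutated / totals
        m = int(mutated.sum())
        if m == 0 or m == totals.sum():
            p, test = 1.0, "degenerate"
        else:
            cont = np.stack([mutated, totals - mutated], axis=1)
            expected = np.outer(cont.sum(axis=1), cont.sum(axis=0)) / cont.sum()
            if (expected < 5).any() and m <= exact_max_mutated:
                if subtypes.size == 2:
                    p = float(stats.fisher_exact(cont)[1])
                    test = "fisher"
                else:
                    p = exact_kx2_test(mutated, totals)
                    test = "exact"
            else:
                p = float(stats.chi2_contingency(cont, correction=False)[1])
                test = "chi2"
        rows.append({"gene": gene, **{f"fraction_{s}": f for s, f in zip(subtypes, fractions)},
                     "p_value": p, "test": test})
    per_gene = pd.DataFrame(rows).set_index("gene")
    per_gene["fdr"] = multipletests(per_gene["p_value"].to_numpy(), method="fdr_bh")[1]
    return MutationSummary(per_gene=per_gene, tmb=tmb)
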