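"""Per-sample gene-set scoring and between-subtype comparisons.

Two scorers: single-sample GSEA (rank-weighted running-sum enrichment,
the engine behind pathway / immune-infiltration / androgen-receptor
signature heatmaps) and a simple mean-z alternative. Subtype comparisons
use the Kruskal-Wallis test with BH correction across sets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection, OmicsLayer


def _expr_frame(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, OmicsLayer) else expr


def ssgsea_scores(
    expr, sets: GeneSetCollection, alpha: float = 0.25,
    normalize: bool = False, min_genes: int = 5,
) -> pd.DataFrame:
    """Single-sample GSEA enrichment scores (set x sample).

    For each sample the genes are ordered by decreasing expression with
    integer rank values N..1; the enrichment score is the sum over all
    positions of P_in(i) - P_out(i), where P_in is the |rank|^alpha-weighted
    cumulative fraction of set genes encountered and P_out the unweighted
    cumulative fraction of non-set genes. ``normalize=True`` rescales the
    whole matrix by (max ES - min ES). Sets with fewer than ``min_genes``
    genes present are dropped with a warning.
    """
    values = _expr_frame(expr)
    genes = list(values.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    X = values.to_numpy(dtype=float)

    kept: list[tuple[str, np.ndarray]] = []
    for name, members in sets:
        rows = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=int)
        if rows.size < min_genes:
            warnings.warn(f"gene set {name!r}: only {rows.size} genes present (< {min_genes}); dropped")
            continue
        mask = np.zeros(N, dtype=bool)
        mask[rows] = True
        kept.append((name, mask))
    if not kept:
        raise ValueError("no gene set retains enough present genes")

    # per sample: walk order = decreasing expression; weights = rank value ^ alpha
    order = np.argsort(-X, axis=0, kind="stable")      # genes x samples walk order
    rank_value = np.arange(N, 0, -1, dtype=float) ** alpha  # position i has value (N-i)^alpha
    ES = np.zeros((len(kept), X.shape[1]))
    for j in range(X.shape[1]):
        ord_j = order[:, j]
        for si, (_, mask) in enumerate(kept):
            in_walk = mask[ord_j]
            w_in = np.where(in_walk, rank_value, 0.0)
            denom_in = w_in.sum()
            P_in = np.cumsum(w_in) / (denom_in if denom_in > 0 else 1.0)
            P_out = np.cumsum(~in_walk) / (N - in_walk.sum())
            ES[si, j] = float((P_in - P_out).sum())
    out = pd.DataFrame(ES, index=[name for name, _ in kept], columns=values.columns)
    if normalize:
        span = float(ES.max() - ES.min())
        if span > 0:
            out = out / span
    return out


def zscore_signature(expr, genes) -> pd.Series:
    """Mean per-gene cohort z-score over a gene set, per sample."""
    values = _expr_frame(expr)
    present = [g for g in genes if g in values.index]
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    sub = values.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    return pd.Series(z.mean(axis=0), index=values.columns, name="signature_score")


@dataclass
class GroupComparison:
    """Per-set Kruskal-Wallis comparison across subtypes."""

    table: pd.DataFrame  # index set, columns H, p_value, fdr, median_<subtype>...


def compare_by_subtype(scores: pd.DataFrame, labels) -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected) per score row across subtype groups,
    BH-adjusted across rows, with per-subtype median scores."""
    labels = np.asarray(labels)
    subtypes = np.unique(labels)
    if subtypes.size < 2:
        raise ValueError("need at least 2 groups")
    for s in subtypes:
        if (labels == s).sum() < 2:
            raise ValueError(f"group {s} has fewer than 2 samples")
    rows = []
    for name, row in scores.iterrows():
        groups = [row.to_numpy(dtype=float)[labels == s] for s in subtypes]
        try:
            H, p = stats.kruskal(*groups)
        except ValueError:  # all values identical -> no evidence of difference
            H, p = 0.0, 1.0
        if not np.isfinite(H):  # scipy yields nan when every value ties
            H, p = 0.0, 1.0
        rows.append({"set": name, "H": float(H), "p_value": float(p),
                     **{f"median_{s}": float(np.median(g)) for s, g in zip(subtypes, groups)}})
    table = pd.DataFrame(rows).set_index("set")
    table.insert(2, "fdr", multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1])
    return GroupComparison(table=table)
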