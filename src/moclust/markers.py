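"""Subtype marker derivation and nearest-template prediction (NTP).

Markers are derived one-vs-rest on the training expression layer: per gene
a Welch t statistic of the subtype against all other samples,
Benjamini-Hochberg control across genes, upregulated significant genes
ranked by statistic and truncated to the top N per subtype (a gene
qualifying for several subtypes goes to the one with the larger
statistic, so marker lists are disjoint).

NTP classifies an external sample by the cosine distance between its
z-scored expression over the pooled marker genes and each subtype's
binary template; significance comes from re-drawing random gene sets of
the same size from all genes, with BH FDR across samples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OmicsLayer


@dataclass
class MarkerSet:
    """Per-subtype ordered marker gene lists (descending score), disjoint."""

    markers: dict[int, list[str]]
    n_top: int = 100

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sub, genes in self.markers.items():
            if len(genes) > self.n_top:
                raise ValueError(f"subtype {sub}: more than n_top={self.n_top} markers")
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"marker lists overlap across subtypes: {sorted(overlap)[:5]}")
            seen |= set(genes)


@dataclass
class TemplateMatrix:
    """Pooled marker genes x subtype binary indicator."""

    genes: list[str]
    templates: pd.DataFrame  # genes x subtypes, 0/1

    def __post_init__(self) -> None:
        v = self.templates.to_numpy()
        if not np.isin(v, (0, 1)).all():
            raise ValueError("templates must be binary")
        if not (v.sum(axis=1) == 1).all():
            raise ValueError("each pooled gene must belong to exactly one subtype template")


def derive_markers(
    expr: OmicsLayer | pd.DataFrame, labels, n_top: int = 100, alpha: float = 0.05,
) -> MarkerSet:
    """Top-N upregulated subtype-specific genes by one-vs-rest Welch t.

    Per subtype, genes with positive Welch t and BH-adjusted p < ``alpha``
    are ranked by t; a gene significant for several subtypes is assigned to
    the subtype with the larger statistic; each list is truncated to
    ``n_top``. A subtype with fewer than ``n_top`` qualifying genes yields a
    shorter list with a warning.
    """
    values = expr.values if isinstance(expr, OmicsLayer) else expr
    labels = np.asarray(labels)
    subtypes = np.unique(labels)
    if subtypes.size < 2:
        raise ValueError("need at least 2 subtypes")
    for s in subtypes:
        if (labels == s).sum() < 3:
            raise ValueError(f"subtype {s} has fewer than 3 samples")
    X = values.to_numpy(dtype=float)
    genes = np.asarray(values.index)

    stat = {}
    qval = {}
    for s in subtypes:
        in_grp = X[:, labels == s]
        out_grp = X[:, labels != s]
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(in_grp, out_grp, axis=1, equal_var=False)
        t = np.nan_to_num(t)
        p = np.where(np.isnan(p), 1.0, p)
        qval[s] = multipletests(p, method="fdr_bh")[1]
        stat[s] = t

    # winner-takes-gene among significant up-regulated candidates
    best_sub = np.full(genes.size, -1, dtype=object)
    best_t = np.full(genes.size, -np.inf)
    for s in subtypes:
        ok = (stat[s] > 0) & (qval[s] < alpha)
        better = ok & (stat[s] > best_t)
        best_sub[better] = s
        best_t[better] = stat[s][better]

    markers: dict[int, list[str]] = {}
    for s in subtypes:
        mine = np.where(best_sub == s)[0]
        order = mine[np.argsort(-best_t[mine])]
        picked = list(genes[order][:n_top])
        if len(picked) < n_top:
            warnings.warn(f"subtype {s}: only {len(picked)} significant up-regulated markers (< {n_top})")
        markers[int(s)] = picked
    return MarkerSet(markers=markers, n_top=n_top)


def build_templates(markers: MarkerSet) -> TemplateMatrix:
    """Binary subtype templates over the pooled marker gene list."""
    if not any(markers.markers.values()):
        raise ValueError("empty marker set")
    pooled: list[str] = []
    owner: list[int] = []
    for s, genes in markers.markers.items():
        pooled.extend(genes)
        owner.extend([s] * len(genes))
    subtypes = sorted(markers.markers)
    T = pd.DataFrame(0, index=pd.Index(pooled, name="gene"), columns=subtypes)
    for g, s in zip(pooled, owner):
        T.loc[g, s] = 1
    return TemplateMatrix(genes=pooled, templates=T)


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _cosine_distance_to_binary(Z: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Cosine distance between each sample's z-profile restricted to the
    template's support and the all-ones template of that size.

    Restricting the sample vector to the support makes the observed
    statistic exchangeable with the random-gene-set null, which uses the
    identical computation on resampled supports.
    """
    sub = Z[mask]
    m = int(mask.sum())
    num = sub.sum(axis=0)
    den = np.linalg.norm(sub, axis=0) * np.sqrt(m)
    den = np.where(den == 0, 1.0, den)
    return 1.0 - num / den


def ntp_classify(
    expr: OmicsLayer | pd.DataFrame,
    templates: TemplateMatrix,
    n_perm: int = 1000,
    fdr_cut: float = 0.05,
    seed: int = 0,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Nearest-template prediction of subtype membership.

    Per sample: cosine distance between its z-scored expression over the
    template genes present in ``expr`` and each subtype's binary template;
    predicted subtype = argmin distance. The nominal p-value compares the
    winning distance against ``n_perm`` null replicates, each the minimum
    distance to one random gene set per template (matched sizes, drawn from
    all genes) so the null mirrors the argmin selection; BH FDR across
    samples; samples with FDR <= ``fdr_cut`` are flagged classifiable.

    Returns a DataFrame indexed by sample with columns ``predicted``,
    ``dist_<subtype>`` per template, ``p_value``, ``fdr``, ``classifiable``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values = expr.values if isinstance(expr, OmicsLayer) else expr
    all_genes = values.index
    present = [g for g in templates.templates.index if g in set(all_genes)]
    coverage = len(present) / len(templates.templates)
    if coverage < min_coverage:
        missing = sorted(set(templates.templates.index) - set(all_genes))
        raise ValueError(
            f"only {coverage:.0%} of template genes present (< {min_coverage:.0%}); "
            f"missing e.g. {missing[:10]}"
        )

    Zfull = _zscore_rows(values.to_numpy(dtype=float))
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    rows = np.array([gene_pos[g] for g in present])
    Z = Zfull[rows]  # template genes x samples
    T = templates.templates.loc[present]
    subtypes = list(T.columns)

    dists = np.column_stack(
        [_cosine_distance_to_binary(Z, T[s].to_numpy().astype(bool)) for s in subtypes]
    )  # samples x subtypes
    pred_idx = dists.argmin(axis=1)
    d_obs = dists[np.arange(dists.shape[0]), pred_idx]

    # null: per replicate, one random gene set per template (matched sizes,
    # drawn from all genes); the null statistic is the minimum distance
    # across them, mirroring the argmin selection of the observed statistic
    rng = np.random.default_rng(seed)
    n_samples = Z.shape[1]
    null_min = np.full((n_perm, n_samples), np.inf)
    for s in subtypes:
        size = int(T[s].sum())
        # bound scratch memory to ~20M floats per chunk
        chunk = max(1, min(n_perm, 20_000_000 // max(1, size * n_samples)))
        for start in range(0, n_perm, chunk):
            stop = min(start + chunk, n_perm)
            idx = rng.integers(0, Zfull.shape[0], size=(stop - start, size))
            sub = Zfull[idx]                          # chunk x size x n_samples
            num = sub.sum(axis=1)
            den = np.linalg.norm(sub, axis=1) * np.sqrt(size)
            null_min[start:stop] = np.minimum(
                null_min[start:stop], 1.0 - num / np.where(den == 0, 1.0, den))
    pvals = (1.0 + (null_min <= d_obs[None, :]).sum(axis=0)) / (n_perm + 1.0)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "predicted": [subtypes[j] for j in pred_idx],
            **{f"dist_{s}": dists[:, j] for j, s in enumerate(subtypes)},
            "p_value": pvals,
            "fdr": fdr,
            "classifiable": fdr <= fdr_cut,
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    return out
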