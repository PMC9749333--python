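"""Histo-genomic association stage.

Connects image-derived risk groups to transcriptomics: zero-expression
filtering, per-gene Wilcoxon rank-sum differential expression with
Benjamini-Hochberg control, hypergeometric over-representation of
user-supplied gene sets among the differential genes, per-sample ssGSEA
pathway scores, and Wilcoxon association of pathway scores with texture
features dichotomized at their median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "filter_zero_genes",
    "bh_adjust",
    "deg_wilcoxon",
    "overrepresentation_test",
    "ssgsea_scores",
    "pathway_feature_association",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT record)."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in set {self.name!r}")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, "
                                 f"description and >=1 gene")
            sets.append(GeneSet(parts[0], parts[1], tuple(parts[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def filter_zero_genes(matrix: pd.DataFrame, rule: str = "all") -> pd.DataFrame:
    """Drop unexpressed genes from a genes x samples matrix.

    ``rule='all'`` (default, most conservative) removes genes that are zero
    in every sample; ``'any'`` removes genes zero in at least one sample;
    ``'fraction:<f>'`` removes genes zero in more than fraction f of samples.
    """
    zero = matrix.to_numpy() == 0
    if rule == "all":
        drop = zero.all(axis=1)
    elif rule == "any":
        drop = zero.any(axis=1)
    elif rule.startswith("fraction:"):
        f = float(rule.split(":", 1)[1])
        drop = zero.mean(axis=1) > f
    else:
        raise ValueError(f"unknown zero-filter rule {rule!r}")
    out = matrix.loc[~drop]
    if out.empty:
        raise ValueError("no expressed genes remain after filtering")
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_arrays(matrix: pd.DataFrame, groups: pd.Series):
    groups = pd.Series(groups).reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError(f"samples without group label: "
                         f"{list(groups.index[groups.isna()])}")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a = matrix.loc[:, groups == labels[0]].to_numpy()
    b = matrix.loc[:, groups == labels[1]].to_numpy()
    return a, b, labels


def deg_wilcoxon(matrix: pd.DataFrame, groups: pd.Series,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between two risk groups.

    Uses the exact null distribution for small groups (both n < 10, no ties)
    and the tie-corrected normal approximation otherwise; p-values are BH
    adjusted across all tested genes. A gene constant across all samples is
    reported with p = 1. Returns a DataFrame indexed by gene with columns
    ``statistic, direction, pvalue, adj_pvalue, significant``.
    """
    a, b, labels = _group_arrays(matrix, groups)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    method = "exact" if (a.shape[1] < 10 and b.shape[1] < 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                             method=method)
    pvals = np.asarray(res.pvalue, dtype=float)
    stat = np.asarray(res.statistic, dtype=float)
    constant = (matrix.to_numpy().std(axis=1) == 0)
    pvals[constant] = 1.0
    # direction: sign of (first-label median - second-label median)
    diff = np.median(a, axis=1) - np.median(b, axis=1)
    adj = bh_adjust(pvals)
    return pd.DataFrame({
        "statistic": stat,
        "direction": np.sign(diff),
        "pvalue": pvals,
        "adj_pvalue": adj,
        "significant": adj < alpha,
    }, index=matrix.index)


def overrepresentation_test(deg_ids, universe_ids, gene_sets: list[GeneSet],
                            alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each set in the DEGs.

    P is the probability of observing at least the seen overlap when drawing
    ``len(deg_ids)`` genes from the universe; sets are intersected with the
    universe first; BH adjustment across sets.
    """
    universe = set(universe_ids)
    if not universe:
        raise ValueError("empty universe")
    degs = set(deg_ids)
    if not degs <= universe:
        raise ValueError("DEGs must be a subset of the universe")
    rows = []
    for gs in gene_sets:
        members = set(gs.genes) & universe
        k = len(members & degs)
        # P(X >= k), X ~ Hypergeom(N=|U|, K=|set|, n=|DEG|)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(degs)))
        rows.append({"set": gs.name, "set_size": len(members),
                     "overlap": k, "pvalue": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set")
    out["adj_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["adj_pvalue"] < alpha
    return out


def ssgsea_scores(matrix: pd.DataFrame, gene_sets: list[GeneSet],
                  alpha: float = 0.25, standardize: bool = False) -> pd.DataFrame:
    """Single-sample GSEA enrichment score per (gene set, sample).

    Per sample, genes are ranked by expression (descending; ties share the
    average rank) and the score is the sum over the ranked list of the
    difference between the rank^alpha-weighted in-set ECDF and the unweighted
    out-of-set ECDF. Scores depend on expression only through ranks, so any
    strictly increasing per-sample transform leaves them unchanged. A set
    with no member in the matrix scores NaN with a warning. Optional
    cross-sample min-max standardization is off by default.
    """
    n_genes = matrix.shape[0]
    gene_index = pd.Index(matrix.index)
    # ranks: highest expression -> rank n_genes (used as the weight base)
    scores = pd.DataFrame(index=[gs.name for gs in gene_sets],
                          columns=matrix.columns, dtype=float)
    in_set_masks = {}
    for gs in gene_sets:
        mask = gene_index.isin(gs.genes)
        if not mask.any():
            warnings.warn(f"gene set {gs.name!r} has no member in the matrix")
        in_set_masks[gs.name] = mask

    X = matrix.to_numpy()
    for si, sample in enumerate(matrix.columns):
        expr = X[:, si]
        # average ranks, ascending, then flip so the top gene has rank n
        asc = stats.rankdata(expr, method="average")
        order = np.argsort(-expr, kind="stable")  # descending walk order
        ranks_desc = asc[order]                   # rank magnitude per position
        for gs in gene_sets:
            mask = in_set_masks[gs.name][order]
            if not mask.any():
                continue
            w = np.abs(ranks_desc) ** alpha
            p_in = np.where(mask, w, 0.0)
            p_in = np.cumsum(p_in) / p_in.sum()
            n_out = n_genes - mask.sum()
            p_out = np.cumsum(np.where(mask, 0.0, 1.0)) / n_out if n_out else \
                np.zeros(n_genes)
            scores.loc[gs.name, sample] = float(np.sum(p_in - p_out))
    if standardize:
        lo = scores.min(axis=None)
        hi = scores.max(axis=None)
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
    return scores


def pathway_feature_association(scores: pd.DataFrame, features: pd.DataFrame,
                                adjust: bool = False) -> pd.DataFrame:
    """Wilcoxon association between pathway scores and texture features.

    Samples are dichotomized at each feature's median (strictly above vs the
    rest); per (set, feature) cell a two-sided rank-sum test compares pathway
    scores between the halves. Returns a sets x features p-value table;
    ``adjust=True`` applies BH across the whole matrix. All-tied features
    are skipped (NaN column) with a warning.
    """
    missing = [s for s in scores.columns if s not in features.index]
    if missing:
        raise ValueError(f"feature values missing for samples: {missing}")
    feats = features.loc[list(scores.columns)]
    out = pd.DataFrame(index=scores.index, columns=feats.columns, dtype=float)
    for fname in feats.columns:
        v = feats[fname].to_numpy(dtype=float)
        med = np.median(v)
        hi = v > med
        if hi.all() or not hi.any():
            warnings.warn(f"feature {fname!r} has no median split; skipped")
            continue
        a = scores.loc[:, hi].to_numpy()
        b = scores.loc[:, ~hi].to_numpy()
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                                 method="asymptotic")
        out[fname] = np.asarray(res.pvalue, dtype=float)
    if adjust:
        flat = out.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = flat.copy()
        adj[ok] = bh_adjust(flat[ok])
        out = pd.DataFrame(adj.reshape(out.shape), index=out.index,
                           columns=out.columns)
    return out
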