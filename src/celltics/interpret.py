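"""Pathway importance from hidden-layer activations, and the CV stochasticity test.

Every hidden neuron corresponds to a pathway (or an artificial pad node).
For pathway p and cell type t, A[t, p] is the mean post-tanh activation
over training cells of type t. Sorting A[., p] descending, the importance
of p is the gap between the two largest type averages,

    d_p = A_(1),p - A_(2),p,

and the pathway is assigned to the top type. Because hidden activations
are shared by every downstream predictive head in this architecture, the
gap is single-valued per neuron and the final score D_p equals d_p; the
layer level is still reported alongside. Pathways with D_p at or above
the threshold (default 0.1) are flagged important.

A pathway flagged important without differential mean expression may
instead show differential expression *variability*: for each gene in the
pathway the coefficient of variation (sd/mean) is computed within two
cell groups, and a Wilcoxon signed-rank test over the genes' paired CVs
assesses whether one group is systematically noisier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .hierarchy import LayeredPathwayGraph, MaskStack
from .network import ModelParams, forward

EXACT_PAIR_LIMIT = 25  # below this many nonzero pairs, use the exact null

__all__ = [
    "pathway_activations",
    "pathway_importance",
    "pathway_cv_test",
    "log_fold_change",
    "export_ranked_genes",
]


def pathway_activations(
    params: ModelParams,
    masks: MaskStack,
    graph: LayeredPathwayGraph,
    X: np.ndarray,
    labels,
) -> pd.DataFrame:
    """Per-type mean activation A[t, p], cell types x pathway neurons.

    ``X`` is cells x genes in mask gene order; ``labels`` the cell types.
    Columns cover every hidden node, artificial pads included (they are
    filtered later, at reporting time).
    """
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels and X disagree on cell count")
    res = forward(params, masks, X)
    col_names: list = []
    blocks = []
    for k, act in enumerate(res.activations):
        col_names.extend(masks.col_ids[k])
        blocks.append(act)
    acts = np.hstack(blocks)
    types = sorted(set(labels.tolist()))
    rows = []
    for t in types:
        sel = labels == t
        if not sel.any():
            raise ValueError(f"cell type {t!r} has no cells")
        rows.append(acts[sel].mean(axis=0))
    return pd.DataFrame(rows, index=types, columns=col_names)


def pathway_importance(
    A: pd.DataFrame,
    threshold: float = 0.1,
    graph: LayeredPathwayGraph | None = None,
    names: dict | None = None,
) -> pd.DataFrame:
    """Rank pathways by the gap between their two largest type averages.

    Returns a DataFrame with pathway_id, pathway_name, level, cell_type
    (the argmax type), d_p, D_p and the important flag, sorted by D_p
    descending. Artificial pad nodes are excluded when ``graph`` is given.
    """
    if A.shape[0] < 2:
        raise ValueError("importance needs >= 2 cell types")
    names = names or {}
    artificial = graph.artificial if graph is not None else set()
    level_of = graph.level_of if graph is not None else {}
    rows = []
    vals = A.to_numpy()
    order = np.sort(vals, axis=0)
    d = order[-1] - order[-2]
    top = A.index.to_numpy()[vals.argmax(axis=0)]
    for j, p in enumerate(A.columns):
        if p in artificial:
            continue
        d_p = float(d[j])
        rows.append(
            {
                "pathway_id": p,
                "pathway_name": names.get(p, p),
                "level": level_of.get(p, np.nan),
                "cell_type": top[j],
                "d_p": d_p,
                "D_p": d_p,
                "important": d_p >= threshold,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["D_p", "pathway_id"], ascending=[False, True]
    ).reset_index(drop=True)
    table.attrs["threshold"] = threshold
    return table


def _cv(values: np.ndarray) -> np.ndarray:
    """Per-gene coefficient of variation: sample sd (ddof=1) over mean."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean > 0, sd / mean, np.nan)


def pathway_cv_test(
    matrix: pd.DataFrame,
    pathway_genes: dict,
    groups: pd.Series,
) -> pd.DataFrame:
    """Wilcoxon signed-rank test on paired per-gene CVs between two groups.

    ``matrix`` is genes x cells (normalized expression), ``groups`` maps
    each cell to one of exactly two group labels. Genes with zero mean in
    either group are excluded (and counted); zero CV differences are
    dropped; the exact null is used below 25 nonzero pairs, otherwise the
    normal approximation with continuity correction. A pathway with no
    testable gene yields p = NaN with a reason code.
    """
    groups = groups.loc[matrix.columns]
    labs = sorted(groups.unique().tolist())
    if len(labs) != 2:
        raise ValueError(f"need exactly two groups, got {labs}")
    sel1 = (groups == labs[0]).to_numpy()
    sel2 = (groups == labs[1]).to_numpy()
    if sel1.sum() < 2 or sel2.sum() < 2:
        raise ValueError("both groups need >= 2 cells")

    rows = []
    for pid, genes in pathway_genes.items():
        genes = [g for g in genes if g in matrix.index]
        row = {
            "pathway_id": pid,
            "n_group1": int(sel1.sum()),
            "n_group2": int(sel2.sum()),
            "group1": labs[0],
            "group2": labs[1],
        }
        if not genes:
            rows.append({**row, "n_genes_tested": 0, "n_excluded": 0,
                         "p_value": np.nan, "direction": None, "reason": "no_gene_in_matrix"})
            continue
        vals = matrix.loc[genes].to_numpy(dtype=float)
        cv1 = _cv(vals[:, sel1])
        cv2 = _cv(vals[:, sel2])
        ok = ~np.isnan(cv1) & ~np.isnan(cv2)
        excluded = int((~ok).sum())
        diffs = cv1[ok] - cv2[ok]
        nonzero = diffs[diffs != 0]
        if diffs.size == 0:
            rows.append({**row, "n_genes_tested": 0, "n_excluded": excluded,
                         "p_value": np.nan, "direction": None, "reason": "no_testable_gene"})
            continue
        if nonzero.size == 0:
            rows.append({**row, "n_genes_tested": int(diffs.size), "n_excluded": excluded,
                         "p_value": 1.0, "direction": "none", "reason": "all_zero_differences"})
            continue
        method = "exact" if nonzero.size < EXACT_PAIR_LIMIT else "approx"
        stat = wilcoxon(
            nonzero,
            alternative="two-sided",
            method=method,
            correction=(method == "approx"),
        )
        direction = labs[0] if np.median(cv1[ok]) > np.median(cv2[ok]) else labs[1]
        if np.median(cv1[ok]) == np.median(cv2[ok]):
            direction = "none"
        rows.append({**row, "n_genes_tested": int(nonzero.size), "n_excluded": excluded,
                     "p_value": float(stat.pvalue), "direction": direction, "reason": ""})
    return pd.DataFrame(rows)


def log_fold_change(matrix: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per-gene difference of mean log-normalized expression between groups.

    Positive values mean higher expression in the alphabetically first
    group.
    """
    groups = groups.loc[matrix.columns]
    labs = sorted(groups.unique().tolist())
    if len(labs) != 2:
        raise ValueError(f"need exactly two groups, got {labs}")
    m1 = matrix.loc[:, (groups == labs[0]).to_numpy()].mean(axis=1)
    m2 = matrix.loc[:, (groups == labs[1]).to_numpy()].mean(axis=1)
    return (m1 - m2).rename("logFC")


def export_ranked_genes(scores: pd.Series, path=None) -> pd.DataFrame:
    """Rank genes by score descending (ties: lexicographic id) for enrichment tools."""
    if len(scores) == 0:
        raise ValueError("empty score vector")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("scores must be finite")
    df = scores.rename("score").rename_axis("gene").reset_index()
    df = df.sort_values(["score", "gene"], ascending=[False, True]).reset_index(drop=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
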