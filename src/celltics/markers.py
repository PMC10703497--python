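"""Cell-type-specific expression scoring and marker gene selection.

A gene is an informative feature either because it is specifically *highly*
expressed in one cell type or specifically *lowly* expressed there. Both
directions are scored with a product of a gene-level dispersion term and a
type-level expression ratio, each bounded in [0, 1]:

high:  x_hat[t, g] = (expr[t, g] + 1) / (max_t' expr[t', g] + 1)
       tau[g]      = sum_t (1 - x_hat[t, g]) / (n - 1)
       phi[t, g]   = tau[g] * x_hat[t, g]

low:   z_hat[t, g] = (min_t' expr[t', g] + 1) / (expr[t, g] + 1)
       omega[g]    = sum_t (1 - z_hat[t, g]) / (n - 1)
       rho[t, g]   = omega[g] * z_hat[t, g]

The +1 pseudo-count damps fold changes among lowly expressed genes. At the
maximum-expressing type phi equals tau exactly; at the minimum-expressing
type rho equals omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerScores",
    "MarkerSet",
    "aggregate_by_type",
    "high_specificity_scores",
    "low_specificity_scores",
    "select_markers",
    "score_and_select",
    "write_marker_report",
]


@dataclass
class MarkerScores:
    """Specificity score tables, all oriented cell types x genes."""

    phi: pd.DataFrame
    tau: pd.Series
    xhat: pd.DataFrame
    rho: pd.DataFrame
    omega: pd.Series
    zhat: pd.DataFrame


@dataclass
class MarkerSet:
    """Selected marker genes per cell type, high and low direction."""

    high: dict = field(default_factory=dict)   # type -> list of genes
    low: dict = field(default_factory=dict)    # type -> list of genes
    alpha: float = 0.95
    beta: float = 0.9
    high_cutoffs: dict = field(default_factory=dict)  # type -> quantile value
    low_cutoffs: dict = field(default_factory=dict)

    @property
    def combined(self) -> list:
        """Union of all per-type marker lists, sorted for reproducibility."""
        genes: set = set()
        for lst in self.high.values():
            genes.update(lst)
        for lst in self.low.values():
            genes.update(lst)
        return sorted(genes)


def aggregate_by_type(
    normalized: pd.DataFrame, annotation: pd.DataFrame, level: str = "cell_type"
) -> pd.DataFrame:
    """Mean normalized expression per label, returned as types x genes.

    ``level`` selects the annotation column (``cell_type`` or
    ``sub_cell_type``). Requires at least two distinct labels covering
    every cell in the matrix.
    """
    if level not in annotation.columns:
        raise ValueError(f"annotation has no column {level!r}")
    labels = annotation.loc[normalized.columns, level]
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:5]
        raise ValueError(f"cells without a {level} label, e.g. {missing}")
    profile = normalized.T.groupby(labels).mean()
    profile = profile.sort_index()
    if profile.shape[0] < 2:
        raise ValueError(f"need >= 2 distinct {level} labels, got {profile.shape[0]}")
    return profile


def high_specificity_scores(profile: pd.DataFrame):
    """Return (phi, tau, xhat) for a types x genes profile."""
    expr = profile.to_numpy(dtype=float)
    n = expr.shape[0]
    if n < 2:
        raise ValueError("profile needs >= 2 cell types")
    xhat = (expr + 1.0) / (expr.max(axis=0, keepdims=True) + 1.0)
    tau = (1.0 - xhat).sum(axis=0) / (n - 1)
    phi = tau[None, :] * xhat
    idx, cols = profile.index, profile.columns
    return (
        pd.DataFrame(phi, index=idx, columns=cols),
        pd.Series(tau, index=cols),
        pd.DataFrame(xhat, index=idx, columns=cols),
    )


def low_specificity_scores(profile: pd.DataFrame):
    """Return (rho, omega, zhat) for a types x genes profile."""
    expr = profile.to_numpy(dtype=float)
    n = expr.shape[0]
    if n < 2:
        raise ValueError("profile needs >= 2 cell types")
    zhat = (expr.min(axis=0, keepdims=True) + 1.0) / (expr + 1.0)
    omega = (1.0 - zhat).sum(axis=0) / (n - 1)
    rho = omega[None, :] * zhat
    idx, cols = profile.index, profile.columns
    return (
        pd.DataFrame(rho, index=idx, columns=cols),
        pd.Series(omega, index=cols),
        pd.DataFrame(zhat, index=idx, columns=cols),
    )


def compute_scores(profile: pd.DataFrame) -> MarkerScores:
    phi, tau, xhat = high_specificity_scores(profile)
    rho, omega, zhat = low_specificity_scores(profile)
    return MarkerScores(phi=phi, tau=tau, xhat=xhat, rho=rho, omega=omega, zhat=zhat)


def select_markers(scores: MarkerScores, alpha: float = 0.95, beta: float = 0.9) -> MarkerSet:
    """Select genes whose phi (rho) strictly exceeds the per-type quantile.

    For each cell type t, gene g is a high marker iff
    ``phi[t, g] > quantile_alpha(phi[t, :])`` and a low marker iff
    ``rho[t, g] > quantile_beta(rho[t, :])``. The strict inequality means
    genes tied with the cutoff are excluded. Quantiles use linear
    interpolation between order statistics.
    """
    for name, q in (("alpha", alpha), ("beta", beta)):
        if not 0 <= q < 1:
            raise ValueError(f"{name} must lie in [0, 1)")
    result = MarkerSet(alpha=alpha, beta=beta)
    for t in scores.phi.index:
        row = scores.phi.loc[t]
        cutoff = float(np.quantile(row.to_numpy(), alpha))
        result.high_cutoffs[t] = cutoff
        result.high[t] = sorted(row.index[row > cutoff])
    for t in scores.rho.index:
        row = scores.rho.loc[t]
        cutoff = float(np.quantile(row.to_numpy(), beta))
        result.low_cutoffs[t] = cutoff
        result.low[t] = sorted(row.index[row > cutoff])
    return result


def score_and_select(
    normalized: pd.DataFrame,
    annotation: pd.DataFrame,
    level: str = "cell_type",
    alpha: float = 0.95,
    beta: float = 0.9,
) -> tuple[MarkerScores, MarkerSet]:
    """Convenience: aggregate, score and select markers in one call."""
    profile = aggregate_by_type(normalized, annotation, level=level)
    scores = compute_scores(profile)
    return scores, select_markers(scores, alpha=alpha, beta=beta)


def write_marker_report(markers: MarkerSet, scores: MarkerScores, path) -> pd.DataFrame:
    """Write the selected markers as TSV: type, gene, direction, score, cutoff."""
    rows = []
    for t, genes in markers.high.items():
        for g in genes:
            rows.append((t, g, "high", float(scores.phi.loc[t, g]), markers.high_cutoffs[t]))
    for t, genes in markers.low.items():
        for g in genes:
            rows.append((t, g, "low", float(scores.rho.loc[t, g]), markers.low_cutoffs[t]))
    report = pd.DataFrame(rows, columns=["cell_type", "gene", "direction", "score", "quantile_cutoff"])
    report = report.sort_values(["cell_type", "direction", "gene"]).reset_index(drop=True)
    report.to_csv(path, sep="\t", index=False)
    return report
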