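"""Synthetic scRNA-seq counts with planted marker structure and a toy pathway tree.

Counts follow a negative-binomial law in the mean/dispersion
parameterization (variance = mu + mu^2 / size), the standard noise model
for UMI counts. Each cell type owns a block of high markers (mean scaled
up by 2**effect for its cells) and a block of low markers (scaled down by
the reciprocal factor); each sub-cell type owns a further nested block of
high markers. The companion toy hierarchy is a balanced tree in the
Reactome TSV dialect whose first leaves are "signal" pathways holding
exactly one cell type's high markers, so marker selection, mask building
and pathway-importance recovery can all be exercised against known truth.

Gene-to-block assignment is a pure function of the configuration (blocks
are laid out in gene-index order), so the matrix generator and the
hierarchy writer agree without sharing state; randomness only enters
through the count draws.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

TOY_PREFIX = "R-TOY"

__all__ = ["SimConfig", "simulate_dataset", "write_toy_hierarchy", "simulate_cv_shift"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give 3 cell types x 2 sub-types x 100 cells = 600 cells over
    120 genes, planted log2 fold change 2, and a depth-2 branching-3 toy
    tree (9 leaf pathways: one pure signal leaf per cell type, the rest
    hosting sub-type markers, low markers and background genes).
    """

    n_types: int = 3
    n_subtypes: int = 2          # per cell type
    cells_per_subtype: int = 100
    n_genes: int = 120
    n_high_markers: int = 8      # per cell type
    n_low_markers: int = 4       # per cell type
    n_sub_markers: int = 6       # per sub-cell type
    effect: float = 2.0          # planted log2 fold change
    baseline_mean: float = 5.0   # NB mean of background genes
    dispersion: float = 2.0      # NB size; CV^2 = 1/mu + 1/size
    annotated_fraction: float = 1.0
    tree_depth: int = 2
    tree_branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_types", "n_subtypes", "cells_per_subtype", "n_genes",
                     "tree_depth", "tree_branching"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0 < self.annotated_fraction <= 1:
            raise ValueError("annotated_fraction must be in (0, 1]")
        if self.n_planted > self.n_genes:
            raise ValueError(
                f"planted markers ({self.n_planted}) exceed n_genes ({self.n_genes})"
            )
        if self.tree_branching ** self.tree_depth < self.n_types:
            raise ValueError("toy tree has fewer leaves than cell types")

    # --- deterministic layout -------------------------------------------------
    @property
    def n_planted(self) -> int:
        return self.n_types * (self.n_high_markers + self.n_low_markers) + \
            self.n_types * self.n_subtypes * self.n_sub_markers

    @property
    def gene_ids(self) -> list:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def type_ids(self) -> list:
        return [f"T{i}" for i in range(self.n_types)]

    def subtype_ids(self, t: str) -> list:
        return [f"{t}.S{j}" for j in range(self.n_subtypes)]

    def marker_layout(self) -> dict:
        """Block layout: which gene indices carry which planted signal."""
        genes = self.gene_ids
        pos = 0
        layout = {"high": {}, "low": {}, "sub": {}, "background": []}
        for t in self.type_ids:
            layout["high"][t] = genes[pos : pos + self.n_high_markers]
            pos += self.n_high_markers
        for t in self.type_ids:
            layout["low"][t] = genes[pos : pos + self.n_low_markers]
            pos += self.n_low_markers
        for t in self.type_ids:
            for s in self.subtype_ids(t):
                layout["sub"][s] = genes[pos : pos + self.n_sub_markers]
                pos += self.n_sub_markers
        layout["background"] = genes[pos:]
        return layout


def simulate_dataset(cfg: SimConfig):
    """Draw counts; returns (counts genes x cells, annotation, truth dict).

    ``truth`` records every planted marker gene and the signal pathway of
    each (sub-)cell type, matching :func:`write_toy_hierarchy`.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids
    layout = cfg.marker_layout()
    gene_index = {g: i for i, g in enumerate(genes)}

    cells, cell_types, sub_types = [], [], []
    for t in cfg.type_ids:
        for s in cfg.subtype_ids(t):
            for c in range(cfg.cells_per_subtype):
                cells.append(f"{s}_c{c:04d}")
                cell_types.append(t)
                sub_types.append(s)

    factor = 2.0 ** cfg.effect
    mu = np.full((cfg.n_genes, len(cells)), cfg.baseline_mean)
    cell_types_arr = np.asarray(cell_types)
    sub_types_arr = np.asarray(sub_types)
    for t in cfg.type_ids:
        cols = cell_types_arr == t
        for g in layout["high"][t]:
            mu[gene_index[g], cols] *= factor
        for g in layout["low"][t]:
            mu[gene_index[g], cols] /= factor
    for t in cfg.type_ids:
        for s in cfg.subtype_ids(t):
            cols = sub_types_arr == s
            for g in layout["sub"][s]:
                mu[gene_index[g], cols] *= factor

    size = cfg.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    matrix = pd.DataFrame(counts, index=genes, columns=cells)
    annotation = pd.DataFrame(
        {"cell_type": cell_types, "sub_cell_type": sub_types},
        index=pd.Index(cells, name="cell_id"),
    )
    truth = {
        "high_markers": layout["high"],
        "low_markers": layout["low"],
        "sub_markers": layout["sub"],
        "background_genes": layout["background"],
        "signal_pathways": _signal_pathways(cfg),
        "background_pathways": _background_pathways(cfg),
        "gene_pathway": _gene_annotation(cfg),
    }
    return matrix, annotation, truth


# --- toy hierarchy ------------------------------------------------------------

def _leaf_ids(cfg: SimConfig) -> list:
    n_leaves = cfg.tree_branching ** cfg.tree_depth
    return [f"{TOY_PREFIX}-L{cfg.tree_depth}-{i}" for i in range(n_leaves)]


def _signal_pathways(cfg: SimConfig) -> dict:
    """Leaf i is the pure signal pathway of cell type i."""
    leaves = _leaf_ids(cfg)
    return {t: leaves[i] for i, t in enumerate(cfg.type_ids)}


def _gene_annotation(cfg: SimConfig) -> dict:
    """Deterministic gene -> leaf pathway map shared by matrix and tree.

    Type-high markers go to their pure signal leaf. The remaining leaves
    are split in two: the first half hosts low and sub-type markers, the
    second half hosts only background genes (so at least one pathway
    carries no planted type signal at all, when leaves permit). With
    annotated_fraction < 1, trailing background genes stay unannotated.
    """
    leaves = _leaf_ids(cfg)
    layout = cfg.marker_layout()
    mapping: dict = {}
    for t, leaf in _signal_pathways(cfg).items():
        for g in layout["high"][t]:
            mapping[g] = leaf
    rest_leaves = leaves[cfg.n_types :] or leaves
    if len(rest_leaves) >= 2:
        marker_leaves = rest_leaves[: len(rest_leaves) // 2]
        bg_leaves = rest_leaves[len(rest_leaves) // 2 :]
    else:
        marker_leaves = bg_leaves = rest_leaves

    other_markers = []
    for t in cfg.type_ids:
        other_markers.extend(layout["low"][t])
    for s in sorted(layout["sub"]):
        other_markers.extend(layout["sub"][s])
    for i, g in enumerate(other_markers):
        mapping[g] = marker_leaves[i % len(marker_leaves)]

    background = layout["background"]
    n_annotated_bg = int(round(cfg.annotated_fraction * len(background)))
    for i, g in enumerate(background[:n_annotated_bg]):
        mapping[g] = bg_leaves[i % len(bg_leaves)]
    return mapping


def _background_pathways(cfg: SimConfig) -> list:
    """Leaves annotated exclusively with background genes (may be empty)."""
    mapping = _gene_annotation(cfg)
    layout = cfg.marker_layout()
    bg = set(layout["background"])
    by_leaf: dict = {}
    for g, p in mapping.items():
        by_leaf.setdefault(p, set()).add(g)
    return sorted(p for p, gs in by_leaf.items() if gs <= bg)


def write_toy_hierarchy(cfg: SimConfig, directory) -> tuple[str, str]:
    """Write relation and annotation TSVs for the balanced toy tree.

    Returns (relations_path, annotations_path). Node ids follow the
    Reactome stable-id shape with the ``R-TOY`` species prefix; node
    ``R-TOY-L<d>-<i>`` at depth d has parent ``R-TOY-L<d-1>-<i // b>``.
    """
    os.makedirs(directory, exist_ok=True)
    rel_path = os.path.join(directory, "toy_relations.tsv")
    ann_path = os.path.join(directory, "toy_annotations.tsv")
    b = cfg.tree_branching
    with open(rel_path, "w") as fh:
        for d in range(2, cfg.tree_depth + 1):
            for i in range(b**d):
                fh.write(f"{TOY_PREFIX}-L{d - 1}-{i // b}\t{TOY_PREFIX}-L{d}-{i}\n")
        if cfg.tree_depth == 1:
            # a depth-1 tree has no internal relations; emit nothing
            pass
    with open(ann_path, "w") as fh:
        for g, p in sorted(_gene_annotation(cfg).items()):
            fh.write(f"{g}\t{p}\n")
    return rel_path, ann_path


# --- CV-shift generator -------------------------------------------------------

def simulate_cv_shift(cfg: SimConfig, multiplier: float, n_cells_per_group: int | None = None):
    """Two equal-mean groups where one group's NB dispersion is inflated.

    Group means are drawn once per gene (log-normal around the baseline)
    and shared by both groups; group "g2" uses size / multiplier, which
    raises the coefficient of variation without moving the mean. Returns
    (matrix genes x cells, group labels Series).
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    n_cells = n_cells_per_group or cfg.cells_per_subtype
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids
    mu = cfg.baseline_mean * rng.lognormal(mean=0.0, sigma=0.4, size=cfg.n_genes)

    def draw(size):
        p = size / (size + mu[:, None])
        return rng.negative_binomial(size, np.broadcast_to(p, (cfg.n_genes, n_cells)))

    g1 = draw(cfg.dispersion)
    g2 = draw(cfg.dispersion / multiplier)
    cells = [f"g1_c{i:04d}" for i in range(n_cells)] + [f"g2_c{i:04d}" for i in range(n_cells)]
    matrix = pd.DataFrame(np.hstack([g1, g2]), index=genes, columns=cells)
    groups = pd.Series(["g1"] * n_cells + ["g2"] * n_cells, index=cells, name="group")
    return matrix, groups
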