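"""Two-stage pathway-constrained cell-type classifier, Model/Results style.

``CellTICS`` is built from a normalized expression matrix, a cell
annotation table and a pathway hierarchy; ``fit()`` returns a
``CellTICSResults`` carrying the trained stage-1 network (cell types) and
one stage-2 sub-network per cell type with at least two sub-cell types.
Every stage recomputes its own marker genes, pruned hierarchy and masks
on its own training cells: stage 2 trains on cells grouped by their
*true* cell type but, at prediction time, test cells are routed to the
sub-network of their *predicted* type — the asymmetry that makes the
second stage usable on unlabeled data.

Typical use::

    model = CellTICS(norm_expr, annotation, tree, n_levels=2)
    res = model.fit(seed=0)
    pred = res.predict(test_expr)          # cell_type + sub_cell_type per cell
    imp = res.pathway_importance()         # ranked pathway table, stage 1
    print(res.summary())
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import interpret as _interpret
from . import markers as _markers
from .hierarchy import (
    LayeredPathwayGraph,
    MaskStack,
    PathwayTree,
    build_layered_graph,
    build_masks,
    prune_to_genes,
)
from .network import ModelParams, TrainingConfig, init_model, predict as _net_predict, train as _net_train

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

__all__ = ["CellTICS", "CellTICSResults", "StageBundle"]


@dataclass
class StageBundle:
    """Everything one trained (sub-)network needs to score new cells."""

    classes: list
    markers: _markers.MarkerSet
    graph: LayeredPathwayGraph
    masks: MaskStack
    params: ModelParams
    loss_trace: list
    passthrough: bool = False   # <= 1 sub-class: emit the cell type itself
    scale_mean: np.ndarray | None = None  # per-gene training mean / sd used to
    scale_sd: np.ndarray | None = None    # standardize network inputs

    def design_matrix(self, matrix: pd.DataFrame) -> np.ndarray:
        """Cells x genes in mask order, standardized with training statistics.

        Genes absent from ``matrix`` are imputed as 0 (on the standardized
        scale, i.e. at the training mean) and counted in the log.
        """
        genes = self.masks.gene_ids
        missing = [g for g in genes if g not in matrix.index]
        if missing:
            logger.info("predict: %d/%d model genes absent from input, imputed as 0",
                        len(missing), len(genes))
        X = np.zeros((matrix.shape[1], len(genes)))
        pos = {g: i for i, g in enumerate(genes)}
        present = [g for g in genes if g in matrix.index]
        idx = [pos[g] for g in present]
        vals = matrix.loc[present].to_numpy(dtype=float).T
        if self.scale_mean is not None:
            vals = (vals - self.scale_mean[idx]) / self.scale_sd[idx]
        X[:, idx] = vals
        return X


class CellTICS:
    """Pathway-constrained two-stage classifier for scRNA-seq.

    Parameters
    ----------
    expression
        Normalized genes x cells matrix (see ``preprocess.normalize_counts``).
    annotation
        Cell table indexed by cell id, columns ``cell_type`` and
        optionally ``sub_cell_type``.
    hierarchy
        Parsed :class:`~celltics.hierarchy.PathwayTree`.
    alpha, beta
        Quantile levels for high/low marker selection (defaults 0.95 / 0.9).
    n_levels
        Pathway depth l = number of hidden layers (default 5).
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        annotation: pd.DataFrame,
        hierarchy: PathwayTree,
        alpha: float = 0.95,
        beta: float = 0.9,
        n_levels: int = 5,
    ):
        missing = [c for c in expression.columns if c not in annotation.index]
        if missing:
            raise ValueError(f"cells without annotation, e.g. {missing[:5]}")
        self.expression = expression
        self.annotation = annotation.loc[expression.columns]
        self.hierarchy = hierarchy
        self.alpha = alpha
        self.beta = beta
        self.n_levels = n_levels

    @classmethod
    def from_files(
        cls,
        expression_csv,
        annotation_csv,
        relations_tsv,
        annotations_tsv,
        species: str,
        normalized: bool = False,
        qc=None,
        transpose: bool = False,
        **kwargs,
    ) -> "CellTICS":
        """Build a model straight from the on-disk CSV/TSV inputs."""
        from .hierarchy import load_pathway_hierarchy
        from .preprocess import normalize_counts, qc_filter, read_annotation_csv, read_expression_csv

        expr = read_expression_csv(expression_csv, transpose=transpose)
        annot = read_annotation_csv(annotation_csv)
        if qc is not None:
            expr, _ = qc_filter(expr, qc)
        if not normalized:
            expr = normalize_counts(expr)
        tree = load_pathway_hierarchy(relations_tsv, annotations_tsv, species)
        return cls(expr, annot.loc[expr.columns], tree, **kwargs)

    # ------------------------------------------------------------------
    def _fit_stage(
        self,
        matrix: pd.DataFrame,
        annotation: pd.DataFrame,
        level: str,
        cfg: TrainingConfig,
        seed: int,
    ) -> StageBundle:
        scores, marker_set = _markers.score_and_select(
            matrix, annotation, level=level, alpha=self.alpha, beta=self.beta
        )
        pruned = prune_to_genes(self.hierarchy, marker_set.combined)
        graph = build_layered_graph(pruned, self.n_levels)
        masks = build_masks(graph)
        X = matrix.loc[masks.gene_ids].to_numpy(dtype=float).T
        # standardize per gene on training cells; tanh units stay in their
        # responsive range regardless of library-size scale
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mean) / sd
        y = annotation.loc[matrix.columns, level].to_numpy()
        classes = sorted(set(y.tolist()))
        params = init_model(masks, classes, seed=seed)
        params, trace = _net_train(params, masks, X, y, cfg)
        return StageBundle(
            classes=classes, markers=marker_set, graph=graph, masks=masks,
            params=params, loss_trace=trace, scale_mean=mean, scale_sd=sd,
        )

    def fit(
        self,
        stage1: TrainingConfig | None = None,
        stage2: TrainingConfig | None = None,
        seed: int = 0,
    ) -> "CellTICSResults":
        """Train stage 1 and the per-cell-type stage-2 sub-networks."""
        stage1 = stage1 or TrainingConfig(epochs=10, seed=seed)
        stage2 = stage2 or TrainingConfig(epochs=50, seed=seed)
        bundle1 = self._fit_stage(self.expression, self.annotation, "cell_type", stage1, seed)

        sub_bundles: dict = {}
        has_sub = "sub_cell_type" in self.annotation.columns
        for i, ctype in enumerate(bundle1.classes):
            cells = self.annotation.index[self.annotation["cell_type"] == ctype]
            subs = (
                sorted(self.annotation.loc[cells, "sub_cell_type"].dropna().unique().tolist())
                if has_sub else []
            )
            if len(subs) < 2:
                sub_bundles[ctype] = StageBundle(
                    classes=subs or [ctype], markers=_markers.MarkerSet(),
                    graph=None, masks=None, params=None, loss_trace=[],
                    passthrough=True,
                )
                continue
            sub_cfg = replace(stage2, seed=stage2.seed + i + 1)
            sub_bundles[ctype] = self._fit_stage(
                self.expression[cells], self.annotation.loc[cells],
                "sub_cell_type", sub_cfg, seed=seed + i + 1,
            )
        return CellTICSResults(model=self, stage1=bundle1, stage2=sub_bundles,
                               configs={"stage1": stage1, "stage2": stage2, "seed": seed})


@dataclass
class CellTICSResults:
    """Fitted two-stage model: trained bundles plus reporting helpers."""

    model: CellTICS | None
    stage1: StageBundle
    stage2: dict
    configs: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def predict(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Predict cell type and sub-cell type for each column of ``matrix``.

        Returns a DataFrame indexed by cell id with predicted_cell_type,
        predicted_sub_cell_type and the per-stage vote margins (fraction
        of predictive heads agreeing with the voted label).
        """
        X1 = self.stage1.design_matrix(matrix)
        res1 = _net_predict(self.stage1.params, self.stage1.masks, X1)
        types = res1.voted
        margin1 = _vote_margin(res1.head_labels, types)

        sub = np.empty(len(types), dtype=object)
        margin2 = np.ones(len(types))
        for ctype in set(types.tolist()):
            sel = np.flatnonzero(types == ctype)
            bundle = self.stage2.get(ctype)
            if bundle is None or bundle.passthrough:
                fallback = bundle.classes[0] if bundle and bundle.classes else ctype
                sub[sel] = fallback
                continue
            Xs = bundle.design_matrix(matrix.iloc[:, sel])
            res2 = _net_predict(bundle.params, bundle.masks, Xs)
            sub[sel] = res2.voted
            margin2[sel] = _vote_margin(res2.head_labels, res2.voted)
        return pd.DataFrame(
            {
                "predicted_cell_type": types,
                "predicted_sub_cell_type": sub,
                "stage1_vote_margin": margin1,
                "stage2_vote_margin": margin2,
            },
            index=pd.Index(matrix.columns, name="cell_id"),
        )

    # ------------------------------------------------------------------
    def pathway_activations(self, stage: str = "cell_type") -> pd.DataFrame:
        """A[t, p] on the training cells, for stage 1 or one cell type's stage 2."""
        bundle, matrix, labels = self._stage_data(stage)
        X = bundle.design_matrix(matrix)
        return _interpret.pathway_activations(bundle.params, bundle.masks, bundle.graph, X, labels)

    def pathway_importance(self, threshold: float = 0.1, stage: str = "cell_type",
                           names: dict | None = None) -> pd.DataFrame:
        """Ranked pathway-importance table (see ``interpret.pathway_importance``)."""
        bundle, _, _ = self._stage_data(stage)
        A = self.pathway_activations(stage)
        return _interpret.pathway_importance(
            A, threshold=threshold, graph=bundle.graph,
            names=names or (self.model.hierarchy.names if self.model else None),
        )

    def _stage_data(self, stage: str):
        if self.model is None:
            raise ValueError("results were loaded without training data; "
                             "use interpret.pathway_activations directly")
        if stage == "cell_type":
            return self.stage1, self.model.expression, self.model.annotation["cell_type"].to_numpy()
        bundle = self.stage2.get(stage)
        if bundle is None or bundle.passthrough:
            raise ValueError(f"no trained stage-2 network for cell type {stage!r}")
        cells = self.model.annotation.index[self.model.annotation["cell_type"] == stage]
        return bundle, self.model.expression[cells], \
            self.model.annotation.loc[cells, "sub_cell_type"].to_numpy()

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable account of markers, architecture and training."""
        lines = ["Two-stage pathway-constrained classifier", "=" * 42]
        b = self.stage1
        lines.append(f"Stage 1: {len(b.classes)} cell types {b.classes}")
        lines.append(f"  markers: {len(b.markers.combined)} genes "
                     f"(alpha={b.markers.alpha}, beta={b.markers.beta}); "
                     f"{len(b.masks.gene_ids)} annotated and used as input")
        widths = [m.shape[1] for m in b.masks.masks]
        lines.append(f"  hidden layer widths (level {len(widths)}..1): {widths}")
        lines.append(f"  final epoch loss: {b.loss_trace[-1]:.4f}")
        for ctype, bundle in self.stage2.items():
            if bundle.passthrough:
                lines.append(f"Stage 2 [{ctype}]: passthrough ({bundle.classes})")
            else:
                widths = [m.shape[1] for m in bundle.masks.masks]
                lines.append(
                    f"Stage 2 [{ctype}]: {len(bundle.classes)} sub-types, "
                    f"{len(bundle.masks.gene_ids)} genes, widths {widths}, "
                    f"final loss {bundle.loss_trace[-1]:.4f}"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        """Serialize bundles (masks, ids, parameters, configs) to one zip archive."""
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            meta = {
                "format_version": FORMAT_VERSION,
                "configs": {
                    k: (v.__dict__ if isinstance(v, TrainingConfig) else v)
                    for k, v in self.configs.items()
                },
                "stage2_types": list(self.stage2),
            }
            zf.writestr("meta.json", json.dumps(meta, indent=2))
            _write_bundle(zf, "stage1", self.stage1)
            for ctype, bundle in self.stage2.items():
                _write_bundle(zf, f"stage2/{ctype}", bundle)

    @classmethod
    def load(cls, path) -> "CellTICSResults":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta["format_version"] != FORMAT_VERSION:
                raise ValueError(f"unsupported archive version {meta['format_version']}")
            stage1 = _read_bundle(zf, "stage1")
            stage2 = {t: _read_bundle(zf, f"stage2/{t}") for t in meta["stage2_types"]}
        return cls(model=None, stage1=stage1, stage2=stage2, configs=meta["configs"])


def _vote_margin(head_labels: np.ndarray, voted: np.ndarray) -> np.ndarray:
    agree = (head_labels.astype(str) == voted.astype(str)[None, :]).mean(axis=0)
    return agree


def _write_bundle(zf: zipfile.ZipFile, prefix: str, bundle: StageBundle) -> None:
    info = {
        "classes": list(map(str, bundle.classes)),
        "passthrough": bundle.passthrough,
        "loss_trace": bundle.loss_trace,
        "markers": {
            "high": bundle.markers.high, "low": bundle.markers.low,
            "alpha": bundle.markers.alpha, "beta": bundle.markers.beta,
        },
    }
    if not bundle.passthrough:
        info["graph"] = {
            "l": bundle.graph.l,
            "levels": {str(k): v for k, v in bundle.graph.levels.items()},
            "genes": bundle.graph.genes,
            "edges": sorted(map(list, bundle.graph.edges)),
            "artificial": sorted(bundle.graph.artificial),
            "level_of": bundle.graph.level_of,
        }
        info["ids"] = {"rows": bundle.masks.row_ids, "cols": bundle.masks.col_ids}
        buf = io.BytesIO()
        arrays = {}
        for i, m in enumerate(bundle.masks.masks):
            arrays[f"mask_{i}"] = m
            arrays[f"w_{i}"] = bundle.params.weights[i]
            arrays[f"b_{i}"] = bundle.params.biases[i]
            arrays[f"hw_{i}"] = bundle.params.head_weights[i]
            arrays[f"hb_{i}"] = bundle.params.head_biases[i]
        if bundle.scale_mean is not None:
            arrays["scale_mean"] = bundle.scale_mean
            arrays["scale_sd"] = bundle.scale_sd
        np.savez(buf, **arrays)
        zf.writestr(f"{prefix}/arrays.npz", buf.getvalue())
    zf.writestr(f"{prefix}/bundle.json", json.dumps(info, indent=2))


def _read_bundle(zf: zipfile.ZipFile, prefix: str) -> StageBundle:
    info = json.loads(zf.read(f"{prefix}/bundle.json"))
    marker_set = _markers.MarkerSet(
        high=info["markers"]["high"], low=info["markers"]["low"],
        alpha=info["markers"]["alpha"], beta=info["markers"]["beta"],
    )
    if info["passthrough"]:
        return StageBundle(classes=info["classes"], markers=marker_set, graph=None,
                           masks=None, params=None, loss_trace=info["loss_trace"],
                           passthrough=True)
    g = info["graph"]
    graph = LayeredPathwayGraph(
        l=g["l"], levels={int(k): v for k, v in g["levels"].items()},
        genes=g["genes"], edges={tuple(e) for e in g["edges"]},
        artificial=set(g["artificial"]), level_of=g["level_of"],
    )
    data = np.load(io.BytesIO(zf.read(f"{prefix}/arrays.npz")))
    n = sum(1 for k in data.files if k.startswith("mask_"))
    masks = MaskStack(
        masks=[data[f"mask_{i}"] for i in range(n)],
        row_ids=info["ids"]["rows"], col_ids=info["ids"]["cols"],
    )
    params = ModelParams(
        weights=[data[f"w_{i}"] for i in range(n)],
        biases=[data[f"b_{i}"] for i in range(n)],
        head_weights=[data[f"hw_{i}"] for i in range(n)],
        head_biases=[data[f"hb_{i}"] for i in range(n)],
        classes=info["classes"],
    )
    return StageBundle(classes=info["classes"], markers=marker_set, graph=graph,
                       masks=masks, params=params, loss_trace=info["loss_trace"],
                       scale_mean=data.get("scale_mean"), scale_sd=data.get("scale_sd"))
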