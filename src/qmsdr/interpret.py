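"""Gradient-based interpretation of trained response models.

The influence of feature f on the prediction is measured by the input
gradient G_f = d(y_hat)/d(f), evaluated in inference mode on held-out
samples.  A feature's importance is the l2 norm of its gradient across
samples; importances are averaged across the cross-validation ensemble,
and a gene's aggregate importance is the l2 norm over its channels.
The report can be exported as a two-sided node/link table (channel
groups -> genes) ready for Sankey rendering by any plotting layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EvaluationError, StateError
from .features import FeatureMatrix
from .network import ResponseNetwork


def feature_gradients(model: ResponseNetwork, features: FeatureMatrix) -> np.ndarray:
    """Exact d(y_hat)/d(feature), shape ``(samples, genes, channels)``.

    Computed analytically through the inference-mode network (dropout
    off, frozen normalisation statistics), so results are deterministic.
    """
    if model.train_mode:
        raise StateError("feature_gradients requires an inference-mode model")
    n = features.n_samples
    grads = model.input_gradients(features.flat())
    return grads.reshape(n, len(features.panel), len(features.channel_names))


@dataclass
class ImportanceReport:
    """Per-(gene, channel) gradient importances, ensemble-averaged.

    ``table`` is genes x channels (non-negative); ``per_gene`` is the l2
    norm over each gene's channels; ``per_channel`` sums each channel
    over genes.  ``provenance`` records the models and sample count
    averaged over.
    """

    table: pd.DataFrame
    provenance: dict

    @property
    def per_gene(self) -> pd.Series:
        return pd.Series(
            np.linalg.norm(self.table.to_numpy(), axis=1), index=self.table.index
        ).sort_values(ascending=False)

    @property
    def per_channel(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.table.to_numpy().sum())


def importance_scores(
    models: Sequence[ResponseNetwork],
    features: FeatureMatrix,
) -> ImportanceReport:
    """l2-norm gradient importances on held-out samples, ensemble-mean.

    ``features`` should hold only samples unseen by the models (test
    partitions).  Per model, each feature's importance is the l2 norm of
    its per-sample gradients; the report is the arithmetic mean across
    models.
    """
    if features.n_samples == 0:
        raise EvaluationError("importance needs at least one sample")
    if not models:
        raise EvaluationError("importance needs at least one model")
    per_model = []
    for model in models:
        g = feature_gradients(model, features)  # (n, genes, channels)
        per_model.append(np.linalg.norm(g, axis=0))  # (genes, channels)
    mean_imp = np.mean(per_model, axis=0)
    table = pd.DataFrame(
        mean_imp, index=list(features.panel.genes), columns=list(features.channel_names)
    )
    return ImportanceReport(
        table=table,
        provenance={
            "n_models": len(models),
            "n_samples": features.n_samples,
        },
    )


def repeat_gene_rankings(
    models: Sequence[ResponseNetwork], features: FeatureMatrix
) -> list[pd.Series]:
    """Per-model gene importance rankings (no ensemble averaging)."""
    rankings = []
    for model in models:
        rep = importance_scores([model], features)
        rankings.append(rep.per_gene)
    return rankings


def sankey_export(
    report: ImportanceReport, top_k: int, residual_label: str = "residual"
) -> dict:
    """Channel-group -> gene node/link table for Sankey rendering.

    Left nodes are the channel groups; right nodes are the ``top_k``
    genes by aggregate importance plus one residual node absorbing all
    remaining genes, so total link weight equals total report
    importance.  Output follows the schema
    ``{nodes: [{id, label, side}], links: [{source, target, value}]}``.
    """
    if top_k < 1:
        raise ConfigError("top_k must be >= 1")
    if report.table.empty:
        raise EvaluationError("importance report is empty")
    channels = list(report.table.columns)
    top_genes = list(report.per_gene.index[:top_k])
    rest = [g for g in report.table.index if g not in top_genes]

    nodes = [{"id": c, "label": c, "side": "left"} for c in channels]
    nodes += [{"id": g, "label": g, "side": "right"} for g in top_genes]
    has_residual = len(rest) > 0 or top_k < len(report.table.index)
    if has_residual:
        nodes.append({"id": residual_label, "label": residual_label, "side": "right"})

    links = []
    for c in channels:
        for g in top_genes:
            links.append(
                {"source": c, "target": g, "value": float(report.table.loc[g, c])}
            )
        if has_residual:
            links.append(
                {
                    "source": c,
                    "target": residual_label,
                    "value": float(report.table.loc[rest, c].sum()) if rest else 0.0,
                }
            )
    return {"nodes": nodes, "links": links}


def write_sankey(sankey: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(sankey, indent=2) + "\n")
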