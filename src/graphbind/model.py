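"""Model/Results interface over the full learning stack.

:class:`AffinityModel` bundles a featurized dataset (complex graphs +
experimental affinities) with a :class:`~graphbind.nn.ModelConfig`;
``fit()`` runs the whole training pipeline —

1. fit min-max normalization statistics on the training graphs,
2. train the message-passing encoder,
3. extract the 256-dimensional embeddings,
4. fit the SVR/XGBoost base regressors and the OLS meta-learner —

and returns an :class:`AffinityResults` carrying the fitted components,
training diagnostics, and ``summary()``.  Prediction on new complexes
applies the stored normalization statistics (no refitting), the encoder,
and the stacked head.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .ensemble import TrainedEnsemble, fit_ensemble
from .errors import DimensionError, InsufficientDataError
from .features import FeatureSchema, default_schema
from .graphs import (ComplexGraph, GraphConfig, NormalizationStats,
                     build_complex_graph, minmax_normalize)
from .nn import Encoder, ModelConfig
from .structures import load_structure, read_manifest

__all__ = ["AffinityModel", "AffinityResults", "predict_affinity"]


class AffinityModel:
    """Binding-affinity regression model over pocket-ligand complex graphs.

    Parameters
    ----------
    graphs : featurized, *unnormalized* complex graphs.
    affinities : aligned experimental affinities, -log10(Kd/Ki).
    config : hyperparameters; defaults to the tuned values.
    schema : feature registry the graphs were built with.
    """

    def __init__(self, graphs: list[ComplexGraph],
                 affinities: np.ndarray | list[float],
                 config: ModelConfig | None = None,
                 schema: FeatureSchema | None = None):
        self.graphs = list(graphs)
        self.endog = np.asarray(affinities, dtype=float)
        if len(self.graphs) != len(self.endog):
            raise DimensionError("graphs and affinities are misaligned")
        if len(self.graphs) == 0:
            raise InsufficientDataError("empty dataset")
        self.config = config or ModelConfig()
        self.schema = schema or default_schema()

    @classmethod
    def from_manifest(cls, manifest_path: str | Path,
                      config: ModelConfig | None = None,
                      graph_config: GraphConfig | None = None,
                      schema: FeatureSchema | None = None,
                      base_dir: str | Path | None = None) -> "AffinityModel":
        """Build the model from a manifest of structure files.

        The manifest (TSV/CSV) lists complex_id, pocket_path, ligand_path,
        affinity and optionally affinity_type; IC50 rows are dropped.
        Relative paths resolve against ``base_dir`` (default: the manifest's
        directory).
        """
        manifest_path = Path(manifest_path)
        base = Path(base_dir) if base_dir else manifest_path.parent
        df = read_manifest(manifest_path)
        graphs, y = [], []
        for row in df.itertuples(index=False):
            pocket_path = Path(row.pocket_path)
            ligand_path = Path(row.ligand_path)
            if not pocket_path.is_absolute():
                pocket_path = base / pocket_path
            if not ligand_path.is_absolute():
                ligand_path = base / ligand_path
            protein = load_structure(pocket_path, role="protein")
            ligand = load_structure(ligand_path, role="ligand")
            graphs.append(build_complex_graph(
                protein, ligand, graph_config, schema,
                complex_id=str(row.complex_id), affinity=float(row.affinity)))
            y.append(float(row.affinity))
        return cls(graphs, np.asarray(y), config=config, schema=schema)

    def fit(self, base_estimators: tuple | None = None) -> "AffinityResults":
        """Run normalization, encoder training, and ensemble stacking."""
        norm_graphs, stats = minmax_normalize(self.graphs)
        encoder = Encoder(node_dim=norm_graphs[0].node_matrix.shape[1],
                          edge_dim=norm_graphs[0].edge_matrix.shape[1],
                          graph_dim=norm_graphs[0].graph_vector.shape[0],
                          config=self.config)
        encoder.fit(norm_graphs, self.endog)
        embeddings = encoder.transform(norm_graphs)
        ens = fit_ensemble(embeddings, self.endog, self.config,
                           base_estimators=base_estimators)
        fitted = ens.predict(embeddings)
        return AffinityResults(self, encoder, ens, stats, fitted)


class AffinityResults:
    """Fitted pipeline: estimates, diagnostics, prediction, persistence."""

    def __init__(self, model: AffinityModel, encoder: Encoder,
                 ensemble: TrainedEnsemble, stats: NormalizationStats,
                 fittedvalues: np.ndarray):
        self.model = model
        self.encoder = encoder
        self.ensemble = ensemble
        self.normalization = stats
        self.fittedvalues = np.asarray(fittedvalues)
        self.resid = model.endog - self.fittedvalues

    # ------------------------------------------------------------- diagnostics
    @property
    def meta_weights(self) -> np.ndarray:
        return self.ensemble.meta_weights

    @property
    def meta_intercept(self) -> float:
        return self.ensemble.meta_intercept

    @property
    def train_mae(self) -> float:
        return float(np.mean(np.abs(self.resid)))

    @property
    def train_pcc(self) -> float:
        if np.std(self.fittedvalues) == 0 or np.std(self.model.endog) == 0:
            return 0.0
        return float(np.corrcoef(self.model.endog, self.fittedvalues)[0, 1])

    # -------------------------------------------------------------- prediction
    def embed(self, graphs: list[ComplexGraph]) -> np.ndarray:
        """Normalized-and-encoded embeddings for new complexes."""
        norm, _ = minmax_normalize(graphs, self.normalization)
        return self.encoder.transform(norm)

    def predict(self, graphs: list[ComplexGraph]) -> np.ndarray:
        """Predicted -log10(Kd/Ki) per complex."""
        return self.ensemble.predict(self.embed(graphs))

    # ----------------------------------------------------------------- summary
    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Binding-affinity stacked-ensemble results",
            "=" * 45,
            f"{'n complexes':<28}{len(self.model.endog):>17}",
            f"{'node feature width':<28}{self.model.graphs[0].node_matrix.shape[1]:>17}",
            f"{'embedding dim':<28}{cfg.embed_dim:>17}",
            f"{'conv layers':<28}{cfg.n_conv_layers:>17}",
            f"{'loss':<28}{cfg.loss.upper():>17}",
            f"{'epochs':<28}{cfg.epochs:>17}",
            "-" * 45,
            f"{'meta weight (SVR)':<28}{self.meta_weights[0]:>17.4f}",
            f"{'meta weight (XGB)':<28}{self.meta_weights[1]:>17.4f}",
            f"{'meta intercept':<28}{self.meta_intercept:>17.4f}",
            f"{'training MAE':<28}{self.train_mae:>17.4f}",
            f"{'training PCC':<28}{self.train_pcc:>17.4f}",
            "=" * 45,
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------- persistence
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.encoder.save(d)
        self.ensemble.save(d)
        self.normalization.to_json(d / "normalization.json")
        self.model.schema.to_json(d / "schema.json")

    @classmethod
    def load(cls, directory: str | Path,
             graphs: list[ComplexGraph] | None = None,
             affinities: np.ndarray | None = None) -> "AffinityResults":
        """Reload a saved pipeline; training data are optional."""
        d = Path(directory)
        encoder = Encoder.load(d)
        ensemble = TrainedEnsemble.load(d)
        stats = NormalizationStats.from_json(d / "normalization.json")
        schema = FeatureSchema.from_json(d / "schema.json")
        if graphs is None:
            graphs, affinities = [], np.zeros(0)
            model = AffinityModel.__new__(AffinityModel)
            model.graphs = graphs
            model.endog = affinities
            model.config = encoder.cfg
            model.schema = schema
            return cls(model, encoder, ensemble, stats, np.zeros(0))
        model = AffinityModel(graphs, affinities, encoder.cfg, schema)
        res = cls(model, encoder, ensemble, stats,
                  ensemble.predict(encoder.transform(
                      minmax_normalize(graphs, stats)[0])))
        return res


def predict_affinity(results: AffinityResults,
                     graphs: list[ComplexGraph]) -> np.ndarray:
    """Functional form of :meth:`AffinityResults.predict`."""
    return results.predict(graphs)
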