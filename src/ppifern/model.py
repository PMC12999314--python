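"""Model / Results objects for the full prediction pipeline.

:class:`PPIModel` holds a pair-feature matrix and labels plus a
:class:`PipelineConfig`; ``fit()`` pretrains and fine-tunes the stacked
denoising autoencoder (unless disabled for the raw-feature ablation),
encodes the training pairs, fits the random-ferns classifier on the
encodings and returns a :class:`PPIResults` carrying the trained bundle,
training-set diagnostics and a ``summary()`` table.  Prediction on new
pairs goes through the same featurization settings recorded in the
bundle.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import evaluate, ferns as ferns_mod, sdae as sdae_mod
from .featurize import (
    FeaturizationSettings,
    feature_matrix,
    featurize_dataset,
)
from .io import ModelBundle, PairTable, PSSMatrix, save_model


def derive_seed(seed: int, component: str) -> int:
    """Fan a global seed out to a stable per-component seed (< 2^31)."""
    return zlib.crc32(f"{seed}:{component}".encode()) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs beyond the data itself."""

    featurization: FeaturizationSettings = field(default_factory=FeaturizationSettings)
    sdae: sdae_mod.SDAEConfig = field(default_factory=sdae_mod.SDAEConfig)
    ferns_S: int = ferns_mod.DEFAULT_S
    ferns_M: int = ferns_mod.DEFAULT_M
    ferns_Nr: float = ferns_mod.DEFAULT_NR
    fern_test_kind: str = "threshold"
    with_sdae: bool = True
    seed: int = 0

    def resolved(self) -> "PipelineConfig":
        """Propagate the global seed into per-component seeds."""
        return replace(
            self, sdae=replace(self.sdae, seed=derive_seed(self.seed, "sdae"))
        )

    def to_dict(self) -> dict:
        return {
            "featurization": self.featurization.to_dict(),
            "sdae": self.sdae.to_dict(),
            "ferns_S": self.ferns_S,
            "ferns_M": self.ferns_M,
            "ferns_Nr": self.ferns_Nr,
            "fern_test_kind": self.fern_test_kind,
            "with_sdae": self.with_sdae,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        d["featurization"] = FeaturizationSettings.from_dict(d["featurization"])
        d["sdae"] = sdae_mod.SDAEConfig.from_dict(d["sdae"])
        return cls(**d)


class PPIModel:
    """A protein-pair interaction classifier before fitting.

    Parameters
    ----------
    X : (n, 800) pair-feature matrix (concatenated per-protein
        cross-product features).
    y : (n,) binary interaction labels.
    config : pipeline configuration; ``with_sdae=False`` fits the ferns
        classifier directly on the raw 800-dimensional features
        (the representation-learning ablation).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: PipelineConfig | None = None,
        pair_ids: list[tuple[str, str]] | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n, D) with one label per row")
        if not np.isfinite(self.X).all():
            raise ValueError("features must be finite")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        self.config = (config or PipelineConfig()).resolved()
        self.pair_ids = pair_ids

    @classmethod
    def from_pair_table(
        cls,
        pairs: PairTable,
        pssm_lookup: Mapping[str, PSSMatrix],
        config: PipelineConfig | None = None,
    ) -> "PPIModel":
        """Build the model from a pair table and per-protein PSSMs."""
        config = config or PipelineConfig()
        vectors = featurize_dataset(pairs, pssm_lookup, config.featurization)
        X, y, ids = feature_matrix(vectors)
        return cls(X, y, config=config, pair_ids=ids)

    def fit(self) -> "PPIResults":
        """Train the SDAE (pretrain + fine-tune) and the ferns classifier."""
        cfg = self.config
        encoder = None
        if cfg.with_sdae:
            rng = np.random.default_rng(cfg.sdae.seed)
            encoder = sdae_mod.pretrain(self.X, cfg.sdae, rng)
            encoder = sdae_mod.fine_tune(encoder, self.X, self.y, cfg.sdae, rng)
            Z = sdae_mod.encode(encoder, self.X)
        else:
            Z = self.X
        fern_seed = derive_seed(cfg.seed, "ferns")
        fern_model = ferns_mod.fit(
            Z,
            self.y,
            S=cfg.ferns_S,
            M=cfg.ferns_M,
            Nr=cfg.ferns_Nr,
            rng=fern_seed,
            test_kind=cfg.fern_test_kind,
        )
        bundle = ModelBundle(
            ferns=fern_model,
            sdae=encoder,
            featurization_settings=cfg.featurization,
            extra={"pipeline_config": cfg.to_dict()},
        )
        return PPIResults(model=self, bundle=bundle)


class PPIResults:
    """A fitted pipeline: trained bundle plus diagnostics."""

    def __init__(self, bundle: ModelBundle, model: PPIModel | None = None) -> None:
        self.model = model
        self.bundle = bundle
        self._train_report: evaluate.MetricsReport | None = None

    # -- prediction ---------------------------------------------------------

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Deep features delivered to the ferns classifier (identity in
        the no-SDAE ablation)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.bundle.sdae is not None:
            return sdae_mod.encode(self.bundle.sdae, X)
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return ferns_mod.predict_proba(self.bundle.ferns, self.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return ferns_mod.predict(self.bundle.ferns, self.transform(X))

    def predict_pairs(
        self, pairs: PairTable, pssm_lookup: Mapping[str, PSSMatrix]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(positive-class probability, hard label) per pair row, using the
        featurization settings recorded in the bundle."""
        settings = self.bundle.featurization_settings or FeaturizationSettings()
        vectors = featurize_dataset(pairs, pssm_lookup, settings)
        X, _, _ = feature_matrix(vectors)
        proba = self.predict_proba(X)[:, 1]
        return proba, (proba > 0.5).astype(int)

    # -- diagnostics --------------------------------------------------------

    @property
    def train_report(self) -> evaluate.MetricsReport:
        if self._train_report is None:
            if self.model is None:
                raise ValueError("training data unavailable for a loaded bundle")
            scores = self.predict_proba(self.model.X)[:, 1]
            y_pred = (scores > 0.5).astype(int)
            self._train_report = evaluate.compute_metrics(
                evaluate.confusion(self.model.y, y_pred), scores, self.model.y
            )
        return self._train_report

    def evaluate_on(
        self, X: np.ndarray, y: np.ndarray
    ) -> evaluate.MetricsReport:
        """Metrics on an independent (X, y) set (e.g. cross-dataset tests)."""
        scores = self.predict_proba(X)[:, 1]
        y_pred = (scores > 0.5).astype(int)
        return evaluate.compute_metrics(evaluate.confusion(y, y_pred), scores, y)

    def summary(self) -> str:
        """Human-readable fit summary."""
        cfg = (
            self.model.config
            if self.model is not None
            else PipelineConfig.from_dict(self.bundle.extra["pipeline_config"])
        )
        fm = self.bundle.ferns
        lines = [
            "Protein-pair interaction model (cross-product PSSM features)",
            "=" * 62,
            f"representation     : "
            + (
                f"SDAE {list(self.bundle.sdae.config.layer_dims)} -> "
                f"{self.bundle.sdae.output_dim}-d encodings"
                if self.bundle.sdae is not None
                else "raw 800-d pair features (no SDAE)"
            ),
            f"ferns              : M={fm.M} ferns, depth S={fm.S} "
            f"(K=2^{fm.S} outcomes), Nr={fm.Nr}",
            f"training pairs     : {int(fm.class_totals.sum())} "
            f"({int(fm.class_totals[1])} positive / "
            f"{int(fm.class_totals[0])} negative)",
            f"featurization      : {cfg.featurization.to_dict()}",
            f"seed               : {cfg.seed}",
        ]
        if self.model is not None:
            r = self.train_report
            lines += [
                "-" * 62,
                "training-set fit (resubstitution, optimistic):",
                f"  ACC={r.acc:.4f}  SN={r.sn:.4f}  PE={r.pe:.4f}  "
                f"MCC={r.mcc:.4f}  AUC={r.auc:.4f}",
            ]
        return "\n".join(lines)

    def save(self, path) -> None:
        save_model(self.bundle, path)

    @classmethod
    def from_bundle(cls, bundle: ModelBundle) -> "PPIResults":
        return cls(bundle=bundle)
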