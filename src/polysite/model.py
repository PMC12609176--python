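"""Model / Results objects: the primary user-facing surface.

`ActiveSiteModel` is constructed from featurized protein records (or a
synthetic corpus); `fit()` runs the training loop and returns an
`ActiveSiteResults` carrying the fitted parameters, class centers, training
history, held-out diagnostics and a `summary()` table; `predict()` and
`evaluate()` hang off the results object, as does checkpoint round-tripping.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .network import ModelParams
from .objective import CenterState
from .pipeline import (EvalReport, PredictionResult, ProteinRecord, TrainConfig,
                       TrainResult, evaluate_records, load_checkpoint,
                       predict_structure, records_from_corpus, save_checkpoint,
                       split_dataset, train)
from .structure import ProteinStructure


class ActiveSiteModel:
    """Residue-level multiclass active-site classifier.

    Parameters
    ----------
    records : list of ProteinRecord
        Featurized proteins with labels.
    config : TrainConfig, optional
        Training and architecture configuration.
    splits : dict protein_id -> {"train", "val", "test"}, optional
        Precomputed split assignment; when omitted, ``fit`` derives a
        cluster-aware 8:1:1 split from the records' cluster ids.
    """

    def __init__(self, records: list[ProteinRecord],
                 config: TrainConfig | None = None,
                 splits: dict[str, str] | None = None):
        if not records:
            raise ConsistencyError("no records")
        self.records = records
        self.config = config or TrainConfig()
        self.splits = splits

    @classmethod
    def from_corpus(cls, corpus, config: TrainConfig | None = None) -> "ActiveSiteModel":
        return cls(records_from_corpus(corpus), config)

    def _resolve_splits(self) -> dict[str, str]:
        if self.splits is not None:
            return self.splits
        manifest = split_dataset(
            {r.protein_id: r.cluster for r in self.records},
            seed=self.config.seed)
        return dict(zip(manifest.protein_id, manifest.split))

    def subset(self, split: str, splits: dict[str, str]) -> list[ProteinRecord]:
        return [r for r in self.records if splits.get(r.protein_id) == split]

    def fit(self, log_path=None) -> "ActiveSiteResults":
        splits = self._resolve_splits()
        result = train(self.subset("train", splits), self.subset("val", splits),
                       self.config, log_path=log_path)
        return ActiveSiteResults(self, result, splits)


class ActiveSiteResults:
    """Fitted classifier with diagnostics."""

    def __init__(self, model: ActiveSiteModel, result: TrainResult,
                 splits: dict[str, str]):
        self.model = model
        self.params: ModelParams = result.params
        self.centers: CenterState = result.centers
        self.history = result.history
        self.best_epoch = result.best_epoch
        self.validation: EvalReport = result.best_val
        self.splits = splits

    # -- evaluation --------------------------------------------------------

    def evaluate(self, split: str = "test", policy: str = "macro",
                 zero_text: bool = False) -> EvalReport:
        records = self.model.subset(split, self.splits)
        if not records:
            raise ConsistencyError(f"no records in split {split!r}")
        return evaluate_records(records, self.params, policy, zero_text)

    def predict(self, structure: ProteinStructure, seq_embedding: np.ndarray,
                text_pooled: np.ndarray, protein_id: str = "query") -> PredictionResult:
        return predict_structure(structure, seq_embedding, text_pooled,
                                 self.params, protein_id)

    # -- reporting ---------------------------------------------------------

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([h for h in self.history if "step" in h])

    def summary(self) -> str:
        cfg = self.model.config
        net = cfg.network
        val = self.validation
        lines = [
            "Residue-level active-site classification results",
            "=" * 52,
            f"proteins: {len(self.model.records)}  "
            f"(train {sum(1 for v in self.splits.values() if v == 'train')}, "
            f"val {sum(1 for v in self.splits.values() if v == 'val')}, "
            f"test {sum(1 for v in self.splits.values() if v == 'test')})",
            f"classes: {net.n_classes}   d_s={net.d_s} d_h={net.d_h} d_t={net.d_t}",
            f"epochs: {cfg.epochs}  base_lr: {cfg.base_lr:g}  "
            f"batch: {cfg.batch_size_proteins} proteins  seed: {cfg.seed}",
            f"best epoch (validation macro-F1): {self.best_epoch}",
            "",
            "validation metrics (macro over classes present)",
            "-" * 52,
            f"precision {val.precision:.4f}  recall {val.recall:.4f}  "
            f"F1 {val.f1:.4f}",
            f"AUROC {val.auroc:.4f}  AUPRC {val.auprc:.4f}  MCC {val.mcc:.4f}",
            "",
            "per-class validation table",
            "-" * 52,
            val.per_class.to_string(index=False),
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        save_checkpoint(path, self.params, self.centers, self.model.config)

    @classmethod
    def load(cls, path, model: ActiveSiteModel) -> "ActiveSiteResults":
        params, centers = load_checkpoint(path)
        out = cls.__new__(cls)
        out.model = model
        out.params = params
        out.centers = centers
        out.history = []
        out.best_epoch = -1
        out.validation = None
        out.splits = model._resolve_splits()
        return out


def smoke_train_config(seed: int = 0) -> TrainConfig:
    """Desk-scale training configuration: 15 epochs, 2-protein batches and a
    base learning rate of 3e-3, sized to the ~1200 optimizer steps a
    200-protein corpus provides (the 5e-5 default belongs to full-scale
    corpora with orders of magnitude more steps)."""
    cfg = TrainConfig(epochs=15, base_lr=3e-3, batch_size_proteins=2, seed=seed)
    return replace(cfg, network=replace(cfg.network, seed=seed))
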