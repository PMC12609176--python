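"""Training, evaluation, prediction, dataset splitting and checkpoints.

Training follows the published recipe: Adam, base learning rate 5e-5, a
linear warm-up over the first 10% of steps followed by cosine annealing to
zero, up to 100 epochs, compound loss (class-weighted CE + center + inter),
and class centers refreshed after each optimizer step on detached features.
Model selection is by best validation macro-F1.

Proteins are batched whole; each protein's forward runs on its own graph and
the residues of the batch are pooled into one loss, which is identical to
padding to a common length and masking the padding out.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, concat
from .constants import CLASS_NAMES
from .errors import ConsistencyError, PolysiteError
from .network import ModelParams, NetworkConfig, forward
from .objective import CenterState, LossConfig, compound_loss, update_centers
from .structure import NodeFeatureMatrix, ProteinStructure, ResidueGraph, featurize

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = "1"


@dataclass
class TrainConfig:
    epochs: int = 100
    base_lr: float = 5e-5
    warmup_frac: float = 0.1
    batch_size_proteins: int = 16
    max_len: int = 1024
    seed: int = 0
    alpha: float = 0.5  # center update rate
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if not (0.0 <= self.warmup_frac < 1.0):
            raise ConsistencyError("warmup_frac must be in [0, 1)")
        if self.epochs < 1:
            raise ConsistencyError("epochs must be >= 1")


@dataclass
class ProteinRecord:
    """One featurized protein ready for the forward pass."""

    protein_id: str
    graph: ResidueGraph
    node_features: NodeFeatureMatrix
    seq_embedding: np.ndarray  # (L, d_s)
    text_pooled: np.ndarray  # (d_t,)
    labels: np.ndarray | None = None  # (L,)
    cluster: int = 0

    @property
    def length(self) -> int:
        return self.graph.n_nodes


def records_from_corpus(corpus) -> list[ProteinRecord]:
    """Featurize a synthetic corpus into forward-ready records."""
    from .embeddings import pool_text

    records = []
    for p in corpus.proteins:
        feats, graph = featurize(p.structure)
        records.append(ProteinRecord(
            protein_id=p.protein_id, graph=graph, node_features=feats,
            seq_embedding=p.seq_embedding,
            text_pooled=pool_text(p.text_tokens).pooled,
            labels=np.asarray(p.labels, dtype=int), cluster=p.cluster))
    return records


def records_from_directory(corpus_dir) -> list[ProteinRecord]:
    """Load the on-disk corpus layout (structures/*.pdb, labels.tsv,
    clusters.tsv, embeddings.h5) into forward-ready records."""
    from pathlib import Path

    from .embeddings import pool_text
    from .structure import parse_structure

    root = Path(corpus_dir)
    # keep_default_na: the class literal "None" must stay a string
    labels_df = pd.read_csv(root / "labels.tsv", sep="\t", keep_default_na=False)
    clusters_df = pd.read_csv(root / "clusters.tsv", sep="\t")
    cluster_of = dict(zip(clusters_df.protein_id, clusters_df.cluster))
    name_to_idx = {n: i for i, n in enumerate(CLASS_NAMES)}
    records = []
    with h5py.File(root / "embeddings.h5", "r") as h5:
        for pid, grp in labels_df.groupby("protein_id", sort=True):
            structure = parse_structure(root / "structures" / f"{pid}.pdb")
            labels = np.array([name_to_idx[n] for n in
                               grp.sort_values("residue_number").label])
            if len(labels) != len(structure):
                raise ConsistencyError(
                    f"{pid}: {len(labels)} labels for {len(structure)} residues")
            feats, graph = featurize(structure)
            seq_emb = np.asarray(h5[pid]["seq_embedding"], dtype=float)
            tokens = np.asarray(h5[pid]["text_tokens"], dtype=float)
            records.append(ProteinRecord(
                protein_id=pid, graph=graph, node_features=feats,
                seq_embedding=seq_emb, text_pooled=pool_text(tokens).pooled,
                labels=labels, cluster=int(cluster_of.get(pid, 0))))
    return records


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

def lr_at_step(step: int, total_steps: int, config: TrainConfig) -> float:
    """Linear ramp 0 -> base_lr over the warm-up, then cosine decay reaching
    exactly 0 at the final step."""
    if total_steps <= 0:
        raise ConsistencyError("total_steps must be positive")
    if not (0 <= step < total_steps):
        raise ConsistencyError(f"step {step} outside [0, {total_steps})")
    warmup = math.ceil(config.warmup_frac * total_steps)
    if step < warmup:
        return config.base_lr * (step + 1) / warmup
    remaining = total_steps - warmup - 1
    progress = 0.0 if remaining <= 0 else (step - warmup) / remaining
    return config.base_lr * 0.5 * (1.0 + math.cos(math.pi * progress))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    auroc: float
    auprc: float
    mcc: float
    averaging: str
    per_class: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("precision", "recall", "f1", "auroc", "auprc", "mcc")}


def evaluate(probs: np.ndarray, labels: np.ndarray,
             policy: str = "macro") -> EvalReport:
    """Macro one-vs-rest Precision/Recall/F1/AUROC/AUPRC over the classes
    present in `labels`, plus multiclass (Gorodkin) MCC.

    policy 'macro' averages over every class present; 'active-only'
    restricts the average to the six active-site classes.
    """
    from sklearn.metrics import (average_precision_score, matthews_corrcoef,
                                 precision_recall_fscore_support, roc_auc_score)

    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim != 2 or probs.shape[0] != labels.shape[0]:
        raise ConsistencyError("probs and labels disagree in length")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-6:
        raise ConsistencyError("probability rows must sum to 1")
    K = probs.shape[1]
    preds = np.argmax(probs, axis=1)
    present = sorted(int(k) for k in np.unique(labels))
    notes = []
    absent = sorted(set(range(K)) - set(present))
    if absent:
        note = f"classes absent from labels excluded from macro average: {absent}"
        notes.append(note)
        logger.info(note)
    eval_classes = [k for k in present if policy != "active-only" or k != 0]
    if not eval_classes:
        raise ConsistencyError("no classes left to evaluate under the policy")

    prec, rec, f1, support = precision_recall_fscore_support(
        labels, preds, labels=eval_classes, average=None, zero_division=0)
    rows = []
    aurocs, auprcs = [], []
    for ci, k in enumerate(eval_classes):
        pos = labels == k
        auroc = auprc = np.nan
        if 0 < pos.sum() < len(labels):
            auroc = roc_auc_score(pos, probs[:, k])
            auprc = average_precision_score(pos, probs[:, k])
            aurocs.append(auroc)
            auprcs.append(auprc)
        else:
            notes.append(f"class {k} lacks both label values; AUROC/AUPRC skipped")
        rows.append({"class": CLASS_NAMES[k] if k < len(CLASS_NAMES) else str(k),
                     "precision": prec[ci], "recall": rec[ci], "f1": f1[ci],
                     "auroc": auroc, "auprc": auprc, "support": int(support[ci])})
    return EvalReport(
        precision=float(np.mean(prec)), recall=float(np.mean(rec)),
        f1=float(np.mean(f1)),
        auroc=float(np.mean(aurocs)) if aurocs else float("nan"),
        auprc=float(np.mean(auprcs)) if auprcs else float("nan"),
        mcc=float(matthews_corrcoef(labels, preds)),
        averaging=policy, per_class=pd.DataFrame(rows), notes=notes)


def evaluate_records(records: list[ProteinRecord], params: ModelParams,
                     policy: str = "macro",
                     zero_text: bool = False) -> EvalReport:
    """Run the forward pass over records and score pooled residues.

    ``zero_text`` replaces the pooled text embedding with zeros at test
    time (modality-ablation probe)."""
    probs, labels = [], []
    for rec in records:
        text = np.zeros_like(rec.text_pooled) if zero_text else rec.text_pooled
        out = forward(rec.graph, rec.node_features.values, rec.seq_embedding,
                      text, params)
        probs.append(out.probs)
        labels.append(rec.labels)
    return evaluate(np.concatenate(probs), np.concatenate(labels), policy)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    params: ModelParams
    centers: CenterState
    history: list[dict]
    best_epoch: int
    best_val: EvalReport
    config: TrainConfig


def train(train_records: list[ProteinRecord], val_records: list[ProteinRecord],
          config: TrainConfig, log_path=None) -> TrainResult:
    """Full training loop; reproducible from (config, seed)."""
    for rec in train_records + val_records:
        if rec.length > config.max_len:
            raise ConsistencyError(
                f"{rec.protein_id} length {rec.length} exceeds max_len {config.max_len}")
        if rec.labels is None:
            raise ConsistencyError(f"{rec.protein_id} has no labels")
    params = ModelParams(config.network)
    centers = CenterState.initialize(config.network.n_classes,
                                     config.network.d_final,
                                     seed=config.seed, alpha=config.alpha)
    optimizer = Adam(params.params)
    n = len(train_records)
    steps_per_epoch = math.ceil(n / config.batch_size_proteins)
    total_steps = steps_per_epoch * config.epochs
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best: tuple[int, EvalReport, dict, CenterState] | None = None
    log_f = open(log_path, "w") if log_path else None
    step = 0
    try:
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            for b in range(steps_per_epoch):
                batch = [train_records[i] for i in order[
                    b * config.batch_size_proteins:(b + 1) * config.batch_size_proteins]]
                f_finals, logits_list, labels_list = [], [], []
                for rec in batch:
                    out = forward(rec.graph, rec.node_features.values,
                                  rec.seq_embedding, rec.text_pooled, params)
                    f_finals.append(out.f_final)
                    logits_list.append(out.logits)
                    labels_list.append(rec.labels)
                f_final = concat(f_finals, axis=0)
                logits = concat(logits_list, axis=0)
                labels = np.concatenate(labels_list)
                total, breakdown = compound_loss(
                    f_final, logits, labels, centers, config.loss)
                if not math.isfinite(breakdown.total):
                    raise PolysiteError(
                        "non-finite loss at step "
                        f"{step}; batch proteins: {[r.protein_id for r in batch]}")
                optimizer.zero_grad()
                total.backward()
                lr = lr_at_step(step, total_steps, config)
                optimizer.step(lr)
                centers = update_centers(centers, f_final.data, labels)
                record = {"step": step, "epoch": epoch, "ce": breakdown.ce,
                          "center": breakdown.center, "inter": breakdown.inter,
                          "total": breakdown.total, "lr": lr}
                history.append(record)
                if log_f:
                    log_f.write(json.dumps(record) + "\n")
                step += 1
            val_report = evaluate_records(val_records, params)
            history.append({"epoch": epoch, "val_f1": val_report.f1,
                            "val_mcc": val_report.mcc})
            if log_f:
                log_f.write(json.dumps(history[-1]) + "\n")
            if best is None or val_report.f1 > best[1].f1:
                best = (epoch, val_report, params.state_arrays(),
                        CenterState(centers.centers.copy(), centers.alpha))
    finally:
        if log_f:
            log_f.close()
    params.load_state_arrays(best[2])
    return TrainResult(params=params, centers=best[3], history=history,
                       best_epoch=best[0], best_val=best[1], config=config)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: ModelParams, centers: CenterState,
                    train_config: TrainConfig | None = None,
                    rng_state: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = CHECKPOINT_VERSION
        f.attrs["network_config"] = params.config.to_json()
        if train_config is not None:
            cfg = asdict(train_config)
            f.attrs["train_config"] = json.dumps(cfg)
        f.attrs["rng_state"] = json.dumps(rng_state or {})
        f.attrs["alpha"] = centers.alpha
        g = f.create_group("params")
        for k, v in params.state_arrays().items():
            g.create_dataset(k, data=v)
        f.create_dataset("centers", data=centers.centers)


def load_checkpoint(path) -> tuple[ModelParams, CenterState]:
    with h5py.File(path, "r") as f:
        if "version" not in f.attrs:
            raise ConsistencyError("checkpoint missing mandatory version field")
        config = NetworkConfig.from_json(f.attrs["network_config"])
        params = ModelParams(config)
        params.load_state_arrays({k: np.asarray(v) for k, v in f["params"].items()})
        centers = CenterState(np.asarray(f["centers"]), float(f.attrs["alpha"]))
    return params, centers


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    protein_id: str
    sequence: str
    probs: np.ndarray  # (L, K)
    predicted: np.ndarray  # (L,) ints

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "residue_number": np.arange(1, len(self.sequence) + 1),
            "aa": list(self.sequence),
            "predicted_class": [CLASS_NAMES[k] for k in self.predicted],
        })
        for k, name in enumerate(CLASS_NAMES):
            df[f"p_{name}"] = self.probs[:, k]
        return df

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {"protein_id": self.protein_id, "classes": list(CLASS_NAMES),
                   "residues": self.frame.to_dict(orient="records")}
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)


def predict_structure(structure: ProteinStructure, seq_embedding: np.ndarray,
                      text_pooled: np.ndarray, params: ModelParams,
                      protein_id: str = "query") -> PredictionResult:
    if seq_embedding.shape[0] != len(structure):
        raise ConsistencyError(
            f"sequence embedding rows {seq_embedding.shape[0]} != structure "
            f"residues {len(structure)}")
    feats, graph = featurize(structure)
    out = forward(graph, feats.values, seq_embedding, text_pooled, params)
    return PredictionResult(protein_id, structure.sequence, out.probs, out.predicted)


# ---------------------------------------------------------------------------
# cluster-aware splitting
# ---------------------------------------------------------------------------

def split_dataset(cluster_assignments: dict[str, int], max_per_cluster: int = 20,
                  ratios: tuple[int, int, int] = (8, 1, 1),
                  seed: int = 0) -> pd.DataFrame:
    """Cap each similarity cluster at `max_per_cluster` seeded picks, then
    assign whole clusters to train/val/test targeting the given ratios by
    protein count. No cluster spans two splits."""
    clusters: dict[int, list[str]] = {}
    for pid, cid in cluster_assignments.items():
        clusters.setdefault(int(cid), []).append(pid)
    if len(clusters) < 3:
        raise ConsistencyError(
            f"need at least 3 clusters to split, got {len(clusters)}")
    rng = np.random.default_rng(seed)
    kept: dict[int, list[str]] = {}
    for cid in sorted(clusters):
        members = sorted(clusters[cid])
        if len(members) > max_per_cluster:
            members = list(rng.choice(members, size=max_per_cluster, replace=False))
        kept[cid] = members
    total = sum(len(v) for v in kept.values())
    fractions = np.asarray(ratios, dtype=float) / sum(ratios)
    targets = fractions * total
    counts = np.zeros(3)
    names = ("train", "val", "test")
    assignment: dict[int, str] = {}
    order = sorted(kept, key=lambda c: (-len(kept[c]), rng.random()))
    for cid in order:
        deficits = targets - counts
        split = int(np.argmax(deficits))
        assignment[cid] = names[split]
        counts[split] += len(kept[cid])
    rows = [{"protein_id": pid, "cluster": cid, "split": assignment[cid]}
            for cid in sorted(kept) for pid in kept[cid]]
    return pd.DataFrame(rows)
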