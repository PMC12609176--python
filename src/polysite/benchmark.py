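"""Desk-scale end-to-end benchmark on the synthetic corpus.

One run: generate the default 200-protein corpus at a given seed, make the
cluster-aware 8:1:1 split, train with the desk-scale configuration, and
score the held-out test proteins — with and without the function-text
embedding at test time (the modality-ablation probe).
"""

from __future__ import annotations

import numpy as np

from .model import ActiveSiteModel, smoke_train_config
from .pipeline import evaluate_records, split_dataset, records_from_corpus
from .synthdata import SyntheticSpec, generate_corpus


def run_smoke(seed: int, keep_results: bool = False):
    """Train once on a fresh default corpus; returns headline numbers
    (and optionally the fitted results object)."""
    spec = SyntheticSpec(seed=seed)
    corpus = generate_corpus(spec)
    records = records_from_corpus(corpus)
    manifest = split_dataset({r.protein_id: r.cluster for r in records},
                             seed=seed)
    splits = dict(zip(manifest.protein_id, manifest.split))
    model = ActiveSiteModel(records, smoke_train_config(seed), splits=splits)
    results = model.fit()
    test = results.evaluate("test")
    ablated = results.evaluate("test", zero_text=True)
    n_test = sum(r.length for r in model.subset("test", splits))
    summary = {
        "seed": seed,
        "val_f1": results.validation.f1,
        "test_f1": test.f1,
        "test_mcc": test.mcc,
        "test_auroc": test.auroc,
        "test_auprc": test.auprc,
        "test_f1_zero_text": ablated.f1,
        "n_test_residues": n_test,
        "n_proteins": len(records),
    }
    return (summary, results) if keep_results else summary


def smoke_median(seeds: tuple[int, int, int], keep_results: bool = False) -> dict:
    """3-seed benchmark medians, as used by the acceptance checks."""
    pairs = [run_smoke(s, keep_results=True) for s in seeds]
    runs = [p[0] for p in pairs]
    return {
        "runs": runs,
        "results": [p[1] for p in pairs] if keep_results else None,
        "median_test_f1": float(np.median([r["test_f1"] for r in runs])),
        "median_zero_text_f1": float(np.median(
            [r["test_f1_zero_text"] for r in runs])),
        "ablation_deltas": [r["test_f1"] - r["test_f1_zero_text"] for r in runs],
        "median_ablation_delta": float(np.median(
            [r["test_f1"] - r["test_f1_zero_text"] for r in runs])),
    }
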