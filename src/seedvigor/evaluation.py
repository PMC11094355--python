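"""Splitting, metrics and end-to-end experiment orchestration.

The canonical experiment: simulate hyperspectral scenes with known per-seed
vigor labels, calibrate, segment, extract 46x46 crops and mean spectra,
PCA-reduce the crops to 5 channels, split seeds 7:3 stratified by class,
train a classifier, and report accuracy + confusion matrix.  A single
top-level seed fans out to per-stage seeds through ``numpy.random
.SeedSequence`` so one integer reproduces the whole run on CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import SpectrumMatrix, pca_reduce
from .segmentation import segment_scene
from .synthetic import SceneSpec, make_class_spectra, render_scene
from .vigor import VIGOR_GRADES

__all__ = [
    "EvalReport",
    "stratified_split",
    "evaluate_model",
    "stage_seeds",
    "build_synthetic_dataset",
    "run_cnn_lstm_experiment",
]


def stage_seeds(top_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-stage seeds (< 2**31) from one seed."""
    ss = np.random.SeedSequence(top_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class EvalReport:
    """Accuracy (percent, 2 decimals), per-class accuracy and confusion matrix."""

    accuracy: float
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray  # true x predicted counts
    class_order: tuple[str, ...]
    split: str = ""
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        obj = {
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion": self.confusion.tolist(),
            "class_order": list(self.class_order),
            "split": self.split,
            "provenance": self.provenance,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        obj = json.loads(Path(path).read_text())
        return cls(
            accuracy=obj["accuracy"],
            per_class_accuracy=obj["per_class_accuracy"],
            confusion=np.array(obj["confusion"]),
            class_order=tuple(obj["class_order"]),
            split=obj.get("split", ""),
            provenance=obj.get("provenance", {}),
        )


def stratified_split(
    labels: np.ndarray, train_fraction: float = 0.7, rng_seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class 7:3 split; the train side gets floor(frac * n_total) samples.

    Per-class train counts start at floor(frac * n_class); leftover seats up
    to the overall floor(frac * n_total) go to the classes with the largest
    fractional remainders, so every class's train share stays within one
    sample of ``train_fraction``.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to split")
    rng = np.random.default_rng(rng_seed)
    total_train = int(np.floor(train_fraction * len(labels)))
    floors = np.floor(train_fraction * counts).astype(int)
    remainders = train_fraction * counts - floors
    take = floors.copy()
    for idx in np.argsort(-remainders):
        if take.sum() >= total_train:
            break
        if take[idx] < counts[idx] - 1:
            take[idx] += 1
    train_idx, test_idx = [], []
    for cls, n_train in zip(classes, take):
        members = np.nonzero(labels == cls)[0]
        perm = rng.permutation(members)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def evaluate_model(
    predictions: np.ndarray,
    true_labels: np.ndarray,
    class_order: tuple[str, ...] = VIGOR_GRADES,
    split: str = "",
    provenance: dict | None = None,
) -> EvalReport:
    """Overall/per-class accuracy and the true x predicted confusion matrix."""
    predictions = np.asarray(predictions)
    true_labels = np.asarray(true_labels)
    if predictions.shape != true_labels.shape:
        raise ValueError("prediction and label vectors must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    bad = set(np.unique(np.concatenate([predictions, true_labels]))) - set(class_order)
    if bad:
        raise ValueError(f"labels outside class order: {sorted(bad)}")
    k = len(class_order)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predictions):
        confusion[index[t], index[p]] += 1
    accuracy = round(100.0 * np.trace(confusion) / confusion.sum(), 2)
    per_class = {}
    for i, c in enumerate(class_order):
        row = confusion[i].sum()
        per_class[c] = round(100.0 * confusion[i, i] / row, 2) if row else float("nan")
    return EvalReport(
        accuracy=accuracy,
        per_class_accuracy=per_class,
        confusion=confusion,
        class_order=tuple(class_order),
        split=split,
        provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# End-to-end synthetic experiment
# ---------------------------------------------------------------------------

def build_synthetic_dataset(
    n_scenes: int = 4,
    rng_seed: int = 0,
    noise_sd: float = 0.01,
    pca_components: int = 5,
    crop: int = 46,
):
    """Simulate scenes, calibrate, segment, and assemble crops + spectra.

    Returns (crops array N x crop x crop x w_pca placeholder…) — concretely a
    dict with raw 46x46x360 crops (float32), mean spectra, true labels and
    wavelengths; PCA reduction is applied by the caller after splitting so
    the model is fitted on training crops only.
    """
    seeds = stage_seeds(rng_seed, 2 + n_scenes)
    models = make_class_spectra(seeds[0], noise_sd=noise_sd)
    crops, spectra, labels = [], [], []
    wavelengths = None
    for s in range(n_scenes):
        spec = SceneSpec(rng_seed=seeds[2 + s])
        scene = render_scene(spec, models)
        cube = scene.calibrated()
        wavelengths = cube.wavelengths
        rois = segment_scene(cube, crop=crop)
        truth = scene.truth.set_index("seed_id")
        for roi in rois:
            # majority label-map id inside the ROI gives the true seed
            ids = scene.label_map[roi.mask]
            ids = ids[ids > 0]
            if ids.size == 0:
                continue
            true_id = int(np.bincount(ids).argmax())
            labels.append(truth.loc[true_id, "vigor"])
            crops.append(roi.crop.astype(np.float32))
            spectra.append(roi.mean_spectrum)
    return {
        "crops": crops,
        "spectra": SpectrumMatrix(np.stack(spectra), np.array(labels), wavelengths),
        "labels": np.array(labels),
        "wavelengths": wavelengths,
        "class_models": models,
        "pca_components": pca_components,
    }


def run_cnn_lstm_experiment(
    rng_seed: int = 0,
    n_scenes: int = 4,
    noise_sd: float = 0.01,
    hp: nn.HyperParams | None = None,
    arch: str = "cnn_lstm",
    dataset: dict | None = None,
) -> dict:
    """The full pipeline: simulate -> extract -> PCA -> train -> evaluate.

    Returns the evaluation report, training history and the fitted model.
    """
    seeds = stage_seeds(rng_seed ^ 0x5EED, 3)
    if dataset is None:
        dataset = build_synthetic_dataset(n_scenes=n_scenes, rng_seed=rng_seed,
                                          noise_sd=noise_sd)
    labels = dataset["labels"]
    class_order = tuple(VIGOR_GRADES)
    y = np.array([class_order.index(l) for l in labels])
    train_idx, test_idx = stratified_split(labels, 0.7, rng_seed=seeds[0])

    crops = dataset["crops"]
    k = dataset["pca_components"]
    train_crops = [crops[i] for i in train_idx]
    test_crops = [crops[i] for i in test_idx]
    train_red, pca_model = pca_reduce(train_crops, k=k, rng_seed=seeds[1])
    test_red, _ = pca_reduce(test_crops, k=k, model=pca_model)
    # scale to unit spread so every architecture sees O(1) inputs
    scale = float(np.std(np.stack(train_red))) or 1.0
    Xtr = np.stack(train_red) / scale
    Xte = np.stack(test_red) / scale

    if hp is None:
        hp = nn.HyperParams(lr=0.002, bs=8, epochs=100, optimizer="adam")
    spec, model = nn.build_model(arch, Xtr.shape[1:], n_classes=len(class_order),
                                 rng_seed=seeds[2])
    model, history = nn.train_model(
        model, (Xtr, y[train_idx]), (Xte, y[test_idx]), hp, rng_seed=seeds[2]
    )
    pred_idx, _ = nn.predict_labels(model, Xte)
    pred = np.array([class_order[i] for i in pred_idx])
    report = evaluate_model(
        pred,
        labels[test_idx],
        class_order,
        split=f"stratified 7:3, seed {rng_seed}",
        provenance={"arch": arch, "lr": hp.lr, "bs": hp.bs, "epochs": hp.epochs,
                    "optimizer": hp.optimizer, "n_seeds": len(labels)},
    )
    return {
        "report": report,
        "history": history,
        "model": model,
        "arch_spec": spec,
        "pca_model": pca_model,
        "scale": scale,
        "split": (train_idx, test_idx),
        "data": (Xtr, y[train_idx], Xte, y[test_idx]),
        "dataset": dataset,
    }
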