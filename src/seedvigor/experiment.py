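"""Pre-wired experiments: firefly (lr, bs) tuning of the CNN-LSTM.

The tuner needs a trainer callback that maps a candidate (lr, bs) to a
validation misclassification rate.  Here that callback trains the CNN-LSTM
for a reduced epoch budget on a fixed inner train/validation split of the
synthetic dataset, so each firefly evaluation stays desk-scale; the final
model is then retrained at the optimum on the full training set.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .evaluation import build_synthetic_dataset, stage_seeds, stratified_split
from .firefly import FAConfig, misclassification_objective, tune_hyperparams
from .preprocess import pca_reduce
from .vigor import VIGOR_GRADES


def prepare_image_dataset(
    n_scenes: int = 2, rng_seed: int = 0, noise_sd: float = 0.01
) -> dict:
    """Simulate scenes and produce PCA-reduced, scaled image stacks + splits."""
    seeds = stage_seeds(rng_seed ^ 0xFA, 3)
    data = build_synthetic_dataset(n_scenes=n_scenes, rng_seed=rng_seed,
                                   noise_sd=noise_sd)
    labels = data["labels"]
    order = tuple(VIGOR_GRADES)
    y = np.array([order.index(l) for l in labels])
    tr, te = stratified_split(labels, 0.7, rng_seed=seeds[0])
    crops = data["crops"]
    train_red, pca_model = pca_reduce([crops[i] for i in tr],
                                      k=data["pca_components"], rng_seed=seeds[1])
    test_red, _ = pca_reduce([crops[i] for i in te], k=data["pca_components"],
                             model=pca_model)
    scale = float(np.std(np.stack(train_red))) or 1.0
    return {
        "Xtr": np.stack(train_red) / scale,
        "ytr": y[tr],
        "Xte": np.stack(test_red) / scale,
        "yte": y[te],
        "seeds": seeds,
        "class_order": order,
    }


def fa_tuning_demo(
    rng_seed: int = 3,
    n_pop: int = 5,
    n_iter: int = 5,
    inner_epochs: int = 10,
    n_scenes: int = 2,
    default_lr: float = 0.001,
    default_bs: int = 8,
    dataset: dict | None = None,
) -> dict:
    """Firefly search over (lr, bs) for the CNN-LSTM on synthetic scenes.

    Candidates are scored by validation misclassification after
    ``inner_epochs`` of training on an inner split of the training set; the
    incumbent default (lr, bs) is planted in the initial population.  Returns
    the best pair, its objective, the default's objective and the full
    evaluation log.
    """
    ds = dataset if dataset is not None else prepare_image_dataset(
        n_scenes=n_scenes, rng_seed=rng_seed
    )
    Xtr, ytr = ds["Xtr"], ds["ytr"]
    inner_tr, inner_val = stratified_split(ytr, 0.7, rng_seed=ds["seeds"][2])
    net_seed = ds["seeds"][2]

    def trainer(lr: float, bs: int) -> float:
        hp = nn.HyperParams(lr=lr, bs=bs, epochs=inner_epochs, optimizer="adam")
        _, model = nn.build_model("cnn_lstm", Xtr.shape[1:],
                                  n_classes=len(ds["class_order"]),
                                  rng_seed=net_seed)
        try:
            model, _ = nn.train_model(
                model, (Xtr[inner_tr], ytr[inner_tr]), None, hp, rng_seed=net_seed
            )
        except nn.DivergenceError:
            return 1.0  # diverged candidates are maximally unfit
        pred, _ = nn.predict_labels(model, Xtr[inner_val])
        return misclassification_objective(ytr[inner_val], pred)

    cfg = FAConfig(n_pop=n_pop, n_iter=n_iter, rng_seed=rng_seed)
    result = tune_hyperparams(
        trainer, cfg, include_default=(default_lr, default_bs)
    )
    result["default_f_obj"] = trainer(default_lr, default_bs)
    result["dataset"] = ds
    return result
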