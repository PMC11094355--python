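"""Spectral preprocessing and band selection.

Covers the chemometric toolbox applied to the n_samples x n_bands matrix of
per-seed mean spectra:

* SNV — per-spectrum standardization to zero mean, unit variance;
* MSC — per-spectrum affine regression against a reference spectrum
  (default: training-set mean), inverting scatter-induced slope/offset;
* SPA — greedy band selection maximizing the residual column norm after
  orthogonal projection onto the already-selected bands;
* CARS — Monte-Carlo band selection shrinking the variable set by PLS-DA
  coefficient weight under an exponentially decreasing retention schedule;
* pixel-wise PCA reduction of 46x46xw crops to 46x46xk image stacks;
* per-band Welch tests marking wavelength regions where two vigor classes do
  not differ significantly.

Fitted transformers (MSC reference, PCA model, band selections) persist to a
JSON sidecar so a trained pipeline can be reapplied to held-out data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .vigor import VIGOR_GRADES

__all__ = [
    "SpectrumMatrix",
    "BandSelection",
    "PcaModel",
    "MscTransformer",
    "snv",
    "msc",
    "spa_select",
    "cars_select",
    "cars_retention_schedule",
    "pca_reduce",
    "band_significance_mask",
]


@dataclass
class SpectrumMatrix:
    """n_samples x n_bands reflectance matrix with labels and wavelengths."""

    X: np.ndarray
    labels: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.labels.size and self.labels.shape[0] != self.X.shape[0]:
            raise ValueError("label count must match sample count")
        if self.wavelengths.shape[0] != self.X.shape[1]:
            raise ValueError("wavelength count must match band count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing/non-finite values")
        bad = set(np.unique(self.labels)) - set(VIGOR_GRADES)
        if self.labels.size and bad:
            raise ValueError(f"unknown labels {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def with_X(self, X: np.ndarray) -> "SpectrumMatrix":
        return SpectrumMatrix(X, self.labels, self.wavelengths)

    def select_bands(self, idx: np.ndarray) -> "SpectrumMatrix":
        return SpectrumMatrix(self.X[:, idx], self.labels, self.wavelengths[idx])


@dataclass
class BandSelection:
    """Sorted unique band indices chosen by a selector, with diagnostics."""

    indices: np.ndarray
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise ValueError("empty band selection")
        if np.any(self.indices < 0):
            raise ValueError("negative band index")
        self.indices = np.unique(self.indices)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "format": "seedvigor.band_selection/1",
                    "method": self.method,
                    "indices": self.indices.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "BandSelection":
        obj = json.loads(Path(path).read_text())
        return cls(np.array(obj["indices"]), obj["method"])


# ---------------------------------------------------------------------------
# Scatter correction
# ---------------------------------------------------------------------------

def snv(spectra: SpectrumMatrix) -> SpectrumMatrix:
    """Standard normal variate: each row to mean 0, sample SD 1 (ddof=1)."""
    X = spectra.X
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.nonzero(sd.ravel() == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance spectrum in row(s) {zero.tolist()}")
    return spectra.with_X((X - mean) / sd)


class MscTransformer:
    """Multiplicative scatter correction against a stored reference spectrum.

    ``fit`` stores the training-set mean spectrum (unless an explicit
    reference is given); ``apply`` regresses each spectrum s on the reference
    (s ≈ a + b·ref, least squares) and returns (s − a)/b.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = None if reference is None else np.asarray(reference, float)

    def fit(self, spectra: SpectrumMatrix) -> "MscTransformer":
        if self.reference is None:
            if spectra.n_samples < 2:
                raise ValueError("MSC needs >= 2 samples to fit a mean reference")
            self.reference = spectra.X.mean(axis=0)
        return self

    def apply(self, spectra: SpectrumMatrix) -> SpectrumMatrix:
        if self.reference is None:
            raise RuntimeError("MscTransformer not fitted")
        ref = self.reference
        refc = ref - ref.mean()
        denom = float(refc @ refc)
        X = spectra.X
        b = (X - X.mean(axis=1, keepdims=True)) @ refc / denom
        a = X.mean(axis=1) - b * ref.mean()
        bad = np.nonzero(np.abs(b) < 1e-8)[0]
        if bad.size:
            raise ValueError(f"degenerate MSC fit (b ~ 0) in row(s) {bad.tolist()}")
        return spectra.with_X((X - a[:, None]) / b[:, None])

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "format": "seedvigor.msc/1",
                    "reference": self.reference.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "MscTransformer":
        obj = json.loads(Path(path).read_text())
        return cls(np.array(obj["reference"]))


def msc(spectra: SpectrumMatrix, reference: np.ndarray | None = None) -> SpectrumMatrix:
    """One-shot MSC (fits the reference on ``spectra`` itself if not given)."""
    return MscTransformer(reference).fit(spectra).apply(spectra)


# ---------------------------------------------------------------------------
# Band selection
# ---------------------------------------------------------------------------

def spa_select(
    spectra: SpectrumMatrix, k: int, first_band: int | None = None
) -> BandSelection:
    """Successive projections algorithm: greedy maximal-residual-norm bands.

    Starting from ``first_band`` (default: largest column norm), repeatedly
    adds the band whose column has the largest norm after projection onto the
    orthogonal complement of the span of the already-selected columns.
    """
    X = spectra.X
    n_bands = X.shape[1]
    if not 1 <= k <= n_bands:
        raise ValueError("k must lie in [1, n_bands]")
    if k > np.linalg.matrix_rank(X):
        raise ValueError(f"k={k} exceeds matrix rank {np.linalg.matrix_rank(X)}")
    norms = np.linalg.norm(X, axis=0)
    start = int(np.argmax(norms)) if first_band is None else int(first_band)
    selected = [start]
    # residuals of every column after projecting out the selected span,
    # updated by Gram-Schmidt against each newly-selected (orthogonalized) column
    R = X.astype(float).copy()
    q = R[:, start] / np.linalg.norm(R[:, start])
    R = R - np.outer(q, q @ R)
    for _ in range(1, k):
        res_norms = np.linalg.norm(R, axis=0)
        res_norms[selected] = -1.0
        nxt = int(np.argmax(res_norms))
        if res_norms[nxt] <= 1e-12:
            raise ValueError("remaining columns are in the selected span (rank)")
        selected.append(nxt)
        q = R[:, nxt] / np.linalg.norm(R[:, nxt])
        R = R - np.outer(q, q @ R)
    return BandSelection(
        np.array(selected), "SPA", {"order": [int(s) for s in selected]}
    )


def cars_retention_schedule(n_bands: int, runs: int) -> np.ndarray:
    """Band counts kept after each CARS run (exponentially decreasing).

    Uses the standard closed form r_i = a·exp(−k·i) with
    a = (p/2)^(1/(N−1)) and k = ln(p/2)/(N−1), so that r_1 = 1 (all bands)
    and r_N = 2/p (two bands), with kept count round(p·r_i).
    """
    if runs < 2:
        raise ValueError("runs must be >= 2")
    p = n_bands
    a = (p / 2.0) ** (1.0 / (runs - 1))
    kcoef = np.log(p / 2.0) / (runs - 1)
    i = np.arange(1, runs + 1)
    counts = np.round(p * a * np.exp(-kcoef * i)).astype(int)
    return np.clip(counts, 2, p)


def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    return Y, classes


def _plsda_fit(X: np.ndarray, labels: np.ndarray, n_components: int) -> PLSRegression:
    Y, _ = _one_hot(labels)
    n_comp = int(min(n_components, X.shape[1], max(1, X.shape[0] - 1)))
    pls = PLSRegression(n_components=n_comp, scale=False)
    pls.fit(X, Y)
    return pls


def _plsda_cv_accuracy(
    X: np.ndarray, labels: np.ndarray, folds: int, n_components: int, rng_seed: int
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    correct = 0
    for tr, te in skf.split(X, labels):
        pls = _plsda_fit(X[tr], labels[tr], n_components)
        tr_classes = np.unique(labels[tr])  # one-hot column order used in the fit
        pred = tr_classes[np.argmax(pls.predict(X[te]), axis=1)]
        correct += int(np.sum(pred == labels[te]))
    return correct / len(labels)


def cars_select(
    spectra: SpectrumMatrix,
    runs: int = 50,
    cv_folds: int = 5,
    rng_seed: int = 0,
    n_components: int = 10,
    calibration_fraction: float = 0.8,
) -> BandSelection:
    """Competitive adaptive reweighted sampling band selection.

    Each run fits PLS-DA on a Monte-Carlo calibration subset, ranks bands by
    absolute regression-coefficient weight, enforces the exponential
    retention schedule, then resamples the survivors by weight (adaptive
    reweighted sampling). The run whose retained subset maximizes
    cross-validated PLS-DA accuracy wins.
    """
    if runs < 2:
        raise ValueError("runs must be >= 2")
    X, labels = spectra.X, spectra.labels
    n, p = X.shape
    if n < cv_folds:
        raise ValueError(f"n_samples={n} < cv_folds={cv_folds}")
    rng = np.random.default_rng(rng_seed)
    schedule = cars_retention_schedule(p, runs)
    retained = np.arange(p)
    history = []
    best = (-1.0, None)
    for run in range(runs):
        n_cal = max(2, int(round(calibration_fraction * n)))
        cal = rng.choice(n, size=n_cal, replace=False)
        # keep all classes represented in the calibration subset
        if len(np.unique(labels[cal])) < len(np.unique(labels)):
            cal = rng.permutation(n)[:n_cal]
        pls = _plsda_fit(X[np.ix_(cal, retained)], labels[cal], n_components)
        weights = np.abs(pls.coef_).sum(axis=0)
        weights = np.asarray(weights, dtype=float).ravel()
        keep_n = min(int(schedule[run]), retained.size)
        # enforced exponential cut: top weights survive
        top = np.argsort(weights)[::-1][:keep_n]
        # adaptive reweighted sampling among survivors
        w = weights[top]
        if w.sum() <= 0:
            chosen = top
        else:
            probs = w / w.sum()
            draws = rng.choice(len(top), size=len(top), replace=True, p=probs)
            chosen = top[np.unique(draws)]
        retained = np.sort(retained[chosen])
        if retained.size < 2:
            retained = np.sort(np.unique(np.concatenate([retained, top[:2]])))
        acc = _plsda_cv_accuracy(
            X[:, retained], labels, cv_folds, n_components, rng_seed
        )
        history.append({"run": run + 1, "n_bands": int(retained.size), "cv_accuracy": acc})
        if acc > best[0]:
            best = (acc, retained.copy())
    return BandSelection(
        best[1], "CARS", {"history": history, "best_cv_accuracy": best[0]}
    )


# ---------------------------------------------------------------------------
# PCA cube reduction
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """Per-band means + top-k loadings fitted on pooled training pixels."""

    mean: np.ndarray
    components: np.ndarray  # k x n_bands
    explained_variance_ratio: np.ndarray

    def transform_crop(self, crop: np.ndarray) -> np.ndarray:
        h, w, nb = crop.shape
        flat = crop.reshape(-1, nb) - self.mean
        return (flat @ self.components.T).reshape(h, w, -1)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "format": "seedvigor.pca/1",
                    "mean": self.mean.tolist(),
                    "components": self.components.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                },
            )
        )

    @classmethod
    def from_json(cls, path) -> "PcaModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            np.array(obj["mean"]),
            np.array(obj["components"]),
            np.array(obj["explained_variance_ratio"]),
        )


def pca_reduce(
    crops: list[np.ndarray],
    k: int = 5,
    model: PcaModel | None = None,
    max_fit_pixels: int = 100_000,
    rng_seed: int = 0,
) -> tuple[list[np.ndarray], PcaModel]:
    """Reduce h x w x n_bands crops to h x w x k via pixel-spectrum PCA.

    The model is fitted on the pooled pixel spectra of the supplied crops
    (subsampled to ``max_fit_pixels`` for large pools) unless an existing
    ``model`` is passed, in which case it is applied unchanged — fit on
    training crops, reuse on held-out crops.
    """
    if not crops:
        raise ValueError("no crops")
    nb = crops[0].shape[2]
    if any(c.shape[2] != nb for c in crops):
        raise ValueError("crops must share band count")
    if k > nb:
        raise ValueError("k exceeds band count")
    if model is None:
        pool = np.concatenate([c.reshape(-1, nb) for c in crops], axis=0)
        if pool.shape[0] > max_fit_pixels:
            rng = np.random.default_rng(rng_seed)
            pool = pool[rng.choice(pool.shape[0], max_fit_pixels, replace=False)]
        if k > min(pool.shape):
            raise ValueError("k exceeds the number of distinct pixel spectra")
        pca = PCA(n_components=k, svd_solver="auto", random_state=rng_seed)
        pca.fit(pool)
        model = PcaModel(
            pca.mean_, pca.components_, pca.explained_variance_ratio_
        )
    reduced = [model.transform_crop(np.asarray(c, dtype=float)) for c in crops]
    return reduced, model


# ---------------------------------------------------------------------------
# Per-band significance
# ---------------------------------------------------------------------------

def band_significance_mask(
    group_a: SpectrumMatrix | np.ndarray,
    group_b: SpectrumMatrix | np.ndarray,
    alpha: float = 0.01,
) -> np.ndarray:
    """Boolean mask of bands where the groups do NOT differ significantly.

    Per-band two-sample Welch t-test; True marks p >= alpha (the shaded
    non-significant wavelength regions when comparing two vigor classes).
    """
    A = group_a.X if isinstance(group_a, SpectrumMatrix) else np.asarray(group_a)
    B = group_b.X if isinstance(group_b, SpectrumMatrix) else np.asarray(group_b)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs >= 2 samples")
    if A.shape[1] != B.shape[1]:
        raise ValueError("band count mismatch")
    _, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    return p >= alpha
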