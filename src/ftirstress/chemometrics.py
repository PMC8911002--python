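"""PCA exploration and PCA-stabilized Fisher discriminant analysis.

The discrimination task has far more wavenumbers (3201 in the 400–3600
cm^-1 feature range) than training spectra, so the within-class scatter
matrix is singular in the raw feature space. The classifier therefore
reduces the training spectra to a rank-``pca_rank`` PCA subspace (default
40), fits the two-class Fisher discriminant there, and back-projects the
discriminant direction to wavenumber space — the PCA-LDA construction
standard in vibrational-spectroscopy chemometrics. The back-projected
direction ("LD1 loadings", unit Euclidean norm) scores a spectrum exactly
as the reduced-space direction scores its PCA coordinates.

Sign convention: the heat class lies on the positive LD1 side; the
decision threshold is the midpoint of the two training-class means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .spectra import SpectrumSet

DEFAULT_FEATURE_RANGE = (400.0, 3600.0)
DEFAULT_PCA_RANK = 40


@dataclass
class PcaModel:
    """Centered (covariance) PCA of a spectrum set."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_components, n_wavenumbers), orthonormal rows
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    wavenumbers: np.ndarray


@dataclass
class SplitRecord:
    """Bookkeeping for one random train/test partition."""

    train_ids: list[str]
    test_ids: list[str]
    ratio: float
    seed: int
    grouping: str = "none"


@dataclass
class LdaModel:
    """A fitted two-class discriminant in wavenumber space."""

    feature_range: tuple[float, float]
    wavenumbers: np.ndarray
    pca_rank: int
    pca_mean: np.ndarray
    pca_components: np.ndarray
    ld1_feature_space: np.ndarray  # unit-norm direction in the PCA subspace
    ld1_loadings: np.ndarray  # unit-norm back-projection over wavenumbers
    class_means_ld1: dict[str, float]
    threshold: float
    split: SplitRecord


def pca_fit(sset: SpectrumSet, n_components: int) -> PcaModel:
    """Centered PCA of the full-grid spectra (no variable scaling).

    Spectra are already total-sum normalized, so components are extracted
    from the covariance structure of the absorbance values directly.
    """
    n = len(sset)
    if n < 2:
        raise ValueError("PCA requires at least 2 spectra")
    max_rank = min(n - 1, sset.absorbance.shape[1])
    if not (1 <= n_components <= max_rank):
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(sset.absorbance)
    return PcaModel(
        mean_spectrum=pca.mean_,
        loadings=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        wavenumbers=sset.wavenumbers.copy(),
    )


def pca_project(model: PcaModel, sset: SpectrumSet) -> np.ndarray:
    """Scores of a set in an existing PCA basis: (X - mean) @ loadings.T."""
    if not np.array_equal(sset.wavenumbers, model.wavenumbers):
        raise ValueError("grid mismatch between PCA model and spectrum set")
    return (sset.absorbance - model.mean_spectrum) @ model.loadings.T


def split_set(
    sset: SpectrumSet,
    ratio: float = 0.6,
    seed: int = 0,
    grouping: str = "none",
) -> SplitRecord:
    """Random class-stratified train/test split.

    Each class contributes ``round(ratio * n_class)`` training spectra.
    With ``grouping='by_disk'`` or ``'by_plant'`` all spectra of one disk
    or plant land on the same side (groups are accumulated until the
    training quota is reached), which avoids replicate leakage at the cost
    of a slightly off-target ratio.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if grouping not in ("none", "by_disk", "by_plant"):
        raise ValueError(f"unknown grouping {grouping!r}")
    meta = sset.meta
    labels = sorted(meta["class_label"].dropna().unique())
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    for label in labels:
        sub = meta[meta["class_label"] == label]
        if len(sub) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 spectra")
        n_train = int(round(ratio * len(sub)))
        if grouping == "none":
            picked = rng.permutation(sub["spectrum_id"].to_numpy())[:n_train]
            train.update(picked)
        else:
            key = "disk_id" if grouping == "by_disk" else "plant_id"
            groups = list(sub[key].dropna().unique())
            rng.shuffle(groups)
            count = 0
            for g in groups:
                if count >= n_train:
                    break
                members = sub.loc[sub[key] == g, "spectrum_id"]
                train.update(members)
                count += len(members)
    order = meta["spectrum_id"].tolist()
    return SplitRecord(
        train_ids=[sid for sid in order if sid in train],
        test_ids=[sid for sid in order if sid not in train],
        ratio=ratio,
        seed=seed,
        grouping=grouping,
    )


def _fisher_direction(T: np.ndarray, is_heat: np.ndarray) -> np.ndarray:
    """Fisher direction Sw^-1 (mu_heat - mu_control) in the reduced space."""
    mu_c = T[~is_heat].mean(axis=0)
    mu_h = T[is_heat].mean(axis=0)
    centered = np.where(is_heat[:, None], T - mu_h, T - mu_c)
    sw = centered.T @ centered / (len(T) - 2)
    try:
        w = np.linalg.solve(sw, mu_h - mu_c)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "within-class scatter is singular at the requested rank; "
            "lower pca_rank"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise ValueError(
            "within-class scatter is numerically singular; lower pca_rank"
        )
    return w


def lda_fit(
    sset: SpectrumSet,
    split: SplitRecord,
    pca_rank: int = DEFAULT_PCA_RANK,
    feature_range: tuple[float, float] = DEFAULT_FEATURE_RANGE,
) -> LdaModel:
    """Fit the PCA-reduced Fisher discriminant on the training spectra."""
    nu, X = sset.restrict(*feature_range)
    id_to_row = {sid: i for i, sid in enumerate(sset.meta["spectrum_id"])}
    train_idx = [id_to_row[sid] for sid in split.train_ids]
    X_train = X[train_idx]
    train_labels = sset.meta["class_label"].to_numpy()[train_idx]
    present = set(train_labels)
    if not {"control", "heat"} <= present:
        raise ValueError(f"training set must contain both classes, has {sorted(present)}")
    n_train = len(train_idx)
    if not (1 <= pca_rank <= n_train - 2):
        raise ValueError(f"pca_rank must be in [1, {n_train - 2}] for {n_train} training spectra")

    pca = PCA(n_components=pca_rank, svd_solver="full")
    T = pca.fit_transform(X_train)
    is_heat = train_labels == "heat"
    w = _fisher_direction(T, is_heat)
    w = w / np.linalg.norm(w)
    loadings = pca.components_.T @ w  # unit norm: components rows orthonormal

    train_scores = T @ w
    mean_c = float(train_scores[~is_heat].mean())
    mean_h = float(train_scores[is_heat].mean())
    if mean_h < mean_c:  # heat on the positive LD1 side
        w, loadings = -w, -loadings
        mean_c, mean_h = -mean_c, -mean_h
    return LdaModel(
        feature_range=feature_range,
        wavenumbers=nu.copy(),
        pca_rank=pca_rank,
        pca_mean=pca.mean_,
        pca_components=pca.components_,
        ld1_feature_space=w,
        ld1_loadings=loadings,
        class_means_ld1={"control": mean_c, "heat": mean_h},
        threshold=(mean_c + mean_h) / 2.0,
        split=split,
    )


def lda_score(model: LdaModel, sset: SpectrumSet) -> pd.DataFrame:
    """LD1 score and predicted label per spectrum.

    A spectrum is called heat iff its LD1 score exceeds the model's
    midpoint threshold.
    """
    nu, X = sset.restrict(*model.feature_range)
    if not np.array_equal(nu, model.wavenumbers):
        raise ValueError("grid mismatch between LDA model and spectrum set")
    scores = (X - model.pca_mean) @ model.ld1_loadings
    return pd.DataFrame(
        {
            "spectrum_id": sset.meta["spectrum_id"].to_numpy(),
            "class_label": sset.meta["class_label"].to_numpy(),
            "ld1_score": scores,
            "predicted_label": np.where(scores > model.threshold, "heat", "control"),
        }
    )


def accuracy(scored: pd.DataFrame) -> float:
    """Fraction of spectra whose predicted label matches the true label."""
    return float((scored["predicted_label"] == scored["class_label"]).mean())
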