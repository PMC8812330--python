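"""Trainable pixel classification for the lipid-droplet channel.

The droplet channel is segmented by a per-pixel random forest over a bank of
image features — Gaussian blurs, pairwise differences of Gaussians, Sobel
gradient magnitudes, Hessian eigenvalues and membrane (rotated line kernel)
projections — at a ladder of scales. The estimator follows scikit-learn
conventions (``fit`` / ``predict`` / ``get_params``), wraps
``sklearn.ensemble.RandomForestClassifier``, and round-trips losslessly
through its own on-disk model directory.

When no trained model is available the pipeline falls back to a Yen
threshold of the droplet channel (see :func:`fallback_ld_mask`).
"""

from __future__ import annotations

import dataclasses
import json
import os

import joblib
import numpy as np
from scipy import ndimage
from skimage.filters import sobel
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .thresholds import auto_mask

FEATURE_KINDS = (
    "gaussian_blur",
    "difference_of_gaussians",
    "sobel",
    "hessian",
    "membrane_projections",
)

DEFAULT_SIGMAS = (1.0, 2.0, 4.0, 8.0, 16.0)


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """Which features are computed and at which scales."""

    kinds: tuple = FEATURE_KINDS
    sigmas: tuple = DEFAULT_SIGMAS
    membrane_size: int = 19   # line-kernel side length, px
    membrane_patch: int = 3   # line thickness, px
    membrane_angles: int = 6  # rotations over 180 degrees (30-degree steps)

    def __post_init__(self) -> None:
        unknown = set(self.kinds) - set(FEATURE_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kinds: {sorted(unknown)}")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        d["kinds"] = tuple(d["kinds"])
        d["sigmas"] = tuple(d["sigmas"])
        return cls(**d)


def _hessian_eigenvalues(smoothed: np.ndarray):
    """Eigenvalue planes (largest, smallest) of the finite-difference Hessian."""
    d_r, d_c = np.gradient(smoothed)
    hrr, hrc = np.gradient(d_r)
    hcc = np.gradient(d_c, axis=1)
    mean = 0.5 * (hrr + hcc)
    root = np.sqrt((0.5 * (hrr - hcc)) ** 2 + hrc**2)
    return mean + root, mean - root


def _membrane_kernels(size: int, patch: int, n_angles: int) -> list:
    base = np.zeros((size, size))
    mid = size // 2
    half = patch // 2
    base[:, mid - half : mid + half + 1] = 1.0
    kernels = []
    for i in range(n_angles):
        angle = 180.0 * i / n_angles
        k = ndimage.rotate(base, angle, reshape=False, order=1)
        kernels.append(k / k.sum())
    return kernels


def compute_features(plane: np.ndarray, config: FeatureConfig | None = None):
    """Feature stack for one plane.

    Returns ``(stack, names)`` where ``stack`` has shape
    ``(n_features, h, w)`` (float32) and ``names`` labels each plane. The raw
    intensity is always the first feature.
    """
    config = config or FeatureConfig()
    plane = np.asarray(plane, dtype=np.float64)
    feats = [plane]
    names = ["original"]

    gaussians = {s: ndimage.gaussian_filter(plane, s) for s in config.sigmas}

    if "gaussian_blur" in config.kinds:
        for s in config.sigmas:
            feats.append(gaussians[s])
            names.append(f"gaussian_{s:g}")
    if "difference_of_gaussians" in config.kinds:
        for i, s1 in enumerate(config.sigmas):
            for s2 in config.sigmas[i + 1 :]:
                feats.append(gaussians[s1] - gaussians[s2])
                names.append(f"dog_{s1:g}_{s2:g}")
    if "sobel" in config.kinds:
        for s in config.sigmas:
            feats.append(sobel(gaussians[s]))
            names.append(f"sobel_{s:g}")
    if "hessian" in config.kinds:
        for s in config.sigmas:
            ev_hi, ev_lo = _hessian_eigenvalues(gaussians[s])
            feats.append(ev_hi)
            names.append(f"hessian_max_{s:g}")
            feats.append(ev_lo)
            names.append(f"hessian_min_{s:g}")
    if "membrane_projections" in config.kinds:
        kernels = _membrane_kernels(
            config.membrane_size, config.membrane_patch, config.membrane_angles
        )
        responses = np.stack(
            [ndimage.convolve(plane, k, mode="nearest") for k in kernels]
        )
        for proj, fn in (
            ("sum", np.sum),
            ("mean", np.mean),
            ("std", np.std),
            ("median", np.median),
            ("max", np.max),
            ("min", np.min),
        ):
            feats.append(fn(responses, axis=0))
            names.append(f"membrane_{proj}")

    stack = np.stack(feats).astype(np.float32)
    if not np.isfinite(stack).all():
        raise ValueError("non-finite values in feature stack")
    return stack, names


def fallback_ld_mask(
    ld_plane: np.ndarray, bit_depth: int = 8, min_size_px: int = 9
) -> np.ndarray:
    """Model-free droplet mask: Yen threshold of the droplet channel.

    Connected components below ``min_size_px`` pixels (sub-resolution
    speckle; well under any real droplet's footprint) are removed.
    """
    from scipy import ndimage

    mask, _ = auto_mask(ld_plane, "yen", bit_depth)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size_px
    keep[0] = False
    return keep[labels]


MODEL_JSON = "model.json"
MODEL_FOREST = "forest.joblib"


class LDPixelClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest pixel classifier for the droplet channel.

    Parameters
    ----------
    feature_config
        :class:`FeatureConfig`; ``None`` means defaults.
    n_estimators
        Trees in the forest.
    max_features
        Features considered per split (``"sqrt"`` of the feature count by
        default).
    max_samples_per_class
        Upper bound on labelled pixels drawn per class per image at fit
        time (keeps training tractable on full-frame label masks).
    random_state
        Seed controlling both the subsampling and the forest; training is
        bit-reproducible given this seed.
    """

    def __init__(
        self,
        feature_config: FeatureConfig | None = None,
        n_estimators: int = 200,
        max_features: str | int = "sqrt",
        max_samples_per_class: int = 4000,
        random_state: int = 0,
    ):
        self.feature_config = feature_config
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.max_samples_per_class = max_samples_per_class
        self.random_state = random_state

    def _config(self) -> FeatureConfig:
        return self.feature_config or FeatureConfig()

    def fit(self, planes, label_masks):
        """Fit on labelled pixels of one or more planes.

        ``planes`` is a 2-D array or a list of them; ``label_masks`` the
        matching integer masks with 0 = unlabelled, 1 = background,
        2 = droplet (a boolean mask is taken as droplet-vs-background with
        every pixel labelled).
        """
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if isinstance(planes, np.ndarray) and planes.ndim == 2:
            planes = [planes]
            label_masks = [label_masks]
        config = self._config()
        rng = np.random.default_rng(self.random_state)
        xs, ys = [], []
        for plane, labels in zip(planes, label_masks):
            labels = np.asarray(labels)
            if labels.dtype == bool:
                labels = np.where(labels, 2, 1)
            stack, names = compute_features(plane, config)
            flat = stack.reshape(stack.shape[0], -1).T
            for cls in (1, 2):
                idx = np.nonzero(labels.ravel() == cls)[0]
                if idx.size > self.max_samples_per_class:
                    idx = np.sort(
                        rng.choice(idx, self.max_samples_per_class, replace=False)
                    )
                xs.append(flat[idx])
                ys.append(np.full(idx.size, cls))
        X = np.concatenate(xs)
        y = np.concatenate(ys)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels must contain both classes")
        self.feature_names_ = names
        self.classes_ = np.array([1, 2])
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=int(self.random_state),
            n_jobs=1,
        ).fit(X, y)
        return self

    def predict(self, plane: np.ndarray) -> np.ndarray:
        """Per-pixel class map (1 = background, 2 = droplet) by forest majority vote."""
        stack, names = compute_features(np.asarray(plane), self._config())
        if names != self.feature_names_:
            raise ValueError("feature configuration differs from the one used at fit time")
        flat = stack.reshape(stack.shape[0], -1).T
        return self.forest_.predict(flat).reshape(plane.shape)

    def predict_mask(self, plane: np.ndarray) -> np.ndarray:
        """Boolean droplet mask."""
        return self.predict(plane) == 2

    # ---- persistence -----------------------------------------------------

    def save(self, model_dir: str | os.PathLike) -> None:
        """Write ``model.json`` (config + metadata) and the forest payload."""
        os.makedirs(model_dir, exist_ok=True)
        meta = {
            "feature_config": self._config().to_dict(),
            "feature_names": self.feature_names_,
            "classes": {"background": 1, "ld": 2},
            "n_estimators": self.n_estimators,
            "max_features": self.max_features,
            "max_samples_per_class": self.max_samples_per_class,
            "random_state": self.random_state,
        }
        with open(os.path.join(model_dir, MODEL_JSON), "w") as fh:
            json.dump(meta, fh, indent=2)
        joblib.dump(self.forest_, os.path.join(model_dir, MODEL_FOREST))

    @classmethod
    def load(cls, model_dir: str | os.PathLike) -> "LDPixelClassifier":
        with open(os.path.join(model_dir, MODEL_JSON)) as fh:
            meta = json.load(fh)
        est = cls(
            feature_config=FeatureConfig.from_dict(meta["feature_config"]),
            n_estimators=meta["n_estimators"],
            max_features=meta["max_features"],
            max_samples_per_class=meta["max_samples_per_class"],
            random_state=meta["random_state"],
        )
        est.feature_names_ = meta["feature_names"]
        est.classes_ = np.array([1, 2])
        est.forest_ = joblib.load(os.path.join(model_dir, MODEL_FOREST))
        return est


def train(stacks, config=None, n_trees: int = 200, seed: int = 0) -> LDPixelClassifier:
    """Functional wrapper: fit a classifier on ``[(plane, label_mask), ...]``."""
    planes = [p for p, _ in stacks]
    labels = [m for _, m in stacks]
    est = LDPixelClassifier(
        feature_config=config, n_estimators=n_trees, random_state=seed
    )
    return est.fit(planes, labels)


def predict_ld_mask(plane: np.ndarray, model: LDPixelClassifier) -> np.ndarray:
    """Functional wrapper over :meth:`LDPixelClassifier.predict_mask`."""
    return model.predict_mask(plane)
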