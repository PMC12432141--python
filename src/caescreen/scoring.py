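"""Image reproduction error (IRE) and the adaptive decision threshold.

The IRE of an image is the 99.99th percentile of its per-pixel squared
reconstruction errors. Using a high percentile instead of the mean keeps the
score sensitive to small artifacts: a compact bright structure moves the far
tail of the error distribution long before it moves the average.

The dataset threshold adapts the 1.5-IQR outlier rule to a population that
may contain many outliers: it uses the lower half-spread q50 - q25 (which
artifacts above the median cannot inflate) and doubles the usual 1.5
multiplier to 3 in compensation:

    threshold = q50 + 3 * (q50 - q25)

An image is called artifact-laden when its IRE lies strictly above the
threshold. All percentiles/quantiles use linear interpolation between order
statistics at rank (n - 1) * q, the convention of mainstream numerics
libraries; the 99.99th percentile of a 500x500 image is sensitive to this
choice, so it is fixed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Percentile of the squared pixel errors used as the per-image score.
IRE_PERCENTILE = 99.99
#: Multiplier on the lower half-spread in the threshold rule.
THRESHOLD_MULTIPLIER = 3.0


def image_reproduction_error(input_img: np.ndarray, output_img: np.ndarray,
                             percentile: float = IRE_PERCENTILE) -> float:
    """The high-percentile squared reconstruction error of one image."""
    inp = np.asarray(input_img, dtype=np.float64)
    out = np.asarray(output_img, dtype=np.float64)
    if inp.shape != out.shape:
        raise ValidationError(
            f"input and output shapes differ: {inp.shape} vs {out.shape}"
        )
    if np.isnan(inp).any() or np.isnan(out).any():
        raise ValidationError("NaN values in input or output image")
    err = (inp - out) ** 2
    return float(np.percentile(err.ravel(), percentile))


def score_images(model, images: np.ndarray, image_ids=None,
                 percentile: float = IRE_PERCENTILE) -> pd.DataFrame:
    """IRE of each image under a trained autoencoder.

    Returns a DataFrame with columns ``image_id`` and ``ire``.
    """
    arr = np.asarray(images)
    if arr.ndim == 2:
        arr = arr[None]
    if image_ids is None:
        image_ids = list(range(len(arr)))
    if len(image_ids) != len(arr):
        raise ValidationError("image_ids length does not match number of images")
    recon = model.reconstruct(arr.astype(np.float32))
    ires = [image_reproduction_error(x, o, percentile) for x, o in zip(arr, recon)]
    return pd.DataFrame({"image_id": image_ids, "ire": ires})


@dataclass(frozen=True)
class DatasetThreshold:
    threshold: float
    q25: float
    q50: float


def dataset_threshold(ires, multiplier: float = THRESHOLD_MULTIPLIER) -> DatasetThreshold:
    """Adaptive per-dataset threshold q50 + multiplier * (q50 - q25).

    Computed over the IREs of all images of a dataset, clean and laden
    together; robust as long as fewer than half the images carry artifacts.
    """
    arr = np.asarray(ires, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 4:
        raise ValidationError(
            f"need at least 4 IRE values for stable quantiles, got {arr.size}"
        )
    if np.isnan(arr).any():
        raise ValidationError("NaN IRE values")
    q25, q50 = np.percentile(arr, [25.0, 50.0])
    return DatasetThreshold(threshold=float(q50 + multiplier * (q50 - q25)),
                            q25=float(q25), q50=float(q50))


def classify(ires, threshold: float) -> np.ndarray:
    """Label each score: strictly above the threshold -> ``artifact``."""
    arr = np.asarray(ires, dtype=np.float64)
    if not np.isfinite(threshold):
        raise ValidationError(f"threshold must be finite, got {threshold}")
    return np.where(arr > threshold, "artifact", "clean")
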