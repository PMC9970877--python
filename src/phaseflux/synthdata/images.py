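"""Synthetic microscopy image fixtures.

Small integer-valued 2-D images for exercising nucleus segmentation (a
bright blob in a mother-cell mask, optionally with sub-threshold decoy
specks) and flat-field correction (frames under a 2-D Gaussian illumination
field with a camera baseline).
"""

from __future__ import annotations

import numpy as np

__all__ = ["simulate_nuclear_images", "simulate_flatfield_frames"]


def _disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def simulate_nuclear_images(
    blob_spec,
    background_level=100.0,
    noise_sd=1.0,
    seed=0,
    shape=(64, 64),
    decoys=(),
):
    """Image with one nucleus-like blob plus optional decoy specks.

    Parameters
    ----------
    blob_spec : dict
        Keys ``center`` (row, col), ``radius`` (px) and ``contrast`` (added
        intensity above background).
    decoys : iterable of dict
        Same keys; intended to be smaller than the downstream size filter.

    Returns
    -------
    (image, mask) : uint16 image and boolean ground-truth nucleus mask.
    """
    rng = np.random.default_rng(seed)
    center = tuple(blob_spec["center"])
    radius = float(blob_spec["radius"])
    if (
        center[0] - radius < 0
        or center[1] - radius < 0
        or center[0] + radius >= shape[0]
        or center[1] + radius >= shape[1]
    ):
        raise ValueError("blob does not fit within the image")
    img = np.full(shape, float(background_level))
    mask = _disk_mask(shape, center, radius)
    img[mask] += float(blob_spec["contrast"])
    for d in decoys:
        img[_disk_mask(shape, tuple(d["center"]), float(d["radius"]))] += float(d["contrast"])
    img += rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return img, mask


def simulate_flatfield_frames(
    gaussian_params,
    n_frames,
    seed=0,
    shape=(64, 64),
    baseline=500.0,
    noise_sd=0.0,
    scene=None,
):
    """Frame stack under Gaussian illumination: ``G * scene + baseline + noise``.

    ``gaussian_params`` is a dict with ``amp``, ``center`` (row, col) and
    ``sigma`` (scalar or (sy, sx)); an infinite/None sigma yields a uniform
    field (correction then reduces to baseline subtraction).
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    amp = float(gaussian_params.get("amp", 1000.0))
    cy, cx = gaussian_params.get("center", (ny / 2, nx / 2))
    sigma = gaussian_params.get("sigma", None)
    if sigma is None or np.isinf(np.max(sigma)):
        field = np.full(shape, amp)
    else:
        sy, sx = (sigma, sigma) if np.isscalar(sigma) else sigma
        field = amp * np.exp(-((yy - cy) ** 2 / (2 * sy**2) + (xx - cx) ** 2 / (2 * sx**2)))
    scene = np.ones(shape) if scene is None else np.asarray(scene, float)
    stack = np.empty((n_frames, ny, nx))
    for i in range(n_frames):
        stack[i] = field * scene + baseline + rng.normal(0.0, noise_sd, size=shape)
    return stack
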