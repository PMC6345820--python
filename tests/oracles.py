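"""Brute-force reference implementations used only as test oracles.

Each function recomputes a primitive by direct enumeration, independent of
the package's implementation path.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def brute_median(values: np.ndarray, window) -> np.ndarray:
    """Per-element sorted-window median with edge replication."""
    values = np.asarray(values, dtype=np.float64)
    if np.isscalar(window):
        window = (int(window),) * values.ndim
    half = [w // 2 for w in window]
    padded = np.pad(values, [(h, h) for h in half], mode="edge")
    out = np.empty_like(values)
    for idx in np.ndindex(values.shape):
        sl = tuple(
            slice(idx[a], idx[a] + window[a]) for a in range(values.ndim)
        )
        out[idx] = np.sort(padded[sl].ravel())[padded[sl].size // 2]
    return out


def brute_otsu_criterion(values: np.ndarray, n_bins: int = 256):
    """Between-class variance at every histogram split point, by direct
    summation. Returns ``(bin_centers, criterion)`` where ``criterion[i]``
    scores the split 'low class = bins 0..i' (-inf for empty classes)."""
    flat = np.asarray(values, dtype=np.float64).ravel()
    hist, edges = np.histogram(flat, bins=n_bins, range=(flat.min(), flat.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = hist.sum()
    crit = np.full(n_bins - 1, -np.inf)
    for split in range(n_bins - 1):        # low class = bins 0..split
        w0 = hist[: split + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: split + 1] * centers[: split + 1]).sum() / w0
        mu1 = (hist[split + 1 :] * centers[split + 1 :]).sum() / w1
        crit[split] = w0 * w1 * (mu0 - mu1) ** 2
    return centers, crit


def _neighbor_offsets(ndim: int, connectivity: int):
    offsets = []
    for off in product((-1, 0, 1), repeat=ndim):
        if all(o == 0 for o in off):
            continue
        manhattan = sum(abs(o) for o in off)
        if ndim == 2:
            if connectivity == 4 and manhattan > 1:
                continue
        else:
            if connectivity == 6 and manhattan > 1:
                continue
            if connectivity == 18 and manhattan > 2:
                continue
        offsets.append(off)
    return offsets


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """BFS connected-component labelling in raster-scan first-encounter
    order; labels match the package's declared ordering contract exactly."""
    mask = np.asarray(mask, dtype=bool)
    offsets = _neighbor_offsets(mask.ndim, connectivity)
    labels = np.zeros(mask.shape, dtype=np.int32)
    next_label = 0
    for start in np.ndindex(mask.shape):
        if not mask[start] or labels[start]:
            continue
        next_label += 1
        queue = deque([start])
        labels[start] = next_label
        while queue:
            cur = queue.popleft()
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(n < 0 or n >= s for n, s in zip(nb, mask.shape)):
                    continue
                if mask[nb] and not labels[nb]:
                    labels[nb] = next_label
                    queue.append(nb)
    return labels


def brute_histogram_assign(volumes, edges) -> np.ndarray:
    """Per-volume bin index for equal-width bins; rightmost edge inclusive."""
    idx = []
    n = len(edges) - 1
    for v in volumes:
        assigned = n - 1
        for b in range(n):
            hi_ok = v <= edges[b + 1] if b == n - 1 else v < edges[b + 1]
            if edges[b] <= v and hi_ok:
                assigned = b
                break
        idx.append(assigned)
    return np.array(idx)
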