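"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the library's own code paths: plain loops and
exhaustive searches, kept small enough to stay fast on fixture-sized
inputs.
"""
import numpy as np

from erythroquant.segment import ball_structuring_element


def ball_opening_oracle(img, radius):
    """Grayscale opening with the exact ball height kernel, by loops."""
    h, fp = ball_structuring_element(radius)
    r = (fp.shape[0] - 1) // 2
    pad = np.pad(img, r, mode="edge")
    offs = [(i - r, j - r) for i in range(fp.shape[0])
            for j in range(fp.shape[1]) if fp[i, j]]
    ero = np.empty_like(img, dtype=float)
    for a in range(img.shape[0]):
        for b in range(img.shape[1]):
            ero[a, b] = min(pad[a + r + di, b + r + dj] - h[di + r, dj + r]
                            for di, dj in offs)
    pe = np.pad(ero, r, mode="edge")
    dil = np.empty_like(ero)
    for a in range(img.shape[0]):
        for b in range(img.shape[1]):
            dil[a, b] = max(pe[a + r + di, b + r + dj] + h[di + r, dj + r]
                            for di, dj in offs)
    return np.minimum(dil, img)


def otsu_oracle(img):
    """Exhaustive between-class-variance search over all distinct values."""
    values = np.unique(img)
    best_t, best_v = None, -1.0
    n = img.size
    for t in values[:-1]:
        lo = img[img <= t]
        hi = img[img > t]
        w0, w1 = lo.size / n, hi.size / n
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def nearest_lumen_distance(lumen_mask, points):
    """Exhaustive nearest-lumen-pixel distances for (row, col) points."""
    lum = np.argwhere(lumen_mask)
    out = np.empty(len(points))
    for k, (r, c) in enumerate(points):
        out[k] = np.min(np.hypot(lum[:, 0] - r, lum[:, 1] - c))
    return out
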