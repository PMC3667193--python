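"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately written as plain Python loops over pixels
and candidate values, sharing no code path with the package.
"""

from collections import deque

import numpy as np


def project_oracle(frames: np.ndarray, method: str) -> np.ndarray:
    """Per-pixel stack reduction via explicit sorting/integer arithmetic.

    Mean and even-count median round half up using exact integer formulas.
    """
    n = frames.shape[0]
    out = np.zeros(frames.shape[1:], dtype=np.int64)
    flat = frames.reshape(n, -1)
    for j in range(flat.shape[1]):
        vals = sorted(int(v) for v in flat[:, j])
        if method == "min":
            r = vals[0]
        elif method == "max":
            r = vals[-1]
        elif method == "mean":
            s = sum(vals)
            r = (2 * s + n) // (2 * n)
        elif method == "median":
            if n % 2 == 1:
                r = vals[n // 2]
            else:
                a, b = vals[n // 2 - 1], vals[n // 2]
                r = (a + b + 1) // 2
        else:
            raise ValueError(method)
        out.reshape(-1)[j] = r
    return out.astype(frames.dtype)


def otsu_oracle(image: np.ndarray, n_levels: int = 256) -> int:
    """Exhaustive search over all thresholds for the max between-class
    variance; ties broken by the middle of the optimal plateau."""
    pixels = [int(v) for v in np.asarray(image).ravel()]
    total = len(pixels)
    best = -1.0
    plateau = []
    for t in range(n_levels):
        low = [p for p in pixels if p <= t]
        high = [p for p in pixels if p > t]
        if not low or not high:
            continue
        w0, w1 = len(low) / total, len(high) / total
        mu0 = sum(low) / len(low)
        mu1 = sum(high) / len(high)
        var = w0 * w1 * (mu0 - mu1) ** 2 * total  # scale-free for comparison
        if var > best + 1e-12:
            best = var
            plateau = [t]
        elif abs(var - best) <= 1e-12:
            plateau.append(t)
    if not plateau:
        raise ValueError("constant image")
    return plateau[len(plateau) // 2]


def flood_fill_components(mask: np.ndarray, connectivity: int):
    """BFS connected-component labelling; returns (labels, count)."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    count = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and labels[r, c] == 0:
                count += 1
                queue = deque([(r, c)])
                labels[r, c] = count
                while queue:
                    cr, cc = queue.popleft()
                    for dr, dc in nbrs:
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols:
                            if mask[nr, nc] and labels[nr, nc] == 0:
                                labels[nr, nc] = count
                                queue.append((nr, nc))
    return labels, count


def exhaustive_shift_search(reference: np.ndarray, frame: np.ndarray, radius: int):
    """Best integer translation of ``frame`` onto ``reference`` by trying
    every circular shift within ``±radius`` and scoring the correlation of
    the mean-subtracted images."""
    ref = reference.astype(float) - reference.mean()
    frm = frame.astype(float) - frame.mean()
    best_score, best_shift = -np.inf, (0, 0)
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            score = float(np.sum(ref * np.roll(frm, (dr, dc), axis=(0, 1))))
            if score > best_score:
                best_score, best_shift = score, (dr, dc)
    return best_shift
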