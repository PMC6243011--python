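"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (per-voxel scans, heapq flooding) and
shares no code with the package's optimized paths.
"""

import heapq
from typing import List, Tuple

import numpy as np


def scan_runs(mask: np.ndarray, offset=(0, 0, 0)) -> List[Tuple[int, int, int, int]]:
    """Per-voxel scan RLE: maximal x-runs sorted by (z, y, x_start)."""
    ox, oy, oz = offset
    runs = []
    Z, Y, X = mask.shape
    for z in range(Z):
        for y in range(Y):
            x = 0
            while x < X:
                if mask[z, y, x]:
                    start = x
                    while x < X and mask[z, y, x]:
                        x += 1
                    runs.append((z + oz, y + oy, start + ox, x - start))
                else:
                    x += 1
    return runs


def or_pool(mask: np.ndarray, levels: int) -> np.ndarray:
    """Dense OR-pooling downsample by 2**levels per axis (pad to multiple)."""
    f = 2**levels
    Z, Y, X = mask.shape
    pad = [(0, (-s) % f) for s in mask.shape]
    m = np.pad(mask, pad)
    z, y, x = (s // f for s in m.shape)
    return m.reshape(z, f, y, f, x, f).any(axis=(1, 3, 5))


def scan_block_cover(mask: np.ndarray, offset, edge: int):
    ox, oy, oz = offset
    cover = set()
    for z, y, x in zip(*np.nonzero(mask)):
        cover.add(((z + oz) // edge, (y + oy) // edge, (x + ox) // edge))
    return sorted(cover)


def scan_surface(mask: np.ndarray):
    """Foreground voxels with a background 6-neighbor, by explicit checks."""
    Z, Y, X = mask.shape
    out = set()
    for z, y, x in zip(*np.nonzero(mask)):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            if not (0 <= nz < Z and 0 <= ny < Y and 0 <= nx < X) or not mask[nz, ny, nx]:
                out.add((int(z), int(y), int(x)))
                break
    return out


def naive_priority_flood(
    grayscale: np.ndarray,
    mask: np.ndarray,
    seeds,
    *,
    invert_intensity: bool = True,
) -> np.ndarray:
    """Heap-based seeded flood: pop lowest (priority, enqueue counter).

    ``seeds`` is an iterable of ((z, y, x), label) in enqueue order. Priority
    is 255 − intensity (ascending); ties break FIFO; 6-connectivity.
    """
    g = np.asarray(grayscale, dtype=np.int64)
    m = np.asarray(mask).astype(bool)
    pr = (255 - g) if invert_intensity else g
    out = np.zeros(m.shape, dtype=np.int32)
    heap = []
    counter = 0
    for (z, y, x), label in seeds:
        if m[z, y, x]:
            heapq.heappush(heap, (int(pr[z, y, x]), counter, (z, y, x), label))
            counter += 1
    Z, Y, X = m.shape
    while heap:
        _, _, (z, y, x), label = heapq.heappop(heap)
        if out[z, y, x]:
            continue
        out[z, y, x] = label
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nz, ny, nx = z + dz, y + dy, x + dx
            if 0 <= nz < Z and 0 <= ny < Y and 0 <= nx < X and m[nz, ny, nx] and not out[nz, ny, nx]:
                heapq.heappush(heap, (int(pr[nz, ny, nx]), counter, (nz, ny, nx), label))
                counter += 1
    return out


def random_flood_case(rng: np.random.Generator, max_edge: int = 12):
    """One random (grayscale, mask, seeds) instance for oracle comparison."""
    shape = tuple(int(v) for v in rng.integers(2, max_edge + 1, size=3))
    gray = rng.integers(0, 256, size=shape).astype(np.uint8)
    mask = rng.random(shape) < rng.uniform(0.4, 0.95)
    n_seeds = int(rng.integers(2, 6))
    seeds = []
    fg = np.argwhere(mask)
    if len(fg) == 0:
        mask[tuple(v // 2 for v in shape)] = True
        fg = np.argwhere(mask)
    for i in range(n_seeds):
        z, y, x = fg[rng.integers(len(fg))]
        seeds.append(((int(z), int(y), int(x)), int(rng.integers(1, 4))))
    return gray, mask, seeds
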