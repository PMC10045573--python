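import heapq
from itertools import product

import numpy as np
import pytest

from cootseg import CrfParams, ProbabilityPair, crf_energy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def dijkstra_oracle(values: np.ndarray, seeds, connectivity: int = 8) -> np.ndarray:
    """Independent hand-coded binary-heap Dijkstra over the explicit pixel
    graph with |intensity difference| edge costs."""
    h, w = values.shape
    if connectivity == 4:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    dist = np.full((h, w), np.inf)
    heap = []
    for s in seeds:
        dist[tuple(s)] = 0.0
        heapq.heappush(heap, (0.0, tuple(s)))
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in offs:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w:
                nd = d + abs(values[r, c] - values[nr, nc])
                if nd < dist[nr, nc]:
                    dist[nr, nc] = nd
                    heapq.heappush(heap, (nd, (nr, nc)))
    return dist


def exhaustive_crf_minimum(R: ProbabilityPair, img: np.ndarray, params: CrfParams):
    """Enumerate all labelings of a tiny grid and return (min energy, argmin)."""
    shape = img.shape
    n = int(np.prod(shape))
    best, best_y = np.inf, None
    for bits in product([0, 1], repeat=n):
        y = np.array(bits, dtype=np.uint8).reshape(shape)
        e = crf_energy(y, R, img, None, params)
        if e < best:
            best, best_y = e, y
    return best, best_y
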