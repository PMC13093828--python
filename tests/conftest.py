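import numpy as np
import pytest

from stressreg import synthetic_data as sd


@pytest.fixture(scope="session")
def default_locus():
    """BTN1-like synthetic convergent locus plus its truth record."""
    return sd.make_locus(sd.LocusSpec(seed=11))


@pytest.fixture(scope="session")
def locus_model(default_locus):
    return default_locus[0].locus_model()


# ---- independent oracles (deliberately naive implementations) ----------------

def brute_force_uorfs(seq: str, window: int):
    """Character-by-character upstream ATG scan, independent of the package.

    Returns {start_pos: [stop positions]} for ATGs with the A in
    [-window, -3], scanning indices left to right.
    """
    length = len(seq)
    found = {}
    for i in range(length):
        pos = i - length  # c. coordinate of this base
        if pos < -window or pos > -3:
            continue
        if seq[i : i + 3] == "ATG":
            stops = []
            j = i + 3
            while j + 3 <= length:
                if seq[j : j + 3] in ("TAA", "TAG", "TGA"):
                    stops.append(j - length)
                j += 3
            found[pos] = stops
    return found


def enumerate_hypergeom_tail(n_pop: int, n_annot: int, n_draw: int, k: int) -> float:
    """P(overlap >= k) by direct summation of the hypergeometric pmf."""
    from math import comb

    total = comb(n_pop, n_draw)
    return sum(
        comb(n_annot, j) * comb(n_pop - n_annot, n_draw - j)
        for j in range(k, min(n_annot, n_draw) + 1)
    ) / total


def exhaustive_kmeans_inertia(points: np.ndarray, k: int = 2) -> float:
    """Minimum within-cluster sum of squares over all k-partitions."""
    n = len(points)
    assert k == 2 and n <= 12
    best = np.inf
    for mask in range(1, 2**n - 1):
        bits = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        inertia = 0.0
        for sel in (bits, ~bits):
            grp = points[sel]
            inertia += ((grp - grp.mean(axis=0)) ** 2).sum()
        best = min(best, inertia)
    return float(best)


# frozen reference: Bioconductor edgeR 4.0.16 calcNormFactors() on this matrix
TMM_TOY_COUNTS = np.array(
    [
        [90, 180, 2700], [398, 796, 398], [344, 688, 344], [247, 494, 247],
        [244, 488, 244], [436, 872, 436], [88, 176, 88], [363, 726, 363],
        [140, 280, 140], [92, 184, 92], [286, 572, 286], [489, 978, 489],
        [381, 762, 381], [392, 784, 392], [372, 744, 372], [403, 806, 403],
        [280, 560, 280], [107, 214, 107], [427, 854, 427], [252, 504, 252],
    ],
    dtype=float,
)
TMM_TOY_FACTORS = np.array([1.131228364925, 1.131228364925, 0.781446818609])
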