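"""Independent brute-force oracles.

Each oracle re-derives the quantity from its definition with the plainest
possible code (python loops, pairwise distances, exhaustive enumeration) so
the production implementations are checked against a second, unshared path.
"""

import itertools
import math

import numpy as np


def isodata_bruteforce(counts):
    """Smallest split where the intermeans update does not move upward."""
    counts = [float(c) for c in counts]
    nz = [i for i, c in enumerate(counts) if c > 0]
    lo, hi = nz[0], nz[-1]
    for s in range(lo, hi):
        below = [(i, c) for i, c in enumerate(counts[: s + 1]) if c > 0]
        above = [(i, c) for i, c in enumerate(counts) if i > s and c > 0]
        if not below or not above:
            continue
        mu_b = sum(i * c for i, c in below) / sum(c for _, c in below)
        mu_a = sum(i * c for i, c in above) / sum(c for _, c in above)
        if math.floor((mu_b + mu_a) / 2.0 + 0.5) <= s:
            return s
    raise AssertionError("no isodata crossing")


def _entropy(weights):
    total = sum(weights)
    h = 0.0
    for w in weights:
        if w > 0:
            p = w / total
            h -= p * math.log(p)
    return h


def kapur_bruteforce(counts):
    """Exhaustive maximum of the two-class entropy sum; smallest tie wins."""
    counts = [float(c) for c in counts]
    best_h, best_s = -np.inf, None
    nz = [i for i, c in enumerate(counts) if c > 0]
    for s in range(nz[0], nz[-1]):
        below = counts[: s + 1]
        above = counts[s + 1:]
        if sum(below) == 0 or sum(above) == 0:
            continue
        h = _entropy(below) + _entropy(above)
        if h > best_h + 1e-10:
            best_h, best_s = h, s
    return best_s


def local_thickness_bruteforce(mask, voxel_size):
    """Maximal-inscribed-sphere local thickness by pairwise search.

    R(p) = distance from object voxel p to the nearest background voxel
    centre; lt(q) = 2 * max{R(p) : |q - p| <= R(p)}.  O(n^2); use on small
    instances only.
    """
    mask = np.asarray(mask, dtype=bool)
    vs = np.asarray(voxel_size, dtype=float)
    if vs.size == 1:
        vs = np.repeat(vs, 3)
    # crop to the bounding box: the nearest background voxel of any object
    # voxel lies within the box plus one-voxel pad
    w = np.argwhere(mask)
    lo = w.min(axis=0)
    hi = w.max(axis=0) + 1
    full_shape = mask.shape
    mask = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    padded = np.pad(mask, 1, constant_values=False)
    obj = np.argwhere(padded).astype(float)
    bg = np.argwhere(~padded).astype(float)
    obj_um = obj * vs
    bg_um = bg * vs
    # radius of the inscribed sphere centred at each object voxel
    radii = np.empty(len(obj))
    for k, p in enumerate(obj_um):
        radii[k] = np.sqrt(((bg_um - p) ** 2).sum(axis=1)).min()
    lt = np.zeros(len(obj))
    for k, q in enumerate(obj_um):
        d = np.sqrt(((obj_um - q) ** 2).sum(axis=1))
        lt[k] = 2.0 * radii[d <= radii + 1e-9].max()
    out_sub = np.zeros(padded.shape)
    idx = obj.astype(int)
    out_sub[idx[:, 0], idx[:, 1], idx[:, 2]] = lt
    out = np.zeros(full_shape)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = out_sub[1:-1, 1:-1, 1:-1]
    return out


def global_test_p_exact(X, y, statistic):
    """Exact permutation p-value by enumerating all label assignments."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = int(y.sum())
    q_obs = statistic(X, y)
    count = total = 0
    for ones in itertools.combinations(range(n), k):
        yy = np.zeros(n)
        yy[list(ones)] = 1.0
        total += 1
        if statistic(X, yy) >= q_obs - 1e-12:
            count += 1
    return count / total


def random_histogram(rng, n_bins=None):
    """A random mixture histogram resembling intensity data."""
    n_bins = n_bins or rng.integers(16, 200)
    counts = np.zeros(int(n_bins))
    for _ in range(rng.integers(1, 4)):
        mu = rng.uniform(0, n_bins)
        sd = rng.uniform(0.5, n_bins / 4)
        mass = rng.integers(50, 5000)
        samples = np.clip(np.round(rng.normal(mu, sd, mass)), 0, n_bins - 1)
        counts += np.bincount(samples.astype(int), minlength=int(n_bins))
    if np.count_nonzero(counts) < 2:  # ensure a valid histogram
        counts[0] += 1
        counts[-1] += 1
    return counts


def make_segmentation(labels, voxel_size=(21.0, 21.0, 21.0),
                      lower=80.0, upper=200.0):
    """Wrap a synthetic label grid as a TissueSegmentation for unit tests."""
    from fishct.segmentation import ThresholdPair, TissueSegmentation

    labels = np.asarray(labels, dtype=np.uint8)
    return TissueSegmentation(
        labels=labels,
        thresholds=ThresholdPair(lower, upper, slice_index=labels.shape[0] // 2),
        body_mask=labels > 0,
        voxel_size=tuple(voxel_size),
    )
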