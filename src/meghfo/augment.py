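"""Virtual sample generation: ADASYN plus the balanced-data three-bin scheme.

ADASYN (adaptive synthetic sampling) oversamples a minority class by linear
interpolation between a minority point and one of its minority k-nearest
neighbors, allocating more synthetic points to minority samples whose
combined-set neighborhoods contain many majority points (the "hard" ones).

For a *balanced* gold standard the imbalance is manufactured deliberately:
each class is split into ``bins`` (default 3) random bins; one bin of the
target class together with all samples of the other class forms a temporary
imbalanced set on which ADASYN synthesizes the target class. Bins rotate and
the procedure repeats until the requested number of virtual samples exists,
split equally between the classes. Virtual samples carry the provenance tag
``"virtual"`` and are never used for evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import HFO, NC, SegmentDataset


@dataclass
class AugmentConfig:
    """Knobs for :func:`balanced_augment`.

    factor : virtual count = ``factor * len(dataset)`` (factor 1 doubles the
             training set; factor 0 is a no-op).
    k_neighbors : ADASYN neighborhood size (Euclidean).
    bins : number of bins the manufactured-imbalance scheme splits each
           class into.
    imbalance_threshold : maximum tolerated minority/majority ratio for
           standalone ADASYN use; the check is bypassed inside
           :func:`balanced_augment` because the imbalance there is
           constructed on purpose.
    """

    factor: float = 1.0
    k_neighbors: int = 5
    bins: int = 3
    imbalance_threshold: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 0:
            raise ValueError("factor must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if not (0 < self.imbalance_threshold <= 1):
            raise ValueError("imbalance_threshold must be in (0, 1]")


@dataclass
class VirtualSampleBatch:
    """Synthetic samples with full interpolation provenance.

    Every row of ``samples`` equals ``minority[i] + lam * (minority[z] -
    minority[i])`` for the recorded ``(i, z)`` parent pair and ``lam`` in
    [0, 1].
    """

    samples: np.ndarray
    label: int
    parent_indices: list[tuple[int, int]]
    lambdas: np.ndarray

    def __len__(self) -> int:
        return self.samples.shape[0]


def _knn_indices(X: np.ndarray, query: np.ndarray, k: int, exclude: int | None = None):
    """Indices of the k nearest rows of X to `query` (Euclidean).

    Ties are broken by lowest index (stable argsort on distances).
    """
    d = np.sqrt(np.sum((X - query) ** 2, axis=1))
    if exclude is not None:
        d[exclude] = np.inf
    order = np.argsort(d, kind="stable")
    return order[:k]


def adasyn_generate(
    minority: np.ndarray,
    majority: np.ndarray,
    k_neighbors: int = 5,
    n_synthetic: int = 0,
    seed: int | np.random.Generator = 0,
    label: int = HFO,
) -> VirtualSampleBatch:
    """Core ADASYN: density-weighted interpolation within the minority class.

    Per minority sample i the hardness weight ``r_i`` is the fraction of
    majority points among its ``k`` nearest neighbors in the combined set;
    normalized weights ``r_hat`` allocate per-sample quotas ``g_i =
    round(r_hat_i * n_synthetic)``, adjusted (truncate / top up, sampling
    parents proportionally to ``r_hat``) so the total is exactly
    ``n_synthetic``. Each synthetic point is ``x_i + lam * (x_z - x_i)`` with
    ``lam ~ U[0, 1]`` and ``x_z`` a random minority k-nearest neighbor of
    ``x_i``.
    """
    minority = np.atleast_2d(np.asarray(minority, dtype=float))
    majority = np.atleast_2d(np.asarray(majority, dtype=float))
    m = minority.shape[0]
    if m < 2:
        raise ValueError("ADASYN needs at least 2 minority samples")
    if k_neighbors >= m + majority.shape[0]:
        raise ValueError("k_neighbors must be smaller than the combined set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_synthetic == 0:
        return VirtualSampleBatch(
            np.empty((0, minority.shape[1])), label, [], np.empty(0)
        )

    combined = np.vstack([minority, majority])
    is_majority = np.concatenate(
        [np.zeros(m, dtype=bool), np.ones(majority.shape[0], dtype=bool)]
    )
    r = np.empty(m)
    for i in range(m):
        nn = _knn_indices(combined, minority[i], k_neighbors, exclude=i)
        r[i] = is_majority[nn].mean()
    if r.sum() == 0:
        warnings.warn(
            "no majority points among any minority neighborhood; "
            "falling back to uniform weights",
            stacklevel=2,
        )
        r_hat = np.full(m, 1.0 / m)
    else:
        r_hat = r / r.sum()

    g = np.round(r_hat * n_synthetic).astype(int)
    # enforce the exact total
    while g.sum() > n_synthetic:
        candidates = np.flatnonzero(g > 0)
        g[rng.choice(candidates, p=r_hat[candidates] / r_hat[candidates].sum())] -= 1
    while g.sum() < n_synthetic:
        g[rng.choice(m, p=r_hat)] += 1

    # minority-only neighbor table for interpolation partners
    k_min = min(k_neighbors, m - 1)
    partners = np.empty((m, k_min), dtype=int)
    for i in range(m):
        partners[i] = _knn_indices(minority, minority[i], k_min, exclude=i)

    rows, parents, lams = [], [], []
    for i in range(m):
        for _ in range(g[i]):
            z = int(partners[i, rng.integers(0, k_min)])
            lam = float(rng.uniform(0.0, 1.0))
            rows.append(minority[i] + lam * (minority[z] - minority[i]))
            parents.append((i, z))
            lams.append(lam)
    return VirtualSampleBatch(np.asarray(rows), label, parents, np.asarray(lams))


def balanced_augment(dataset: SegmentDataset, cfg: AugmentConfig) -> SegmentDataset:
    """Grow a balanced dataset with ``factor * n`` virtual samples.

    Implements the manufactured three-bin imbalance described in the module
    docstring; output = original samples (bit-identical, provenance
    preserved) followed by the virtual samples tagged ``"virtual"``.
    """
    if cfg.factor == 0:
        return dataset
    n_total = len(dataset)
    n_virtual = int(round(cfg.factor * n_total))
    quota = {HFO: n_virtual - n_virtual // 2, NC: n_virtual // 2}
    rng = np.random.default_rng(cfg.seed)

    idx_by_class = {c: np.flatnonzero(dataset.y == c) for c in (HFO, NC)}
    for c, idx in idx_by_class.items():
        if idx.size < cfg.bins:
            raise ValueError(
                f"class {c} has {idx.size} samples; cannot form {cfg.bins} bins"
            )
        if idx.size < 2 * cfg.bins and quota[c] > 0:
            # each bin needs >= 2 samples for interpolation
            raise ValueError(
                f"class {c} too small ({idx.size}) for {cfg.bins}-bin augmentation"
            )

    virtual_X, virtual_y = [], []
    for c in (HFO, NC):
        remaining = quota[c]
        if remaining == 0:
            continue
        own = idx_by_class[c]
        other = idx_by_class[HFO if c == NC else NC]
        perm = rng.permutation(own)
        bins = np.array_split(perm, cfg.bins)
        majority_X = dataset.X[other]
        rotation = 0
        while remaining > 0:
            bin_idx = bins[rotation % cfg.bins]
            if rotation % cfg.bins == 0:
                per_rotation = int(np.ceil(remaining / cfg.bins))
            chunk = min(per_rotation, remaining)
            minority_X = dataset.X[bin_idx]
            k = min(cfg.k_neighbors, minority_X.shape[0] - 1)
            batch = adasyn_generate(minority_X, majority_X, k, chunk, rng, label=c)
            virtual_X.append(batch.samples)
            virtual_y.append(np.full(len(batch), c, dtype=int))
            remaining -= chunk
            rotation += 1

    VX = np.vstack(virtual_X) if virtual_X else np.empty((0, dataset.segment_length))
    Vy = np.concatenate(virtual_y) if virtual_y else np.empty(0, dtype=int)
    virtual = SegmentDataset(
        VX,
        Vy,
        dataset.fs,
        source=["virtual"] * len(Vy),
        channel_id=[""] * len(Vy),
        start_time=np.zeros(len(Vy)),
    )
    return SegmentDataset.concat([dataset, virtual])
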