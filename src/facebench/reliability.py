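"""Split-half reliability and noise-corrected i1n correlation.

Image-level behavioral patterns from two observer pools are compared by a
split-half procedure: each pool's trials are randomly partitioned into two
halves (stratified by image), i1n is computed per half, and the raw
cross-pool correlation is normalized by a noise ceiling derived from each
pool's own split-half (internal) consistency:

    r_nc = mean[ r(Va0, Vb1), r(Va1, Vb0) ] / ceiling

where Va0/Va1 are pool a's half i1n vectors and the default ceiling is the
geometric mean sqrt(r(Va0,Va1) * r(Vb0,Vb1)).  An alternative
``printed_sum`` ceiling sqrt(r_a + r_b) is available for exact-formula
replication; both are reported.  Averaging over many partitions reduces
the variance of the estimate.

Implementation note: for a 2AFC table, everything i1n depends on reduces
to per-image presentation/correct counts, and a uniformly random
stratified half-split induces exactly a hypergeometric draw of per-half
correct counts.  The partition loop therefore runs on count arrays
(vectorized over images) rather than re-slicing trial tables; this is
distributionally identical to splitting the table and recomputing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .metrics import clip_rate

DENOMINATOR_MODES = ("geometric_mean", "printed_sum")


def split_trials(trials: pd.DataFrame, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random stratified half-split of a trial table.

    Each image's trials are shuffled and assigned alternately, so the two
    halves differ by at most one trial per image and their multiset union
    reproduces the input exactly.
    """
    n = len(trials)
    if n < 2:
        raise ValueError("need at least 2 trials to split")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    codes, uniques = pd.factorize(trials["image_id"], sort=True)
    perm = rng.permutation(n)
    codes_p = codes[perm]
    order = np.argsort(codes_p, kind="stable")  # random order within image
    sorted_rows = perm[order]
    sorted_codes = codes_p[order]
    starts = np.r_[0, 1 + np.flatnonzero(np.diff(sorted_codes))]
    group_start = np.repeat(starts, np.diff(np.r_[starts, n]))
    ranks = np.arange(n) - group_start
    flip = rng.integers(0, 2, size=len(uniques))
    half_id = (ranks + flip[sorted_codes]) % 2
    h0 = trials.iloc[sorted_rows[half_id == 0]].reset_index(drop=True)
    h1 = trials.iloc[sorted_rows[half_id == 1]].reset_index(drop=True)
    return h0, h1


@dataclass
class SplitHalfCorrelation:
    """All components of the noise-corrected split-half correlation."""

    r_cross: float
    r_internal_a: float
    r_internal_b: float
    ceiling: float
    r_nc: float
    n_partitions: int
    denominator_mode: str
    n_images: int
    n_dropped_images: int = 0
    per_partition: pd.DataFrame | None = None
    seed: int | None = None

    def to_dict(self, include_partitions: bool = True) -> dict:
        out = {
            "r_cross": self.r_cross,
            "r_internal_a": self.r_internal_a,
            "r_internal_b": self.r_internal_b,
            "ceiling": self.ceiling,
            "r_nc": self.r_nc,
            "n_partitions": self.n_partitions,
            "denominator_mode": self.denominator_mode,
            "n_images": self.n_images,
            "n_dropped_images": self.n_dropped_images,
            "seed": self.seed,
        }
        if include_partitions and self.per_partition is not None:
            out["per_partition"] = {
                c: list(self.per_partition[c]) for c in self.per_partition.columns
            }
        return out


def _count_reduction(trials: pd.DataFrame):
    """Per-image (category, n, k) arrays, images sorted by id."""
    correct = (trials["true_category"] == trials["response_category"]).astype(int)
    g = (
        pd.DataFrame(
            {
                "image_id": trials["image_id"].to_numpy(),
                "category": trials["true_category"].to_numpy(),
                "correct": correct.to_numpy(),
            }
        )
        .groupby("image_id", sort=True)
        .agg(category=("category", "first"), n=("correct", "size"), k=("correct", "sum"))
    )
    return g


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _half_dprime(n_half, k_half, cats, categories):
    hr = clip_rate(k_half, np.maximum(n_half, 1))
    z_fa = np.full(len(n_half), np.nan)
    for c in categories:
        other = cats != c
        denom = n_half[other].sum()
        if denom == 0:
            continue
        fa = float(clip_rate((n_half[other] - k_half[other]).sum(), denom))
        z_fa[cats == c] = norm.ppf(fa)
    return norm.ppf(hr) - z_fa


def _center_by_category(v, cats, categories):
    out = v.copy()
    for c in categories:
        m = cats == c
        out[m] = v[m] - v[m].mean()
    return out


def _partition_halves(counts: pd.DataFrame, rng: np.random.Generator):
    """One stratified split at the count level: hypergeometric per image."""
    n = counts["n"].to_numpy(dtype=np.int64)
    k = counts["k"].to_numpy(dtype=np.int64)
    m0 = n // 2 + (n % 2) * rng.integers(0, 2, size=len(n))
    k0 = rng.hypergeometric(np.maximum(k, 0), n - k, np.maximum(m0, 0)) if len(n) else m0
    k0 = np.where(m0 == 0, 0, k0)
    return (m0, k0), (n - m0, k - k0)


def noise_corrected_correlation(
    trials_a: pd.DataFrame,
    trials_b: pd.DataFrame,
    n_partitions: int = 100,
    seed: int = 0,
    denominator_mode: str = "geometric_mean",
) -> SplitHalfCorrelation:
    """Noise-corrected correlation between two pools' i1n vectors.

    Both tables are reduced to the image set they share (a warning is
    issued if either scores extra images).  Per partition, each pool is
    split in half, i1n is computed per half (normalized within the shared
    image set), and the cross and internal correlations are recorded; the
    components are averaged over partitions before the ceiling is applied.
    Images unscorable in any half of either pool in a given partition are
    dropped pairwise for that partition.
    """
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(f"denominator_mode must be one of {DENOMINATOR_MODES}")
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    ca = _count_reduction(trials_a)
    cb = _count_reduction(trials_b)
    common = ca.index.intersection(cb.index)
    if len(common) < len(ca.index) or len(common) < len(cb.index):
        warnings.warn(
            f"image sets differ; restricting to {len(common)} shared images",
            stacklevel=2,
        )
    if len(common) < 3:
        raise ValueError("need at least 3 shared images")
    ca = ca.loc[common]
    cb = cb.loc[common]
    cats = ca["category"].to_numpy()
    categories = sorted(set(cats))
    dropped = 0

    rows = []
    for child in np.random.SeedSequence(seed).spawn(n_partitions):
        # the same child seeds both pools' splits, so byte-identical inputs
        # produce byte-identical halves (and r_nc = 1 exactly)
        rng_a = np.random.default_rng(child)
        rng_b = np.random.default_rng(child)
        (na0, ka0), (na1, ka1) = _partition_halves(ca, rng_a)
        (nb0, kb0), (nb1, kb1) = _partition_halves(cb, rng_b)
        ok = (na0 > 0) & (na1 > 0) & (nb0 > 0) & (nb1 > 0)
        dropped += int((~ok).sum())
        if ok.sum() < 3:
            rows.append((np.nan, np.nan, np.nan))
            continue
        c_ok = cats[ok]
        halves = []
        for n_h, k_h in ((na0, ka0), (na1, ka1), (nb0, kb0), (nb1, kb1)):
            d = _half_dprime(n_h[ok], k_h[ok], c_ok, categories)
            halves.append(_center_by_category(d, c_ok, categories))
        va0, va1, vb0, vb1 = halves
        r_cross = 0.5 * (_corr(va0, vb1) + _corr(va1, vb0))
        rows.append((r_cross, _corr(va0, va1), _corr(vb0, vb1)))

    per_part = pd.DataFrame(rows, columns=["r_cross", "r_internal_a", "r_internal_b"])
    r_cross = float(np.nanmean(per_part["r_cross"]))
    ra = float(np.nanmean(per_part["r_internal_a"]))
    rb = float(np.nanmean(per_part["r_internal_b"]))
    if denominator_mode == "geometric_mean":
        ceiling = float(np.sqrt(ra * rb)) if (ra > 0 and rb > 0) else float("nan")
    else:
        ceiling = float(np.sqrt(ra + rb)) if (ra + rb) > 0 else float("nan")
    if np.isnan(ceiling) or ceiling <= 0:
        warnings.warn("non-positive noise ceiling; r_nc undefined", stacklevel=2)
        r_nc = float("nan")
    else:
        r_nc = r_cross / ceiling
    return SplitHalfCorrelation(
        r_cross=r_cross,
        r_internal_a=ra,
        r_internal_b=rb,
        ceiling=ceiling,
        r_nc=r_nc,
        n_partitions=n_partitions,
        denominator_mode=denominator_mode,
        n_images=int(len(common)),
        n_dropped_images=dropped,
        per_partition=per_part,
        seed=seed,
    )


def internal_consistency(
    trials: pd.DataFrame, n_partitions: int = 100, seed: int = 0
) -> float:
    """Mean within-pool split-half correlation of i1n.

    Returns NaN when the correlation is undefined in every partition
    (e.g. a single trial per image everywhere).
    """
    counts = _count_reduction(trials)
    cats = counts["category"].to_numpy()
    categories = sorted(set(cats))
    rs = []
    for child in np.random.SeedSequence(seed).spawn(n_partitions):
        rng = np.random.default_rng(child)
        (n0, k0), (n1, k1) = _partition_halves(counts, rng)
        ok = (n0 > 0) & (n1 > 0)
        if ok.sum() < 3:
            rs.append(np.nan)
            continue
        c_ok = cats[ok]
        v0 = _center_by_category(_half_dprime(n0[ok], k0[ok], c_ok, categories), c_ok, categories)
        v1 = _center_by_category(_half_dprime(n1[ok], k1[ok], c_ok, categories), c_ok, categories)
        rs.append(_corr(v0, v1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(rs))
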