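"""Condition-wise performance and bootstrap effect sizes.

The canonical viewing conditions are defined on the stimulus metadata:

* ``upright``  — upright faces lit from above (normal viewing),
* ``inverted`` — inverted faces lit from below (the light source is still
  overhead in world coordinates),
* ``contrast_reversed`` — upright faces with reversed contrast polarity,

each comprising 25 non-token images per category under the default
stimulus set.  An effect (e.g. the inversion effect) is the difference of
the average per-image d' between two conditions; its uncertainty is
estimated by repeatedly subsampling images within each condition (by
default 25 of the 50, without replacement) and taking percentile bounds of
the resampled differences.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

from .metrics import clip_rate, dprime_per_image, normalize_i1, tabulate_counts


@dataclass(frozen=True)
class ConditionSpec:
    """A filter over stimulus metadata (None matches anything).

    Token images are never part of a condition.
    """

    orientation: str | None
    lighting: str | None
    label: str

    def match(self, stim_table: pd.DataFrame) -> np.ndarray:
        mask = ~stim_table["is_token"].to_numpy()
        if self.orientation is not None:
            mask &= (stim_table["orientation"] == self.orientation).to_numpy()
        if self.lighting is not None:
            mask &= (stim_table["lighting"] == self.lighting).to_numpy()
        return mask


UPRIGHT = ConditionSpec("upright", "above", "upright")
INVERTED = ConditionSpec("inverted", "below", "inverted")
CONTRAST_REVERSED = ConditionSpec("upright", "reversed", "contrast_reversed")
CANONICAL_CONDITIONS = {c.label: c for c in (UPRIGHT, INVERTED, CONTRAST_REVERSED)}


@dataclass
class ConditionDprime:
    label: str
    mean_dprime: float
    i1: pd.DataFrame
    n_trials: int
    n_images: int


def _stim_table(stimuli) -> pd.DataFrame:
    return stimuli.table if hasattr(stimuli, "table") else stimuli


def condition_dprime(trials: pd.DataFrame, spec: ConditionSpec, stimuli) -> ConditionDprime:
    """Mean and per-image d' within one condition.

    Trials are subset to the condition's images and d' is computed within
    that subset, so the false-alarm pools are restricted to condition
    trials; i1n normalization is likewise recomputed within the subset.
    """
    table = _stim_table(stimuli)
    mask = spec.match(table)
    images = set(table.loc[mask, "image_id"])
    cats_present = set(table.loc[mask, "category"])
    if not images or len(cats_present) < 2:
        raise ValueError(f"condition {spec.label!r} matches no image pair of categories")
    sub = trials[trials["image_id"].isin(images)]
    if len(sub) == 0:
        raise ValueError(f"no trials fall in condition {spec.label!r}")
    i1 = normalize_i1(dprime_per_image(tabulate_counts(sub)))
    scored = i1[i1["scorable"]]
    return ConditionDprime(
        label=spec.label,
        mean_dprime=float(scored["dprime"].mean()),
        i1=i1,
        n_trials=int(len(sub)),
        n_images=int(len(i1)),
    )


@dataclass
class EffectEstimate:
    """Bootstrap estimate of a condition contrast delta d' = mean_b - mean_a."""

    label_a: str
    label_b: str
    delta_dprime: float
    ci_low: float
    ci_high: float
    boot_samples: np.ndarray
    n_boot: int
    subsample_k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "delta_dprime": float(self.delta_dprime),
            "ci": [float(self.ci_low), float(self.ci_high)],
            "n_boot": self.n_boot,
            "subsample_k": self.subsample_k,
            "seed": self.seed,
        }


def _condition_rng(seed: int, label: str) -> np.random.Generator:
    # seed the subsample stream by (seed, label) so that swapping the two
    # conditions mirrors the pairing exactly (antisymmetry of the effect)
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def _subsample_indices(m: int, k: int, n_boot: int,
                       rng: np.random.Generator, with_replacement: bool) -> np.ndarray:
    if with_replacement:
        return rng.integers(0, m, size=(n_boot, k))
    keys = rng.random((n_boot, m))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def _draw_valid_subsamples(cats: np.ndarray, k: int, n_boot: int,
                           rng: np.random.Generator,
                           with_replacement: bool) -> np.ndarray:
    """Image subsamples that contain both categories (d' needs an FA pool).

    Single-category draws — possible for small conditions — are redrawn
    from the same stream, i.e. the bootstrap is conditioned on a scorable
    subsample.
    """
    if k < 2:
        raise ValueError("subsample_k must be >= 2 (both categories needed)")
    m = len(cats)
    idx = _subsample_indices(m, k, n_boot, rng, with_replacement)
    for _ in range(200):
        c = cats[idx]
        bad = np.flatnonzero((c == c[:, :1]).all(axis=1))
        if len(bad) == 0:
            return idx
        idx[bad] = _subsample_indices(m, k, len(bad), rng, with_replacement)
    raise ValueError(
        "could not draw image subsamples containing both categories; "
        "condition too small or single-category"
    )


def _subsample_mean_dprime(i1_counts: pd.DataFrame, idx: np.ndarray) -> np.ndarray:
    """Mean d' of each image subsample, with FA pools recomputed per draw.

    ``i1_counts`` needs columns category, n_presented, n_correct, z_hr
    (hit-rate quantile, fixed per image); the false-alarm pool of each
    category is re-tallied from the other-category images actually drawn,
    so the bootstrap propagates the shared-FA component of the estimator.
    """
    cats = pd.factorize(i1_counts["category"], sort=True)[0]
    n = i1_counts["n_presented"].to_numpy(dtype=float)
    wrong = n - i1_counts["n_correct"].to_numpy(dtype=float)
    z_hr = i1_counts["z_hr"].to_numpy()

    cat_sel = cats[idx]                      # (n_boot, k)
    is1 = cat_sel == 1
    cnt1 = is1.sum(axis=1)
    cnt0 = idx.shape[1] - cnt1
    n_sel = n[idx]
    wrong_sel = wrong[idx]
    # false alarms for category c come from the drawn other-category images
    denom0 = np.where(is1, n_sel, 0.0).sum(axis=1)
    fa_k0 = np.where(is1, wrong_sel, 0.0).sum(axis=1)
    denom1 = np.where(is1, 0.0, n_sel).sum(axis=1)
    fa_k1 = np.where(is1, 0.0, wrong_sel).sum(axis=1)
    z_fa0 = norm.ppf(clip_rate(fa_k0, denom0))
    z_fa1 = norm.ppf(clip_rate(fa_k1, denom1))
    mean_zhr = z_hr[idx].mean(axis=1)
    mean_zfa = (cnt0 * z_fa0 + cnt1 * z_fa1) / idx.shape[1]
    return mean_zhr - mean_zfa


def effect_size(
    trials: pd.DataFrame,
    stimuli,
    cond_a: ConditionSpec,
    cond_b: ConditionSpec,
    n_boot: int = 1000,
    subsample_k: int = 25,
    seed: int = 0,
    with_replacement: bool = False,
) -> EffectEstimate:
    """Image-subsampling bootstrap of the d' difference between conditions.

    Each bootstrap replicate draws ``subsample_k`` images (without
    replacement by default) from each condition, recomputes the average d'
    over the drawn images — hit rates are per image, false-alarm pools are
    re-tallied from the drawn images of the other category — and records
    the difference (condition B minus condition A).  The 95% CI is the
    (2.5, 97.5) percentile interval of the replicates.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    res_a = condition_dprime(trials, cond_a, stimuli)
    res_b = condition_dprime(trials, cond_b, stimuli)
    boots = {}
    for spec, res in ((cond_a, res_a), (cond_b, res_b)):
        i1 = res.i1[res.i1["scorable"]].reset_index(drop=True)
        if subsample_k > len(i1):
            raise ValueError(
                f"subsample_k={subsample_k} exceeds the {len(i1)} scorable "
                f"images of condition {spec.label!r}"
            )
        counts = i1.assign(z_hr=norm.ppf(i1["hit_rate"]))
        idx = _draw_valid_subsamples(
            pd.factorize(i1["category"], sort=True)[0], subsample_k, n_boot,
            _condition_rng(seed, spec.label), with_replacement,
        )
        boots[spec.label] = _subsample_mean_dprime(counts, idx)
    boot = boots[cond_b.label] - boots[cond_a.label]
    lo, hi = np.percentile(boot, [2.5, 97.5]) if n_boot > 1 else (boot[0], boot[0])
    return EffectEstimate(
        label_a=cond_a.label,
        label_b=cond_b.label,
        delta_dprime=float(res_b.mean_dprime - res_a.mean_dprime),
        ci_low=float(lo),
        ci_high=float(hi),
        boot_samples=boot,
        n_boot=n_boot,
        subsample_k=subsample_k,
        seed=seed,
    )


@dataclass
class EffectComparison:
    statistic: float
    p_value: float
    method: str


def compare_effects(
    eff_1: EffectEstimate, eff_2: EffectEstimate, method: str = "percentile_diff"
) -> EffectComparison:
    """Two-sided comparison of two bootstrap effect estimates.

    ``percentile_diff`` forms the bootstrap distribution of the difference
    of the two deltas (pairing replicates by index) and reports the
    two-sided sign-crossing p-value; the statistic is the difference of
    the point estimates.  ``welch_boot`` runs a Welch two-sample t-test
    over the replicate arrays — note that bootstrap replicates are not
    independent observations, so this emulates, rather than reproduces,
    a conventional t-test (a warning records the caveat).
    """
    for eff in (eff_1, eff_2):
        b = getattr(eff, "boot_samples", None)
        if b is None or len(b) == 0:
            raise ValueError("effect estimate carries no bootstrap samples")
    if method == "welch_boot":
        warnings.warn(
            "welch_boot treats bootstrap replicates as independent samples; "
            "interpret the t statistic as descriptive",
            stacklevel=2,
        )
        t, p = stats.ttest_ind(eff_1.boot_samples, eff_2.boot_samples, equal_var=False)
        return EffectComparison(float(t), float(p), method)
    if method == "percentile_diff":
        n = min(len(eff_1.boot_samples), len(eff_2.boot_samples))
        d = eff_1.boot_samples[:n] - eff_2.boot_samples[:n]
        p_low = float(np.mean(d <= 0))
        p_high = float(np.mean(d >= 0))
        p = min(1.0, 2.0 * min(p_low, p_high))
        return EffectComparison(float(eff_1.delta_dprime - eff_2.delta_dprime), p, method)
    raise ValueError(f"unknown method {method!r}")
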