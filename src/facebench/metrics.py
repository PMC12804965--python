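"""Per-image signal-detection metrics for 2AFC trial tables.

The central quantity is the per-image sensitivity

    d'_j = z(HR_j) - z(FA_j)

where z is the standard-normal quantile function, HR_j is the hit rate of
image j (trials showing j answered with j's category) and FA_j is the
false-alarm rate of j's *category*: the proportion of trials showing the
other category that were answered with j's category.  The false-alarm pool
is therefore shared across all images of a category, so within-category
differences in the i1 vector are driven by hit rates alone.

The vector of d'_j over the stimulus set is called i1; subtracting each
category's mean d' gives the normalized i1n, which removes any overall
difficulty offset between the two categories before image-level patterns
are compared across observer pools.

Lapse rate — the error floor from non-perceptual failures — is estimated
by cross-validation: find the best-performing image in a random half of
the trials and measure its error rate in the held-out half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

LAPSE_MODELS = ("always_wrong", "guess")


@dataclass
class ImageCounts:
    """Exact integer tallies backing the d' computation.

    ``per_image`` is indexed by image_id with columns ``category``,
    ``n_presented``, ``n_correct``; ``per_category`` is indexed by category
    with columns ``n_other`` (false-alarm denominator: trials of the other
    category) and ``n_fa`` (those answered with this category).
    """

    per_image: pd.DataFrame
    per_category: pd.DataFrame
    n_trials: int


def tabulate_counts(trials: pd.DataFrame, categories=None) -> ImageCounts:
    """Tally presentations, hits, and false alarms from a trial table."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    true_cat = trials["true_category"].to_numpy()
    resp_cat = trials["response_category"].to_numpy()
    if categories is None:
        categories = sorted(set(true_cat) | set(resp_cat))
    else:
        categories = sorted(categories)
    if len(categories) > 2:
        # blame the rows carrying the least-frequent label(s)
        labels, freq = np.unique(np.concatenate([true_cat, resp_cat]), return_counts=True)
        majority = set(labels[np.argsort(freq)][-2:])
        bad = ~(np.isin(true_cat, list(majority)) & np.isin(resp_cat, list(majority)))
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"more than two category labels {categories}; "
            f"first offending row index {row}"
        )
    bad = ~(np.isin(true_cat, categories) & np.isin(resp_cat, categories))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"unknown category label on row index {row} "
            f"(expected one of {categories})"
        )

    correct = true_cat == resp_cat
    per_image = (
        pd.DataFrame(
            {
                "image_id": trials["image_id"].to_numpy(),
                "category": true_cat,
                "correct": correct.astype(int),
            }
        )
        .groupby("image_id", sort=True)
        .agg(category=("category", "first"), n_presented=("correct", "size"),
             n_correct=("correct", "sum"))
    )
    rows = {}
    for c in categories:
        other = true_cat != c
        rows[c] = {
            "n_other": int(other.sum()),
            "n_fa": int((other & (resp_cat == c)).sum()),
        }
    per_category = pd.DataFrame.from_dict(rows, orient="index")
    per_category.index.name = "category"
    return ImageCounts(per_image, per_category, int(len(trials)))


def clip_rate(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Empirical rate k/n with 0 -> 1/(2n) and 1 -> 1 - 1/(2n).

    The half-count convention keeps z(rate) finite and monotone in the
    counts; it activates only at rates of exactly 0 or 1.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    rate = k / n
    rate = np.where(rate == 0.0, 1.0 / (2.0 * n), rate)
    rate = np.where(rate == 1.0, 1.0 - 1.0 / (2.0 * n), rate)
    return rate


def dprime_per_image(counts: ImageCounts, clip=clip_rate) -> pd.DataFrame:
    """Per-image d' (the i1 vector) from tallied counts.

    Returns a frame with columns ``image_id, category, n_presented,
    hit_rate, false_alarm_rate, dprime, scorable``.  Images whose category
    has a zero false-alarm denominator are flagged ``scorable=False`` with
    NaN d' rather than silently dropped.
    """
    pi = counts.per_image
    pc = counts.per_category
    hr = clip(pi["n_correct"].to_numpy(), pi["n_presented"].to_numpy())

    fa_rate = {}
    scorable_cat = {}
    for c, row in pc.iterrows():
        if row["n_other"] == 0:
            fa_rate[c] = np.nan
            scorable_cat[c] = False
        else:
            fa_rate[c] = float(clip(row["n_fa"], row["n_other"]))
            scorable_cat[c] = True
    cats = pi["category"].to_numpy()
    fa = np.array([fa_rate.get(c, np.nan) for c in cats])
    scorable = np.array([scorable_cat.get(c, False) for c in cats])

    with np.errstate(invalid="ignore"):
        dprime = norm.ppf(hr) - norm.ppf(fa)
    return pd.DataFrame(
        {
            "image_id": pi.index.to_numpy(),
            "category": cats,
            "n_presented": pi["n_presented"].to_numpy(),
            "n_correct": pi["n_correct"].to_numpy(),
            "hit_rate": hr,
            "false_alarm_rate": fa,
            "dprime": np.where(scorable, dprime, np.nan),
            "scorable": scorable,
        }
    ).reset_index(drop=True)


def normalize_i1(i1: pd.DataFrame) -> pd.DataFrame:
    """Subtract each category's mean d' over scored images (i1 -> i1n)."""
    out = i1.copy()
    scored = out[out["scorable"]]
    for c in out["category"].unique():
        if (scored["category"] == c).sum() == 0:
            raise ValueError(f"category {c!r} has no scorable images")
    means = scored.groupby("category")["dprime"].mean()
    out["i1n"] = out["dprime"] - out["category"].map(means)
    return out


@dataclass
class LapseEstimate:
    """Cross-validated best-image error floor."""

    lapse: float
    best_image_ids: list
    n_heldout_trials: list
    correction_model: str = "always_wrong"
    n_partitions: int = 0
    per_partition_error: list = field(default_factory=list)


def estimate_lapse(
    trials: pd.DataFrame,
    n_partitions: int = 50,
    seed: int = 0,
    correction_model: str = "always_wrong",
    max_retries: int = 10,
) -> LapseEstimate:
    """Estimate the lapse rate from cross-validated best-image performance.

    For each of ``n_partitions`` random stratified half-splits, the image
    with the highest accuracy in one half (ties broken by larger trial
    count, then lexicographically smaller id) is evaluated in the other
    half; both directions are used.  The lapse rate is the mean held-out
    error rate over all partition-directions.
    """
    from .reliability import split_trials

    if correction_model not in LAPSE_MODELS:
        raise ValueError(f"unknown correction model {correction_model!r}")
    per_img_total = trials.groupby("image_id").size()
    if per_img_total.max() < 2:
        raise ValueError("need at least one image with >= 2 trials")

    ss = np.random.SeedSequence(seed)
    errors, best_ids, n_heldout = [], [], []
    for child in ss.spawn(n_partitions):
        for sub in child.spawn(max_retries + 1):
            h0, h1 = split_trials(trials, seed=int(sub.generate_state(1)[0] % (2**31)))
            ok = True
            pair_results = []
            for sel, held in ((h0, h1), (h1, h0)):
                stats = (
                    sel.assign(correct=sel["true_category"] == sel["response_category"])
                    .groupby("image_id")["correct"]
                    .agg(["mean", "size"])
                )
                # best accuracy, then most trials, then lexicographic id
                stats = stats.sort_values(
                    by=["mean", "size"], ascending=[False, False], kind="stable"
                )
                top = stats[
                    (stats["mean"] == stats["mean"].iloc[0])
                    & (stats["size"] == stats["size"].iloc[0])
                ]
                best = min(top.index)
                held_best = held[held["image_id"] == best]
                if len(held_best) == 0:
                    ok = False
                    break
                err = float(
                    (held_best["true_category"] != held_best["response_category"]).mean()
                )
                pair_results.append((best, err, len(held_best)))
            if ok:
                for best, err, n in pair_results:
                    errors.append(err)
                    best_ids.append(best)
                    n_heldout.append(n)
                break
        else:
            raise RuntimeError(
                "best image repeatedly absent from held-out half; "
                "not enough trials per image"
            )
    return LapseEstimate(
        lapse=float(np.mean(errors)),
        best_image_ids=best_ids,
        n_heldout_trials=n_heldout,
        correction_model=correction_model,
        n_partitions=n_partitions,
        per_partition_error=errors,
    )


def lapse_corrected_accuracy(p_obs: float, lapse: float, model: str = "always_wrong") -> float:
    """Correct an observed proportion correct for the measured lapse rate.

    ``always_wrong`` assumes every lapse trial is scored incorrect, so the
    measured best-image error floor is the lapse rate itself and
    p_corr = p_obs / (1 - lapse).  ``guess`` assumes lapse trials are
    coin flips, so the floor is half the true lapse rate; with
    lam* = 2*lapse, p_corr = (p_obs - lam*/2) / (1 - lam*).  Results are
    clamped to [0, 1].
    """
    if not 0 <= p_obs <= 1:
        raise ValueError(f"p_obs must be in [0, 1], got {p_obs}")
    if model == "always_wrong":
        if lapse >= 1:
            raise ValueError("lapse must be < 1")
        p = p_obs / (1.0 - lapse)
    elif model == "guess":
        lam = 2.0 * lapse
        if lam >= 1:
            raise ValueError("effective lapse 2*lapse must be < 1")
        p = (p_obs - lam / 2.0) / (1.0 - lam)
    else:
        raise ValueError(f"unknown correction model {model!r}")
    return float(min(1.0, max(0.0, p)))


@dataclass
class PooledPerformance:
    """Pooled accuracy with a trial bootstrap."""

    accuracy: float          # lapse-corrected if a lapse was supplied
    accuracy_raw: float
    boot_mean: float
    boot_sd: float
    n_boot: int
    n_trials: int
    lapse: float | None = None
    lapse_model: str | None = None


def pooled_performance(
    trials: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    lapse: "LapseEstimate | float | None" = None,
    lapse_model: str = "always_wrong",
) -> PooledPerformance:
    """Overall proportion correct, with SD over trial-bootstrap resamples.

    Trials are resampled with replacement ``n_boot`` times; because the
    per-trial outcome is binary, the resampled accuracy is distributed as
    Binomial(n, p_hat)/n, which is drawn directly.  If a lapse estimate is
    supplied, the correction is applied to the point estimate and to every
    bootstrap replicate.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if isinstance(lapse, LapseEstimate):
        lam, model = lapse.lapse, lapse.correction_model
    elif lapse is None:
        lam, model = None, None
    else:
        lam, model = float(lapse), lapse_model

    correct = (trials["true_category"] == trials["response_category"]).to_numpy()
    n = len(correct)
    p_hat = float(correct.mean())
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    boot = rng.binomial(n, p_hat, size=n_boot) / n
    if lam is not None:
        acc = lapse_corrected_accuracy(p_hat, lam, model)
        boot = np.array([lapse_corrected_accuracy(b, lam, model) for b in boot])
    else:
        acc = p_hat
    return PooledPerformance(
        accuracy=acc,
        accuracy_raw=p_hat,
        boot_mean=float(boot.mean()),
        boot_sd=float(boot.std()),
        n_boot=n_boot,
        n_trials=n,
        lapse=lam,
        lapse_model=model,
    )


def i1_from_trials(trials: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
    """Convenience: trial table -> i1 (optionally i1n) in one call."""
    i1 = dprime_per_image(tabulate_counts(trials))
    return normalize_i1(i1) if normalize else i1
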