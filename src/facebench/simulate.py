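"""Synthetic stimuli, observer pools, and feature clouds.

This module generates everything the analysis pipeline consumes, with the
statistical structure the real experiment has:

* a stimulus set of two categories ("A" and "B", e.g. two face species),
  each rendered in 6 contexts — 2 in-plane orientations (upright/inverted)
  crossed with 3 lighting contexts (lit from above, lit from below,
  contrast reversed) — with latent rendering parameters (size in degrees of
  visual angle, horizontal and vertical rotation) drawn uniformly from
  their experimental ranges, plus one canonical "token" exemplar per
  category;
* observer pools with per-image latent difficulty, lapse rate, and response
  bias, optionally linked across pools by a configurable latent correlation
  and per-context difficulty shifts (to inject inversion / contrast-reversal
  deficits);
* two-class Gaussian feature clouds of configurable dimension and
  separability for the linear-readout stage.

Latent per-image difficulty is parameterized as a d' and mapped to a
probability correct via ``p_true = Phi(d'/2)`` (symmetric criterion), so
the downstream per-image d' estimator recovers the latent value in
expectation.  All generators take explicit seeds; there is no global
random state.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .decoder import FeatureSet

CATEGORIES = ("A", "B")
ORIENTATIONS = ("upright", "inverted")
LIGHTINGS = ("above", "below", "reversed")

SIZE_RANGE_DEG = (4.5, 9.0)
AZIMUTH_RANGE_DEG = (-90.0, 90.0)
ELEVATION_RANGE_DEG = (-45.0, 45.0)
N_BACKGROUNDS = 10
TOKEN_BACKGROUND = -1  # tokens are rendered without a background

STIMULUS_COLUMNS = [
    "image_id", "category", "orientation", "lighting",
    "size_deg", "azimuth_deg", "elevation_deg", "background_id", "is_token",
]

TRIAL_COLUMNS = [
    "subject_id", "pool_id", "image_id",
    "true_category", "response_category", "session",
]


@dataclass
class StimulusSet:
    """Image metadata table for one 2AFC task.

    ``table`` has exactly the columns in :data:`STIMULUS_COLUMNS` plus a
    derived ``lighting_congruent`` flag (the light source is overhead in
    world coordinates: upright+above or inverted+below).
    """

    table: pd.DataFrame
    n_per_context: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in STIMULUS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"stimulus table missing columns: {missing}")
        if "lighting_congruent" not in self.table.columns:
            t = self.table
            self.table = t.assign(
                lighting_congruent=(
                    ((t.orientation == "upright") & (t.lighting == "above"))
                    | ((t.orientation == "inverted") & (t.lighting == "below"))
                )
            )

    @property
    def image_ids(self) -> np.ndarray:
        return self.table["image_id"].to_numpy()

    @property
    def n_images(self) -> int:
        return len(self.table)

    def context_images(
        self,
        orientation: str | None = None,
        lighting: str | None = None,
        include_tokens: bool = False,
    ) -> pd.DataFrame:
        t = self.table
        mask = np.ones(len(t), dtype=bool)
        if orientation is not None:
            mask &= (t["orientation"] == orientation).to_numpy()
        if lighting is not None:
            mask &= (t["lighting"] == lighting).to_numpy()
        if not include_tokens:
            mask &= ~t["is_token"].to_numpy()
        return t[mask]

    def subset(self, image_ids) -> "StimulusSet":
        keep = self.table["image_id"].isin(set(image_ids))
        return StimulusSet(
            self.table[keep].reset_index(drop=True),
            self.n_per_context,
            dict(self.params),
        )

    def to_csv(self, path, sidecar: bool = True) -> None:
        from .io import write_csv_atomic

        path = Path(path)
        write_csv_atomic(self.table[STIMULUS_COLUMNS], path)
        if sidecar:
            meta = {"n_per_context": self.n_per_context, "params": self.params}
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path) -> "StimulusSet":
        path = Path(path)
        table = pd.read_csv(path, dtype={"image_id": str, "category": str})
        table["is_token"] = table["is_token"].astype(bool)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            return cls(table, int(meta["n_per_context"]), meta.get("params", {}))
        n_ctx = int((~table["is_token"]).sum() // (len(CATEGORIES) * 6)) if len(table) else 0
        return cls(table, n_ctx)


def generate_stimulus_set(n_per_context: int = 25, seed: int = 0) -> StimulusSet:
    """Generate the fully crossed stimulus metadata table.

    With the default ``n_per_context=25`` this yields 151 images per
    category (6 contexts x 25 images + 1 token), 302 in total.  Latent
    rendering parameters are i.i.d. uniform over their experimental ranges;
    tokens are frontal (azimuth = elevation = 0), upright, lit from above,
    at the maximum size, with no background.
    """
    n_per_context = int(n_per_context)
    if n_per_context < 0:
        raise ValueError(f"n_per_context must be >= 0, got {n_per_context}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for cat, orient, light in itertools.product(CATEGORIES, ORIENTATIONS, LIGHTINGS):
        for i in range(n_per_context):
            rows.append(
                {
                    "image_id": f"{cat}_{orient}_{light}_{i:03d}",
                    "category": cat,
                    "orientation": orient,
                    "lighting": light,
                    "size_deg": rng.uniform(*SIZE_RANGE_DEG),
                    "azimuth_deg": rng.uniform(*AZIMUTH_RANGE_DEG),
                    "elevation_deg": rng.uniform(*ELEVATION_RANGE_DEG),
                    "background_id": int(rng.integers(N_BACKGROUNDS)),
                    "is_token": False,
                }
            )
    for cat in CATEGORIES:
        rows.append(
            {
                "image_id": f"{cat}_token",
                "category": cat,
                "orientation": "upright",
                "lighting": "above",
                "size_deg": SIZE_RANGE_DEG[1],
                "azimuth_deg": 0.0,
                "elevation_deg": 0.0,
                "background_id": TOKEN_BACKGROUND,
                "is_token": True,
            }
        )
    table = pd.DataFrame(rows, columns=STIMULUS_COLUMNS)
    return StimulusSet(table, n_per_context, {"seed": int(seed)})


@dataclass
class ObserverModel:
    """Generative description of one observer pool.

    On each trial the observer lapses with probability ``lapse``; a lapse
    response is independent of the image.  Non-lapse trials are correct
    with probability ``p_true[image]``.  The lapse response distribution is
    parameterized jointly by ``lapse_guess_correct`` (probability a lapse
    trial is scored correct, category-averaged) and ``bias_A`` (overall
    probability a lapse response is category A):

        P(respond A | true A) = bias_A + lapse_guess_correct - 1/2
        P(respond A | true B) = bias_A - lapse_guess_correct + 1/2

    Defaults (0.5, 0.5) give unbiased coin-flip lapses;
    ``lapse_guess_correct=0`` gives an always-wrong lapse observer.
    Observed per-image accuracy equals
    ``(1 - lapse) * p_true + lapse * lapse_guess_correct``
    (exactly per image when ``bias_A=0.5``, category-averaged otherwise).
    """

    pool_id: str
    p_true: pd.Series
    lapse: float = 0.0
    lapse_guess_correct: float = 0.5
    bias_A: float = 0.5
    latent_dprime: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.p_true, pd.Series):
            self.p_true = pd.Series(self.p_true, dtype=float)
        p = self.p_true.to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p_true values must lie in [0, 1]")
        if not 0 <= self.lapse < 1:
            raise ValueError(f"lapse must be in [0, 1), got {self.lapse}")
        pa_a = self.bias_A + self.lapse_guess_correct - 0.5
        pa_b = self.bias_A - self.lapse_guess_correct + 0.5
        if not (0 <= pa_a <= 1 and 0 <= pa_b <= 1):
            raise ValueError(
                "incompatible bias_A / lapse_guess_correct: lapse response "
                f"probabilities ({pa_a:.3f}, {pa_b:.3f}) fall outside [0, 1]"
            )

    def lapse_response_prob_A(self, true_category: str) -> float:
        if true_category == "A":
            return self.bias_A + self.lapse_guess_correct - 0.5
        return self.bias_A - self.lapse_guess_correct + 0.5

    def expected_accuracy(self) -> float:
        """Expected pooled accuracy under uniform image presentation."""
        return float(
            (1 - self.lapse) * self.p_true.mean() + self.lapse * self.lapse_guess_correct
        )


def simulate_trials(
    observer: ObserverModel,
    stimuli: StimulusSet,
    n_trials: int | None = None,
    *,
    trials_per_image: int | None = None,
    weights: np.ndarray | None = None,
    seed: int = 0,
    subject_id: str | None = None,
    session: str = "s1",
) -> pd.DataFrame:
    """Simulate a 2AFC trial table.

    Either ``n_trials`` (images sampled uniformly with replacement, or by
    ``weights``) or ``trials_per_image`` (balanced design: exactly that many
    presentations of every image) must be given.
    """
    if (n_trials is None) == (trials_per_image is None):
        raise ValueError("give exactly one of n_trials or trials_per_image")
    ids = stimuli.table["image_id"].to_numpy()
    cats = stimuli.table["category"].to_numpy()
    missing = [i for i in ids if i not in observer.p_true.index]
    if missing:
        raise KeyError(f"observer has no p_true entry for image {missing[0]!r}")
    p = observer.p_true.loc[ids].to_numpy(dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if trials_per_image is not None:
        if trials_per_image < 1:
            raise ValueError("trials_per_image must be >= 1")
        idx = np.repeat(np.arange(len(ids)), int(trials_per_image))
    else:
        if n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            if len(w) != len(ids) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("weights must be nonnegative, one per image")
            w = w / w.sum()
        else:
            w = None
        idx = rng.choice(len(ids), size=int(n_trials), p=w)

    n = len(idx)
    true_cat = cats[idx]
    is_lapse = rng.random(n) < observer.lapse
    correct = rng.random(n) < p[idx]
    other = np.where(true_cat == "A", "B", "A")
    response = np.where(correct, true_cat, other)

    if is_lapse.any():
        pa = np.where(
            true_cat == "A",
            observer.lapse_response_prob_A("A"),
            observer.lapse_response_prob_A("B"),
        )
        lapse_resp = np.where(rng.random(n) < pa, "A", "B")
        response = np.where(is_lapse, lapse_resp, response)

    return pd.DataFrame(
        {
            "subject_id": subject_id or observer.pool_id,
            "pool_id": observer.pool_id,
            "image_id": ids[idx],
            "true_category": true_cat,
            "response_category": response,
            "session": session,
        },
        columns=TRIAL_COLUMNS,
    )


def make_context_shifts(
    inversion: float = 0.0,
    contrast_reversal: float = 0.0,
    lit_below: float = 0.0,
) -> dict:
    """Additive latent-d' shift per (orientation, lighting) context.

    The inversion shift applies to every inverted context, the reversal
    shift to every contrast-reversed context, the lit-below shift to every
    lit-from-below context; shifts combine additively so e.g. the
    (inverted, reversed) context receives both deficits.
    """
    shifts = {}
    for orient, light in itertools.product(ORIENTATIONS, LIGHTINGS):
        delta = 0.0
        if orient == "inverted":
            delta += inversion
        if light == "reversed":
            delta += contrast_reversal
        if light == "below":
            delta += lit_below
        shifts[(orient, light)] = delta
    return shifts


def _shift_vector(table: pd.DataFrame, shifts: dict | None) -> np.ndarray:
    if not shifts:
        return np.zeros(len(table))
    return np.array(
        [shifts.get((o, l), 0.0) for o, l in zip(table["orientation"], table["lighting"])]
    )


def make_observer(
    stimuli: StimulusSet,
    mean_dprime: float = 1.5,
    sd_dprime: float = 0.4,
    lapse: float = 0.0,
    context_shifts: dict | None = None,
    seed: int = 0,
    pool_id: str = "pool",
    lapse_guess_correct: float = 0.5,
    bias_A: float = 0.5,
) -> ObserverModel:
    """Draw a single observer pool with Gaussian latent per-image d'."""
    if sd_dprime < 0:
        raise ValueError("sd_dprime must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = stimuli.table
    latent = mean_dprime + sd_dprime * rng.standard_normal(len(t)) + _shift_vector(
        t, context_shifts
    )
    latent_s = pd.Series(latent, index=t["image_id"].to_numpy())
    return ObserverModel(
        pool_id=pool_id,
        p_true=pd.Series(norm.cdf(latent / 2.0), index=t["image_id"].to_numpy()),
        lapse=lapse,
        lapse_guess_correct=lapse_guess_correct,
        bias_A=bias_A,
        latent_dprime=latent_s,
    )


@dataclass
class LinkedObserverPair:
    """Two observer pools with correlated latent per-image difficulty."""

    observer_a: ObserverModel
    observer_b: ObserverModel
    latent: pd.DataFrame  # image_id, category, dprime_a, dprime_b
    realized_rho: float


def _as_pair(x) -> tuple[float, float]:
    if np.isscalar(x):
        return float(x), float(x)
    a, b = x
    return float(a), float(b)


def _center_by_category(v: np.ndarray, cats: np.ndarray) -> np.ndarray:
    out = v.astype(float).copy()
    for c in np.unique(cats):
        m = cats == c
        out[m] -= out[m].mean()
    return out


def _solve_base_rho(
    target: float, s_a: float, s_b: float,
    shift_a: np.ndarray, shift_b: np.ndarray, cats: np.ndarray,
) -> float:
    """Image-specific correlation needed for a target total correlation.

    Deterministic per-context shifts shared (in pattern) by the two pools
    already induce image-level correlation; the base bivariate-normal
    correlation is solved so that the category-centered final latent
    vectors correlate at ``target``.
    """
    ca = _center_by_category(shift_a, cats)
    cb = _center_by_category(shift_b, cats)
    v_a, v_b = float(np.mean(ca**2)), float(np.mean(cb**2))
    cov_shift = float(np.mean(ca * cb))
    if s_a <= 0 or s_b <= 0:
        raise ValueError("rho_is_total requires positive sd_dprime for both pools")
    need = target * np.sqrt((s_a**2 + v_a) * (s_b**2 + v_b)) - cov_shift
    base = need / (s_a * s_b)
    if not -1.0 <= base <= 1.0:
        raise ValueError(
            f"target correlation {target} infeasible with these shifts/spreads "
            f"(required base correlation {base:.3f})"
        )
    return float(base)


def make_linked_observers(
    stimuli: StimulusSet,
    rho: float,
    mean_dprime=1.5,
    sd_dprime=0.4,
    lapses=(0.0, 0.0),
    seed: int = 0,
    context_shifts=None,
    pool_ids=("pool_a", "pool_b"),
    lapse_guess_correct: float = 0.5,
    rho_is_total: bool = False,
) -> LinkedObserverPair:
    """Draw two observer pools whose latent d' vectors correlate at ``rho``.

    Per image, the pair of latent d' values is bivariate normal with
    correlation ``rho``; each is mapped to p_true via Phi(d'/2).
    ``mean_dprime`` / ``sd_dprime`` may be scalars or per-pool pairs, and
    ``context_shifts`` may be a single mapping (applied to both pools) or a
    pair of mappings; deterministic shifts are added after the correlated
    draw, so the reported ``realized_rho`` (Pearson correlation of the
    category-centered final latent vectors) includes any shared shift
    structure.  With ``rho_is_total=True``, ``rho`` is interpreted as the
    target correlation of those final vectors and the image-specific base
    correlation is solved to achieve it.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    m_a, m_b = _as_pair(mean_dprime)
    s_a, s_b = _as_pair(sd_dprime)
    if s_a < 0 or s_b < 0:
        raise ValueError("sd_dprime must be >= 0")
    lapse_a, lapse_b = _as_pair(lapses)
    if context_shifts is None or isinstance(context_shifts, dict):
        shifts_a = shifts_b = context_shifts
    else:
        shifts_a, shifts_b = context_shifts

    t = stimuli.table
    n = len(t)
    cats_arr = t["category"].to_numpy()
    if rho_is_total:
        rho = _solve_base_rho(
            rho, s_a, s_b,
            _shift_vector(t, shifts_a), _shift_vector(t, shifts_b), cats_arr,
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    # Cholesky-style construction: exact at rho = +/-1
    base_a = z1
    base_b = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2
    d_a = m_a + s_a * base_a + _shift_vector(t, shifts_a)
    d_b = m_b + s_b * base_b + _shift_vector(t, shifts_b)

    da_c = _center_by_category(d_a, cats_arr)
    db_c = _center_by_category(d_b, cats_arr)
    if np.std(da_c) > 0 and np.std(db_c) > 0:
        realized = float(np.corrcoef(da_c, db_c)[0, 1])
    else:
        realized = float("nan")

    ids = t["image_id"].to_numpy()
    obs = []
    for pool_id, d, lapse in ((pool_ids[0], d_a, lapse_a), (pool_ids[1], d_b, lapse_b)):
        obs.append(
            ObserverModel(
                pool_id=pool_id,
                p_true=pd.Series(norm.cdf(d / 2.0), index=ids),
                lapse=lapse,
                lapse_guess_correct=lapse_guess_correct,
                latent_dprime=pd.Series(d, index=ids),
            )
        )
    latent = pd.DataFrame(
        {
            "image_id": ids,
            "category": t["category"].to_numpy(),
            "dprime_a": d_a,
            "dprime_b": d_b,
        }
    )
    return LinkedObserverPair(obs[0], obs[1], latent, realized)


def generate_feature_set(
    n_per_class: int,
    dim: int,
    separation: float,
    seed: int = 0,
    class_labels=CATEGORIES,
    id_prefix: str = "feat",
) -> FeatureSet:
    """Two isotropic unit-variance Gaussian clouds along a random direction.

    The class means differ by ``separation`` along a random unit vector, so
    the Bayes-optimal accuracy is Phi(separation/2); it is recorded in the
    returned metadata together with the generating parameters.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    u = rng.standard_normal(dim)
    u /= np.linalg.norm(u)
    la, lb = class_labels
    X = rng.standard_normal((2 * n_per_class, dim))
    X[:n_per_class] -= (separation / 2.0) * u
    X[n_per_class:] += (separation / 2.0) * u
    ids = np.array(
        [f"{id_prefix}_{la}_{i:05d}" for i in range(n_per_class)]
        + [f"{id_prefix}_{lb}_{i:05d}" for i in range(n_per_class)],
        dtype=object,
    )
    labels = np.array([la] * n_per_class + [lb] * n_per_class, dtype=object)
    return FeatureSet(
        ids, labels, X,
        metadata={
            "separation": float(separation),
            "dim": int(dim),
            "bayes_accuracy": float(norm.cdf(separation / 2.0)),
            "seed": int(seed),
            "direction": u.tolist(),
        },
    )
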