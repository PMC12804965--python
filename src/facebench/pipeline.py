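"""End-to-end report assembly: configuration, filtering, and orchestration.

A single :class:`AnalysisConfig` (YAML/JSON-loadable) drives the whole
pipeline: load or simulate two observer pools' trial tables, apply the
subject-exclusion rules, estimate lapse rates, compute pooled and
per-condition performance, bootstrap the inversion and contrast-reversal
effects, cross the pools' i1n vectors through the noise-corrected
correlation, and optionally run the linear-decoder model observer.  All
seeds and counts are recorded in the report, and a rerun with the same
config writes a byte-identical JSON report.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import binomtest

from . import decoder as dec
from . import io as fio
from . import metrics, reliability, simulate
from .effects import (
    CANONICAL_CONDITIONS,
    CONTRAST_REVERSED,
    INVERTED,
    UPRIGHT,
    condition_dprime,
    effect_size,
)

logger = logging.getLogger("facebench")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class AnalysisConfig:
    """Full provenance for one pipeline run.

    Exactly one of ``trials_paths`` (pool -> CSV path, plus
    ``stimuli_path``) or ``simulation`` (generator parameters) must be
    given.  Every count, seed, and mode flag used downstream lives here
    and is echoed into the report.
    """

    seed: int = 0
    outdir: str | None = None
    trials_paths: dict = field(default_factory=dict)
    stimuli_path: str | None = None
    simulation: dict | None = None
    min_trials: int = 20
    chance_rule: str = "binomial"        # or "fixed"
    chance_alpha: float = 0.05
    chance_threshold: float = 0.55
    n_boot: int = 1000
    n_partitions: int = 100
    lapse_partitions: int = 25
    subsample_k: int = 25
    lapse_model: str = "always_wrong"
    denominator_mode: str = "geometric_mean"
    decoder: dict | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            k: copy.deepcopy(getattr(self, k)) for k in self.__dataclass_fields__
        }


def validate_and_filter_subjects(
    trials: pd.DataFrame,
    min_trials: int = 20,
    chance_rule: str = "binomial",
    alpha: float = 0.05,
    threshold: float = 0.55,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop subjects with too few trials or near-chance accuracy.

    ``binomial`` keeps a subject only if a one-sided binomial test rejects
    accuracy <= 0.5 at level ``alpha``; ``fixed`` keeps subjects at or
    above ``threshold``.  Returns the filtered table and a report listing
    each exclusion with its reason.
    """
    if chance_rule not in ("binomial", "fixed"):
        raise ValueError(f"unknown chance rule {chance_rule!r}")
    report = []
    keep_ids = []
    for subject, sub in trials.groupby("subject_id", sort=True):
        n = len(sub)
        k = int((sub["true_category"] == sub["response_category"]).sum())
        acc = k / n
        entry = {"subject_id": subject, "n_trials": n, "accuracy": acc}
        if n < min_trials:
            report.append({**entry, "excluded": True, "reason": "min_trials"})
            continue
        if chance_rule == "binomial":
            above = binomtest(k, n, 0.5, alternative="greater").pvalue < alpha
        else:
            above = acc >= threshold
        if not above:
            report.append({**entry, "excluded": True, "reason": "near_chance"})
            continue
        report.append({**entry, "excluded": False, "reason": None})
        keep_ids.append(subject)
    if not keep_ids:
        raise ValueError("all subjects excluded")
    return trials[trials["subject_id"].isin(keep_ids)].reset_index(drop=True), report


def demo_config(
    seed: int = 0,
    trials_per_image: int = 150,
    n_boot: int = 1000,
    n_partitions: int = 50,
    outdir: str | None = None,
    with_decoder: bool = True,
) -> AnalysisConfig:
    """Two linked synthetic pools mimicking the study's species contrast.

    The human-like pool is more sensitive overall with a strong inversion
    deficit; the marmoset-like pool is less sensitive with a weaker
    inversion but stronger contrast-reversal deficit; their latent
    image-level difficulty correlates at 0.4 before the shared context
    shifts are added.
    """
    return AnalysisConfig(
        seed=seed,
        outdir=outdir,
        simulation={
            "pool_ids": ["human_like", "marmoset_like"],
            "n_per_context": 25,
            "rho": 0.4,
            "rho_is_total": True,
            "mean_dprime": [3.2, 1.8],
            "sd_dprime": [0.4, 0.3],
            "lapses": [0.02, 0.02],
            "context_shifts": [
                {"inversion": -0.9, "contrast_reversal": -0.4},
                {"inversion": -0.31, "contrast_reversal": -0.6},
            ],
            "trials_per_image": trials_per_image,
            "n_subjects": 4,
        },
        n_boot=n_boot,
        n_partitions=n_partitions,
        decoder=(
            {
                "n_per_class": 600,
                "dim": 128,
                "separation": 1.6,
                "n_train_per_class": 200,
                "n_resamples": 100,
                "C": 1.0,
            }
            if with_decoder
            else None
        ),
    )


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {name!r} failed: {e}") from e


def _simulate_inputs(sim: dict, seed_seq: np.random.SeedSequence):
    sim = dict(sim)
    pool_ids = sim.get("pool_ids", ["pool_a", "pool_b"])
    n_subjects = int(sim.get("n_subjects", 1))
    trials_per_image = int(sim.get("trials_per_image", 100))
    shifts_cfg = sim.get("context_shifts")
    if shifts_cfg is None:
        shifts = None
    elif isinstance(shifts_cfg, dict):
        shifts = simulate.make_context_shifts(**shifts_cfg)
    else:
        shifts = tuple(simulate.make_context_shifts(**s) for s in shifts_cfg)

    s_stim, s_obs, s_trials = seed_seq.spawn(3)
    stimuli = simulate.generate_stimulus_set(
        n_per_context=int(sim.get("n_per_context", 25)),
        seed=int(s_stim.generate_state(1)[0] % (2**31)),
    )
    pair = simulate.make_linked_observers(
        stimuli,
        rho=float(sim.get("rho", 0.0)),
        mean_dprime=sim.get("mean_dprime", 1.5),
        sd_dprime=sim.get("sd_dprime", 0.4),
        lapses=sim.get("lapses", (0.0, 0.0)),
        seed=int(s_obs.generate_state(1)[0] % (2**31)),
        context_shifts=shifts,
        pool_ids=tuple(pool_ids),
        rho_is_total=bool(sim.get("rho_is_total", False)),
    )
    tables = {}
    subject_seeds = s_trials.spawn(2 * n_subjects)
    per_subject = max(1, trials_per_image // n_subjects)
    for i, obs in enumerate((pair.observer_a, pair.observer_b)):
        parts = [
            simulate.simulate_trials(
                obs,
                stimuli,
                trials_per_image=per_subject,
                seed=int(subject_seeds[i * n_subjects + j].generate_state(1)[0] % (2**31)),
                subject_id=f"{obs.pool_id}_s{j + 1}",
            )
            for j in range(n_subjects)
        ]
        tables[obs.pool_id] = pd.concat(parts, ignore_index=True)
    meta = {"realized_rho": pair.realized_rho, "pool_ids": list(pool_ids)}
    return stimuli, tables, meta


def _load_inputs(config: AnalysisConfig):
    if config.stimuli_path is None:
        raise ValueError("stimuli_path is required when trial paths are given")
    stimuli = simulate.StimulusSet.from_csv(config.stimuli_path)
    tables = {
        pool: fio.read_trials_csv(path) for pool, path in config.trials_paths.items()
    }
    return stimuli, tables, {"pool_ids": list(config.trials_paths)}


def _decoder_stage(cfg: dict, seed_seq: np.random.SeedSequence) -> dict:
    s_feat, s_fit = seed_seq.spawn(2)
    if "train_features" in cfg:
        train = fio.read_feature_set(cfg["train_features"], cfg["train_labels"])
        test = fio.read_feature_set(cfg["test_features"], cfg["test_labels"])
    else:
        # train and test are disjoint splits of one cloud pair so they share
        # the same class-separation direction
        n_train_pool = int(cfg.get("n_per_class", 400))
        n_test = max(50, n_train_pool // 4)
        full = simulate.generate_feature_set(
            n_train_pool + n_test, int(cfg.get("dim", 128)),
            float(cfg.get("separation", 1.6)),
            seed=int(s_feat.generate_state(1)[0] % (2**31)),
        )
        is_train = np.zeros(len(full.labels), dtype=bool)
        for c in full.classes:
            idx = np.flatnonzero(full.labels == c)
            is_train[idx[:n_train_pool]] = True
        train = full.subset(is_train)
        test = full.subset(~is_train)
    result = dec.train_readout(
        train,
        test,
        n_train_per_class=int(cfg.get("n_train_per_class", 200)),
        n_resamples=int(cfg.get("n_resamples", 100)),
        C=float(cfg.get("C", 1.0)),
        seed=int(s_fit.generate_state(1)[0] % (2**31)),
    )
    out = result.summary()
    out["bayes_accuracy"] = train.metadata.get("bayes_accuracy")
    out["n_test_images"] = int(len(result.labels))
    return out


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute every analysis stage and return the report bundle.

    With ``config.outdir`` set, writes ``report.json``, per-pool i1n
    tables, and a log file there (atomically); the JSON report is
    byte-identical across reruns of the same config.
    """
    root = np.random.SeedSequence(config.seed)
    s_sim, s_lapse, s_pool, s_eff, s_rel, s_decoder = root.spawn(6)

    outdir = Path(config.outdir) if config.outdir else None
    handler = None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)

    try:
        if (config.simulation is None) == (not config.trials_paths):
            raise PipelineError(
                "config must provide exactly one of simulation or trials_paths"
            )
        if config.simulation is not None:
            stimuli, tables, meta = _stage(
                "simulate", _simulate_inputs, config.simulation, s_sim
            )
        else:
            stimuli, tables, meta = _stage("load", _load_inputs, config)
        pool_ids = meta["pool_ids"]
        logger.info("pools: %s", pool_ids)

        # echo full provenance except the output sink, so reruns of the same
        # analysis are byte-identical wherever they are written
        config_echo = {k: v for k, v in config.to_dict().items() if k != "outdir"}
        report: dict = {"config": config_echo, "pools": {}, "inputs": meta}
        i1n_tables = {}
        lapse_seeds = s_lapse.spawn(len(pool_ids))
        pool_seeds = s_pool.spawn(len(pool_ids))
        eff_seeds = s_eff.spawn(2 * len(pool_ids))

        for i, pool in enumerate(pool_ids):
            trials = tables[pool]
            filtered, excl = _stage(
                f"filter[{pool}]", validate_and_filter_subjects,
                trials, config.min_trials, config.chance_rule,
                config.chance_alpha, config.chance_threshold,
            )
            lapse = _stage(
                f"lapse[{pool}]", metrics.estimate_lapse,
                filtered, n_partitions=config.lapse_partitions,
                seed=int(lapse_seeds[i].generate_state(1)[0] % (2**31)),
                correction_model=config.lapse_model,
            )
            pooled = _stage(
                f"pooled[{pool}]", metrics.pooled_performance,
                filtered, n_boot=config.n_boot,
                seed=int(pool_seeds[i].generate_state(1)[0] % (2**31)),
                lapse=lapse,
            )
            i1n = _stage(f"i1n[{pool}]", metrics.i1_from_trials, filtered)
            i1n_tables[pool] = i1n

            conditions = {}
            for label, spec in CANONICAL_CONDITIONS.items():
                res = _stage(
                    f"condition[{pool}:{label}]", condition_dprime,
                    filtered, spec, stimuli,
                )
                conditions[label] = {
                    "mean_dprime": res.mean_dprime,
                    "n_images": res.n_images,
                    "n_trials": res.n_trials,
                }
            effects_out = {}
            for j, (name, cond_b) in enumerate(
                (("inversion", INVERTED), ("contrast_reversal", CONTRAST_REVERSED))
            ):
                eff = _stage(
                    f"effect[{pool}:{name}]", effect_size,
                    filtered, stimuli, UPRIGHT, cond_b,
                    n_boot=config.n_boot, subsample_k=config.subsample_k,
                    seed=int(eff_seeds[2 * i + j].generate_state(1)[0] % (2**31)),
                )
                effects_out[name] = eff.to_dict()
            report["pools"][pool] = {
                "n_trials_raw": int(len(trials)),
                "n_trials": int(len(filtered)),
                "subjects": excl,
                "lapse": {
                    "rate": lapse.lapse,
                    "model": lapse.correction_model,
                    "n_partitions": lapse.n_partitions,
                },
                "pooled_performance": {
                    "accuracy": pooled.accuracy,
                    "accuracy_raw": pooled.accuracy_raw,
                    "boot_mean": pooled.boot_mean,
                    "boot_sd": pooled.boot_sd,
                    "n_boot": pooled.n_boot,
                },
                "conditions": conditions,
                "effects": effects_out,
            }
            tables[pool] = filtered

        if len(pool_ids) >= 2:
            a, b = pool_ids[:2]
            shc = _stage(
                "reliability", reliability.noise_corrected_correlation,
                tables[a], tables[b], n_partitions=config.n_partitions,
                seed=int(s_rel.generate_state(1)[0] % (2**31)),
                denominator_mode=config.denominator_mode,
            )
            report["reliability"] = shc.to_dict(include_partitions=False)
        else:
            report["reliability"] = {"skipped": True, "reason": "fewer than two pools"}

        if config.decoder:
            report["decoder"] = _stage("decoder", _decoder_stage, config.decoder, s_decoder)
        else:
            report["decoder"] = {"skipped": True, "reason": "no feature configuration"}
            logger.info("decoder stage skipped (no features)")

        if outdir:
            fio.write_json_atomic(report, outdir / "report.json")
            for pool, i1n in i1n_tables.items():
                fio.write_csv_atomic(i1n, outdir / f"i1n_{pool}.csv")
        return report
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()
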