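"""Experiment orchestration: the training-noise sweep and the
training-sample-size sweep.

Both experiments train seeded replicate detectors (5 runs by default)
and score them out-of-domain on the identical held-out test subjects of
the high-noise cohort.  The noise sweep trains one detector family per
low-noise-cohort reconstruction profile plus an in-domain upper-bound
condition trained on the high-noise cohort itself; the sample-size
sweep trains on nested fractions of the noise-matched training split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import SET1_PROFILES
from .detector import LesionDetector, LossConfig, NetworkConfig, TrainConfig
from .evaluation import evaluate_testset
from .phantom import Subject

__all__ = [
    "SplitSpec",
    "ExperimentResult",
    "split_dataset",
    "noise_sweep",
    "sample_size_sweep",
    "compare_f1",
]

DEFAULT_RUN_SEEDS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class SplitSpec:
    """60/20/20 train/validation/test split, stratified by abnormal
    status, deterministic in ``split_seed``."""

    train_fraction: float = 0.60
    val_fraction: float = 0.20
    test_fraction: float = 0.20
    split_seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(cohort: list[Subject], spec: SplitSpec | None = None) -> dict:
    """Partition subject indices into disjoint, exhaustive train/val/
    test sets.

    Overall sizes follow round(train_fraction*n), round(val_fraction*n)
    and the remainder (83 subjects -> 50/17/16).  Within that, subjects
    are allocated stratified by abnormal status so desk-scale training
    splits never degenerate to all-normal.  The same partition applies
    to every rendering profile of the cohort (subjects, not images, are
    split).
    """
    spec = spec or SplitSpec()
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    n_train = _round_half_up(spec.train_fraction * n)
    n_val = _round_half_up(spec.val_fraction * n)
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split fractions produce a negative subset")
    rng = np.random.default_rng(spec.split_seed)
    if spec.stratify:
        groups = [
            [s.index for s in cohort if s.is_abnormal],
            [s.index for s in cohort if not s.is_abnormal],
        ]
    else:
        groups = [[s.index for s in cohort]]
    pools = [rng.permutation(g).tolist() for g in groups if g]
    # interleave strata proportionally, then cut at the exact sizes
    order: list[int] = []
    counters = [0] * len(pools)
    while any(c < len(p) for c, p in zip(counters, pools)):
        # pick the stratum lagging most behind its proportional share
        fracs = [
            counters[i] / len(pools[i]) if len(pools[i]) else 1.0
            for i in range(len(pools))
        ]
        i = int(np.argmin(fracs))
        order.append(pools[i][counters[i]])
        counters[i] += 1
    return {
        "train": np.array(sorted(order[:n_train]), dtype=int),
        "val": np.array(sorted(order[n_train : n_train + n_val]), dtype=int),
        "test": np.array(sorted(order[n_train + n_val :]), dtype=int),
    }


@dataclass
class ExperimentResult:
    """Per-run metrics with mean/SD aggregation and pairwise tests."""

    per_run: pd.DataFrame  # columns: condition, run_seed, f1, ppv, sensitivity
    table: pd.DataFrame  # one row per condition: mean (SD) per metric
    pvalues: pd.DataFrame  # pairwise Welch p-values on per-run F1

    def runs(self, condition: str) -> np.ndarray:
        return self.per_run.loc[
            self.per_run.condition == condition, "f1"
        ].to_numpy()


def compare_f1(runs_a, runs_b) -> float:
    """Two-sided Welch two-sample t-test on per-run F1 values.

    Replicate runs differ only in training seed and are independent
    trainings, hence a two-sample (not paired) comparison.  Identical
    samples return p = 1.
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.size != b.size:
        raise ValueError("run counts differ")
    if a.size < 2:
        raise ValueError("need at least 2 runs per condition")
    if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
        return 1.0 if np.allclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _subject_arrays(cohort, indices, profile_name):
    by_index = {s.index: s for s in cohort}
    subs = [by_index[i] for i in indices]
    X = np.stack([s.images[profile_name].voxels for s in subs])
    y = np.stack([np.asarray(s.gold[profile_name].labels) > 0 for s in subs])
    return X, y, subs


def _train_and_score(
    set_train,
    set_val,
    test_pairs,
    net_cfg,
    train_cfg,
    loss_cfg,
    seed,
):
    det = LesionDetector(
        network=net_cfg, loss=loss_cfg, train=replace(train_cfg, seed=seed)
    )
    det.fit(set_train[0], set_train[1], X_val=set_val[0], y_val=set_val[1])
    metrics, _ = evaluate_testset(det, test_pairs)
    return det, metrics


def _aggregate(per_run: pd.DataFrame, condition_order) -> pd.DataFrame:
    rows = []
    for cond in condition_order:
        sub = per_run[per_run.condition == cond]
        row = {"condition": cond, "n_runs": len(sub)}
        for m in ("f1", "ppv", "sensitivity"):
            row[f"{m}_mean"] = sub[m].mean()
            row[f"{m}_sd"] = sub[m].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def _pairwise_pvalues(per_run: pd.DataFrame, condition_order) -> pd.DataFrame:
    mat = pd.DataFrame(index=condition_order, columns=condition_order, dtype=float)
    for a in condition_order:
        for b in condition_order:
            if a == b:
                mat.loc[a, b] = 1.0
            else:
                mat.loc[a, b] = compare_f1(
                    per_run.loc[per_run.condition == a, "f1"],
                    per_run.loc[per_run.condition == b, "f1"],
                )
    return mat


def noise_sweep(
    set1_cohort: list[Subject],
    set2_cohort: list[Subject],
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    run_seeds=DEFAULT_RUN_SEEDS,
    split_spec: SplitSpec | None = None,
    profiles=SET1_PROFILES,
    upper_bound: bool = True,
    test_profile: str = "Set2-OSEM",
    in_domain_test: bool = False,
) -> ExperimentResult:
    """Training-noise sweep.

    For each low-noise-cohort profile, train ``len(run_seeds)`` seeded
    detectors on that profile's training split (validating on the same
    profile's validation split) and score each on the high-noise
    cohort's test split.  With ``upper_bound=True`` an in-domain
    condition trained on the high-noise cohort's training split is
    added.  ``in_domain_test=True`` scores every condition on its own
    training domain instead (control experiment without domain shift).
    """
    net_cfg = net_cfg or NetworkConfig()
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    split_spec = split_spec or SplitSpec()
    for name in profiles:
        if any(name not in s.images for s in set1_cohort):
            raise ValueError(f"profile {name!r} missing from cohort renderings")
    split1 = split_dataset(set1_cohort, split_spec)
    split2 = split_dataset(set2_cohort, split_spec)
    X2t, y2t, subs2_test = _subject_arrays(set2_cohort, split2["test"], test_profile)
    test_pairs_set2 = [
        (s.images[test_profile], s.gold[test_profile]) for s in subs2_test
    ]
    rows = []
    conditions = list(profiles) + (["Set2-OSEM (upper bound)"] if upper_bound else [])
    for cond in conditions:
        if cond.endswith("(upper bound)"):
            Xtr, ytr, _ = _subject_arrays(set2_cohort, split2["train"], test_profile)
            Xv, yv, subs_val = _subject_arrays(set2_cohort, split2["val"], test_profile)
            val_golds = [s.gold[test_profile] for s in subs_val]
            test_pairs = test_pairs_set2
        else:
            Xtr, ytr, _ = _subject_arrays(set1_cohort, split1["train"], cond)
            Xv, yv, subs_val = _subject_arrays(set1_cohort, split1["val"], cond)
            val_golds = [s.gold[cond] for s in subs_val]
            if in_domain_test:
                _, _, subs1_test = _subject_arrays(set1_cohort, split1["test"], cond)
                test_pairs = [(s.images[cond], s.gold[cond]) for s in subs1_test]
            else:
                test_pairs = test_pairs_set2
        for seed in run_seeds:
            _, metrics = _train_and_score(
                (Xtr, ytr), (Xv, val_golds), test_pairs,
                net_cfg, train_cfg, loss_cfg, seed,
            )
            rows.append(
                {
                    "condition": cond,
                    "run_seed": seed,
                    "f1": metrics.f1,
                    "ppv": metrics.ppv,
                    "sensitivity": metrics.sensitivity,
                    "tp": metrics.tp,
                    "fp": metrics.fp,
                    "fn": metrics.fn,
                }
            )
    per_run = pd.DataFrame(rows)
    return ExperimentResult(
        per_run=per_run,
        table=_aggregate(per_run, conditions),
        pvalues=_pairwise_pvalues(per_run, conditions),
    )


def sample_size_sweep(
    set1_cohort: list[Subject],
    set2_cohort: list[Subject],
    fractions=(0.25, 0.50, 0.75, 1.00),
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    run_seeds=DEFAULT_RUN_SEEDS,
    split_spec: SplitSpec | None = None,
    train_profile: str = "Set1-VPFXS-2min",
    test_profile: str = "Set2-OSEM",
) -> ExperimentResult:
    """Training-sample-size sweep on the noise-matched profile.

    Per run, nested seeded subsets of the training split (25% of the
    subjects is a subset of 50%, and so on) are trained with the same
    validation split and the same out-of-domain test split throughout.
    """
    net_cfg = net_cfg or NetworkConfig()
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    split_spec = split_spec or SplitSpec()
    fractions = sorted(float(f) for f in fractions)
    if not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    split1 = split_dataset(set1_cohort, split_spec)
    split2 = split_dataset(set2_cohort, split_spec)
    if any(_round_half_up(f * len(split1["train"])) < 1 for f in fractions):
        raise ValueError("smallest fraction yields fewer than one subject")
    Xv, yv, subs_val = _subject_arrays(set1_cohort, split1["val"], train_profile)
    val_golds = [s.gold[train_profile] for s in subs_val]
    _, _, subs2_test = _subject_arrays(set2_cohort, split2["test"], test_profile)
    test_pairs = [(s.images[test_profile], s.gold[test_profile]) for s in subs2_test]
    train_idx = split1["train"]
    rows = []
    subset_log: dict[tuple[float, int], np.ndarray] = {}
    for seed in run_seeds:
        perm = np.random.default_rng(seed).permutation(train_idx)
        for frac in fractions:
            k = max(1, _round_half_up(frac * len(train_idx)))
            subset = np.sort(perm[:k])
            subset_log[(frac, seed)] = subset
            Xtr, ytr, _ = _subject_arrays(set1_cohort, subset, train_profile)
            _, metrics = _train_and_score(
                (Xtr, ytr), (Xv, val_golds), test_pairs,
                net_cfg, train_cfg, loss_cfg, seed,
            )
            rows.append(
                {
                    "condition": f"{frac:.0%}",
                    "fraction": frac,
                    "run_seed": seed,
                    "n_train": k,
                    "f1": metrics.f1,
                    "ppv": metrics.ppv,
                    "sensitivity": metrics.sensitivity,
                    "tp": metrics.tp,
                    "fp": metrics.fp,
                    "fn": metrics.fn,
                }
            )
    per_run = pd.DataFrame(rows)
    conditions = [f"{f:.0%}" for f in fractions]
    result = ExperimentResult(
        per_run=per_run,
        table=_aggregate(per_run, conditions),
        pvalues=_pairwise_pvalues(per_run, conditions),
    )
    result.subsets = subset_log
    return result
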