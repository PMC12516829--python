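"""Stratified splitting, regression metrics, and the multi-trial protocol.

Compounds are split 70/15/15 into train/validation/test with stratification
on membership in the high-quality intrinsic-solubility subset, so that
high-quality measurements appear in every partition and the test-set S0
metrics can be restricted to them.  Model stability is reported as the mean
and sample standard deviation of RMSE / R2 over several independent splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .curation import TaskTable, TASK_NAMES
from .gt_model import ModelConfig, train
from .molgraph import MolecularGraph

__all__ = [
    "SplitResult",
    "MetricsReport",
    "stratified_split",
    "rmse",
    "r2",
    "run_trials",
    "TrialSummary",
]


@dataclass(frozen=True)
class SplitResult:
    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]
    seed: int


def stratified_split(
    n: int,
    hq_flags,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitResult:
    """Split indices 0..n-1 stratified on the high-quality flag.

    Within each stratum the validation and test counts are rounded to the
    nearest integer and the remainder goes to train.  A stratum with fewer
    than 3 members is assigned entirely to train (with a warning).
    """
    hq = np.asarray(hq_flags, bool)
    if len(hq) != n:
        raise ValueError("hq_flags length must equal n")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []
    for flag in (True, False):
        idx = np.flatnonzero(hq == flag)
        if len(idx) == 0:
            continue
        if len(idx) < 3:
            warnings.warn(
                f"stratum hq={flag} has {len(idx)} member(s); assigned to train"
            )
            tr.extend(idx.tolist())
            continue
        idx = rng.permutation(idx)
        n_val = int(round(fractions[1] * len(idx)))
        n_test = int(round(fractions[2] * len(idx)))
        te.extend(idx[:n_test].tolist())
        va.extend(idx[n_test:n_test + n_val].tolist())
        tr.extend(idx[n_test + n_val:].tolist())
    return SplitResult(
        train=tuple(sorted(tr)), val=tuple(sorted(va)),
        test=tuple(sorted(te)), seed=seed,
    )


def rmse(y, yhat) -> float:
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("r2 needs at least 2 points")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 undefined for zero-variance y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


@dataclass
class MetricsReport:
    """Per-task RMSE / R2 on one evaluation set (NaN where not computable)."""

    rmse: dict[str, float]
    r2: dict[str, float]
    n: dict[str, int]

    @staticmethod
    def compute(y: np.ndarray, yhat: np.ndarray, observed: np.ndarray,
                task_names=TASK_NAMES) -> "MetricsReport":
        out_rmse, out_r2, out_n = {}, {}, {}
        for t, name in enumerate(task_names):
            o = observed[:, t]
            out_n[name] = int(o.sum())
            if o.sum() == 0:
                out_rmse[name] = out_r2[name] = float("nan")
                continue
            out_rmse[name] = rmse(y[o, t], yhat[o, t])
            try:
                out_r2[name] = r2(y[o, t], yhat[o, t])
            except ValueError:
                out_r2[name] = float("nan")
        return MetricsReport(rmse=out_rmse, r2=out_r2, n=out_n)


@dataclass
class TrialSummary:
    """Mean (SD) of S0 test metrics over independent splits.

    S0 metrics are computed on the high-quality members of each trial's test
    set only; ``all_task`` carries the unrestricted per-task reports.
    """

    s0_rmse: list[float] = field(default_factory=list)
    s0_r2: list[float] = field(default_factory=list)
    n_eval: list[int] = field(default_factory=list)
    all_task: list[MetricsReport] = field(default_factory=list)

    @staticmethod
    def _mean_sd(xs):
        xs = np.asarray(xs, float)
        sd = float(xs.std(ddof=1)) if len(xs) > 1 else 0.0
        return float(xs.mean()), sd

    @property
    def rmse_mean_sd(self):
        return self._mean_sd(self.s0_rmse)

    @property
    def r2_mean_sd(self):
        return self._mean_sd(self.s0_r2)

    def format_table(self) -> str:
        rm, rs = self.rmse_mean_sd
        qm, qs = self.r2_mean_sd
        lines = [
            "S0 test metrics (high-quality subset), "
            f"{len(self.s0_rmse)} trials",
            f"RMSE (std)  {rm:.2f} ({rs:.2f})",
            f"R2 (std)    {qm:.2f} ({qs:.2f})",
        ]
        return "\n".join(lines)


def run_trials(
    task_table: TaskTable,
    graphs: list[MolecularGraph],
    config: ModelConfig | None = None,
    n_trials: int = 5,
    seeds: list[int] | None = None,
) -> TrialSummary:
    """Train/evaluate over ``n_trials`` different stratified splits.

    Each trial: split with its own seed, train, predict the test set, report
    S0 RMSE / R2 on the high-quality test compounds plus all-task metrics.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    config = config or ModelConfig()
    seeds = list(seeds) if seeds is not None else list(range(n_trials))
    if len(seeds) != n_trials:
        raise ValueError("need one seed per trial")

    summary = TrialSummary()
    hq = np.asarray(task_table.high_quality_s0, bool)
    s0_col = TASK_NAMES.index("S0")
    for seed in seeds:
        split = stratified_split(task_table.n_compounds, hq, seed=seed)
        trial_cfg = ModelConfig(**{**config.__dict__, "seed": seed})
        model, _ = train(task_table, graphs, split, trial_cfg)
        test_idx = np.asarray(split.test, int)
        preds = model.predict([graphs[i] for i in test_idx])
        y = task_table.values[test_idx]
        obs = task_table.observed[test_idx]
        summary.all_task.append(MetricsReport.compute(y, preds, obs))
        eval_mask = hq[test_idx] & obs[:, s0_col]
        summary.n_eval.append(int(eval_mask.sum()))
        if eval_mask.sum() >= 2:
            summary.s0_rmse.append(
                rmse(y[eval_mask, s0_col], preds[eval_mask, s0_col])
            )
            summary.s0_r2.append(
                r2(y[eval_mask, s0_col], preds[eval_mask, s0_col])
            )
    return summary
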