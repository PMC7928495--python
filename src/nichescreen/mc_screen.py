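"""Monte Carlo screening of a predictor pool by random-subset model runs.

The screening experiment ("ensemble") is a sequence of sprints; each sprint
is a block of independent model runs, each fitted on a small random subset
of the variable pool. A tally table accumulates, per variable, the number
of runs it appeared in and its cumulative permutation importance; the
ratio — average permutation importance — is the screening score. At the end
of each sprint a checkpoint model is fitted on the current top-k variables
and its AICc/AUC recorded, giving an evolving progression of models that
converges on a stable top-k assemblage without ever fitting the full pool.

Every run is independent: its result depends only on (subset, data,
settings, run seed), with per-run seeds derived deterministically from the
master seed and the global run index, so the ensemble is reproducible under
any execution order or degree of parallelism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .maxent_engine import ConvergenceError, MaxentModel, ModelSettings, fit, predict
from .model_metrics import aicc, auc, permutation_importance

__all__ = [
    "ScreenConfig", "ScreenData", "TallyTable", "SprintRecord",
    "EnsembleResult", "draw_subset", "execute_run", "update_tally",
    "top_k", "run_sprint", "run_ensemble", "stability_sprint", "subset_count",
]


def subset_count(n: int, k: int) -> int:
    """Exact number of k-variable subsets of an n-variable pool, C(n, k)."""
    if k < 0 or n < 0:
        raise ValueError("n and k must be non-negative")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    return math.comb(n, k)


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of a screening ensemble.

    Defaults mirror the standard experiment shape: 100 sprints of 10 runs,
    a top-6 selection, LQHP features with regularization multiplier 1.0,
    and checkpoints at sprints 25/50/100 (scaled when n_sprints differs).
    """

    pool: tuple[str, ...]
    k_per_run: int
    runs_per_sprint: int = 10
    n_sprints: int = 100
    top_k: int = 6
    settings: ModelSettings = field(default_factory=ModelSettings)
    master_seed: int = 0
    checkpoints: tuple[int, ...] | None = None
    sprint_models: str = "all"          # all | checkpoints | none
    stop_after_stable: int | None = None  # experimental early stopping

    def __post_init__(self) -> None:
        object.__setattr__(self, "pool", tuple(self.pool))
        if not 1 <= self.k_per_run <= len(self.pool):
            raise ValueError("k_per_run must be in 1..|pool|")
        if self.top_k > len(self.pool):
            raise ValueError("top_k exceeds pool size")
        if self.checkpoints is None:
            cps = sorted({max(1, self.n_sprints // 4),
                          max(1, self.n_sprints // 2), self.n_sprints})
            object.__setattr__(self, "checkpoints", tuple(cps))
        else:
            cps = tuple(sorted(set(self.checkpoints)))
            if any(c < 1 or c > self.n_sprints for c in cps):
                raise ValueError("checkpoints must lie in 1..n_sprints")
            object.__setattr__(self, "checkpoints", cps)
        if self.sprint_models not in ("all", "checkpoints", "none"):
            raise ValueError("sprint_models must be all|checkpoints|none")

    @property
    def total_runs(self) -> int:
        return self.n_sprints * self.runs_per_sprint


@dataclass
class ScreenData:
    """Presence and background predictor tables over the full pool."""

    presence: pd.DataFrame
    background: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.presence.columns) != list(self.background.columns):
            raise ValueError("presence and background must share columns")


class TallyTable:
    """Running per-variable use counts and cumulative permutation importance."""

    def __init__(self, pool: Sequence[str]):
        self.pool = list(pool)
        self._index = {n: i for i, n in enumerate(self.pool)}
        self.use_count = np.zeros(len(self.pool), dtype=int)
        self.cum_importance = np.zeros(len(self.pool))

    @property
    def avg_importance(self) -> np.ndarray:
        """cum_importance / use_count, 0 where a variable was never used."""
        with np.errstate(invalid="ignore", divide="ignore"):
            avg = np.where(self.use_count > 0,
                           self.cum_importance / np.maximum(self.use_count, 1), 0.0)
        return avg

    def copy(self) -> "TallyTable":
        out = TallyTable(self.pool)
        out.use_count = self.use_count.copy()
        out.cum_importance = self.cum_importance.copy()
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": self.pool, "use_count": self.use_count,
                             "cum_importance": self.cum_importance,
                             "avg_importance": self.avg_importance})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def draw_subset(pool: Sequence[str], k: int, rng: np.random.Generator) -> list[str]:
    """Draw k distinct variables uniformly from the pool (order by pool)."""
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    idx = np.sort(rng.choice(len(pool), size=k, replace=False))
    return [pool[i] for i in idx]


def update_tally(tally: TallyTable, run_importances: dict[str, float]) -> TallyTable:
    """Apply one run's importances in place: count +1, importance accumulated."""
    for name, imp in run_importances.items():
        if name not in tally._index:
            raise KeyError(f"variable {name!r} not in pool")
        i = tally._index[name]
        tally.use_count[i] += 1
        tally.cum_importance[i] += imp
    return tally


def top_k(tally: TallyTable, k: int) -> list[str] | None:
    """Top-k variables by average importance; None while < k variables used.

    Ties break by pool order (stable sort on the negated averages).
    """
    used = np.flatnonzero(tally.use_count > 0)
    if used.size < k:
        return None  # deferred: too few variables seen so far
    avg = tally.avg_importance
    order = used[np.argsort(-avg[used], kind="stable")]
    return [tally.pool[i] for i in order[:k]]


def _run_seed(master_seed: int, run_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), int(run_index)])


def execute_run(subset: Sequence[str], presence_X: pd.DataFrame,
                background_X: pd.DataFrame, settings: ModelSettings,
                run_seed: int | np.random.SeedSequence) -> dict[str, float]:
    """Fit one model on exactly ``subset`` and return its importance vector.

    The returned percentages sum to 100 over the subset. Results depend
    only on the arguments — runs are fully independent and parallelizable.
    """
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    ss = (run_seed if isinstance(run_seed, np.random.SeedSequence)
          else np.random.SeedSequence(int(run_seed)))
    fit_seed, perm_seed = (int(s) for s in ss.generate_state(2) % (2 ** 31))
    subset = list(subset)
    if len(subset) == 1 and "P" in settings.feature_classes:
        settings = replace(settings,
                           feature_classes=settings.feature_classes.replace("P", ""))
    model = fit(presence_X[subset], background_X[subset], settings, seed=fit_seed)
    if len(subset) == 1:
        return {subset[0]: 100.0}
    imp = permutation_importance(model, presence_X[subset], background_X[subset],
                                 seed=perm_seed)
    return {name: float(imp[name]) for name in subset}


@dataclass
class SprintRecord:
    """Everything logged for one sprint."""

    sprint_index: int
    subsets: list[list[str]]
    importances: list[dict[str, float] | None]   # None for failed/dry runs
    failed_runs: list[int]
    tally_snapshot: pd.DataFrame
    top_list: list[str] | None            # None while selection is deferred
    model_aicc: float | None = None
    model_auc: float | None = None
    note: str = ""


@dataclass
class EnsembleResult:
    """Full record of a screening ensemble."""

    config: ScreenConfig
    records: list[SprintRecord]
    tally: TallyTable
    checkpoint_models: dict[int, MaxentModel]
    total_runs: int
    stopped_early: bool = False

    @property
    def final_top(self) -> list[str] | None:
        return self.records[-1].top_list if self.records else None

    def stability(self, mode: str = "set") -> int | None:
        return stability_sprint(self.records, mode)

    def sprint_log_frame(self) -> pd.DataFrame:
        """Sprint × variable membership grid (1 = in that sprint's top-k),
        with AICc and AUC columns — the tabular form of a sprint log plot."""
        rows = []
        for rec in self.records:
            row = {"sprint": rec.sprint_index}
            members = set(rec.top_list or [])
            for v in self.config.pool:
                row[v] = int(v in members)
            row["aicc"] = rec.model_aicc
            row["auc"] = rec.model_auc
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "pool_size": len(self.config.pool),
            "k_per_run": self.config.k_per_run,
            "n_sprints_completed": len(self.records),
            "total_runs": self.total_runs,
            "final_top": self.final_top,
            "stability_sprint_set": self.stability("set"),
            "stability_sprint_order": self.stability("order"),
            "mean_samples_per_variable": float(self.tally.use_count.mean()),
            "stopped_early": self.stopped_early,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def _sprint_end_model(config: ScreenConfig, data: ScreenData,
                      top: list[str], sprint_seed: int):
    settings = config.settings
    if len(top) == 1 and "P" in settings.feature_classes:
        settings = replace(settings,
                           feature_classes=settings.feature_classes.replace("P", ""))
    model = fit(data.presence[top], data.background[top], settings, seed=sprint_seed)
    pr = predict(model, data.presence[top], "raw")
    br = predict(model, data.background[top], "raw")
    return model, aicc(model, data.presence[top], data.background[top]), auc(pr, br)


def run_sprint(config: ScreenConfig, data: ScreenData, sprint_index: int,
               tally: TallyTable, dry_run: bool = False,
               workers: int = 1) -> tuple[SprintRecord, MaxentModel | None]:
    """Execute one sprint of runs, update the tally, and fit the sprint-end
    model on the current top-k (unless deferred, disabled, or dry).

    Returns the record and the sprint-end model (None when not fitted).
    """
    base = (sprint_index - 1) * config.runs_per_sprint
    subsets, importances, failed = [], [], []
    seeds = [_run_seed(config.master_seed, base + j)
             for j in range(config.runs_per_sprint)]
    for j, ss in enumerate(seeds):
        rng = np.random.default_rng(ss.spawn(1)[0])
        subsets.append(draw_subset(config.pool, config.k_per_run, rng))

    if dry_run:
        results: list[dict[str, float] | None] = [None] * len(subsets)
        for sub in subsets:
            update_tally(tally, {v: 0.0 for v in sub})
    else:
        def _one(sub, ss):
            try:
                return execute_run(sub, data.presence, data.background,
                                   config.settings, ss)
            except (ConvergenceError, ValueError) as exc:
                return exc

        if workers > 1:
            raw = Parallel(n_jobs=workers)(
                delayed(_one)(sub, ss) for sub, ss in zip(subsets, seeds))
        else:
            raw = [_one(sub, ss) for sub, ss in zip(subsets, seeds)]
        results = []
        # tally updates applied in run-index order for deterministic logs
        for j, r in enumerate(raw):
            if isinstance(r, Exception):
                failed.append(j)
                results.append(None)
            else:
                update_tally(tally, r)
                results.append(r)
        if all(r is None for r in results):
            raise RuntimeError(f"all runs failed in sprint {sprint_index}")
    importances = results

    top = top_k(tally, config.top_k)
    record = SprintRecord(sprint_index, subsets, importances, failed,
                          tally.to_frame(), top)
    model = None
    want_model = (not dry_run and top is not None and
                  (config.sprint_models == "all" or
                   (config.sprint_models == "checkpoints" and
                    sprint_index in config.checkpoints)))
    if top is None:
        record.note = "top-k deferred: fewer used variables than top_k"
    if want_model:
        # sprint-end seeds offset far above any run index to avoid collision
        sprint_seed = int(_run_seed(config.master_seed, 2 ** 31 + sprint_index)
                          .generate_state(1)[0] % (2 ** 31))
        model, record.model_aicc, record.model_auc = _sprint_end_model(
            config, data, top, sprint_seed)
    return record, model


def run_ensemble(config: ScreenConfig, data: ScreenData | None = None,
                 dry_run: bool = False, workers: int = 1) -> EnsembleResult:
    """Run the full screening ensemble.

    ``dry_run`` draws subsets and maintains use counts without fitting any
    model (importances skipped) — useful for sampling-design accounting.
    Per-run seeds are keyed by (master_seed, global run index), so results
    are identical for any ``workers`` setting.
    """
    if data is None and not dry_run:
        raise ValueError("data is required unless dry_run=True")
    tally = TallyTable(config.pool)
    records: list[SprintRecord] = []
    checkpoint_models: dict[int, MaxentModel] = {}
    total = 0
    stable_streak = 0
    stopped = False
    for s in range(1, config.n_sprints + 1):
        record, model = run_sprint(config, data, s, tally,
                                   dry_run=dry_run, workers=workers)
        total += config.runs_per_sprint
        records.append(record)
        if model is not None and s in config.checkpoints:
            checkpoint_models[s] = model
        if config.stop_after_stable is not None and len(records) >= 2:
            prev, cur = records[-2].top_list, records[-1].top_list
            same = (prev is not None and cur is not None
                    and set(prev) == set(cur))
            stable_streak = stable_streak + 1 if same else 0
            if stable_streak >= config.stop_after_stable:
                stopped = True
                break
    return EnsembleResult(config, records, tally, checkpoint_models, total,
                          stopped_early=stopped)


def stability_sprint(records: Sequence[SprintRecord], mode: str = "set") -> int | None:
    """Smallest sprint index from which the top-k never changes again.

    ``mode='set'`` compares membership; ``mode='order'`` the ranked list.
    Returns None if the final sprint's selection is missing or the top-k
    still changed at the end.
    """
    if mode not in ("set", "order"):
        raise ValueError("mode must be 'set' or 'order'")
    if not records:
        raise ValueError("no sprint records")
    last = records[-1].top_list
    if last is None:
        return None
    key = (lambda t: frozenset(t)) if mode == "set" else tuple
    target = key(last)
    stable_from = records[-1].sprint_index
    for rec in reversed(records[:-1]):
        if rec.top_list is not None and key(rec.top_list) == target:
            stable_from = rec.sprint_index
        else:
            break
    if len(records) > 1 and stable_from == records[-1].sprint_index:
        return None  # selection still changing at the end: never stable
    return stable_from
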