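"""Decision-level fusion of per-channel predictions.

Each sample carries up to 24 channel votes (one per modality x SDS).  Three
fusion methods are provided — plain majority voting, accuracy-weighted voting
and stacking (a meta-classifier trained on the vector of channel votes) — at
three grouping levels: all 24 channels together, per modality (6 groups of 4)
or per SDS (4 groups of 6).  Channels that abstained for a sample (e.g. the
replicate screen removed its measurement on that channel) contribute zero
weight; stacking encodes abstention as an explicit category.  True labels are
never used at prediction time: weights and the stacker are computed from
folds other than the one being predicted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .channels import ALL_CHANNELS, channel_from_key
from .datamodel import ConfigError, DataError, LeakageError
from .evaluate import SEVERITY_ORDER, PerformanceReport, performance_report

ABSTAIN = "__abstain__"

#: Most-severe-first tie-break priority (a tied diagnosis resolves to the more
#: pathological class, the clinically safer call).
DEFAULT_PRIORITY = tuple(reversed(SEVERITY_ORDER))


@dataclass
class FusionSpec:
    method: str = "weighted"  # majority | weighted | stacking
    level: str = "all"  # all | per_modality | per_sds
    weights: dict | None = None  # channel key -> weight (weighted only)
    meta: str = "svm"  # svm | random_forest (stacking only)
    n_trees: int = 80
    seed: int = 0
    priority: tuple = DEFAULT_PRIORITY

    def __post_init__(self) -> None:
        if self.method not in ("majority", "weighted", "stacking"):
            raise ConfigError(f"unknown fusion method {self.method!r}")
        if self.level not in ("all", "per_modality", "per_sds"):
            raise ConfigError(f"unknown fusion level {self.level!r}")
        if self.weights is not None:
            w = np.array(list(self.weights.values()), dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ConfigError("weights must be >= 0 and not all zero")


def _priority_pick(candidates, priority) -> str:
    for cls in priority:
        if cls in candidates:
            return cls
    return sorted(candidates)[0]


def majority_vote(votes, scores: dict | None = None, priority=DEFAULT_PRIORITY) -> str:
    """Label with the most votes; ties by summed score, then severity priority."""
    votes = [v for v in votes if v is not None and v != ABSTAIN]
    if not votes:
        raise DataError("all channels abstained; sample is unfusable")
    counts = Counter(votes)
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    if scores:
        best = max(tied, key=lambda c: scores.get(c, -np.inf))
        runners = [c for c in tied if scores.get(c, -np.inf) == scores.get(best, -np.inf)]
        if len(runners) == 1:
            return best
        tied = runners
    return _priority_pick(tied, priority)


def weighted_vote(votes: dict, weights: dict, priority=DEFAULT_PRIORITY) -> str:
    """Label maximizing the summed weight of the channels voting for it."""
    totals: dict[str, float] = {}
    for ch, label in votes.items():
        if label is None or label == ABSTAIN:
            continue
        totals[label] = totals.get(label, 0.0) + float(weights.get(ch, 0.0))
    if not totals:
        raise DataError("all channels abstained; sample is unfusable")
    top = max(totals.values())
    tied = [c for c, t in totals.items() if t >= top - 1e-12]
    if len(tied) == 1:
        return tied[0]
    return _priority_pick(tied, priority)


def channel_weights(decisions: pd.DataFrame, exclude_fold: int | None = None) -> dict:
    """Per-channel mean accuracy, rescaled to sum to 1.

    ``exclude_fold`` drops that fold's rows so that weights applied to a test
    fold never saw its samples.
    """
    df = decisions
    if exclude_fold is not None:
        df = df[df["fold"] != exclude_fold]
    accs = (
        df.assign(hit=(df["truth"] == df["pred"]).astype(float))
        .groupby("channel")["hit"]
        .mean()
    )
    total = accs.sum()
    if total <= 0:
        return {ch: 1.0 / len(accs) for ch in accs.index}
    return (accs / total).to_dict()


# --- stacking -----------------------------------------------------------------

def _vote_matrix(decisions: pd.DataFrame, channel_order: list[str]) -> tuple[np.ndarray, pd.DataFrame]:
    """Pivot long decisions to one row per (sample, repeat) of channel votes."""
    pivot = decisions.pivot_table(
        index=["sample_id", "repeat"],
        columns="channel",
        values="pred",
        aggfunc="first",
    )
    for ch in channel_order:
        if ch not in pivot.columns:
            pivot[ch] = None
    pivot = pivot[channel_order]
    meta = decisions.groupby(["sample_id", "repeat"]).agg(
        truth=("truth", "first"), fold=("fold", "first")
    )
    meta = meta.loc[pivot.index]
    votes = pivot.fillna(ABSTAIN).to_numpy(dtype=object)
    return votes, meta.reset_index()


def _one_hot(votes: np.ndarray, classes: list[str]) -> np.ndarray:
    cats = list(classes) + [ABSTAIN]
    out = np.zeros((votes.shape[0], votes.shape[1] * len(cats)))
    for j in range(votes.shape[1]):
        for k, cls in enumerate(cats):
            out[:, j * len(cats) + k] = votes[:, j] == cls
    return out


class Stacker:
    """Meta-classifier over one-hot-encoded channel votes."""

    def __init__(self, meta: str = "svm", n_trees: int = 80, seed: int = 0):
        if meta not in ("svm", "random_forest"):
            raise ConfigError(f"unknown meta classifier {meta!r}")
        self.meta = meta
        self.n_trees = n_trees
        self.seed = int(seed) % (2**31)
        self.classes: list[str] = []
        self.channel_order: list[str] = []
        self.model = None

    @property
    def n_estimators(self) -> int | None:
        if self.meta == "random_forest" and self.model is not None:
            return self.model.n_estimators
        return None

    def fit(self, votes: np.ndarray, truth: np.ndarray, classes: list[str],
            channel_order: list[str]) -> "Stacker":
        self.classes = list(classes)
        self.channel_order = list(channel_order)
        X = _one_hot(votes, self.classes)
        if self.meta == "svm":
            self.model = SVC(kernel="linear", random_state=self.seed)
        else:
            self.model = RandomForestClassifier(
                n_estimators=self.n_trees, random_state=self.seed
            )
        self.model.fit(X, truth)
        return self

    def predict(self, votes: np.ndarray) -> np.ndarray:
        return self.model.predict(_one_hot(votes, self.classes))


def fit_stacker(
    train_decisions: pd.DataFrame,
    meta: str = "svm",
    seed: int = 0,
    n_trees: int = 80,
    channel_order: list[str] | None = None,
    test_sample_ids=None,
) -> Stacker:
    """Fit a stacking meta-model on out-of-fold channel predictions.

    Raises :class:`LeakageError` if any training row belongs to a sample
    flagged as test.
    """
    if test_sample_ids is not None:
        overlap = set(train_decisions["sample_id"]) & set(test_sample_ids)
        if overlap:
            raise LeakageError(
                f"test samples present in stacker training input: {sorted(overlap)[:5]}"
            )
    if channel_order is None:
        present = set(train_decisions["channel"])
        channel_order = [c.key for c in ALL_CHANNELS if c.key in present]
    classes = sorted(set(train_decisions["truth"]) | set(train_decisions["pred"]))
    votes, info = _vote_matrix(train_decisions, channel_order)
    return Stacker(meta, n_trees, seed).fit(
        votes, info["truth"].to_numpy(), classes, channel_order
    )


# --- top-level fusion ------------------------------------------------------------

def _groups(channel_keys: list[str], level: str) -> dict[str, list[str]]:
    if level == "all":
        return {"all": list(channel_keys)}
    if level == "per_modality":
        out: dict[str, list[str]] = {}
        for ck in channel_keys:
            out.setdefault(channel_from_key(ck).modality.value, []).append(ck)
        return out
    out = {}
    for ck in channel_keys:
        out.setdefault(f"SDS{channel_from_key(ck).sds}", []).append(ck)
    return out


@dataclass
class FusionResult:
    spec: FusionSpec
    fused: pd.DataFrame  # sample_id, repeat, group, fold, truth, pred
    reports: dict[str, PerformanceReport] = field(default_factory=dict)
    n_unfusable: int = 0


def fuse(decisions: pd.DataFrame, spec: FusionSpec) -> FusionResult:
    """Fuse per-channel decisions within each channel group of ``spec.level``.

    The decision table must hold out-of-fold predictions with columns
    sample_id, channel, repeat, fold, truth, pred (plus optional score_*
    columns used for majority tie-breaking).  Weighted voting derives each
    fold's weights from the other folds' accuracies; stacking trains the meta
    model per fold on the remaining folds.
    """
    channel_keys = [c.key for c in ALL_CHANNELS if c.key in set(decisions["channel"])]
    if not channel_keys:
        raise DataError("decision table contains no known channels")
    classes = sorted(set(decisions["truth"]) | set(decisions["pred"]))
    score_cols = {
        c[len("score_"):]: c for c in decisions.columns if c.startswith("score_")
    }
    rows = []
    n_unfusable = 0

    for group_name, group_channels in _groups(channel_keys, spec.level).items():
        gdec = decisions[decisions["channel"].isin(group_channels)]
        # fold assignments are repeat-specific, so training-fold exclusion for
        # weights and stacking must stay within the sample's own repeat
        for rep, rdec in gdec.groupby("repeat"):
            votes, info = _vote_matrix(rdec, group_channels)

            if spec.method == "stacking":
                pred = np.empty(len(info), dtype=object)
                for f in sorted(info["fold"].unique()):
                    te_mask = (info["fold"] == f).to_numpy()
                    stk = fit_stacker(
                        rdec[rdec["fold"] != f],
                        meta=spec.meta,
                        seed=spec.seed,
                        n_trees=spec.n_trees,
                        channel_order=group_channels,
                        test_sample_ids=info.loc[te_mask, "sample_id"],
                    )
                    pred[te_mask] = stk.predict(votes[te_mask])
                for i in range(len(info)):
                    rows.append(
                        {
                            "sample_id": info["sample_id"].iat[i],
                            "repeat": rep,
                            "group": group_name,
                            "fold": info["fold"].iat[i],
                            "truth": info["truth"].iat[i],
                            "pred": pred[i],
                        }
                    )
                continue

            fold_weights = {
                f: channel_weights(rdec, exclude_fold=f)
                for f in sorted(rdec["fold"].unique())
            }
            if spec.weights is not None:
                fold_weights = {f: spec.weights for f in fold_weights}

            for i in range(len(info)):
                vote_map = {
                    ch: (votes[i, j] if votes[i, j] != ABSTAIN else None)
                    for j, ch in enumerate(group_channels)
                }
                try:
                    if spec.method == "majority":
                        scores = None
                        if score_cols:
                            sid = info["sample_id"].iat[i]
                            sub = rdec[rdec["sample_id"] == sid]
                            scores = {
                                cls: float(sub[col].sum())
                                for cls, col in score_cols.items()
                            }
                        pred_i = majority_vote(
                            vote_map.values(), scores=scores, priority=spec.priority
                        )
                    else:
                        w = fold_weights[info["fold"].iat[i]]
                        pred_i = weighted_vote(vote_map, w, priority=spec.priority)
                except DataError:
                    n_unfusable += 1
                    continue
                rows.append(
                    {
                        "sample_id": info["sample_id"].iat[i],
                        "repeat": rep,
                        "group": group_name,
                        "fold": info["fold"].iat[i],
                        "truth": info["truth"].iat[i],
                        "pred": pred_i,
                    }
                )

    fused = pd.DataFrame(rows)
    result = FusionResult(spec=spec, fused=fused, n_unfusable=n_unfusable)
    if not fused.empty:
        for group_name, g in fused.groupby("group"):
            result.reports[group_name] = performance_report(
                g["truth"], g["pred"], classes, repeats=g["repeat"]
            )
    return result
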