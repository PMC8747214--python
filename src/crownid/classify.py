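"""Species classification: balanced random forests, feature selection,
out-of-bag evaluation, and the NOCAI comparability index.

The forest is "balanced" in the bootstrap sense: every tree draws, with
replacement, an equal number of samples from each class — the minority-class
count — so imbalanced training sets do not bias the vote. Out-of-bag (OOB)
predictions come from the trees for which a sample was not drawn; OOB
accuracy is the headline figure, averaged over 20 independently seeded
forests in the standard protocol.

Feature selection runs in three stages: (1) permutation-importance (MDA)
filtering, (2) removal of one member of every feature pair correlated beyond
|r| > 0.9 (the lower-MDA member goes), and (3) a two-phase stepwise
selection in the style of the VSURF heuristic — rank by mean MDA over
repeated forests, drop features indistinguishable from the permutation null,
then ascend through the ranking keeping features that reduce mean OOB error.

MDA here is the raw OOB permutation accuracy decrease expressed in
percentage points; the default retention threshold of 0.1 therefore means "a
permutation of this feature costs at least 0.1 points of OOB accuracy".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .species import TREE_TYPE

# ---------------------------------------------------------------------------
# rounding (report convention: percentages pass through one decimal place)
# ---------------------------------------------------------------------------


def round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10.0**ndigits
    return np.floor(x * scale + 0.5) / scale


def percent_whole(fraction: float) -> int:
    """Fraction -> whole percent, rounding half-up through one decimal place."""
    return int(round_half_up(round_half_up(fraction * 100.0, 1), 0))


# ---------------------------------------------------------------------------
# grouping schemes
# ---------------------------------------------------------------------------

_FUNCTIONAL = {
    "BA": "Hardwood", "BE": "Hardwood", "MA": "Hardwood",
    "AS": "IntolerantHardwood", "BI": "IntolerantHardwood",
    "OK": "IntolerantHardwood", "PO": "IntolerantHardwood",
    "CE": "OtherSoftwood", "BF": "OtherSoftwood", "LA": "OtherSoftwood",
    "PI": "Pine", "SP": "Spruce",
}
_GENERA = {"MA": "Acer", "PI": "Pinus", "PO": "Populus", "SP": "Picea"}


@dataclass(frozen=True)
class GroupingScheme:
    """Partial map from species codes to class labels; unmapped crowns drop."""

    name: str
    mapping: dict[str, str]

    @property
    def k(self) -> int:
        return len(set(self.mapping.values()))

    def apply(self, labels: pd.Series) -> pd.Series:
        mapped = labels.map(self.mapping)
        return mapped.dropna()


GROUPINGS: dict[str, GroupingScheme] = {
    "type": GroupingScheme("type", {c: t.upper()[:2] for c, t in TREE_TYPE.items()}),
    "four_genera": GroupingScheme("four_genera", _GENERA),
    "functional_group": GroupingScheme("functional_group", _FUNCTIONAL),
    "twelve_species": GroupingScheme("twelve_species", {c: c for c in TREE_TYPE}),
}


# ---------------------------------------------------------------------------
# balanced random forest
# ---------------------------------------------------------------------------


class BalancedRandomForest:
    """Random forest with per-tree balanced bootstrap at minority-class size.

    Exposes OOB votes/predictions, Gini importance, and raw OOB permutation
    importance (MDA). Deterministic for a given seed.
    """

    def __init__(self, n_estimators: int = 500, seed: int = 0,
                 max_features: str = "sqrt"):
        self.n_estimators = n_estimators
        self.seed = seed
        self.max_features = max_features

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        counts = np.bincount(y_enc)
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 samples")
        n_min = int(counts.min())
        n, p = X.shape
        ss = np.random.SeedSequence(self.seed)
        self._tree_rngs = [np.random.default_rng(s) for s in ss.spawn(self.n_estimators)]
        self.trees_: list[DecisionTreeClassifier] = []
        self.inbag_: list[np.ndarray] = []  # boolean masks
        self.inbag_counts_: list[np.ndarray] = []  # per-sample draw counts
        by_class = [np.flatnonzero(y_enc == k) for k in range(len(counts))]
        votes = np.zeros((n, len(self.classes_)), dtype=np.int32)
        importances = np.zeros(p)
        for rng in self._tree_rngs:
            idx = np.concatenate([
                rng.choice(members, size=n_min, replace=True) for members in by_class
            ])
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[idx], y_enc[idx])
            inbag = np.zeros(n, dtype=bool)
            inbag[idx] = True
            self.inbag_counts_.append(np.bincount(idx, minlength=n))
            oob = ~inbag
            if oob.any():
                pred = tree.predict(X[oob])
                votes[np.flatnonzero(oob), pred] += 1
            self.trees_.append(tree)
            self.inbag_.append(inbag)
            importances += tree.feature_importances_
        self._X = X
        self._y = y_enc
        self.oob_votes_ = votes
        self.feature_importances_ = importances / self.n_estimators
        voted = votes.sum(axis=1) > 0
        self.oob_prediction_ = np.where(voted, votes.argmax(axis=1), -1)
        correct = (self.oob_prediction_ == y_enc) & voted
        self.oob_accuracy_ = float(correct.sum() / max(voted.sum(), 1))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        votes = np.zeros((len(X), len(self.classes_)), dtype=np.int32)
        for tree in self.trees_:
            votes[np.arange(len(X)), tree.predict(X)] += 1
        return self.classes_[votes.argmax(axis=1)]

    def oob_confusion(self) -> np.ndarray:
        """Confusion matrix of OOB votes; rows = true class, cols = predicted."""
        k = len(self.classes_)
        cm = np.zeros((k, k), dtype=int)
        voted = self.oob_prediction_ >= 0
        for t, pr in zip(self._y[voted], self.oob_prediction_[voted]):
            cm[t, pr] += 1
        return cm

    def mda(self) -> np.ndarray:
        """Raw OOB permutation importance in accuracy percentage points.

        Per-tree OOB accuracy drop after permuting one feature, averaged over
        ALL trees (trees that never split on the feature contribute zero) —
        the convention of the classic R implementation.
        """
        n, p = self._X.shape
        deltas = np.zeros(p)
        for tree, inbag, rng in zip(self.trees_, self.inbag_, self._tree_rngs):
            oob = np.flatnonzero(~inbag)
            if len(oob) == 0:
                continue
            Xo = self._X[oob]
            yo = self._y[oob]
            base = (tree.predict(Xo) == yo).mean()
            used = set(tree.tree_.feature[tree.tree_.feature >= 0])
            perm = rng.permutation(len(oob))
            for j in range(p):
                if j not in used:
                    continue
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                acc = (tree.predict(Xp) == yo).mean()
                deltas[j] += base - acc
        return deltas / self.n_estimators * 100.0


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


class EmptySelectionError(ValueError):
    """All features were eliminated by a selection stage."""


@dataclass
class SelectionResult:
    all_features: list[str]
    after_mda: list[str]
    after_correlation: list[str]
    final: list[str]
    mda_scores: dict[str, float] = field(default_factory=dict)
    removal_log: list[str] = field(default_factory=list)
    step_log: list[dict] = field(default_factory=list)

    def validate_nesting(self) -> bool:
        return (
            set(self.final) <= set(self.after_correlation)
            <= set(self.after_mda) <= set(self.all_features)
        )


def mda_filter(
    table: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 0.1,
    seed: int = 0,
    n_estimators: int = 300,
) -> SelectionResult:
    """Stage 1: drop features whose permutation importance is <= threshold."""
    X = table.to_numpy(float)
    y = labels.loc[table.index].to_numpy()
    forest = BalancedRandomForest(n_estimators=n_estimators, seed=seed).fit(X, y)
    scores = dict(zip(table.columns, forest.mda()))
    kept = [c for c in table.columns if scores[c] > threshold]
    if not kept:
        raise EmptySelectionError("MDA filter removed every feature")
    return SelectionResult(
        all_features=list(table.columns), after_mda=kept,
        after_correlation=kept, final=kept, mda_scores=scores,
        removal_log=[f"mda<= {threshold}: {c} ({scores[c]:.3f})"
                     for c in table.columns if c not in kept],
    )


def correlation_filter(
    table: pd.DataFrame,
    selection: SelectionResult,
    r_max: float = 0.9,
) -> SelectionResult:
    """Stage 2: among |r| > r_max pairs keep the larger-MDA member.

    Features are visited in descending MDA order; a feature survives only if
    it is not over-correlated with any already-kept feature.
    """
    feats = sorted(selection.after_mda, key=lambda c: -selection.mda_scores[c])
    corr = table[feats].corr().abs()
    kept: list[str] = []
    log = list(selection.removal_log)
    for c in feats:
        partner = next((k for k in kept if corr.loc[c, k] > r_max), None)
        if partner is None:
            kept.append(c)
        else:
            log.append(f"|r|>{r_max} with {partner}: dropped {c} "
                       f"(mda {selection.mda_scores[c]:.3f})")
    kept = [c for c in selection.after_mda if c in set(kept)]  # original order
    return SelectionResult(
        all_features=selection.all_features, after_mda=selection.after_mda,
        after_correlation=kept, final=kept,
        mda_scores=selection.mda_scores, removal_log=log,
    )


def vsurf_select(
    table: pd.DataFrame,
    labels: pd.Series,
    selection: SelectionResult,
    n_perm: int = 50,
    seed: int = 0,
    n_estimators: int = 100,
    step_repeats: int = 3,
) -> SelectionResult:
    """Stage 3: two-phase stepwise selection (VSURF-style heuristic).

    Phase 1 ranks features by mean MDA over ``n_perm`` forests and drops
    those indistinguishable from the permutation null (threshold = mean +
    1 sd of the magnitudes of negative MDAs). Phase 2 ascends through the
    ranking, keeping a feature iff adding it lowers mean OOB error (over
    ``step_repeats`` forests) by more than one between-forest sd.
    """
    feats = selection.after_correlation
    X = table[feats].to_numpy(float)
    y = labels.loc[table.index].to_numpy()
    ss = np.random.SeedSequence(seed)
    n_seeds = n_perm + step_repeats * (len(feats) + 2)
    seeds = [int(s) for s in ss.generate_state(n_seeds) % 2**31]

    mdas = np.zeros((n_perm, len(feats)))
    for i in range(n_perm):
        forest = BalancedRandomForest(n_estimators=n_estimators, seed=seeds[i]).fit(X, y)
        mdas[i] = forest.mda()
    mean_mda = mdas.mean(axis=0)
    neg = np.abs(mdas[mdas < 0])
    null_thr = float(neg.mean() + neg.std()) if len(neg) else 0.0
    order = np.argsort(-mean_mda)
    ranked = [feats[i] for i in order if mean_mda[i] > null_thr]
    if not ranked:
        ranked = [feats[int(order[0])]]

    def mean_err(cols: list[str], at: int) -> tuple[float, float]:
        errs = []
        sub = table[cols].to_numpy(float)
        for r in range(step_repeats):
            f = BalancedRandomForest(n_estimators=n_estimators,
                                     seed=seeds[n_perm + at * step_repeats + r])
            errs.append(1.0 - f.fit(sub, y).oob_accuracy_)
        return float(np.mean(errs)), float(np.std(errs))

    current: list[str] = [ranked[0]]
    cur_err, cur_sd = mean_err(current, 0)
    steps = [{"feature": ranked[0], "accepted": True, "oob_error": cur_err}]
    for at, feat in enumerate(ranked[1:], start=1):
        trial = current + [feat]
        err, sd = mean_err(trial, at)
        tol = max(cur_sd, sd, 1e-4)
        accepted = err < cur_err - tol
        steps.append({"feature": feat, "accepted": accepted, "oob_error": err})
        if accepted:
            current, cur_err, cur_sd = trial, err, sd
    return SelectionResult(
        all_features=selection.all_features, after_mda=selection.after_mda,
        after_correlation=feats, final=current,
        mda_scores=selection.mda_scores, removal_log=selection.removal_log,
        step_log=steps,
    )


def select_features(
    table: pd.DataFrame,
    labels: pd.Series,
    mda_threshold: float = 0.1,
    r_max: float = 0.9,
    n_perm: int = 50,
    seed: int = 0,
    n_estimators: int = 300,
    vsurf_estimators: int = 100,
) -> SelectionResult:
    """MDA filter -> correlation filter -> VSURF-style stepwise selection."""
    stage1 = mda_filter(table, labels, mda_threshold, seed, n_estimators)
    stage2 = correlation_filter(table, stage1, r_max)
    return vsurf_select(table, labels, stage2, n_perm, seed, vsurf_estimators)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------


def train_balanced_rf(
    table: pd.DataFrame,
    labels: pd.Series,
    selected: list[str] | None = None,
    seed: int = 0,
    n_estimators: int = 500,
) -> BalancedRandomForest:
    cols = selected or list(table.columns)
    X = table[cols].to_numpy(float)
    y = labels.loc[table.index].to_numpy()
    return BalancedRandomForest(n_estimators=n_estimators, seed=seed).fit(X, y)


@dataclass
class ClassificationReport:
    grouping: str
    feature_set_id: str
    features: list[str]
    run_accuracies: list[float]
    mean_accuracy: float
    confusion: pd.DataFrame  # OOB votes of the designated (first) run
    per_class_percent: dict[str, int | None]
    gini_ranking: list[tuple[str, float]]
    nocai: float
    k: int

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "feature_set_id": self.feature_set_id,
            "features": self.features,
            "run_accuracies": self.run_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.to_dict(),
            "per_class_percent": self.per_class_percent,
            "gini_ranking": self.gini_ranking,
            "nocai": self.nocai,
            "k": self.k,
        }


def per_class_accuracy(confusion: pd.DataFrame | np.ndarray) -> dict[str, int | None]:
    """Per-class OOB accuracy in whole percent (diagonal over row sum).

    Percentages pass through one decimal place before the final integer
    rounding (both half-up). Zero rows report None.
    """
    cm = pd.DataFrame(confusion)
    if (cm.to_numpy() < 0).any():
        raise ValueError("confusion matrix must be non-negative")
    out: dict[str, int | None] = {}
    for cls in cm.index:
        row = cm.loc[cls]
        total = int(row.sum())
        out[str(cls)] = percent_whole(row[cls] / total) if total else None
    return out


def nocai(accuracy: float, k: int) -> float:
    """Accuracy over the 1/k random-assignment expectation, to one decimal."""
    if not 0 <= accuracy <= 1:
        raise ValueError("accuracy must be in [0, 1]")
    if k < 2:
        raise ValueError("k must be >= 2")
    return round_half_up(accuracy * k, 1)


def evaluate(
    table: pd.DataFrame,
    labels: pd.Series,
    grouping: str | GroupingScheme,
    feature_set_id: str = "all",
    selected: list[str] | None = None,
    n_runs: int = 20,
    seed: int = 0,
    n_estimators: int = 500,
) -> ClassificationReport:
    """Mean OOB accuracy over ``n_runs`` forests plus diagnostics.

    ``feature_set_id``: 'all' (the selected set, or every column), '3D', 'I'
    (name-prefix subsets), 'top25'/'top15' (by Gini importance of a full
    model). Feature selection is done once upstream; runs differ only in the
    forest seed.
    """
    scheme = GROUPINGS[grouping] if isinstance(grouping, str) else grouping
    mapped = scheme.apply(labels)
    idx = table.index.intersection(mapped.index)
    table = table.loc[idx]
    mapped = mapped.loc[idx]

    cols = selected or list(table.columns)
    if feature_set_id == "3D":
        cols = [c for c in cols if c.startswith("3D_")]
    elif feature_set_id == "I":
        cols = [c for c in cols if c.startswith("I_")]
    elif feature_set_id in ("top25", "top15"):
        n_top = int(feature_set_id[3:])
        ref = train_balanced_rf(table, mapped, cols, seed=seed,
                                n_estimators=n_estimators)
        rank = np.argsort(-ref.feature_importances_)
        cols = [cols[i] for i in rank[:n_top]]
    elif feature_set_id != "all":
        raise ValueError(f"unknown feature_set_id {feature_set_id!r}")
    if not cols:
        raise ValueError("empty feature set")

    accs = []
    first = None
    for r in range(n_runs):
        forest = train_balanced_rf(table, mapped, cols, seed=seed + r,
                                   n_estimators=n_estimators)
        accs.append(forest.oob_accuracy_)
        if first is None:
            first = forest
    cm = pd.DataFrame(first.oob_confusion(), index=first.classes_,
                      columns=first.classes_)
    mean_acc = float(np.mean(accs))
    k = scheme.k
    gini = sorted(zip(cols, first.feature_importances_), key=lambda t: -t[1])
    return ClassificationReport(
        grouping=scheme.name, feature_set_id=feature_set_id, features=cols,
        run_accuracies=[float(a) for a in accs], mean_accuracy=mean_acc,
        confusion=cm, per_class_percent=per_class_accuracy(cm),
        gini_ranking=[(c, float(g)) for c, g in gini],
        nocai=nocai(mean_acc, k), k=k,
    )
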