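"""Behavioural classification of GPS fixes: rest / commute / forage.

Candidate classifiers combine up to three information streams — path
geometry (step length and signed turning angle; always present), habitat
(land-cover class at the fix) and body movement (ground speed plus the
accelerometer-derived class) — with a moving input window of 1, 3 or 5
points, giving 12 candidate input structures.  For each structure an
ensemble of decision trees (random forest) is tuned over tree count and
depth by grouped cross-validation on the training half of the
individuals; the structure with the best internal Cohen's kappa is
selected and validated on the held-out individuals, which never
contribute to training or selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold

from .trackdata import great_circle_km, initial_bearing_rad

CLASSES = ("rest", "commute", "forage")
STREAM_SETS = (
    ("geometry",),
    ("geometry", "habitat"),
    ("geometry", "body"),
    ("geometry", "habitat", "body"),
)
WINDOWS = (1, 3, 5)


@dataclass(frozen=True)
class CandidateStructure:
    streams: tuple
    window: int

    def __post_init__(self):
        if "geometry" not in self.streams:
            raise ValueError("geometry stream is always required")
        if self.window not in WINDOWS:
            raise ValueError(f"window must be one of {WINDOWS}")

    def label(self) -> str:
        return "+".join(self.streams) + f"|w{self.window}"


def all_structures() -> list[CandidateStructure]:
    """The 12 candidate input structures (4 stream sets x 3 windows)."""
    return [CandidateStructure(s, w) for s in STREAM_SETS for w in WINDOWS]


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------


def _point_features(fixes: pd.DataFrame, streams: tuple) -> pd.DataFrame:
    """Per-fix features for one time-sorted individual; endpoints get NaN
    geometry (no previous/next fix) and are dropped by the windowing."""
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    n = len(fixes)
    step = np.full(n, np.nan)
    turn = np.full(n, np.nan)
    if n >= 2:
        step[1:] = great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:]) * 1000.0
    if n >= 3:
        b_in = initial_bearing_rad(lat[:-2], lon[:-2], lat[1:-1], lon[1:-1])
        b_out = initial_bearing_rad(lat[1:-1], lon[1:-1], lat[2:], lon[2:])
        d = b_out - b_in
        # bearings are clockwise from north, so a left turn decreases the
        # bearing: negate and wrap to (-pi, pi] for left-positive angles
        turn[1:-1] = -(np.mod(d + np.pi, 2.0 * np.pi) - np.pi)
    out = pd.DataFrame({"step_length": step, "turning_angle": turn}, index=fixes.index)
    if "body" in streams:
        out["ground_speed"] = fixes["ground_speed"].to_numpy(dtype=float)
        out["acc_class"] = fixes["acc_class"].astype(str).to_numpy()
    if "habitat" in streams:
        out["habitat"] = fixes["habitat"].astype(str).to_numpy()
    return out


def _one_hot(values: np.ndarray, categories: list, name: str) -> pd.DataFrame:
    cols = {}
    known = set(categories)
    unseen = sorted(set(values) - known)
    if unseen:
        warnings.warn(f"unseen {name} categories at prediction time: {unseen}; "
                      "encoded as all-zeros", stacklevel=3)
    for c in categories:
        cols[f"{name}={c}"] = (values == c).astype(float)
    return pd.DataFrame(cols)


def extract_features(fixes: pd.DataFrame, structure: CandidateStructure,
                     label_col: str | None = "true_behaviour",
                     categories: dict | None = None
                     ) -> tuple[pd.DataFrame, pd.Series | None, dict]:
    """Windowed feature matrix (and labels) for a fix table.

    The window concatenates the focal fix's features with those of the
    (window-1)/2 previous and following fixes; rows without the full
    context (track ends) are dropped.  ``categories`` fixes the one-hot
    vocabularies of habitat/acc_class (pass the dict returned at
    training time when predicting).  Individuals with too few fixes for
    the window are skipped with a warning.
    """
    half = (structure.window - 1) // 2
    blocks_X, blocks_y, keys = [], [], []
    cats = dict(categories or {})
    learn_cats = categories is None
    pieces = []
    for ind, grp in fixes.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        if len(grp) < max(3, structure.window):
            warnings.warn(f"individual {ind!r} has too few fixes for window "
                          f"{structure.window}; skipped", stacklevel=2)
            continue
        pf = _point_features(grp, structure.streams)
        pieces.append((ind, grp, pf))
    if learn_cats:
        for name in ("habitat", "acc_class"):
            vals = sorted(set().union(*[set(pf[name].dropna()) for _, _, pf in pieces
                                        if name in pf.columns]) if pieces else set())
            if any(name in pf.columns for _, _, pf in pieces):
                cats[name] = vals
    for ind, grp, pf in pieces:
        num_cols = [c for c in pf.columns if c not in ("habitat", "acc_class")]
        enc = [pf[num_cols].reset_index(drop=True)]
        for name in ("habitat", "acc_class"):
            if name in pf.columns:
                enc.append(_one_hot(pf[name].to_numpy(), cats.get(name, []), name))
        base = pd.concat(enc, axis=1)
        n = len(base)
        offs = range(-half, half + 1)
        shifted = []
        for o in offs:
            s = base.shift(-o)
            s.columns = [f"{c}@{o:+d}" if o else c for c in base.columns]
            shifted.append(s)
        X = pd.concat(shifted, axis=1)
        valid = X.notna().all(axis=1)
        blocks_X.append(X.loc[valid])
        if label_col is not None:
            y = grp[label_col].reset_index(drop=True)
            blocks_y.append(y.loc[valid.to_numpy()])
        keys.extend([ind] * int(valid.sum()))
    if not blocks_X:
        return pd.DataFrame(), (pd.Series(dtype=object) if label_col else None), cats
    Xall = pd.concat(blocks_X, ignore_index=True)
    Xall["individual_id"] = keys
    yall = pd.concat(blocks_y, ignore_index=True) if label_col is not None else None
    return Xall, yall, cats


def split_by_individual(fixes: pd.DataFrame, fraction: float = 0.5,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random split at the individual level: no bird contributes to both
    the training and the validation side."""
    rng = rng or np.random.default_rng()
    inds = np.array(sorted(fixes["individual_id"].unique()))
    if len(inds) < 2:
        raise ValueError("need at least two individuals to split")
    n_train = int(round(fraction * len(inds)))
    n_train = min(max(n_train, 1), len(inds) - 1)
    train_ids = set(rng.choice(inds, size=n_train, replace=False))
    is_train = fixes["individual_id"].isin(train_ids)
    return fixes.loc[is_train].copy(), fixes.loc[~is_train].copy()


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def metrics_from_confusion(confusion: np.ndarray, labels=CLASSES) -> dict:
    """Accuracy, Cohen's kappa and per-class precision/recall/specificity
    from a confusion matrix with rows = truth, columns = prediction."""
    C = np.asarray(confusion, dtype=float)
    N = C.sum()
    if N == 0:
        raise ValueError("empty confusion matrix")
    acc = np.trace(C) / N
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    p_e = float((row * col).sum() / N ** 2)
    kappa = 0.0 if abs(1.0 - p_e) < 1e-15 else (acc - p_e) / (1.0 - p_e)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.diag(C) / col
        recall = np.diag(C) / row
    tn = N - row - col + np.diag(C)
    with np.errstate(invalid="ignore", divide="ignore"):
        specificity = tn / (N - row)
    return dict(
        accuracy=float(acc), kappa=float(kappa),
        precision={l: float(p) for l, p in zip(labels, precision)},
        recall={l: float(r) for l, r in zip(labels, recall)},
        specificity={l: float(s) for l, s in zip(labels, specificity)},
        confusion=C,
    )


def _kappa(y_true, y_pred, labels=CLASSES) -> float:
    idx = {l: i for i, l in enumerate(labels)}
    C = np.zeros((len(labels), len(labels)))
    for t, p in zip(y_true, y_pred):
        C[idx[t], idx[p]] += 1
    return metrics_from_confusion(C, labels)["kappa"]


# ---------------------------------------------------------------------------
# training, selection, evaluation
# ---------------------------------------------------------------------------


@dataclass
class FittedAnnotator:
    model: RandomForestClassifier
    structure: CandidateStructure
    categories: dict
    train_individuals: set
    n_trees: int
    tree_depth: int | None
    selection_trace: pd.DataFrame

    def predict(self, fixes: pd.DataFrame) -> pd.Series:
        X, _, _ = extract_features(fixes, self.structure, label_col=None,
                                   categories=self.categories)
        feats = X.drop(columns=["individual_id"])
        return pd.Series(self.model.predict(feats), index=feats.index, name="pred_behaviour")


@dataclass
class TrainingReport:
    best_structure: CandidateStructure
    n_trees: int
    tree_depth: int | None
    accuracy: float
    kappa: float
    confusion: np.ndarray
    precision: dict
    recall: dict
    specificity: dict
    flagged_empty_classes: list = field(default_factory=list)


DEFAULT_TREE_GRID = (25, 50)
DEFAULT_DEPTH_GRID = (5, None)


def train_select(train_fixes: pd.DataFrame, seed: int = 0,
                 tree_grid=DEFAULT_TREE_GRID, depth_grid=DEFAULT_DEPTH_GRID,
                 n_folds: int = 3, label_col: str = "true_behaviour"
                 ) -> FittedAnnotator:
    """Tune and select among the 12 candidate structures on training birds only.

    For each structure, tree count and depth are tuned by grouped
    k-fold cross-validation (folds split by individual) on the training
    half; the structure maximising internal Cohen's kappa wins, with
    ties broken toward smaller windows and fewer streams.  The selected
    configuration is refit on the full training half.
    """
    present = set(train_fixes[label_col].unique())
    missing = [c for c in CLASSES if c not in present]
    if missing:
        raise ValueError(f"training data lacks behaviour class(es): {missing}")
    trace_rows = []
    best = None
    for structure in all_structures():
        X, y, cats = extract_features(train_fixes, structure, label_col=label_col)
        groups = X["individual_id"].to_numpy()
        feats = X.drop(columns=["individual_id"])
        k = min(n_folds, len(np.unique(groups)))
        best_grid = None
        for n_trees in tree_grid:
            for depth in depth_grid:
                preds = np.empty(len(y), dtype=object)
                if k >= 2:
                    for tr_idx, te_idx in GroupKFold(n_splits=k).split(feats, y, groups):
                        clf = RandomForestClassifier(
                            n_estimators=n_trees, max_depth=depth, random_state=seed)
                        clf.fit(feats.iloc[tr_idx], y.iloc[tr_idx])
                        preds[te_idx] = clf.predict(feats.iloc[te_idx])
                else:
                    clf = RandomForestClassifier(
                        n_estimators=n_trees, max_depth=depth, random_state=seed)
                    clf.fit(feats, y)
                    preds[:] = clf.predict(feats)
                kap = _kappa(y.to_numpy(), preds)
                acc = float((preds == y.to_numpy()).mean())
                cand = (kap, n_trees, depth, acc)
                if best_grid is None or cand[0] > best_grid[0]:
                    best_grid = cand
        kap, n_trees, depth, acc = best_grid
        trace_rows.append(dict(structure=structure.label(), window=structure.window,
                               streams=len(structure.streams), n_trees=n_trees,
                               tree_depth=-1 if depth is None else depth,
                               internal_kappa=kap, internal_accuracy=acc))
        key = (kap, -structure.window, -len(structure.streams))
        if best is None or key > best[0]:
            best = (key, structure, n_trees, depth, cats)
    _, structure, n_trees, depth, cats = best
    X, y, cats = extract_features(train_fixes, structure, label_col=label_col)
    feats = X.drop(columns=["individual_id"])
    model = RandomForestClassifier(n_estimators=n_trees, max_depth=depth, random_state=seed)
    model.fit(feats, y)
    return FittedAnnotator(model, structure, cats,
                           set(train_fixes["individual_id"].unique()),
                           n_trees, depth, pd.DataFrame(trace_rows))


def evaluate(annotator: FittedAnnotator, validation_fixes: pd.DataFrame,
             label_col: str = "true_behaviour") -> TrainingReport:
    """Validation metrics on held-out individuals (must be disjoint from
    the training birds)."""
    overlap = annotator.train_individuals & set(validation_fixes["individual_id"].unique())
    if overlap:
        raise ValueError(f"validation individuals overlap training: {sorted(overlap)}")
    X, y, _ = extract_features(validation_fixes, annotator.structure,
                               label_col=label_col, categories=annotator.categories)
    feats = X.drop(columns=["individual_id"])
    preds = annotator.model.predict(feats)
    idx = {l: i for i, l in enumerate(CLASSES)}
    C = np.zeros((3, 3))
    for t, p in zip(y.to_numpy(), preds):
        C[idx[t], idx[p]] += 1
    m = metrics_from_confusion(C)
    empty = [c for c in CLASSES if C[idx[c]].sum() == 0]
    if empty:
        warnings.warn(f"validation lacks class(es) {empty}; their recall is undefined",
                      stacklevel=2)
    return TrainingReport(annotator.structure, annotator.n_trees, annotator.tree_depth,
                          m["accuracy"], m["kappa"], C, m["precision"], m["recall"],
                          m["specificity"], flagged_empty_classes=empty)
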