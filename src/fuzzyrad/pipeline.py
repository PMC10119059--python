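"""Harmonized Monte-Carlo cross-validation and the mixed voting ensemble.

The scheme mirrors a 100-fold Monte-Carlo cross-validation with a 90/10
train-test ratio in which

* the per-class test size is 10% of the *minority* class (floored, at
  least 1), so every test subset is exactly class-balanced;
* test lesions are drawn patient-wise — no patient contributes lesions
  to both sides of a split — and only unique folds are accepted;
* the identical fold list is reused for all four delineation tables;
* each training subset is balanced with SMOTE (synthetic minority rows
  as convex combinations of minority nearest neighbors);
* features are ranked by univariate R-squared against the binary label
  and the top f = ceil(sqrt(0.9 * 2 * M)) are kept, M being the
  majority-class training count before SMOTE;
* the classifier is a fixed-hyperparameter ensemble of four random
  forests and one multi-Gaussian (class-conditional Gaussian density)
  model combined by majority vote; the vote fraction serves as the ROC
  score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier

from .errors import FoldError
from .tables import FeatureTable

__all__ = [
    "FoldSplit",
    "EnsembleConfig",
    "EnsembleModel",
    "MultiGaussianClassifier",
    "select_feature_count",
    "make_mc_folds",
    "smote_balance",
    "rank_features",
    "train_ensemble",
    "predict",
    "cross_validate",
]

DEFAULT_N_FOLDS = 100
DEFAULT_TEST_FRACTION = 0.10
_MAX_FOLD_RETRIES = 500

#: Fixed hyperparameter sets of the four random-forest voters.
DEFAULT_RF_PARAMS: tuple[dict, ...] = (
    dict(n_estimators=100, max_depth=None, max_features="sqrt", min_samples_leaf=1),
    dict(n_estimators=150, max_depth=8, max_features="sqrt", min_samples_leaf=2),
    dict(n_estimators=75, max_depth=None, max_features=0.5, min_samples_leaf=1),
    dict(n_estimators=125, max_depth=12, max_features="log2", min_samples_leaf=3),
)


def select_feature_count(majority_count: int, available: int | None = None) -> int:
    """Feature budget f = ceil(sqrt(0.9 * 2 * M)), floored at 1.

    ``M`` is the majority-class sample count of the training subset
    before oversampling; the budget is capped at the available feature
    count when given.
    """
    if majority_count < 1:
        raise ValueError("majority count must be >= 1")
    f = max(1, math.ceil(math.sqrt(0.9 * 2.0 * majority_count)))
    if available is not None:
        f = min(f, available)
    return f


@dataclass(frozen=True)
class FoldSplit:
    """One harmonized Monte-Carlo train/test split (lesion ids)."""

    fold_id: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    test_per_class: int

    def signature(self) -> frozenset:
        return frozenset(self.test_ids)


def _patients_by_class(meta: pd.DataFrame) -> dict[int, list[tuple[str, list[str]]]]:
    """Patients grouped by the label of their lesions (labels are
    patient-level: mixed-label patients are rejected)."""
    out: dict[int, list[tuple[str, list[str]]]] = {0: [], 1: []}
    for pid, grp in meta.groupby("patient_id", sort=True):
        labels = set(grp["label"].astype(int))
        if len(labels) != 1:
            raise FoldError(
                f"patient {pid} has lesions with both labels; patient-wise "
                "balanced test sampling requires patient-level labels"
            )
        out[labels.pop()].append((pid, list(grp.index)))
    return out


def _draw_class_test(
    patients: list[tuple[str, list[str]]], quota: int, rng: np.random.Generator
) -> list[str] | None:
    """Draw patients until the lesion quota is met exactly; None on failure."""
    for _ in range(50):
        order = rng.permutation(len(patients))
        picked: list[str] = []
        for idx in order:
            _, lesions = patients[idx]
            if len(picked) + len(lesions) <= quota:
                picked.extend(lesions)
                if len(picked) == quota:
                    return picked
        # overshoot everywhere -> reshuffle and retry
    return None


def make_mc_folds(
    meta: pd.DataFrame,
    n_folds: int = DEFAULT_N_FOLDS,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = 0,
) -> list[FoldSplit]:
    """Unique, patient-leak-free, class-balanced Monte-Carlo splits.

    ``meta`` is indexed by lesion_id with patient_id and label columns.
    """
    if meta.index.name != "lesion_id":
        meta = meta.set_index("lesion_id")
    labels = meta["label"].astype(int)
    counts = labels.value_counts()
    if len(counts) != 2:
        raise FoldError("both classes must be present")
    minority = int(counts.min())
    per_class = max(1, int(math.floor(test_fraction * minority)))
    by_class = _patients_by_class(meta)
    for cls in (0, 1):
        if sum(len(l) for _, l in by_class[cls]) < per_class + 1:
            raise FoldError(f"class {cls} too small for balanced test subsets")

    rng = np.random.default_rng(seed)
    folds: list[FoldSplit] = []
    seen: set[frozenset] = set()
    attempts = 0
    all_ids = list(meta.index)
    while len(folds) < n_folds:
        attempts += 1
        if attempts > _MAX_FOLD_RETRIES * n_folds:
            raise FoldError("exhausted retries generating unique folds")
        test: list[str] = []
        ok = True
        for cls in (0, 1):
            picked = _draw_class_test(by_class[cls], per_class, rng)
            if picked is None:
                ok = False
                break
            test.extend(picked)
        if not ok:
            raise FoldError("cannot meet the per-class test quota patient-wise")
        sig = frozenset(test)
        if sig in seen:
            continue
        seen.add(sig)
        test_patients = set(meta.loc[test, "patient_id"])
        train = [
            i for i in all_ids
            if i not in sig and meta.loc[i, "patient_id"] not in test_patients
        ]
        folds.append(
            FoldSplit(len(folds) + 1, tuple(train), tuple(test), per_class)
        )
    return folds


def smote_balance(
    x: np.ndarray, y: np.ndarray, seed: int = 0, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by synthetic minority oversampling.

    New rows are convex combinations of a minority row and one of its
    k nearest minority neighbors (k capped at minority-1).  Original
    rows are preserved and returned first.
    """
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE requires exactly two classes in the training set")
    minority_cls = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    need = int(n_maj - n_min)
    if need == 0:
        return x.copy(), y.copy()

    rng = np.random.default_rng(seed)
    minority = x[y == minority_cls]
    k_eff = min(k, n_min - 1)
    dist = cdist(minority, minority)
    np.fill_diagonal(dist, np.inf)
    nn = np.argsort(dist, axis=1)[:, :k_eff]

    base = rng.integers(0, n_min, size=need)
    pick = rng.integers(0, k_eff, size=need)
    lam = rng.uniform(0.0, 1.0, size=need)[:, None]
    synth = minority[base] + lam * (minority[nn[base, pick]] - minority[base])
    x_out = np.vstack([x, synth])
    y_out = np.concatenate([y, np.full(need, minority_cls)])
    return x_out, y_out


def rank_features(features: pd.DataFrame, labels: pd.Series | np.ndarray) -> list[str]:
    """Features ordered by descending univariate R^2 against the label.

    R^2 is the squared Pearson (point-biserial) correlation; features
    with zero variance get R^2 = 0; ties break by feature name.
    """
    y = np.asarray(labels, dtype=float)
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    scores = {}
    for name in features.columns:
        v = features[name].to_numpy(dtype=float)
        vc = v - v.mean()
        sv = np.sqrt((vc**2).sum())
        if sv == 0 or sy == 0:
            scores[name] = 0.0
        else:
            r = float((vc * yc).sum() / (sv * sy))
            scores[name] = r * r
    return sorted(features.columns, key=lambda n: (-scores[n], n))


class MultiGaussianClassifier:
    """Class-conditional multivariate Gaussian density classifier.

    Each class is modelled by its maximum-likelihood mean and
    covariance with ridge shrinkage (lambda = 1e-3 * trace / d); a
    sample is assigned to the class of higher likelihood under equal
    priors (training sets are SMOTE-balanced).
    """

    def __init__(self, ridge: float = 1e-3):
        self.ridge = ridge

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MultiGaussianClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need two classes to fit")
        self._params = {}
        d = x.shape[1]
        for cls in self.classes_:
            xc = x[y == cls]
            mu = xc.mean(axis=0)
            cov = np.cov(xc, rowvar=False, bias=True).reshape(d, d)
            cov = cov + self.ridge * (np.trace(cov) / d + 1e-12) * np.eye(d)
            sign, logdet = np.linalg.slogdet(cov)
            self._params[int(cls)] = (mu, np.linalg.inv(cov), logdet)
        return self

    def _log_likelihood(self, x: np.ndarray) -> np.ndarray:
        lls = []
        for cls in self.classes_:
            mu, prec, logdet = self._params[int(cls)]
            diff = x - mu
            maha = np.einsum("ij,jk,ik->i", diff, prec, diff)
            lls.append(-0.5 * (maha + logdet))
        return np.stack(lls, axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        ll = self._log_likelihood(np.asarray(x, dtype=float))
        return self.classes_[np.argmax(ll, axis=1)]


@dataclass
class EnsembleConfig:
    rf_params: tuple[dict, ...] = DEFAULT_RF_PARAMS
    mg_ridge: float = 1e-3


@dataclass
class EnsembleModel:
    """Four random forests + one multi-Gaussian voter, majority vote."""

    voters: list
    feature_names: list[str]

    def vote_matrix(self, x: np.ndarray) -> np.ndarray:
        return np.stack([np.asarray(v.predict(x), dtype=int) for v in self.voters])


def train_ensemble(
    x: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    config: EnsembleConfig | None = None,
) -> EnsembleModel:
    """Fit the five fixed-hyperparameter voters on a balanced train set."""
    config = config or EnsembleConfig()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rf_seeds = np.random.SeedSequence(seed).generate_state(len(config.rf_params))
    voters: list = [
        RandomForestClassifier(random_state=int(s % (2**31)), n_jobs=1, **params).fit(x, y)
        for params, s in zip(config.rf_params, rf_seeds)
    ]
    voters.append(MultiGaussianClassifier(config.mg_ridge).fit(x, y))
    return EnsembleModel(voters, list(feature_names))


def predict(model: EnsembleModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and the vote-fraction score in {0,.2,...,1}."""
    if x.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {x.shape[1]}"
        )
    votes = model.vote_matrix(x)
    score = votes.mean(axis=0)
    labels = (score > 0.5).astype(int)  # 5 voters -> no ties
    return labels, score


def cross_validate(
    table: FeatureTable,
    folds: list[FoldSplit],
    seed: int = 0,
    config: EnsembleConfig | None = None,
) -> pd.DataFrame:
    """Run the full per-fold pipeline on one delineation table.

    Returns one row per test prediction: lesion_id, fold_id,
    delineation, true label, predicted label and vote score.
    """
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(2 * len(folds)).reshape(-1, 2)
    # Eq.-1 budget from the whole (pre-SMOTE) dataset's majority count,
    # matching the printed per-cohort selected-feature counts
    majority = int(np.bincount(table.labels.to_numpy()).max())
    f = select_feature_count(majority, available=len(table.feature_names))
    rows = []
    for fold, (smote_seed, model_seed) in zip(folds, fold_seeds):
        train = table.select(lesion_ids=fold.train_ids)
        test = table.select(lesion_ids=fold.test_ids)
        y_train = train.labels.to_numpy()
        ranked = rank_features(train.features, y_train)[:f]

        x_train = train.features[ranked].to_numpy(dtype=float)
        x_test = test.features[ranked].to_numpy(dtype=float)
        # z-score on train statistics: SMOTE's nearest-neighbor geometry
        # and the MG covariance shrinkage are scale-sensitive, and raw
        # radiomic features span many orders of magnitude
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd == 0] = 1.0
        x_train = (x_train - mu) / sd
        x_test = (x_test - mu) / sd
        x_bal, y_bal = smote_balance(x_train, y_train, seed=int(smote_seed % (2**31)))
        model = train_ensemble(x_bal, y_bal, ranked, seed=int(model_seed % (2**31)),
                               config=config)
        y_hat, score = predict(model, x_test)
        for lid, yt, yp, sc in zip(fold.test_ids, test.labels.to_numpy(), y_hat, score):
            rows.append(
                {
                    "lesion_id": lid,
                    "fold_id": fold.fold_id,
                    "delineation": table.delineation,
                    "true": int(yt),
                    "predicted": int(yp),
                    "vote_score": float(sc),
                }
            )
    return pd.DataFrame(rows)
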