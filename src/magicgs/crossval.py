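"""Cross-validated predictive ability and prediction accuracy for GBLUP.

Folds partition lines (never individual plants), and the model is fitted
in means mode on adjusted line means, refitting variance components for
every training set. Per repeat, one predictive ability r is the Pearson
correlation between the held-out lines' adjusted means and their predicted
additive genetic values, pooled over the k folds. Prediction accuracy
rescales r by the square root of the narrow-sense heritability from the
complete-data fit: accuracy = r / sqrt(h2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GRM
from .gblup import GBLUP, AdjustedMeans

__all__ = ["CvResult", "loocv", "kfold_cv", "prediction_accuracy", "cv_table"]


@dataclass
class CvResult:
    """Cross-validation outcome for one trait."""

    trait: str
    scheme: str  # "loocv" or "kfold"
    k: int
    n_repeats: int
    seed: int | None
    r_per_repeat: np.ndarray = field(repr=False)
    predictions: pd.Series = field(repr=False)  # last repeat's pooled held-out predictions
    h2: float | None = None
    n_failed_folds: int = 0
    fold_assignments: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def r(self) -> float:
        """Mean predictive ability over repeats."""
        vals = self.r_per_repeat[~np.isnan(self.r_per_repeat)]
        return float(vals.mean()) if len(vals) else float("nan")

    @property
    def r_se(self) -> float:
        """Standard error of r over repeats (0 for a single repeat)."""
        if len(self.r_per_repeat) < 2:
            return 0.0
        return float(np.nanstd(self.r_per_repeat, ddof=1) / np.sqrt(len(self.r_per_repeat)))

    @property
    def accuracy(self) -> float:
        if self.h2 is None:
            raise ValueError("no h2 attached; pass h2 to the CV call")
        return prediction_accuracy(self.r, self.h2)

    def summary_row(self) -> dict:
        row = {
            "trait": self.trait, "scheme": self.scheme, "k": self.k,
            "repeats": self.n_repeats, "r": self.r, "r_se": self.r_se,
        }
        if self.h2 is not None:
            row["h2"] = self.h2
            row["accuracy"] = self.accuracy
        return row


def prediction_accuracy(r: float, h2: float) -> float:
    """Predictive ability adjusted by the square root of heritability.

    The sign of r is carried through, so negative predictive abilities give
    negative accuracies.
    """
    if not 0 < h2 <= 1:
        raise ValueError("h2 must be in (0, 1] for prediction accuracy")
    return float(r / np.sqrt(h2))


def _as_series(means) -> tuple[pd.Series, str]:
    if isinstance(means, AdjustedMeans):
        return means.means.dropna(), means.trait
    ser = pd.Series(means).dropna()
    return ser, str(ser.name or "trait")


def _run_folds(y: pd.Series, grm: GRM, folds: list[list[str]]):
    """Fit GBLUP without each fold and predict its lines; pool predictions."""
    preds = {}
    failed = 0
    for fold in folds:
        train = y.drop(index=fold)
        try:
            fit = GBLUP.from_means(train, grm).fit()
            pred = fit.predict(fold, grm)
        except (RuntimeError, np.linalg.LinAlgError):
            failed += 1
            continue
        preds.update(pred.to_dict())
    pred_ser = pd.Series(preds, name="prediction").reindex(
        [l for f in folds for l in f]
    ).dropna()
    return pred_ser, failed


def _pearson(obs: pd.Series, pred: pd.Series) -> float:
    common = obs.index.intersection(pred.index)
    if len(common) < 3 or obs[common].std() == 0 or pred[common].std() == 0:
        return float("nan")
    return float(np.corrcoef(obs[common], pred[common])[0, 1])


def loocv(means, grm: GRM, h2: float | None = None) -> CvResult:
    """Leave-one-out cross-validation: each line predicted from the rest.

    Variance components are re-estimated for every training set. Returns a
    single pooled predictive ability over all held-out (observed,
    predicted) pairs.
    """
    y, trait = _as_series(means)
    if len(y) < 10:
        raise ValueError("LOOCV needs at least 10 lines")
    if y.std() == 0:
        return CvResult(trait, "loocv", len(y), 1, None,
                        np.array([np.nan]), pd.Series(dtype=float), h2=h2)
    folds = [[l] for l in y.index]
    preds, failed = _run_folds(y, grm, folds)
    r = _pearson(y, preds)
    return CvResult(trait, "loocv", len(y), 1, None, np.array([r]), preds,
                    h2=h2, n_failed_folds=failed)


def kfold_cv(means, grm: GRM, k: int = 5, repeats: int = 100,
             seed: int = 0, h2: float | None = None) -> CvResult:
    """Repeated k-fold cross-validation over lines.

    Per repeat the lines are randomly partitioned into k folds; each fold
    is predicted from the remaining lines and one pooled r is computed.
    The summary is the mean and standard error over repeats. A fixed seed
    reproduces fold assignments exactly; with ``k == n`` and a single
    repeat the result equals LOOCV.
    """
    y, trait = _as_series(means)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError("k must satisfy 2 <= k <= n")
    rng = np.random.default_rng(seed)
    rs = []
    assignments = []
    preds = pd.Series(dtype=float)
    failed = 0
    for rep in range(repeats):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        for fi, chunk in enumerate(np.array_split(perm, k)):
            fold_of[chunk] = fi
        folds = [list(y.index[fold_of == fi]) for fi in range(k)]
        assignments.append(pd.Series(fold_of, index=y.index, name=f"repeat{rep}"))
        preds, nf = _run_folds(y, grm, folds)
        failed += nf
        rs.append(_pearson(y, preds))
    return CvResult(trait, "kfold", k, repeats, seed, np.array(rs), preds,
                    h2=h2, n_failed_folds=failed,
                    fold_assignments=pd.concat(assignments, axis=1))


def cv_table(means_by_trait: dict, grm: GRM, h2_by_trait: dict,
             k: int = 5, repeats: int = 100, seed: int = 0) -> pd.DataFrame:
    """LOOCV and repeated k-fold summaries for several traits.

    Returns one row per trait: LOOCV r and accuracy, k-fold mean r with
    standard error, and k-fold accuracy (the shape of a published
    cross-validation table).
    """
    rows = []
    for trait, means in means_by_trait.items():
        h2 = h2_by_trait.get(trait)
        lo = loocv(means, grm, h2=h2)
        kf = kfold_cv(means, grm, k=k, repeats=repeats, seed=seed, h2=h2)
        rows.append({
            "trait": trait,
            "loocv_r": lo.r,
            "loocv_accuracy": lo.accuracy if h2 and h2 > 0 else np.nan,
            "kfold_r": kf.r,
            "kfold_r_se": kf.r_se,
            "kfold_accuracy": kf.accuracy if h2 and h2 > 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("trait")
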