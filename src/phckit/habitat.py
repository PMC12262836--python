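"""Ensemble habitat-suitability modeling (Model / Results objects).

:class:`HabitatSuitabilityModel` holds occurrence data and a covariate stack;
``fit`` runs the repeated stratified 70/30 evaluation over six classifier
families (CTA, FDA, GBM, GLM, MARS, RF), filters out families whose mean AUC
or mean TSS falls below a cutoff (0.85 by default), refits the survivors on
the full data, and returns a :class:`HabitatSuitabilityResults` carrying the
per-repeat evaluation records, the included set, ensemble prediction, and
binarization at the sensitivity+specificity-maximizing threshold.

AUC is the rank (Mann-Whitney) statistic with ties counted half; TSS is the
true skill statistic, max over thresholds of sensitivity + specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .covariates import design_matrix
from .landscape import OccurrenceSet
from .raster import RasterGrid

__all__ = [
    "ALGORITHMS",
    "ModelEvalRecord",
    "SuitabilityProduct",
    "HabitatSuitabilityModel",
    "HabitatSuitabilityResults",
    "split_data",
    "evaluate_model",
    "max_sens_spec_threshold",
    "filter_algorithms",
]


class AllModelsExcludedError(RuntimeError):
    """Every algorithm fell below the performance cutoff; review thresholds."""


def _make_cta(seed: int):
    return DecisionTreeClassifier(max_depth=8, min_samples_leaf=5, random_state=seed)


def _make_fda(seed: int):
    # discriminant analysis on an adaptive piecewise-linear basis
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("basis", SplineTransformer(n_knots=5, degree=1, include_bias=False)),
            ("lda", LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")),
        ]
    )


def _make_gbm(seed: int):
    return GradientBoostingClassifier(
        n_estimators=100, learning_rate=0.1, max_depth=3, random_state=seed
    )


def _make_glm(seed: int):
    # ridge-stabilized logistic regression (handles near-singular designs)
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("glm", LogisticRegression(C=100.0, max_iter=2000)),
        ]
    )


def _make_mars(seed: int):
    # hinge-basis expansion with L1 term selection: a piecewise-linear
    # adaptive-regression-splines analogue
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("basis", SplineTransformer(n_knots=7, degree=1, include_bias=False)),
            ("lasso", LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                                         max_iter=2000, random_state=seed)),
        ]
    )


def _make_rf(seed: int):
    return RandomForestClassifier(n_estimators=200, min_samples_leaf=2, random_state=seed)


ALGORITHMS = {
    "CTA": _make_cta,
    "FDA": _make_fda,
    "GBM": _make_gbm,
    "GLM": _make_glm,
    "MARS": _make_mars,
    "RF": _make_rf,
}


# ---------------------------------------------------------------------------
# metrics and splitting


def split_data(
    labels: np.ndarray, train_fraction: float = 0.7, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split; disjoint, union = all indices."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be strictly between 0 and 1")
    rng = rng or np.random.default_rng()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to split")
    train_parts, test_parts = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise ValueError("split leaves a class empty in train or test")
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def evaluate_model(predictions: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(AUC, TSS) of probabilistic predictions against binary truth.

    AUC is the rank statistic (concordant presence-absence pairs, ties count
    half); TSS = max over thresholds of (sensitivity + specificity - 1).
    """
    truth = np.asarray(truth).astype(int)
    predictions = np.asarray(predictions, dtype=float)
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    auc = float(roc_auc_score(truth, predictions))
    fpr, tpr, _ = roc_curve(truth, predictions)
    tss = float(np.max(tpr - fpr))
    return auc, tss


def max_sens_spec_threshold(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity over the unique
    predicted values (binary rule: prediction >= threshold); ties resolved to
    the lowest such threshold.
    """
    truth = np.asarray(truth).astype(int)
    predictions = np.asarray(predictions, dtype=float)
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    candidates = np.unique(predictions)
    n_pos = truth.sum()
    n_neg = len(truth) - n_pos
    best_t, best_val = candidates[0], -np.inf
    for t in candidates:
        pred_pos = predictions >= t
        sens = np.sum(pred_pos & (truth == 1)) / n_pos
        spec = np.sum(~pred_pos & (truth == 0)) / n_neg
        val = sens + spec
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return float(best_t)


def filter_algorithms(
    evals: pd.DataFrame, auc_cutoff: float = 0.85, tss_cutoff: float = 0.85
) -> list[str]:
    """Algorithms whose mean AUC and mean TSS both reach the cutoffs.

    ``evals`` needs columns algorithm, auc, tss (one row per repeat).
    """
    means = evals.groupby("algorithm", sort=False)[["auc", "tss"]].mean()
    return [
        a for a in means.index
        if means.loc[a, "auc"] >= auc_cutoff and means.loc[a, "tss"] >= tss_cutoff
    ]


# ---------------------------------------------------------------------------
# model / results


@dataclass
class ModelEvalRecord:
    algorithm: str
    repeat_index: int
    auc: float
    tss: float


@dataclass
class SuitabilityProduct:
    """Continuous suitability, its binarization threshold and binary map."""

    continuous: RasterGrid
    threshold: float
    binary: RasterGrid
    evals: pd.DataFrame
    included_models: list[str]


class HabitatSuitabilityModel:
    """Occurrence data + covariate stack, ready to fit the ensemble.

    Parameters
    ----------
    occurrences : OccurrenceSet or DataFrame with x, y, label columns
    stack : dict of layer name -> RasterGrid
        The shared-grid covariate stack.
    algorithms : sequence of str, optional
        Subset of ``ALGORITHMS`` keys; all six by default.
    """

    def __init__(self, occurrences, stack: dict[str, RasterGrid], algorithms=None):
        records = occurrences.records if isinstance(occurrences, OccurrenceSet) else occurrences
        self.records = records.reset_index(drop=True)
        self.stack = stack
        self.algorithms = list(algorithms) if algorithms else list(ALGORITHMS)
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")
        xy = self.records[["x", "y"]].to_numpy()
        self.exog = design_matrix(stack, xy)
        self.endog = (self.records["label"] == "presence").to_numpy().astype(int)
        if self.endog.sum() < 10 or (1 - self.endog).sum() < 10:
            raise ValueError("need at least 10 records of each label")

    @classmethod
    def from_landscape(cls, occurrences, stack, **kw) -> "HabitatSuitabilityModel":
        return cls(occurrences, stack, **kw)

    def fit(
        self,
        n_repeats: int = 10,
        train_fraction: float = 0.7,
        auc_cutoff: float = 0.85,
        tss_cutoff: float = 0.85,
        weighting: str = "tss",
        seed: int | None = None,
    ) -> "HabitatSuitabilityResults":
        """Repeated split-sample evaluation, filtering, and full-data refit.

        Each repeat draws a fresh stratified ``train_fraction`` split; every
        algorithm is fitted on the training part and scored (AUC, TSS) on
        the held-out part.  An algorithm enters the ensemble iff its mean
        AUC >= ``auc_cutoff`` AND mean TSS >= ``tss_cutoff``.
        """
        rng = np.random.default_rng(seed)
        X = self.exog.to_numpy(dtype=float)
        y = self.endog
        records: list[ModelEvalRecord] = []
        for rep in range(n_repeats):
            tr, te = split_data(y, train_fraction, rng)
            for name in self.algorithms:
                est = ALGORITHMS[name](int(rng.integers(2**31 - 1)))
                est.fit(X[tr], y[tr])
                pred = est.predict_proba(X[te])[:, 1]
                auc, tss = evaluate_model(pred, y[te])
                records.append(ModelEvalRecord(name, rep, auc, tss))

        evals = pd.DataFrame([r.__dict__ for r in records])
        means = evals.groupby("algorithm")[["auc", "tss"]].mean()
        included = filter_algorithms(evals, auc_cutoff, tss_cutoff)
        if not included:
            raise AllModelsExcludedError(
                "no algorithm reached the performance cutoffs "
                f"(AUC >= {auc_cutoff}, TSS >= {tss_cutoff}); best mean AUC "
                f"{means['auc'].max():.3f}, best mean TSS {means['tss'].max():.3f}. "
                "Review the cutoffs or the input data."
            )
        if weighting == "tss":
            weights = {a: float(means.loc[a, "tss"]) for a in included}
        elif weighting == "uniform":
            weights = {a: 1.0 for a in included}
        else:
            raise ValueError("weighting must be 'tss' or 'uniform'")
        if sum(weights.values()) <= 0:  # degenerate: fall back to unweighted
            weights = {a: 1.0 for a in included}

        fitted = {}
        for name in included:
            est = ALGORITHMS[name](int(rng.integers(2**31 - 1)))
            est.fit(X, y)
            fitted[name] = est
        return HabitatSuitabilityResults(self, evals, included, weights, fitted)


class HabitatSuitabilityResults:
    """Fit results: evaluation records, the filtered ensemble, prediction
    surfaces and binarization."""

    def __init__(self, model, evals, included_models, weights, fitted):
        self.model = model
        self.evals = evals
        self.included_models = included_models
        self.weights = weights
        self._fitted = fitted

    # -- prediction ---------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weighted-mean ensemble probability for rows of a design matrix."""
        X = np.asarray(X, dtype=float)
        total = sum(self.weights.values())
        out = np.zeros(X.shape[0])
        for name in self.included_models:
            out += self.weights[name] * self._fitted[name].predict_proba(X)[:, 1]
        return out / total

    def predict_raster(self, stack: dict[str, RasterGrid] | None = None) -> RasterGrid:
        """Ensemble suitability surface over all valid cells of the stack."""
        stack = stack or self.model.stack
        ref = stack["elevation"]
        xs, ys = ref.cell_centers()
        valid = ~ref.nodata_mask
        xy = np.stack([xs[valid], ys[valid]], axis=1)
        X = design_matrix(stack, xy).to_numpy(dtype=float)
        vals = np.zeros(ref.shape)
        vals[valid] = self.predict(X)
        return ref.like(vals)

    def binarize(
        self,
        continuous: RasterGrid | None = None,
        test_predictions: np.ndarray | None = None,
        test_labels: np.ndarray | None = None,
    ) -> SuitabilityProduct:
        """Threshold the suitability surface at max(sensitivity+specificity).

        By default the threshold is calibrated on the ensemble's predictions
        at all occurrence points (the calibration-data convention); pass an
        explicit held-out ``test_predictions`` / ``test_labels`` pair to
        calibrate on independent data instead.
        """
        if continuous is None:
            continuous = self.predict_raster()
        if test_predictions is None:
            test_predictions = self.predict(self.model.exog.to_numpy(dtype=float))
            test_labels = self.model.endog
        thr = max_sens_spec_threshold(test_predictions, test_labels)
        binary = continuous.like(
            np.where(~continuous.nodata_mask, (continuous.values >= thr).astype(int), 0)
        )
        return SuitabilityProduct(continuous, thr, binary, self.evals, self.included_models)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        means = self.evals.groupby("algorithm")[["auc", "tss"]].agg(["mean", "std"])
        lines = [
            "Habitat suitability ensemble",
            "=" * 52,
            f"{'algorithm':<10}{'AUC':>12}{'TSS':>14}{'included':>12}",
            "-" * 52,
        ]
        for name in self.model.algorithms:
            if name not in means.index:
                continue
            am, asd = means.loc[name, ("auc", "mean")], means.loc[name, ("auc", "std")]
            tm, tsd = means.loc[name, ("tss", "mean")], means.loc[name, ("tss", "std")]
            flag = "yes" if name in self.included_models else "no"
            lines.append(f"{name:<10}{am:>7.3f}±{asd:.3f}{tm:>8.3f}±{tsd:.3f}{flag:>9}")
        lines.append("-" * 52)
        lines.append(f"ensemble members: {', '.join(self.included_models)}")
        return "\n".join(lines)

    def plot_evals(self, ax=None):
        """AUC-vs-TSS scatter of per-repeat evaluation records."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, grp in self.evals.groupby("algorithm"):
            ax.scatter(grp["auc"], grp["tss"], label=name, alpha=0.7)
        ax.set_xlabel("AUC")
        ax.set_ylabel("TSS")
        ax.legend(fontsize=8)
        return ax
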