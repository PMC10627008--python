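"""Cross-validated prediction accuracy.

k-fold cross-validation (default fivefold, 30 repeats): the population is
randomly partitioned per repeat, each fold is predicted from a model
trained on the complement with the fold's phenotypes masked, and accuracy
is the Pearson correlation between observed and predicted values in the
fold.  Fold randomization is shared across models and marker sets within a
repeat, so model comparisons are paired.  The headline summary is the
median r across all fold x repeat values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PavcallError
from .grm import GRM, epistatic_grm
from .models import (
    FixedDesign,
    fit_bayesian_lasso,
    fit_gblup,
    fit_egblup,
    fit_rkhs,
    gaussian_kernels,
    predict_masked,
)

log = logging.getLogger(__name__)


def make_folds(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded random partition of ``range(n)`` into k folds of size n//k or n//k+1.

    Returns an integer fold label (0..k-1) per sample.
    """
    if n < k:
        raise PavcallError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    labels[perm] = np.arange(n) % k
    return labels


def pearson_accuracy(obs, pred) -> float:
    """Pearson correlation between observed and predicted values.

    Returns NaN (with a warning) when either vector is constant.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if len(obs) < 3:
        raise PavcallError("need at least 3 observations for a Pearson accuracy")
    if obs.std() == 0 or pred.std() == 0:
        warnings.warn("constant vector in accuracy computation; recording NaN", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1])


@dataclass
class ModelSpec:
    """Names a predictor and its settings for the CV engine.

    ``name`` is one of ``gblup``, ``egblup``, ``rkhs``, ``blasso`` or
    ``adapter``; for ``adapter``, *params['factory']* must be a callable
    returning an object with ``fit(features, y)`` and ``predict(features)``
    so external learners can be plugged in.
    """

    name: str
    params: dict = field(default_factory=dict)


@dataclass
class DataBundle:
    """Everything the CV engine needs: phenotype, design, marker matrices.

    *marker_sets* maps a tag (snp / failed / failed_ps / failed_ld /
    combined...) to the numeric samples x markers matrix for that set.
    GRMs and kernels are derived per marker set on demand and cached.
    """

    y: np.ndarray
    X: FixedDesign
    marker_sets: dict
    sample_ids: np.ndarray | None = None
    _grm_cache: dict = field(default_factory=dict, repr=False)

    def matrix(self, tag: str) -> np.ndarray:
        try:
            m = self.marker_sets[tag]
        except KeyError:
            raise PavcallError(f"unknown marker set {tag!r}") from None
        return np.asarray(getattr(m, "values", m), dtype=float)

    def grm(self, tag: str) -> GRM:
        if tag not in self._grm_cache:
            from .grm import vanraden_grm

            self._grm_cache[tag] = vanraden_grm(
                self.marker_sets[tag], marker_set=tag
            ).bend()
        return self._grm_cache[tag]


@dataclass
class CVResult:
    """Per-(repeat, fold) accuracies plus fold bookkeeping."""

    table: pd.DataFrame  # repeat, fold, model, marker_set, r, n_test, seed
    fold_assignments: dict  # repeat -> fold label array
    n_failed_folds: int = 0

    @property
    def median_r(self) -> float:
        return float(self.table["r"].median())

    @property
    def mean_r(self) -> float:
        return float(self.table["r"].mean())


def _fit_and_predict(spec: ModelSpec, bundle: DataBundle, tag: str,
                     train, test) -> np.ndarray:
    y_tr = bundle.y[train]
    X_full = bundle.X.X
    X_tr = X_full[train]
    if spec.name == "gblup":
        G = bundle.grm(tag).G
        fit = fit_gblup(y_tr, X_tr, G[np.ix_(train, train)])
        return predict_masked(fit, {"additive": G}, train, test, X_full)
    if spec.name == "egblup":
        G = bundle.grm(tag)
        Gaa = epistatic_grm(G)
        fit = fit_egblup(y_tr, X_tr, G.G[np.ix_(train, train)],
                         Gaa.G[np.ix_(train, train)])
        return predict_masked(fit, {"additive": G.G, "epistasis": Gaa.G},
                              train, test, X_full)
    if spec.name == "rkhs":
        ks = gaussian_kernels(bundle.matrix(tag),
                              spec.params.get("bandwidths", (0.1, 0.5, 2.5)))
        full = ks.as_dict()
        sub = {nm: K[np.ix_(train, train)] for nm, K in full.items()}
        from .models import fit_variance_components

        fit = fit_variance_components(y_tr, X_tr, sub)
        return predict_masked(fit, full, train, test, X_full)
    if spec.name == "blasso":
        M = bundle.matrix(tag)
        chain = {k: spec.params[k] for k in ("iters", "burn_in", "thin") if k in spec.params}
        fit = fit_bayesian_lasso(y_tr, X_tr, M[train],
                                 seed=spec.params.get("seed", 0), **chain)
        return fit.predict(X_full[test], M[test])
    if spec.name == "adapter":
        model = spec.params["factory"]()
        feats = np.column_stack([bundle.matrix(tag), X_full[:, 1:]])
        model.fit(feats[train], y_tr)
        return np.asarray(model.predict(feats[test]), dtype=float)
    raise PavcallError(f"unknown model {spec.name!r}")


def cross_validate(
    bundle: DataBundle,
    spec: ModelSpec,
    marker_set: str = "snp",
    k: int = 5,
    repeats: int = 30,
    base_seed: int = 0,
) -> CVResult:
    """Repeated k-fold CV of one model on one marker set.

    Fold assignments depend only on ``base_seed + repeat``, so runs with
    different models or marker sets at the same base seed are paired.
    Folds where the model fails are recorded with NaN accuracy and counted.
    """
    n = len(bundle.y)
    if n // k < 3:
        raise PavcallError("validation folds of fewer than 3 samples cannot yield r")
    rows = []
    assignments = {}
    n_failed = 0
    for rep in range(repeats):
        seed = base_seed + rep
        folds = make_folds(n, k, seed)
        assignments[rep] = folds
        for f in range(k):
            test = np.flatnonzero(folds == f)
            train = np.flatnonzero(folds != f)
            try:
                pred = _fit_and_predict(spec, bundle, marker_set, train, test)
                r = pearson_accuracy(bundle.y[test], pred)
            except (PavcallError, np.linalg.LinAlgError) as exc:
                log.warning("fold %d of repeat %d failed: %s", f, rep, exc)
                r = float("nan")
                n_failed += 1
            rows.append({"repeat": rep, "fold": f, "model": spec.name,
                         "marker_set": marker_set, "r": r,
                         "n_test": len(test), "seed": seed})
    return CVResult(pd.DataFrame(rows), assignments, n_failed)
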