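"""Null simulation: random failed calls carry no predictive signal.

Each replicate takes a genotype matrix (here synthetic; any call matrix
works), simulates an additive trait from sampled QTL with N(0,1) effects
and residual variance Ve = Vg/H^2 - Vg, injects purely random failed
calls, re-runs the recoding pipeline and both filtering pipelines, and
cross-validates GBLUP on the SNP set and on the failed-call set.  Because
the failures are independent of genotype and pool, the filters should
retain (almost) nothing and the failed-call accuracy should sit at zero.

Injected random failures are so dilute per marker that the failed-call
frequency filter empties the candidate set at realistic rates; the
prediction arm therefore uses the complete failed-call set (every marker
with at least one failure and non-constant indicator), which is also what
makes the null result a meaningful control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FF, CallMatrix, FailMatrix, PavcallError
from .crossval import DataBundle, ModelSpec, cross_validate
from .filters import filter_pool_specific, ld_filter
from .models import build_fixed_design, FixedDesign
from .popstruct import kmeans_pools
from .preprocess import fail_frequency_filter, filter_expected_het, impute_snp, maf_filter, split_matrices

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Settings for the random-failure simulation study."""

    n_qtl: int = 100
    h2: float = 0.6
    fail_rate: float = 0.02  # fraction of matrix entries set to FF
    n_fail_entries: int | None = None  # overrides fail_rate when given
    cv_k: int = 5
    cv_repeats: int = 10
    n_sims: int = 100
    seed: int = 0
    run_cv: bool = True  # False: filters and survivor counts only

    def __post_init__(self) -> None:
        if not 0 < self.h2 <= 1:
            raise PavcallError("h2 must be in (0, 1]")


def simulate_phenotype(dm, n_qtl: int, h2: float, seed=None, rng=None):
    """Additive trait on a dosage matrix: QTL without replacement, N(0,1) effects.

    Returns (y, qtl_idx, effects, Vg, Ve) with Ve = Vg/h^2 - Vg.
    """
    if not 0 < h2 <= 1:
        raise PavcallError("h2 must be in (0, 1]")
    values = np.asarray(getattr(dm, "values", dm), dtype=float)
    n, m = values.shape
    if n_qtl > m:
        raise PavcallError(f"n_qtl={n_qtl} exceeds marker count {m}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    qtl = rng.choice(m, size=n_qtl, replace=False)
    effects = rng.standard_normal(n_qtl)
    g = values[:, qtl] @ effects
    vg = float(np.var(g))
    if vg <= 0:
        raise PavcallError("zero genetic variance in simulated trait")
    ve = vg / h2 - vg if h2 < 1 else 0.0
    y = g + (rng.normal(0.0, np.sqrt(ve), size=n) if ve > 0 else 0.0)
    return y, qtl, effects, vg, ve


def inject_random_failures(cm: CallMatrix, n_entries=None, rate=None, seed=None, rng=None) -> CallMatrix:
    """Set exactly *n_entries* distinct cells to FF, uniformly at random.

    Either an absolute entry count or a rate (fraction of all cells) must
    be given.  Cells are drawn without replacement over the whole matrix;
    already-failed cells may be drawn (they stay FF), matching sampling of
    matrix entries rather than of successful calls.
    """
    total = cm.calls.size
    if n_entries is None:
        if rate is None:
            raise PavcallError("give n_entries or rate")
        n_entries = int(round(rate * total))
    if n_entries > total:
        raise PavcallError("n_entries exceeds the number of matrix cells")
    if n_entries == 0:
        return cm.copy()
    rng = rng if rng is not None else np.random.default_rng(seed)
    flat = rng.choice(total, size=n_entries, replace=False)
    out = cm.copy()
    out.calls.ravel()[flat] = FF
    return out


def _complete_failed_set(fail_all: FailMatrix) -> FailMatrix:
    """All failed-call markers with a non-constant indicator (no frequency filter)."""
    f = fail_all.fail_freq
    return fail_all.subset_markers((f > 0) & (f < 1))


def run_simulation(cm: CallMatrix, sim: SimConfig, X: FixedDesign | None = None) -> pd.DataFrame:
    """Run the full null-simulation study on a genotype matrix.

    Per replicate: simulate trait -> inject random failures -> He filter,
    split, impute, frequency filters -> pool-specificity and LD filters ->
    GBLUP CV on the SNP set and on the complete failed-call set.  Returns
    one row per replicate; failed replicates are flagged, not fatal.
    """
    rows = []
    for s in range(sim.n_sims):
        seed = sim.seed + s
        row = {"sim": s, "seed": seed, "h2": sim.h2, "n_qtl": sim.n_qtl,
               "failed": False}
        try:
            row.update(_run_one(cm, sim, seed, X))
        except PavcallError as exc:
            log.warning("simulation %d failed: %s", s, exc)
            row["failed"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def _run_one(cm: CallMatrix, sim: SimConfig, seed: int, X: FixedDesign | None) -> dict:
    rng = np.random.default_rng(seed)
    # trait on the clean ("true") genotypes
    dosage_true = np.where(cm.calls == FF, 0, cm.calls).astype(float)
    y, qtl, effects, vg, ve = simulate_phenotype(dosage_true, sim.n_qtl, sim.h2, rng=rng)
    g = dosage_true[:, qtl] @ effects
    ve_realized = float(np.var(y - g))
    realized_h2 = vg / (vg + ve_realized) if ve_realized > 0 else 1.0
    # random failure injection, then the full recoding pipeline
    injected = inject_random_failures(cm, n_entries=sim.n_fail_entries,
                                      rate=sim.fail_rate, rng=rng)
    he_cm = filter_expected_het(injected)
    snp_calls, fail_all = split_matrices(he_cm)
    dm = maf_filter(impute_snp(snp_calls, seed=seed))
    fm_filtered = fail_frequency_filter(fail_all)
    fm_complete = _complete_failed_set(fail_all)
    # filtering pipelines on the frequency-filtered candidates
    n_ps = n_ld = 0
    if fm_filtered.n_markers:
        pools = kmeans_pools(dm.values, seed=seed, sample_ids=dm.sample_ids)
        ps_report, _ = filter_pool_specific(fm_filtered, pools)
        n_ps = int(ps_report.table["keep"].sum())
        ld_report, _ = ld_filter(fm_filtered, dm)
        n_ld = int(ld_report.table["keep"].sum())
    # GBLUP CV on both marker sets
    acc_snp = acc_failed = zero_var_frac = np.nan
    if sim.run_cv:
        if X is None:
            X = FixedDesign(np.ones((cm.n_samples, 1)), "intercept_only")
        bundle = DataBundle(y=y, X=X,
                            marker_sets={"snp": dm, "failed": fm_complete})
        spec = ModelSpec("gblup")
        cv_snp = cross_validate(bundle, spec, "snp", k=sim.cv_k,
                                repeats=sim.cv_repeats, base_seed=seed)
        acc_snp = cv_snp.mean_r
        if fm_complete.n_markers >= 2:
            cv_fail = cross_validate(bundle, spec, "failed", k=sim.cv_k,
                                     repeats=sim.cv_repeats, base_seed=seed)
            acc_failed = cv_fail.mean_r
            zero_var_frac = _zero_variance_fraction(bundle, sim, seed)
    return {
        "vg": vg, "ve": ve, "ve_realized": ve_realized, "realized_h2": realized_h2,
        "n_failed_candidates": fail_all.n_markers,
        "n_failed_freq_filtered": fm_filtered.n_markers,
        "n_failed_complete": fm_complete.n_markers,
        "n_survive_pool_specificity": n_ps,
        "n_survive_ld": n_ld,
        "acc_snp": acc_snp,
        "acc_failed": acc_failed,
        "zero_genetic_variance_frac": zero_var_frac,
    }


def _zero_variance_fraction(bundle: DataBundle, sim: SimConfig, seed: int) -> float:
    """Fraction of training fits attributing ~zero variance to failed calls."""
    from .crossval import make_folds
    from .models import fit_gblup

    G = bundle.grm("failed").G
    n = len(bundle.y)
    zero = 0
    total = 0
    for rep in range(min(sim.cv_repeats, 2)):  # a spot check is enough
        folds = make_folds(n, sim.cv_k, seed + rep)
        for f in range(sim.cv_k):
            train = np.flatnonzero(folds != f)
            fit = fit_gblup(bundle.y[train], bundle.X.X[train],
                            G[np.ix_(train, train)])
            total += 1
            if fit.h2 < 1e-3:
                zero += 1
    return zero / total if total else float("nan")
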