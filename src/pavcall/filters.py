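"""Filters separating biologically caused from random failed calls.

Two pipelines operate on the failed-call matrix:

* **Pool specificity** — a chi-squared test of independence on the 2x2
  table (pool x called/failed) per marker.  Technical dropout cannot be
  pool specific, so a significant association (BH-adjusted p < alpha) is
  evidence of a biological cause and the marker is *kept*.

* **Linkage disequilibrium** — per marker, the LD (r^2, squared dosage
  correlation) of the failed-call profile with every other SNP on the same
  chromosome is compared with the LD of the marker's own SNP profile to
  those same SNPs, by a paired one-sided t-test (H1: failed-call LD is
  lower on average).  Failing to reject keeps the marker: its failure
  pattern is inherited with the local haplotype.  This keep-on-nonrejection
  rule is anticonservative by construction; it is applied as stated and
  noted in the docs.

BH adjustment is applied once across all candidate markers per pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DosageMatrix, FailMatrix, MarkerMap, PavcallError
from .popstruct import PoolAssignment

ALPHA = 0.05


@dataclass
class FilterReport:
    """Per-marker test results of one filtering pipeline."""

    pipeline: str  # "pool_specificity" | "ld"
    table: pd.DataFrame

    def kept_ids(self) -> list:
        if self.table.empty:
            return []
        return list(self.table.loc[self.table["keep"], "marker_id"])


@dataclass
class FilteredSets:
    """Marker-id lists for the candidate and retained failed-call sets."""

    all_failed: list = field(default_factory=list)
    failed_ps: list = field(default_factory=list)
    failed_ld: list = field(default_factory=list)


def chi2_pool_specificity(fail_col: np.ndarray, pools: PoolAssignment) -> tuple[float, float]:
    """Chi-squared test of independence of failure status and pool (df=1).

    Closed form on the 2x2 table, no continuity correction:
    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    failed = np.asarray(fail_col) == 2
    in_b = pools.as_bool()
    if len(failed) != len(in_b):
        raise PavcallError("fail column and pool assignment differ in length")
    if in_b.all() or not in_b.any():
        raise PavcallError("a pool has zero samples")
    nf = failed.sum()
    if nf == 0 or nf == len(failed):
        raise PavcallError("marker has 0 or n failures; frequency pre-filter violated")
    a = float((failed & ~in_b).sum())  # pool A, failed
    b = float((~failed & ~in_b).sum())  # pool A, called
    c = float((failed & in_b).sum())
    d = float((~failed & in_b).sum())
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = n * (a * d - b * c) ** 2 / denom
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _chi2_all(values: np.ndarray, in_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closed-form 2x2 chi-squared over all fail-matrix columns."""
    failed = values == 2
    a = (failed[~in_b]).sum(axis=0).astype(float)
    b = ((~failed)[~in_b]).sum(axis=0).astype(float)
    c = (failed[in_b]).sum(axis=0).astype(float)
    d = ((~failed)[in_b]).sum(axis=0).astype(float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    pvals = stats.chi2.sf(chi2, df=1)
    expected_min = np.minimum.reduce(
        [(a + b) * (a + c), (a + b) * (b + d), (c + d) * (a + c), (c + d) * (b + d)]
    ) / np.maximum(n, 1)
    return chi2, pvals, expected_min


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise PavcallError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_pool_specific(
    fm: FailMatrix, pools: PoolAssignment, alpha: float = ALPHA
) -> tuple[FilterReport, FilteredSets]:
    """Keep failed-call markers whose failure is pool specific (BH-adj p < alpha)."""
    if fm.n_markers == 0:
        report = FilterReport(
            "pool_specificity",
            pd.DataFrame(
                columns=["marker_id", "statistic", "p_raw", "p_adj", "keep",
                         "n_failed_a", "n_called_a", "n_failed_b", "n_called_b",
                         "low_expected_count"]
            ),
        )
        return report, FilteredSets()
    if not np.array_equal(fm.sample_ids, pools.sample_ids):
        raise PavcallError("fail matrix and pool assignment sample order differ")
    in_b = pools.as_bool()
    if in_b.all() or not in_b.any():
        raise PavcallError("a pool has zero samples")
    chi2, p_raw, expected_min = _chi2_all(fm.values, in_b)
    p_adj = bh_adjust(p_raw)
    keep = p_adj < alpha
    failed = fm.values == 2
    report = FilterReport(
        "pool_specificity",
        pd.DataFrame(
            {
                "marker_id": fm.map.marker_id,
                "statistic": chi2,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "keep": keep,
                "n_failed_a": failed[~in_b].sum(axis=0),
                "n_called_a": (~failed)[~in_b].sum(axis=0),
                "n_failed_b": failed[in_b].sum(axis=0),
                "n_called_b": (~failed)[in_b].sum(axis=0),
                "low_expected_count": expected_min < 5,
            }
        ),
    )
    sets = FilteredSets(
        all_failed=list(fm.map.marker_id), failed_ps=report.kept_ids()
    )
    return report, sets


def pairwise_r2(x, y) -> float:
    """LD as the squared Pearson correlation of two dosage-coded vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise PavcallError("zero-variance vector; r^2 undefined")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def _r2_profile(target: np.ndarray, block: np.ndarray) -> np.ndarray:
    """r^2 of *target* against every column of *block* (NaN where undefined)."""
    t = target - target.mean()
    st = t.std()
    b = block - block.mean(axis=0, keepdims=True)
    sb = b.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (b.T @ t) / (len(t) * np.where(sb > 0, sb, np.nan) * (st if st > 0 else np.nan))
    return r**2


def ld_profiles(
    marker_id: str, fm: FailMatrix, dm: DosageMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Paired same-chromosome LD profiles of a failed-call marker.

    Returns ``(u, v)``: r^2 of the marker's failed-call profile (u) and of
    its standard-SNP profile (v) against the identical set of other SNPs on
    the marker's chromosome.  The marker's own SNP column is excluded;
    pairs where either r^2 is undefined are dropped from both profiles.
    """
    jf = fm.map.index_of(marker_id)
    js = dm.map.index_of(marker_id)
    chrom = fm.map.chrom[jf]
    others = np.flatnonzero((dm.map.chrom == chrom) & (dm.map.marker_id != marker_id))
    if len(others) < 2:
        raise PavcallError(f"marker {marker_id}: fewer than 2 same-chromosome SNPs")
    block = dm.values[:, others].astype(float)
    u = _r2_profile(fm.values[:, jf].astype(float), block)
    v = _r2_profile(dm.values[:, js].astype(float), block)
    ok = ~(np.isnan(u) | np.isnan(v))
    if ok.sum() < 2:
        raise PavcallError(f"marker {marker_id}: fewer than 2 valid LD pairs")
    return u[ok], v[ok]


def ld_filter(
    fm: FailMatrix, dm: DosageMatrix, alpha: float = ALPHA
) -> tuple[FilterReport, FilteredSets]:
    """Keep failed-call markers whose LD is not significantly below their SNP's.

    Per marker: paired one-sided t-test of u - v (H1: mean(u) < mean(v));
    BH across markers; keep iff adjusted p >= alpha.  Markers that cannot
    be tested (no SNP counterpart, too few valid pairs) are flagged
    untestable and are not kept.
    """
    rows = []
    for marker_id in fm.map.marker_id:
        row = {"marker_id": marker_id, "statistic": np.nan, "p_raw": np.nan,
               "mean_r2_failed": np.nan, "mean_r2_snp": np.nan,
               "n_pairs": 0, "untestable": True}
        try:
            u, v = ld_profiles(marker_id, fm, dm)
        except (PavcallError, KeyError):
            rows.append(row)
            continue
        if fm.values[:, fm.map.index_of(marker_id)].std() == 0:
            rows.append(row)
            continue
        t, p = stats.ttest_rel(u, v, alternative="less")
        if np.isnan(p):  # u - v constant (e.g. identically zero differences)
            p = 1.0
            t = 0.0
        row.update(
            statistic=float(t), p_raw=float(p),
            mean_r2_failed=float(u.mean()), mean_r2_snp=float(v.mean()),
            n_pairs=int(len(u)), untestable=False,
        )
        rows.append(row)
    table = pd.DataFrame(
        rows, columns=["marker_id", "statistic", "p_raw", "mean_r2_failed",
                       "mean_r2_snp", "n_pairs", "untestable"]
    )
    testable = ~table["untestable"]
    p_adj = np.full(len(table), np.nan)
    if testable.any():
        p_adj[testable.to_numpy()] = bh_adjust(table.loc[testable, "p_raw"])
    table["p_adj"] = p_adj
    table["keep"] = testable.to_numpy() & (p_adj >= alpha)
    report = FilterReport("ld", table)
    sets = FilteredSets(all_failed=list(fm.map.marker_id), failed_ld=report.kept_ids())
    return report, sets
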