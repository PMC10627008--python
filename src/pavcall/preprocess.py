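"""Recoding and filtering of raw call matrices.

The pipeline treats a failed call (``FF``) as a third allele ``F`` next to
``A`` and ``B``.  Markers are first screened on expected heterozygosity
He = 1 - sum(p_i^2) over the three allele frequencies, with threshold
0.095 — the He of a biallelic locus at minor allele frequency 0.05, so the
screen reduces to the usual MAF >= 0.05 rule when no calls fail.  The
surviving matrix is then split into two branches:

* the SNP branch, where FF is re-declared missing, imputed, coded 0/1/2
  and MAF-filtered;
* the failed-call branch, recoded 0 (any successful call) / 2 (F/F) and
  filtered on the frequency of the failed state.

Imputation here is a deliberately simple stand-in (seeded draws from the
observed genotype frequencies, or modal genotype): downstream models only
consume dosages, and externally imputed input is accepted as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AA, AB, BB, FF, CallMatrix, DosageMatrix, FailMatrix, PavcallError

HE_THRESHOLD = 0.095
MIN_MAF = 0.05


def allele_frequencies_triallelic(cm: CallMatrix, marker: int | None = None) -> np.ndarray:
    """Allele frequencies (pA, pB, pF) treating the failed call as allele F.

    pA = (2 nAA + nAB) / 2n, pB = (2 nBB + nAB) / 2n, pF = 2 nFF / 2n.
    Returns a (3,) vector for one marker, or a (n_markers, 3) array when
    *marker* is None.
    """
    calls = cm.calls if marker is None else cm.calls[:, [marker]]
    n = calls.shape[0]
    if n == 0:
        raise PavcallError("empty call matrix")
    n_aa = (calls == AA).sum(axis=0)
    n_ab = (calls == AB).sum(axis=0)
    n_bb = (calls == BB).sum(axis=0)
    n_ff = (calls == FF).sum(axis=0)
    p = np.stack(
        [
            (2 * n_aa + n_ab) / (2 * n),
            (2 * n_bb + n_ab) / (2 * n),
            2 * n_ff / (2 * n),
        ],
        axis=-1,
    )
    return p[0] if marker is not None else p


def expected_het(p) -> float | np.ndarray:
    """Expected heterozygosity He = 1 - sum(p_i^2) of an allele-frequency set."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise PavcallError("negative allele frequency")
    s = p.sum(axis=-1)
    if not np.allclose(s, 1.0, atol=1e-9):
        raise PavcallError("allele frequencies must sum to 1")
    he = 1.0 - (p**2).sum(axis=-1)
    return float(he) if he.ndim == 0 else he


def filter_expected_het(cm: CallMatrix, threshold: float = HE_THRESHOLD) -> CallMatrix:
    """Retain markers with triallelic expected heterozygosity >= *threshold*."""
    he = expected_het(allele_frequencies_triallelic(cm))
    keep = he >= threshold
    if not keep.any():
        raise PavcallError(
            f"no marker passes He >= {threshold}; review the threshold or input"
        )
    return cm.subset_markers(keep)


def split_matrices(cm: CallMatrix) -> tuple[CallMatrix, FailMatrix]:
    """Split a (He-filtered) call matrix into its SNP and failed-call copies.

    The SNP copy is the input unchanged (FF cells are the to-impute set);
    the failed-call copy is 2 exactly where the input is FF, else 0,
    regardless of allelic state.  No frequency filter is applied here.
    """
    fail_values = np.where(cm.calls == FF, 2, 0).astype(np.int8)
    return cm.copy(), FailMatrix(fail_values, cm.sample_ids, cm.map)


def impute_snp(snp_calls: CallMatrix, method: str = "freq_draw", seed: int | None = 0) -> DosageMatrix:
    """Replace FF cells and convert to 0/1/2 dosages.

    ``freq_draw`` draws AA/AB/BB per failed cell proportional to the
    marker's observed genotype frequencies (seeded); ``mode`` uses the most
    frequent observed genotype, ties broken in AA < AB < BB order.
    Successful calls are never altered.
    """
    if method not in ("freq_draw", "mode"):
        raise PavcallError(f"unknown imputation method {method!r}")
    rng = np.random.default_rng(seed)
    values = snp_calls.calls.astype(np.int8).copy()
    counts = np.stack([(values == g).sum(axis=0) for g in (AA, AB, BB)], axis=1)
    zero = counts.sum(axis=1) == 0
    if zero.any():
        bad = snp_calls.map.marker_id[zero][:5]
        raise PavcallError(f"markers with zero successful calls: {list(bad)}")
    for j in np.flatnonzero((values == FF).any(axis=0)):
        miss = values[:, j] == FF
        if method == "mode":
            fill = int(np.argmax(counts[j]))  # argmax ties -> lowest code = AA<AB<BB
            values[miss, j] = fill
        else:
            probs = counts[j] / counts[j].sum()
            values[miss, j] = rng.choice(3, size=miss.sum(), p=probs)
    return DosageMatrix(values, snp_calls.sample_ids, snp_calls.map)


def maf_filter(dm: DosageMatrix, min_maf: float = MIN_MAF) -> DosageMatrix:
    """Retain markers with minor allele frequency >= *min_maf* (inclusive)."""
    p = dm.allele_freq()
    keep = np.minimum(p, 1.0 - p) >= min_maf - 1e-12
    return dm.subset_markers(keep)


def fail_frequency_filter(fm: FailMatrix, min_freq: float = MIN_MAF) -> FailMatrix:
    """Retain markers whose F/F genotype frequency lies in [min_freq, 1-min_freq].

    Mirrors the MAF filter of the SNP branch under the homozygous 0/2
    coding of the failed-call copy.
    """
    f = fm.fail_freq
    keep = (f >= min_freq - 1e-12) & (f <= 1.0 - min_freq + 1e-12)
    return fm.subset_markers(keep)


@dataclass
class PreprocessReport:
    """Marker counts at each stage of the two-branch pipeline."""

    n_input: int
    n_after_he: int
    n_snp_final: int
    n_failed_final: int
    snp_maf_summary: dict = field(default_factory=dict)
    fail_freq_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_he": self.n_after_he,
            "n_snp_final": self.n_snp_final,
            "n_failed_final": self.n_failed_final,
            "snp_maf_summary": self.snp_maf_summary,
            "fail_freq_summary": self.fail_freq_summary,
        }


def _summary(x: np.ndarray) -> dict:
    if x.size == 0:
        return {"n": 0}
    return {
        "n": int(x.size),
        "min": float(x.min()),
        "median": float(np.median(x)),
        "max": float(x.max()),
    }


def preprocess(
    cm: CallMatrix,
    he_threshold: float = HE_THRESHOLD,
    min_maf: float = MIN_MAF,
    impute_method: str = "freq_draw",
    seed: int | None = 0,
) -> tuple[DosageMatrix, FailMatrix, PreprocessReport]:
    """Run the full recoding pipeline: He filter, split, impute, frequency filters.

    Returns the final SNP dosage matrix, the final failed-call matrix and a
    stage-count report.
    """
    he_cm = filter_expected_het(cm, he_threshold)
    snp_calls, fail_all = split_matrices(he_cm)
    dm = maf_filter(impute_snp(snp_calls, impute_method, seed), min_maf)
    fm = fail_frequency_filter(fail_all, min_maf)
    report = PreprocessReport(
        n_input=cm.n_markers,
        n_after_he=he_cm.n_markers,
        n_snp_final=dm.n_markers,
        n_failed_final=fm.n_markers,
        snp_maf_summary=_summary(np.minimum(dm.allele_freq(), 1 - dm.allele_freq())),
        fail_freq_summary=_summary(fm.fail_freq),
    )
    return dm, fm, report
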