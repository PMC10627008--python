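"""Genomic relationship matrices and their comparison.

The additive GRM follows VanRaden: G = Z Z' / (2 sum p_i (1 - p_i)), with
Z the genotype matrix centered by twice the column allele frequency.  The
same construction applies to the 0/2-coded failed-call matrix, where p_i
is the frequency of the failed "allele".  An additive-by-additive
epistatic GRM is the Hadamard square G # G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import DosageMatrix, FailMatrix, PavcallError

log = logging.getLogger(__name__)


@dataclass
class GRM:
    """A genomic relationship matrix with its centering frequencies."""

    G: np.ndarray
    p: np.ndarray  # per-marker allele frequencies used in centering
    sample_ids: np.ndarray
    marker_set: str  # snp | failed | failed_ps | failed_ld | combined | aa
    Z: np.ndarray | None = None  # centered incidence (transient)

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def denominator(self) -> float:
        """The VanRaden scaling constant 2 sum p(1-p) of this marker set."""
        return float(2.0 * np.sum(self.p * (1.0 - self.p)))

    def bend(self, tol: float = 1e-8) -> "GRM":
        """Shift the diagonal if the smallest eigenvalue is materially negative."""
        w = np.linalg.eigvalsh(self.G)
        floor = -tol * max(abs(w[-1]), 1.0)
        if w[0] < floor:
            eps = -w[0] + tol
            log.info("bending GRM (%s): min eigenvalue %.3e, adding %.3e to diagonal",
                     self.marker_set, w[0], eps)
            return GRM(self.G + eps * np.eye(self.n), self.p, self.sample_ids,
                       self.marker_set, self.Z)
        return self


def _values_and_freq(m) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, DosageMatrix):
        vals = m.values.astype(float)
        p = m.allele_freq()
    elif isinstance(m, FailMatrix):
        vals = m.values.astype(float)
        p = vals.mean(axis=0) / 2.0  # frequency of the failed allele
    else:
        vals = np.asarray(m, dtype=float)
        p = vals.mean(axis=0) / 2.0
    return vals, p


def vanraden_grm(m, marker_set: str = "snp", sample_ids=None) -> GRM:
    """VanRaden additive GRM of a dosage (0/1/2) or failed-call (0/2) matrix."""
    vals, p = _values_and_freq(m)
    if sample_ids is None:
        sample_ids = getattr(m, "sample_ids", np.arange(vals.shape[0]).astype(str))
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise PavcallError("all markers monomorphic; VanRaden denominator is zero")
    z = vals - 2.0 * p
    g = (z @ z.T) / denom
    return GRM(g, p, np.asarray(sample_ids, dtype=object), marker_set, Z=z)


def epistatic_grm(g: GRM) -> GRM:
    """Additive-by-additive epistatic GRM: the Hadamard square G # G."""
    return GRM(g.G * g.G, g.p, g.sample_ids, marker_set=f"{g.marker_set}_aa")


def combine_marker_sets(dm: DosageMatrix, fm, marker_set: str = "combined") -> GRM:
    """GRM of the column-concatenated SNP + failed-call marker matrix.

    A single VanRaden scaling constant is computed over all columns, so the
    combined G equals the denominator-weighted average of the per-set GRMs.
    *fm* may be a FailMatrix or any 0/2 numeric matrix on the same samples
    (in the same order); an empty failed set reduces to the SNP GRM.
    """
    fvals = fm.values if isinstance(fm, FailMatrix) else np.asarray(fm)
    if fvals.size:
        f_ids = getattr(fm, "sample_ids", dm.sample_ids)
        if not np.array_equal(np.asarray(f_ids), dm.sample_ids):
            raise PavcallError("SNP and failed matrices have different samples")
        joint = np.concatenate([dm.values.astype(float), fvals.astype(float)], axis=1)
    else:
        joint = dm.values.astype(float)
    return vanraden_grm(joint, marker_set=marker_set, sample_ids=dm.sample_ids)


def relationship_correlation(g1: GRM, g2: GRM) -> float:
    """Pearson correlation of off-diagonal relationship coefficients.

    Diagonals mix inbreeding with relationship and are excluded; the
    strictly lower triangles of the two matrices are correlated.
    """
    if g1.n != g2.n or not np.array_equal(g1.sample_ids, g2.sample_ids):
        raise PavcallError("GRMs cover different samples")
    iu = np.tril_indices(g1.n, k=-1)
    a, b = g1.G[iu], g2.G[iu]
    if a.std() == 0 or b.std() == 0:
        raise PavcallError("constant relationship matrix; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
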