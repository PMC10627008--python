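"""Synthetic two-pool doubled-haploid populations.

The generator emulates the statistical structure a hybrid-breeding
SNP-array dataset presents to the analysis:

* two heterotic pools whose allele frequencies diverge under a
  Balding-Nichols model with a tunable Fst;
* fully homozygous DH lines (no heterozygous calls), one haplotype per
  chromosome, with chromosome-local LD from first-order Markov copying:
  each marker copies the previous marker's allele with probability rho,
  else draws fresh from the pool frequency;
* presence-absence deletion events that set all spanned markers to FF for
  carrier lines, with pool-specific carrier frequencies and carrier status
  linked to the local haplotype (so planted deletions are in LD with
  flanking SNPs);
* independent technical dropout at rate epsilon (the null process);
* additive phenotypes from sampled SNP QTL plus per-deletion carrier
  effects, with the residual variance set as Ve = Vg/h^2 - Vg.

Deleted (FF) cells contribute zero B-allele dosage to the genetic value:
the allele is absent, which is what makes deletion effects invisible to a
SNP-only analysis and recoverable from the failed-call matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AA, BB, FF, CallMatrix, MarkerMap, PavcallError, PhenotypeTable


@dataclass
class DeletionEvent:
    """A presence-absence deletion spanning consecutive markers on one chromosome."""

    chrom: str
    start_marker: int  # index within the chromosome, inclusive
    end_marker: int  # inclusive
    freq_pool_a: float
    freq_pool_b: float
    effect: float = 0.0


@dataclass
class PopulationConfig:
    n_per_pool: int = 250
    n_chrom: int = 10
    markers_per_chrom: int = 200
    anc_freq_range: tuple = (0.1, 0.9)
    fst: float = 0.2
    rho: float = 0.9  # adjacent-marker copying probability (LD strength)
    deletions: list = field(default_factory=list)
    epsilon: float = 0.0  # technical dropout rate
    h2: float = 0.6
    n_trait_qtl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise PavcallError("Fst must be in [0, 1)")
        if not 0 <= self.epsilon < 1:
            raise PavcallError("epsilon must be in [0, 1)")
        if not 0 <= self.rho <= 1:
            raise PavcallError("rho must be in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth of a generated population, for power/FDR assertions."""

    pool: np.ndarray  # per-sample "A"/"B"
    carrier: np.ndarray  # samples x events bool
    events: list
    in_deletion: np.ndarray  # per-marker bool
    haplotypes: np.ndarray  # samples x markers 0/1 pre-deletion alleles
    qtl_idx: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None


def simulate_pool_frequencies(p_anc, fst: float, seed=None, rng=None) -> np.ndarray:
    """Per-pool allele frequencies under the Balding-Nichols model.

    Each pool draws Beta(p (1-Fst)/Fst, (1-p)(1-Fst)/Fst) independently;
    Fst = 0 returns the ancestral frequencies unchanged.  Returns an array
    of shape (2, n_markers).
    """
    if not 0 <= fst < 1:
        raise PavcallError("Fst must be in [0, 1)")
    p_anc = np.atleast_1d(np.asarray(p_anc, dtype=float))
    if fst == 0:
        return np.vstack([p_anc, p_anc])
    rng = rng if rng is not None else np.random.default_rng(seed)
    scale = (1.0 - fst) / fst
    out = rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=(2, len(p_anc)))
    return np.clip(out, 1e-6, 1 - 1e-6)


def _markov_haplotypes(n: int, freqs: np.ndarray, rho: float, rng) -> np.ndarray:
    """n haplotypes over one chromosome with first-order Markov LD.

    Transition probabilities are chosen so every marker keeps exactly its
    own marginal frequency while adjacent markers have allele correlation
    rho (a naive copy-with-probability-rho rule would smear each marker's
    frequency into a moving average of its upstream neighbours, eroding the
    planted pool divergence).
    """
    m = len(freqs)
    h = np.empty((n, m), dtype=np.int8)
    h[:, 0] = rng.random(n) < freqs[0]
    for k in range(1, m):
        p_prev, p = freqs[k - 1], freqs[k]
        s = rho * np.sqrt(p * (1.0 - p) * p_prev * (1.0 - p_prev))
        p11 = np.clip(p + s / p_prev, 0.0, 1.0)
        p10 = np.clip(p - s / (1.0 - p_prev), 0.0, 1.0)
        prob = np.where(h[:, k - 1] == 1, p11, p10)
        h[:, k] = rng.random(n) < prob
    return h


def simulate_dh_genotypes(cfg: PopulationConfig, rng=None) -> tuple[CallMatrix, TruthRecord]:
    """Generate the two-pool DH call matrix (AA/BB only) and its truth record.

    Allele frequencies are drawn per *frequency block*, not per marker: a
    new block starts with probability 1 - rho at each marker, and all
    markers of a block share one ancestral frequency and one
    Balding-Nichols draw per pool.  Markers in strong LD therefore have
    matching frequencies, as in real haplotype blocks; without this, the
    copying chain could not reach high adjacent-marker r^2 (binary
    correlation is Frechet-bounded by the marginal mismatch).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_markers = cfg.n_chrom * cfg.markers_per_chrom
    # blockwise frequency field, blocks never crossing chromosome ends
    new_block = rng.random(n_markers) >= cfg.rho
    new_block[:: cfg.markers_per_chrom] = True
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    p_anc_block = rng.uniform(*cfg.anc_freq_range, size=n_blocks)
    pool_freq_block = simulate_pool_frequencies(p_anc_block, cfg.fst, rng=rng)
    pool_freq = pool_freq_block[:, block_id]
    n = cfg.n_per_pool
    hap_blocks = []
    for c in range(cfg.n_chrom):
        sl = slice(c * cfg.markers_per_chrom, (c + 1) * cfg.markers_per_chrom)
        hap_a = _markov_haplotypes(n, pool_freq[0, sl], cfg.rho, rng)
        hap_b = _markov_haplotypes(n, pool_freq[1, sl], cfg.rho, rng)
        hap_blocks.append(np.vstack([hap_a, hap_b]))
    hap = np.concatenate(hap_blocks, axis=1)
    calls = np.where(hap == 1, BB, AA).astype(np.int8)
    pool = np.array(["A"] * n + ["B"] * n, dtype=object)
    sample_ids = np.array(
        [f"A{i:04d}" for i in range(n)] + [f"B{i:04d}" for i in range(n)], dtype=object
    )
    marker_ids = [
        f"chr{c + 1}_m{k + 1}"
        for c in range(cfg.n_chrom)
        for k in range(cfg.markers_per_chrom)
    ]
    chroms = [f"chr{c + 1}" for c in range(cfg.n_chrom) for _ in range(cfg.markers_per_chrom)]
    pos = [1000 * (k + 1) for _ in range(cfg.n_chrom) for k in range(cfg.markers_per_chrom)]
    cm = CallMatrix(calls, sample_ids, MarkerMap(marker_ids, chroms, pos))
    truth = TruthRecord(
        pool=pool,
        carrier=np.zeros((2 * n, 0), dtype=bool),
        events=[],
        in_deletion=np.zeros(n_markers, dtype=bool),
        haplotypes=hap,
    )
    return cm, truth


def plant_deletions(
    cm: CallMatrix, truth: TruthRecord, events: list, seed=None, rng=None
) -> tuple[CallMatrix, TruthRecord]:
    """Plant presence-absence deletions: carriers go FF across the span.

    Carrier status is linked to the local haplotype: within each pool,
    samples carrying allele 1 at the first span marker are enrolled first
    (random order within the two allele classes), until the pool's target
    carrier count round(freq * n_pool) is reached.  With rho > 0 this makes
    the deletion travel with the surrounding haplotype block, i.e. planted
    deletions are in LD with flanking SNPs.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    cm = cm.copy()
    n = cm.n_samples
    in_del = truth.in_deletion.copy()
    carrier_cols = [truth.carrier[:, j] for j in range(truth.carrier.shape[1])]
    chrom_index = {}
    for c in np.unique(cm.map.chrom):
        chrom_index[c] = np.flatnonzero(cm.map.chrom == c)
    for ev in events:
        idx = chrom_index[ev.chrom][ev.start_marker : ev.end_marker + 1]
        if len(idx) == 0:
            raise PavcallError(f"deletion span empty on {ev.chrom}")
        if in_del[idx].any():
            raise PavcallError("overlapping deletion events on shared markers")
        allele = truth.haplotypes[:, idx[0]]
        carrier = np.zeros(n, dtype=bool)
        for pool_label, freq in (("A", ev.freq_pool_a), ("B", ev.freq_pool_b)):
            members = np.flatnonzero(truth.pool == pool_label)
            target = int(round(freq * len(members)))
            order = np.concatenate(
                [rng.permutation(members[allele[members] == 1]),
                 rng.permutation(members[allele[members] == 0])]
            )
            carrier[order[:target]] = True
        cm.calls[np.ix_(carrier, idx)] = FF
        in_del[idx] = True
        carrier_cols.append(carrier)
    new_truth = TruthRecord(
        pool=truth.pool,
        carrier=np.column_stack(carrier_cols) if carrier_cols else np.zeros((n, 0), dtype=bool),
        events=list(truth.events) + list(events),
        in_deletion=in_del,
        haplotypes=truth.haplotypes,
        qtl_idx=truth.qtl_idx,
        qtl_effects=truth.qtl_effects,
    )
    return cm, new_truth


def add_technical_failures(cm: CallMatrix, epsilon: float, seed=None, rng=None) -> CallMatrix:
    """Set each non-FF cell to FF independently with probability epsilon."""
    if not 0 <= epsilon < 1:
        raise PavcallError("epsilon must be in [0, 1)")
    if epsilon == 0:
        return cm.copy()
    rng = rng if rng is not None else np.random.default_rng(seed)
    cm = cm.copy()
    hit = (rng.random(cm.calls.shape) < epsilon) & (cm.calls != FF)
    cm.calls[hit] = FF
    return cm


def simulate_trait(
    cm: CallMatrix,
    truth: TruthRecord,
    h2: float,
    n_qtl: int,
    seed=None,
    rng=None,
    trait_name: str = "trait",
) -> tuple[PhenotypeTable, TruthRecord]:
    """Additive phenotype from SNP QTL plus deletion-carrier effects.

    QTL markers are sampled without replacement among markers outside
    deletion spans; their effects are N(0, 1).  Deletion events contribute
    ``carrier * effect``.  The residual variance is Ve = Vg/h^2 - Vg with
    Vg the realized variance of the genetic values, so the realized
    heritability matches the target in expectation.
    """
    if not 0 < h2 <= 1:
        raise PavcallError("h2 must be in (0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    dosage = np.where(cm.calls == FF, 0, cm.calls).astype(float)  # FF: allele absent
    candidates = np.flatnonzero(~truth.in_deletion)
    if n_qtl > len(candidates):
        raise PavcallError("n_qtl exceeds the number of eligible markers")
    qtl = rng.choice(candidates, size=n_qtl, replace=False) if n_qtl else np.empty(0, dtype=int)
    effects = rng.standard_normal(n_qtl)
    g = dosage[:, qtl] @ effects if n_qtl else np.zeros(cm.n_samples)
    for j, ev in enumerate(truth.events):
        g = g + truth.carrier[:, j].astype(float) * ev.effect
    vg = float(np.var(g))
    if vg <= 0:
        raise PavcallError("zero genetic variance; no QTL or deletion effects")
    ve = vg / h2 - vg
    y = g + rng.normal(0.0, np.sqrt(ve), size=len(g))
    table = pd.DataFrame({trait_name: y, "pool": truth.pool},
                         index=pd.Index(cm.sample_ids, name="sample_id"))
    pheno = PhenotypeTable(table, trait_names=[trait_name], covariate_names=["pool"])
    new_truth = TruthRecord(
        pool=truth.pool, carrier=truth.carrier, events=truth.events,
        in_deletion=truth.in_deletion, haplotypes=truth.haplotypes,
        qtl_idx=qtl, qtl_effects=effects,
    )
    return pheno, new_truth


def generate_population(cfg: PopulationConfig) -> tuple[CallMatrix, TruthRecord, PhenotypeTable]:
    """Full generator: genotypes -> deletions -> dropout -> phenotype."""
    rng = np.random.default_rng(cfg.seed)
    cm, truth = simulate_dh_genotypes(cfg, rng=rng)
    if cfg.deletions:
        cm, truth = plant_deletions(cm, truth, cfg.deletions, rng=rng)
    if cfg.epsilon > 0:
        cm = add_technical_failures(cm, cfg.epsilon, rng=rng)
    pheno, truth = simulate_trait(cm, truth, cfg.h2, cfg.n_trait_qtl, rng=rng)
    return cm, truth, pheno


def truth_to_frames(truth: TruthRecord, cm: CallMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular views of a truth record (per-sample and per-marker)."""
    per_sample = pd.DataFrame({"sample_id": cm.sample_ids, "pool": truth.pool})
    for j in range(truth.carrier.shape[1]):
        per_sample[f"carrier_event{j}"] = truth.carrier[:, j]
    per_marker = pd.DataFrame(
        {"marker_id": cm.map.marker_id, "in_deletion": truth.in_deletion}
    )
    return per_sample, per_marker
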