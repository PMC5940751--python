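"""Bayesian pairwise-GWAS scan of a genomic region.

Compares five hypotheses for one region given paired summary statistics for
two traits: no association (model 0), a causal variant for trait 1 only
(model 1), for trait 2 only (model 2), one variant shared by both traits
(model 3), or two distinct variants, one per trait (model 4). Evidence is
built from per-variant Wakefield approximate Bayes factors under a
single-causal-variant-per-model assumption; all sums run on the log scale
so that association signals as extreme as z = 60 do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .sumstats import HaplotypePanel, ld_d_prime_r2

__all__ = [
    "ScanPriors",
    "RegionData",
    "RegionModelPosteriors",
    "wakefield_abf",
    "log_wakefield_abf",
    "region_posteriors",
    "scan_signal_table",
]

#: default prior effect-size variance on the log-odds scale
DEFAULT_W = 0.04


@dataclass
class ScanPriors:
    """Per-variant prior probabilities of affecting trait 1 only (pi1),
    trait 2 only (pi2), or both (pi12), plus prior effect variances."""

    pi1: float = 1e-4
    pi2: float = 1e-4
    pi12: float = 1e-5
    w1: float = DEFAULT_W
    w2: float = DEFAULT_W

    def __post_init__(self) -> None:
        if min(self.pi1, self.pi2, self.pi12, self.w1, self.w2) <= 0:
            raise ValueError("priors and effect variances must be positive")
        if self.pi1 + self.pi2 + self.pi12 >= 1:
            raise ValueError("pi1 + pi2 + pi12 must be < 1")


@dataclass
class RegionData:
    """Paired per-variant effects for two traits over one region."""

    rsids: list[str]
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    pos: np.ndarray | None = None
    chrom: str = ""

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.se1 = np.asarray(self.se1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.se2 = np.asarray(self.se2, dtype=float)
        n = len(self.rsids)
        if n == 0:
            raise ValueError("region must contain at least one variant")
        for arr, name in [(self.beta1, "beta1"), (self.se1, "se1"),
                          (self.beta2, "beta2"), (self.se2, "se2")]:
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per variant")
        if (self.se1 <= 0).any() or (self.se2 <= 0).any():
            raise ValueError("standard errors must be positive")
        if self.pos is not None:
            self.pos = np.asarray(self.pos)

    def __len__(self) -> int:
        return len(self.rsids)

    def swapped_traits(self) -> "RegionData":
        return RegionData(rsids=list(self.rsids), beta1=self.beta2, se1=self.se2,
                          beta2=self.beta1, se2=self.se1, pos=self.pos, chrom=self.chrom)


@dataclass
class RegionModelPosteriors:
    """Posterior probabilities of the five region models; they sum to one."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    @property
    def modal_model(self) -> int:
        return int(np.argmax(self.as_array()))


def log_wakefield_abf(beta: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    """log of the Wakefield approximate Bayes factor (association vs null).

    With V = se² and z = beta/se:
    ABF = sqrt(V/(V+w)) · exp(z²·w / (2(V+w))).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("se must be positive")
    if w < 0:
        raise ValueError("prior variance w must be nonnegative")
    v = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + w)) + z2 * w / (2 * (v + w))


def wakefield_abf(beta: float, se: float, w: float) -> float:
    """Wakefield approximate Bayes factor on the natural scale."""
    return float(np.exp(log_wakefield_abf(np.array([beta]), np.array([se]), w)[0]))


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) − exp(b)) for a >= b; −inf when equal."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def region_posteriors(region: RegionData, priors: ScanPriors | None = None) -> RegionModelPosteriors:
    """Posterior probabilities of the five region models.

    Unnormalised evidences, with per-variant Bayes factors A_i (trait 1) and
    B_i (trait 2):

    * E0 = 1
    * E1 = pi1 · ΣA_i
    * E2 = pi2 · ΣB_i
    * E3 = pi12 · Σ A_i·B_i              (same causal variant)
    * E4 = pi1·pi2 · Σ_{i≠j} A_i·B_j     (distinct causal variants)

    computed on the log scale; E4 uses the identity
    Σ_{i≠j} A_iB_j = (ΣA)(ΣB) − Σ A_iB_i. A single-variant region has
    pp4 = 0 exactly.
    """
    priors = priors or ScanPriors()
    la = log_wakefield_abf(region.beta1, region.se1, priors.w1)
    lb = log_wakefield_abf(region.beta2, region.se2, priors.w2)
    lsa = logsumexp(la)
    lsb = logsumexp(lb)
    lsab = logsumexp(la + lb)
    log_e = np.empty(5)
    log_e[0] = 0.0
    log_e[1] = np.log(priors.pi1) + lsa
    log_e[2] = np.log(priors.pi2) + lsb
    log_e[3] = np.log(priors.pi12) + lsab
    log_e[4] = np.log(priors.pi1) + np.log(priors.pi2) + _log_diff_exp(lsa + lsb, lsab)
    log_post = log_e - logsumexp(log_e)
    pp = np.exp(log_post)
    pp /= pp.sum()
    return RegionModelPosteriors(*pp.tolist())


def scan_signal_table(
    region: RegionData,
    priors: ScanPriors | None = None,
    index: str | None = None,
    panel: HaplotypePanel | None = None,
) -> pd.DataFrame:
    """Per-variant association table for signal plots.

    Columns: −log10 p for each trait (from the two-sided normal tail of
    z = beta/se, safe for |z| well past 60), log ABFs, and r² to the index
    variant. The index defaults to the strongest trait-2 signal; its r²
    column entry is 1 by definition. LD requires a haplotype panel covering
    the region; without one the r² column is NaN.
    """
    priors = priors or ScanPriors()
    z1 = region.beta1 / region.se1
    z2 = region.beta2 / region.se2
    if index is None:
        index = region.rsids[int(np.argmax(np.abs(z2)))]
    if index not in region.rsids:
        raise KeyError(f"index variant {index} not in region")
    la = log_wakefield_abf(region.beta1, region.se1, priors.w1)
    lb = log_wakefield_abf(region.beta2, region.se2, priors.w2)
    r2 = np.full(len(region), np.nan)
    for i, rsid in enumerate(region.rsids):
        if rsid == index:
            r2[i] = 1.0
        elif panel is not None and rsid in panel and index in panel:
            r2[i] = ld_d_prime_r2(panel, index, rsid).r2
    return pd.DataFrame({
        "rsid": region.rsids,
        "pos": region.pos if region.pos is not None else np.arange(len(region)),
        "neglog10_p_trait1": _neglog10_p(z1),
        "neglog10_p_trait2": _neglog10_p(z2),
        "log_abf_trait1": la,
        "log_abf_trait2": lb,
        "r2_to_index": r2,
        "is_index": [r == index for r in region.rsids],
    })


def _neglog10_p(z: np.ndarray) -> np.ndarray:
    """−log10 of the two-sided normal p-value, stable for huge |z|."""
    return -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / np.log(10.0)
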