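"""Synthetic paired-GWAS data with known ground truth.

Every generator works at the summary-statistic level (betas, standard
errors, z-scores), which is sufficient for all estimators in this package
and orders of magnitude faster than genotype-level simulation. Each call
takes an explicit seed, draws all randomness from one
``numpy.random.default_rng`` generator, and emits a :class:`TruthRecord` so
recovery tests read the truth from the artifact rather than re-deriving it.

Default scales echo a large CAD -> late-onset Alzheimer's two-sample MR
setting: 52 instruments, exposure GWAS of 60,801 cases / 123,504 controls,
outcome GWAS of 17,008 cases / 37,154 controls, per-allele exposure effects
with |beta| in [0.03, 0.3] (odds ratios about 1.03-1.35), and an optional
outlier with a direct outcome effect of log 3.2 — the scale of the APOE e4
heterozygote odds ratio.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .ldsc import LDScoreEntry
from .pairwise import RegionData
from .sumstats import COMPLEMENT, HaplotypePanel, SumStatsTable, VariantAssociation

__all__ = [
    "TruthRecord",
    "SimConfig",
    "PleiotropySpec",
    "simulate_mr_study",
    "simulate_ldsc_panel",
    "simulate_region",
    "simulate_haplotypes",
    "binary_trait_se",
]

#: exposure GWAS size (cases, controls)
DEFAULT_N_EXP = (60801, 123504)
#: outcome GWAS size (cases, controls)
DEFAULT_N_OUT = (17008, 37154)
#: default instrument count
DEFAULT_K = 52
#: direct (pleiotropic) outcome effect of the planted outlier
APOE_OUTLIER_EFFECT = float(np.log(3.2))
#: spread of true per-allele exposure effect magnitudes
BETA_EXP_RANGE = (0.03, 0.3)

REGION_CONFIGS = ("null", "trait1", "trait2", "shared", "distinct")


@dataclass
class TruthRecord:
    """Ground-truth parameters written next to every simulated dataset."""

    seed: int
    gamma: float | None = None
    pleiotropy: list[float] | None = None
    h2_true: tuple[float, float] | None = None
    rg_true: float | None = None
    overlap: float | None = None
    intercept_x_true: float | None = None
    region_config: str | None = None
    causal_indices: list[int] | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "TruthRecord":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path, encoding="utf-8") as fh:
                d = json.load(fh)
        if d.get("h2_true") is not None:
            d["h2_true"] = tuple(d["h2_true"])
        return cls(**d)


@dataclass
class SimConfig:
    """Reproducible simulation settings: same config + seed => identical output."""

    k: int = DEFAULT_K
    m: int = 5000
    n_exp: tuple[int, int] = DEFAULT_N_EXP
    n_out: tuple[int, int] = DEFAULT_N_OUT
    gamma: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class PleiotropySpec:
    """Direct (non-exposure-mediated) outcome effects of the instruments.

    ``none``: all zero. ``directional``: a common offset ``mean`` on every
    variant (violates the zero-average-pleiotropy assumption, detectable by
    the Egger intercept). ``outlier``: a single variant at ``index`` with a
    large direct effect, the APOE-like scenario.
    """

    kind: str = "none"
    mean: float = 0.0
    index: int = 0
    effect: float = APOE_OUTLIER_EFFECT

    def alphas(self, k: int) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(k)
        if self.kind == "directional":
            return np.full(k, self.mean)
        if self.kind == "outlier":
            if not (0 <= self.index < k):
                raise ValueError("outlier index outside instrument range")
            a = np.zeros(k)
            a[self.index] = self.effect
            return a
        raise ValueError(f"unknown pleiotropy kind {self.kind!r}")


def binary_trait_se(eaf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    """Standard error of a per-allele log-odds effect in a case/control GWAS:
    1 / sqrt(2 p(1-p) · N · phi(1-phi)) with phi the case fraction."""
    n = n_cases + n_controls
    phi = n_cases / n
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n * phi * (1.0 - phi))


_NON_PALINDROMIC = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    p = 2 * stats.norm.sf(np.abs(z))
    return np.maximum(p, 5e-324)  # keep within the (0, 1] invariant


def simulate_mr_study(
    k: int = DEFAULT_K,
    gamma: float = 0.0,
    pleiotropy: PleiotropySpec | None = None,
    n_exp: tuple[int, int] = DEFAULT_N_EXP,
    n_out: tuple[int, int] = DEFAULT_N_OUT,
    seed: int = 0,
) -> tuple[SumStatsTable, SumStatsTable, TruthRecord]:
    """Simulate a two-sample MR study at the summary-statistic level.

    True exposure effects have magnitudes uniform on [0.03, 0.3] with random
    signs; observed effects add sampling noise at the binary-trait standard
    error. The outcome effect of variant i is
    gamma · beta_exp_true_i + alpha_i + noise(se_out_i),
    with alpha the pleiotropy vector. Allele representations in the outcome
    table are randomly swapped and/or strand-complemented so harmonization
    is exercised end to end; palindromic pairs are avoided by construction
    so no instrument is lost to strand ambiguity.
    """
    if k < 2:
        raise ValueError("need at least 2 instruments")
    pleiotropy = pleiotropy or PleiotropySpec()
    rng = np.random.default_rng(seed)

    eaf = rng.uniform(0.10, 0.90, size=k)
    beta_true = rng.uniform(*BETA_EXP_RANGE, size=k) * rng.choice([-1.0, 1.0], size=k)
    se_exp = binary_trait_se(eaf, *n_exp)
    se_out = binary_trait_se(eaf, *n_out)
    beta_exp_obs = beta_true + rng.normal(0.0, se_exp)
    alpha = pleiotropy.alphas(k)
    beta_out_true = gamma * beta_true + alpha
    beta_out_obs = beta_out_true + rng.normal(0.0, se_out)

    allele_idx = rng.integers(0, len(_NON_PALINDROMIC), size=k)
    swap = rng.random(k) < 0.3
    flip = rng.random(k) < 0.3

    exp_records, out_records = [], []
    for i in range(k):
        rsid = f"sim{i:03d}"
        ea, oa = _NON_PALINDROMIC[allele_idx[i]]
        exp_records.append(VariantAssociation(
            rsid=rsid, chrom="1", pos=1_000_000 * (i + 1),
            effect_allele=ea, other_allele=oa, eaf=float(eaf[i]),
            beta=float(beta_exp_obs[i]), se=float(se_exp[i]),
            pvalue=float(_two_sided_p(beta_exp_obs[i] / se_exp[i])),
            n_cases=n_exp[0], n_controls=n_exp[1],
        ))
        o_ea, o_oa, o_beta, o_eaf = ea, oa, float(beta_out_obs[i]), float(eaf[i])
        if swap[i]:
            o_ea, o_oa, o_beta, o_eaf = o_oa, o_ea, -o_beta, 1.0 - o_eaf
        if flip[i]:
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        out_records.append(VariantAssociation(
            rsid=rsid, chrom="1", pos=1_000_000 * (i + 1),
            effect_allele=o_ea, other_allele=o_oa, eaf=o_eaf,
            beta=o_beta, se=float(se_out[i]),
            pvalue=float(_two_sided_p(o_beta / se_out[i])),
            n_cases=n_out[0], n_controls=n_out[1],
        ))

    exposure = SumStatsTable.from_records(exp_records, provenance="simulated-exposure")
    outcome = SumStatsTable.from_records(out_records, provenance="simulated-outcome")
    truth = TruthRecord(
        seed=seed, gamma=gamma, pleiotropy=alpha.tolist(),
        extras={
            "k": k, "n_exp": list(n_exp), "n_out": list(n_out),
            "beta_exp_true": beta_true.tolist(),
            "pleiotropy_kind": pleiotropy.kind,
            "outlier_rsid": f"sim{pleiotropy.index:03d}" if pleiotropy.kind == "outlier" else None,
        },
    )
    return exposure, outcome, truth


#: default phenotypic correlation among overlapping samples
DEFAULT_RHO_PHENO = 0.5


def simulate_ldsc_panel(
    m: int = 5000,
    h2_1: float = 0.3,
    h2_2: float = 0.3,
    rg: float = 0.0,
    n1: float = 184.0,
    n2: float = 54.0,
    overlap: float = 0.0,
    rho_pheno: float = DEFAULT_RHO_PHENO,
    ld_scores: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[LDScoreEntry], TruthRecord]:
    """Genome-wide z-score pairs under the cross-trait LD-score model.

    Per variant j the pair (z1j, z2j) is bivariate normal with variances
    1 + n_t·h2_t·l_j/m and covariance
    sqrt(n1·n2)·rg·sqrt(h2_1·h2_2)·l_j/m + intercept_x,
    where intercept_x = rho_pheno · N_s / sqrt(n1·n2) encodes N_s shared
    samples (``overlap`` is the shared fraction of the smaller study).

    The panel is a scaled-down genome: m defaults to 5,000 rather than the
    millions of a real regression, so the default sample sizes are scaled
    by the same factor (~1/1000 of a 185k/54k-participant study pair) to
    keep the per-variant chi-square statistics on a realistic scale.
    """
    if not (0 <= h2_1 <= 1 and 0 <= h2_2 <= 1):
        raise ValueError("heritabilities must be in [0, 1]")
    if abs(rg) > 1:
        raise ValueError("|rg| must be <= 1")
    if not (0 <= overlap <= 1):
        raise ValueError("overlap fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if ld_scores is None:
        l = 1.0 + rng.gamma(shape=2.0, scale=40.0, size=m)
    else:
        l = np.asarray(ld_scores, dtype=float)
        if l.shape != (m,):
            raise ValueError("ld_scores must have length m")

    n_s = overlap * min(n1, n2)
    icx = rho_pheno * n_s / np.sqrt(n1 * n2)
    var1 = 1.0 + n1 * h2_1 * l / m
    var2 = 1.0 + n2 * h2_2 * l / m
    cov = np.sqrt(n1 * n2) * rg * np.sqrt(h2_1 * h2_2) * l / m + icx
    if np.any(cov**2 >= var1 * var2):
        raise ValueError("infeasible covariance: |corr| >= 1 for some variant")

    u1 = rng.standard_normal(m)
    u2 = rng.standard_normal(m)
    z1 = np.sqrt(var1) * u1
    z2 = (cov / np.sqrt(var1)) * u1 + np.sqrt(var2 - cov**2 / var1) * u2

    entries = [LDScoreEntry(rsid=f"sim{j:06d}", l=float(l[j]), chrom="1", pos=j + 1)
               for j in range(m)]
    truth = TruthRecord(
        seed=seed, h2_true=(h2_1, h2_2), rg_true=rg, overlap=overlap,
        intercept_x_true=float(icx),
        extras={"m": m, "n1": n1, "n2": n2, "rho_pheno": rho_pheno},
    )
    return z1, z2, entries, truth


def _ar1_correlation(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_region(
    m: int = 200,
    ld_corr: float | np.ndarray = 0.5,
    config: str = "null",
    z_causal: float = 8.0,
    se: float = 0.02,
    causal_indices: tuple[int, ...] | None = None,
    seed: int = 0,
) -> tuple[RegionData, TruthRecord]:
    """Regional paired summary statistics under a known causal configuration.

    The z-vector of each trait is multivariate normal with covariance R (the
    LD correlation matrix) and mean R·lambda, lambda nonzero only at the
    causal index/indices: ``null`` (no signal), ``trait1``/``trait2`` (one
    causal variant for one trait), ``shared`` (the same variant for both),
    ``distinct`` (two well-separated variants, one per trait). ``ld_corr``
    may be a full PSD matrix or an AR(1) decay parameter rho in [0, 1).
    Betas are z·se with constant standard error.
    """
    if config not in REGION_CONFIGS:
        raise ValueError(f"config must be one of {REGION_CONFIGS}")
    if np.isscalar(ld_corr):
        rho = float(ld_corr)
        if not (0 <= rho < 1):
            raise ValueError("AR(1) decay parameter must be in [0, 1)")
        r = _ar1_correlation(m, rho)
    else:
        r = np.asarray(ld_corr, dtype=float)
        if r.shape != (m, m):
            raise ValueError("correlation matrix must be m x m")
        if np.linalg.eigvalsh(r).min() < -1e-8:
            raise ValueError("LD correlation matrix is not positive semi-definite")

    if causal_indices is None:
        if config == "distinct":
            causal_indices = (m // 4, (3 * m) // 4)
        elif config == "null":
            causal_indices = ()
        else:
            causal_indices = (m // 2,)
    lam1 = np.zeros(m)
    lam2 = np.zeros(m)
    if config == "trait1":
        lam1[causal_indices[0]] = z_causal
    elif config == "trait2":
        lam2[causal_indices[0]] = z_causal
    elif config == "shared":
        lam1[causal_indices[0]] = z_causal
        lam2[causal_indices[0]] = z_causal
    elif config == "distinct":
        lam1[causal_indices[0]] = z_causal
        lam2[causal_indices[1]] = z_causal

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(r + 1e-10 * np.eye(m))
    z1 = r @ lam1 + chol @ rng.standard_normal(m)
    z2 = r @ lam2 + chol @ rng.standard_normal(m)

    region = RegionData(
        rsids=[f"reg{j:04d}" for j in range(m)],
        beta1=z1 * se, se1=np.full(m, se),
        beta2=z2 * se, se2=np.full(m, se),
        pos=np.arange(1, m + 1) * 1000, chrom="19",
    )
    truth = TruthRecord(
        seed=seed, region_config=config,
        causal_indices=list(causal_indices),
        extras={"m": m, "z_causal": z_causal, "se": se},
    )
    return region, truth


def simulate_haplotypes(
    m: int = 50,
    n_hap: int = 100,
    decay: float = 1.0,
    plant_apoe_block: bool = False,
    seed: int = 0,
) -> HaplotypePanel:
    """Markovian copying process along variants.

    Each haplotype copies its previous-variant allele with probability
    exp(−decay), otherwise redraws from that variant's allele frequency —
    so decay = 0 makes all variants identical (r² = 1 everywhere) and large
    decay makes them independent.

    With ``plant_apoe_block`` four extra variants are appended that
    reproduce the APOE-locus LD signature: ``planted_lowfreq`` (an
    epsilon-2-like rare allele carried only by haplotypes bearing the
    ``planted_partner`` allele, giving D' = 1 with low r²) plus two noisy
    copies of the partner in moderate LD with it.
    """
    if n_hap < 4:
        raise ValueError("need at least 4 haplotypes")
    rng = np.random.default_rng(seed)
    retain_p = float(np.exp(-decay))
    freqs = rng.uniform(0.1, 0.9, size=m)
    mat = np.empty((m, n_hap), dtype=int)
    mat[0] = (rng.random(n_hap) < freqs[0]).astype(int)
    for j in range(1, m):
        fresh = (rng.random(n_hap) < freqs[j]).astype(int)
        keep = rng.random(n_hap) < retain_p
        mat[j] = np.where(keep, mat[j - 1], fresh)
    rsids = [f"hap{j:04d}" for j in range(m)]
    pos = list(np.arange(1, m + 1) * 1000)

    if plant_apoe_block:
        partner = np.zeros(n_hap, dtype=int)
        n_partner = max(2, round(0.4 * n_hap))
        partner[:n_partner] = 1
        lowfreq = np.zeros(n_hap, dtype=int)
        lowfreq[: max(1, round(0.02 * n_hap))] = 1  # subset of partner carriers
        noisy1, noisy2 = partner.copy(), partner.copy()
        for arr in (noisy1, noisy2):
            flips = rng.random(n_hap) < 0.10
            arr[flips] = 1 - arr[flips]
        mat = np.vstack([mat, lowfreq, partner, noisy1, noisy2])
        base = (m + 1) * 1000
        rsids += ["planted_lowfreq", "planted_partner", "planted_proxy1", "planted_proxy2"]
        pos += [base, base + 1000, base + 2000, base + 3000]

    return HaplotypePanel(rsids=rsids, matrix=mat, pos=np.array(pos))
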