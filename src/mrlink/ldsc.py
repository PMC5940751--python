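"""Cross-trait LD-score regression.

Estimates SNP heritability per trait, genetic covariance and genetic
correlation (rg) from genome-wide z-scores, with uncertainty from a
delete-one-block jackknife over contiguous genomic blocks. Sample overlap
between the two GWAS inflates only the cross-trait intercept, never the
slope, which is what makes rg robust to shared participants.

Model: E[z1j·z2j] = sqrt(n1·n2)·gcov·l_j/m + intercept_x, where l_j is the
LD score of variant j, m the number of variants, and the single-trait
special case E[z²] = 1 + n·h²·l_j/m + (confounding offset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LDScoreEntry",
    "H2Fit",
    "LdscFit",
    "read_ldscores",
    "h2_regression",
    "rg_regression",
    "block_jackknife",
    "make_blocks",
]

DEFAULT_N_BLOCKS = 200
#: chi-square cap applied to z² before fitting (outlier guard)
DEFAULT_CHI2_MAX = 80.0


class LdscError(ValueError):
    pass


@dataclass
class LDScoreEntry:
    """Per-variant LD score: sum of r² with surrounding panel variants."""

    rsid: str
    l: float
    chrom: str = ""
    pos: int = 0

    def __post_init__(self) -> None:
        if self.l < 0:
            raise LdscError(f"{self.rsid}: negative LD score")


def read_ldscores(path) -> list[LDScoreEntry]:
    """Read a whitespace-delimited LD-score file (rsid, chrom, pos, l)."""
    df = pd.read_csv(path, sep=r"\s+")
    cols = {c.lower(): c for c in df.columns}
    return [
        LDScoreEntry(rsid=str(r[cols["rsid"]]), chrom=str(r[cols["chrom"]]),
                     pos=int(r[cols["pos"]]), l=float(r[cols["l"]]))
        for _, r in df.iterrows()
    ]


def make_blocks(m: int, n_blocks: int) -> list[tuple[int, int]]:
    """Contiguous, near-equal index blocks covering range(m)."""
    if n_blocks < 2:
        raise LdscError("need at least 2 jackknife blocks")
    if m < n_blocks:
        raise LdscError(f"fewer variants ({m}) than blocks ({n_blocks})")
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def block_jackknife(
    values: np.ndarray,
    block_bounds: Sequence[tuple[int, int]],
    estimator: Callable[[np.ndarray], float],
) -> float:
    """Delete-one-block jackknife standard error of ``estimator(values)``.

    ``values`` holds per-variant contributions (any array indexed on axis 0
    by variant); blocks are (start, end) index ranges.
    """
    g = len(block_bounds)
    if g < 2:
        raise LdscError("jackknife undefined for a single block")
    m = values.shape[0]
    deleted = np.empty(g)
    for j, (a, b) in enumerate(block_bounds):
        keep = np.r_[0:a, b:m]
        deleted[j] = estimator(values[keep])
    return float(np.sqrt((g - 1) / g * np.sum((deleted - deleted.mean()) ** 2)))


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares fit of y = intercept + slope·x; returns
    (slope, intercept)."""
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
    return float(coef[1]), float(coef[0])


def _h2_weights(l: np.ndarray, n: float, m: int, h2: float) -> np.ndarray:
    lf = np.maximum(l, 1.0)
    v = 1.0 + n * max(h2, 0.0) * lf / m
    return 1.0 / (lf * v * v)


def _cross_weights(l, n1, n2, m, h2_1, h2_2) -> np.ndarray:
    lf = np.maximum(l, 1.0)
    v1 = 1.0 + n1 * max(h2_1, 0.0) * lf / m
    v2 = 1.0 + n2 * max(h2_2, 0.0) * lf / m
    return 1.0 / (lf * v1 * v2)


@dataclass
class H2Fit:
    h2: float
    intercept: float
    h2_se: float
    intercept_se: float
    n_blocks: int


def _cap_z(z: np.ndarray, chi2_max: float) -> np.ndarray:
    zmax = np.sqrt(chi2_max)
    return np.clip(z, -zmax, zmax)


def h2_regression(
    z2: np.ndarray,
    ldscores: Sequence[LDScoreEntry] | np.ndarray,
    n: float,
    m: int | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    chi2_max: float = DEFAULT_CHI2_MAX,
) -> H2Fit:
    """Single-trait SNP heritability by LD-score regression.

    Regresses (capped) z² on n·l/m with a free intercept. Two-pass
    heteroskedasticity weights: an unweighted pass yields a provisional h²,
    which parameterises weights 1/(l·(1 + n·h²·l/m)²) for the final fit.
    The intercept sits near 1 absent confounding. Standard errors come from
    a delete-one-block jackknife over contiguous blocks.
    """
    z2 = np.minimum(np.asarray(z2, dtype=float), chi2_max)
    l = _ld_array(ldscores)
    if z2.shape != l.shape:
        raise LdscError("z² and LD scores must be matched per variant")
    if m is None:
        m = len(l)
    x = n * l / m
    slope0, _ = _wls_line(x, z2, np.ones_like(x))
    w = _h2_weights(l, n, m, slope0)
    slope, intercept = _wls_line(x, z2, w)
    blocks = make_blocks(len(l), n_blocks)
    vals = np.column_stack([x, z2, w])
    se_h2 = block_jackknife(vals, blocks, lambda v: _wls_line(v[:, 0], v[:, 1], v[:, 2])[0])
    se_int = block_jackknife(vals, blocks, lambda v: _wls_line(v[:, 0], v[:, 1], v[:, 2])[1])
    return H2Fit(h2=slope, intercept=intercept, h2_se=se_h2,
                 intercept_se=se_int, n_blocks=n_blocks)


def _ld_array(ldscores) -> np.ndarray:
    if isinstance(ldscores, np.ndarray):
        return ldscores.astype(float)
    return np.array([e.l for e in ldscores], dtype=float)


@dataclass
class LdscFit:
    """Cross-trait LD-score regression result.

    ``intercept_x`` estimates rho·N_s/sqrt(n1·n2), the phenotypic-correlation
    times sample-overlap term; rg is reported unclamped, with
    ``rg_out_of_range`` set when |rg| > 1.
    """

    h2_1: float
    h2_2: float
    gcov: float
    rg: float
    intercept_1: float
    intercept_2: float
    intercept_x: float
    h2_1_se: float
    h2_2_se: float
    gcov_se: float
    rg_se: float
    intercept_x_se: float
    p_rg: float
    n_blocks: int

    @property
    def rg_out_of_range(self) -> bool:
        return abs(self.rg) > 1

    @property
    def rg_ci95(self) -> tuple[float, float]:
        return self.rg - 1.96 * self.rg_se, self.rg + 1.96 * self.rg_se


def rg_regression(
    z1: np.ndarray,
    z2: np.ndarray,
    ldscores: Sequence[LDScoreEntry] | np.ndarray,
    n1: float,
    n2: float,
    m: int | None = None,
    n_blocks: int = DEFAULT_N_BLOCKS,
    chi2_max: float = DEFAULT_CHI2_MAX,
) -> LdscFit:
    """Genetic correlation between two traits from paired z-scores.

    Fits the two single-trait regressions, then regresses z1·z2 on
    sqrt(n1·n2)·l/m with a free intercept; the slope is the genetic
    covariance and rg = gcov / sqrt(h²_1·h²_2). All standard errors (and the
    normal-approximation p-value for rg = 0) come from one joint
    delete-one-block jackknife so correlated estimation error propagates.
    """
    z1 = _cap_z(np.asarray(z1, dtype=float), chi2_max)
    z2 = _cap_z(np.asarray(z2, dtype=float), chi2_max)
    l = _ld_array(ldscores)
    if not (z1.shape == z2.shape == l.shape):
        raise LdscError("z-scores and LD scores must be matched per variant")
    if np.allclose(l, l[0]):
        raise LdscError("constant LD scores: slope and intercept are unidentifiable")
    if m is None:
        m = len(l)

    fit1 = h2_regression(z1**2, l, n1, m, n_blocks, chi2_max)
    fit2 = h2_regression(z2**2, l, n2, m, n_blocks, chi2_max)
    x1, x2 = n1 * l / m, n2 * l / m
    xc = np.sqrt(n1 * n2) * l / m
    y = z1 * z2
    # all three fits draw their heteroskedasticity weights from the same
    # generation (the unweighted first pass), so two identical traits give
    # gcov == h2 and rg == 1 exactly
    slope0_1, _ = _wls_line(x1, z1**2, np.ones_like(x1))
    slope0_2, _ = _wls_line(x2, z2**2, np.ones_like(x2))
    wc = _cross_weights(l, n1, n2, m, slope0_1, slope0_2)
    gcov, intercept_x = _wls_line(xc, y, wc)
    w1 = _h2_weights(l, n1, m, slope0_1)
    w2 = _h2_weights(l, n2, m, slope0_2)

    def _rg_parts(v: np.ndarray) -> tuple[float, float, float, float]:
        h2a, _ = _wls_line(v[:, 0], v[:, 3], v[:, 5])
        h2b, _ = _wls_line(v[:, 1], v[:, 4], v[:, 6])
        gc, ix = _wls_line(v[:, 2], v[:, 7], v[:, 8])
        return h2a, h2b, gc, ix

    def _rg_of(v: np.ndarray) -> float:
        h2a, h2b, gc, _ = _rg_parts(v)
        denom = np.sqrt(max(h2a, 0.0) * max(h2b, 0.0))
        if denom == 0:
            return np.nan
        return gc / denom

    vals = np.column_stack([x1, x2, xc, z1**2, z2**2, w1, w2, y, wc])
    blocks = make_blocks(len(l), n_blocks)
    gcov_se = block_jackknife(vals, blocks, lambda v: _rg_parts(v)[2])
    ix_se = block_jackknife(vals, blocks, lambda v: _rg_parts(v)[3])

    denom = np.sqrt(max(fit1.h2, 0.0) * max(fit2.h2, 0.0))
    rg = gcov / denom if denom > 0 else np.nan
    rg_se = block_jackknife(vals, blocks, _rg_of)
    if np.isnan(rg):
        p_rg = np.nan
    elif rg_se == 0:
        p_rg = 1.0 if rg == 0 else 0.0
    else:
        p_rg = float(2 * stats.norm.sf(abs(rg) / rg_se))

    return LdscFit(
        h2_1=fit1.h2, h2_2=fit2.h2, gcov=gcov, rg=float(rg),
        intercept_1=fit1.intercept, intercept_2=fit2.intercept,
        intercept_x=intercept_x,
        h2_1_se=fit1.h2_se, h2_2_se=fit2.h2_se,
        gcov_se=gcov_se, rg_se=rg_se, intercept_x_se=ix_se,
        p_rg=p_rg, n_blocks=n_blocks,
    )
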