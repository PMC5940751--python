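"""GWAS summary statistics: reading, validation, allele harmonization,
LD metrics from haplotype panels, proxy search and instrument selection.

Conventions
-----------
* Effects (``beta``) are on the log-odds scale, per copy of the effect allele.
* Coordinates are 1-based, inclusive.
* Alleles are single nucleotides (A/C/G/T); indels are rejected because the
  estimators downstream assume biallelic SNVs.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VariantAssociation",
    "SumStatsTable",
    "HaplotypePanel",
    "LDPair",
    "HarmonizedPair",
    "InstrumentSelection",
    "read_sumstats",
    "harmonize",
    "ld_d_prime_r2",
    "find_proxy",
    "select_instruments",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names for tab-delimited GWAS summary files
DEFAULT_COLUMNS = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "FRQ",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n_cases": "N_CASES",
    "n_controls": "N_CONTROLS",
    "recessive": "RECESSIVE",
}

#: half-width of the allele-frequency window around 0.5 inside which a
#: palindromic (A/T or C/G) variant cannot be reliably oriented
DEFAULT_PALINDROME_WINDOW = 0.08


class SumStatsError(ValueError):
    """Raised for invalid summary-statistic inputs or configuration."""


@dataclass
class VariantAssociation:
    """Per-effect-allele association of one variant in one GWAS."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise SumStatsError(f"{self.rsid}: alleles must be single nucleotides A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise SumStatsError(f"{self.rsid}: effect and other allele identical")
        if not np.isfinite(self.beta):
            raise SumStatsError(f"{self.rsid}: non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            raise SumStatsError(f"{self.rsid}: se must be positive and finite")
        if not (0 < self.pvalue <= 1):
            raise SumStatsError(f"{self.rsid}: p-value outside (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumStatsError(f"{self.rsid}: eaf outside [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def z(self) -> float:
        return self.beta / self.se


_COLUMN_ORDER = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n_cases", "n_controls",
]


@dataclass
class SumStatsTable:
    """A validated collection of :class:`VariantAssociation`, unique by rsid."""

    df: pd.DataFrame
    provenance: str = ""
    rejected: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.df.index.name != "rsid":
            self.df = self.df.set_index("rsid", drop=False)
        if self.df.index.has_duplicates:
            dupes = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise SumStatsError(f"duplicate rsids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.df.index

    @property
    def rsids(self) -> list[str]:
        return self.df.index.tolist()

    def get(self, rsid: str) -> VariantAssociation:
        row = self.df.loc[rsid]
        return VariantAssociation(
            rsid=rsid,
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            beta=float(row["beta"]),
            se=float(row["se"]),
            pvalue=float(row["pvalue"]),
            eaf=None if pd.isna(row.get("eaf")) else float(row["eaf"]),
            n_cases=None if pd.isna(row.get("n_cases")) else int(row["n_cases"]),
            n_controls=None if pd.isna(row.get("n_controls")) else int(row["n_controls"]),
        )

    def subset(self, rsids: Sequence[str]) -> "SumStatsTable":
        keep = [r for r in rsids if r in self.df.index]
        return SumStatsTable(self.df.loc[keep].copy(), provenance=self.provenance)

    @classmethod
    def from_records(cls, records: Iterable[VariantAssociation], provenance: str = "") -> "SumStatsTable":
        rows = []
        for rec in records:
            rec.validate()
            rows.append({k: getattr(rec, k) for k in _COLUMN_ORDER})
        df = pd.DataFrame(rows, columns=_COLUMN_ORDER)
        return cls(df, provenance=provenance)

    def to_tsv(self, path, column_map: Mapping[str, str] | None = None) -> None:
        cmap = dict(DEFAULT_COLUMNS)
        if column_map:
            cmap.update(column_map)
        out = self.df[_COLUMN_ORDER].rename(columns={k: cmap[k] for k in _COLUMN_ORDER})
        out.to_csv(path, sep="\t", index=False)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> SumStatsTable:
    """Read a delimited GWAS summary-statistics file.

    Rows failing validation (non-positive se, out-of-range p or frequency,
    non-SNV alleles, duplicate rsid) are rejected individually and reported
    in the returned table's ``rejected`` frame, never silently kept.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited text file with a header row; ``.gz``
        transparently supported.
    column_map
        Overrides for :data:`DEFAULT_COLUMNS` (logical name -> file header).
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    try:
        with _open_text(path) as fh:
            raw = pd.read_csv(fh, sep=r"\s+", dtype=str)
    except OSError as exc:
        raise IOError(f"cannot read summary statistics from {path}: {exc}") from exc

    mandatory = ["rsid", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue"]
    missing = [cmap[k] for k in mandatory if cmap[k] not in raw.columns]
    if missing:
        raise SumStatsError(f"missing mandatory column(s) {missing} in {path}")

    optional = ["eaf", "n_cases", "n_controls"]
    records: list[dict] = []
    rejected: list[dict] = []
    seen: set[str] = set()
    for i, row in raw.iterrows():
        try:
            rec = VariantAssociation(
                rsid=str(row[cmap["rsid"]]),
                chrom=str(row[cmap["chrom"]]),
                pos=int(row[cmap["pos"]]),
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pvalue=float(row[cmap["pvalue"]]),
                eaf=_opt_float(row, cmap["eaf"]),
                n_cases=_opt_int(row, cmap["n_cases"]),
                n_controls=_opt_int(row, cmap["n_controls"]),
            )
            rec.validate()
            if rec.rsid in seen:
                raise SumStatsError(f"{rec.rsid}: duplicate rsid")
        except (SumStatsError, ValueError, TypeError) as exc:
            rejected.append({"row": int(i), "rsid": str(row.get(cmap["rsid"], "?")), "reason": str(exc)})
            continue
        seen.add(rec.rsid)
        d = {k: getattr(rec, k) for k in _COLUMN_ORDER}
        if cmap["recessive"] in raw.columns:
            d["recessive"] = str(row[cmap["recessive"]]).strip().lower() in {"1", "true", "yes"}
        records.append(d)

    cols = _COLUMN_ORDER + (["recessive"] if records and "recessive" in records[0] else [])
    df = pd.DataFrame(records, columns=cols)
    table = SumStatsTable(df, provenance=provenance or str(path))
    table.rejected = pd.DataFrame(rejected, columns=["row", "rsid", "reason"])
    return table


def _opt_float(row, col):
    if col not in row.index or pd.isna(row[col]):
        return None
    return float(row[col])


def _opt_int(row, col):
    if col not in row.index or pd.isna(row[col]):
        return None
    return int(float(row[col]))


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedPair:
    """Exposure/outcome effects for one variant, sign-aligned to the
    exposure effect allele."""

    rsid: str
    action: str  # kept | swapped | strand-flipped | swapped+flipped | dropped-*
    beta_exp: float = np.nan
    se_exp: float = np.nan
    beta_out: float = np.nan
    se_out: float = np.nan
    eaf_exp: float | None = None
    eaf_out: float | None = None
    reason: str = ""

    @property
    def dropped(self) -> bool:
        return self.action.startswith("dropped")


def _freq_side(eaf: float | None, window: float) -> int:
    """-1 / +1 for eaf decisively below/above 0.5, 0 if ambiguous or missing."""
    if eaf is None:
        return 0
    if eaf < 0.5 - window:
        return -1
    if eaf > 0.5 + window:
        return 1
    return 0


def harmonize(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure effect allele, variant by variant.

    Matching rules, applied per shared rsid:

    * same allele pair -> ``kept``;
    * alleles swapped -> outcome beta negated, eaf complemented (``swapped``);
    * alleles match only after strand complement -> complement, then the same
      two rules (``strand-flipped`` / ``swapped+flipped``);
    * palindromic variants (A/T, C/G) cannot be oriented from labels, so they
      are resolved by allele-frequency agreement — only when both frequencies
      are decisively away from 0.5 (outside ``0.5 +/- palindrome_eaf_window``),
      otherwise ``dropped-palindromic``;
    * rsids absent from the outcome -> ``dropped-missing``;
    * irreconcilable allele pairs -> ``dropped`` with reason
      ``allele-mismatch``, never silently kept.
    """
    pairs: list[HarmonizedPair] = []
    for rsid in exposure.rsids:
        if rsid not in outcome:
            pairs.append(HarmonizedPair(rsid, "dropped-missing", reason="absent from outcome"))
            continue
        e = exposure.get(rsid)
        o = outcome.get(rsid)
        pairs.append(_harmonize_one(e, o, palindrome_eaf_window))
    return pairs


def _harmonize_one(e: VariantAssociation, o: VariantAssociation, window: float) -> HarmonizedPair:
    rsid = e.rsid
    base = dict(beta_exp=e.beta, se_exp=e.se, eaf_exp=e.eaf)

    if e.is_palindromic or o.is_palindromic:
        o_alleles = {o.effect_allele, o.other_allele}
        if {e.effect_allele, e.other_allele} != o_alleles and \
                {COMPLEMENT[e.effect_allele], COMPLEMENT[e.other_allele]} != o_alleles:
            return HarmonizedPair(rsid, "dropped", reason="allele-mismatch", **base)
        side_e = _freq_side(e.eaf, window)
        side_o = _freq_side(o.eaf, window)
        if side_e == 0 or side_o == 0:
            return HarmonizedPair(
                rsid, "dropped-palindromic", **base,
                reason=f"eaf within 0.5+/-{window} or missing",
            )
        # labels are uninformative under strand ambiguity; orient by frequency
        if side_e == side_o:
            return HarmonizedPair(rsid, "kept", beta_out=o.beta, se_out=o.se,
                                  eaf_out=o.eaf, **base)
        return HarmonizedPair(rsid, "swapped+flipped", beta_out=-o.beta, se_out=o.se,
                              eaf_out=None if o.eaf is None else 1 - o.eaf, **base)

    if (e.effect_allele, e.other_allele) == (o.effect_allele, o.other_allele):
        return HarmonizedPair(rsid, "kept", beta_out=o.beta, se_out=o.se,
                              eaf_out=o.eaf, **base)
    if (e.effect_allele, e.other_allele) == (o.other_allele, o.effect_allele):
        return HarmonizedPair(rsid, "swapped", beta_out=-o.beta, se_out=o.se,
                              eaf_out=None if o.eaf is None else 1 - o.eaf, **base)
    fe, fo = COMPLEMENT[o.effect_allele], COMPLEMENT[o.other_allele]
    if (e.effect_allele, e.other_allele) == (fe, fo):
        return HarmonizedPair(rsid, "strand-flipped", beta_out=o.beta, se_out=o.se,
                              eaf_out=o.eaf, **base)
    if (e.effect_allele, e.other_allele) == (fo, fe):
        return HarmonizedPair(rsid, "swapped+flipped", beta_out=-o.beta, se_out=o.se,
                              eaf_out=None if o.eaf is None else 1 - o.eaf, **base)
    return HarmonizedPair(rsid, "dropped", reason="allele-mismatch", **base)


def harmonization_report(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """TSV-ready per-variant report of harmonization actions."""
    return pd.DataFrame(
        [{"rsid": p.rsid, "action": p.action, "reason": p.reason} for p in pairs],
        columns=["rsid", "action", "reason"],
    )


# ---------------------------------------------------------------------------
# Linkage disequilibrium from a haplotype panel
# ---------------------------------------------------------------------------

class MonomorphicVariantError(ValueError):
    """LD is undefined for a variant with a single observed allele."""


@dataclass
class LDPair:
    """|D'| and r-squared between two variants."""

    d_prime: float
    r2: float


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes: ``matrix[i, h]`` is the allele (0/1) of
    variant ``i`` on haplotype ``h``.

    The "1" allele is the coded allele named in ``alt_alleles``; allele
    frequencies below refer to it.
    """

    rsids: list[str]
    matrix: np.ndarray  # (n_variants, n_haplotypes), entries in {0,1}
    pos: np.ndarray | None = None
    ref_alleles: list[str] | None = None
    alt_alleles: list[str] | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.rsids):
            raise ValueError("haplotype matrix must be (n_variants, n_haplotypes)")
        if self.matrix.shape[1] < 2:
            raise ValueError("panel needs at least 2 haplotypes")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("haplotype matrix entries must be 0/1")
        if len(set(self.rsids)) != len(self.rsids):
            raise ValueError("panel rsids must be unique")
        if self.pos is not None:
            self.pos = np.asarray(self.pos)
        self._index = {r: i for i, r in enumerate(self.rsids)}

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def row(self, rsid: str) -> np.ndarray:
        try:
            return self.matrix[self._index[rsid]]
        except KeyError:
            raise KeyError(f"variant {rsid} not in haplotype panel") from None

    def position(self, rsid: str) -> float:
        if self.pos is None:
            return np.nan
        return float(self.pos[self._index[rsid]])

    @classmethod
    def from_matrix_files(cls, matrix_path, variants_path) -> "HaplotypePanel":
        """Load from a 0/1 matrix (variants x haplotypes, whitespace-delimited)
        plus a sidecar variant list (rsid, pos[, ref, alt])."""
        mat = np.loadtxt(matrix_path, dtype=int, ndmin=2)
        var = pd.read_csv(variants_path, sep=r"\s+", header=None)
        rsids = var.iloc[:, 0].astype(str).tolist()
        pos = var.iloc[:, 1].to_numpy() if var.shape[1] > 1 else None
        return cls(rsids=rsids, matrix=mat, pos=pos)

    @classmethod
    def from_vcf(cls, path) -> "HaplotypePanel":
        """Load phased GT fields from an (uncompressed or gzipped) VCF."""
        rsids, rows, pos, refs, alts = [], [], [], [], []
        with _open_text(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, p, rsid, ref, alt = f[0], f[1], f[2], f[3], f[4]
                alleles = []
                for sample in f[9:]:
                    gt = sample.split(":")[0]
                    alleles.extend(int(a) for a in gt.replace("|", "/").split("/"))
                rsids.append(rsid)
                rows.append(alleles)
                pos.append(int(p))
                refs.append(ref)
                alts.append(alt)
        return cls(rsids=rsids, matrix=np.array(rows), pos=np.array(pos),
                   ref_alleles=refs, alt_alleles=alts)


def ld_d_prime_r2(panel: HaplotypePanel, v1: str, v2: str) -> LDPair:
    """|D'| and r² between two panel variants from haplotype frequencies.

    With coded-allele frequencies p_A, p_B and joint frequency p_AB:
    D = p_AB − p_A·p_B; D' = |D|/D_max with the sign-dependent frequency
    bound D_max; r² = D² / (p_A(1−p_A) p_B(1−p_B)).
    """
    a = panel.row(v1).astype(float)
    b = panel.row(v2).astype(float)
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0):
        raise MonomorphicVariantError(f"{v1} is monomorphic in the panel")
    if p_b in (0.0, 1.0):
        raise MonomorphicVariantError(f"{v2} is monomorphic in the panel")
    p_ab = (a * b).mean()
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    # guard against float round-off at the theoretical bounds
    return LDPair(d_prime=float(np.clip(d_prime, 0.0, 1.0)),
                  r2=float(np.clip(r2, 0.0, 1.0)))


def find_proxy(
    target: str,
    candidates: SumStatsTable,
    panel: HaplotypePanel,
    r2_min: float = 0.80,
) -> str | None:
    """Best LD proxy for ``target`` among ``candidates`` present in the panel.

    Returns the candidate with maximal r² to the target provided r² >= r2_min;
    ties broken by smaller base-position distance, then lexicographic rsid.
    """
    if not (0 < r2_min <= 1):
        raise ValueError("r2_min must be in (0, 1]")
    if target not in panel:
        raise KeyError(f"proxy target {target} not in haplotype panel")
    t_pos = panel.position(target)
    best: tuple | None = None
    for rsid in candidates.rsids:
        if rsid not in panel:
            continue
        if rsid == target:
            r2 = 1.0
        else:
            try:
                r2 = ld_d_prime_r2(panel, target, rsid).r2
            except MonomorphicVariantError:
                continue
        if r2 < r2_min:
            continue
        dist = abs(panel.position(rsid) - t_pos) if np.isfinite(t_pos) else np.inf
        key = (-r2, dist, rsid)
        if best is None or key < best[0]:
            best = (key, rsid)
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Instrument selection
# ---------------------------------------------------------------------------

GWS_ALPHA = 5e-8


@dataclass
class InstrumentSelection:
    """Selected instruments with low-MAF annotations (flagged, not removed)."""

    rsids: list[str]
    low_maf: set[str]
    mode: str

    def __iter__(self):
        return iter(self.rsids)

    def __len__(self) -> int:
        return len(self.rsids)


def select_instruments(
    table: SumStatsTable,
    mode: str = "gws",
    gws_alpha: float = GWS_ALPHA,
    fdr_q: float = 0.05,
    maf_min: float = 0.05,
) -> InstrumentSelection:
    """Select instrument variants at genome-wide significance or by FDR.

    ``gws`` keeps variants with p <= ``gws_alpha`` (default 5e-8); ``fdr``
    applies Benjamini–Hochberg at rate ``fdr_q`` over the whole table. In
    both modes, variants with minor allele frequency below ``maf_min`` are
    flagged in the result but deliberately not removed.
    """
    if mode not in {"gws", "fdr"}:
        raise ValueError(f"unknown selection mode {mode!r}")
    if len(table) == 0:
        import warnings

        warnings.warn("instrument selection on an empty table", stacklevel=2)
        return InstrumentSelection([], set(), mode)
    p = table.df["pvalue"].to_numpy(dtype=float)
    if mode == "gws":
        keep = p <= gws_alpha
    else:
        keep, _, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    rsids = [r for r, k in zip(table.rsids, keep) if k]
    low_maf = set()
    for r in rsids:
        maf = table.get(r).maf
        if maf is not None and maf < maf_min:
            low_maf.add(r)
    return InstrumentSelection(rsids, low_maf, mode)
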