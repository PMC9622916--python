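"""Weighted genetic risk score (wGRS) construction for bladder cancer.

The score for individual *i* over a panel of risk variants is

    wGRS_i = sum_x beta_x * d_ix / n_SNPs

where ``d_ix`` in [0, 2] is the expected count of effect alleles (genotype
dosage) and ``beta_x = ln(OR_x)`` is the per-allele log odds ratio reported
by bladder-cancer GWAS.  The division by the number of SNPs is a pure
rescaling kept for fidelity with the published equation; standardized
(z-score) versions of the score are invariant to it.

The packaged default weight table carries the 18 GWAS variants (rsid,
gene region, alleles, effect-allele frequency, OR and ln OR) used in the
cohort analysis this package implements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpWeight",
    "default_weights_path",
    "load_weights",
    "write_weights",
    "load_dosages_tsv",
    "load_dosages_vcf",
    "compute_wgrs",
    "standardize",
    "assign_groups",
]

#: tolerance for agreement between a supplied ln(OR) column and ln of the
#: supplied OR; weight tables print ln(OR) to 6 decimals, so rounding error
#: is at most 5e-7.
LNOR_TOL = 1e-6

@dataclass(frozen=True)
class SnpWeight:
    """One variant's identity, alleles, frequency and log-odds weight."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    odds_ratio: float
    weight: float
    gene: str = ""

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.rsid}: odds ratio must be > 0, got {self.odds_ratio}")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.rsid}: EAF must lie strictly in (0, 1), got {self.eaf}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if abs(self.weight - math.log(self.odds_ratio)) > LNOR_TOL:
            raise ValueError(
                f"{self.rsid}: weight {self.weight} disagrees with "
                f"ln(OR) = {math.log(self.odds_ratio):.6f} beyond {LNOR_TOL}"
            )


def default_weights_path() -> Path:
    """Path of the packaged 18-SNP bladder-cancer weight table."""
    return Path(str(resources.files("bpgrs").joinpath("data/bladder_snp_weights.tsv")))


def load_weights(path: str | Path | None = None) -> list[SnpWeight]:
    """Read a SNP weight table (TSV) into validated :class:`SnpWeight` records.

    The table must have columns ``rsid``, ``effect_allele``, ``other_allele``,
    ``eaf`` (fraction) and ``or``; ``ln_or`` is optional.  The weight used
    downstream is always ``ln(OR)`` recomputed at full precision — a supplied
    ``ln_or`` column is only validated against it (to 1e-6, i.e. the printed
    precision), never substituted, so rounding error is not compounded.
    """
    path = default_weights_path() if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str})
    required = {"rsid", "effect_allele", "other_allele", "eaf", "or"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight table {path} lacks columns: {sorted(missing)}")
    dup = df["rsid"][df["rsid"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate rsid(s) in weight table: {sorted(dup)}")

    weights: list[SnpWeight] = []
    for row in df.to_dict("records"):  # "or" is a keyword, so no itertuples
        rsid = str(row["rsid"])
        odds_ratio = float(row["or"])
        if odds_ratio <= 0:
            raise ValueError(f"{rsid}: odds ratio must be > 0, got {odds_ratio}")
        weight = math.log(odds_ratio)
        if not pd.isna(row.get("ln_or", np.nan)):
            stated = float(row["ln_or"])
            if abs(stated - weight) > LNOR_TOL:
                raise ValueError(
                    f"{rsid}: stated ln(OR) {stated} differs from "
                    f"ln({odds_ratio}) = {weight:.7f} by more than {LNOR_TOL}"
                )
        weights.append(
            SnpWeight(
                rsid=rsid,
                effect_allele=str(row["effect_allele"]),
                other_allele=str(row["other_allele"]),
                eaf=float(row["eaf"]),
                odds_ratio=odds_ratio,
                weight=weight,
                gene=str(row.get("gene", "")),
            )
        )
    return weights


def write_weights(weights: Sequence[SnpWeight], path: str | Path) -> None:
    """Write a weight table TSV that :func:`load_weights` round-trips."""
    df = pd.DataFrame(
        {
            "rsid": [w.rsid for w in weights],
            "gene": [w.gene for w in weights],
            "effect_allele": [w.effect_allele for w in weights],
            "other_allele": [w.other_allele for w in weights],
            "eaf": [w.eaf for w in weights],
            "or": [w.odds_ratio for w in weights],
            "ln_or": [round(w.weight, 6) for w in weights],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_dosages_tsv(path: str | Path) -> pd.DataFrame:
    """Read a dosage matrix: rows = individuals (first column id), columns = rsids.

    Values are expected effect-allele counts in [0, 2]; empty cells are missing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    _validate_dosage_range(df)
    return df


def load_dosages_vcf(path: str | Path, weights: Sequence[SnpWeight]) -> pd.DataFrame:
    """Extract a dosage matrix from a VCF, harmonizing alleles to the weight table.

    Uses the ``DS`` FORMAT field when present, otherwise converts hard GT calls
    to 0/1/2 (missing GT -> NaN).  A site whose ALT matches the variant's
    *other* allele (and REF the effect allele) is flipped to ``2 - d`` so that
    dosages always count effect alleles.  Sites with alleles matching neither
    orientation raise.
    """
    from cyvcf2 import VCF  # optional dependency

    by_rsid = {w.rsid: w for w in weights}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid not in by_rsid:
            continue
        w = by_rsid[rsid]
        alt = variant.ALT[0] if variant.ALT else ""
        ref = variant.REF
        if ref == w.other_allele and alt == w.effect_allele:
            flip = False
        elif ref == w.effect_allele and alt == w.other_allele:
            flip = True
        else:
            raise ValueError(
                f"{rsid}: VCF alleles {ref}/{alt} match neither orientation of "
                f"{w.effect_allele}/{w.other_allele}"
            )
        try:
            ds = np.asarray(variant.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            ds = None
        if ds is None:
            gt = np.asarray(variant.gt_types, dtype=float)  # 0,1,3 = counts; 2 = unknown
            ds = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        if flip:
            ds = 2.0 - ds
        rows[rsid] = ds
    missing = [r for r in by_rsid if r not in rows]
    if missing:
        raise ValueError(f"VCF lacks weight-table variants: {missing}")
    df = pd.DataFrame(rows, index=pd.Index(samples, name="id"))
    _validate_dosage_range(df)
    return df


def _validate_dosage_range(df: pd.DataFrame) -> None:
    vals = df.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if finite.any():
        if np.nanmin(vals) < 0:
            raise ValueError("negative genotype dosage encountered")
        if np.nanmax(vals) > 2:
            raise ValueError("genotype dosage above 2 encountered")


def compute_wgrs(
    dosages: pd.DataFrame,
    weights: Sequence[SnpWeight],
    missing_policy: Literal["exclude", "impute"] = "exclude",
) -> pd.DataFrame:
    """Compute the weighted genetic risk score for every individual.

    Parameters
    ----------
    dosages
        Individuals x rsids dosage matrix (NaN = missing genotype).
    weights
        Variant weights; every rsid must be a column of ``dosages``.
    missing_policy
        ``"exclude"`` drops individuals with any missing genotype (the
        analysis default); ``"impute"`` substitutes the population
        expectation ``2 * EAF`` for missing entries.

    Returns
    -------
    DataFrame indexed by individual id with column ``raw_score``; the number
    of excluded individuals is available as ``result.attrs["n_excluded"]``.
    """
    rsids = [w.rsid for w in weights]
    absent = [r for r in rsids if r not in dosages.columns]
    if absent:
        raise ValueError(f"dosage matrix lacks weight-table variants: {absent}")
    mat = dosages[rsids].to_numpy(dtype=float)
    finite = np.isfinite(mat)
    if finite.any() and (np.nanmin(mat) < 0 or np.nanmax(mat) > 2):
        raise ValueError("dosages must lie in [0, 2]")
    beta = np.array([w.weight for w in weights])
    index = dosages.index
    if missing_policy == "impute":
        expect = 2.0 * np.array([w.eaf for w in weights])
        mat = np.where(finite, mat, np.broadcast_to(expect, mat.shape))
        n_excluded = 0
    elif missing_policy == "exclude":
        keep = finite.all(axis=1)
        n_excluded = int((~keep).sum())
        mat = mat[keep]
        index = index[keep]
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    raw = mat @ beta / len(weights)
    out = pd.DataFrame({"raw_score": raw}, index=index)
    out.index.name = "id"
    out.attrs["n_excluded"] = n_excluded
    return out


def standardize(score: pd.DataFrame, column: str = "raw_score") -> pd.DataFrame:
    """Add a ``z_score`` column: z = (x - mean) / SD with the n-1 denominator."""
    x = score[column].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("cannot standardize: fewer than 2 distinct score values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize: zero variance")
    out = score.copy()
    out["z_score"] = (x - x.mean()) / sd
    return out


def assign_groups(
    score: pd.DataFrame,
    scheme: Literal["quartiles", "median", "both"] = "both",
    column: str = "raw_score",
) -> pd.DataFrame:
    """Assign quantile groups from the sample distribution of the score.

    Quartile labels 1-4 use sample 25/50/75 percentile cut points; a value
    equal to a cut point is placed in the lower group, so group sizes differ
    only by the number of boundary ties.  The median scheme labels
    ``lower50`` / ``upper50`` by the same <= rule.
    """
    x = score[column].to_numpy(dtype=float)
    out = score.copy()
    if scheme in ("quartiles", "both"):
        if len(x) < 4:
            raise ValueError("need at least 4 individuals for quartiles")
        cuts = np.percentile(x, [25, 50, 75])
        out["quartile"] = 1 + (x[:, None] > cuts[None, :]).sum(axis=1)
    if scheme in ("median", "both"):
        if len(x) < 2:
            raise ValueError("need at least 2 individuals for a median split")
        med = np.percentile(x, 50)
        out["median_group"] = np.where(x > med, "upper50", "lower50")
    if scheme not in ("quartiles", "median", "both"):
        raise ValueError(f"unknown grouping scheme {scheme!r}")
    return out
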