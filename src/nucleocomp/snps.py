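"""Classify strain polymorphisms and compare rare-allele fractions.

Biallelic intergenic SNPs called in more than 20 strains are classified by
the A/T balance of their alleles: a SNP is *A/T gaining* when the major
allele is C or G and the minor allele is A or T (the population is moving
toward A/T), *A/T losing* in the reciprocal case, and *A/T conserving*
otherwise. SNPs are further stratified by flanking context (G/C-flanked iff
both reference flanks are G or C) and by nucleosome occupancy class.

Under weak selection on local G+C content the site-frequency spectrum of
deleterious changes shifts toward rare alleles; the summary statistic is the
fraction of SNPs with minor-allele frequency below a threshold (default
0.20), compared between classes with a 2x2 Pearson chi-squared test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

AT = frozenset("AT")
GC = frozenset("GC")

MIN_STRAINS = 20
RARE_THRESHOLD = 0.20

REQUIRED_COLUMNS = ["allele1", "allele2", "count1", "count2",
                    "n_called", "flank5", "flank3", "occupancy", "intergenic"]


@dataclass
class RareFractionSummary:
    n_snps: int
    n_rare: int

    @property
    def fraction(self) -> float:
        if self.n_snps == 0:
            raise ValueError("empty class: rare fraction undefined")
        return self.n_rare / self.n_snps


def filter_snps(records: pd.DataFrame,
                min_strains: int = MIN_STRAINS) -> pd.DataFrame:
    """Keep intergenic biallelic SNPs called in more than ``min_strains``.

    Biallelic means exactly two distinct alleles each seen at least once.
    """
    df = records
    biallelic = ((df["count1"] >= 1) & (df["count2"] >= 1)
                 & (df["allele1"] != df["allele2"]))
    keep = df["intergenic"].astype(bool) & biallelic & (df["n_called"] > min_strains)
    return df.loc[keep].reset_index(drop=True)


def classify_snps(records: pd.DataFrame) -> pd.DataFrame:
    """Attach direction / context / tie columns to filtered SNP records.

    Major allele = higher strain count. Exact 50/50 ties carry
    ``direction = "tie"`` and are excluded from downstream summaries (they
    are tallied by the caller via the column). Context is read from the
    reference flanks: GC_flanked iff both flanks are G or C.
    """
    df = records.copy()
    c1 = df["count1"].to_numpy()
    c2 = df["count2"].to_numpy()
    a1 = df["allele1"].to_numpy(dtype=object)
    a2 = df["allele2"].to_numpy(dtype=object)
    major = np.where(c1 >= c2, a1, a2)
    minor = np.where(c1 >= c2, a2, a1)
    tie = c1 == c2

    major_gc = np.isin(major, list(GC))
    minor_gc = np.isin(minor, list(GC))
    direction = np.full(len(df), "AT_conserving", dtype=object)
    direction[major_gc & ~minor_gc] = "AT_gain"
    direction[~major_gc & minor_gc] = "AT_loss"
    direction[tie] = "tie"

    gc_flanked = (df["flank5"].isin(GC) & df["flank3"].isin(GC)).to_numpy()
    df["major"] = major
    df["minor"] = minor
    df["minor_count"] = np.minimum(c1, c2)
    df["maf"] = df["minor_count"] / df["n_called"]
    df["direction"] = direction
    df["context"] = np.where(gc_flanked, "GC_flanked", "non_GC")
    return df


def classify_snp(record: pd.Series) -> tuple[str, str, object]:
    """(direction, context, occupancy) triple for a single filtered record."""
    df = classify_snps(pd.DataFrame([record]))
    row = df.iloc[0]
    if row["direction"] == "tie":
        raise ValueError("exact 50/50 allele tie: record excluded")
    return row["direction"], row["context"], row["occupancy"]


def rare_fraction(classified: pd.DataFrame,
                  threshold: float = RARE_THRESHOLD,
                  by: tuple[str, ...] = ("direction",)) -> pd.DataFrame:
    """Per-class rare-allele fractions (minor-allele frequency < threshold).

    Ties are dropped. Classes with no SNPs are reported with NaN fraction.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError("threshold must be in (0, 0.5]")
    df = classified[classified["direction"] != "tie"]
    rows = []
    for key, grp in df.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        n_rare = int((grp["maf"] < threshold).sum())
        rows.append(dict(zip(by, key)) | {"n_snps": n, "n_rare": n_rare,
                                          "fraction": n_rare / n if n else np.nan})
    return pd.DataFrame(rows)


def compare_classes(summary_a: RareFractionSummary | dict,
                    summary_b: RareFractionSummary | dict) -> dict:
    """2x2 Pearson chi-squared test (no continuity correction) of equal
    rare-allele fractions between two SNP classes.

    Returns {"statistic", "dof", "p_value", "warning"}; a warning is attached
    when any expected cell count is below 1.
    """
    def cells(s):
        if isinstance(s, dict):
            s = RareFractionSummary(s["n_snps"], s["n_rare"])
        if s.n_snps == 0:
            raise ValueError("cannot compare an empty class")
        return [s.n_rare, s.n_snps - s.n_rare]

    table = np.array([cells(summary_a), cells(summary_b)], dtype=float)
    res = chi2_contingency(table, correction=False)
    warning = None
    if np.any(res.expected_freq < 1.0):
        warning = "expected cell count below 1: chi-squared approximation poor"
    return {"statistic": float(res.statistic), "dof": int(res.dof),
            "p_value": float(res.pvalue), "warning": warning}
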