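"""Independence and concordance statistics for epigenotype profiles.

Covers the genome-wide 2x2 test of methylation status against bud-failure
exhibition (Pearson chi-square, phi coefficient, Pearson residuals), the
stratified Cochran–Mantel–Haenszel conditional-independence test, Kendall
tau-b concordance between accession methylation profiles, and the screen
for bands whose methylation corresponds perfectly with the BF grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

from .bandmatrix_io import AccessionMeta, BandId
from .epigenotyping import EpigenotypeMatrix

__all__ = [
    "IndependenceResult",
    "ConcordanceMatrix",
    "build_2x2",
    "phi_coefficient",
    "pearson_chi2",
    "conditional_independence_test",
    "kendall_tau_b",
    "pairwise_concordance",
    "perfectly_associated_bands",
]


@dataclass
class IndependenceResult:
    chi2: float
    df: int
    p_value: float
    phi: float | None  # 2x2 tables only
    residuals: pd.DataFrame | None
    n: int


@dataclass
class ConcordanceMatrix:
    tau: pd.DataFrame  # accessions x accessions, NaN where undefined
    genotype: Mapping[str, str]

    def summary(self) -> dict[str, float]:
        """Mean tau within and between genotype groups (off-diagonal pairs)."""
        labels = list(self.tau.index)
        within, between = [], []
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                v = self.tau.loc[a, b]
                if np.isnan(v):
                    continue
                (within if self.genotype[a] == self.genotype[b] else between).append(v)
        return {
            "mean_within_genotype": float(np.mean(within)) if within else float("nan"),
            "mean_between_genotype": float(np.mean(between)) if between else float("nan"),
            "mean_overall": float(np.mean(within + between)) if within + between else float("nan"),
        }


def build_2x2(epi: EpigenotypeMatrix, grouping: Mapping[str, str]) -> pd.DataFrame:
    """Counts of methylated/unmethylated cells per BF group over all bands.

    Rows: methylated, unmethylated.  Columns: the two group labels, BF-like
    group first when the labels are BF/NBF.
    """
    groups = sorted(set(grouping[a] for a in epi.accessions))
    if len(groups) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {groups}")
    table = pd.DataFrame(0, index=["methylated", "unmethylated"], columns=groups, dtype=int)
    binary = epi.binary_methylated
    for accession in epi.accessions:
        g = grouping[accession]
        row = binary.loc[accession]
        n_meth = int(row.sum())
        table.loc["methylated", g] += n_meth
        table.loc["unmethylated", g] += int(row.notna().sum()) - n_meth
    if (table.sum(axis=0) == 0).any():
        raise ValueError("a group has no scored cells")
    return table


def phi_coefficient(table: pd.DataFrame | np.ndarray) -> float:
    """Phi (mean-square contingency) coefficient of a 2x2 table.

    phi = (n11 n22 - n12 n21) / sqrt(n1. n2. n.1 n.2); undefined when any
    margin is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("phi coefficient requires a 2x2 table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ZeroDivisionError("phi undefined: a table margin is zero")
    num = t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]
    return float(num / np.sqrt(rows.prod() * cols.prod()))


def pearson_chi2(table: pd.DataFrame | np.ndarray, correction: bool = False) -> IndependenceResult:
    """Pearson chi-square test of independence for a two-way table.

    Returns the statistic, degrees of freedom, upper-tail p-value, Pearson
    residuals (O-E)/sqrt(E) per cell, and the phi coefficient for 2x2.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("pearson_chi2 expects a two-way table")
    chi2, p, df, expected = stats.chi2_contingency(t, correction=correction)
    if (expected <= 0).any():
        raise ValueError("zero expected count; test undefined")
    resid = (t - expected) / np.sqrt(expected)
    if isinstance(table, pd.DataFrame):
        resid = pd.DataFrame(resid, index=table.index, columns=table.columns)
    else:
        resid = pd.DataFrame(resid)
    phi = phi_coefficient(t) if t.shape == (2, 2) else None
    return IndependenceResult(
        chi2=float(chi2), df=int(df), p_value=float(p), phi=phi, residuals=resid,
        n=int(t.sum()),
    )


def conditional_independence_test(
    strata: Sequence[np.ndarray | pd.DataFrame], correction: bool = True
) -> IndependenceResult:
    """Cochran–Mantel–Haenszel test over 2x2xK strata.

    Tests conditional independence of the two 2-level factors given the
    stratifying variable; ``correction`` applies the classical continuity
    correction (conservative under the null).  Strata with a zero margin
    are skipped with a warning.  Per-stratum Pearson residuals are
    concatenated for mosaic export.
    """
    kept = []
    for k, s in enumerate(strata):
        t = np.asarray(s, dtype=float)
        if t.shape != (2, 2):
            raise ValueError("each stratum must be a 2x2 table")
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            warnings.warn(f"stratum {k} has a zero margin; skipped", stacklevel=2)
            continue
        kept.append(t)
    if not kept:
        raise ValueError("no usable strata")
    st = StratifiedTable(np.stack(kept, axis=-1))
    res = st.test_null_odds(correction=correction)
    resid_frames = []
    for k, t in enumerate(kept):
        expected = stats.contingency.expected_freq(t)
        r = pd.DataFrame((t - expected) / np.sqrt(expected))
        r["stratum"] = k
        resid_frames.append(r)
    residuals = pd.concat(resid_frames, ignore_index=True)
    return IndependenceResult(
        chi2=float(res.statistic), df=1, p_value=float(res.pvalue), phi=None,
        residuals=residuals, n=int(sum(t.sum() for t in kept)),
    )


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau adjusted for ties (tau-b).

    (C - D) / sqrt((n0 - n1)(n0 - n2)) with n0 = n(n-1)/2 and n1, n2 the
    tied-pair counts of each vector.  Undefined (raises) when either vector
    is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ZeroDivisionError("tau-b undefined for a constant vector")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def pairwise_concordance(
    epi: EpigenotypeMatrix, meta: Iterable[AccessionMeta]
) -> ConcordanceMatrix:
    """Tau-b between every pair of binary methylation profiles.

    Pairs involving a constant profile are flagged as missing (NaN).  The
    diagonal is 1 for non-constant profiles.
    """
    accessions = epi.accessions
    if len(accessions) < 2:
        raise ValueError("need at least two accessions")
    genotype = {m.accession_id: m.genotype for m in meta}
    binary = epi.binary_methylated
    tau = pd.DataFrame(np.nan, index=accessions, columns=accessions)
    for i, a in enumerate(accessions):
        xa = binary.loc[a].to_numpy(dtype=float)
        if not np.all(xa == xa[0]):
            tau.loc[a, a] = 1.0
        for b in accessions[i + 1 :]:
            xb = binary.loc[b].to_numpy(dtype=float)
            try:
                t = kendall_tau_b(xa, xb)
            except ZeroDivisionError:
                t = np.nan
            tau.loc[a, b] = tau.loc[b, a] = t
    return ConcordanceMatrix(tau=tau, genotype=genotype)


def perfectly_associated_bands(
    epi: EpigenotypeMatrix, grouping: Mapping[str, str]
) -> list[tuple[BandId, str]]:
    """Bands whose binary methylation separates the two groups exactly.

    Returns (band, orientation) pairs where orientation is
    ``"methylated_in_BF"`` when the band is methylated in every accession
    of the first (BF-like) group and unmethylated in every accession of the
    other, or ``"methylated_in_NBF"`` for the exact complement.
    """
    groups = sorted(set(grouping[a] for a in epi.accessions))
    if len(groups) != 2 or any(
        sum(grouping[a] == g for a in epi.accessions) == 0 for g in groups
    ):
        raise ValueError("grouping must be non-degenerate with two levels")
    g1, g2 = groups  # "BF" sorts before "NBF"
    in_g1 = [a for a in epi.accessions if grouping[a] == g1]
    in_g2 = [a for a in epi.accessions if grouping[a] == g2]
    binary = epi.binary_methylated
    hits: list[tuple[BandId, str]] = []
    band_by_name = {b.name: b for b in epi.bands}
    meth_g1 = binary.loc[in_g1]
    meth_g2 = binary.loc[in_g2]
    all1_g1 = (meth_g1 == 1).all(axis=0)
    all0_g1 = (meth_g1 == 0).all(axis=0)
    all1_g2 = (meth_g2 == 1).all(axis=0)
    all0_g2 = (meth_g2 == 0).all(axis=0)
    for name in binary.columns:
        if all1_g1[name] and all0_g2[name]:
            hits.append((band_by_name[name], f"methylated_in_{g1}"))
        elif all0_g1[name] and all1_g2[name]:
            hits.append((band_by_name[name], f"methylated_in_{g2}"))
    return hits
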