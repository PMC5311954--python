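"""Four-state methylation epigenotyping from paired HpaII/MspI calls.

The two isoschizomers recognize CCGG but differ in methylation sensitivity,
so the joint banding pattern of the HPA and MSP assays encodes the
methylation state of the site:

====  ====  ==============================
HPA   MSP   state
====  ====  ==============================
1     1     demethylated
1     0     hemimethylated
0     1     internal cytosine methylation
0     0     full methylation
====  ====  ==============================

The absent/absent pattern is scored as full methylation by default; because
it can also reflect loss of the restriction target, a ``missing_pattern``
switch lets callers treat it as uninformative instead.

Loci are partitioned into methylation-susceptible loci (MSL) — bands whose
fraction of non-demethylated accessions exceeds an error threshold — and
non-methylated loci (NML); MSL are further flagged polymorphic when at
least two distinct states occur across accessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .bandmatrix_io import AccessionMeta, BandId, BandMatrix

__all__ = [
    "MethState",
    "EpigenotypeMatrix",
    "MethylationFractionTable",
    "classify_pattern",
    "classify_matrix",
    "partition_loci",
    "polymorphic_loci",
    "methylation_fraction_table",
    "dichotomize_bf",
]


class MethState(IntEnum):
    DEMETHYLATED = 0
    HEMIMETHYLATED = 1
    INTERNAL_C_METHYLATION = 2
    FULL_METHYLATION = 3


#: Human-readable labels matching the isoschizomer banding patterns.
STATE_PATTERN: Mapping[MethState, tuple[int, int]] = {
    MethState.DEMETHYLATED: (1, 1),
    MethState.HEMIMETHYLATED: (1, 0),
    MethState.INTERNAL_C_METHYLATION: (0, 1),
    MethState.FULL_METHYLATION: (0, 0),
}


_CODE = {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}


def classify_pattern(h: int, m: int) -> MethState:
    """Map one (HPA, MSP) presence pair to its methylation state."""
    if h not in (0, 1) or m not in (0, 1):
        raise ValueError(f"calls must be binary, got ({h!r}, {m!r})")
    return MethState(_CODE[(h, m)])


@dataclass
class EpigenotypeMatrix:
    """Per-(band, accession) methylation states plus locus annotations.

    ``states`` is an accessions x bands frame of :class:`MethState` codes;
    ``binary_methylated`` is 1 wherever the state is anything but
    demethylated (the deMet01 score used downstream).
    """

    states: pd.DataFrame
    bands: list[BandId]
    locus_class: pd.Series | None = None  # "MSL"/"NML" per band
    polymorphic: pd.Series | None = None  # bool per band
    error_threshold: float | None = None
    binary_methylated: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        binary = (self.states != int(MethState.DEMETHYLATED)).astype("float64")
        binary = binary.where(self.states.notna())
        if self.states.notna().to_numpy().all():
            binary = binary.astype("int8")
        self.binary_methylated = binary

    @property
    def accessions(self) -> list[str]:
        return list(self.states.index)

    @property
    def band_names(self) -> list[str]:
        return list(self.states.columns)


def classify_matrix(bands: BandMatrix, absent_as_missing: bool = False) -> EpigenotypeMatrix:
    """Classify every (band, accession) cell of a band matrix.

    With ``absent_as_missing=True`` the absent/absent pattern is scored as
    missing (NaN) instead of full methylation, for the alternative MSAP
    convention in which it may indicate loss of the CCGG target.
    """
    hpa = bands.assay("HPA").to_numpy()
    msp = bands.assay("MSP").to_numpy()
    codes = (2 * (1 - hpa) + (1 - msp)).astype("float64" if absent_as_missing else "int8")
    if absent_as_missing:
        codes[codes == 3] = np.nan
    states = pd.DataFrame(codes, index=bands.accessions, columns=bands.band_names)
    return EpigenotypeMatrix(states=states, bands=list(bands.bands))


def partition_loci(epi: EpigenotypeMatrix, error_threshold: float = 0.05) -> EpigenotypeMatrix:
    """Split bands into MSL/NML.

    A band is methylation-susceptible when the fraction of accessions in a
    non-demethylated state exceeds ``error_threshold`` (interpreted as the
    tolerated scoring-error rate); otherwise it is a non-methylated locus.
    """
    if not 0 <= error_threshold < 1:
        raise ValueError("error_threshold must lie in [0, 1)")
    frac = epi.binary_methylated.mean(axis=0)
    epi.locus_class = pd.Series(
        np.where(frac > error_threshold, "MSL", "NML"), index=epi.states.columns
    )
    epi.error_threshold = error_threshold
    return epi


def polymorphic_loci(epi: EpigenotypeMatrix) -> EpigenotypeMatrix:
    """Flag MSL bands showing at least two distinct states across accessions."""
    if epi.locus_class is None:
        raise ValueError("partition_loci must run before polymorphic_loci")
    n_states = epi.states.nunique(axis=0)
    epi.polymorphic = (n_states >= 2) & (epi.locus_class == "MSL")
    return epi


@dataclass
class MethylationFractionTable:
    """Group-conditional state fractions plus the raw counts behind them.

    ``fractions`` are conditional on the group (each group's four fractions
    sum to one); ``fractions_of_total`` divide by the grand total instead,
    which is the denominator used when quoting genome-wide percentages.
    """

    counts: pd.DataFrame  # states x groups
    fractions: pd.DataFrame
    fractions_of_total: pd.DataFrame


def methylation_fraction_table(
    epi: EpigenotypeMatrix, grouping: Mapping[str, str]
) -> MethylationFractionTable:
    """Tabulate state fractions conditional on a BF/NBF (or any) grouping."""
    missing = [a for a in epi.accessions if a not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover accessions: {missing}")
    groups = sorted(set(grouping[a] for a in epi.accessions))
    counts = pd.DataFrame(
        0, index=[s.name for s in MethState], columns=groups, dtype=int
    )
    for accession in epi.accessions:
        g = grouping[accession]
        vc = epi.states.loc[accession].value_counts()
        for code, n in vc.items():
            counts.loc[MethState(code).name, g] += int(n)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"empty group(s): {empty}")
    fractions = counts / totals
    fractions_of_total = counts / counts.to_numpy().sum()
    return MethylationFractionTable(counts, fractions, fractions_of_total)


def dichotomize_bf(
    meta: Iterable[AccessionMeta], threshold: int = 4
) -> dict[str, str]:
    """Map accessions to BF/NBF: exhibiting when bf_score >= threshold.

    The default threshold of 4 ("Medium" and above) splits the 22-accession
    fixture 11/11.
    """
    return {
        m.accession_id: ("BF" if m.bf_score >= threshold else "NBF") for m in meta
    }
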