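"""Reading, validation and writing of MS-AFLP presence/absence band matrices.

The on-disk convention mirrors how MSAP-style scoring tables are laid out:
one CSV row per (accession, assay) pair, a leading column with the
bud-failure exhibition category, the accession name, the assay label
(``HPA`` for the EcoRI+HpaII digest, ``MSP`` for EcoRI+MspI), and then one
binary column per scored band.  Band columns are named ``<primer><index>``
with primers ``a``–``i`` and indices ordered from the heaviest to the
lightest fragment within a primer combination.

The accession metadata for the 22 almond clonal sources of the study
(genotype, bud-failure category on the six-level ordinal scale, and clonal
age in decades since first use as a budwood propagation source) ships as a
packaged fixture and is served by :func:`load_accession_metadata`.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AccessionMeta",
    "BandId",
    "BandMatrix",
    "BandMatrixError",
    "BF_CATEGORY_TO_SCORE",
    "PRIMERS",
    "DEFAULT_BANDS_PER_PRIMER",
    "read_band_matrix",
    "write_band_matrix",
    "load_accession_metadata",
]


class BandMatrixError(ValueError):
    """Raised when a band matrix file violates the format contract."""


#: Bijective mapping between the ordinal bud-failure exhibition labels and
#: their numerical scores (6 = high ... 1 = no exhibition).
BF_CATEGORY_TO_SCORE: Mapping[str, int] = {
    "High": 6,
    "Medium to High": 5,
    "Medium": 4,
    "Low to Medium": 3,
    "Low": 2,
    "No": 1,
}

BF_SCORE_TO_CATEGORY: Mapping[int, str] = {v: k for k, v in BF_CATEGORY_TO_SCORE.items()}

PRIMERS: tuple[str, ...] = tuple("abcdefghi")

#: Bands scored per primer combination a..i in the study.
DEFAULT_BANDS_PER_PRIMER: tuple[int, ...] = (120, 136, 125, 161, 114, 214, 133, 121, 124)

_ASSAY_SYNONYMS = {
    "HPA": "HPA",
    "MSP": "MSP",
    "ECORI+HPAII": "HPA",
    "ECORI+MSPI": "MSP",
    "HPAII": "HPA",
    "MSPI": "MSP",
}

_BAND_RE = re.compile(r"^([a-i])([1-9][0-9]*)$")


@dataclass(frozen=True)
class AccessionMeta:
    """Metadata for one clonal accession."""

    accession_id: str
    genotype: str
    bf_category: str
    bf_score: int
    clonal_age: int

    def __post_init__(self) -> None:
        if self.bf_score not in range(1, 7):
            raise ValueError(f"bf_score must be in 1..6, got {self.bf_score}")
        if BF_CATEGORY_TO_SCORE.get(self.bf_category) != self.bf_score:
            raise ValueError(
                f"bf_category {self.bf_category!r} does not map to score {self.bf_score}"
            )
        if self.clonal_age < 1:
            raise ValueError("clonal_age must be >= 1 decade")


@dataclass(frozen=True, order=True)
class BandId:
    """A scored band: primer combination letter plus heavy-to-light index."""

    primer: str
    index: int

    def __post_init__(self) -> None:
        if self.primer not in PRIMERS:
            raise ValueError(f"primer must be one of {PRIMERS}, got {self.primer!r}")
        if self.index < 1:
            raise ValueError("band index must be positive")

    @property
    def name(self) -> str:
        return f"{self.primer}{self.index}"

    @classmethod
    def from_name(cls, name: str) -> "BandId":
        m = _BAND_RE.match(name)
        if m is None:
            raise BandMatrixError(f"not a valid band column name: {name!r}")
        return cls(m.group(1), int(m.group(2)))


class BandMatrix:
    """Presence/absence calls per (accession, assay, band).

    Internally a DataFrame indexed by ``(accession, assay)`` with one int8
    column per band.  Every accession carries exactly one HPA and one MSP
    row over an identical ordered band set, and all calls are strictly 0/1.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        bf_category: Mapping[str, str],
        bands: Sequence[BandId] | None = None,
    ) -> None:
        if bands is None:
            bands = [BandId.from_name(c) for c in calls.columns]
        self.bands: list[BandId] = list(bands)
        self.calls = calls
        self.bf_category = dict(bf_category)
        self._validate()

    # -- accessors ---------------------------------------------------------
    @property
    def accessions(self) -> list[str]:
        return list(dict.fromkeys(self.calls.index.get_level_values(0)))

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def assay(self, label: str) -> pd.DataFrame:
        """Calls of one assay (HPA or MSP) as accessions x bands."""
        sub = self.calls.xs(label, level=1)
        return sub.loc[self.accessions]

    def bands_per_primer(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.bands:
            counts[b.primer] = counts.get(b.primer, 0) + 1
        return counts

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        if not self.bands:
            raise BandMatrixError("band matrix has an empty band set")
        if [BandId.from_name(c) for c in self.calls.columns] != self.bands:
            raise BandMatrixError("call columns do not match the declared band set")
        seen_per_primer: dict[str, int] = {}
        for b in self.bands:
            expect = seen_per_primer.get(b.primer, 0) + 1
            if b.index != expect:
                raise BandMatrixError(
                    f"band {b.name} out of order: indices must run 1..n within primer {b.primer}"
                )
            seen_per_primer[b.primer] = b.index
        counts = self.calls.groupby(level=0).size()
        for accession, rows in counts.items():
            present = set(self.calls.loc[accession].index)
            for assay in ("HPA", "MSP"):
                if assay not in present:
                    raise BandMatrixError(
                        f"accession {accession!r} is missing its {assay} assay row"
                    )
            if rows != 2:
                raise BandMatrixError(
                    f"accession {accession!r} has {rows} assay rows, expected exactly 2"
                )
        values = self.calls.to_numpy()
        bad = ~((values == 0) | (values == 1))
        if bad.any():
            i, j = [int(x[0]) for x in bad.nonzero()]
            raise BandMatrixError(
                f"non-binary call at row {self.calls.index[i]}, column "
                f"{self.calls.columns[j]!r}: {values[i, j]!r}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.bands == other.bands
            and self.bf_category == other.bf_category
            and self.calls.equals(other.calls)
        )


def read_band_matrix(path: str | Path | io.TextIOBase) -> BandMatrix:
    """Read and validate a band matrix CSV.

    Accepts both the canonical assay labels HPA/MSP and the
    ``EcoRI+HpaII``/``EcoRI+MspI`` phrasing used in some scoring sheets.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["bf_category", "accession", "assay"]
    if list(df.columns[:3]) != required:
        raise BandMatrixError(
            f"first three columns must be {required}, got {list(df.columns[:3])}"
        )
    band_cols = list(df.columns[3:])
    if not band_cols:
        raise BandMatrixError("no band columns found")
    bands = [BandId.from_name(c) for c in band_cols]

    assay = df["assay"].str.upper().map(_ASSAY_SYNONYMS)
    if assay.isna().any():
        bad = df.loc[assay.isna(), "assay"].iloc[0]
        raise BandMatrixError(f"unrecognized assay label {bad!r}")

    calls = df[band_cols].copy()
    non_binary = ~calls.isin(["0", "1"])
    if non_binary.to_numpy().any():
        i = non_binary.any(axis=1).idxmax()
        j = non_binary.loc[i].idxmax()
        raise BandMatrixError(
            f"non-binary call for accession {df.loc[i, 'accession']!r}, "
            f"band {j!r}: {calls.loc[i, j]!r}"
        )
    calls = calls.astype("int8")
    calls.index = pd.MultiIndex.from_arrays(
        [df["accession"], assay], names=["accession", "assay"]
    )
    bf_category = dict(zip(df["accession"], df["bf_category"]))
    return BandMatrix(calls, bf_category, bands)


def write_band_matrix(matrix: BandMatrix, path: str | Path) -> None:
    """Write a band matrix in the same CSV dialect :func:`read_band_matrix` reads.

    Output is byte-stable for a fixed matrix: rows are emitted in accession
    order with HPA before MSP.
    """
    if not matrix.bands:
        raise BandMatrixError("refusing to write a matrix with no bands")
    rows = []
    for accession in matrix.accessions:
        for assay in ("HPA", "MSP"):
            row = {
                "bf_category": matrix.bf_category.get(accession, ""),
                "accession": accession,
                "assay": assay,
            }
            row.update(matrix.calls.loc[(accession, assay)].to_dict())
            rows.append(row)
    out = pd.DataFrame(rows, columns=["bf_category", "accession", "assay", *matrix.band_names])
    out.to_csv(path, index=False, lineterminator="\n")


def load_accession_metadata() -> list[AccessionMeta]:
    """The 22 almond accessions of the study with genotype, BF category/score
    and clonal age in decades."""
    with resources.files("msapbf.data").joinpath("accession_metadata.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        AccessionMeta(
            accession_id=r.accession_id,
            genotype=r.genotype,
            bf_category=r.bf_category,
            bf_score=int(r.bf_score),
            clonal_age=int(r.clonal_age_decades),
        )
        for r in df.itertuples()
    ]


def metadata_by_id(meta: Iterable[AccessionMeta]) -> dict[str, AccessionMeta]:
    return {m.accession_id: m for m in meta}
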