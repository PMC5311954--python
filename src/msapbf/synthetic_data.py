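"""Synthetic MS-AFLP band matrices with known statistical structure.

The study's raw gel scores were never deposited, so every pipeline stage is
exercised on generated matrices that reproduce the data's *shape*: the 22
accessions with their bud-failure scores and clonal ages, nine primer
combinations with the scored band counts (120, 136, 125, 161, 114, 214,
133, 121, 124), and two assay rows (HPA, MSP) per accession.

Methylation of each (band, accession) cell is drawn from a logistic model
in the accession's BF score, clonal age and genotype, on top of a per-band
baseline drawn once per band; conditional on being methylated, the state
(hemi / internal-C / full) is drawn from configurable probabilities and
mapped back to HPA/MSP calls by inverting the isoschizomer scheme.
Independent call errors can flip individual HPA or MSP calls, which
deliberately creates state misclassification to exercise the MSL error
threshold.  Everything is deterministic under the configured seed and the
generating coefficients are returned as a :class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bandmatrix_io import (
    DEFAULT_BANDS_PER_PRIMER,
    PRIMERS,
    AccessionMeta,
    BandId,
    BandMatrix,
    load_accession_metadata,
)
from .bayes_loglinear import HierarchicalModel, ModelFrame, design_matrix
from .epigenotyping import STATE_PATTERN, EpigenotypeMatrix, MethState

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate",
    "plant_perfect_band",
    "frame_from_matrix",
    "simulate_loglinear_frame",
]


@dataclass
class SimulationConfig:
    """Generating conditions for a synthetic band matrix.

    Defaults emulate the study: the packaged 22-accession metadata, the
    per-primer band counts, an overall methylation level near one half
    with a mild positive dependence on BF score and clonal age, state
    probabilities conditional on methylation matching the observed
    hemi/internal/full balance, and a small per-call scoring error rate.
    """

    accessions: Sequence[AccessionMeta] | None = None
    bands_per_primer: Sequence[int] = DEFAULT_BANDS_PER_PRIMER
    base_logit_mean: float = 0.0
    band_logit_sd: float = 1.5
    effect_bf: float = 0.09  # per BF-score unit, log-odds of methylation
    effect_age: float = 0.02  # per decade
    genotype_effects: Mapping[str, float] = field(default_factory=dict)
    state_probs_given_methylated: tuple[float, float, float] = (0.16, 0.19, 0.65)
    call_error_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accessions is None:
            self.accessions = load_accession_metadata()
        p = np.asarray(self.state_probs_given_methylated, float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("state_probs_given_methylated must be a probability 3-vector")
        if not 0 <= self.call_error_rate < 0.5:
            raise ValueError("call_error_rate must lie in [0, 0.5)")
        if len(self.bands_per_primer) > len(PRIMERS):
            raise ValueError(f"at most {len(PRIMERS)} primer combinations supported")


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate the matrix bit-exactly."""

    seed: int
    effect_bf: float
    effect_age: float
    genotype_effects: dict[str, float]
    band_base_logits: dict[str, float]
    state_probs_given_methylated: tuple[float, float, float]
    call_error_rate: float
    planted_bands: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _band_ids(bands_per_primer: Sequence[int]) -> list[BandId]:
    return [
        BandId(primer, idx)
        for primer, n in zip(PRIMERS, bands_per_primer)
        for idx in range(1, n + 1)
    ]


def generate(config: SimulationConfig) -> tuple[BandMatrix, SyntheticTruth]:
    """Draw a band matrix from the configured logistic methylation model."""
    rng = np.random.default_rng(config.seed)
    meta = list(config.accessions)
    bands = _band_ids(config.bands_per_primer)
    n_bands = len(bands)
    n_acc = len(meta)

    base = config.base_logit_mean + config.band_logit_sd * rng.standard_normal(n_bands)
    bf = np.array([m.bf_score for m in meta], float)
    age = np.array([m.clonal_age for m in meta], float)
    geno = np.array([config.genotype_effects.get(m.genotype, 0.0) for m in meta])
    # center covariates so base_logit_mean controls the overall level
    eta = (
        base[None, :]
        + config.effect_bf * (bf - bf.mean())[:, None]
        + config.effect_age * (age - age.mean())[:, None]
        + geno[:, None]
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    methylated = rng.uniform(size=(n_acc, n_bands)) < p
    state = np.zeros((n_acc, n_bands), dtype=np.int8)  # DEMETHYLATED
    n_meth = int(methylated.sum())
    state[methylated] = rng.choice(
        [int(MethState.HEMIMETHYLATED), int(MethState.INTERNAL_C_METHYLATION),
         int(MethState.FULL_METHYLATION)],
        size=n_meth,
        p=config.state_probs_given_methylated,
    )
    hpa = np.zeros_like(state)
    msp = np.zeros_like(state)
    for s, (h, m) in STATE_PATTERN.items():
        mask = state == int(s)
        hpa[mask] = h
        msp[mask] = m
    if config.call_error_rate > 0:
        flip_h = rng.uniform(size=hpa.shape) < config.call_error_rate
        flip_m = rng.uniform(size=msp.shape) < config.call_error_rate
        hpa = np.where(flip_h, 1 - hpa, hpa)
        msp = np.where(flip_m, 1 - msp, msp)

    band_names = [b.name for b in bands]
    rows = []
    index = []
    for i, m in enumerate(meta):
        rows.append(hpa[i])
        index.append((m.accession_id, "HPA"))
        rows.append(msp[i])
        index.append((m.accession_id, "MSP"))
    calls = pd.DataFrame(
        np.asarray(rows, dtype="int8"),
        index=pd.MultiIndex.from_tuples(index, names=["accession", "assay"]),
        columns=band_names,
    )
    bf_category = {m.accession_id: m.bf_category for m in meta}
    matrix = BandMatrix(calls, bf_category, bands)
    truth = SyntheticTruth(
        seed=config.seed,
        effect_bf=config.effect_bf,
        effect_age=config.effect_age,
        genotype_effects=dict(config.genotype_effects),
        band_base_logits=dict(zip(band_names, base.tolist())),
        state_probs_given_methylated=tuple(config.state_probs_given_methylated),
        call_error_rate=config.call_error_rate,
    )
    return matrix, truth


def plant_perfect_band(
    matrix: BandMatrix,
    truth: SyntheticTruth,
    grouping: Mapping[str, str],
    band: BandId | None = None,
) -> tuple[BandMatrix, SyntheticTruth]:
    """Force one band to correspond perfectly with the BF grouping.

    The designated band (the first band when unspecified) is set fully
    methylated (HPA-/MSP-) in every BF accession and demethylated
    (HPA+/MSP+) in every NBF accession.  Idempotent; the planted band id is
    recorded in the truth.
    """
    groups = sorted(set(grouping.values()))
    if len(groups) != 2:
        raise ValueError("grouping must have two levels")
    bf_label = groups[0]  # "BF" sorts before "NBF"
    band = band or matrix.bands[0]
    calls = matrix.calls.copy()
    for accession in matrix.accessions:
        is_bf = grouping[accession] == bf_label
        calls.loc[(accession, "HPA"), band.name] = 0 if is_bf else 1
        calls.loc[(accession, "MSP"), band.name] = 0 if is_bf else 1
    planted = sorted(set(truth.planted_bands) | {band.name})
    new_truth = SyntheticTruth(
        **{**asdict(truth), "planted_bands": planted}
    )
    return BandMatrix(calls, matrix.bf_category, matrix.bands), new_truth


def frame_from_matrix(
    epi: EpigenotypeMatrix, meta: Sequence[AccessionMeta]
) -> ModelFrame:
    """One record per (band, accession) with deMet01, ChronoAge, GenotypeN, BF.

    Genotypes are coded contiguously 1..K in sorted label order.
    """
    by_id = {m.accession_id: m for m in meta}
    missing = [a for a in epi.accessions if a not in by_id]
    if missing:
        raise ValueError(f"metadata missing for accessions: {missing}")
    genotypes = sorted({by_id[a].genotype for a in epi.accessions})
    geno_code = {g: i + 1 for i, g in enumerate(genotypes)}
    n_bands = len(epi.band_names)
    frames = []
    for a in epi.accessions:
        m = by_id[a]
        frames.append(
            pd.DataFrame(
                {
                    "accession": a,
                    "band": epi.band_names,
                    "deMet01": epi.binary_methylated.loc[a].to_numpy(),
                    "ChronoAge": float(m.clonal_age),
                    "GenotypeN": geno_code[m.genotype],
                    "bf_score": m.bf_score,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    records["deMet01"] = records["deMet01"].astype(int)
    return ModelFrame(records=records)


def simulate_loglinear_frame(
    coefficients: Mapping[str, float],
    model: HierarchicalModel,
    accessions: Sequence[AccessionMeta],
    n_records: int,
    seed: int,
) -> ModelFrame:
    """Sample a record-level frame from a known log-linear cell model.

    Cells are the accession covariate profiles crossed with deMet01; cell
    probabilities are proportional to exp(X beta) and ``n_records`` records
    are drawn multinomially.  Because the truth lies inside the fitted
    family, this is the generator used for coverage checks of the
    posterior.  Coefficient keys must match :func:`design_matrix` column
    names; missing keys default to zero.
    """
    genotypes = sorted({m.genotype for m in accessions})
    geno_code = {g: i + 1 for i, g in enumerate(genotypes)}
    profiles = pd.DataFrame(
        {
            "bf_score": [m.bf_score for m in accessions],
            "GenotypeN": [geno_code[m.genotype] for m in accessions],
            "ChronoAge": [float(m.clonal_age) for m in accessions],
        }
    ).drop_duplicates()
    cells = profiles.merge(pd.DataFrame({"deMet01": [0, 1]}), how="cross")
    cells = cells.sort_values(["bf_score", "GenotypeN", "ChronoAge", "deMet01"]).reset_index(
        drop=True
    )
    cells["count"] = 0
    x, names = design_matrix(cells, model)
    beta = np.array([coefficients.get(n, 0.0) for n in names])
    eta = x @ beta
    p = np.exp(eta - eta.max())
    p /= p.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_records, p)
    rows = cells.drop(columns=["count"]).loc[
        np.repeat(np.arange(len(cells)), counts)
    ]
    return ModelFrame(records=rows.reset_index(drop=True))
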