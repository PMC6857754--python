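"""Instrument panel: the SNPs, alleles and per-allele weights behind the genetic score.

A single panel object is shared between the cohort simulator and the score
builder so that effect-allele orientation can never drift between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class InstrumentPanel:
    """A weighted multi-SNP instrument for a quantitative exposure.

    Parameters
    ----------
    snp_ids
        rs identifiers, unique.
    effect_alleles, other_alleles
        Single-nucleotide allele labels; weights are expressed per copy of
        the effect allele.
    weights
        Effect on the (log) exposure per effect allele, finite.
    effect_allele_freqs
        Optional effect-allele frequencies, used for mean imputation of
        missing dosages and by the simulator.
    first_stage_se
        Optional per-SNP standard errors of the exposure association.
    """

    snp_ids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    other_alleles: tuple[str, ...]
    weights: tuple[float, ...]
    effect_allele_freqs: tuple[float, ...] | None = None
    first_stage_se: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.snp_ids)
        if len(set(self.snp_ids)) != n:
            raise ValueError("snp_ids must be unique")
        for name in ("effect_alleles", "other_alleles", "weights"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match snp_ids")
        for allele in (*self.effect_alleles, *self.other_alleles):
            if allele not in _NUCLEOTIDES:
                raise ValueError(f"invalid allele {allele!r}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.effect_allele_freqs is not None:
            f = np.asarray(self.effect_allele_freqs, dtype=float)
            if len(f) != n or np.any((f <= 0) | (f >= 1)):
                raise ValueError("effect_allele_freqs must lie in (0, 1)")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    @property
    def freq_array(self) -> np.ndarray:
        if self.effect_allele_freqs is None:
            raise ValueError("panel carries no allele frequencies")
        return np.asarray(self.effect_allele_freqs, dtype=float)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InstrumentPanel":
        cols = {"snp_id", "effect_allele", "other_allele", "weight"}
        missing = cols - set(frame.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        freqs = None
        if "effect_allele_freq" in frame.columns:
            freqs = tuple(frame["effect_allele_freq"].astype(float))
        se = None
        if "first_stage_se" in frame.columns:
            se = tuple(frame["first_stage_se"].astype(float))
        return cls(
            snp_ids=tuple(frame["snp_id"].astype(str)),
            effect_alleles=tuple(frame["effect_allele"].astype(str)),
            other_alleles=tuple(frame["other_allele"].astype(str)),
            weights=tuple(frame["weight"].astype(float)),
            effect_allele_freqs=freqs,
            first_stage_se=se,
        )

    @classmethod
    def from_csv(cls, path) -> "InstrumentPanel":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "effect_allele": self.effect_alleles,
                "other_allele": self.other_alleles,
                "weight": self.weights,
            }
        )
        if self.effect_allele_freqs is not None:
            out["effect_allele_freq"] = self.effect_allele_freqs
        return out


def default_panel() -> InstrumentPanel:
    """The bundled six-SNP vitamin D panel.

    Effect-allele frequencies are derived from published biobank genotype
    counts for a White British population; the weights are documented
    placeholders (the source GWAS per-SNP estimates are not redistributable
    here) and should be replaced by users with real first-stage coefficients.
    """
    with resources.files("mrphewas.data").joinpath("default_panel.csv").open() as fh:
        return InstrumentPanel.from_csv(fh)
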