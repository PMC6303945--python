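"""Shared data containers for the pipeline.

Every analysis stage exchanges three kinds of tables: a gene x sample
expression matrix with a declared value kind, a locus x sample genotype
dosage matrix, and a per-sample clinical trait table.  They are thin,
validated wrappers around :class:`pandas.DataFrame` so that downstream
code can rely on unique identifiers, finite values and aligned samples
without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALUE_KINDS = ("counts", "fpkm", "log", "residual")

APOE_GENOTYPES = ("E23", "E33", "E34")

#: clinical trait columns with their admissible ranges
TRAIT_RANGES = {
    "CDR": (0.0, 5.0),
    "Braak": (0.0, 6.0),
    "CERAD": (1.0, 4.0),
    "MMSE": (0.0, 30.0),
    "PLQ_Mn": (0.0, np.inf),
    "NTrSum": (0.0, np.inf),
    "AOD": (0.0, 130.0),
}


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values of a declared kind.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
    value_kind
        One of ``counts``, ``fpkm``, ``log`` or ``residual``.
    dataset
        Cohort/dataset identifier carried through every output table.
    """

    values: pd.DataFrame
    value_kind: str = "log"
    dataset: str = "dataset"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(
                f"value_kind {self.value_kind!r} not in {VALUE_KINDS}"
            )
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must all be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(samples)], self.value_kind, self.dataset
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(genes)], self.value_kind, self.dataset
        )

    def with_values(self, values: pd.DataFrame, value_kind: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, value_kind, self.dataset)


@dataclass
class GenotypeMatrix:
    """Locus x sample allele-dosage matrix with entries in {0, 1, 2}.

    Missing genotypes are encoded as ``-1`` and must be declared through
    ``missing_marker``; silent NaNs are rejected.
    """

    dosages: pd.DataFrame
    missing_marker: int = -1

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "locus ids")
        _check_unique(self.dosages.columns, "sample ids")
        arr = self.dosages.to_numpy()
        valid = np.isin(arr, [0, 1, 2, self.missing_marker])
        if not valid.all():
            bad = np.unique(arr[~valid])
            raise ValueError(f"dosage values outside {{0,1,2,missing}}: {bad[:5]}")

    @property
    def loci(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def samples(self) -> list[str]:
        return list(self.dosages.columns)

    def aligned_to(self, expr: ExpressionMatrix) -> "GenotypeMatrix":
        """Reorder samples to match an expression matrix; all must be present."""
        missing = set(expr.samples) - set(self.samples)
        if missing:
            raise ValueError(f"samples missing from genotypes: {sorted(missing)[:5]}")
        return GenotypeMatrix(self.dosages.loc[:, expr.samples], self.missing_marker)


@dataclass
class TraitTable:
    """Per-sample clinical traits (samples on the index).

    Recognised numeric columns are range-checked against the clinical
    scales (CDR 0-5, Braak 0-6, CERAD 1-4, MMSE 0-30, nonnegative plaque
    and tangle densities).  Unknown values must be explicit NaN; they are
    propagated by pairwise-complete deletion downstream, never imputed.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample ids")
        for col, (lo, hi) in TRAIT_RANGES.items():
            if col in self.table.columns:
                vals = pd.to_numeric(self.table[col], errors="raise")
                ok = vals.dropna().between(lo, hi)
                if not ok.all():
                    raise ValueError(f"trait {col} outside [{lo}, {hi}]")
        if "sex" in self.table.columns:
            bad = set(self.table["sex"].dropna()) - {"F", "M"}
            if bad:
                raise ValueError(f"unknown sex codes: {bad}")
        if "APOE" in self.table.columns:
            bad = set(self.table["APOE"].dropna()) - set(APOE_GENOTYPES)
            if bad:
                raise ValueError(f"unknown APOE genotypes: {bad}")
        if "diagnosis" in self.table.columns:
            bad = set(self.table["diagnosis"].dropna()) - {"control", "AD"}
            if bad:
                raise ValueError(f"unknown diagnosis labels: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def subset(self, samples) -> "TraitTable":
        return TraitTable(self.table.loc[list(samples)])


@dataclass
class Cohort:
    """One simulated or observed cohort: expression + genotypes + traits."""

    dataset: str
    expression: ExpressionMatrix
    genotypes: GenotypeMatrix | None = None
    traits: TraitTable | None = None
    #: pre-binning latent trait scores (simulation provenance, optional)
    trait_scores: pd.DataFrame | None = None

    @property
    def ad_samples(self) -> list[str]:
        if self.traits is None or "diagnosis" not in self.traits.table.columns:
            raise ValueError(f"cohort {self.dataset} has no diagnosis labels")
        mask = self.traits.table["diagnosis"] == "AD"
        return list(self.traits.table.index[mask])

    @property
    def control_samples(self) -> list[str]:
        if self.traits is None or "diagnosis" not in self.traits.table.columns:
            raise ValueError(f"cohort {self.dataset} has no diagnosis labels")
        mask = self.traits.table["diagnosis"] == "control"
        return list(self.traits.table.index[mask])


@dataclass
class CohortCollection:
    """Cohorts sharing one underlying regulatory network."""

    cohorts: list[Cohort] = field(default_factory=list)
    attenuation: float | None = None  # calibrated disease edge multiplier

    def __iter__(self):
        return iter(self.cohorts)

    def __len__(self) -> int:
        return len(self.cohorts)

    def __getitem__(self, i: int) -> Cohort:
        return self.cohorts[i]
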