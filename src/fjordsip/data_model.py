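"""Domain containers shared by every analysis stage.

A SIP experiment is organised as *treatments* (condition x substrate x
isotope), each fractionated in up to three technical ultracentrifugation
replicates.  Each replicate yields an ordered series of density fractions
with a qPCR 16S copy total (SQ), and sequenced fractions contribute columns
to an ASV x sample read-count matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "TableFormatError",
    "SampleKey",
    "DensityFraction",
    "GradientReplicate",
    "TreatmentDesign",
    "FeatureCountMatrix",
    "TaxonomyTable",
    "RANKS",
    "ORGANELLE_TERMS",
]

DENSITY_RANGE = (1.60, 1.80)  # plausible CsCl buoyant densities, g/mL

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

# rank values that mark eukaryotic organelle reads
ORGANELLE_TERMS = ("chloroplast", "mitochondria", "mitochondrion")


class SchemaError(ValueError):
    """A table is missing or mis-declares a required column."""


class TableFormatError(ValueError):
    """A table row violates the format (non-numeric cell, duplicate key...)."""


class SampleKey(NamedTuple):
    """Identifies one sequenced fraction: (treatment, replicate, fraction)."""

    treatment: str
    replicate: int
    fraction: str


@dataclass(frozen=True)
class DensityFraction:
    """One gradient fraction: buoyant density plus its qPCR copy total.

    ``copies`` may be None for fractions that were collected but never
    quantified/sequenced; the density must always be present.
    """

    fraction_id: str
    density: float
    copies: Optional[float] = None
    sequenced: bool = False

    def __post_init__(self) -> None:
        if not (DENSITY_RANGE[0] <= self.density <= DENSITY_RANGE[1]):
            raise ValueError(
                f"fraction {self.fraction_id!r}: density {self.density} g/mL "
                f"outside plausible range {DENSITY_RANGE}"
            )
        if self.copies is not None:
            if not math.isfinite(self.copies) or self.copies < 0:
                raise ValueError(
                    f"fraction {self.fraction_id!r}: copies must be a finite "
                    f"non-negative number, got {self.copies!r}"
                )


@dataclass(frozen=True)
class GradientReplicate:
    """One technical ultracentrifugation run of one treatment.

    Fractions are stored in canonical ascending-density order regardless of
    collection order; the original order, if it matters, belongs in
    provenance metadata.  At least two fractions are required; the 7-14
    sequenced-fraction guideline is a QC check, not a construction error.
    """

    treatment_id: str
    replicate_id: int
    fractions: tuple[DensityFraction, ...]

    def __post_init__(self) -> None:
        if len(self.fractions) < 2:
            raise ValueError(
                f"{self.treatment_id}/r{self.replicate_id}: a gradient needs "
                f"at least 2 fractions, got {len(self.fractions)}"
            )
        ordered = tuple(sorted(self.fractions, key=lambda f: f.density))
        object.__setattr__(self, "fractions", ordered)

    @property
    def densities(self) -> np.ndarray:
        return np.array([f.density for f in self.fractions])

    @property
    def copies(self) -> np.ndarray:
        """SQ per fraction; NaN where not quantified."""
        return np.array(
            [np.nan if f.copies is None else f.copies for f in self.fractions]
        )

    @property
    def sequenced_fractions(self) -> tuple[DensityFraction, ...]:
        return tuple(f for f in self.fractions if f.sequenced)

    def fraction(self, fraction_id: str) -> DensityFraction:
        for f in self.fractions:
            if f.fraction_id == fraction_id:
                return f
        raise KeyError(
            f"{self.treatment_id}/r{self.replicate_id}: no fraction "
            f"{fraction_id!r}"
        )

    def peak_index(self) -> int:
        """Index of the copy-number peak; ties break toward lower density."""
        copies = self.copies
        if np.all(np.isnan(copies)):
            raise ValueError("no fraction has a copy total; peak undefined")
        filled = np.where(np.isnan(copies), -np.inf, copies)
        return int(np.argmax(filled))  # argmax takes the first (lowest density)


CONDITIONS = ("oxic", "hypoxic")
SUBSTRATES = ("taurine", "methionine", "glucose", "none")
ISOTOPES = ("12C", "13C")


@dataclass(frozen=True)
class TreatmentDesign:
    """One incubation bottle: condition, labeled substrate, isotope, dosing."""

    treatment_id: str
    condition: str
    labeled_substrate: str
    isotope: str
    substrate_concentration_nM: float = 40.0
    incubation_hours: float = 48.0
    temperature_C: float = 4.0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.labeled_substrate not in SUBSTRATES:
            raise ValueError(f"labeled_substrate must be one of {SUBSTRATES}")
        if self.isotope not in ISOTOPES:
            raise ValueError(f"isotope must be one of {ISOTOPES}")
        if self.isotope == "13C" and self.labeled_substrate == "none":
            raise ValueError("a 13C treatment must name a labeled substrate")
        if self.substrate_concentration_nM < 0:
            raise ValueError("substrate concentration must be >= 0")


class FeatureCountMatrix:
    """ASV x sample read counts with (treatment, replicate, fraction) columns.

    Thin wrapper over a pandas DataFrame whose columns are a 3-level
    MultiIndex of sample keys.  Counts are non-negative integers; filtering
    never alters count values, only row membership.
    """

    def __init__(self, df: pd.DataFrame):
        if df.columns.nlevels != 3:
            raise SchemaError(
                "count matrix columns must be (treatment, replicate, fraction)"
            )
        values = df.to_numpy()
        if values.size and (
            not np.issubdtype(values.dtype, np.number)
            or np.any(values < 0)
            or np.any(values != np.floor(values))
        ):
            raise TableFormatError("counts must be non-negative integers")
        df = df.astype(np.int64)
        df.columns = df.columns.set_names(["treatment", "replicate", "fraction"])
        df.index = df.index.astype(str).rename("asv_id")
        self._df = df

    @classmethod
    def from_arrays(
        cls,
        asv_ids: Sequence[str],
        sample_keys: Sequence[SampleKey],
        counts: np.ndarray,
    ) -> "FeatureCountMatrix":
        cols = pd.MultiIndex.from_tuples(
            [(k.treatment, int(k.replicate), str(k.fraction)) for k in sample_keys]
        )
        return cls(pd.DataFrame(np.asarray(counts), index=list(asv_ids), columns=cols))

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def asv_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_keys(self) -> list[SampleKey]:
        return [SampleKey(t, int(r), str(f)) for t, r, f in self._df.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self._df.columns.get_level_values(0)))

    def total_reads(self) -> int:
        return int(self._df.to_numpy().sum())

    def asv_totals(self) -> pd.Series:
        return self._df.sum(axis=1)

    def subset_asvs(self, asv_ids: Iterable[str]) -> "FeatureCountMatrix":
        keep = [a for a in self.asv_ids if a in set(asv_ids)]
        return FeatureCountMatrix(self._df.loc[keep])

    def treatment_slice(self, treatment_id: str) -> pd.DataFrame:
        if treatment_id not in self.treatments:
            raise KeyError(f"unknown treatment {treatment_id!r}")
        return self._df.xs(treatment_id, axis=1, level="treatment")

    def replicate_slice(self, treatment_id: str, replicate_id: int) -> pd.DataFrame:
        """Columns of one gradient replicate, indexed by fraction id."""
        sub = self.treatment_slice(treatment_id)
        if int(replicate_id) not in set(sub.columns.get_level_values(0)):
            raise KeyError(
                f"no replicate {replicate_id} in treatment {treatment_id!r}"
            )
        return sub.xs(int(replicate_id), axis=1, level="replicate")

    def replicates_of(self, treatment_id: str) -> list[int]:
        return sorted(set(self.treatment_slice(treatment_id).columns.get_level_values(0)))

    def __repr__(self) -> str:  # pragma: no cover
        n, m = self.shape
        return f"<FeatureCountMatrix {n} ASVs x {m} samples>"


UNASSIGNED = "unassigned"


class TaxonomyTable:
    """ASV -> ranked lineage plus an organelle flag.

    The table accepts QIIME-style ``d__...;p__...`` strings or one column per
    rank; every ASV in a count matrix either has a lineage or an explicit
    ``unassigned`` record.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [r for r in RANKS if r not in df.columns]
        if missing:
            raise SchemaError(f"taxonomy is missing rank column(s): {missing}")
        df = df.copy()
        df.index = df.index.astype(str).rename("asv_id")
        for r in RANKS:
            df[r] = df[r].fillna(UNASSIGNED).astype(str)
        if "organelle" in df.columns:
            df["organelle"] = (
                df["organelle"]
                .map(lambda v: str(v).strip().lower() in ("1", "true", "yes"))
                .astype(bool)
            )
        else:
            df["organelle"] = df[list(RANKS)].apply(
                lambda row: any(
                    term in str(v).lower() for v in row for term in ORGANELLE_TERMS
                ),
                axis=1,
            )
        self._df = df[list(RANKS) + ["organelle"]]

    @classmethod
    def from_lineages(
        cls, lineages: dict[str, Sequence[str]]
    ) -> "TaxonomyTable":
        rows = {}
        for asv, ranks in lineages.items():
            vals = list(ranks)[: len(RANKS)]
            vals += [UNASSIGNED] * (len(RANKS) - len(vals))
            rows[asv] = vals
        return cls(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))

    @staticmethod
    def parse_qiime_string(s: str) -> list[str]:
        """Split ``d__Bacteria; p__...`` into bare rank values."""
        parts = [p.strip() for p in str(s).split(";")]
        out = []
        for p in parts:
            if "__" in p:
                p = p.split("__", 1)[1]
            out.append(p if p else UNASSIGNED)
        return out

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def asv_ids(self) -> list[str]:
        return list(self._df.index)

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        return tuple(self._df.loc[str(asv_id), list(RANKS)])

    def is_organelle(self, asv_id: str) -> bool:
        return bool(self._df.loc[str(asv_id), "organelle"])

    def rank_value(self, asv_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise KeyError(f"unknown rank {rank!r}")
        return str(self._df.loc[str(asv_id), rank])

    def lineage_contains(self, asv_id: str, term: str) -> bool:
        term = term.lower()
        return any(term in v.lower() for v in self.lineage(asv_id))

    def with_unassigned(self, asv_ids: Iterable[str]) -> "TaxonomyTable":
        """Return a copy covering ``asv_ids``, adding unassigned records."""
        missing = [a for a in asv_ids if str(a) not in set(self._df.index)]
        if not missing:
            return self
        pad = pd.DataFrame(
            {r: UNASSIGNED for r in RANKS}, index=pd.Index(missing, dtype=str)
        )
        pad["organelle"] = False
        return TaxonomyTable(pd.concat([self._df, pad]))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TaxonomyTable {len(self._df)} ASVs>"
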