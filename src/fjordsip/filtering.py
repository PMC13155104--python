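"""The three-step ASV quality-filter cascade with an auditable ledger.

Stage 1 removes list-based contaminants (genus/family name matches at any
rank, case-insensitive substring) and eukaryotic organelle reads
(mitochondria, chloroplasts).  Stage 2 removes globally rare ASVs (total
reads below a threshold, default: keep >= 10).  Stage 3 restricts each
treatment's analysis set to ASVs with strictly more than a threshold of
reads in *every* technical replicate of that treatment (default: > 10);
this last stage changes membership metadata only, never the matrix.

Count values are never modified by any stage; only row membership changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data_model import FeatureCountMatrix, TaxonomyTable

__all__ = [
    "DEFAULT_BLOCKLIST",
    "LedgerEntry",
    "FilterLedger",
    "remove_contaminants",
    "filter_low_abundance",
    "filter_per_replicate",
    "run_filter_cascade",
]

# genera repeatedly flagged as reagent/lab contaminants; user-extensible
DEFAULT_BLOCKLIST = ("Ralstonia", "Variovorax", "Streptococcus")


@dataclass(frozen=True)
class LedgerEntry:
    stage: str
    n_removed: int
    asv_ids: tuple[str, ...]
    reads_removed_fraction: float  # of the stage's input reads
    detail: dict = field(default_factory=dict)


class FilterLedger:
    """Ordered record of what each stage removed and why."""

    def __init__(self) -> None:
        self.entries: list[LedgerEntry] = []

    def append(self, entry: LedgerEntry) -> None:
        removed_before = set().union(*(e.asv_ids for e in self.entries), set())
        overlap = removed_before & set(entry.asv_ids)
        if overlap:
            raise ValueError(
                f"stage {entry.stage!r} re-removes ASV(s) already removed: "
                f"{sorted(overlap)[:5]}"
            )
        if not 0.0 <= entry.reads_removed_fraction <= 1.0:
            raise ValueError("reads_removed_fraction must lie in [0, 1]")
        self.entries.append(entry)

    @property
    def total_removed(self) -> int:
        return sum(e.n_removed for e in self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": e.stage,
                    "n_removed": e.n_removed,
                    "reads_removed_fraction": e.reads_removed_fraction,
                    "asv_ids": ";".join(e.asv_ids),
                }
                for e in self.entries
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _entry(
    stage: str, m: FeatureCountMatrix, removed: list[str], **detail
) -> LedgerEntry:
    total = m.total_reads()
    removed_reads = int(m.df.loc[removed].to_numpy().sum()) if removed else 0
    return LedgerEntry(
        stage=stage,
        n_removed=len(removed),
        asv_ids=tuple(removed),
        reads_removed_fraction=(removed_reads / total) if total else 0.0,
        detail=detail,
    )


def remove_contaminants(
    m: FeatureCountMatrix,
    tax: TaxonomyTable,
    blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST,
) -> tuple[FeatureCountMatrix, LedgerEntry]:
    """Drop blocklisted lineages and organelle-flagged ASVs."""
    if not m.asv_ids:
        raise ValueError("empty count matrix")
    terms = [t.lower() for t in blocklist]
    removed = [
        a
        for a in m.asv_ids
        if tax.is_organelle(a)
        or any(term in v.lower() for v in tax.lineage(a) for term in terms)
    ]
    kept = m.subset_asvs([a for a in m.asv_ids if a not in set(removed)])
    return kept, _entry("contaminants_organelles", m, removed, blocklist=blocklist)


def filter_low_abundance(
    m: FeatureCountMatrix, min_total: int = 10
) -> tuple[FeatureCountMatrix, LedgerEntry]:
    """Drop ASVs with fewer than ``min_total`` reads summed over all samples."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    if not m.asv_ids:
        raise ValueError("empty count matrix")
    totals = m.asv_totals()
    removed = [a for a in m.asv_ids if totals[a] < min_total]
    kept = m.subset_asvs([a for a in m.asv_ids if totals[a] >= min_total])
    return kept, _entry("low_abundance", m, removed, min_total=min_total)


def filter_per_replicate(
    m: FeatureCountMatrix, min_reads: int = 10
) -> tuple[dict[str, frozenset[str]], LedgerEntry]:
    """Per-treatment inclusion sets: ASVs with > ``min_reads`` in every replicate.

    Membership metadata only — the matrix is left untouched.  The threshold
    is strict (10 reads in one replicate excludes at the default).
    """
    if not m.asv_ids:
        raise ValueError("empty count matrix")
    inclusion: dict[str, frozenset[str]] = {}
    for treatment in m.treatments:
        reps = m.replicates_of(treatment)
        if not reps:
            raise ValueError(f"treatment {treatment!r} has no replicates")
        per_rep = pd.DataFrame(
            {r: m.replicate_slice(treatment, r).sum(axis=1) for r in reps}
        )
        ok = (per_rep > min_reads).all(axis=1)
        inclusion[treatment] = frozenset(ok.index[ok])
    entry = LedgerEntry(
        stage="per_replicate",
        n_removed=0,  # membership metadata only; nothing leaves the matrix
        asv_ids=(),
        reads_removed_fraction=0.0,
        detail={
            "min_reads": min_reads,
            "retained_per_treatment": {t: len(s) for t, s in inclusion.items()},
        },
    )
    return inclusion, entry


def run_filter_cascade(
    m: FeatureCountMatrix,
    tax: TaxonomyTable,
    blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST,
    min_total: int = 10,
    min_per_replicate: int = 10,
) -> tuple[FeatureCountMatrix, dict[str, frozenset[str]], FilterLedger]:
    """Apply the full cascade in its fixed order and return the ledger."""
    ledger = FilterLedger()
    m1, e1 = remove_contaminants(m, tax, blocklist)
    ledger.append(e1)
    m2, e2 = filter_low_abundance(m1, min_total)
    ledger.append(e2)
    inclusion, e3 = filter_per_replicate(m2, min_per_replicate)
    ledger.append(e3)
    return m2, inclusion, ledger
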