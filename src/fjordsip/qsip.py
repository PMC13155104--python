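"""Core isotope inference: from fraction-level reads and qPCR totals to
per-ASV 13C excess atom fractions (EAF) with bootstrap confidence intervals.

The chain, per technical replicate:

1.  allocate each fraction's qPCR 16S copy total (SQ) to ASVs in proportion
    to their reads in that fraction;
2.  take the copy-weighted mean buoyant density W of each ASV;
3.  convert the unlabeled reference density W_light to GC content, then to
    the light and maximally heavy molecular weights of a nucleotide pair;
4.  infer the labeled molecular weight from the relative density shift,
    M_lab = (W_lab / W_light) * M_light, and express the shift as an excess
    atom fraction EAF = (M_lab - M_light) / (M_heavymax - M_light) * (1 - nat13c).

The point estimate per ASV is the median EAF over labeled technical
replicates (against the mean unlabeled W); uncertainty comes from a
bootstrap that resamples labeled and unlabeled replicate sets independently
with replacement.  An ASV is called an incorporator when the lower bound of
its 90% interval is strictly above zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, IsotopeConstants
from .data_model import FeatureCountMatrix, GradientReplicate

log = logging.getLogger("fjordsip")

__all__ = [
    "EAFEstimate",
    "taxon_copies",
    "weighted_mean_density",
    "taxon_density_profiles",
    "bulk_weighted_density",
    "treatment_bulk_density",
    "gc_from_density",
    "molecular_weights",
    "eaf_per_replicate",
    "estimate_eaf",
    "estimate_eaf_table",
    "call_incorporators",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class EAFEstimate:
    """Per-ASV excess atom fraction with its bootstrap 90% interval."""

    asv_id: str
    treatment_id: str
    per_replicate_eaf: tuple[float, ...]
    median_eaf: float
    ci_low: float
    ci_high: float
    is_incorporator: bool
    ci_level: float = 0.90
    n_boot: int = 1000


def taxon_copies(
    m: FeatureCountMatrix,
    rep: GradientReplicate,
    inclusion: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Allocate each sequenced fraction's SQ to ASVs by read proportion.

    Returns an ASV x fraction table of 16S copy numbers with
    ``copies[i, k] = reads[i, k] / sum_i reads[i, k] * SQ_k``.  Column sums
    therefore reproduce SQ exactly for every fraction with reads.
    """
    reads = m.replicate_slice(rep.treatment_id, rep.replicate_id)
    seq = [f for f in rep.sequenced_fractions if f.fraction_id in set(reads.columns)]
    if not seq:
        raise ValueError(
            f"{rep.treatment_id}/r{rep.replicate_id}: no sequenced fractions "
            f"with count columns"
        )
    if inclusion is not None:
        keep = [a for a in reads.index if a in set(inclusion)]
        reads = reads.loc[keep]
    out = {}
    for f in seq:
        col = reads[f.fraction_id].astype(float)
        total = col.sum()
        if total == 0:
            log.info(
                "%s/r%d fraction %s has zero total reads; contributes no copies",
                rep.treatment_id, rep.replicate_id, f.fraction_id,
            )
            out[f.fraction_id] = col * 0.0
            continue
        sq = f.copies if f.copies is not None else np.nan
        if np.isnan(sq):
            raise ValueError(
                f"{rep.treatment_id}/r{rep.replicate_id}: sequenced fraction "
                f"{f.fraction_id} has no qPCR copy total"
            )
        out[f.fraction_id] = col / total * sq
    return pd.DataFrame(out)


def weighted_mean_density(
    copy_table: pd.DataFrame, rep: GradientReplicate
) -> pd.DataFrame:
    """Copy-weighted mean density W per ASV from a :func:`taxon_copies` table.

    ASVs with zero copies everywhere get ``W = NaN`` (missing, not zero) and
    are flagged in the log.
    """
    densities = np.array([rep.fraction(c).density for c in copy_table.columns])
    copies = copy_table.to_numpy(dtype=float)
    totals = copies.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (copies * densities).sum(axis=1) / totals
    w = np.where(totals > 0, w, np.nan)
    n_missing = int(np.sum(totals == 0))
    if n_missing:
        log.info(
            "%s/r%d: %d ASV(s) with zero copies -> missing W",
            rep.treatment_id, rep.replicate_id, n_missing,
        )
    return pd.DataFrame(
        {"W": w, "total_copies": totals}, index=copy_table.index
    )


def taxon_density_profiles(
    m: FeatureCountMatrix,
    reps: Sequence[GradientReplicate],
    inclusion: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Long table of (asv_id, treatment_id, replicate_id, W, total_copies)."""
    frames = []
    for rep in reps:
        prof = weighted_mean_density(taxon_copies(m, rep, inclusion), rep)
        prof = prof.reset_index().rename(columns={"index": "asv_id"})
        prof["treatment_id"] = rep.treatment_id
        prof["replicate_id"] = rep.replicate_id
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)[
        ["asv_id", "treatment_id", "replicate_id", "W", "total_copies"]
    ]


def bulk_weighted_density(rep: GradientReplicate) -> float:
    """SQ-weighted mean density over all fractions of one replicate."""
    copies = rep.copies
    if np.any(np.isnan(copies)):
        raise ValueError(
            f"{rep.treatment_id}/r{rep.replicate_id}: all fractions need a "
            f"copy total for the bulk weighted density"
        )
    total = copies.sum()
    if total == 0:
        raise ValueError(
            f"{rep.treatment_id}/r{rep.replicate_id}: zero total copies"
        )
    return float((rep.densities * copies).sum() / total)


def treatment_bulk_density(
    reps: Sequence[GradientReplicate],
) -> tuple[float, float, list[float]]:
    """Mean +/- SD of the bulk weighted density over technical replicates."""
    per_rep = [bulk_weighted_density(r) for r in reps]
    return (
        float(np.mean(per_rep)),
        float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else 0.0,
        per_rep,
    )


def gc_from_density(
    w_light: ArrayLike, constants: IsotopeConstants = DEFAULT_CONSTANTS
) -> ArrayLike:
    """GC content from the unlabeled buoyant density.

    Values outside [0, 1] are returned as-is (downstream algebra tolerates
    them) but flagged in the log.
    """
    g = (np.asarray(w_light, dtype=float) - constants.gc_intercept) / constants.gc_slope
    out_of_range = np.sum((g < 0) | (g > 1))
    if out_of_range:
        log.warning("%d GC value(s) outside [0, 1]", int(out_of_range))
    return float(g) if np.ndim(w_light) == 0 else g


def molecular_weights(
    gc: ArrayLike, constants: IsotopeConstants = DEFAULT_CONSTANTS
) -> tuple[ArrayLike, ArrayLike]:
    """Light and maximally-13C-labeled molecular weights (g/mol) at given GC."""
    g = np.asarray(gc, dtype=float)
    m_light = constants.mw_gc_slope * g + constants.mw_intercept
    m_heavy = constants.heavy_gc_slope * g + constants.heavy_offset + m_light
    if np.ndim(gc) == 0:
        return float(m_light), float(m_heavy)
    return m_light, m_heavy


def eaf_per_replicate(
    w_lab: ArrayLike,
    w_light_mean: ArrayLike,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Excess atom fraction from one labeled W against the unlabeled reference.

    Negative values are preserved (no clamping): the bootstrap interval
    criterion needs the full sampling distribution around zero.
    """
    w_lab = np.asarray(w_lab, dtype=float)
    w_light = np.asarray(w_light_mean, dtype=float)
    g = (w_light - constants.gc_intercept) / constants.gc_slope
    m_light = constants.mw_gc_slope * g + constants.mw_intercept
    m_heavy = constants.heavy_gc_slope * g + constants.heavy_offset + m_light
    m_lab = (w_lab / w_light) * m_light
    eaf = (m_lab - m_light) / (m_heavy - m_light) * (1.0 - constants.nat13c)
    if np.ndim(eaf) == 0:
        return float(eaf)
    return eaf


def estimate_eaf(
    asv_id: str,
    treatment_id: str,
    labeled_w: Sequence[float],
    unlabeled_w: Sequence[float],
    n_boot: int = 1000,
    ci_level: float = 0.90,
    seed: Optional[Union[int, np.random.Generator]] = None,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> EAFEstimate:
    """Median EAF over labeled replicates with a replicate-bootstrap interval.

    Each bootstrap iteration resamples the labeled replicate set and the
    unlabeled replicate set independently with replacement, recomputes the
    unlabeled mean W and the median EAF; the interval is the percentile
    interval of the bootstrap medians at ``ci_level``.
    """
    lab = np.asarray([w for w in labeled_w if np.isfinite(w)], dtype=float)
    unl = np.asarray([w for w in unlabeled_w if np.isfinite(w)], dtype=float)
    if lab.size == 0 or unl.size == 0:
        raise ValueError(
            f"{asv_id}: needs >= 1 labeled and >= 1 unlabeled replicate W"
        )
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    w_light_mean = unl.mean()
    per_rep = eaf_per_replicate(lab, w_light_mean, constants)
    per_rep = np.atleast_1d(per_rep)
    point = float(np.median(per_rep))

    il = rng.integers(0, lab.size, size=(n_boot, lab.size))
    iu = rng.integers(0, unl.size, size=(n_boot, unl.size))
    w_light_boot = unl[iu].mean(axis=1)
    eafs = eaf_per_replicate(lab[il], w_light_boot[:, None], constants)
    medians = np.median(eafs, axis=1)
    alpha = (1.0 - ci_level) / 2.0
    ci_low, ci_high = np.quantile(medians, [alpha, 1.0 - alpha])

    return EAFEstimate(
        asv_id=asv_id,
        treatment_id=treatment_id,
        per_replicate_eaf=tuple(float(e) for e in per_rep),
        median_eaf=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        is_incorporator=bool(ci_low > 0),
        ci_level=ci_level,
        n_boot=n_boot,
    )


def estimate_eaf_table(
    labeled_profiles: pd.DataFrame,
    unlabeled_profiles: pd.DataFrame,
    treatment_id: Optional[str] = None,
    n_boot: int = 1000,
    ci_level: float = 0.90,
    seed: Optional[int] = None,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> list[EAFEstimate]:
    """Estimate EAF for every ASV present in both profile tables.

    Profile tables are the long format of :func:`taxon_density_profiles`.
    ASVs absent (or all-NaN) in the unlabeled reference are excluded with a
    logged reason — without an unlabeled W the GC baseline is undefined.
    The per-ASV bootstrap streams are drawn from one seeded generator over
    ASVs in sorted order, so results do not depend on input row order.
    """
    if treatment_id is None:
        ids = labeled_profiles["treatment_id"].unique()
        if len(ids) != 1:
            raise ValueError("labeled profiles span several treatments; pass treatment_id")
        treatment_id = str(ids[0])
    lab_w = (
        labeled_profiles.dropna(subset=["W"])
        .sort_values(["asv_id", "replicate_id"])
        .groupby("asv_id")["W"]
        .agg(list)
    )
    unl_w = (
        unlabeled_profiles.dropna(subset=["W"])
        .sort_values(["asv_id", "replicate_id"])
        .groupby("asv_id")["W"]
        .agg(list)
    )
    rng = np.random.default_rng(seed)
    estimates = []
    for asv in sorted(lab_w.index):
        if asv not in unl_w.index:
            log.info(
                "%s: ASV %s absent from all unlabeled replicates; EAF undefined",
                treatment_id, asv,
            )
            continue
        estimates.append(
            estimate_eaf(
                asv,
                treatment_id,
                lab_w[asv],
                unl_w[asv],
                n_boot=n_boot,
                ci_level=ci_level,
                seed=rng,
                constants=constants,
            )
        )
    return estimates


def call_incorporators(
    estimates: Sequence[EAFEstimate],
    matrix: Optional[FeatureCountMatrix] = None,
    treatment_id: Optional[str] = None,
) -> tuple[pd.DataFrame, dict]:
    """Annotate estimates with the incorporator call and summarise.

    The call is strict: ``ci_low > 0`` (an interval touching zero is not an
    incorporator).  When a count matrix and treatment are given, the summary
    adds the summed mean relative read abundance of incorporator ASVs over
    that treatment's sequenced-fraction samples.
    """
    levels = {e.ci_level for e in estimates}
    if len(levels) > 1:
        raise ValueError(f"estimates mix ci_levels: {sorted(levels)}")
    rows = [
        {
            "asv_id": e.asv_id,
            "treatment_id": e.treatment_id,
            "median_eaf": e.median_eaf,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "is_incorporator": e.ci_low > 0,
        }
        for e in estimates
    ]
    table = pd.DataFrame(rows)
    incorporators = [r["asv_id"] for r in rows if r["is_incorporator"]]
    summary = {
        "n_estimates": len(rows),
        "n_incorporators": len(incorporators),
        "incorporator_ids": incorporators,
    }
    if matrix is not None and treatment_id is not None:
        sub = matrix.treatment_slice(treatment_id)
        col_totals = sub.sum(axis=0)
        nonzero = col_totals > 0
        rel = sub.loc[:, nonzero].div(col_totals[nonzero], axis=1)
        mean_rel = rel.mean(axis=1)
        summary["incorporator_relative_abundance"] = float(
            mean_rel.reindex(incorporators).fillna(0.0).sum()
        )
    return table, summary
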