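"""Gradient quality control.

Checks mirror how gradients were fractionated and selected for sequencing:
adjacent fraction spacing should fall in 0.005-0.007 g/mL, 7-14 fractions
should be sequenced, and the sequenced window must span the copy-number peak
with at least one sequenced fraction on each flank.  All checks are pure:
re-validating the same replicate yields an identical report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data_model import GradientReplicate

__all__ = ["Finding", "validate_gradient", "SPACING_RANGE", "SEQUENCED_RANGE"]

SPACING_RANGE = (0.005, 0.007)  # g/mL between adjacent fractions
SEQUENCED_RANGE = (7, 14)       # fractions selected for sequencing


@dataclass(frozen=True)
class Finding:
    level: Literal["pass", "warn", "fail"]
    code: str
    message: str


def validate_gradient(
    rep: GradientReplicate,
    min_spacing: float = SPACING_RANGE[0],
    max_spacing: float = SPACING_RANGE[1],
) -> list[Finding]:
    """QC report for one gradient replicate (list of pass/warn/fail findings)."""
    if not rep.fractions:
        raise ValueError("empty gradient replicate")
    findings: list[Finding] = []
    densities = rep.densities

    # (iv) canonical order is ascending; duplicates mean non-monotonic input
    if np.any(np.diff(densities) <= 0):
        findings.append(
            Finding(
                "fail",
                "non_monotonic_density",
                "densities are not strictly monotonic after canonical ordering",
            )
        )
        return findings

    # (i) adjacent spacing
    spacing = np.diff(densities)
    bad = np.where((spacing < min_spacing) | (spacing > max_spacing))[0]
    if bad.size:
        findings.append(
            Finding(
                "warn",
                "fraction_spacing",
                f"{bad.size} adjacent interval(s) outside "
                f"[{min_spacing}, {max_spacing}] g/mL "
                f"(e.g. {spacing[bad[0]]:.4f} g/mL after fraction "
                f"{rep.fractions[bad[0]].fraction_id})",
            )
        )
    else:
        findings.append(Finding("pass", "fraction_spacing", "spacing within range"))

    # (ii) sequenced-fraction count
    seq_idx = [i for i, f in enumerate(rep.fractions) if f.sequenced]
    n_seq = len(seq_idx)
    if not SEQUENCED_RANGE[0] <= n_seq <= SEQUENCED_RANGE[1]:
        findings.append(
            Finding(
                "warn",
                "sequenced_count",
                f"{n_seq} sequenced fraction(s); expected "
                f"{SEQUENCED_RANGE[0]}-{SEQUENCED_RANGE[1]}",
            )
        )
    else:
        findings.append(Finding("pass", "sequenced_count", f"{n_seq} sequenced fractions"))

    # (iii) sequenced window must span the copy peak
    try:
        peak = rep.peak_index()
    except ValueError:
        findings.append(
            Finding("warn", "peak_span", "no copy totals; peak coverage unknown")
        )
        return findings
    spans = (
        peak in seq_idx
        and any(i < peak for i in seq_idx)
        and any(i > peak for i in seq_idx)
    )
    if spans:
        findings.append(
            Finding("pass", "peak_span", "sequenced fractions span the copy peak")
        )
    else:
        findings.append(
            Finding(
                "warn",
                "peak_span",
                f"sequenced fractions do not span the copy peak (fraction "
                f"{rep.fractions[peak].fraction_id} at "
                f"{rep.fractions[peak].density:.4f} g/mL)",
            )
        )
    return findings
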