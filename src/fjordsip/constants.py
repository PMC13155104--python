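"""Physical constants of the GC/buoyant-density/molecular-weight model.

The coefficients map between the buoyant density of unlabeled DNA in a CsCl
gradient, its GC content, and its molecular weight per nucleotide pair, and
set the maximum density shift attainable when every carbon atom is replaced
by 13C.  They are the standard qSIP calibration coefficients; all of them can
be overridden through :class:`IsotopeConstants` or a config file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class IsotopeConstants:
    """Coefficients of the density -> GC -> molecular-weight chain.

    Attributes
    ----------
    gc_slope : float
        Slope of the unlabeled density vs GC relation, g/mL per GC unit.
        GC is recovered as ``(W_light - gc_intercept) / gc_slope``.
    gc_intercept : float
        Unlabeled buoyant density at GC = 0, g/mL.
    mw_gc_slope, mw_intercept : float
        Linear map from GC to the light (natural-abundance) molecular weight
        of a nucleotide pair, g/mol.
    heavy_gc_slope, heavy_offset : float
        GC dependence of the extra mass carried by a fully 13C-labeled
        nucleotide pair: ``M_heavymax = heavy_gc_slope*G + heavy_offset + M_light``.
    nat13c : float
        Natural 13C atom fraction of carbon; the attainable excess atom
        fraction is bounded by ``1 - nat13c``.
    """

    gc_slope: float = 0.083506
    gc_intercept: float = 1.646057
    mw_gc_slope: float = 0.496
    mw_intercept: float = 307.691
    heavy_gc_slope: float = -0.4987282
    heavy_offset: float = 9.974564
    nat13c: float = 0.01111233

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "heavy_gc_slope":
                continue
            if not v > 0:
                raise ValueError(f"{f.name} must be positive, got {v!r}")
        if not (0.0 < self.nat13c < 0.02):
            raise ValueError(f"nat13c out of range (0, 0.02): {self.nat13c!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "IsotopeConstants":
        """Build constants from a (possibly partial) key/value mapping."""
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown isotope constant(s): {sorted(unknown)}")
        return cls(**mapping)


DEFAULT_CONSTANTS = IsotopeConstants()
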