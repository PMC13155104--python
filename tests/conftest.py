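"""Shared fixtures: small hand-built gradients and count matrices."""

import numpy as np
import pytest

from fjordsip import (
    DensityFraction,
    FeatureCountMatrix,
    GradientReplicate,
    SampleKey,
    TaxonomyTable,
)


def make_gradient(
    treatment="hypoxic_13C-taurine",
    replicate=1,
    densities=None,
    copies=None,
    sequenced=None,
):
    if densities is None:
        densities = [1.67 + 0.006 * k for k in range(10)]
    if copies is None:
        copies = [100.0] * len(densities)
    if sequenced is None:
        sequenced = [True] * len(densities)
    fractions = tuple(
        DensityFraction(f"F{k+1:02d}", d, c, s)
        for k, (d, c, s) in enumerate(zip(densities, copies, sequenced))
    )
    return GradientReplicate(treatment, replicate, fractions)


def make_matrix(counts, treatment="hypoxic_13C-taurine", replicate=1, fractions=None):
    """ASV x fraction counts for one replicate of one treatment."""
    counts = np.asarray(counts)
    if fractions is None:
        fractions = [f"F{k+1:02d}" for k in range(counts.shape[1])]
    keys = [SampleKey(treatment, replicate, f) for f in fractions]
    asvs = [f"ASV{i+1}" for i in range(counts.shape[0])]
    return FeatureCountMatrix.from_arrays(asvs, keys, counts)


@pytest.fixture
def toy_gradient():
    return make_gradient()


@pytest.fixture
def toy_taxonomy():
    return TaxonomyTable.from_lineages(
        {
            "ASV1": ("Bacteria", "Bacteroidota", "Bacteroidia", "Flavobacteriales",
                     "Flavobacteriaceae", "Ulvibacter"),
            "ASV2": ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                     "Oceanospirillales", "Oleiphilaceae", "Oleiphilus"),
            "ASV3": ("Bacteria", "Proteobacteria", "Betaproteobacteria",
                     "Burkholderiales", "Burkholderiaceae", "Ralstonia"),
            "ASV4": ("Bacteria", "Cyanobacteria", "Cyanobacteriia", "Chloroplast",
                     "unassigned", "unassigned"),
            "ASV5": ("Bacteria", "Planctomycetota", "Planctomycetes", "Pirellulales",
                     "Pirellulaceae", "Gimesia"),
        }
    )
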