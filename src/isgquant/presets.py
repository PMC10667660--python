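"""Published primer sets and default experimental constants.

The five primer pairs target the particulate methane monooxygenase gene
(pmoA, two nested reverse primers), the ammonia monooxygenase gene (amoA)
of betaproteobacterial ammonia oxidizers, and the V3-4 and V4 regions of
the 16S rRNA gene.  805R is shared between the two 16S pairs.  Product
lengths include both primer binding sites.
"""

from __future__ import annotations

from .calibration import ConversionFactors, SpikeInSeries, build_spikein_series
from .design import DesignConstraints, PrimerSet

__all__ = [
    "PUBLISHED_PRIMER_SETS",
    "DEFAULT_CONSTRAINTS",
    "DEFAULT_GRADIENT_LEVELS",
    "default_spikein",
    "DEFAULT_CONVERSION_FACTORS",
]

PUBLISHED_PRIMER_SETS: tuple[PrimerSet, ...] = (
    PrimerSet(
        name="pmoA-189f/650r",
        forward="GGNGACTGGGACTTCTGG",
        reverse="ACGTCCTTACCGAAGGT",
        target_gene="pmoA",
        expected_amplicon_len=500,
        forward_name="pmoA-189f",
        reverse_name="pmoA-650r",
    ),
    PrimerSet(
        name="pmoA-189f/682r",
        forward="GGNGACTGGGACTTCTGG",
        reverse="GAASGCNGAGAAGAASGC",
        target_gene="pmoA",
        expected_amplicon_len=531,
        forward_name="pmoA-189f",
        reverse_name="pmoA-682r",
    ),
    PrimerSet(
        name="amoA-1F/2R",
        forward="GGGGTTTCTACTGGTGGT",
        reverse="CCCCTCKGSAAAGCCTTCTTC",
        target_gene="amoA",
        expected_amplicon_len=491,
        forward_name="amoA-1F",
        reverse_name="amoA-2R",
    ),
    PrimerSet(
        name="16S-341F/805R",
        forward="CCTACGGGNGGCWGCAG",
        reverse="GACTACHVGGGTATCTAATCC",
        target_gene="16S rRNA V3-4",
        expected_amplicon_len=465,
        forward_name="341F",
        reverse_name="805R",
    ),
    PrimerSet(
        name="16S-515F/805R",
        forward="GTGCCAGCMGCCGCGGTAA",
        reverse="GACTACHVGGGTATCTAATCC",
        target_gene="16S rRNA V4",
        expected_amplicon_len=291,
        forward_name="515F",
        reverse_name="805R",
    ),
)

#: 615-bp synthesis length, GC balanced around 50%.
DEFAULT_CONSTRAINTS = DesignConstraints()

#: Gradient dilutions of the four standards before equal-volume mixing
#: (copies per uL): 4.0e6, 4.0e5, 4.0e4, 4.0e3.
DEFAULT_GRADIENT_LEVELS: tuple[float, ...] = (4.0e6, 4.0e5, 4.0e4, 4.0e3)

#: Template-mix volume ratios: 1 volume standard : 3 volumes sample in the
#: template (F=3, G=4), 2.5 uL template in a 50 uL reaction; no upstream
#: sample dilution by default (D=E=1).
DEFAULT_CONVERSION_FACTORS = ConversionFactors(D=1.0, E=1.0, F=3.0, G=4.0, H=2.5, I=50.0)


def default_spikein() -> SpikeInSeries:
    """Four variants at the default gradient levels, equal-volume mixed."""
    return build_spikein_series(DEFAULT_GRADIENT_LEVELS)
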