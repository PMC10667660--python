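"""Synthetic spike-in amplicon experiments with known ground truth.

Emulates the statistical structure of a spiked sequencing library: every
standard observation and every biological taxon yields a read count drawn
from a negative binomial whose mean is

    mu = detection_efficiency * amplification_efficiency * reaction_conc,

where the reaction concentration follows the volumetric chain of the
protocol.  Sequencer error, chimeras and merge losses are summarized by
the per-taxon amplification-efficiency multiplier; the calibration model
only ever sees counts.  All draws are reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import (
    ConversionFactors,
    SampleFactors,
    SpikeInSeries,
    build_spikein_series,
    expected_reaction_conc,
    isg_reaction_conc,
)
from .design import PrimerSet, concretize_primer, insilico_pcr, reverse_complement

__all__ = [
    "TaxonSpec",
    "SimulationConfig",
    "SimulatedLibrary",
    "nb_draw",
    "simulate_library",
    "simulate_mock_references",
]


@dataclass(frozen=True)
class TaxonSpec:
    """A biological taxon with its true concentration (copies/uL DNA)."""

    taxon_id: str
    conc_dna: float
    amplification_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.conc_dna <= 0:
            raise ValueError("conc_dna must be > 0")
        if not 0.0 < self.amplification_efficiency <= 1.0:
            raise ValueError("amplification_efficiency must be in (0, 1]")


def _default_taxa() -> tuple[TaxonSpec, ...]:
    # mock-community style: members mixed at equivalent amounts
    return tuple(TaxonSpec(f"taxon{i + 1}", 3.0e4) for i in range(5))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulated spike-in library.

    Defaults mirror the reference experiment: a 4-level gradient
    (4.0e6..4.0e3 copies/uL before equal-volume mixing) carried by 4
    standard variants, five mock taxa at 3.0e4 copies/uL DNA each,
    detection efficiency 8 reads/copy and NB size (dispersion) 5.
    Every (variant, level) pair is one standard observation, so a full
    library contributes 16 calibration points.
    """

    seed: int = 0
    gradient_levels: tuple[float, ...] = (4.0e6, 4.0e5, 4.0e4, 4.0e3)
    n_variants: int = 4
    taxa: tuple[TaxonSpec, ...] = field(default_factory=_default_taxa)
    detection_efficiency: float = 8.0
    dispersion: float = 5.0
    factors: ConversionFactors = field(default_factory=ConversionFactors)
    sample: SampleFactors | None = None

    def __post_init__(self) -> None:
        if self.detection_efficiency <= 0:
            raise ValueError("detection_efficiency must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not self.gradient_levels or any(c <= 0 for c in self.gradient_levels):
            raise ValueError("gradient levels must be positive")

    @property
    def spike(self) -> SpikeInSeries:
        return build_spikein_series(
            self.gradient_levels,
            mix_fraction_sample=self.factors.sample_fraction,
        )


@dataclass(frozen=True)
class SimulatedLibrary:
    """ASV count rows plus the ground truth they were generated from."""

    asv_table: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def nb_draw(rng: np.random.Generator, mean, size_param: float) -> np.ndarray:
    """Negative-binomial draw parameterized by (mean, size).

    Gamma-Poisson mixture: lambda ~ Gamma(size, mean/size), y ~ Poisson(lambda),
    giving Var = mean + mean^2/size, the same parameterization the fitting
    module uses.
    """
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=size_param, scale=mean / size_param)
    return rng.poisson(lam)


def simulate_library(config: SimulationConfig) -> SimulatedLibrary:
    """Draw one spiked library under the configured study conditions."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_levels = len(config.gradient_levels)
    factors = config.factors
    de = config.detection_efficiency

    rows = []
    for v in range(config.n_variants):
        vid = f"ISG{v + 1:02d}"
        for l, level in enumerate(config.gradient_levels):
            mix_conc = level / n_levels  # equal-volume mixing of the levels
            z = isg_reaction_conc(mix_conc, factors)
            mu = de * z
            rows.append(
                {
                    "asv_id": f"{vid}-L{l + 1}",
                    "sequence": "",
                    "reads": 0,
                    "label": "ISG",
                    "variant_id": vid,
                    "spike_conc": mix_conc,
                    "expected_reads": mu,
                }
            )
    truth_rows = []
    for taxon in config.taxa:
        z = expected_reaction_conc(taxon.conc_dna, factors, include_sample_mix=True)
        mu = de * taxon.amplification_efficiency * z
        rows.append(
            {
                "asv_id": taxon.taxon_id,
                "sequence": "",
                "reads": 0,
                "label": "biological",
                "variant_id": "",
                "spike_conc": np.nan,
                "expected_reads": mu,
            }
        )
        truth_rows.append(
            {
                "taxon_id": taxon.taxon_id,
                "conc_dna": taxon.conc_dna,
                "amplification_efficiency": taxon.amplification_efficiency,
                "expected_reads": mu,
            }
        )
    table = pd.DataFrame(rows)
    table["reads"] = nb_draw(rng, table["expected_reads"].to_numpy(), config.dispersion)
    truth = pd.DataFrame(
        truth_rows,
        columns=["taxon_id", "conc_dna", "amplification_efficiency", "expected_reads"],
    )
    return SimulatedLibrary(asv_table=table, truth=truth, config=config)


def simulate_mock_references(
    config: SimulationConfig,
    primer_sets: Sequence[PrimerSet] = (),
    template_length: int = 1200,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Synthetic genome-like templates with planted primer-flanked amplicons.

    For every taxon in the config a random template is emitted that carries
    exactly one amplicon of one of the given primer pairs (pairs are cycled
    across taxa), so the templates exercise the in-silico PCR -> partition
    -> quantification path end to end.  Returns ``(records, truth)`` where
    records are (id, sequence) pairs and truth lists copies/uL per taxon.
    """
    if not primer_sets and config.taxa:
        raise ValueError("at least one primer set is needed to plant amplicons")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    bases = np.array(list("ACGT"))
    records: list[tuple[str, str]] = []
    truth_rows = []
    for i, taxon in enumerate(config.taxa):
        ps = primer_sets[i % len(primer_sets)]
        fwd = concretize_primer(ps.forward)
        rev_site = reverse_complement(concretize_primer(ps.reverse))
        interior_len = ps.expected_amplicon_len - len(fwd) - len(rev_site)
        interior = "".join(rng.choice(bases, size=interior_len))
        amplicon = fwd + interior + rev_site
        flank_total = max(template_length - len(amplicon), 0)
        left = flank_total // 2
        template = (
            "".join(rng.choice(bases, size=left))
            + amplicon
            + "".join(rng.choice(bases, size=flank_total - left))
        )
        # re-draw flanks that accidentally create a second product
        for _ in range(20):
            if len(insilico_pcr(template, ps.forward, ps.reverse)) == 1:
                break
            template = (
                "".join(rng.choice(bases, size=left))
                + amplicon
                + "".join(rng.choice(bases, size=flank_total - left))
            )
        records.append((taxon.taxon_id, template))
        truth_rows.append(
            {
                "taxon_id": taxon.taxon_id,
                "primer_set": ps.name,
                "conc": taxon.conc_dna,
                "amplicon": amplicon,
            }
        )
    truth = pd.DataFrame(truth_rows, columns=["taxon_id", "primer_set", "conc", "amplicon"])
    return records, truth
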