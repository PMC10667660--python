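"""File formats, run configuration and the end-to-end pipeline.

Tabular files are tab-separated UTF-8 with a header and '.' decimals;
concentrations are serialized in scientific notation.  FASTA goes through
Biopython with sequences normalized to upper case.  A pipeline run writes
a JSON manifest carrying the package version, seed and a hash of the
configuration so identical invocations are byte-identical (timestamps are
excluded from hashed content).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .calibration import (
    ConversionFactors,
    SampleFactors,
    SpikeInSeries,
    build_spikein_series,
    quantify_asvs,
)
from .qc import partition_isg_reads
from .simulate import SimulationConfig, TaxonSpec, simulate_library

logger = logging.getLogger("isgquant")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_asv_table",
    "write_quant_table",
    "RunConfig",
    "load_run_config",
    "run_pipeline",
]

REQUIRED_ASV_COLUMNS = ("asv_id", "sequence", "sample_id", "reads")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, upper-case sequence) pairs; warns when empty."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(seq.upper()), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
    return path


def read_asv_table(path: str | Path, required: Sequence[str] = REQUIRED_ASV_COLUMNS) -> pd.DataFrame:
    """Read a tab-separated ASV count table, validating required columns."""
    table = pd.read_csv(path, sep="\t", dtype={"asv_id": str, "sequence": str})
    for col in required:
        if col not in table.columns:
            raise ValueError(f"ASV table {path} is missing required column {col!r}")
    if "reads" in table.columns and (table["reads"] < 0).any():
        raise ValueError(f"ASV table {path} contains negative read counts")
    return table


def write_quant_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a quantification table as TSV with scientific-notation floats."""
    path = Path(path)
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.10e}")
    out.to_csv(path, sep="\t", index=False)
    return path


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Configuration of a pipeline run (paths, spike design, factors)."""

    seed: int = 0
    asv_table: str | None = None  # None -> simulate inputs
    isg_fasta: str | None = None
    spike_levels: tuple[float, ...] = (4.0e6, 4.0e5, 4.0e4, 4.0e3)
    factors: ConversionFactors = dataclasses.field(default_factory=ConversionFactors)
    sample: SampleFactors | None = None
    read_length: int | None = 251
    mismatch_tolerance: int = 2
    ggc_boundary: int = 251
    taxa: tuple[TaxonSpec, ...] = ()
    detection_efficiency: float = 8.0
    dispersion: float = 5.0

    def spike(self) -> SpikeInSeries:
        return build_spikein_series(
            self.spike_levels, mix_fraction_sample=self.factors.sample_fraction
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration with unit validation."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in (
        "seed", "asv_table", "isg_fasta", "read_length",
        "mismatch_tolerance", "ggc_boundary", "detection_efficiency", "dispersion",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "spike_levels" in raw:
        kwargs["spike_levels"] = tuple(float(v) for v in raw["spike_levels"])
    if "factors" in raw:
        kwargs["factors"] = ConversionFactors(**{k: float(v) for k, v in raw["factors"].items()})
    if "sample" in raw:
        s = raw["sample"]
        if "unit" not in s:
            raise ValueError("sample factors require a 'unit' tag ('g' or 'L')")
        kwargs["sample"] = SampleFactors(
            c_extraction_vol=float(s["c_extraction_vol"]),
            a_sample_amount=float(s["a_sample_amount"]),
            unit=str(s["unit"]),
        )
    if "taxa" in raw:
        kwargs["taxa"] = tuple(
            TaxonSpec(
                taxon_id=str(t["taxon_id"]),
                conc_dna=float(t["conc_dna"]),
                amplification_efficiency=float(t.get("amplification_efficiency", 1.0)),
            )
            for t in raw["taxa"]
        )
    config = RunConfig(**kwargs)
    for p in (config.asv_table, config.isg_fasta):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured path does not exist: {p}")
    return config


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def run_pipeline(config: RunConfig, output_dir: str | Path) -> Path:
    """Partition -> calibrate -> quantify -> QC, writing all reports.

    Inputs are loaded from the configured paths, or simulated under the
    configured study conditions when no ASV table is given.  Any stage
    error aborts with the stage name and cause.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if config.asv_table is not None:
            table = read_asv_table(config.asv_table)
        else:
            sim_taxa = config.taxa or tuple(
                TaxonSpec(f"taxon{i + 1}", 3.0e4) for i in range(5)
            )
            sim = simulate_library(
                SimulationConfig(
                    seed=config.seed,
                    gradient_levels=config.spike_levels,
                    taxa=sim_taxa,
                    detection_efficiency=config.detection_efficiency,
                    dispersion=config.dispersion,
                    factors=config.factors,
                )
            )
            table = sim.asv_table
            sim.truth.to_csv(out / "truth.tsv", sep="\t", index=False)

        stage = "partition"
        if "label" not in table.columns:
            if config.isg_fasta is None:
                raise ValueError(
                    "table has no 'label' column and no ISG reference FASTA is configured"
                )
            refs = read_fasta(config.isg_fasta)
            table = partition_isg_reads(table, refs, read_length=config.read_length)

        stage = "calibrate/quantify"
        quant, curve = quantify_asvs(
            table, config.spike(), config.factors, config.sample
        )
        write_quant_table(quant, out / "quantified_asvs.tsv")
        curve_report = {
            "intercept_b": curve.intercept_b,
            "detection_efficiency": curve.detection_efficiency,
            "dispersion": curve.dispersion,
            "intercept_se": curve.intercept_se,
            "wald_p_free_slope": curve.wald_p_free_slope,
            "n_points": curve.n_points,
            "converged": curve.converged,
            "loq_threshold": quant.attrs.get("loq_threshold"),
        }
        (out / "curve_report.json").write_text(json.dumps(curve_report, indent=2))

        stage = "qc"
        qc_summary = (
            quant.groupby("label", as_index=False)["reads"].sum().sort_values("label")
        )
        qc_summary.to_csv(out / "qc_read_partition.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "package": "isgquant",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
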