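"""Read-processing and sequence-composition diagnostics.

Covers the quality checks that accompany spike-in quantification: read
recovery through the denoising pipeline (read-out / read-in), the
single-end versus paired-end increment factor, partitioning of ASV reads
into standard-derived and biological fractions, GGC-motif profiling (a
trinucleotide associated with sequencer dephasing errors, counted in
front of and behind the forward-read boundary) and amplicon GC tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Amplicon, PrimerSet, gc_content, insilico_pcr

__all__ = [
    "ReadFlow",
    "GgcProfile",
    "read_recovery_ratio",
    "increment_factor",
    "partition_isg_reads",
    "ggc_profile",
    "amplicon_gc_table",
]


@dataclass(frozen=True)
class ReadFlow:
    """Ordered read counts through a processing pipeline (read-in .. read-out)."""

    stage_counts: tuple[tuple[str, int], ...]
    dataset_kind: str = "paired-end"  # or "single-end-forward"
    primer_set: str = ""
    category: str = "all"  # ISG | biological | all

    def __post_init__(self) -> None:
        if len(self.stage_counts) < 2:
            raise ValueError("a read flow needs at least read-in and read-out")
        counts = [c for _, c in self.stage_counts]
        if any(c < 0 for c in counts):
            raise ValueError("read counts must be >= 0")
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("read counts cannot increase through the pipeline")

    @property
    def read_in(self) -> int:
        return self.stage_counts[0][1]

    @property
    def read_out(self) -> int:
        return self.stage_counts[-1][1]


def read_recovery_ratio(flow: ReadFlow) -> float:
    """read-out / read-in of a pipeline, in [0, 1]."""
    if flow.read_in == 0:
        raise ValueError("read-in is zero; recovery ratio undefined")
    return flow.read_out / flow.read_in


def increment_factor(se_ratio: float, pe_ratio: float) -> float:
    """Fold increase of single-end over paired-end read recovery."""
    if pe_ratio <= 0:
        raise ValueError("paired-end recovery ratio must be > 0")
    return se_ratio / pe_ratio


@dataclass(frozen=True)
class GgcProfile:
    """GGC occurrences split at the forward-read boundary."""

    total: int
    n_front: int
    n_behind: int
    boundary: int = 251

    def __post_init__(self) -> None:
        if self.total != self.n_front + self.n_behind:
            raise ValueError("total must equal n_front + n_behind")


def ggc_profile(sequence: str, boundary: int = 251) -> GgcProfile:
    """Count every (overlap-aware) GGC on the sense strand.

    Occurrences are partitioned by their 1-based start position: at or
    before ``boundary`` (covered by a forward read of that length) versus
    strictly behind it.
    """
    if boundary < 0:
        raise ValueError("boundary must be >= 0")
    seq = sequence.upper()
    starts = []
    pos = seq.find("GGC")
    while pos != -1:
        starts.append(pos + 1)
        pos = seq.find("GGC", pos + 1)
    n_front = sum(1 for s in starts if s <= boundary)
    return GgcProfile(
        total=len(starts), n_front=n_front, n_behind=len(starts) - n_front,
        boundary=boundary,
    )


def partition_isg_reads(
    asv_rows: pd.DataFrame,
    isg_references: Mapping[str, str] | Sequence[tuple[str, str]],
    read_length: int | None = None,
    max_mismatch_discard: int = 2,
) -> pd.DataFrame:
    """Label each ASV as standard-derived, discard, or biological.

    References are truncated to ``read_length`` (single-end data compares
    only the sequenced prefix).  An ASV whose sequence equals a truncated
    reference is ``ISG``; one within ``max_mismatch_discard`` substitutions
    of a reference (same length) is ``discard`` — the manual mismatch
    removal applied to standard-derived error reads; everything else is
    ``biological``.  Returns a copy with a ``label`` column.
    """
    refs = dict(isg_references)
    if not refs:
        raise ValueError("at least one reference sequence is required")
    if asv_rows["asv_id"].duplicated().any():
        dup = asv_rows.loc[asv_rows["asv_id"].duplicated(), "asv_id"].iloc[0]
        raise ValueError(f"duplicate ASV id {dup!r}")
    trunc = {
        name: (seq.upper()[:read_length] if read_length else seq.upper())
        for name, seq in refs.items()
    }

    def _label(asv_seq: str) -> tuple[str, str]:
        s = asv_seq.upper()
        if read_length:
            s = s[:read_length]
        best_name, best_d = "", None
        for name, ref in trunc.items():
            if len(ref) != len(s):
                continue
            d = sum(a != b for a, b in zip(s, ref))
            if best_d is None or d < best_d:
                best_name, best_d = name, d
        if best_d is None:
            return "biological", ""
        if best_d == 0:
            return "ISG", best_name
        if best_d <= max_mismatch_discard:
            return "discard", best_name
        return "biological", ""

    out = asv_rows.copy()
    labels = out["sequence"].map(lambda s: _label(str(s)))
    out["label"] = labels.map(lambda t: t[0])
    out["variant_id"] = labels.map(lambda t: t[1])
    return out


def amplicon_gc_table(
    templates: Mapping[str, str] | Sequence[tuple[str, str]],
    primer_sets: Sequence[PrimerSet],
    mismatch_tolerance: int = 2,
) -> pd.DataFrame:
    """In-silico PCR each template with each primer pair and report GC.

    One row per (template, primer set); templates without a product get an
    empty length/GC.  GC is reported in percent.
    """
    templates = dict(templates)
    if not templates:
        raise ValueError("at least one template is required")
    rows = []
    for tname, tseq in templates.items():
        for ps in primer_sets:
            products = insilico_pcr(tseq, ps.forward, ps.reverse, mismatch_tolerance)
            if not products:
                rows.append(
                    {"template": tname, "primer_set": ps.name,
                     "amplicon_length": np.nan, "gc_percent": np.nan}
                )
            for amp in products:
                rows.append(
                    {
                        "template": tname,
                        "primer_set": ps.name,
                        "amplicon_length": amp.length,
                        "gc_percent": 100.0 * gc_content(amp.sequence),
                    }
                )
    return pd.DataFrame(rows, columns=["template", "primer_set", "amplicon_length", "gc_percent"])
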