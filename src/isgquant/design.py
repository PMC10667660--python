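"""Design of synthetic internal-standard genes (ISGs).

An ISG is a synthetic DNA molecule that embeds the binding sites of several
amplicon-sequencing primer pairs at positions chosen so that each pair
amplifies a product of a prescribed length.  The space between the primer
sites is filled with GC-balanced spacer sequence that is screened against
unintended primer binding, so that every primer pair yields exactly one
product on the molecule.  Several sequence variants sharing one layout but
differing in their spacers can be generated, allowing each variant to be
spiked at a different known copy number (a concentration gradient read out
as distinguishable amplicon sequence variants).

This module provides the layout solver, the spacer generator, IUPAC-aware
primer scanning (both strands, with mismatches) and in-silico PCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IUPAC_CODES",
    "PrimerSet",
    "LayoutSite",
    "DesignConstraints",
    "IsgDesign",
    "PrimerHit",
    "Amplicon",
    "DesignError",
    "LayoutError",
    "reverse_complement",
    "concretize_primer",
    "gc_content",
    "primer_mismatch_profile",
    "screen_primer_matches",
    "insilico_pcr",
    "build_layout",
    "generate_spacers",
    "design_isgs",
]

# --------------------------------------------------------------------------
# IUPAC alphabet
# --------------------------------------------------------------------------

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# bitmask encoding: A=1, C=2, G=4, T=8; a degenerate code is the OR of its
# class members.  Two codes are compatible iff their masks intersect.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_BITS = {
    code: int(np.bitwise_or.reduce([_BASE_BIT[b] for b in bases]))
    for code, bases in IUPAC_CODES.items()
}


class DesignError(ValueError):
    """Raised when a design constraint cannot be satisfied."""


class LayoutError(DesignError):
    """Raised when no primer-site layout satisfies the constraints."""


def _validate_alphabet(seq: str, *, what: str = "sequence") -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid character {ch!r} at position {i + 1} in {what}")
    return seq


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    seq = _validate_alphabet(seq)
    return "".join(_COMPLEMENT[ch] for ch in reversed(seq))


def gc_content(sequence: str) -> float:
    """Fraction of G+C bases; requires a non-empty concrete sequence."""
    if not sequence:
        raise ValueError("gc_content of empty sequence is undefined")
    seq = sequence.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"gc_content requires concrete bases, found {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def concretize_primer(primer: str, policy: str = "first-of-class") -> str:
    """Replace degenerate IUPAC codes by concrete bases.

    ``first-of-class`` picks the alphabetically first base of each code's
    class (A < C < G < T), e.g. N -> A, W -> A, S -> C.  Idempotent on
    concrete input.
    """
    if policy != "first-of-class":
        raise ValueError(f"unknown concretization policy {policy!r}")
    seq = _validate_alphabet(primer, what="primer")
    return "".join(min(IUPAC_CODES[ch]) for ch in seq)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerSet:
    """A named degenerate primer pair with its expected product length."""

    name: str
    forward: str
    reverse: str
    target_gene: str
    expected_amplicon_len: int
    forward_name: str = ""
    reverse_name: str = ""

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primer sequences must be non-empty")
        object.__setattr__(self, "forward", _validate_alphabet(self.forward, what="forward primer"))
        object.__setattr__(self, "reverse", _validate_alphabet(self.reverse, what="reverse primer"))
        if self.expected_amplicon_len < len(self.forward) + len(self.reverse):
            raise ValueError(
                f"{self.name}: expected amplicon length {self.expected_amplicon_len} "
                f"shorter than the two primers combined"
            )
        if not self.forward_name:
            object.__setattr__(self, "forward_name", f"{self.name}-F")
        if not self.reverse_name:
            object.__setattr__(self, "reverse_name", f"{self.name}-R")


@dataclass(frozen=True)
class LayoutSite:
    """Occupancy of one primer on the ISG plus strand (1-based, inclusive).

    Reverse-orientation sites store the interval occupied by the reverse
    complement of the primer on the plus strand.
    """

    primer_name: str
    orientation: str  # "forward" | "reverse"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid site interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable constraints of the ISG designer."""

    total_length: int = 615
    gc_target: float = 0.50
    gc_tolerance: float = 0.03
    min_gap: int = 1
    n_variants: int = 4
    mismatch_tolerance: int = 2

    def __post_init__(self) -> None:
        if self.total_length < 1:
            raise ValueError("total_length must be positive")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if self.gc_tolerance < 0:
            raise ValueError("gc_tolerance must be >= 0")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.mismatch_tolerance < 0:
            raise ValueError("mismatch_tolerance must be >= 0")


@dataclass(frozen=True)
class IsgDesign:
    """One synthetic internal-standard sequence with its site layout."""

    variant_id: str
    sequence: str
    total_length: int
    sites: tuple[LayoutSite, ...]
    gc_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if self.total_length != len(self.sequence):
            raise ValueError("total_length must equal len(sequence)")


@dataclass(frozen=True)
class PrimerHit:
    primer_name: str
    strand: str  # "+" | "-"
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int
    length: int
    sequence: str


# --------------------------------------------------------------------------
# IUPAC-aware scanning
# --------------------------------------------------------------------------


def _encode_bits(seq: str) -> np.ndarray:
    return np.array([_CODE_BITS[ch] for ch in seq], dtype=np.uint8)


def primer_mismatch_profile(sequence: str, primer: str) -> np.ndarray:
    """Mismatch count of ``primer`` at every plus-strand offset.

    Position ``i`` of the result is the number of primer positions whose
    IUPAC class does not intersect the template's class in the window
    starting at 0-based offset ``i``.  Empty array when the template is
    shorter than the primer.
    """
    sequence = _validate_alphabet(sequence)
    primer = _validate_alphabet(primer, what="primer")
    n, m = len(sequence), len(primer)
    if n < m:
        return np.zeros(0, dtype=np.int64)
    t = _encode_bits(sequence)
    p = _encode_bits(primer)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    match = (windows & p[None, :]) != 0
    return (m - match.sum(axis=1)).astype(np.int64)


def _scan_hits(sequence: str, primer: str, name: str, tol: int) -> list[PrimerHit]:
    hits: list[PrimerHit] = []
    m = len(primer)
    for strand, probe in (("+", primer), ("-", reverse_complement(primer))):
        prof = primer_mismatch_profile(sequence, probe)
        for off in np.flatnonzero(prof <= tol):
            hits.append(
                PrimerHit(name, strand, int(off) + 1, int(off) + m, int(prof[off]))
            )
    return hits


def _distinct_primers(primers: Iterable[PrimerSet]) -> list[tuple[str, str]]:
    """(name, sequence) for every distinct primer in a list of pairs."""
    seen: dict[str, str] = {}
    for ps in primers:
        for nm, seq in ((ps.forward_name, ps.forward), (ps.reverse_name, ps.reverse)):
            if nm in seen and seen[nm] != seq:
                raise ValueError(f"primer name {nm!r} reused with a different sequence")
            seen.setdefault(nm, seq)
    return list(seen.items())


def screen_primer_matches(
    sequence: str,
    primers: Sequence[PrimerSet],
    allowed_sites: Sequence[LayoutSite] = (),
    mismatch_tolerance: int = 2,
) -> list[PrimerHit]:
    """Find primer hits outside the declared sites.

    Both strands are scanned at every offset for every distinct primer;
    degenerate codes match any base of their class.  A hit whose interval
    lies within an allowed site's interval is whitelisted.  An empty result
    means the sequence passes screening.
    """
    if mismatch_tolerance < 0:
        raise ValueError("mismatch_tolerance must be >= 0")
    allowed = [(s.start, s.end) for s in allowed_sites]
    violations: list[PrimerHit] = []
    for name, probe in _distinct_primers(primers):
        for hit in _scan_hits(sequence, probe, name, mismatch_tolerance):
            if any(hit.start >= a and hit.end <= b for a, b in allowed):
                continue
            violations.append(hit)
    return violations


def insilico_pcr(
    template: str,
    forward: str,
    reverse: str,
    mismatch_tolerance: int = 0,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    The forward primer is matched on the plus strand and the reverse primer
    on the minus strand (i.e. its reverse complement on the plus strand).
    Every combination of a forward site strictly upstream of a reverse site
    yields a product; the reported length includes both primer sites, with
    1-based inclusive coordinates.
    """
    template = _validate_alphabet(template, what="template")
    forward = _validate_alphabet(forward, what="forward primer")
    reverse = _validate_alphabet(reverse, what="reverse primer")
    if len(template) < len(forward) + len(reverse):
        raise ValueError("template shorter than the two primers combined")
    f_prof = primer_mismatch_profile(template, forward)
    r_prof = primer_mismatch_profile(template, reverse_complement(reverse))
    f_starts = [int(i) + 1 for i in np.flatnonzero(f_prof <= mismatch_tolerance)]
    r_starts = [int(i) + 1 for i in np.flatnonzero(r_prof <= mismatch_tolerance)]
    products: list[Amplicon] = []
    for fs in f_starts:
        f_end = fs + len(forward) - 1
        for rs in r_starts:
            r_end = rs + len(reverse) - 1
            if f_end < rs:  # non-overlapping, forward upstream of reverse
                products.append(
                    Amplicon(fs, r_end, r_end - fs + 1, template[fs - 1 : r_end])
                )
    products.sort(key=lambda a: (a.start, a.end))
    return products


# --------------------------------------------------------------------------
# Layout solver
# --------------------------------------------------------------------------


def _site_table(primer_sets: Sequence[PrimerSet]):
    """Distinct sites (name, orientation, length) and per-pair constraints."""
    sites: dict[tuple[str, str], int] = {}
    order: list[tuple[str, str]] = []
    pair_constraints: list[tuple[tuple[str, str], tuple[str, str], int, str]] = []
    _distinct_primers(primer_sets)  # raises on name reuse with different sequence
    for ps in primer_sets:
        fkey = (ps.forward_name, "forward")
        rkey = (ps.reverse_name, "reverse")
        for key, length in ((fkey, len(ps.forward)), (rkey, len(ps.reverse))):
            if key not in sites:
                sites[key] = length
                order.append(key)
        pair_constraints.append((fkey, rkey, ps.expected_amplicon_len, ps.name))
    return sites, order, pair_constraints


def build_layout(
    primer_sets: Sequence[PrimerSet],
    constraints: DesignConstraints,
    max_nodes: int = 2_000_000,
) -> list[LayoutSite]:
    """Place every distinct primer site so all product lengths are realized.

    Deterministic depth-first search assigning sites in input order at the
    smallest feasible coordinate, propagating the amplicon-length equalities
    (a shared reverse primer such as 805R couples two pairs) and the
    pairwise-gap requirement.  Raises :class:`LayoutError` naming the
    violated constraint when no placement exists.
    """
    if not primer_sets:
        raise LayoutError("no primer sets given")
    sites, order, pairs = _site_table(primer_sets)
    total = constraints.total_length
    gap = constraints.min_gap

    for fkey, rkey, amp, name in pairs:
        if amp > total:
            raise LayoutError(
                f"pair {name}: amplicon length {amp} exceeds total length {total}"
            )
        if amp < sites[fkey] + sites[rkey] + gap:
            raise LayoutError(
                f"pair {name}: amplicon length {amp} cannot contain both primers "
                f"plus the minimum gap {gap}"
            )
    need = sum(sites.values()) + gap * (len(sites) - 1)
    if need > total:
        raise LayoutError(
            f"sites need {need} bp (lengths plus gaps) but total length is {total}"
        )

    nodes = 0

    def intervals_ok(pos: dict) -> bool:
        ivs = sorted((s, s + sites[k] - 1) for k, s in pos.items())
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1 + gap:
                return False
        return True

    def propagate(pos: dict) -> dict | None:
        pos = dict(pos)
        changed = True
        while changed:
            changed = False
            for fkey, rkey, amp, name in pairs:
                f_in, r_in = fkey in pos, rkey in pos
                if f_in and r_in:
                    if pos[rkey] + sites[rkey] - 1 - pos[fkey] + 1 != amp:
                        return None
                elif f_in:
                    r_end = pos[fkey] + amp - 1
                    r_start = r_end - sites[rkey] + 1
                    if r_start < 1 or r_end > total:
                        return None
                    pos[rkey] = r_start
                    changed = True
                elif r_in:
                    f_start = pos[rkey] + sites[rkey] - 1 - amp + 1
                    if f_start < 1:
                        return None
                    pos[fkey] = f_start
                    changed = True
        if not intervals_ok(pos):
            return None
        return pos

    def search(pos: dict) -> dict | None:
        nonlocal nodes
        unassigned = [k for k in order if k not in pos]
        if not unassigned:
            return pos
        key = unassigned[0]
        for start in range(1, total - sites[key] + 2):
            nodes += 1
            if nodes > max_nodes:
                raise LayoutError(
                    f"layout search exceeded {max_nodes} nodes; constraints likely infeasible"
                )
            nxt = propagate({**pos, key: start})
            if nxt is None:
                continue
            sol = search(nxt)
            if sol is not None:
                return sol
        return None

    solution = search({})
    if solution is None:
        raise LayoutError(
            "no placement satisfies the amplicon-length and gap constraints "
            f"(total_length={total}, min_gap={gap})"
        )
    return [
        LayoutSite(name, orient, solution[(name, orient)],
                   solution[(name, orient)] + sites[(name, orient)] - 1)
        for name, orient in order
    ]


def check_layout(
    layout: Sequence[LayoutSite],
    primer_sets: Sequence[PrimerSet],
    constraints: DesignConstraints,
) -> None:
    """Verify a layout against all constraints; raises on violation."""
    by_key = {(s.primer_name, s.orientation): s for s in layout}
    for ps in primer_sets:
        f = by_key[(ps.forward_name, "forward")]
        r = by_key[(ps.reverse_name, "reverse")]
        span = r.end - f.start + 1
        if span != ps.expected_amplicon_len:
            raise LayoutError(f"pair {ps.name}: span {span} != {ps.expected_amplicon_len}")
        if f.length != len(ps.forward) or r.length != len(ps.reverse):
            raise LayoutError(f"pair {ps.name}: site length mismatch")
    ivs = sorted((s.start, s.end) for s in layout)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1 + constraints.min_gap:
            raise LayoutError(f"sites [{s1},{e1}] and [{s2},{e2}] violate the gap")
    for s in layout:
        if s.start < 1 or s.end > constraints.total_length:
            raise LayoutError(f"site {s.primer_name} outside [1, {constraints.total_length}]")


# --------------------------------------------------------------------------
# Spacer generation
# --------------------------------------------------------------------------


def _site_contents(layout: Sequence[LayoutSite], primer_sets: Sequence[PrimerSet]) -> dict:
    """Concrete plus-strand content of every site (degenerate codes fixed)."""
    seqs = dict(_distinct_primers(primer_sets))
    contents = {}
    for site in layout:
        primer = seqs[site.primer_name]
        concrete = concretize_primer(primer)
        if site.orientation == "reverse":
            concrete = reverse_complement(concrete)
        if len(concrete) != site.length:
            raise DesignError(f"site {site.primer_name} length != primer length")
        contents[site] = concrete
    return contents


def generate_spacers(
    layout: Sequence[LayoutSite],
    constraints: DesignConstraints,
    primers: Sequence[PrimerSet],
    seed: int,
    max_retries: int = 50,
) -> list[IsgDesign]:
    """Fill the gaps between primer sites with screened, GC-balanced spacers.

    Returns ``n_variants`` designs sharing the layout and differing only in
    spacer bases.  The number of G/C bases placed in the spacers is chosen
    so the whole molecule lands on ``gc_target`` (within rounding); a
    variant is redrawn (bounded retries) if any primer matches the spacer
    region within ``mismatch_tolerance`` mismatches on either strand.
    Byte-identical output for identical inputs and seed.
    """
    total = constraints.total_length
    template: list[str | None] = [None] * total
    for site, content in _site_contents(layout, primers).items():
        if site.end > total:
            raise DesignError(f"site {site.primer_name} extends past total_length")
        for i, ch in enumerate(content, start=site.start - 1):
            if template[i] is not None:
                raise DesignError("overlapping sites in layout")
            template[i] = ch

    gap_idx = [i for i, ch in enumerate(template) if ch is None]
    fixed_gc = sum(1 for ch in template if ch in ("G", "C"))
    n_gc = round(constraints.gc_target * total) - fixed_gc
    n_gc = min(max(n_gc, 0), len(gap_idx))
    overall_gc = (fixed_gc + n_gc) / total
    if abs(overall_gc - constraints.gc_target) > constraints.gc_tolerance:
        raise DesignError(
            f"achievable GC {overall_gc:.3f} outside "
            f"{constraints.gc_target} +/- {constraints.gc_tolerance} "
            "(primer sites alone force it out of band)"
        )

    children = np.random.SeedSequence(seed).spawn(constraints.n_variants)
    designs: list[IsgDesign] = []
    seen: set[str] = set()
    for v, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        for attempt in range(max_retries):
            filled = list(template)
            perm = rng.permutation(len(gap_idx))
            gc_positions = set(perm[:n_gc].tolist())
            picks = rng.integers(0, 2, size=len(gap_idx))
            for j, gi in enumerate(gap_idx):
                pool = "GC" if j in gc_positions else "AT"
                filled[gi] = pool[picks[j]]
            seq = "".join(filled)  # type: ignore[arg-type]
            if seq in seen:
                continue
            if screen_primer_matches(seq, primers, layout, constraints.mismatch_tolerance):
                continue
            seen.add(seq)
            designs.append(
                IsgDesign(
                    variant_id=f"ISG{v:02d}",
                    sequence=seq,
                    total_length=total,
                    sites=tuple(layout),
                    gc_fraction=gc_content(seq),
                    seed=seed,
                )
            )
            break
        else:
            raise DesignError(
                f"variant {v}: no spacer passed screening after {max_retries} retries"
            )
    return designs


def design_isgs(
    primer_sets: Sequence[PrimerSet],
    constraints: DesignConstraints | None = None,
    seed: int = 0,
) -> list[IsgDesign]:
    """Convenience wrapper: solve the layout, then generate spacer variants."""
    constraints = constraints or DesignConstraints()
    layout = build_layout(primer_sets, constraints)
    return generate_spacers(layout, constraints, primer_sets, seed)
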