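"""Internal-standard calibration: read counts to absolute gene copies.

The dose-response of spiked internal-standard genes (ISGs) is modelled as a
negative-binomial GLM with natural-log link and the slope fixed at 1:

    ln E[Y_i] = x_i + b,      Var(Y_i) = mu_i + mu_i**2 / theta,

where ``Y_i`` is the read count of standard observation ``i``, ``x_i`` the
natural log of its known concentration in the PCR reaction (copies per uL
reaction) entering as an offset, ``b`` the intercept and ``theta`` the NB
size (dispersion) parameter.  ``exp(b)`` is the detection efficiency in
reads per copy, and a biological read count ``y`` converts to a reaction
concentration ``z = y / exp(b)``.

Reaction concentrations chain back to per-uL-DNA and per-sample
concentrations through the volumetric conversion factors of the protocol
(dilution D/E, sample fraction F/G of the sample+standard template mix,
template fraction H/I of the PCR reaction, and the DNA-extraction to
sample-amount ratio C/A).

Both the intercept and the dispersion are estimated by alternating profile
maximum likelihood; a free-slope companion model supplies the Wald test of
the dose coefficient as a calibration diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "AVOGADRO",
    "ConversionFactors",
    "SampleFactors",
    "SpikeInSeries",
    "CalibrationPoint",
    "CalibrationCurve",
    "CalibrationError",
    "mass_to_copies",
    "build_spikein_series",
    "expected_reaction_conc",
    "isg_reaction_conc",
    "reaction_to_dna_conc",
    "dna_to_sample_conc",
    "detection_efficiency",
    "nb_loglik",
    "poisson_intercept",
    "fit_internal_standard_curve",
    "reads_to_reaction_conc",
    "loq_threshold",
    "quantify_asvs",
]

AVOGADRO = 6.02e23  # mol^-1, at the precision used in the unit conversion
_MEAN_BP_WEIGHT = 660.0  # g mol^-1 bp^-1 for double-stranded DNA


class CalibrationError(RuntimeError):
    """Raised when the standard curve cannot be fitted."""


# --------------------------------------------------------------------------
# Unit conversions
# --------------------------------------------------------------------------


def mass_to_copies(mass_conc: float, dna_length: int) -> float:
    """Convert a dsDNA mass concentration (ng/uL) to copies/uL.

    C = M * 6.02e23 / (660 * 1e9 * L) for a molecule of L base pairs.
    """
    if dna_length <= 0:
        raise ValueError("dna_length must be positive")
    if mass_conc < 0:
        raise ValueError("mass_conc must be >= 0")
    return mass_conc * AVOGADRO / (_MEAN_BP_WEIGHT * 1e9 * dna_length)


@dataclass(frozen=True)
class ConversionFactors:
    """Volumetric factors of the dilution/mixing/PCR chain (all uL).

    D: sample volume taken into dilution; E: total diluted volume;
    F: diluted sample volume in the sample+standard template mix;
    G: total template-mix volume; H: template volume put into the PCR;
    I: PCR reaction volume.
    """

    D: float = 1.0
    E: float = 1.0
    F: float = 3.0
    G: float = 4.0
    H: float = 2.5
    I: float = 50.0

    def __post_init__(self) -> None:
        for name in "DEFGHI":
            if getattr(self, name) <= 0:
                raise ValueError(f"conversion factor {name} must be > 0")
        if self.F > self.G:
            raise ValueError("F (sample volume) cannot exceed G (mix volume)")
        if self.H > self.I:
            raise ValueError("H (template volume) cannot exceed I (reaction volume)")
        if self.D > self.E:
            raise ValueError("D (sample volume) cannot exceed E (diluted volume)")

    @property
    def sample_fraction(self) -> float:
        """F/G: volume fraction of sample in the template mix."""
        return self.F / self.G

    @property
    def isg_fraction(self) -> float:
        """(G - F)/G: volume fraction of the standard mix in the template."""
        return (self.G - self.F) / self.G


@dataclass(frozen=True)
class SampleFactors:
    """DNA-extraction volume (uL) and sample amount with its unit."""

    c_extraction_vol: float
    a_sample_amount: float
    unit: str = "g"  # "g" or "L"

    def __post_init__(self) -> None:
        if self.c_extraction_vol <= 0 or self.a_sample_amount <= 0:
            raise ValueError("extraction volume and sample amount must be > 0")
        if self.unit not in ("g", "L"):
            raise ValueError("unit must be 'g' or 'L'")


@dataclass(frozen=True)
class SpikeInSeries:
    """Known per-variant concentrations in the mixed gradient standard."""

    per_variant_conc: Mapping[str, float]
    mix_fraction_sample: float = 0.75

    def __post_init__(self) -> None:
        if not self.per_variant_conc:
            raise ValueError("spike-in series needs at least one variant")
        if any(c <= 0 for c in self.per_variant_conc.values()):
            raise ValueError("spike-in concentrations must be > 0")
        if not 0.0 <= self.mix_fraction_sample < 1.0:
            raise ValueError("mix_fraction_sample must be in [0, 1)")

    @property
    def total_conc(self) -> float:
        """Total standard concentration after mixing (copies/uL)."""
        return float(sum(self.per_variant_conc.values()))


def build_spikein_series(
    level_concs: Sequence[float] | None = None,
    *,
    stock_conc: float | None = None,
    dilution_factors: Sequence[float] | None = None,
    variant_ids: Sequence[str] | None = None,
    mix_fraction_sample: float = 0.75,
) -> SpikeInSeries:
    """Build the mixed gradient standard from per-variant dilution levels.

    Either pass the pre-mix level concentrations directly, or a stock
    concentration plus dilution factors (level = stock / factor).  Mixing
    ``n`` solutions at equal volumes leaves each variant at level/n, so the
    total is sum(levels)/n.
    """
    if level_concs is None:
        if stock_conc is None or dilution_factors is None:
            raise ValueError("give level_concs, or stock_conc with dilution_factors")
        if stock_conc <= 0:
            raise ValueError("stock_conc must be > 0")
        if len(dilution_factors) == 0:
            raise ValueError("dilution_factors must be non-empty")
        if any(f <= 0 for f in dilution_factors):
            raise ValueError("dilution factors must be > 0")
        level_concs = [stock_conc / f for f in dilution_factors]
    level_concs = list(level_concs)
    if not level_concs:
        raise ValueError("at least one dilution level is required")
    n = len(level_concs)
    if variant_ids is None:
        variant_ids = [f"ISG{i + 1:02d}" for i in range(n)]
    if len(variant_ids) != n:
        raise ValueError("one variant id per dilution level is required")
    per_variant = {v: c / n for v, c in zip(variant_ids, level_concs)}
    return SpikeInSeries(per_variant, mix_fraction_sample=mix_fraction_sample)


def expected_reaction_conc(
    conc: float,
    factors: ConversionFactors,
    include_sample_mix: bool = True,
) -> float:
    """Concentration in the PCR reaction of a sample-borne gene.

    Z = Y * D/E * (F/G if the sample+standard mixing step applies) * H/I.
    With ``include_sample_mix=False`` this is the qPCR chain (no standard
    added to the template).
    """
    z = conc * (factors.D / factors.E) * (factors.H / factors.I)
    if include_sample_mix:
        z *= factors.sample_fraction
    return z


def isg_reaction_conc(conc: float, factors: ConversionFactors) -> float:
    """Reaction concentration of the spiked standard.

    The standard mix enters the template at the complementary volume
    fraction (G-F)/G and is not subject to the sample dilution D/E.
    """
    return conc * factors.isg_fraction * (factors.H / factors.I)


def reaction_to_dna_conc(
    z: float,
    factors: ConversionFactors,
    include_sample_mix: bool = True,
) -> float:
    """Exact inverse of :func:`expected_reaction_conc` (copies/uL DNA)."""
    y = z * (factors.E / factors.D) * (factors.I / factors.H)
    if include_sample_mix:
        y /= factors.sample_fraction
    return y


def dna_to_sample_conc(y: float, sample: SampleFactors) -> float:
    """Copies per uL DNA extract to copies per g or L of sample (X = Y*C/A)."""
    return y * sample.c_extraction_vol / sample.a_sample_amount


def detection_efficiency(reads: float, copies: float) -> float:
    """Reads obtained per standard copy in the reaction (reads/copy)."""
    if copies <= 0:
        raise ValueError("copies must be > 0")
    return reads / copies


# --------------------------------------------------------------------------
# Negative-binomial fixed-slope fit
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationPoint:
    """One standard observation: ln reaction concentration and its reads."""

    x_ln_conc: float
    reads: int
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.reads < 0:
            raise ValueError("reads must be >= 0")
        if not math.isfinite(self.x_ln_conc):
            raise ValueError("x_ln_conc must be finite")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted fixed-slope NB dose-response curve."""

    intercept_b: float
    dispersion: float  # NB size parameter theta
    intercept_se: float
    wald_p_free_slope: float
    n_points: int
    converged: bool
    loglik: float = float("nan")
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_points < 2:
            raise ValueError("a curve needs at least 2 points")

    @property
    def detection_efficiency(self) -> float:
        """exp(b): reads per copy per uL reaction."""
        return math.exp(self.intercept_b)


_THETA_LOG_BOUNDS = (-7.0, 16.0)  # theta in [~1e-3, ~8.9e6]
_POISSON_THETA = math.exp(_THETA_LOG_BOUNDS[1])


def nb_loglik(b: float, theta: float, x: np.ndarray, y: np.ndarray) -> float:
    """NB(mean exp(x+b), size theta) log-likelihood of counts y."""
    mu = np.exp(x + b)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * (np.log(theta) - np.log(theta + mu))
            + y * (np.log(mu) - np.log(theta + mu))
        )
    )


def poisson_intercept(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form fixed-slope Poisson MLE: b = ln(sum y / sum e^x)."""
    return float(np.log(np.sum(y) / np.sum(np.exp(x))))


def _profile_intercept(theta: float, x: np.ndarray, y: np.ndarray, b0: float) -> float:
    """Maximize the NB log-likelihood over b at fixed theta (Newton)."""
    b = b0
    for _ in range(100):
        mu = np.exp(x + b)
        score = theta * np.sum((y - mu) / (theta + mu))
        info = theta * np.sum(mu * (theta + y) / (theta + mu) ** 2)
        if info <= 0:
            break
        step = score / info
        b += step
        if abs(step) < 1e-12:
            break
    return b


def _moment_theta(x: np.ndarray, y: np.ndarray, b: float) -> float:
    mu = np.exp(x + b)
    denom = float(np.sum(mu**2))
    excess = float(np.sum((y - mu) ** 2 - mu))
    if denom <= 0 or excess <= 0:
        return _POISSON_THETA
    return float(np.clip(denom / excess, math.exp(_THETA_LOG_BOUNDS[0]), _POISSON_THETA))


def _theta_step(b: float, lt_current: float, x: np.ndarray, y: np.ndarray) -> float:
    """Maximize the log-likelihood over log-theta at fixed intercept.

    The bounded Brent optimum is compared against the interval endpoints and
    the current value so the step is monotone and stable when the optimum
    sits on the Poisson boundary.
    """
    res = optimize.minimize_scalar(
        lambda lt: -nb_loglik(b, math.exp(lt), x, y),
        bounds=_THETA_LOG_BOUNDS,
        method="bounded",
        options={"xatol": 1e-10},
    )
    candidates = [float(res.x), lt_current, *_THETA_LOG_BOUNDS]
    return max(candidates, key=lambda lt: nb_loglik(b, math.exp(lt), x, y))


def _wald_p_free_slope(x: np.ndarray, y: np.ndarray, theta_hint: float) -> float:
    """Wald p-value of the dose coefficient in a free-slope NB companion fit."""
    import statsmodels.api as sm
    from statsmodels.discrete.discrete_model import NegativeBinomial

    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = NegativeBinomial(y, exog).fit(disp=0, maxiter=200)
            p = float(res.pvalues[1])
            if math.isfinite(p):
                return p
        except Exception:
            pass
        try:
            res = sm.GLM(
                y, exog, family=sm.families.NegativeBinomial(alpha=1.0 / theta_hint)
            ).fit()
            return float(res.pvalues[1])
        except Exception:
            return float("nan")


def fit_internal_standard_curve(
    points: Iterable[CalibrationPoint],
    fix_slope_at_one: bool = True,
    compute_wald: bool = True,
    tol: float = 1e-8,
    max_outer: int = 100,
) -> CalibrationCurve:
    """Fit the NB dose-response curve of the internal standards.

    Alternating profile maximum likelihood: the intercept is updated by
    Fisher scoring at the current dispersion, then the dispersion by
    bounded 1-D maximization at the current intercept, until the
    log-likelihood changes by less than ``tol``.  The moment estimate of
    the dispersion initializes the search and the closed-form Poisson
    intercept initializes b; when no overdispersion is detected the fit
    falls back to the Poisson limit (dispersion at its upper bound).

    ``fix_slope_at_one=False`` reports the free-slope companion model's
    intercept and slope instead (the Wald p-value is always taken from the
    companion model).
    """
    pts = list(points)
    if len(pts) < 2:
        raise CalibrationError("at least 2 calibration points are required")
    x = np.array([p.x_ln_conc for p in pts], dtype=float)
    y = np.array([p.reads for p in pts], dtype=float)
    if np.unique(x).size < 2:
        raise CalibrationError("calibration points must span >= 2 distinct doses")
    if not np.any(y > 0):
        raise CalibrationError("all calibration read counts are zero")

    b = poisson_intercept(x, y)
    # initialize from the best of the moment estimate and a coarse profiled
    # scan over log-theta; the scan keeps the alternating scheme out of the
    # coordinate-wise trap at the Poisson boundary
    lt_candidates = [math.log(_moment_theta(x, y, b))] + list(
        np.linspace(*_THETA_LOG_BOUNDS, 24)
    )
    scan = [
        (nb_loglik(_profile_intercept(math.exp(lt), x, y, b), math.exp(lt), x, y), lt)
        for lt in lt_candidates
    ]
    _, lt = max(scan)
    theta = math.exp(lt)
    ll = nb_loglik(b, theta, x, y)
    converged = False
    for _ in range(max_outer):
        b = _profile_intercept(theta, x, y, b)
        lt = _theta_step(b, lt, x, y)
        theta = math.exp(lt)
        ll_new = nb_loglik(b, theta, x, y)
        if abs(ll_new - ll) < tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    if not converged:
        raise CalibrationError(
            f"dose-response fit did not converge in {max_outer} iterations "
            f"(last b={b:.6g}, theta={theta:.6g}, loglik={ll:.6g})"
        )
    # Poisson fallback: dispersion at the search boundary means no
    # measurable overdispersion; the intercept then equals the closed form.
    if theta >= _POISSON_THETA * 0.99:
        theta = _POISSON_THETA
        b = poisson_intercept(x, y)
        ll = nb_loglik(b, theta, x, y)

    mu = np.exp(x + b)
    info = float(np.sum(theta * mu / (theta + mu)))
    se = 1.0 / math.sqrt(info) if info > 0 else float("nan")

    wald_p = float("nan")
    slope = 1.0
    intercept = b
    if compute_wald or not fix_slope_at_one:
        import statsmodels.api as sm
        from statsmodels.discrete.discrete_model import NegativeBinomial

        wald_p = _wald_p_free_slope(x, y, theta)
        if not fix_slope_at_one:
            exog = sm.add_constant(x)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = NegativeBinomial(y, exog).fit(disp=0, maxiter=200)
                    intercept, slope = float(res.params[0]), float(res.params[1])
                except Exception as exc:  # pragma: no cover - companion fit edge
                    raise CalibrationError(f"free-slope fit failed: {exc}") from exc

    return CalibrationCurve(
        intercept_b=intercept,
        dispersion=theta,
        intercept_se=se,
        wald_p_free_slope=wald_p,
        n_points=len(pts),
        converged=converged,
        loglik=ll,
        slope=slope,
    )


def reads_to_reaction_conc(reads: float, curve: CalibrationCurve) -> float:
    """Invert the standard curve: Z = (reads / e^b)^(1/slope); 0 reads -> 0."""
    if reads < 0:
        raise ValueError("reads must be >= 0")
    if reads == 0:
        return 0.0
    if curve.slope == 1.0:
        return reads / math.exp(curve.intercept_b)
    return math.exp((math.log(reads) - curve.intercept_b) / curve.slope)


def loq_threshold(isg_counts: Mapping[float, float | Sequence[float]]) -> float:
    """Read count of the lowest detected standard level.

    ``isg_counts`` maps each gradient concentration to the read count(s) of
    the variant(s) observed at that level.  A level is detected when its
    mean read count is positive; the threshold is the mean read count at
    the lowest detected concentration.  Reads strictly below the threshold
    are below the limit of quantification.
    """
    if not isg_counts:
        raise CalibrationError("no internal-standard levels provided")
    means = {}
    for conc, reads in isg_counts.items():
        arr = np.atleast_1d(np.asarray(reads, dtype=float))
        means[float(conc)] = float(arr.mean())
    detected = {c: m for c, m in means.items() if m > 0}
    if not detected:
        raise CalibrationError("no internal standard detected; quantification impossible")
    return detected[min(detected)]


# --------------------------------------------------------------------------
# Table-level quantification
# --------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("asv_id", "reads", "label")


def quantify_asvs(
    asv_table: pd.DataFrame,
    spike: SpikeInSeries,
    factors: ConversionFactors,
    sample: SampleFactors | None = None,
    fix_slope_at_one: bool = True,
    compute_wald: bool = True,
) -> tuple[pd.DataFrame, CalibrationCurve]:
    """Calibrate on the labelled standard rows and quantify every ASV.

    The table needs columns ``asv_id``, ``reads`` and ``label`` (``ISG`` /
    ``biological``; rows labelled otherwise, e.g. ``discard``, are carried
    through unconverted).  Standard rows take their known mixed-standard
    concentration from a ``spike_conc`` column when present, otherwise from
    ``spike.per_variant_conc[variant_id]``.  Zero-read standard levels are
    excluded from the fit but set the limit of quantification.

    Returns the quantified table (reaction, per-uL-DNA and, when sample
    factors are given, per-sample concentrations plus ``above_loq`` flags)
    and the fitted curve.
    """
    for col in _REQUIRED_COLUMNS:
        if col not in asv_table.columns:
            raise ValueError(f"ASV table is missing required column {col!r}")
    if asv_table["asv_id"].duplicated().any():
        dup = asv_table.loc[asv_table["asv_id"].duplicated(), "asv_id"].iloc[0]
        raise ValueError(f"duplicate ASV id {dup!r}")
    if (asv_table["reads"] < 0).any():
        raise ValueError("negative read counts in ASV table")

    table = asv_table.copy()
    isg = table[table["label"] == "ISG"]
    if isg.empty:
        raise CalibrationError("no internal-standard rows in the table")

    def _mix_conc(row: pd.Series) -> float:
        if "spike_conc" in row.index and pd.notna(row.get("spike_conc")):
            return float(row["spike_conc"])
        vid = row.get("variant_id")
        if vid not in spike.per_variant_conc:
            raise CalibrationError(
                f"standard row {row['asv_id']!r} has no spike concentration "
                f"(unknown variant {vid!r})"
            )
        return float(spike.per_variant_conc[vid])

    mix_concs = isg.apply(_mix_conc, axis=1).astype(float)
    reaction_concs = mix_concs.map(lambda c: isg_reaction_conc(c, factors))

    detected = isg["reads"] > 0
    points = [
        CalibrationPoint(
            x_ln_conc=math.log(z), reads=int(r), variant_id=str(row.get("variant_id", ""))
        )
        for (_, row), z, r, ok in zip(
            isg.iterrows(), reaction_concs, isg["reads"], detected
        )
        if ok
    ]
    curve = fit_internal_standard_curve(
        points, fix_slope_at_one=fix_slope_at_one, compute_wald=compute_wald
    )

    level_reads: dict[float, list[float]] = {}
    for conc, reads in zip(mix_concs, isg["reads"]):
        level_reads.setdefault(float(conc), []).append(float(reads))
    loq = loq_threshold(level_reads)

    convertible = table["label"].isin(["ISG", "biological"])
    z = table.loc[convertible, "reads"].map(lambda r: reads_to_reaction_conc(r, curve))
    table.loc[convertible, "conc_reaction"] = z
    table.loc[convertible, "conc_dna"] = z.map(
        lambda v: reaction_to_dna_conc(v, factors, include_sample_mix=True)
    )
    if sample is not None:
        table.loc[convertible, "conc_sample"] = table.loc[convertible, "conc_dna"].map(
            lambda v: dna_to_sample_conc(v, sample)
        )
        table["sample_unit"] = sample.unit
    table["above_loq"] = table["reads"] >= loq
    table.attrs["loq_threshold"] = loq
    return table, curve
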