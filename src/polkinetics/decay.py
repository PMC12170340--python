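"""Promoter-proximal Pol II clearance kinetics under initiation inhibition.

After blocking transcription initiation (triptolide), promoter-proximal
Pol II occupancy decays as polymerases leave the region by either productive
elongation or premature termination.  Fitting the spike-in-normalized
ChIP-nexus signal at the pause site (±20 bp) to ``p(t) = p0 * exp(-k t)``
yields the decay constant ``k`` and hence:

* half-life           ``t½ = ln2 / k``            (min)
* total turnover rate ``r  = -ln2 * p0 / t½``     (a.u./min; |r| = p0 * k)
* productive elongation fraction ``I / |r|``
* termination fraction           ``1 - I / |r|``

``I`` and ``|r|`` are each known only up to an assay proportionality
constant, so on real data the termination fraction is a *relative* measure;
only in unit-calibrated simulation is it exact.

Control (DMSO) samples represent steady state and enter the fit as t = 0
observations; triptolide samples enter at their inhibition times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress

from .annotation import GeneModel
from .errors import FitError, InputError

LN2 = math.log(2.0)

NEXUS_HALFWIDTH = 20

STATUS_OK = "ok"
STATUS_ZERO = "excluded_zero"
STATUS_INCREASE = "excluded_increase"
STATUS_FLAT = "degenerate_flat"


def extract_peak_window(
    signal, model: GeneModel, pause_offset: int, halfwidth: int = NEXUS_HALFWIDTH
) -> float:
    """Both-strand signal summed over the pause site ± ``halfwidth`` bp.

    The window is inclusive on both ends (2*halfwidth + 1 bases): the
    off-by-one matters at base resolution, and "±20 bp" is read literally.
    """
    center = model.offset_to_genomic(pause_offset)
    lo, hi = center - halfwidth, center + halfwidth + 1
    return signal.count(model.chrom, "+", lo, hi) + signal.count(model.chrom, "-", lo, hi)


def filter_decay_genes(condition_means: dict[tuple[str, float], float]) -> str:
    """Eligibility of one gene for the decay fit.

    ``condition_means`` maps (condition, inhibition time) to the
    replicate-mean windowed coverage, condition in {"DMSO", "TRP"}.
    Excluded if any condition mean is zero, or if coverage at the final
    inhibition time is not below the control mean (no observed decay).
    """
    if any(v == 0 for v in condition_means.values()):
        return STATUS_ZERO
    dmso = [v for (cond, _), v in condition_means.items() if cond == "DMSO"]
    trp_times = [tau for (cond, tau) in condition_means if cond == "TRP"]
    if not dmso or not trp_times:
        raise InputError("need both DMSO and TRP condition means")
    last = max(trp_times)
    if condition_means[("TRP", last)] >= float(np.mean(dmso)):
        return STATUS_INCREASE
    return STATUS_OK


def fit_exponential_decay(
    times: np.ndarray, values: np.ndarray
) -> tuple[float, float, float, str]:
    """Least-squares fit of ``v(t) = p0 * exp(-k t)`` with ``k >= 0``.

    Initialized from the log-linear regression of ``ln v`` on ``t`` and
    refined by untransformed nonlinear least squares (log-space fitting would
    over-weight small late counts under Poisson noise).  Returns
    ``(p0, k, rss, status)``; a flat series yields ``k = 0`` with status
    ``degenerate_flat``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 3 or np.unique(times).size < 2:
        raise FitError("need >= 3 observations spanning >= 2 distinct times")
    if np.any(values <= 0):
        raise FitError("values must be positive after filtering")

    slope, intercept = linregress(times, np.log(values))[:2]
    k0 = max(-float(slope), 0.0)
    p00 = float(np.exp(intercept))

    def resid(theta):
        return theta[0] * np.exp(-theta[1] * times) - values

    sol = least_squares(
        resid,
        x0=[p00, k0],
        bounds=([1e-300, 0.0], [np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    p0_hat, k_hat = float(sol.x[0]), float(sol.x[1])
    rss = float(np.sum(sol.fun**2))
    status = STATUS_FLAT if k_hat < 1e-10 else STATUS_OK
    if status == STATUS_FLAT:
        k_hat = 0.0
    return p0_hat, k_hat, rss, status


def half_life(k: float) -> float:
    """t½ = ln2 / k; a zero decay constant maps to the +inf sentinel."""
    if k < 0:
        raise InputError("decay constant must be non-negative")
    return math.inf if k == 0 else LN2 / k


def turnover_rate(p0: float, thalf: float) -> float:
    """Total turnover r = -ln2 * p0 / t½ (signed; |r| = p0 * k)."""
    if p0 < 0 or thalf <= 0:
        raise InputError("need p0 >= 0 and t½ > 0")
    if math.isinf(thalf):
        return 0.0
    return -LN2 * p0 / thalf


def termination_fraction(
    initiation: float, r_abs: float, clamp: bool = False
) -> tuple[float, float]:
    """(elongation fraction, termination fraction) = (I/|r|, 1 - I/|r|).

    Raw values may leave [0, 1] when I and |r| carry different assay
    constants; ``clamp=True`` restricts both to [0, 1].
    """
    if initiation < 0:
        raise InputError("I must be non-negative")
    if r_abs <= 0:
        raise InputError("termination fraction undefined for |r| = 0")
    elong = initiation / r_abs
    term = 1.0 - elong
    if clamp:
        elong = min(max(elong, 0.0), 1.0)
        term = 1.0 - elong
    return elong, term


# --------------------------------------------------------------------------
# cohort driver
# --------------------------------------------------------------------------

@dataclass
class DecayFit:
    """Per-gene clearance fit at one profiled time point."""

    gene_id: str
    time_h: int
    status: str
    p0: float = math.nan
    k: float = math.nan
    half_life_min: float = math.nan
    r_abs: float = math.nan
    initiation: float = math.nan
    elongation_fraction: float = math.nan
    termination_fraction: float = math.nan
    rss: float = math.nan
    observations: list = field(default_factory=list)


def fit_decay_table(
    windowed: pd.DataFrame,
    i_values: pd.Series,
    clamp: bool = False,
    ratio_mode: bool = False,
) -> pd.DataFrame:
    """Fit clearance kinetics for every gene at one profiled time point.

    Parameters
    ----------
    windowed:
        Long table with columns ``gene_id``, ``condition`` ("DMSO"/"TRP"),
        ``tau_min``, ``replicate``, ``value`` — spike-in normalized windowed
        coverages.
    i_values:
        Productive initiation frequency per gene (a.u.), same scale family as
        the ChIP-nexus signal in unit-calibrated data.
    ratio_mode:
        Fit triptolide/DMSO coverage ratios (R(0) = 1) instead of absolute
        coverages with DMSO at t = 0.

    Returns a per-gene frame with p0, k, t½, |r|, I, both fractions, rss and
    status.
    """
    rows = []
    for gid, grp in windowed.groupby("gene_id", sort=True):
        means = (
            grp.groupby(["condition", "tau_min"])["value"].mean().to_dict()
        )
        status = filter_decay_genes(means)
        if status != STATUS_OK:
            rows.append(DecayFit(gene_id=gid, time_h=-1, status=status))
            continue
        if ratio_mode:
            dmso_mean = float(np.mean([v for (c, _), v in means.items() if c == "DMSO"]))
            trp = grp[grp["condition"] == "TRP"]
            times = np.concatenate([[0.0], trp["tau_min"].to_numpy(float)])
            values = np.concatenate([[1.0], trp["value"].to_numpy(float) / dmso_mean])
        else:
            times = np.where(
                grp["condition"].to_numpy() == "DMSO", 0.0, grp["tau_min"].to_numpy(float)
            )
            values = grp["value"].to_numpy(float)
        keep = values > 0
        p0_hat, k_hat, rss, status = fit_exponential_decay(times[keep], values[keep])
        thalf = half_life(k_hat)
        r = turnover_rate(p0_hat, thalf)
        fit = DecayFit(
            gene_id=gid, time_h=-1, status=status, p0=p0_hat, k=k_hat,
            half_life_min=thalf, r_abs=abs(r), rss=rss,
        )
        if gid in i_values.index and not math.isinf(thalf):
            fit.initiation = float(i_values[gid])
            if fit.r_abs > 0:
                fit.elongation_fraction, fit.termination_fraction = termination_fraction(
                    fit.initiation, fit.r_abs, clamp=clamp
                )
        rows.append(fit)
    cols = [
        "gene_id", "status", "p0", "k", "half_life_min", "r_abs", "initiation",
        "elongation_fraction", "termination_fraction", "rss",
    ]
    return pd.DataFrame([{c: getattr(f, c) for c in cols} for f in rows]).set_index(
        "gene_id", drop=False
    )
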