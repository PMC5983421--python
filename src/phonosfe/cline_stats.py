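"""Diversity statistic, distance binning, and cline regressions.

The diversity of a set of languages is measured by the evenness statistic

    t_F = 1 / sum_i p_i^2 - 1

where p_i is the relative frequency of phoneme i over the set (occurrences
of phoneme i across languages divided by total phoneme occurrences).  t_F is
0 when a single phoneme carries all the frequency and n-1 when n phonemes
are equally frequent (it is the inverse Simpson concentration minus one).

Clines are summarized by ordinary least-squares fits of a linguistic
quantity (phoneme count per language, or t_F per distance bin) against
distance from the dispersal origin, with t-based 95% confidence intervals
for single fits and mean +- 2 sigma across an ensemble of simulation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import SimConfig, SimulationResult, expand_rows, run

__all__ = [
    "FrequencyVector",
    "ClineFit",
    "EnsembleSummary",
    "phoneme_frequencies",
    "t_f",
    "bin_by_distance",
    "binned_tf",
    "fit_cline",
    "count_cline_from_run",
    "tf_cline_from_run",
    "ensemble_slopes",
]

#: vector of relative phoneme frequencies (sums to 1)
FrequencyVector = np.ndarray


@dataclass(frozen=True)
class ClineFit:
    """OLS fit of a linguistic quantity against distance (km)."""

    slope: float            # per km
    intercept: float
    ci_low: float           # 95% CI bounds for the slope
    ci_high: float
    r: float
    p: float
    stderr: float
    n: int

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-run slopes of an ensemble, with mean +- 2 sigma interval."""

    slopes: np.ndarray
    mean: float
    sigma: float
    interval: tuple[float, float]   # mean +- 2 sigma
    normality_stat: float
    normality_p: float
    normality_test: str
    fits: tuple[ClineFit, ...] = field(default=())
    #: runs whose expansion stalled before covering the lattice (possible
    #: for low net fecundity); excluded from the slope sample
    n_stalled: int = 0

    def overlaps(self, other: "EnsembleSummary") -> bool:
        return self.interval[0] <= other.interval[1] and other.interval[0] <= self.interval[1]


def phoneme_frequencies(masks) -> FrequencyVector:
    """Relative phoneme frequencies over a set of presence vectors.

    Each row (one language/tribe) contributes one occurrence per present
    phoneme; p_i = occurrences of phoneme i / total occurrences.
    """
    m = np.atleast_2d(np.asarray(masks))
    if m.size == 0:
        raise ValueError("empty language set")
    occ = m.sum(axis=0, dtype=np.float64)
    total = occ.sum()
    if total == 0:
        raise ValueError("no phonemes present in the language set")
    return occ / total


def t_f(p: FrequencyVector) -> float:
    """Evenness diversity 1/sum(p_i^2) - 1 of a frequency vector."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0 or np.any(p < 0):
        raise ValueError("invalid frequency vector")
    s = float(np.sum(p * p))
    if s == 0.0:
        raise ValueError("zero frequency vector")
    return 1.0 / s - 1.0


def bin_by_distance(records: pd.DataFrame, width_km: float,
                    column: str = "distance_km") -> list[tuple[float, pd.DataFrame]]:
    """Group records into half-open bins [k*w, (k+1)*w), anchored at 0.

    Returns (bin center, member records) pairs; empty bins are omitted.
    """
    if width_km <= 0:
        raise ValueError("bin width must be positive")
    idx = np.floor(records[column].to_numpy() / width_km).astype(int)
    out = []
    for k in sorted(set(idx)):
        out.append(((k + 0.5) * width_km, records[idx == k]))
    return out


def binned_tf(distances, masks, width_km: float = 1000.0) -> pd.DataFrame:
    """t_F per distance bin over full-space presence vectors.

    Each row of ``masks`` is one language occurrence (a tribe in simulated
    data, a database language in observed data).
    Returns columns bin_center_km, n_languages, t_F.
    """
    distances = np.asarray(distances, dtype=np.float64)
    masks = np.atleast_2d(np.asarray(masks))
    if distances.size != masks.shape[0]:
        raise ValueError("one distance per mask row")
    idx = np.floor(distances / width_km).astype(int)
    rows = []
    for k in sorted(set(idx)):
        sel = idx == k
        rows.append(((k + 0.5) * width_km, int(sel.sum()),
                     t_f(phoneme_frequencies(masks[sel]))))
    return pd.DataFrame(rows, columns=["bin_center_km", "n_languages", "t_F"])


def fit_cline(x, y) -> ClineFit:
    """OLS fit of y on x with a t-based 95% CI for the slope."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (x, y) points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all distances equal")
    if np.ptp(y) == 0:
        # flat response: exact zero-slope fit (linregress yields nan r here)
        return ClineFit(slope=0.0, intercept=float(y[0]), ci_low=0.0,
                        ci_high=0.0, r=0.0, p=1.0, stderr=0.0, n=int(x.size))
    res = stats.linregress(x, y)
    df = x.size - 2
    tcrit = stats.t.ppf(0.975, df)
    half = tcrit * res.stderr
    return ClineFit(
        slope=float(res.slope), intercept=float(res.intercept),
        ci_low=float(res.slope - half), ci_high=float(res.slope + half),
        r=float(res.rvalue), p=float(res.pvalue),
        stderr=float(res.stderr), n=int(x.size),
    )


def count_cline_from_run(result: SimulationResult) -> ClineFit:
    """Phoneme-count-vs-distance fit over the run's transect records."""
    rec = result.records
    return fit_cline(rec["distance_km"], rec["phoneme_count"])


def tf_cline_from_run(result: SimulationResult, width_km: float = 1000.0) -> ClineFit:
    """Binned-t_F-vs-distance fit over the run's transect records.

    Use a single-axis transect for this quantity: t_F is nonlinear in the
    language set, and pooling transects whose far cells fixed on different
    ancestral languages inflates far-bin diversity and masks the cline.
    """
    if result.config.transect_axis == "all":
        raise ValueError(
            "binned t_F needs a single-axis transect; run with "
            "transect_axis='+x' (or another single axis)")
    rec = result.records
    masks = expand_rows(result.state, rec["language_id"].to_numpy())
    table = binned_tf(rec["distance_km"].to_numpy(), masks, width_km)
    return fit_cline(table["bin_center_km"], table["t_F"])


def ensemble_slopes(config: SimConfig, n_runs: int, seeds: Sequence[int] | None = None,
                    seed_base: int | None = None, quantity: str = "count",
                    bin_km: float = 1000.0) -> EnsembleSummary:
    """Run the simulator ``n_runs`` times with distinct seeds and summarize
    the fitted cline slopes.

    ``quantity`` is ``"count"`` (phoneme count per tribe vs distance) or
    ``"tf"`` (binned t_F vs bin center).  The interval is mean +- 2 sigma
    across runs; normality of the slope distribution is checked with the
    D'Agostino-Pearson omnibus test.

    Runs whose expansion stalls before covering the lattice (a possibility
    of the integer-tribe demography at low R0) carry no cline and are
    excluded: further seeds are drawn until ``n_runs`` covered runs have
    been collected (at most ``3 * n_runs`` attempts).  The number of
    stalled runs is reported in the summary.
    """
    if n_runs < 2:
        raise ValueError("an ensemble needs at least 2 runs")
    if seeds is None:
        base = config.seed if seed_base is None else seed_base
        seeds = [base + k for k in range(3 * n_runs)]
    seeds = list(seeds)
    if len(seeds) < n_runs or len(set(seeds)) != len(seeds):
        raise ValueError("need at least n_runs distinct seeds")
    if quantity not in ("count", "tf"):
        raise ValueError("quantity must be 'count' or 'tf'")

    fits = []
    n_stalled = 0
    for i, s in enumerate(seeds):
        if len(fits) == n_runs:
            break
        try:
            result = run(replace(config, seed=int(s)))
            if result.stalled:
                n_stalled += 1
                continue
            if quantity == "count":
                fits.append(count_cline_from_run(result))
            else:
                fits.append(tf_cline_from_run(result, width_km=bin_km))
        except Exception as err:  # noqa: BLE001 - annotate which run failed
            raise RuntimeError(f"ensemble run {i} (seed {s}) failed: {err}") from err
    if len(fits) < n_runs:
        raise RuntimeError(
            f"only {len(fits)} of {n_runs} runs covered the lattice "
            f"({n_stalled} stalled) within {len(seeds)} attempts")

    slopes = np.array([f.slope for f in fits])
    mean = float(slopes.mean())
    sigma = float(slopes.std(ddof=0))
    if np.allclose(slopes, slopes[0]):
        nstat, npval, test = 0.0, 1.0, "degenerate"
    elif slopes.size >= 20:
        nstat, npval = stats.normaltest(slopes)
        test = "dagostino-pearson"
    else:
        nstat, npval = stats.shapiro(slopes)
        test = "shapiro-wilk"
    return EnsembleSummary(
        slopes=slopes, mean=mean, sigma=sigma,
        interval=(mean - 2 * sigma, mean + 2 * sigma),
        normality_stat=float(nstat), normality_p=float(npval),
        normality_test=test,
        fits=tuple(fits), n_stalled=n_stalled,
    )
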