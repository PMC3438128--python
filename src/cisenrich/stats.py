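"""Significance calls from observed vs randomized-background statistics.

For each target and each of the four statistics, the observed value is
compared to the empirical background by a standard Z-score,

    z = (observed - background mean) / background SD,

with the SD taken over the randomized reference sets (n-1 divisor). The
raw p-value is the one-sided standard-normal tail probability in the
observed direction: enrichment and depletion are reported as separate
signed findings. This is only calibrated when the background is
approximately Gaussian, so every record carries a moment-based
normality flag; for extremely overabundant motifs (the MRE2 situation)
the presence statistic I violates normality and the density statistic II
is the one to consult.

Multiple testing across targets and parameters is handled by Bonferroni
correction (default family: number of targets x 4 parameters). The
recommended thresholds are alpha <= 0.05 on corrected p-values, or
alpha <= 0.01 when working uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .iupac_motifs import IUPACPattern
from .promoter_io import PromoterSet, subset_by_genes
from .randomization import (
    BackgroundDistribution,
    RandomizationConfig,
    background_from_counts,
    sample_index_matrix,
    _parameter_samples,
)
from .scanner import (
    PARAMETER_IDS,
    ParameterVector,
    Target,
    count_occurrences,
    parameters_from_counts,
    resolve_targets,
)

__all__ = [
    "SignificanceRecord",
    "EnrichmentResult",
    "z_pvalue",
    "bonferroni_correct",
    "gaussian_diagnostic",
    "enrichment_analysis",
    "false_positive_rate",
]


@dataclass
class SignificanceRecord:
    """One significance call: target x parameter."""

    target: str
    parameter: str  # "I", "II", "III", "IV"
    observed: float
    bg_mean: float
    bg_sd: float
    z: float
    p_raw: float
    direction: str  # "enriched", "depleted", "none"
    gaussian_ok: bool = True
    degenerate: bool = False
    p_corrected: float | None = None
    retained: bool | None = None
    dataset: str = ""


def _tail_stats(observed: np.ndarray, bg: np.ndarray):
    """Vectorised z / one-sided p / direction for observed values against
    background sample columns. Degenerate backgrounds (SD == 0) give p = 1
    when the observation equals the background, else p = 0."""
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    mean = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    delta = observed - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, np.sign(delta) * np.inf, delta / np.maximum(sd, 1e-300))
    z = np.where(degenerate & (delta == 0), 0.0, z)
    p = sps.norm.sf(np.abs(z))
    p = np.where(degenerate, np.where(delta == 0, 1.0, 0.0), p)
    direction = np.where(delta > 0, "enriched", np.where(delta < 0, "depleted", "none"))
    return mean, sd, z, p, direction, degenerate


def z_pvalue(observed: float, samples: Sequence[float]) -> SignificanceRecord:
    """Z-score significance of one observed value against its empirical
    background distribution (at least 100 background samples)."""
    bg = np.asarray(samples, dtype=float)
    if bg.size < 100:
        raise ValueError(f"need >= 100 background samples, got {bg.size}")
    mean, sd, z, p, direction, degenerate = _tail_stats(
        [observed], bg.reshape(-1, 1)
    )
    return SignificanceRecord(
        target="",
        parameter="",
        observed=float(observed),
        bg_mean=float(mean[0]),
        bg_sd=float(sd[0]),
        z=float(z[0]),
        p_raw=float(p[0]),
        direction=str(direction[0]),
        degenerate=bool(degenerate[0]),
    )


def bonferroni_correct(
    records: Sequence[SignificanceRecord],
    family_size: int,
    alpha: float = 0.05,
) -> list[SignificanceRecord]:
    """Attach corrected p-values (min(1, p_raw * family_size)) and the
    retain flag (p_corrected <= alpha) to each record, in place."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    for rec in records:
        rec.p_corrected = min(1.0, rec.p_raw * family_size)
        rec.retained = rec.p_corrected <= alpha
    return list(records)


def gaussian_diagnostic(samples: Sequence[float]) -> tuple[bool, dict]:
    """Moment-based screen for an approximately Gaussian background.

    Fails when |skewness| > 0.5, |excess kurtosis| > 1, or more than 10%
    of the samples tie at a single value (heavy discreteness, e.g. a
    presence count pinned at the set size for an overabundant motif).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 100:
        raise ValueError(f"need >= 100 samples, got {x.size}")
    if np.ptp(x) == 0.0:
        summary = {"skewness": 0.0, "excess_kurtosis": 0.0, "max_tie_fraction": 1.0}
        return False, summary
    skew = float(sps.skew(x))
    kurt = float(sps.kurtosis(x))  # Fisher: excess kurtosis
    _, tie_counts = np.unique(x, return_counts=True)
    tie_frac = float(tie_counts.max() / x.size)
    summary = {
        "skewness": skew,
        "excess_kurtosis": kurt,
        "max_tie_fraction": tie_frac,
    }
    ok = abs(skew) <= 0.5 and abs(kurt) <= 1.0 and tie_frac <= 0.10
    return ok, summary


@dataclass
class EnrichmentResult:
    """Full output of one enrichment analysis."""

    dataset: str
    n: int
    records: list[SignificanceRecord]
    observed: dict[str, ParameterVector]
    backgrounds: list[BackgroundDistribution]
    missing: list[str] = field(default_factory=list)
    family_size: int = 1
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dataset": r.dataset,
                "target": r.target,
                "parameter": r.parameter,
                "observed": r.observed,
                "bg_mean": r.bg_mean,
                "bg_sd": r.bg_sd,
                "z": r.z,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "direction": r.direction,
                "gaussian_ok": r.gaussian_ok,
                "degenerate": r.degenerate,
                "retained": r.retained,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def enrichment_analysis(
    pool: PromoterSet,
    experimental_ids: Sequence[str],
    targets: Sequence[Target | str],
    config: RandomizationConfig | None = None,
    registry: Mapping[str, IUPACPattern] | None = None,
    strand_policy: str = "auto_antisense",
    alpha: float | None = None,
    correction: str = "bonferroni",
    family_size: int | None = None,
    dataset_label: str = "experimental",
    counts: pd.DataFrame | None = None,
) -> EnrichmentResult:
    """The full randomization pipeline for one experimental gene list.

    Scans the pool once for all targets, computes the observed statistics
    on the experimental subset, builds shared randomized backgrounds of
    the same set size, and returns Z-score significance records for every
    target x parameter with Bonferroni correction over the whole family
    (``correction="none"`` skips correction; the default alpha is then
    0.01 instead of 0.05, per the recommendation for uncorrected p-values).

    A precomputed ``counts`` matrix (from :func:`count_occurrences` on the
    same pool) may be passed to skip rescanning.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if alpha is None:
        alpha = 0.05 if correction == "bonferroni" else 0.01
    config = config or RandomizationConfig()
    targets = resolve_targets(targets, registry)
    subset, missing = subset_by_genes(pool, experimental_ids, label=dataset_label)
    if counts is None:
        counts = count_occurrences(pool, targets, registry, strand_policy)
    n = len(subset)

    frame = None
    if config.exclude_experimental:
        in_subset = counts.index.isin(subset.gene_ids)
        frame = np.flatnonzero(~in_subset)
    samples, tally, _ = background_from_counts(counts, n, config, frame=frame)

    exp_counts = counts.loc[list(subset.gene_ids)]
    observed: dict[str, ParameterVector] = {}
    records: list[SignificanceRecord] = []
    backgrounds: list[BackgroundDistribution] = []
    for name in counts.columns:
        pv = parameters_from_counts(exp_counts[name].to_numpy())
        observed[name] = pv
        bg = samples[name].to_numpy()
        mean, sd, z, p, direction, degenerate = _tail_stats(pv.as_array(), bg)
        for j, pid in enumerate(PARAMETER_IDS):
            ok, _ = gaussian_diagnostic(bg[:, j]) if sd[j] > 0 else (False, None)
            records.append(
                SignificanceRecord(
                    target=name,
                    parameter=pid,
                    observed=float(pv.as_array()[j]),
                    bg_mean=float(mean[j]),
                    bg_sd=float(sd[j]),
                    z=float(z[j]),
                    p_raw=float(p[j]),
                    direction=str(direction[j]),
                    gaussian_ok=bool(ok),
                    degenerate=bool(degenerate[j]),
                    dataset=dataset_label,
                )
            )
        backgrounds.append(BackgroundDistribution(name, samples[name], tally))

    m = family_size if family_size is not None else len(counts.columns) * 4
    if correction == "bonferroni":
        bonferroni_correct(records, m, alpha)
    else:
        for rec in records:
            rec.p_corrected = rec.p_raw
            rec.retained = rec.p_raw <= alpha
        m = 1
    return EnrichmentResult(
        dataset=dataset_label,
        n=n,
        records=records,
        observed=observed,
        backgrounds=backgrounds,
        missing=missing,
        family_size=m,
        alpha=alpha,
    )


def false_positive_rate(
    pool: PromoterSet | None,
    set_size: int,
    targets: Sequence[Target | str],
    alpha: float = 0.01,
    trials: int = 1000,
    config: RandomizationConfig | None = None,
    registry: Mapping[str, IUPACPattern] | None = None,
    strand_policy: str = "auto_antisense",
    direction: str = "enriched",
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Empirical false-positive error rate of the pipeline on null data.

    Each trial draws a random "experimental" set of ``set_size`` promoters
    from the pool, runs the enrichment computation against a fresh
    randomized background, and records whether the target is called at
    uncorrected p_raw <= alpha. Since the trial sets are themselves
    random, a calibrated test calls at rate alpha (per direction).

    direction:
        "enriched" (default; probability a motif is termed enriched by
        mistake, nominal rate alpha), "depleted" (nominal alpha), or
        "any" (either tail, nominal 2 * alpha).

    Returns a tidy frame with one row per target x parameter: number of
    calls, empirical rate, exact binomial 99% CI and the nominal rate.
    All targets share the same trial and background draws, so their rates
    are computed on identical null data.
    """
    if direction not in ("enriched", "depleted", "any"):
        raise ValueError(f"unknown direction {direction!r}")
    if trials < 100:
        raise ValueError("trials must be >= 100")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    config = config or RandomizationConfig()
    if counts is None:
        if pool is None:
            raise ValueError("either pool or counts must be given")
        targets = resolve_targets(targets, registry)
        counts = count_occurrences(pool, targets, registry, strand_policy)
    count_vectors = {name: counts[name].to_numpy() for name in counts.columns}
    pool_size = len(counts)
    rng = np.random.default_rng(config.seed)

    calls = {name: np.zeros(4, dtype=np.int64) for name in counts.columns}
    for _ in range(trials):
        # row 0 is the trial's "experimental" set, the rest its background
        idx = sample_index_matrix(rng, pool_size, set_size, config.n_reps + 1)
        for name, vec in count_vectors.items():
            params = _parameter_samples(vec, idx)
            _, _, _, p, direc, _ = _tail_stats(params[0], params[1:])
            hit = p <= alpha
            if direction != "any":
                hit &= direc == direction
            calls[name] += hit
    nominal = alpha * (2 if direction == "any" else 1)
    rows = []
    for name in counts.columns:
        for j, pid in enumerate(PARAMETER_IDS):
            k = int(calls[name][j])
            ci = sps.binomtest(k, trials).proportion_ci(
                confidence_level=0.99, method="exact"
            )
            rows.append(
                {
                    "target": name,
                    "parameter": pid,
                    "set_size": set_size,
                    "alpha": alpha,
                    "direction": direction,
                    "trials": trials,
                    "calls": k,
                    "rate": k / trials,
                    "ci99_low": float(ci.low),
                    "ci99_high": float(ci.high),
                    "nominal": nominal,
                }
            )
    return pd.DataFrame(rows)
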