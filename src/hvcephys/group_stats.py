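"""Per-neuron summaries and juvenile-vs-adult comparison battery.

Metric summaries follow the field's reporting conventions: median with
raw median absolute deviation (MAD, no consistency scaling) for
rank-based tests, mean with standard deviation for t-tests.  The battery
reports unadjusted p-values, as is conventional for these descriptive
comparisons; the number of tests run is logged on each result set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "NeuronSummary",
    "compare_cohorts",
    "comparison_table",
    "fisher_exact_2x2",
    "median_mad",
    "two_sample_t",
    "wilcoxon_rank_sum",
]

log = logging.getLogger(__name__)

#: Relative tolerance when comparing table probabilities in the two-sided
#: Fisher rule (guards against floating-point ties).
_FISHER_RTOL = 1e-7


def median_mad(values: Sequence[float]) -> tuple[float, float]:
    """Median and raw median absolute deviation (no 1.4826 factor)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("median_mad of empty data is undefined")
    med = float(np.median(x))
    return med, float(np.median(np.abs(x - med)))


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-group test with its matching summaries."""

    metric: str
    test: str                    # wilcoxon_rank_sum | two_sample_t | fisher_exact
    statistic: float
    p_value: float
    group_summaries: dict        # group -> (median, MAD) or (mean, SD) or counts
    n: tuple

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      metric: str = "") -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both samples are small
    (min(n, m) <= 10) and tie-free, otherwise the normal approximation
    with tie and continuity corrections.  Summaries are median + MAD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return ComparisonResult(
        metric=metric, test="wilcoxon_rank_sum",
        statistic=float(res.statistic), p_value=float(res.pvalue),
        group_summaries={"x": median_mad(x), "y": median_mad(y)},
        n=(int(x.size), int(y.size)),
    )


def two_sample_t(x: Sequence[float], y: Sequence[float], metric: str = "",
                 welch: bool = False) -> ComparisonResult:
    """Two-sided two-sample t-test (pooled variance; Welch on request).

    Summaries are mean +/- SD.  Raises when both groups are constant
    (zero pooled variance: p undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t-test needs n >= 2 per group")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0 and x.mean() != y.mean():
        raise ValueError("zero pooled variance with unequal means: p undefined")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat):           # identical constant groups: no difference
        stat, p = 0.0, 1.0
    return ComparisonResult(
        metric=metric, test="two_sample_t", statistic=stat, p_value=p,
        group_summaries={"x": (float(x.mean()), float(np.std(x, ddof=1))),
                         "y": (float(y.mean()), float(np.std(y, ddof=1)))},
        n=(int(x.size), int(y.size)),
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     metric: str = "") -> ComparisonResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The p-value sums the hypergeometric probabilities (margins fixed) of
    every table no more likely than the observed one — the
    probability-mass convention.  All-zero margins give p = 1.
    """
    for cell in (a, b, c, d):
        if cell < 0 or int(cell) != cell:
            raise ValueError("cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0:
        p = 1.0
        odds = np.nan
    else:
        support = np.arange(max(0, col1 - (n_total - row1)),
                            min(row1, col1) + 1)
        pmf = sps.hypergeom.pmf(support, n_total, row1, col1)
        p_obs = pmf[support == a][0]
        p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_RTOL)].sum())
        p = min(p, 1.0)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return ComparisonResult(
        metric=metric, test="fisher_exact", statistic=float(odds), p_value=p,
        group_summaries={"x": (a, b), "y": (c, d)},
        n=(a + b, c + d),
    )


# ---------------------------------------------------------------------------
# Per-neuron summaries and the comparison battery
# ---------------------------------------------------------------------------

@dataclass
class NeuronSummary:
    """Feature vector of one neuron, pooled over its motif renditions."""

    neuron_id: str
    age_group: str
    projection_class: str
    n_trials: int = 0
    max_bursts: int = 0
    mean_spikes_per_motif: float = 0.0
    mean_single_spikes_per_motif: float = 0.0
    mean_burst_spikes_per_motif: float = 0.0
    spikes_per_burst: list = field(default_factory=list)
    burst_ifrs: list = field(default_factory=list)
    burst_durations_ms: list = field(default_factory=list)
    delta_spikes_values: list = field(default_factory=list)
    recurring_count: int = 0
    total_bursts: int = 0
    progression_means: list = field(default_factory=list)
    progression_counts: list = field(default_factory=list)
    psp_amplitudes: list = field(default_factory=list)
    psp_durations_ms: list = field(default_factory=list)
    psp_frequency: float | None = None
    subthreshold_stereotypy: float | None = None
    preburst_stereotypy: float | None = None

    def __post_init__(self) -> None:
        if self.recurring_count > self.total_bursts:
            raise ValueError("recurring_count cannot exceed total_bursts")


def _pool(summaries: Sequence[NeuronSummary], attr: str) -> list[float]:
    out: list[float] = []
    for s in summaries:
        v = getattr(s, attr)
        if v is None:
            continue
        out.extend(v) if isinstance(v, list) else out.append(v)
    return out


def _neuron_means(summaries: Sequence[NeuronSummary], attr: str) -> list[float]:
    return [float(np.mean(getattr(s, attr)))
            for s in summaries if len(getattr(s, attr))]


def compare_cohorts(summaries: Sequence[NeuronSummary],
                    pool_projection_classes: bool = True,
                    params=None) -> list[ComparisonResult]:
    """Run the juvenile-vs-adult comparison battery.

    Neuron-level metrics (max bursts, spike counts, stereotypy, PSP
    frequency, mean PSP duration) and event-level metrics (spikes per
    burst, burst duration, IFR, delta-spikes, PSP amplitude) each use the
    test family the field reports for them; the recurring-burst fractions
    are compared with a Fisher exact test on pooled counts.  With
    ``pool_projection_classes`` off, the battery runs on the HVC-RA
    subset only.  Metrics with insufficient data are skipped and logged.
    """
    if not pool_projection_classes:
        summaries = [s for s in summaries if s.projection_class == "HVC_RA"]
    juv = [s for s in summaries if s.age_group == "juvenile"]
    adu = [s for s in summaries if s.age_group == "adult"]
    if len(juv) < 2 or len(adu) < 2:
        raise ValueError("compare_cohorts needs >= 2 neurons per age group")

    results: list[ComparisonResult] = []

    def run(fn, name, xs, ys, **kw):
        try:
            if len(xs) == 0 or len(ys) == 0:
                raise ValueError("no data")
            results.append(fn(xs, ys, metric=name, **kw))
        except ValueError as exc:
            log.info("skipping metric %s: %s", name, exc)

    run(wilcoxon_rank_sum, "max_bursts_per_motif",
        [s.max_bursts for s in juv], [s.max_bursts for s in adu])
    run(two_sample_t, "spikes_per_motif",
        [s.mean_spikes_per_motif for s in juv],
        [s.mean_spikes_per_motif for s in adu])
    run(two_sample_t, "single_spikes_per_motif",
        [s.mean_single_spikes_per_motif for s in juv],
        [s.mean_single_spikes_per_motif for s in adu])
    run(two_sample_t, "burst_spikes_per_motif",
        [s.mean_burst_spikes_per_motif for s in juv],
        [s.mean_burst_spikes_per_motif for s in adu])
    run(wilcoxon_rank_sum, "spikes_per_burst",
        _pool(juv, "spikes_per_burst"), _pool(adu, "spikes_per_burst"))
    run(wilcoxon_rank_sum, "delta_spikes",
        _pool(juv, "delta_spikes_values"), _pool(adu, "delta_spikes_values"))
    run(wilcoxon_rank_sum, "burst_duration_ms",
        _pool(juv, "burst_durations_ms"), _pool(adu, "burst_durations_ms"))
    run(wilcoxon_rank_sum, "burst_ifr_hz",
        _pool(juv, "burst_ifrs"), _pool(adu, "burst_ifrs"))

    # relative progression: per-neuron mean deviation of the neuron's
    # per-ISI trajectory from the own-group mean trajectory
    def _relative(groups):
        vals: list[float] = []
        sums = np.zeros(5)
        counts = np.zeros(5, dtype=int)
        for s in groups:
            m = np.asarray(s.progression_means, dtype=float)
            c = np.asarray(s.progression_counts, dtype=int)
            k = min(m.size, 5)
            sums[:k] += m[:k] * c[:k]
            counts[:k] += c[:k]
        n_valid = int(np.count_nonzero(counts))  # counts fill a prefix
        if n_valid == 0:
            return vals
        ref = sums[:n_valid] / counts[:n_valid]
        for s in groups:
            m = np.asarray(s.progression_means, dtype=float)
            k = min(m.size, n_valid)
            if k:
                vals.append(float(np.mean(m[:k] - ref[:k])))
        return vals

    run(wilcoxon_rank_sum, "relative_progression_hz",
        _relative(juv), _relative(adu))

    jr = sum(s.recurring_count for s in juv)
    jt = sum(s.total_bursts for s in juv)
    ar = sum(s.recurring_count for s in adu)
    at = sum(s.total_bursts for s in adu)
    if jt and at:
        results.append(fisher_exact_2x2(jr, jt - jr, ar, at - ar,
                                        metric="recurring_fraction"))
    else:
        log.info("skipping metric recurring_fraction: no bursts")

    run(wilcoxon_rank_sum, "subthreshold_stereotypy",
        [s.subthreshold_stereotypy for s in juv
         if s.subthreshold_stereotypy is not None],
        [s.subthreshold_stereotypy for s in adu
         if s.subthreshold_stereotypy is not None])
    run(wilcoxon_rank_sum, "preburst_stereotypy",
        [s.preburst_stereotypy for s in juv if s.preburst_stereotypy is not None],
        [s.preburst_stereotypy for s in adu if s.preburst_stereotypy is not None])
    run(wilcoxon_rank_sum, "psp_duration_ms",
        _neuron_means(juv, "psp_durations_ms"),
        _neuron_means(adu, "psp_durations_ms"))
    run(wilcoxon_rank_sum, "psp_amplitude_mv",
        _pool(juv, "psp_amplitudes"), _pool(adu, "psp_amplitudes"))
    run(wilcoxon_rank_sum, "psp_frequency_hz",
        [s.psp_frequency for s in juv if s.psp_frequency is not None],
        [s.psp_frequency for s in adu if s.psp_frequency is not None])

    log.info("comparison battery: %d tests, unadjusted p-values", len(results))
    return results


def comparison_table(results: Sequence[ComparisonResult]):
    """Render a battery as a pandas DataFrame (one row per metric)."""
    import pandas as pd

    rows = []
    for r in results:
        sx, sy = r.group_summaries["x"], r.group_summaries["y"]
        rows.append({
            "metric": r.metric, "test": r.test,
            "juvenile": f"{sx[0]:.4g} ({sx[1]:.4g})",
            "adult": f"{sy[0]:.4g} ({sy[1]:.4g})",
            "n_juvenile": r.n[0], "n_adult": r.n[1],
            "statistic": r.statistic, "p": r.p_value,
        })
    return pd.DataFrame(rows)
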