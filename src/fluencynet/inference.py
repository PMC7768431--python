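"""Validation statistics for group semantic networks.

Three pieces of machinery:

* **Random-network nulls** -- Erdos-Renyi G(n, m) ensembles matched on node
  and edge count; each draw yields (CC, ASPL, Q, S), and an empirical network
  measure is compared with the resulting null distribution by a one-sample
  Z-test.
* **Graded partial-network bootstrap** -- repeatedly draw a node subset
  (50-90% of words, without replacement, the *same* subset for both groups),
  re-estimate each group's network from the column-restricted incidence
  matrices, and compare the per-measure low/high samples with a pooled
  two-sample t-test and Cohen's d.  Effect sizes growing with the retained
  proportion indicate a robust group difference.
* **Unique-response McNemar test** -- of the word universe, which words did
  only one group produce?  The discordant counts are compared by McNemar's
  chi-squared with Edwards' continuity correction; the effect size is
  phi = sqrt(chi2 / N).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .construction import estimate_network
from .exceptions import ValidationError
from .metrics import MEASURE_NAMES, aspl, clustering_coefficient, modularity, \
    random_reference_stats, small_worldness

logger = logging.getLogger(__name__)

DEFAULT_PROPORTIONS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class NullDistribution:
    """Simulated null of one network measure under matched random graphs."""

    measure: str
    values: np.ndarray
    n_sims: int = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_sims = len(self.values)
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=1))


@dataclass(frozen=True)
class BootstrapResult:
    """Paired low/high bootstrap samples of one measure at one retention level."""

    proportion: float
    measure: str
    low_values: np.ndarray
    high_values: np.ndarray
    t: float
    p: float
    d: float

    @property
    def df(self) -> int:
        return len(self.low_values) + len(self.high_values) - 2


@dataclass(frozen=True)
class UniqueResponseCounts:
    """Contingency of the word universe: produced by both, one, or neither group."""

    n_total: int
    both: int
    high_only: int
    low_only: int

    @property
    def high_pct(self) -> float:
        """Percentage of the universe produced by the high group."""
        return 100.0 * (self.both + self.high_only) / self.n_total

    @property
    def low_pct(self) -> float:
        """Percentage of the universe produced by the low group."""
        return 100.0 * (self.both + self.low_only) / self.n_total


def random_network_null(
    n_nodes: int,
    n_edges: int,
    n_sims: int = 1000,
    seed: int = 0,
    restarts: int = 10,
    n_ref: int = 100,
) -> dict[str, NullDistribution]:
    """Null distributions of CC, ASPL, Q and S over Erdos-Renyi G(n, m) draws.

    All draws share one small-world-ness reference ensemble, which is exact
    here because every draw has identical node and edge counts.  ASPL of a
    disconnected draw is computed on its largest component and counted.
    """
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValidationError("more edges requested than the complete graph holds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    ref_stats = random_reference_stats(n_nodes, n_edges, n_ref=n_ref,
                                       seed=int(rng.integers(2**31)))
    sims = {name: np.empty(n_sims) for name in MEASURE_NAMES}
    n_disconnected = 0
    for i in range(n_sims):
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            n_disconnected += 1
        sims["cc"][i] = clustering_coefficient(g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sims["aspl"][i] = aspl(g)
            sims["s"][i] = small_worldness(g, ref_stats=ref_stats)
        sims["q"][i], _ = modularity(g, seed=int(rng.integers(2**31)), restarts=restarts)
    if n_disconnected:
        logger.info("%d of %d random draws were disconnected; ASPL used the "
                    "largest component", n_disconnected, n_sims)
        if n_disconnected > 0.01 * n_sims:
            warnings.warn(
                f"{n_disconnected}/{n_sims} random graphs disconnected at this density",
                stacklevel=2,
            )
    return {name: NullDistribution(name, values) for name, values in sims.items()}


def z_test(empirical: float, null: NullDistribution) -> tuple[float, float]:
    """One-sample Z of an empirical measure against its simulated null."""
    if null.sd == 0:
        raise ValidationError("null distribution has zero spread; Z is undefined")
    z = (empirical - null.mean) / null.sd
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _pooled_t(high: np.ndarray, low: np.ndarray) -> tuple[float, float, float]:
    """Pooled-variance two-sample t (high - low), two-sided p, Cohen's d."""
    n1, n2 = len(high), len(low)
    pooled_var = (
        ((n1 - 1) * high.var(ddof=1) + (n2 - 1) * low.var(ddof=1)) / (n1 + n2 - 2)
    )
    diff = high.mean() - low.mean()
    if pooled_var == 0:
        warnings.warn("zero pooled variance; t is infinite", stacklevel=2)
        t = np.inf * np.sign(diff) if diff else 0.0
        return float(t), 0.0 if diff else 1.0, float(t)
    t = diff / np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    p = 2.0 * stats.t.sf(abs(t), n1 + n2 - 2)
    d = diff / np.sqrt(pooled_var)
    return float(t), float(p), float(d)


def _subset_size(proportion: float, n: int) -> int:
    # round half away from zero, e.g. 0.5 * 31 = 15.5 -> 16
    return int(np.floor(proportion * n + 0.5))


def bootstrap_partial(
    mat_low: pd.DataFrame,
    mat_high: pd.DataFrame,
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
    n_boot: int = 1000,
    seed: int = 0,
    measures: tuple[str, ...] = MEASURE_NAMES,
    restarts: int = 10,
    n_ref: int = 100,
) -> list[BootstrapResult]:
    """Graded partial-network bootstrap comparison of two equated groups.

    Per realization one word subset of size round(p * n) is drawn without
    replacement and applied to *both* incidence matrices, so each comparison
    is paired on content; each group's network is then re-estimated from
    scratch (cosine similarity -> planar filter -> binarize) on the restricted
    matrix and measured.  Per (proportion, measure) the n_boot low and high
    values are compared by a pooled t-test (t oriented high - low) with
    Cohen's d.

    Realization randomness comes from per-counter substreams of ``seed``, so
    enlarging ``n_boot`` extends, rather than reshuffles, the draw sequence.
    Small-world-ness reference ensembles are cached per graph size.
    """
    if list(mat_low.columns) != list(mat_high.columns):
        raise ValidationError("group matrices must be equated (identical word columns)")
    words = np.array(mat_low.columns)
    n = len(words)
    for p in proportions:
        if _subset_size(p, n) < 4:
            raise ValidationError(f"proportion {p} keeps fewer than 4 of {n} words")

    ref_cache: dict[tuple[int, int], tuple[float, float]] = {}
    results: list[BootstrapResult] = []
    for pi, p in enumerate(proportions):
        size = _subset_size(p, n)
        samples = {m: (np.empty(n_boot), np.empty(n_boot)) for m in measures}
        for r in range(n_boot):
            rng = np.random.default_rng(np.random.SeedSequence([seed, pi, r]))
            cols = words[np.sort(rng.choice(n, size=size, replace=False))]
            sub_low, sub_high = mat_low[cols], mat_high[cols]
            dead = [w for w in cols
                    if sub_low[w].sum() == 0 or sub_high[w].sum() == 0]
            if dead:  # cannot occur for equated inputs (column sums >= 2)
                logger.debug("realization %d: dropping %d producer-less columns",
                             r, len(dead))
                sub_low = sub_low.drop(columns=dead)
                sub_high = sub_high.drop(columns=dead)
            # one Louvain seed per realization, shared by both groups, so the
            # low/high comparison is paired on detection randomness too
            q_seed = int(rng.integers(2**31))
            for gi, sub in enumerate((sub_low, sub_high)):
                g = estimate_network(sub)
                key = (g.number_of_nodes(), g.number_of_edges())
                if ("s" in measures) and key not in ref_cache:
                    ref_cache[key] = random_reference_stats(
                        *key, n_ref=n_ref,
                        seed=int(np.random.default_rng(
                            np.random.SeedSequence([seed, 997, *key])).integers(2**31)),
                    )
                for m in measures:
                    if m == "cc":
                        val = clustering_coefficient(g)
                    elif m == "aspl":
                        val = aspl(g)
                    elif m == "q":
                        val, _ = modularity(g, seed=q_seed, restarts=restarts)
                    elif m == "s":
                        val = small_worldness(g, ref_stats=ref_cache[key])
                    else:
                        raise ValidationError(f"unknown measure {m!r}")
                    samples[m][gi][r] = val
        for m in measures:
            low_vals, high_vals = samples[m]
            t, pval, d = _pooled_t(high_vals, low_vals)
            results.append(BootstrapResult(
                proportion=p, measure=m,
                low_values=low_vals, high_values=high_vals,
                t=t, p=pval, d=d,
            ))
    return results


def mcnemar_unique(
    mat_low: pd.DataFrame,
    mat_high: pd.DataFrame,
) -> tuple[UniqueResponseCounts, float, float, float]:
    """McNemar test on words produced by only one group.

    Both matrices must live over the same word universe (the un-equated,
    whole-sample token set).  The discordant counts are b = words with at
    least one producer in the high group only and c = low group only; the
    continuity-corrected statistic is chi2 = (|b - c| - 1)^2 / (b + c) with
    1 df, and phi = sqrt(chi2 / N) over the N-word universe.

    Returns ``(counts, chi2, p, phi)``; with no discordant words the test is
    undefined and (counts, nan, nan, nan) is returned with a warning.
    """
    universe = sorted(set(mat_low.columns) | set(mat_high.columns))
    low = mat_low.reindex(columns=universe, fill_value=0).sum(axis=0) > 0
    high = mat_high.reindex(columns=universe, fill_value=0).sum(axis=0) > 0
    counts = UniqueResponseCounts(
        n_total=len(universe),
        both=int((low & high).sum()),
        high_only=int((high & ~low).sum()),
        low_only=int((low & ~high).sum()),
    )
    return (counts,) + mcnemar_from_counts(counts.high_only, counts.low_only,
                                           counts.n_total)


def mcnemar_from_counts(b: int, c: int, n_total: int) -> tuple[float, float, float]:
    """Continuity-corrected McNemar chi2, p and phi from discordant counts."""
    if b + c == 0:
        warnings.warn("no discordant words between the groups; McNemar undefined",
                      stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    phi = float(np.sqrt(chi2 / n_total))
    return float(chi2), p, phi
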