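"""Unstable-locus calling: per-locus KS tests under FDR control.

A tumor sample's length distribution at each analysis locus is compared
against a matched normal profile or the synthesized reference normal with a
two-sample Kolmogorov-Smirnov test.  Only loci with at least ``min_reads``
observations on *both* sides are tested.  Benjamini-Hochberg correction is
applied across all tested loci of the sample, and a locus is called
unstable when its adjusted value falls below ``fdr_alpha``.  Per-sample
unstable counts, stratified by genic region and repeat class, are the
downstream classification features; cohort-level group differences are
assessed with the Wilcoxon rank-sum test.

The KS statistic is the supremum of the absolute ECDF difference evaluated
on the merged discrete support.  With the heavy ties of discrete length
data the asymptotic p-value is conservative; an exact small-sample mode and
a seeded permutation p-value are available for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import MicrosatelliteLocus, REGIONS, REPEAT_CLASSES
from .profiler import LengthProfile
from .refnormal import ReferenceNormal


class InstabilityError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for unstable-locus detection.

    ``min_reads`` applies to tumor and normal sides alike; ``fdr_alpha`` is
    the adjusted-value cutoff; ``test`` selects the KS p-value route
    (asymptotic always, or exact when both sides are at most
    ``exact_n_cap``).
    """

    min_reads: int = 5
    fdr_alpha: float = 0.05
    agreement_threshold: float = 0.95
    test: str = "ks_asymptotic"
    exact_n_cap: int = 25

    def __post_init__(self):
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.test not in ("ks_asymptotic", "ks_exact_smalln"):
            raise ValueError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class InstabilityCall:
    locus_id: str
    n_tumor: int
    n_normal: int
    D: float
    p: float
    q: float
    unstable: bool


@dataclass
class SampleInstabilitySummary:
    """Per-sample unstable/tested locus counts by (region, repeat class)."""

    sample_id: str
    strata: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def n_tested(self, region: Optional[str] = None, repeat_class: Optional[str] = None) -> int:
        return sum(
            t
            for (reg, cls), (t, _) in self.strata.items()
            if (region is None or reg == region)
            and (repeat_class is None or cls == repeat_class)
        )

    def n_unstable(self, region: Optional[str] = None, repeat_class: Optional[str] = None) -> int:
        return sum(
            u
            for (reg, cls), (_, u) in self.strata.items()
            if (region is None or reg == region)
            and (repeat_class is None or cls == repeat_class)
        )


def _expand(counts: Mapping[int, int]) -> np.ndarray:
    lengths = np.fromiter(counts.keys(), dtype=float)
    reps = np.fromiter(counts.values(), dtype=int)
    return np.repeat(lengths, reps)


def ks_two_sample(
    x: Mapping[int, int],
    y: Mapping[int, int],
    *,
    method: str = "asymp",
    exact_n_cap: int = 25,
) -> tuple[float, float]:
    """Two-sample KS test on discrete length multisets.

    ``x`` and ``y`` are length->count mappings.  ``method`` is ``"asymp"``
    (asymptotic p with effective size n_x*n_y/(n_x+n_y)), ``"exact"``, or
    ``"auto_exact"`` (exact when both sizes <= ``exact_n_cap``).  Returns
    ``(D, p)``.
    """
    if not x or not y:
        raise InstabilityError("ks_two_sample requires two non-empty multisets")
    xa, ya = _expand(x), _expand(y)
    if method == "auto_exact":
        method = "exact" if max(len(xa), len(ya)) <= exact_n_cap else "asymp"
    res = stats.ks_2samp(xa, ya, method=method)
    # the asymptotic tail underflows to 0 for extreme D; keep p in (0, 1]
    p = min(max(float(res.pvalue), np.finfo(float).tiny), 1.0)
    return float(res.statistic), p


def ks_permutation_pvalue(
    x: Mapping[int, int],
    y: Mapping[int, int],
    n_perm: int = 2000,
    seed: int = 0,
) -> float:
    """Seeded permutation p-value for the KS statistic (tie-robust audit)."""
    xa, ya = _expand(x), _expand(y)
    d_obs = stats.ks_2samp(xa, ya, method="asymp").statistic
    pooled = np.concatenate([xa, ya])
    rng = np.random.default_rng(seed)
    n_x = len(xa)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        d = stats.ks_2samp(pooled[:n_x], pooled[n_x:], method="asymp").statistic
        if d >= d_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise InstabilityError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


NormalSource = Union[LengthProfile, ReferenceNormal]


def _normal_counts(normal: NormalSource, locus_id: str) -> Optional[Mapping[int, int]]:
    if isinstance(normal, ReferenceNormal):
        return normal.lengths(locus_id) if locus_id in normal else None
    return normal.counts.get(locus_id)


def call_unstable(
    tumor: LengthProfile,
    normal: NormalSource,
    loci: Sequence[MicrosatelliteLocus],
    cfg: DetectionConfig = DetectionConfig(),
) -> tuple[list[InstabilityCall], SampleInstabilitySummary]:
    """Call unstable loci for one tumor sample.

    ``loci`` is the analysis locus set (normally the invariable loci, or
    the cross-cancer intersection when building region models); the
    BH correction spans all loci of this set that pass the two-sided
    ``min_reads`` filter.  A ReferenceNormal contributes its consensus
    length repeated ``ref_count`` times.

    Returns the per-locus calls and a region x repeat-class summary.
    Raises :class:`InstabilityError` when no locus is testable.
    """
    method = "asymp" if cfg.test == "ks_asymptotic" else "auto_exact"
    tested: list[tuple[MicrosatelliteLocus, int, int, float, float]] = []
    for locus in loci:
        t_counts = tumor.counts.get(locus.locus_id)
        n_counts = _normal_counts(normal, locus.locus_id)
        if t_counts is None or n_counts is None:
            continue
        n_t, n_n = sum(t_counts.values()), sum(n_counts.values())
        if n_t < cfg.min_reads or n_n < cfg.min_reads:
            continue
        d, p = ks_two_sample(
            t_counts, n_counts, method=method, exact_n_cap=cfg.exact_n_cap
        )
        tested.append((locus, n_t, n_n, d, p))

    if not tested:
        raise InstabilityError(
            f"sample {tumor.sample_id}: no testable locus (locus set of "
            f"{len(loci)}; coverage below min_reads={cfg.min_reads} or "
            "loci absent from the normal source)"
        )

    q_values = bh_fdr([p for *_, p in tested])
    calls = []
    strata: dict[tuple[str, str], list[int]] = {}
    for (locus, n_t, n_n, d, p), q in zip(tested, q_values):
        unstable = bool(q < cfg.fdr_alpha)
        calls.append(
            InstabilityCall(
                locus_id=locus.locus_id,
                n_tumor=n_t,
                n_normal=n_n,
                D=d,
                p=p,
                q=float(q),
                unstable=unstable,
            )
        )
        key = (locus.region, locus.repeat_class)
        cell = strata.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += int(unstable)

    summary = SampleInstabilitySummary(
        sample_id=tumor.sample_id,
        strata={k: (t, u) for k, (t, u) in strata.items()},
    )
    return calls, summary


def compare_groups(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) on per-sample counts.

    Exact for small samples without ties; otherwise the tie-corrected
    normal approximation (no continuity correction, so identical groups
    give p = 1).  Returns ``(U, p)``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InstabilityError("compare_groups requires two non-empty groups")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def write_calls(calls: Sequence[InstabilityCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tn_tumor\tn_normal\tD\tp\tq\tunstable\n")
        for c in calls:
            fh.write(
                f"{c.locus_id}\t{c.n_tumor}\t{c.n_normal}\t{c.D:.6g}\t"
                f"{c.p:.6g}\t{c.q:.6g}\t{int(c.unstable)}\n"
            )


def write_summary(summary: SampleInstabilitySummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tregion\trepeat_class\tn_tested\tn_unstable\n")
        for (region, cls) in sorted(summary.strata):
            t, u = summary.strata[(region, cls)]
            fh.write(f"{summary.sample_id}\t{region}\t{cls}\t{t}\t{u}\n")
        fh.write(
            f"{summary.sample_id}\tALL\tALL\t{summary.n_tested()}\t"
            f"{summary.n_unstable()}\n"
        )
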