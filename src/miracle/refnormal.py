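"""Invariable-locus selection and reference-normal construction.

RNA-seq cohorts rarely provide a matched normal for every tumor, and
expression differences between individuals perturb per-locus read depth.
Both problems are addressed by restricting analysis to *invariable*
microsatellite loci — loci where more than 95% of informative normal
samples share the same modal tract length — and by synthesizing a
*reference normal* from the normal cohort: for each invariable locus the
consensus modal length is repeated a number of times equal to the median,
across informative normals, of each sample's modal-length read count.  The
tumor length distribution at a locus is later compared against this
degenerate single-length distribution.

"Informative" means depth >= ``min_reads`` at the locus; low-coverage
normals are excluded from the agreement denominator rather than counted as
disagreement, so coverage is not conflated with instability.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .profiler import LengthProfile


class RefNormalError(ValueError):
    pass


def modal_length(lengths: Mapping[int, int]) -> tuple[int, int]:
    """Return ``(modal length, its read count)`` for a length->count mapping.

    Ties on count are broken toward the smallest length.  Raises on an
    empty mapping.
    """
    if not lengths:
        raise RefNormalError("modal_length of an empty length mapping")
    best = max(lengths.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0], best[1]


@dataclass
class NormalCohortSummary:
    """Per-locus modal-length agreement statistics over a normal cohort.

    ``table`` has one row per locus with columns ``consensus_length``,
    ``n_informative`` and ``agreement`` (fraction of informative samples
    whose modal length equals the cohort consensus).  ``modal_freqs`` maps
    locus_id to the list of per-sample modal-length read counts, in cohort
    order, for the informative samples.
    """

    table: pd.DataFrame
    modal_freqs: dict[str, list[int]] = field(default_factory=dict)


def summarize_normals(
    normals: Sequence[LengthProfile], min_reads: int = 5
) -> NormalCohortSummary:
    """Compute per-locus modal lengths, agreement and modal frequencies."""
    modal_by_locus: dict[str, list[tuple[int, int]]] = {}
    for prof in normals:
        for locus_id, counts in prof.counts.items():
            if sum(counts.values()) < min_reads:
                continue
            modal_by_locus.setdefault(locus_id, []).append(modal_length(counts))

    rows = []
    modal_freqs: dict[str, list[int]] = {}
    for locus_id, modals in modal_by_locus.items():
        votes = Counter(m for m, _ in modals)
        top = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
        consensus, n_agree = top
        rows.append(
            {
                "locus_id": locus_id,
                "consensus_length": consensus,
                "n_informative": len(modals),
                "agreement": n_agree / len(modals),
            }
        )
        modal_freqs[locus_id] = [freq for _, freq in modals]
    table = pd.DataFrame(
        rows, columns=["locus_id", "consensus_length", "n_informative", "agreement"]
    ).set_index("locus_id")
    return NormalCohortSummary(table=table, modal_freqs=modal_freqs)


def select_invariable(
    normals: Sequence[LengthProfile],
    *,
    min_reads: int = 5,
    agreement_threshold: float = 0.95,
    min_normals: int = 10,
) -> tuple[set[str], NormalCohortSummary]:
    """Select invariable loci from a cohort of normal profiles.

    A locus is invariable iff at least ``min_normals`` normals are
    informative there and the modal-length agreement is *strictly* greater
    than ``agreement_threshold`` (19 of 20 — exactly 0.95 — does not
    qualify at the default).
    """
    if len(normals) < min_normals:
        raise RefNormalError(
            f"normal cohort of {len(normals)} is smaller than min_normals="
            f"{min_normals}; lower min_normals to proceed"
        )
    summary = summarize_normals(normals, min_reads=min_reads)
    t = summary.table
    mask = (t["n_informative"] >= min_normals) & (t["agreement"] > agreement_threshold)
    return set(t.index[mask]), summary


@dataclass
class ReferenceNormal:
    """Synthetic normal: per invariable locus a single consensus length
    replicated ``ref_count`` times.

    ``entries`` maps locus_id -> (ref_length in bases, ref_count reads).
    """

    entries: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.entries

    def lengths(self, locus_id: str) -> dict[int, int]:
        """The implied length->count mapping at a locus."""
        ref_length, ref_count = self.entries[locus_id]
        return {ref_length: ref_count}

    def depth(self, locus_id: str) -> int:
        return self.entries[locus_id][1] if locus_id in self.entries else 0


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def build_reference_normal(
    normals: Sequence[LengthProfile],
    invariable: Iterable[str],
    *,
    min_reads: int = 5,
    summary: Optional[NormalCohortSummary] = None,
    global_median: bool = False,
) -> ReferenceNormal:
    """Construct the reference normal over an invariable locus set.

    ``ref_length`` is the cohort-consensus modal length; ``ref_count`` is
    the median across informative normals of each sample's modal-length
    read count, rounded half-up and floored at ``min_reads`` so every
    reference locus remains testable.  With ``global_median`` the median is
    taken over all (locus, sample) modal frequencies and applied uniformly
    (sensitivity-analysis mode).
    """
    if summary is None:
        summary = summarize_normals(normals, min_reads=min_reads)
    invariable = set(invariable)
    missing = invariable - set(summary.table.index)
    if missing:
        raise RefNormalError(
            f"{len(missing)} invariable loci absent from all normals, "
            f"e.g. {sorted(missing)[:3]}"
        )
    if global_median:
        pooled = [
            f for lid in invariable for f in summary.modal_freqs[lid]
        ]
        global_count = max(min_reads, _round_half_up(float(pd.Series(pooled).median())))
    entries = {}
    for locus_id in invariable:
        ref_length = int(summary.table.at[locus_id, "consensus_length"])
        if global_median:
            ref_count = global_count
        else:
            freqs = summary.modal_freqs[locus_id]
            ref_count = max(
                min_reads, _round_half_up(float(pd.Series(freqs).median()))
            )
        entries[locus_id] = (ref_length, ref_count)
    return ReferenceNormal(entries=entries)


def intersect_invariable(sets: Sequence[Iterable[str]]) -> set[str]:
    """Intersection of per-cohort invariable locus sets (cross-cancer core)."""
    if not sets:
        return set()
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


def write_reference_normal(ref: ReferenceNormal, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tref_length\tref_count\n")
        for locus_id in sorted(ref.entries):
            length, count = ref.entries[locus_id]
            fh.write(f"{locus_id}\t{length}\t{count}\n")


def read_reference_normal(path) -> ReferenceNormal:
    ref = ReferenceNormal()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["locus_id", "ref_length", "ref_count"]:
            raise RefNormalError(f"{path}: unexpected reference-normal header")
        for line in fh:
            locus_id, length, count = line.rstrip("\n").split("\t")
            ref.entries[locus_id] = (int(length), int(count))
    return ref


def write_cohort_summary(summary: NormalCohortSummary, path) -> None:
    summary.table.to_csv(path, sep="\t")
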