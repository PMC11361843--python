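"""Per-sample microsatellite tract-length measurement from aligned reads.

For every catalog locus, reads overlapping the tract are inspected through
their alignment (CIGAR).  A read contributes one length observation when it
spans the tract plus ``flank_len`` bases on both sides, the read bases
abutting the tract match the reference flanks exactly, and no deletion or
splice crosses a flank/tract boundary.  The observed tract length is the
number of read bases strictly between the two flank anchors, i.e. the
reference tract length plus insertions minus deletions inside the tract.
The per-locus multiset of observed lengths across reads is the sample's
"Length list".

Reads failing a check are tallied under an enumerated rejection reason
(``filtered_flag``, ``low_mapq``, ``not_spanning``, ``boundary_indel``,
``flank_mismatch``, ``short_tract``) so that filter behaviour is auditable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pysam

from .catalog import MicrosatelliteLocus

logger = logging.getLogger(__name__)

PROFILE_FORMAT_VERSION = "v1"

REJECTION_REASONS = (
    "filtered_flag",
    "low_mapq",
    "not_spanning",
    "boundary_indel",
    "flank_mismatch",
    "short_tract",
)

# CIGAR operation codes that consume reference positions without aligning
# read bases: deletion (2) and reference skip / splice (3)
_REF_GAP_OPS = (2, 3)


class ProfileFormatError(ValueError):
    """Raised when a profile file has an unexpected header or version."""


@dataclass(frozen=True)
class ProfilerConfig:
    """Read-level filters for tract-length measurement.

    ``min_tract_len`` is in bases (observed lengths below it are discarded);
    ``flank_len`` is the number of reference-matching bases required on each
    side of the tract.  MAPQ and flag filters follow standard practice and
    can be relaxed (``min_mapq=0``) for permissive operation.
    """

    min_tract_len: int = 5
    flank_len: int = 2
    min_mapq: int = 20
    drop_duplicates: bool = True
    drop_secondary: bool = True
    drop_supplementary: bool = True
    drop_qcfail: bool = True

    def __post_init__(self):
        if self.min_tract_len < 1:
            raise ValueError("min_tract_len must be >= 1")
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")


@dataclass
class LengthProfile:
    """Per-sample mapping locus_id -> {tract length (bases) -> read count}.

    ``rejections`` carries per-locus rejection tallies from profiling; it is
    diagnostic only and excluded from equality and serialization.
    """

    sample_id: str
    counts: dict[str, dict[int, int]] = field(default_factory=dict)
    rejections: dict[str, Counter] = field(default_factory=dict, compare=False)

    def depth(self, locus_id: str) -> int:
        return sum(self.counts.get(locus_id, {}).values())

    def loci(self) -> list[str]:
        return list(self.counts)


def _read_passes_filters(read: pysam.AlignedSegment, cfg: ProfilerConfig) -> Optional[str]:
    """Return a rejection reason for flag/MAPQ filters, or None if the read passes."""
    if read.is_unmapped:
        return "filtered_flag"
    if cfg.drop_duplicates and read.is_duplicate:
        return "filtered_flag"
    if cfg.drop_secondary and read.is_secondary:
        return "filtered_flag"
    if cfg.drop_supplementary and read.is_supplementary:
        return "filtered_flag"
    if cfg.drop_qcfail and read.is_qcfail:
        return "filtered_flag"
    if read.mapping_quality < cfg.min_mapq:
        return "low_mapq"
    return None


def measure_tract_length(
    read: pysam.AlignedSegment,
    locus: MicrosatelliteLocus,
    flanks: tuple[str, str],
    cfg: ProfilerConfig = ProfilerConfig(),
) -> tuple[Optional[int], Optional[str]]:
    """Measure the observed tract length of one read at one locus.

    Returns ``(length, None)`` on success or ``(None, reason)`` on
    rejection.  ``flanks`` are the reference bases immediately 5' and 3' of
    the tract, each of length ``cfg.flank_len``.

    The measurement anchors on the last read base aligned to the reference
    position just before the tract and the first read base aligned to the
    position just after it; the length is the count of read bases strictly
    between the anchors.  Soft-clipped bases are never used as evidence: the
    aligned span itself must cover tract plus flanks.
    """
    start, end = locus.start, locus.end
    flank_len = cfg.flank_len
    flank5, flank3 = flanks[0].upper(), flanks[1].upper()

    seq = read.query_sequence
    if seq is None or read.cigartuples is None:
        return None, "not_spanning"
    # aligned (non-clipped) span must cover [start - flank_len, end + flank_len)
    if read.reference_start > start - flank_len or read.reference_end < end + flank_len:
        return None, "not_spanning"
    # splices across the window cannot provide contiguous evidence
    ref_pos = read.reference_start
    for op, n in read.cigartuples:
        if op == 3:  # N: reference skip
            if ref_pos < end + flank_len and ref_pos + n > start - flank_len:
                return None, "not_spanning"
        if op in (0, 7, 8, 2, 3):  # ops consuming reference
            ref_pos += n
    # ref position -> query position for aligned bases
    ref2query = {
        rpos: qpos
        for qpos, rpos in read.get_aligned_pairs(matches_only=True)
    }

    # 5' flank: every flank reference base aligned, contiguous in the read,
    # and matching the reference sequence
    q5 = _check_flank(
        seq, ref2query, range(start - flank_len, start), flank5
    )
    if q5 is None:
        return None, _flank_failure(ref2query, range(start - flank_len, start))
    q3 = _check_flank(
        seq, ref2query, range(end, end + flank_len), flank3
    )
    if q3 is None:
        return None, _flank_failure(ref2query, range(end, end + flank_len))

    q_last_5 = ref2query[start - 1]   # last read base of the 5' flank
    q_first_3 = ref2query[end]        # first read base of the 3' flank
    return q_first_3 - q_last_5 - 1, None


def _check_flank(seq, ref2query, ref_range, expected: str) -> Optional[bool]:
    """Verify a flank: aligned at every position, contiguous, sequence-identical.

    Returns True on success, None on any failure (caller resolves the reason).
    """
    qpositions = []
    for rpos in ref_range:
        q = ref2query.get(rpos)
        if q is None:
            return None
        qpositions.append(q)
    for a, b in zip(qpositions, qpositions[1:]):
        if b != a + 1:  # insertion inside the flank
            return None
    bases = "".join(seq[q] for q in qpositions).upper()
    if "N" in bases or bases != expected:
        return None
    return True


def _flank_failure(ref2query, ref_range) -> str:
    """Deletion/splice over a flank base is a boundary indel; otherwise the
    flank sequence simply mismatched."""
    for rpos in ref_range:
        if rpos not in ref2query:
            return "boundary_indel"
    return "flank_mismatch"


def profile_sample(
    alignments,
    loci: Sequence[MicrosatelliteLocus],
    cfg: ProfilerConfig = ProfilerConfig(),
    sample_id: Optional[str] = None,
    genome=None,
) -> LengthProfile:
    """Build the per-sample Length list over a locus catalog.

    Parameters
    ----------
    alignments
        Path to a coordinate-sorted, indexed BAM (or an open
        ``pysam.AlignmentFile``).
    loci
        Validated catalog loci.  Flanks recorded at catalog load are used;
        ``genome`` is consulted only for loci lacking them.

    Returns a :class:`LengthProfile`; per-locus rejection tallies are kept
    on the profile's ``rejections`` attribute.  Loci on chromosomes absent
    from the alignment header are skipped with a warning; loci whose
    accepted-read count is zero are absent from the profile.
    """
    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    bam = (
        pysam.AlignmentFile(str(alignments)) if own_handle else alignments
    )
    if sample_id is None:
        sample_id = Path(str(alignments)).name.split(".")[0] if own_handle else "sample"
    if not bam.has_index():
        raise FileNotFoundError(f"alignment file {alignments} has no index")

    profile = LengthProfile(sample_id=sample_id)
    valid_chroms = set(bam.references)
    missing_warned: set[str] = set()
    try:
        for locus in loci:
            if locus.chrom not in valid_chroms:
                if locus.chrom not in missing_warned:
                    logger.warning(
                        "chromosome %s absent from alignment header; skipping its loci",
                        locus.chrom,
                    )
                    missing_warned.add(locus.chrom)
                continue
            flanks = _locus_flanks(locus, genome, cfg.flank_len)
            counter: Counter = Counter()
            rejected: Counter = Counter()
            for read in bam.fetch(locus.chrom, locus.start, locus.end):
                reason = _read_passes_filters(read, cfg)
                if reason is not None:
                    rejected[reason] += 1
                    continue
                length, reason = measure_tract_length(read, locus, flanks, cfg)
                if reason is not None:
                    rejected[reason] += 1
                    continue
                if length < cfg.min_tract_len:
                    rejected["short_tract"] += 1
                    continue
                counter[length] += 1
            if counter:
                profile.counts[locus.locus_id] = dict(sorted(counter.items()))
            if rejected:
                profile.rejections[locus.locus_id] = rejected
    finally:
        if own_handle:
            bam.close()
    return profile


def _locus_flanks(locus: MicrosatelliteLocus, genome, flank_len: int) -> tuple[str, str]:
    if locus.flank5 is not None and locus.flank3 is not None:
        return locus.flank5, locus.flank3
    if genome is None:
        raise ValueError(
            f"{locus.locus_id}: no recorded flanks and no genome supplied"
        )
    chrom = genome[locus.chrom]
    return (
        str(chrom[locus.start - flank_len : locus.start]).upper(),
        str(chrom[locus.end : locus.end + flank_len]).upper(),
    )


def write_profile(profile: LengthProfile, path) -> None:
    """Write a profile as versioned TSV (locus_id, length, count)."""
    with open(path, "w") as fh:
        fh.write(f"#miracle_profile\t{PROFILE_FORMAT_VERSION}\n")
        fh.write(f"#sample_id\t{profile.sample_id}\n")
        fh.write("locus_id\tlength\tcount\n")
        for locus_id in sorted(profile.counts):
            for length, count in sorted(profile.counts[locus_id].items()):
                fh.write(f"{locus_id}\t{length}\t{count}\n")


def read_profile(path) -> LengthProfile:
    """Read a profile written by :func:`write_profile` (lossless round-trip)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2 or header[0] != "#miracle_profile":
            raise ProfileFormatError(f"{path}: not a profile file")
        if header[1] != PROFILE_FORMAT_VERSION:
            raise ProfileFormatError(
                f"{path}: version {header[1]} != {PROFILE_FORMAT_VERSION}"
            )
        sample_line = fh.readline().rstrip("\n").split("\t")
        if sample_line[0] != "#sample_id" or len(sample_line) != 2:
            raise ProfileFormatError(f"{path}: missing sample_id header")
        profile = LengthProfile(sample_id=sample_line[1])
        fh.readline()  # column header
        for line in fh:
            locus_id, length, count = line.rstrip("\n").split("\t")
            profile.counts.setdefault(locus_id, {})[int(length)] = int(count)
    return profile
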