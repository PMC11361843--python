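"""Shared fixtures: a toy reference with one mononucleotide tract, and
helpers for constructing aligned reads with arbitrary CIGARs."""

import numpy as np
import pysam
import pytest

from miracle.catalog import MicrosatelliteLocus, make_locus_id

TOY_CHROM = "chrT"
# 20 bp left flank | A x 10 tract | 20 bp right flank; flanks chosen free of
# runs that could extend the tract
TOY_LEFT = "GCTAGCTTGACCTGATCGTC"
TOY_RIGHT = "CTGGATCGTTCAGGTCCAGT"
TOY_TRACT = "A" * 10
TOY_REF = TOY_LEFT + TOY_TRACT + TOY_RIGHT
TOY_START, TOY_END = 20, 30


@pytest.fixture(scope="session")
def toy_locus():
    return MicrosatelliteLocus(
        chrom=TOY_CHROM,
        start=TOY_START,
        end=TOY_END,
        motif="A",
        region="UTR3",
        gene="GENE1",
        locus_id=make_locus_id(TOY_CHROM, TOY_START, TOY_END),
        flank5=TOY_REF[TOY_START - 2 : TOY_START],
        flank3=TOY_REF[TOY_END : TOY_END + 2],
        perfect=True,
    )


@pytest.fixture(scope="session")
def toy_header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": TOY_CHROM, "LN": len(TOY_REF)}]}
    )


def make_read(header, rstart, cigar, seq, mapq=60, flag=0, name="r1"):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = 0
    a.reference_start = rstart
    a.mapping_quality = mapq
    a.cigartuples = cigar
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


def make_tract_read(header, rstart=10, rend=50, ins_at=None, ins_len=0,
                    del_at=None, del_len=0, seq_override=None, **kw):
    """A read over the toy locus, optionally with one indel inside the tract.

    ``ins_at``/``del_at`` are offsets in tract bases from TOY_START.  The
    sequence is built to match the reference outside the event, inserting
    motif bases for insertions.
    """
    assert rstart <= TOY_START - 2 and rend >= TOY_END + 2
    if ins_len and del_len:
        raise ValueError("one event per read in this helper")
    if ins_len:
        k = ins_at
        seq = (TOY_REF[rstart : TOY_START + k] + "A" * ins_len
               + TOY_REF[TOY_START + k : rend])
        cigar = [(0, TOY_START + k - rstart), (1, ins_len),
                 (0, rend - (TOY_START + k))]
    elif del_len:
        k = del_at
        seq = TOY_REF[rstart : TOY_START + k] + TOY_REF[TOY_START + k + del_len : rend]
        cigar = [(0, TOY_START + k - rstart), (2, del_len),
                 (0, rend - (TOY_START + k + del_len))]
    else:
        seq = TOY_REF[rstart:rend]
        cigar = [(0, rend - rstart)]
    if seq_override is not None:
        seq = seq_override
    return make_read(header, rstart, cigar, seq, **kw)


def replay_tract_length(rstart, cigar, start, end):
    """Independent base-by-base replay of an alignment: the number of query
    bases strictly between the base aligned at start-1 and the base aligned
    at end, or None if either anchor is unaligned."""
    qpos, rpos = 0, rstart
    q5 = q3 = None
    for op, n in cigar:
        if op in (0, 7, 8):
            for _ in range(n):
                if rpos == start - 1:
                    q5 = qpos
                if rpos == end and q3 is None:
                    q3 = qpos
                rpos += 1
                qpos += 1
        elif op in (1, 4):
            qpos += n
        elif op in (2, 3):
            rpos += n
    if q5 is None or q3 is None:
        return None
    return q3 - q5 - 1


def profile_from_counts(sample_id, counts):
    """Build a LengthProfile directly from {locus_id: {length: count}}."""
    from miracle.profiler import LengthProfile

    return LengthProfile(sample_id=sample_id, counts={k: dict(v) for k, v in counts.items()})
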