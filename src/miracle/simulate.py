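"""Synthetic microsatellite data: genomes, catalogs, aligned-read cohorts.

The simulator builds a small reference genome whose contigs are chains of
microsatellite loci (random non-extending flanks around a perfect motif
tandem), the matching BED4+2 catalog, and per-sample coordinate-sorted
indexed BAMs with ground truth.  Its generative model mirrors the
assumptions behind length-distribution MSI detection:

* every read spanning a locus observes the sample's allele length plus
  optional *stutter* noise — with probability ``stutter_rate`` the
  observation slips by a geometric number of motif units, in either
  direction (``stutter_del_bias`` sets the deletion probability);
* normal and MSS samples carry the reference allele everywhere;
* an MSI-H sample destabilizes a random fraction of loci, each with a
  fixed somatic shift of 1-3 motif units; a destabilized locus expresses
  the shifted allele in a ``tumor_purity`` fraction of its reads.

Reads are single-end, primary, MAPQ 60, no clipping; the CIGAR encodes the
exact tract indel relative to the reference, so the profiler can be checked
against truth read-for-read.  Alignment pathologies (soft clips, splices,
low MAPQ) are exercised by dedicated test fixtures, not by this generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .catalog import MicrosatelliteLocus, make_locus_id, write_catalog

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# catalog composition of the exome-wide locus pool: region proportions
# (CDS / 3'UTR / 5'UTR) and repeat-class proportions (mono/di/tri/tetra)
DEFAULT_REGION_MIX = {"CDS": 0.400, "UTR3": 0.469, "UTR5": 0.131}
DEFAULT_CLASS_MIX = {"mono": 0.292, "di": 0.164, "tri": 0.342, "tetra": 0.202}

_UNIT_BY_CLASS = {"mono": 1, "di": 2, "tri": 3, "tetra": 4}

STATUSES = ("normal", "MSS", "MSI-H")


@dataclass
class SimulationConfig:
    """Generative parameters for synthetic cohorts.

    Lengths are in motif units where noted; ``tumor_purity`` is the
    fraction of reads at a destabilized locus carrying the shifted allele;
    ``destabilized_regions`` restricts somatic shifts to given genic
    regions (None = any region).
    """

    n_loci: int = 500
    region_mix: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    flank_len_ref: int = 60
    tract_units: tuple[int, int] = (5, 15)
    coverage_mean: float = 30.0
    read_len: int = 100
    stutter_rate: float = 0.02
    stutter_magnitude: float = 0.8
    stutter_del_bias: float = 0.5
    destabilized_fraction: float = 0.3
    shift_units: tuple[int, int] = (1, 3)
    tumor_purity: float = 0.7
    destabilized_regions: Optional[frozenset] = None
    loci_per_contig: int = 50
    seed: int = 0

    def __post_init__(self):
        for name in ("stutter_rate", "stutter_del_bias", "destabilized_fraction",
                     "tumor_purity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 < self.stutter_magnitude <= 1:
            raise ValueError("stutter_magnitude must be in (0, 1]")
        for mix, labels in ((self.region_mix, "region_mix"), (self.class_mix, "class_mix")):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{labels} proportions must sum to 1")
        if self.shift_units[0] < 1:
            raise ValueError("somatic shifts must be at least one motif unit")
        if self.tract_units[0] < 1 or self.tract_units[0] > self.tract_units[1]:
            raise ValueError("invalid tract_units range")


def _is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def _random_motif(rng: np.random.Generator, unit_len: int) -> str:
    while True:
        motif = "".join(rng.choice(_BASES, size=unit_len))
        if _is_primitive(motif):
            return motif


def _random_flank(rng: np.random.Generator, n: int, forbidden_first: str,
                  forbidden_last: str) -> str:
    """Random flank whose boundary bases cannot extend an adjacent tract."""
    flank = rng.choice(_BASES, size=n)
    if flank[0] == forbidden_first:
        flank[0] = rng.choice([b for b in "ACGT" if b != forbidden_first])
    if flank[-1] == forbidden_last:
        flank[-1] = rng.choice([b for b in "ACGT" if b != forbidden_last])
    return "".join(flank)


def generate_reference(
    cfg: SimulationConfig, out_dir
) -> tuple[Path, list[MicrosatelliteLocus], dict[str, str]]:
    """Build the synthetic genome FASTA (+.fai) and locus catalog.

    Each contig carries up to ``loci_per_contig`` loci laid out as
    ``flank + motif^u + flank`` segments; region and repeat-class labels
    are drawn from the configured mixes.  Returns the FASTA path, the
    catalog (with flanks recorded and ``perfect=True``), and the raw
    contig sequences.  A BED4+2 catalog file is written alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 1])

    regions = list(cfg.region_mix)
    region_p = np.array([cfg.region_mix[r] for r in regions])
    classes = list(cfg.class_mix)
    class_p = np.array([cfg.class_mix[c] for c in classes])

    loci: list[MicrosatelliteLocus] = []
    contigs: dict[str, str] = {}
    n_contigs = -(-cfg.n_loci // cfg.loci_per_contig)
    locus_no = 0
    for ci in range(n_contigs):
        chrom = f"contig{ci + 1:04d}"
        parts: list[str] = []
        pos = 0
        for _ in range(min(cfg.loci_per_contig, cfg.n_loci - locus_no)):
            unit_len = _UNIT_BY_CLASS[classes[int(rng.choice(len(classes), p=class_p))]]
            motif = _random_motif(rng, unit_len)
            units = int(rng.integers(cfg.tract_units[0], cfg.tract_units[1] + 1))
            tract = motif * units
            left = _random_flank(rng, cfg.flank_len_ref, "N", motif[-1])
            right = _random_flank(rng, cfg.flank_len_ref, motif[0], "N")
            start = pos + len(left)
            end = start + len(tract)
            region = regions[int(rng.choice(len(regions), p=region_p))]
            locus_no += 1
            loci.append(
                MicrosatelliteLocus(
                    chrom=chrom,
                    start=start,
                    end=end,
                    motif=motif,
                    region=region,
                    gene=f"GENE{locus_no:05d}",
                    locus_id=make_locus_id(chrom, start, end),
                    flank5=left[-2:],
                    flank3=right[:2],
                    perfect=True,
                )
            )
            parts.extend((left, tract, right))
            pos = end + len(right)
        contigs[chrom] = "".join(parts)

    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom, seq in contigs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(fasta_path))
    write_catalog(loci, out_dir / "catalog.bed")
    return fasta_path, loci, contigs


def _stutter_slip(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    """Signed slip in motif units (0 with probability 1 - stutter_rate)."""
    if rng.random() >= cfg.stutter_rate:
        return 0
    size = int(rng.geometric(cfg.stutter_magnitude))
    sign = -1 if rng.random() < cfg.stutter_del_bias else 1
    return sign * size


def simulate_sample(
    contigs: dict[str, str],
    catalog: Sequence[MicrosatelliteLocus],
    cfg: SimulationConfig,
    status: str,
    out_bam,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> list[dict]:
    """Write one sample's coordinate-sorted indexed BAM; return truth rows.

    Truth rows record, per locus: the reference tract length (bases), the
    destabilized flag, the somatic shift in bases, the expected modal
    length, and whether the locus is spannable at the configured read
    length.
    """
    if status not in STATUSES:
        raise ValueError(f"unknown sample status {status!r}")
    chrom_order = list(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(contigs[c])} for c in chrom_order],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    chrom_idx = {c: i for i, c in enumerate(chrom_order)}
    truth: list[dict] = []
    reads: list[tuple[int, int, pysam.AlignedSegment]] = []
    hdr = pysam.AlignmentHeader.from_dict(header)

    for locus in catalog:
        ref_len = locus.end - locus.start
        unit = locus.unit_len
        destabilized = False
        shift_bases = 0
        if status == "MSI-H":
            region_ok = (
                cfg.destabilized_regions is None
                or locus.region in cfg.destabilized_regions
            )
            if region_ok and rng.random() < cfg.destabilized_fraction:
                destabilized = True
                units = int(rng.integers(cfg.shift_units[0], cfg.shift_units[1] + 1))
                sign = -1 if rng.random() < 0.5 else 1
                if sign < 0 and ref_len - units * unit < unit:
                    sign = 1  # keep at least one unit of tract
                shift_bases = sign * units * unit

        spannable = ref_len + abs(shift_bases) + 4 <= cfg.read_len
        expected_modal = (
            ref_len + shift_bases
            if destabilized and cfg.tumor_purity > 0.5
            else ref_len
        )
        truth.append(
            {
                "sample_id": sample_id,
                "locus_id": locus.locus_id,
                "region": locus.region,
                "repeat_class": locus.repeat_class,
                "ref_length": ref_len,
                "destabilized": destabilized,
                "shift_bases": shift_bases,
                "expected_modal": expected_modal,
                "spannable": spannable,
            }
        )
        if not spannable:
            logger.warning("locus %s unspannable at read length %d",
                           locus.locus_id, cfg.read_len)
            continue

        depth = int(rng.poisson(cfg.coverage_mean))
        seq_chrom = contigs[locus.chrom]
        for ri in range(depth):
            allele = ref_len
            if destabilized and rng.random() < cfg.tumor_purity:
                allele = ref_len + shift_bases
            obs = allele + _stutter_slip(rng, cfg) * unit
            obs = max(obs, unit)
            if obs + 4 > cfg.read_len:
                obs = allele  # slip would outgrow the read; fall back
            lo = max(2, cfg.read_len - obs - cfg.flank_len_ref)
            hi = min(cfg.flank_len_ref, cfg.read_len - obs - 2)
            left = int(rng.integers(lo, hi + 1))
            right = cfg.read_len - left - obs
            rstart = locus.start - left
            tract_obs = (locus.motif * (obs // unit + 2))[:obs]
            seq = (
                seq_chrom[rstart : locus.start]
                + tract_obs
                + seq_chrom[locus.end : locus.end + right]
            )
            if obs == ref_len:
                cigar = [(0, cfg.read_len)]
            elif obs > ref_len:
                cigar = [(0, left + ref_len), (1, obs - ref_len), (0, right)]
            else:
                cigar = [(0, left + obs), (2, ref_len - obs), (0, right)]
            a = pysam.AlignedSegment(hdr)
            a.query_name = f"{sample_id}_{locus.locus_id}_{ri}"
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = chrom_idx[locus.chrom]
            a.reference_start = rstart
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("RG", sample_id)
            reads.append((a.reference_id, rstart, a))

    reads.sort(key=lambda t: (t[0], t[1]))
    out_bam = Path(out_bam)
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
        for _, _, a in reads:
            bam.write(a)
    pysam.index(str(out_bam))
    return truth


def simulate_cohort(
    out_dir,
    cfg: SimulationConfig,
    n_normal: int,
    n_mss: int,
    n_msih: int,
):
    """Generate reference + a full cohort; returns a :class:`CohortSim`.

    Per-sample random generators are derived from the master seed, so the
    same configuration reproduces the cohort byte-for-byte.  Destabilized
    locus sets are drawn independently per MSI-H sample.
    """
    out_dir = Path(out_dir)
    fasta_path, catalog, contigs = generate_reference(cfg, out_dir)
    samples = []
    truth_rows: list[dict] = []
    plan = (
        [("normal", f"N{i + 1:03d}") for i in range(n_normal)]
        + [("MSS", f"MSS{i + 1:03d}") for i in range(n_mss)]
        + [("MSI-H", f"MSIH{i + 1:03d}") for i in range(n_msih)]
    )
    for idx, (status, sample_id) in enumerate(plan):
        rng = np.random.default_rng([cfg.seed, 1000 + idx])
        bam = out_dir / f"{sample_id}.bam"
        truth_rows.extend(
            simulate_sample(contigs, catalog, cfg, status, bam, rng, sample_id)
        )
        samples.append({"sample_id": sample_id, "status": status, "bam": str(bam)})

    sheet = pd.DataFrame(samples, columns=["sample_id", "status", "bam"])
    truth = pd.DataFrame(truth_rows)
    sheet_path = out_dir / "samples.tsv"
    truth_path = out_dir / "truth.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    truth.to_csv(truth_path, sep="\t", index=False)
    return CohortSim(
        genome_path=fasta_path,
        catalog=catalog,
        contigs=contigs,
        sheet=sheet,
        truth=truth,
        sheet_path=sheet_path,
        truth_path=truth_path,
    )


@dataclass
class CohortSim:
    genome_path: Path
    catalog: list[MicrosatelliteLocus]
    contigs: dict[str, str]
    sheet: pd.DataFrame
    truth: pd.DataFrame
    sheet_path: Path
    truth_path: Path
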