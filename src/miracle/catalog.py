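"""Microsatellite locus catalog: loading, validation, filtering, writing.

A catalog is a BED-derived table of short tandem repeat tracts, one row per
locus, using 0-based half-open coordinates throughout.  The dialect is
BED4+2: ``chrom  start  end  motif  region  gene`` (tab-separated, optional
``#``-prefixed header lines).  Region labels classify the locus by genic
context (CDS, 5'UTR, 3'UTR, or OTHER); repeat class (mono/di/tri/tetra)
follows from the motif length.

When a reference genome is supplied at load time each locus is validated
against the reference sequence: the tract must be a whole or partial tandem
of the motif, and the 2-bp flanking sequences on both sides are recorded for
later use by the read-level profiler.  Loci whose reference tract is not a
perfect tandem are kept but flagged; motifs annotated on the minus strand
are normalized to the forward strand with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

REGIONS = ("CDS", "UTR5", "UTR3", "OTHER")
REPEAT_CLASSES = ("mono", "di", "tri", "tetra")

_CLASS_BY_LEN = {1: "mono", 2: "di", 3: "tri", 4: "tetra"}
_REGION_ALIASES = {
    "CDS": "CDS",
    "CODING": "CDS",
    "UTR5": "UTR5",
    "5UTR": "UTR5",
    "5'UTR": "UTR5",
    "UTR3": "UTR3",
    "3UTR": "UTR3",
    "3'UTR": "UTR3",
    "OTHER": "OTHER",
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


class CatalogError(ValueError):
    """Raised for malformed catalog input or invalid locus definitions."""


def classify_motif(motif: str) -> str:
    """Return the repeat class (mono/di/tri/tetra) for a motif.

    Raises :class:`CatalogError` if the motif is empty, longer than four
    bases, or contains characters outside {A, C, G, T}.
    """
    motif = motif.upper()
    if not motif or len(motif) > 4:
        raise CatalogError(f"motif must have length 1-4, got {motif!r}")
    if not set(motif) <= _ALPHABET:
        raise CatalogError(f"motif {motif!r} contains non-ACGT characters")
    return _CLASS_BY_LEN[len(motif)]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _tandem(motif: str, n_bases: int) -> str:
    """Motif repeated cyclically and truncated to ``n_bases`` bases."""
    reps = n_bases // len(motif) + 1
    return (motif * reps)[:n_bases]


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """One catalog entry: a tandem-repeat tract on the forward strand.

    ``flank5``/``flank3`` hold the reference bases immediately outside the
    tract (recorded during genome validation; ``None`` until then).
    ``perfect`` is ``None`` before validation, then ``True`` when the
    reference tract is an exact cyclic tandem of the motif.
    """

    chrom: str
    start: int
    end: int
    motif: str
    region: str
    gene: str = ""
    locus_id: str = ""
    flank5: Optional[str] = None
    flank3: Optional[str] = None
    perfect: Optional[bool] = None

    @property
    def unit_len(self) -> int:
        return len(self.motif)

    @property
    def repeat_class(self) -> str:
        return _CLASS_BY_LEN[len(self.motif)]

    @property
    def tract_len(self) -> int:
        return self.end - self.start


def make_locus_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def validate_locus(locus: MicrosatelliteLocus, min_tract_len: int = 5) -> None:
    """Check structural invariants; raise :class:`CatalogError` on failure."""
    if locus.start < 0 or locus.start >= locus.end:
        raise CatalogError(
            f"{locus.locus_id}: invalid interval [{locus.start}, {locus.end})"
        )
    if locus.tract_len < min_tract_len:
        raise CatalogError(
            f"{locus.locus_id}: tract length {locus.tract_len} below "
            f"minimum {min_tract_len}"
        )
    classify_motif(locus.motif)
    if locus.region not in REGIONS:
        raise CatalogError(f"{locus.locus_id}: unknown region {locus.region!r}")


def normalize_region(label: str) -> str:
    key = label.strip().upper().replace("_", "")
    if key not in _REGION_ALIASES:
        raise CatalogError(f"unknown region label {label!r}")
    return _REGION_ALIASES[key]


def _genome_fetch(genome, chrom: str, start: int, end: int) -> Optional[str]:
    """Fetch genome[chrom][start:end] from a dict or a pyfaidx.Fasta."""
    if chrom not in genome:
        return None
    seq = genome[chrom][start:end]
    return str(seq).upper()


DEFAULT_COLUMNS = ("chrom", "start", "end", "motif", "region", "gene")


def read_catalog(
    path,
    genome=None,
    *,
    strict: bool = True,
    min_tract_len: int = 5,
    flank_len: int = 2,
    drop_log: Optional[list] = None,
    columns: Sequence[str] = DEFAULT_COLUMNS,
) -> list[MicrosatelliteLocus]:
    """Read a BED4+2 catalog, validating each locus.

    Parameters
    ----------
    path
        Tab-separated file with columns chrom, start, end, motif, region,
        gene; lines starting with ``#`` are skipped.
    genome
        Optional reference sequence source: a ``pyfaidx.Fasta`` (or any
        chrom-keyed mapping of sequences).  When given, the reference tract
        is checked to be a tandem of the motif and the 2-bp flanks are
        recorded; loci on missing chromosomes or without full flanks are
        dropped with a warning.
    strict
        If True (default), malformed lines raise :class:`CatalogError`
        naming the line number.  If False, bad lines are dropped and
        appended to ``drop_log`` as ``(line_number, reason)``.
    columns
        Column order of the file, for catalogs in other dialects; must
        contain chrom/start/end/motif/region, optionally gene.  Extra
        column names are parsed and ignored.

    Returns
    -------
    list of validated :class:`MicrosatelliteLocus`, in file order.
    """
    if drop_log is None:
        drop_log = []
    loci: list[MicrosatelliteLocus] = []
    seen_ids: set[str] = set()

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                locus = _parse_line(line, line_no, min_tract_len, columns)
            except CatalogError as exc:
                if strict:
                    raise CatalogError(f"line {line_no}: {exc}") from exc
                logger.warning("dropping catalog line %d: %s", line_no, exc)
                drop_log.append((line_no, str(exc)))
                continue
            if locus.locus_id in seen_ids:
                raise CatalogError(
                    f"line {line_no}: duplicate locus_id {locus.locus_id!r}"
                )
            if genome is not None:
                locus = _validate_against_genome(locus, genome, flank_len)
                if locus is None:
                    drop_log.append((line_no, "genome_validation_failed"))
                    continue
            seen_ids.add(locus.locus_id)
            loci.append(locus)
    return loci


def _parse_line(
    line: str, line_no: int, min_tract_len: int,
    columns: Sequence[str] = DEFAULT_COLUMNS,
) -> MicrosatelliteLocus:
    fields = line.split("\t")
    idx = {name: i for i, name in enumerate(columns)}
    missing = {"chrom", "start", "end", "motif", "region"} - set(idx)
    if missing:
        raise CatalogError(f"column spec lacks {sorted(missing)}")
    n_required = max(i for name, i in idx.items() if name != "gene") + 1
    if len(fields) < n_required:
        raise CatalogError(
            f"expected >= {n_required} tab-separated fields, got {len(fields)}"
        )
    chrom, start_s, end_s = fields[idx["chrom"]], fields[idx["start"]], fields[idx["end"]]
    motif = fields[idx["motif"]]
    region = normalize_region(fields[idx["region"]])
    gene = fields[idx["gene"]] if "gene" in idx and len(fields) > idx["gene"] else ""
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise CatalogError(f"non-integer coordinates {start_s!r}/{end_s!r}") from exc
    locus = MicrosatelliteLocus(
        chrom=chrom,
        start=start,
        end=end,
        motif=motif.upper(),
        region=region,
        gene=gene,
        locus_id=make_locus_id(chrom, start, end),
    )
    validate_locus(locus, min_tract_len)
    return locus


def _validate_against_genome(
    locus: MicrosatelliteLocus, genome, flank_len: int
) -> Optional[MicrosatelliteLocus]:
    tract = _genome_fetch(genome, locus.chrom, locus.start, locus.end)
    if tract is None:
        logger.warning(
            "dropping %s: chromosome %s absent from genome", locus.locus_id, locus.chrom
        )
        return None
    motif = locus.motif
    perfect = tract == _tandem(motif, len(tract))
    if not perfect:
        # minus-strand annotation: the forward-strand tract is a tandem of
        # the reverse-complemented motif
        rc = reverse_complement(motif)
        if tract == _tandem(rc, len(tract)):
            logger.warning(
                "%s: motif %s normalized to forward strand (%s)",
                locus.locus_id, motif, rc,
            )
            motif, perfect = rc, True
    if locus.start < flank_len:
        logger.warning("dropping %s: no room for 5' flank", locus.locus_id)
        return None
    flank5 = _genome_fetch(genome, locus.chrom, locus.start - flank_len, locus.start)
    flank3 = _genome_fetch(genome, locus.chrom, locus.end, locus.end + flank_len)
    if flank3 is None or len(flank3) < flank_len or len(flank5) < flank_len:
        logger.warning("dropping %s: incomplete flanks", locus.locus_id)
        return None
    return replace(
        locus, motif=motif, flank5=flank5, flank3=flank3, perfect=perfect
    )


def write_catalog(loci: Iterable[MicrosatelliteLocus], path) -> None:
    """Write loci in the same BED4+2 dialect read_catalog consumes."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tmotif\tregion\tgene\n")
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.motif}\t"
                f"{loc.region}\t{loc.gene}\n"
            )


def write_drop_log(drops: Sequence[tuple[int, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("line\treason\n")
        for line_no, reason in drops:
            fh.write(f"{line_no}\t{reason}\n")


def filter_catalog(
    loci: Sequence[MicrosatelliteLocus],
    regions: Optional[Iterable[str]] = None,
    classes: Optional[Iterable[str]] = None,
    ids: Optional[Iterable[str]] = None,
    exclude_imperfect: bool = False,
) -> list[MicrosatelliteLocus]:
    """Intersection of region / repeat-class / id filters, preserving order.

    Unknown region or class labels raise :class:`CatalogError`; an empty
    result is allowed.  ``exclude_imperfect`` drops loci flagged during
    genome validation as not being exact tandem repeats.
    """
    if regions is not None:
        regions = {normalize_region(r) for r in regions}
    if classes is not None:
        classes = set(classes)
        unknown = classes - set(REPEAT_CLASSES)
        if unknown:
            raise CatalogError(f"unknown repeat class labels: {sorted(unknown)}")
    if ids is not None:
        ids = set(ids)
    out = []
    for loc in loci:
        if regions is not None and loc.region not in regions:
            continue
        if classes is not None and loc.repeat_class not in classes:
            continue
        if ids is not None and loc.locus_id not in ids:
            continue
        if exclude_imperfect and loc.perfect is False:
            continue
        out.append(loc)
    return out


def strata_counts(loci: Sequence[MicrosatelliteLocus]) -> dict:
    """Counts of loci by (region, repeat_class) stratum."""
    counts: dict = {}
    for loc in loci:
        key = (loc.region, loc.repeat_class)
        counts[key] = counts.get(key, 0) + 1
    return counts
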