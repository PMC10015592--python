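"""Reading, writing and validation of the standard formats the pipeline touches.

Formats
-------
* Rearrangement tables in the AIRR Rearrangement TSV dialect (tab-separated,
  header row, ``.`` for IMGT alignment gaps, empty string for missing values).
  One row is one annotated Ig heavy-chain sequence carrying its sorted-cell
  population label (GC, MBC1, MBC2, MBC3 by default, extensible) and isotype
  (IgM/IgG).
* Germline V/D/J segments as FASTA plus a region map TSV giving the IMGT
  framework/CDR boundaries of each V segment (0-based, half-open).

Conventions fixed here, once, for the whole package:

* ``junction`` includes the conserved flanking residues (IMGT junction:
  C104 ... W118); the H-CDR3 proper is ``junction_aa`` minus its first and
  last residue. All clonotyping operates on ``junction_aa`` as printed.
* Alignment coordinates stored with each record follow AIRR conventions:
  ``v_germline_end`` is the number of V-reference nucleotides retained after
  3' trimming, ``j_germline_start`` is the 1-based position in the J
  reference where the aligned J begins, and ``cdr3_start``/``cdr3_end`` are
  1-based inclusive positions of the CDR3 in the (ungapped-coordinate)
  alignment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, SchemaError

logger = logging.getLogger(__name__)

GAP = "."
MASK = "N"
NUCLEOTIDES = frozenset("ACGT")

#: Canonical sorted-population and isotype labels of the study design.
POPULATIONS = ("GC", "MBC1", "MBC2", "MBC3")
ISOTYPES = ("IgM", "IgG")

#: V-segment regions in IMGT order (CDR3 is part of the junction, not listed).
REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

#: Mandatory AIRR columns for this pipeline.
REQUIRED_COLUMNS = (
    "sequence_id",
    "population",
    "isotype",
    "v_call",
    "j_call",
    "sequence_alignment",
    "junction",
    "junction_aa",
)

#: Optional columns with their fill value for missing entries.
OPTIONAL_COLUMNS = {
    "germline_alignment": "",
    "duplicate_count": 1,
    "cdr3_start": pd.NA,
    "cdr3_end": pd.NA,
    "v_germline_end": pd.NA,
    "j_germline_start": pd.NA,
    "clone_id": "",
}

_INT_COLUMNS = ("duplicate_count", "cdr3_start", "cdr3_end", "v_germline_end", "j_germline_start")

#: Fixed on-disk column order (documented contract of write_airr).
COLUMN_ORDER = tuple(REQUIRED_COLUMNS) + tuple(OPTIONAL_COLUMNS)


# ---------------------------------------------------------------------------
# Germline segments
# ---------------------------------------------------------------------------

_SEGMENT_NAME = re.compile(r"^IGH(?P<kind>[VDJ])(?P<family>\d+)\D")


@dataclass
class GermlineSegment:
    """A germline V, D or J reference segment.

    ``region_map`` maps FR1/CDR1/FR2/CDR2/FR3 to (start, end) half-open,
    0-based intervals in the segment sequence; V segments only, and the
    regions must tile the whole sequence in IMGT order.
    """

    name: str
    family: str
    kind: str
    sequence: str
    region_map: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("V", "D", "J"):
            raise ConfigurationError(f"segment {self.name}: kind must be V/D/J, got {self.kind!r}")
        if self.kind == "V":
            self.validate_region_map()

    def validate_region_map(self) -> None:
        """Check contiguity, order and span of the FR/CDR boundaries."""
        if set(self.region_map) != set(REGIONS):
            raise ConfigurationError(
                f"segment {self.name}: region map must define exactly {REGIONS}"
            )
        cursor = 0
        for region in REGIONS:
            start, end = self.region_map[region]
            if start != cursor or end <= start:
                raise ConfigurationError(
                    f"segment {self.name}: region {region} [{start},{end}) breaks "
                    f"contiguity at position {cursor}"
                )
            cursor = end
        if cursor != len(self.sequence):
            raise ConfigurationError(
                f"segment {self.name}: regions span {cursor} nt but sequence is "
                f"{len(self.sequence)} nt"
            )

    @property
    def gene(self) -> str:
        """Gene-level name with the allele suffix stripped (IGHV1-2*01 -> IGHV1-2)."""
        return strip_allele(self.name)


def strip_allele(call: str) -> str:
    """Reduce a segment call to gene level by dropping the ``*NN`` allele suffix."""
    return call.split("*", 1)[0]


def family_of(call: str) -> str:
    """V-family label parsed from an IMGT-style segment name.

    Header grammar: names start ``IGH<kind><family-number>`` followed by a
    non-digit, e.g. ``IGHV14-3*01`` -> ``VH14``.
    """
    m = _SEGMENT_NAME.match(call)
    if not m:
        raise ConfigurationError(f"cannot parse segment name {call!r}")
    return f"{m.group('kind')}H{m.group('family')}"


def read_germlines(fasta_path, region_map_path) -> dict[str, GermlineSegment]:
    """Load germline segments from FASTA plus a V region-map TSV.

    The region map has columns ``segment``, ``region``, ``start``, ``end``
    (0-based half-open). Every V segment in the FASTA must have a complete
    region-map entry; D and J segments need none.
    """
    regions = pd.read_csv(region_map_path, sep="\t")
    missing = {"segment", "region", "start", "end"} - set(regions.columns)
    if missing:
        raise SchemaError(f"region map missing columns: {sorted(missing)}")
    by_segment: dict[str, dict[str, tuple[int, int]]] = {}
    for row in regions.itertuples(index=False):
        by_segment.setdefault(row.segment, {})[row.region] = (int(row.start), int(row.end))

    segments: dict[str, GermlineSegment] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        name = rec.id
        fam = family_of(name)
        kind = fam[0]
        region_map = by_segment.get(name, {})
        if kind == "V" and not region_map:
            raise ConfigurationError(f"V segment {name} has no region-map entry")
        segments[name] = GermlineSegment(
            name=name, family=fam, kind=kind, sequence=str(rec.seq).upper(),
            region_map=region_map,
        )
    return segments


def write_germlines(segments, fasta_path, region_map_path) -> None:
    """Write segments as FASTA + region-map TSV (inverse of :func:`read_germlines`)."""
    ordered = sorted(segments.values() if isinstance(segments, dict) else segments,
                     key=lambda s: (s.kind, s.name))
    records = [SeqRecord(Seq(s.sequence), id=s.name, description="") for s in ordered]
    with open(fasta_path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")
    rows = [
        {"segment": s.name, "region": region, "start": start, "end": end}
        for s in ordered
        for region, (start, end) in sorted(s.region_map.items(), key=lambda kv: kv[1])
    ]
    pd.DataFrame(rows, columns=["segment", "region", "start", "end"]).to_csv(
        region_map_path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Rearrangement tables
# ---------------------------------------------------------------------------

def translate_nt(nt: str) -> str:
    """Translate a nucleotide string (len % 3 == 0); ambiguous codons give 'X'."""
    return str(Seq(nt).translate())


def _row_problem(row) -> str | None:
    """Return a human-readable invariant violation for a record, or None."""
    if not row["sequence_id"]:
        return "empty sequence_id"
    seq = row["sequence_alignment"]
    if not seq:
        return "empty sequence_alignment"
    germ = row.get("germline_alignment", "")
    if germ and len(germ) != len(seq):
        return (
            f"germline_alignment length {len(germ)} != sequence_alignment length {len(seq)}"
        )
    junction = row["junction"]
    junction_aa = row["junction_aa"]
    if junction_aa:
        if len(junction) % 3 != 0:
            return f"junction length {len(junction)} not a multiple of 3"
        translated = translate_nt(junction)
        if translated != junction_aa:
            return f"junction translates to {translated!r}, not {junction_aa!r}"
    return None


def validate_rearrangements(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Apply the Rearrangement invariants row-wise.

    Returns the valid subset and a list of ``(row_number, reason)`` for
    excluded rows (row numbers are 0-based positions in the input frame).
    """
    problems: list[tuple[int, str]] = []
    keep = []
    for pos, (_, row) in enumerate(df.iterrows()):
        problem = _row_problem(row)
        if problem is None:
            keep.append(pos)
        else:
            problems.append((pos, problem))
    good = df.iloc[keep].reset_index(drop=True)
    for pos, reason in problems:
        logger.warning("row %d excluded: %s", pos, reason)
    logger.info("validated rearrangements: %d kept, %d dropped", len(good), len(problems))
    return good, problems


def read_airr(path) -> pd.DataFrame:
    """Read and validate an AIRR Rearrangement TSV.

    Rows failing record invariants are excluded (and logged with their row
    numbers); a missing mandatory column raises :class:`SchemaError`.
    ``sample`` is accepted as an alias for the ``population`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "population" not in df.columns and "sample" in df.columns:
        df = df.rename(columns={"sample": "population"})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory columns: {sorted(missing)}")
    for col, default in OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = default
    for col in _INT_COLUMNS:
        df[col] = pd.to_numeric(df[col].replace("", pd.NA), errors="coerce").astype("Int64")
    df["duplicate_count"] = df["duplicate_count"].fillna(1)
    good, _ = validate_rearrangements(df)
    return good


def write_airr(records: pd.DataFrame, path) -> None:
    """Write records as AIRR TSV: fixed column order, sorted by sequence_id, '\\n' EOL."""
    df = records.copy()
    for col, default in OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = default
    df = df[list(COLUMN_ORDER)].sort_values("sequence_id", kind="mergesort")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="")
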