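"""Somatic-hypermutation quantification against reconstructed germlines.

For each sequence the germline is rebuilt from its V/J calls with the
junction N/D segment masked ('N', unknowable from the germline), mutations
are enumerated position-wise over the V region (FR1-FR3), classified as
replacement (R) or silent (S) in germline codon context, and aggregated per
population x isotype: mean frequency (mutations per 100 informative V nt),
binned mutation-count distributions, and per-region R/S frequencies.

Conventions
-----------
* The frequency denominator is the informative aligned V length: positions
  in FR1-FR3 where both sequence and germline are plain A/C/G/T (gaps and
  masked positions excluded). J-region mutations are not counted.
* R/S is evaluated one mutation at a time against the germline codon; a
  codon containing a gap or masked base gives class ``indeterminate``
  (counted in the total, excluded from R/S tallies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, GermlineReferenceError, SchemaError
from .io import GermlineSegment, MASK, NUCLEOTIDES, REGIONS, translate_nt

#: Default mutation-count histogram bins (inclusive ranges; None = open end).
DEFAULT_BINS = ((0, 0), (1, 5), (6, 10), (11, 15), (16, None))


def bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">{lo - 1}"
    return str(lo) if lo == hi else f"{lo}-{hi}"


@dataclass
class Mutation:
    position: int          # 0-based index in the gapped alignment
    region: str            # FR1/CDR1/FR2/CDR2/FR3
    from_base: str
    to_base: str
    rs_class: str          # "R", "S" or "indeterminate"


@dataclass
class MutationProfile:
    sequence_id: str
    n_mutations: int
    informative_length: int
    frequency: float       # mutations per 100 informative positions
    region_counts: dict    # region -> {"R": int, "S": int, "indeterminate": int}
    region_lengths: dict   # region -> informative positions compared


# ---------------------------------------------------------------------------
# Germline reconstruction
# ---------------------------------------------------------------------------

def reconstruct_germline(record, germlines: dict[str, GermlineSegment]) -> str:
    """Rebuild the germline alignment for one rearrangement.

    Layout: the V reference over the V-encoded prefix (``v_germline_end``
    nt), 'N' over the junction N/D segment, and the J reference (from
    ``j_germline_start``) over the J-encoded suffix. Same length as the
    sequence alignment. ``record`` is any mapping with the AIRR fields.
    """
    v_call, j_call = record["v_call"], record["j_call"]
    if v_call not in germlines:
        raise GermlineReferenceError(f"unknown V segment {v_call!r}")
    if j_call not in germlines:
        raise GermlineReferenceError(f"unknown J segment {j_call!r}")
    length = len(record["sequence_alignment"])
    for key in ("v_germline_end", "j_germline_start"):
        if pd.isna(record.get(key)):
            raise SchemaError(f"germline reconstruction needs {key}")
    vge = int(record["v_germline_end"])
    jgs = int(record["j_germline_start"])
    j_ref = germlines[j_call].sequence[jgs - 1:]
    j_start = length - len(j_ref)
    if vge > j_start or j_start < 0:
        raise AlignmentError(
            f"{record['sequence_id']}: V end {vge} and J start {j_start} overlap"
        )
    germline = germlines[v_call].sequence[:vge] + MASK * (j_start - vge) + j_ref
    if len(germline) != length:
        raise AlignmentError(
            f"{record['sequence_id']}: reconstructed germline length "
            f"{len(germline)} != alignment length {length}"
        )
    return germline


def fill_germlines(records: pd.DataFrame, germlines) -> pd.DataFrame:
    """Return a copy with empty ``germline_alignment`` fields reconstructed."""
    out = records.copy()
    todo = out["germline_alignment"].eq("") | out["germline_alignment"].isna()
    out.loc[todo, "germline_alignment"] = out.loc[todo].apply(
        lambda row: reconstruct_germline(row, germlines), axis=1
    )
    return out


# ---------------------------------------------------------------------------
# Mutation enumeration and R/S classification
# ---------------------------------------------------------------------------

def classify_rs(position: int, to_base: str, germline_alignment: str,
                reading_frame: int = 0) -> str:
    """Replacement/silent call for a single substitution in germline context.

    The mutated base is substituted into the germline codon containing
    ``position``; a changed amino acid is "R", an unchanged one "S". Codons
    containing a gap, mask or alignment edge are "indeterminate".
    """
    offset = (position - reading_frame) % 3
    start = position - offset
    if start < 0 or start + 3 > len(germline_alignment):
        return "indeterminate"
    codon = germline_alignment[start:start + 3]
    if any(b not in NUCLEOTIDES for b in codon):
        return "indeterminate"
    mutated = codon[:offset] + to_base + codon[offset + 1:]
    return "S" if translate_nt(mutated) == translate_nt(codon) else "R"


def enumerate_mutations(sequence_alignment: str, germline_alignment: str,
                        region_map: dict, reading_frame: int = 0,
                        ) -> tuple[list[Mutation], dict[str, int]]:
    """List substitutions over the mapped V regions.

    Positions where either side is a gap or 'N' are skipped and excluded
    from the informative length; positions outside the region map (junction,
    J) are never visited. Returns ``(mutations, informative_length_by_region)``.
    """
    if len(sequence_alignment) != len(germline_alignment):
        raise AlignmentError(
            f"alignment lengths differ: {len(sequence_alignment)} vs "
            f"{len(germline_alignment)}"
        )
    mutations: list[Mutation] = []
    lengths: dict[str, int] = {}
    for region in REGIONS:
        if region not in region_map:
            continue
        start, end = region_map[region]
        end = min(end, len(sequence_alignment))
        informative = 0
        for pos in range(start, end):
            obs, germ = sequence_alignment[pos], germline_alignment[pos]
            if obs not in NUCLEOTIDES or germ not in NUCLEOTIDES:
                continue
            informative += 1
            if obs != germ:
                mutations.append(Mutation(
                    position=pos, region=region, from_base=germ, to_base=obs,
                    rs_class=classify_rs(pos, obs, germline_alignment, reading_frame),
                ))
        lengths[region] = informative
    return mutations, lengths


def compute_profile(record, germlines: dict[str, GermlineSegment]) -> MutationProfile:
    """Mutation profile for one record (reconstructs the germline if absent)."""
    germ = record.get("germline_alignment") or reconstruct_germline(record, germlines)
    region_map = germlines[record["v_call"]].region_map
    mutations, lengths = enumerate_mutations(record["sequence_alignment"], germ, region_map)
    informative = sum(lengths.values())
    counts = {r: {"R": 0, "S": 0, "indeterminate": 0} for r in lengths}
    for m in mutations:
        counts[m.region][m.rs_class] += 1
    n = len(mutations)
    return MutationProfile(
        sequence_id=record["sequence_id"],
        n_mutations=n,
        informative_length=informative,
        frequency=100.0 * n / informative if informative else float("nan"),
        region_counts=counts,
        region_lengths=lengths,
    )


def profiles_frame(records: pd.DataFrame, germlines) -> pd.DataFrame:
    """Per-sequence profile table: one row per record, wide R/S columns."""
    rows = []
    for _, rec in records.iterrows():
        p = compute_profile(rec, germlines)
        row = {
            "sequence_id": p.sequence_id,
            "population": rec["population"],
            "isotype": rec["isotype"],
            "n_mutations": p.n_mutations,
            "informative_length": p.informative_length,
            "frequency": p.frequency,
        }
        for region in REGIONS:
            c = p.region_counts.get(region, {})
            row[f"{region}_R"] = c.get("R", 0)
            row[f"{region}_S"] = c.get("S", 0)
            row[f"{region}_indeterminate"] = c.get("indeterminate", 0)
            row[f"{region}_len"] = p.region_lengths.get(region, 0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Aggregation and group comparison
# ---------------------------------------------------------------------------

def aggregate_profiles(profiles: pd.DataFrame,
                       group_keys: tuple[str, ...] = ("population", "isotype"),
                       bins=DEFAULT_BINS) -> pd.DataFrame:
    """Per-group summary: mean frequency, binned counts, per-region R/S rates.

    Region R/S rates are per 100 informative region nucleotides. Empty
    groups are simply absent from the output.
    """
    out = []
    for keys, grp in profiles.groupby(list(group_keys), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(group_keys, keys))
        row["n_sequences"] = len(grp)
        row["mean_frequency"] = grp["frequency"].mean()
        row["mean_n_mutations"] = grp["n_mutations"].mean()
        for lo, hi in bins:
            upper = np.inf if hi is None else hi
            frac = grp["n_mutations"].between(lo, upper).mean()
            row[f"bin_{bin_label(lo, hi)}"] = frac
        for region in REGIONS:
            region_nt = grp[f"{region}_len"].sum()
            for klass in ("R", "S"):
                total = grp[f"{region}_{klass}"].sum()
                row[f"{region}_{klass}_per100"] = (
                    100.0 * total / region_nt if region_nt else float("nan")
                )
        out.append(row)
    return pd.DataFrame(out)


def frequency_vectors(profiles: pd.DataFrame,
                      group_keys=("population", "isotype")) -> dict:
    """Per-group per-sequence frequency vectors (for the significance tests)."""
    return {
        keys if isinstance(keys, tuple) else (keys,): grp["frequency"].to_numpy()
        for keys, grp in profiles.groupby(list(group_keys), sort=True)
    }


def compare_groups(freq_a: np.ndarray, freq_b: np.ndarray) -> dict:
    """Unpaired two-sample t-test plus chi-square on mutated-vs-unmutated.

    Both vectors need n >= 2. Degenerate input (zero variance on both sides
    with equal means) reports p = 1 with a warning.
    """
    a = np.asarray(freq_a, float)
    b = np.asarray(freq_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = len(a) + len(b) - 2
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups; reporting p = 1")
            return {"t": 0.0, "df": df, "p_t": 1.0, "p_chi2": 1.0, "chi2": 0.0}
        t, p_t = np.inf if a.mean() > b.mean() else -np.inf, 0.0
    else:
        t, p_t = stats.ttest_ind(a, b, equal_var=True)
    table = np.array([
        [(a > 0).sum(), (a == 0).sum()],
        [(b > 0).sum(), (b == 0).sum()],
    ])
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        chi2, p_chi2 = 0.0, 1.0
    else:
        chi2, p_chi2, _, _ = stats.chi2_contingency(table)
    return {"t": float(t), "df": df, "p_t": float(p_t),
            "chi2": float(chi2), "p_chi2": float(p_chi2)}


def tukey_groups(vectors: dict) -> pd.DataFrame:
    """Tukey HSD across >2 groups of per-sequence frequencies."""
    labels = sorted(vectors)
    if len(labels) < 3:
        raise ValueError("Tukey HSD needs more than 2 groups")
    res = stats.tukey_hsd(*[np.asarray(vectors[k], float) for k in labels])
    rows = []
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                rows.append({
                    "group_a": a, "group_b": b,
                    "statistic": float(res.statistic[i, j]),
                    "p": float(res.pvalue[i, j]),
                })
    return pd.DataFrame(rows)
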