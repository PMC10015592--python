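"""Unique-sequence deduplication and the two clone definitions.

Two complementary clone definitions are implemented, matching standard
repertoire practice:

* **Clonotype** — exact (100%) amino-acid identity of the H-CDR3 junction
  (``junction_aa`` as printed), grouped per isotype or pooled across
  isotypes.
* **Clonal group** — records sharing V gene, J gene (allele-stripped) and
  junction length, clustered by single linkage at a normalized nucleotide
  hamming distance threshold (default 0.16, the value used with
  distance-to-nearest threshold diagnostics).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import strip_allele

logger = logging.getLogger(__name__)

DEFAULT_CLONE_THRESHOLD = 0.16

_DEDUP_KEY = ("population", "isotype", "sequence_alignment")


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse to unique sequences.

    Uniqueness key is (population, isotype, full nucleotide alignment):
    the same nucleotide sequence observed in two samples stays two records.
    ``duplicate_count`` is summed; the surviving row is the one with the
    smallest sequence_id; output is sorted by the key.
    """
    df = records.sort_values("sequence_id", kind="mergesort")
    agg = {col: "first" for col in df.columns if col not in _DEDUP_KEY}
    agg["duplicate_count"] = "sum"
    out = (
        df.groupby(list(_DEDUP_KEY), as_index=False, sort=True)
        .agg(agg)
        .reindex(columns=df.columns)
        .reset_index(drop=True)
    )
    logger.info("deduplicated %d records to %d unique sequences", len(df), len(out))
    return out


def define_cdr3_clonotypes(unique_records: pd.DataFrame, scope: str = "per_isotype",
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact H-CDR3 amino-acid clonotypes.

    ``scope`` is ``"per_isotype"`` (grouping key = isotype + junction_aa, as
    in the per-isotype sharing table) or ``"pooled"`` (junction_aa only, as
    in the all-samples heatmap). Records with an empty junction_aa are
    excluded with a warning.

    Returns ``(clonotypes, membership)``: the clonotype table has per-sample
    unique-sequence counts in wide ``n_<population>_<isotype>`` columns; the
    membership frame maps sequence_id -> clonotype_id.
    """
    if scope not in ("per_isotype", "pooled"):
        raise ValueError(f"unknown scope {scope!r}")
    df = unique_records
    empty = df["junction_aa"].eq("") | df["junction_aa"].isna()
    if empty.any():
        logger.warning("excluding %d records with empty junction_aa", int(empty.sum()))
        df = df[~empty]
    keys = ["isotype", "junction_aa"] if scope == "per_isotype" else ["junction_aa"]

    rows, members = [], []
    for i, (key, grp) in enumerate(df.groupby(keys, sort=True), start=1):
        if not isinstance(key, tuple):
            key = (key,)
        clonotype_id = f"CT{i:06d}"
        junction_aa = key[-1]
        pops = sorted(set(grp["population"]))
        isotypes = sorted(set(grp["isotype"]))
        row = {
            "clonotype_id": clonotype_id,
            "scope": scope,
            "isotype": key[0] if scope == "per_isotype" else "",
            "junction_aa": junction_aa,
            "n_members": len(grp),
            "populations": ",".join(pops),
            "n_populations": len(pops),
            "isotypes": ",".join(isotypes),
            "member_ids": ",".join(sorted(grp["sequence_id"])),
        }
        counts = grp.groupby(["population", "isotype"]).size()
        for (pop, iso), n in counts.items():
            row[f"n_{pop}_{iso}"] = int(n)
        rows.append(row)
        members.extend((sid, clonotype_id) for sid in grp["sequence_id"])
    clonotypes = pd.DataFrame(rows)
    count_cols = [c for c in clonotypes.columns
                  if c.startswith("n_") and c not in ("n_members", "n_populations")]
    clonotypes[count_cols] = clonotypes[count_cols].fillna(0).astype(int)
    membership = pd.DataFrame(members, columns=["sequence_id", "clonotype_id"])
    return clonotypes, membership


def hamming_distance_normalized(junction_a: str, junction_b: str) -> float:
    """Fraction of differing positions between equal-length junctions.

    Positions with 'N' on either side are excluded from numerator and
    denominator. Equal lengths are the caller's contract (partition by
    length first).
    """
    if len(junction_a) != len(junction_b):
        raise ValueError("junctions must have equal length")
    informative = diffs = 0
    for a, b in zip(junction_a, junction_b):
        if a == "N" or b == "N":
            continue
        informative += 1
        if a != b:
            diffs += 1
    return diffs / informative if informative else float("nan")


def _pairwise_normalized(junctions: list[str]) -> np.ndarray:
    """Vectorized all-pairs normalized hamming matrix, 'N'-aware."""
    arr = np.frombuffer("".join(junctions).encode(), dtype="S1").reshape(len(junctions), -1)
    valid = arr != b"N"
    diff = (arr[:, None, :] != arr[None, :, :]) & valid[:, None, :] & valid[None, :, :]
    denom = (valid[:, None, :] & valid[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, diff.sum(axis=2) / np.maximum(denom, 1), np.nan)


def _partitions(df: pd.DataFrame):
    """Yield the V-gene / J-gene / junction-length partitions, sorted."""
    work = df.assign(
        _v_gene=df["v_call"].map(strip_allele),
        _j_gene=df["j_call"].map(strip_allele),
        _jlen=df["junction"].str.len(),
    )
    yield from work.groupby(["_v_gene", "_j_gene", "_jlen"], sort=True)


def group_clones(unique_records: pd.DataFrame,
                 threshold: float = DEFAULT_CLONE_THRESHOLD) -> pd.DataFrame:
    """Assign clonal groups: V/J gene + junction length, single linkage at 0.16.

    Within each (v_gene, j_gene, junction_length) partition, records whose
    normalized junction hamming distance is <= threshold are linked;
    connected components are the clones (isotypes pooled). Returns a copy of
    the input with a ``clone_id`` column; labels are canonical (assigned in
    order of each clone's smallest member sequence_id), so the result is
    invariant to input order.
    """
    components: list[tuple[str, list[str]]] = []  # (min sequence_id, member ids)
    for _, part in _partitions(unique_records):
        part = part.sort_values("sequence_id", kind="mergesort")
        ids = part["sequence_id"].tolist()
        if len(ids) == 1:
            components.append((ids[0], ids))
            continue
        dist = _pairwise_normalized(part["junction"].tolist())
        adj = csr_matrix(np.nan_to_num(dist, nan=1.0) <= threshold)
        n_comp, labels = connected_components(adj, directed=False)
        for comp in range(n_comp):
            member_ids = [ids[i] for i in np.flatnonzero(labels == comp)]
            components.append((min(member_ids), member_ids))

    components.sort(key=lambda c: c[0])
    assignment = {
        sid: f"CL{i:06d}"
        for i, (_, member_ids) in enumerate(components, start=1)
        for sid in member_ids
    }
    out = unique_records.copy()
    out["clone_id"] = out["sequence_id"].map(assignment)
    return out


def distance_to_nearest(unique_records: pd.DataFrame) -> pd.DataFrame:
    """Per-record minimum normalized distance to any partition neighbour.

    Records alone in their V/J/length partition get NaN with
    ``singleton=True`` — the standard diagnostic for choosing the clonal
    threshold from the bimodal distance distribution.
    """
    rows = []
    for _, part in _partitions(unique_records):
        ids = part["sequence_id"].tolist()
        if len(ids) == 1:
            rows.append({"sequence_id": ids[0], "dist_to_nearest": np.nan,
                         "singleton": True})
            continue
        dist = _pairwise_normalized(part["junction"].tolist())
        np.fill_diagonal(dist, np.nan)
        mins = np.nanmin(dist, axis=1)
        rows.extend(
            {"sequence_id": sid, "dist_to_nearest": float(m), "singleton": False}
            for sid, m in zip(ids, mins)
        )
    return pd.DataFrame(rows).sort_values("sequence_id").reset_index(drop=True)
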