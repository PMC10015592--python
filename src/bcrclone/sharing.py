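"""Single-vs-shared clone classification and repertoire overlap statistics.

A clonotype is **shared** when its members come from at least two sorted
populations (within the isotype scope under analysis) and **single**
otherwise — expansion within one population does not make a clone shared.
This module produces the per-isotype summary table (single/shared clone and
sequence counts per population with integer percentages), pairwise
relative-overlap matrices over population x isotype samples, k-way sharing
counts, and the single-vs-shared mutation comparison.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import POPULATIONS
from .mutations import compare_groups


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero (as printed tables do)."""
    return int(math.floor(x + 0.5))


def classify_single_shared(clonotypes: pd.DataFrame) -> pd.Series:
    """Label each clonotype 'shared' (>=2 distinct populations) or 'single'."""
    return clonotypes["n_populations"].ge(2).map({True: "shared", False: "single"})


def _pop_counts(clonotypes: pd.DataFrame, populations) -> pd.DataFrame:
    """Per-clonotype per-population unique-sequence counts (all isotypes pooled)."""
    out = pd.DataFrame(index=clonotypes.index)
    for pop in populations:
        cols = [c for c in clonotypes.columns if c.startswith(f"n_{pop}_")]
        out[pop] = clonotypes[cols].sum(axis=1) if cols else 0
    return out


@dataclass
class SharingTable:
    """Per-isotype bookkeeping of single vs shared clones and sequences.

    A shared clone contributes its per-population sequence counts to every
    population it touches (so per-population shared-clone counts sum to more
    than the number of unique shared clones). Percentages are recomputed
    from the counts, rounded half-up to integers.
    """

    isotype: str
    populations: tuple = POPULATIONS
    total_clones: int = 0
    total_sequences: int = 0
    single_clones: dict = field(default_factory=dict)
    single_sequences: dict = field(default_factory=dict)
    shared_clones: dict = field(default_factory=dict)
    shared_sequences: dict = field(default_factory=dict)
    kway_sequences: dict = field(default_factory=dict)  # populations spanning all k

    # -- derived percentages -------------------------------------------------
    @property
    def n_single_clones(self) -> int:
        return sum(self.single_clones.values())

    @property
    def n_unique_shared_clones(self) -> int:
        return self.total_clones - self.n_single_clones

    @property
    def n_single_sequences(self) -> int:
        return sum(self.single_sequences.values())

    @property
    def n_shared_sequences(self) -> int:
        return sum(self.shared_sequences.values())

    @property
    def n_kway_sequences(self) -> int:
        return sum(self.kway_sequences.values())

    def single_clone_pct(self) -> int:
        return round_half_up(100.0 * self.n_single_clones / self.total_clones)

    def shared_clone_pct(self) -> int:
        return round_half_up(100.0 * self.n_unique_shared_clones / self.total_clones)

    def single_sequence_pct(self) -> int:
        return round_half_up(100.0 * self.n_single_sequences / self.total_sequences)

    def shared_sequence_pct(self) -> int:
        return round_half_up(100.0 * self.n_shared_sequences / self.total_sequences)

    def kway_sequence_pct(self) -> int:
        return round_half_up(100.0 * self.n_kway_sequences / self.total_sequences)

    def validate(self) -> int:
        """Sequence-conservation residual: single + shared - total (0 when exact)."""
        return self.n_single_sequences + self.n_shared_sequences - self.total_sequences

    @classmethod
    def from_counts(cls, isotype, total_clones, total_sequences, single_clones,
                    single_sequences, shared_clones, shared_sequences,
                    kway_sequences=None, populations=POPULATIONS) -> "SharingTable":
        """Build from externally tabulated counts (worked-example arithmetic)."""
        return cls(
            isotype=isotype, populations=tuple(populations),
            total_clones=int(total_clones), total_sequences=int(total_sequences),
            single_clones=dict(single_clones), single_sequences=dict(single_sequences),
            shared_clones=dict(shared_clones), shared_sequences=dict(shared_sequences),
            kway_sequences=dict(kway_sequences or {}),
        )


def build_sharing_table(clonotypes: pd.DataFrame, isotype: str,
                        populations=POPULATIONS) -> SharingTable:
    """Tabulate single/shared clone and sequence counts for one isotype.

    ``clonotypes`` must come from the per-isotype clonotype scope; rows of
    other isotypes are ignored. Conservation (single + shared = total
    sequences) holds exactly by construction.
    """
    sub = clonotypes[clonotypes["isotype"] == isotype]
    labels = classify_single_shared(sub)
    counts = _pop_counts(sub, populations)
    single = labels.eq("single")
    shared = labels.eq("shared")
    touches = counts.gt(0)

    n_pops = len(populations)
    kway = shared & touches.sum(axis=1).eq(n_pops)
    table = SharingTable(
        isotype=isotype, populations=tuple(populations),
        total_clones=len(sub),
        total_sequences=int(counts.to_numpy().sum()),
        single_clones={p: int((single & touches[p]).sum()) for p in populations},
        single_sequences={p: int(counts.loc[single, p].sum()) for p in populations},
        shared_clones={p: int((shared & touches[p]).sum()) for p in populations},
        shared_sequences={p: int(counts.loc[shared, p].sum()) for p in populations},
        kway_sequences={p: int(counts.loc[kway, p].sum()) for p in populations},
    )
    return table


def sharing_table_frame(table: SharingTable) -> pd.DataFrame:
    """Render a SharingTable in the printed-summary layout (rows x populations)."""
    pops = list(table.populations)
    rows = [
        {"block": f"All {table.isotype}", "measure": "clones",
         **{p: "" for p in pops}, "total_or_pct": table.total_clones},
        {"block": f"All {table.isotype}", "measure": "sequences",
         **{p: "" for p in pops}, "total_or_pct": table.total_sequences},
        {"block": f"Single {table.isotype}", "measure": "clones",
         **table.single_clones, "total_or_pct": table.single_clone_pct()},
        {"block": f"Single {table.isotype}", "measure": "sequences",
         **table.single_sequences, "total_or_pct": table.single_sequence_pct()},
        {"block": f"Shared {table.isotype}", "measure": "clones",
         **table.shared_clones, "total_or_pct": table.shared_clone_pct()},
        {"block": f"Shared {table.isotype}", "measure": "sequences",
         **table.shared_sequences, "total_or_pct": table.shared_sequence_pct()},
    ]
    if table.kway_sequences:
        rows.append({
            "block": f"Shared {table.isotype} (all populations)",
            "measure": "sequences", **table.kway_sequences,
            "total_or_pct": f"{table.n_kway_sequences}/{table.kway_sequence_pct()}",
        })
    return pd.DataFrame(rows, columns=["block", "measure", *pops, "total_or_pct"])


# ---------------------------------------------------------------------------
# Overlap matrix (heatmap machinery)
# ---------------------------------------------------------------------------

def relative_overlap(sample_a_junctions, sample_b_junctions) -> float:
    """Overlapping H-CDR3 amino-acid variants over the total unique variants
    of the pairwise comparison: |A ∩ B| / |A ∪ B|. NaN when both empty."""
    a, b = set(sample_a_junctions), set(sample_b_junctions)
    union = a | b
    if not union:
        return float("nan")
    return len(a & b) / len(union)


def overlap_matrix(samples: dict) -> pd.DataFrame:
    """All pairwise relative overlaps over population x isotype samples.

    ``samples`` maps label -> set of unique junction_aa strings. Symmetric;
    diagonal 1 for non-empty samples, NaN rows/columns flag empty samples.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    labels = list(samples)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            val = relative_overlap(samples[a], samples[b])
            mat.loc[a, b] = mat.loc[b, a] = val
    return mat


def junction_sets(unique_records: pd.DataFrame,
                  by=("population", "isotype")) -> dict:
    """Unique junction_aa sets per sample, keyed '<population>_<isotype>'."""
    return {
        "_".join(keys if isinstance(keys, tuple) else (keys,)):
            set(grp["junction_aa"]) - {""}
        for keys, grp in unique_records.groupby(list(by), sort=True)
    }


# ---------------------------------------------------------------------------
# k-way sharing (3- and 4-population clone counts)
# ---------------------------------------------------------------------------

def kway_sharing(clonotypes: pd.DataFrame, k: int,
                 populations=POPULATIONS) -> pd.DataFrame:
    """Clone and sequence counts per combination of exactly k populations.

    For each k-subset of populations: the number of clonotypes whose
    population membership equals that combination exactly (plus an
    ``at_least_k`` column counting superset memberships) and the summed
    unique-sequence counts of the exact matches.
    """
    if k < 2 or k > len(populations):
        raise ValueError(f"k must be in [2, {len(populations)}]")
    counts = _pop_counts(clonotypes, populations)
    member_sets = counts.gt(0)
    rows = []
    for combo in itertools.combinations(populations, k):
        in_combo = member_sets[list(combo)].all(axis=1)
        outside = member_sets[[p for p in populations if p not in combo]].any(axis=1)
        exact = in_combo & ~outside
        rows.append({
            "populations": "+".join(combo),
            "k": k,
            "clone_count": int(exact.sum()),
            "sequence_count": int(counts.loc[exact].to_numpy().sum()),
            "clone_count_at_least": int(in_combo.sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shared-vs-single SHM comparison
# ---------------------------------------------------------------------------

def shared_vs_single_shm(profiles: pd.DataFrame, membership: pd.DataFrame,
                         clonotypes: pd.DataFrame, alpha: float = 0.05,
                         ) -> pd.DataFrame:
    """Mutation frequency of sequences in single vs shared clonotypes.

    Per population x isotype group: n and mean frequency on each side and
    the unpaired t-test between them; a group with an empty side is reported
    with the comparison skipped (NaN p).
    """
    labels = clonotypes.set_index("clonotype_id")["n_populations"].ge(2)
    seq_shared = membership.set_index("sequence_id")["clonotype_id"].map(labels)
    work = profiles.join(seq_shared.rename("is_shared"), on="sequence_id")
    work = work[work["is_shared"].notna()]

    rows = []
    for (pop, iso), grp in work.groupby(["population", "isotype"], sort=True):
        single = grp.loc[~grp["is_shared"].astype(bool), "frequency"].to_numpy()
        shared = grp.loc[grp["is_shared"].astype(bool), "frequency"].to_numpy()
        row = {
            "population": pop, "isotype": iso,
            "n_single": len(single), "n_shared": len(shared),
            "mean_single": float(np.mean(single)) if len(single) else np.nan,
            "mean_shared": float(np.mean(shared)) if len(shared) else np.nan,
            "t": np.nan, "p_t": np.nan, "significant": False, "skipped": False,
        }
        if len(single) >= 2 and len(shared) >= 2:
            res = compare_groups(shared, single)
            row.update(t=res["t"], p_t=res["p_t"],
                       significant=bool(res["p_t"] < alpha))
        else:
            row["skipped"] = True
        rows.append(row)
    return pd.DataFrame(rows)
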